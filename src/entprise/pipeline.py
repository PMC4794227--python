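"""Per-protein feature context and bulk featurization.

A ProteinContext bundles everything needed to featurize substitutions on one
protein: the query sequence, its entropy track (from a filtered homolog
alignment), a C-alpha structure model, and the domain segment table.  Variants
on proteins without a structure model, or at positions the model does not
cover, receive the zero contact sentinel and are dropped by default
(configurable), mirroring a predictor that only returns results for
structurally covered variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from .feature_encoding import FeatureConfig, assemble
from .io_formats import VariantRecord
from .profile_entropy import (
    AlignmentSet,
    EntropyTrack,
    build_profile,
    filter_by_identity,
    relative_entropy,
)
from .structure_features import (
    DomainSegment,
    StructureModel,
    contact_composition,
    domain_composition,
    segment_of,
)


@dataclass
class ProteinContext:
    protein_id: str
    sequence: str
    entropy: Optional[EntropyTrack] = None
    structure: Optional[StructureModel] = None
    segments: list[DomainSegment] = field(default_factory=list)

    @classmethod
    def from_alignment(
        cls,
        aln: AlignmentSet,
        structure: Optional[StructureModel] = None,
        segments: Optional[list[DomainSegment]] = None,
        min_id: float = 0.35,
        max_id: float = 0.90,
    ) -> "ProteinContext":
        """Filter homologs to the 35-90 window, build the profile and entropy."""
        filtered = filter_by_identity(aln, min_id=min_id, max_id=max_id)
        track = relative_entropy(build_profile(filtered))
        return cls(
            protein_id=aln.query_id,
            sequence=aln.rows[0],
            entropy=track,
            structure=structure,
            segments=list(segments or []),
        )

    def covers(self, position: int, config: FeatureConfig) -> bool:
        """Whether every enabled positional feature is computable here."""
        if not 1 <= position <= len(self.sequence):
            return False
        if config.use_entropy and (
            self.entropy is None or position > self.entropy.length
        ):
            return False
        if config.use_contact and (
            self.structure is None or not self.structure.has_position(position)
        ):
            return False
        return True

    def features_for(self, variant: VariantRecord, config: FeatureConfig) -> np.ndarray:
        """Feature vector for one substitution, with reference checking."""
        pos = variant.position
        if not 1 <= pos <= len(self.sequence):
            raise ValueError(
                f"position {pos} outside {self.protein_id} (length {len(self.sequence)})"
            )
        domain = None
        if config.use_domain:
            seg = segment_of(pos, self.segments, len(self.sequence), self.protein_id)
            domain = domain_composition(self.sequence, seg)
        contact = None
        if config.use_contact:
            if self.structure is None or not self.structure.has_position(pos):
                contact = np.zeros(20)
            else:
                contact = contact_composition(self.structure, pos, config.contact_cutoff)
        return assemble(
            variant,
            self.entropy,
            domain,
            contact,
            config,
            reference_aa=self.sequence[pos - 1],
        ).values


def featurize_variants(
    variants: Iterable[VariantRecord],
    contexts: dict[str, ProteinContext],
    config: FeatureConfig,
    on_missing: str = "drop",
) -> tuple[np.ndarray, list[VariantRecord], list[VariantRecord]]:
    """Build the design matrix for a variant table.

    Returns (X, kept, dropped).  `on_missing` controls variants whose protein
    lacks a context or whose position is not structurally/profile covered:
    "drop" (default) excludes them, "zero" scores them with zero-sentinel
    positional features where possible, "error" raises.
    """
    if on_missing not in ("drop", "zero", "error"):
        raise ValueError(f"on_missing must be drop|zero|error, got {on_missing!r}")
    rows: list[np.ndarray] = []
    kept: list[VariantRecord] = []
    dropped: list[VariantRecord] = []
    for v in variants:
        ctx = contexts.get(v.protein_id)
        pos = v.position
        # "zero" can only stand in for a missing structural block; a variant
        # without a context, sequence coverage or entropy coverage is always
        # unscoreable.
        hard_missing = (
            ctx is None
            or pos > len(ctx.sequence)
            or (
                config.use_entropy
                and (ctx.entropy is None or pos > ctx.entropy.length)
            )
        )
        struct_missing = not hard_missing and config.use_contact and (
            ctx.structure is None or not ctx.structure.has_position(pos)
        )
        if hard_missing or struct_missing:
            if on_missing == "error":
                raise ValueError(f"no feature context for {v.protein_id}:{pos}")
            if hard_missing or on_missing == "drop":
                dropped.append(v)
                continue
            # on_missing == "zero": fall through with the zero contact sentinel
        rows.append(ctx.features_for(v, config))
        kept.append(v)
    X = np.vstack(rows) if rows else np.empty((0, config.n_features))
    return X, kept, dropped
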