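"""Assembly of the 81-variable feature vector and its ablation layouts.

Full layout, in this fixed block order:

    [ RS (1) | wild one-hot (20) | mutant one-hot (20)
      | domain composition (20) | contacting composition (20) ]

Named ablation presets switch whole blocks off (or change the contact
cutoff); a disabled block is omitted, so vector length is
1*entropy + 40*types + 20*domain + 20*contact.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .alphabet import N_AA, aa_index
from .io_formats import VariantRecord
from .profile_entropy import EntropyTrack


@dataclass(frozen=True)
class FeatureConfig:
    name: str = "ENTPRISE"
    use_types: bool = True
    use_domain: bool = True
    use_contact: bool = True
    use_entropy: bool = True
    contact_cutoff: float = 12.0

    def __post_init__(self) -> None:
        if not (self.use_types or self.use_domain or self.use_contact or self.use_entropy):
            raise ValueError("at least one feature block must be enabled")

    @property
    def n_features(self) -> int:
        return (
            int(self.use_entropy)
            + 2 * N_AA * int(self.use_types)
            + N_AA * int(self.use_domain)
            + N_AA * int(self.use_contact)
        )


PRESETS: dict[str, FeatureConfig] = {
    "ENTPRISE": FeatureConfig("ENTPRISE"),
    "ENTPRISE_CUT8": FeatureConfig("ENTPRISE_CUT8", contact_cutoff=8.0),
    "ENTPRISE_NOTYP": FeatureConfig("ENTPRISE_NOTYP", use_types=False),
    "ENTPRISE_NODOM": FeatureConfig("ENTPRISE_NODOM", use_domain=False),
    "ENTPRISE_NOCNT": FeatureConfig("ENTPRISE_NOCNT", use_contact=False),
    "ENTPRISE_NOENT": FeatureConfig("ENTPRISE_NOENT", use_entropy=False),
    "ENTPRISE_ONLYDOM": FeatureConfig(
        "ENTPRISE_ONLYDOM", use_types=False, use_contact=False, use_entropy=False
    ),
}


def get_config(name: str) -> FeatureConfig:
    """Look up a preset by its full name or short suffix (e.g. 'noent')."""
    key = name.upper()
    if key in PRESETS:
        return PRESETS[key]
    key = f"ENTPRISE_{key}"
    if key in PRESETS:
        return PRESETS[key]
    raise KeyError(f"unknown feature configuration {name!r}; "
                   f"choose from {sorted(PRESETS)}")


@dataclass
class FeatureVector:
    values: np.ndarray
    variant: VariantRecord
    config: str


def one_hot_aa(aa: str) -> np.ndarray:
    """20-vector with a single 1 at the letter's alphabetical index."""
    vec = np.zeros(N_AA)
    vec[aa_index(aa)] = 1.0
    return vec


def assemble(
    variant: VariantRecord,
    entropy: Optional[EntropyTrack],
    domain: Optional[np.ndarray],
    contact: Optional[np.ndarray],
    config: FeatureConfig,
    reference_aa: Optional[str] = None,
) -> FeatureVector:
    """Concatenate the enabled blocks for one substitution, in fixed order.

    When `reference_aa` (the query sequence letter at the variant position)
    is supplied, a disagreement with the record's wild type raises: silently
    scoring the wrong residue is the worst failure mode of a variant
    annotator.
    """
    if reference_aa is not None and reference_aa.upper() != variant.wild_aa:
        raise ValueError(
            f"reference mismatch at {variant.protein_id}:{variant.position}: "
            f"table says {variant.wild_aa}, sequence has {reference_aa.upper()}"
        )
    blocks: list[np.ndarray] = []
    if config.use_entropy:
        if entropy is None:
            raise ValueError("entropy track required by this configuration")
        blocks.append(np.array([entropy.rs_at(variant.position)]))
    if config.use_types:
        blocks.append(one_hot_aa(variant.wild_aa))
        blocks.append(one_hot_aa(variant.mutant_aa))
    if config.use_domain:
        if domain is None:
            raise ValueError("domain composition required by this configuration")
        blocks.append(np.asarray(domain, dtype=float))
    if config.use_contact:
        if contact is None:
            raise ValueError("contact composition required by this configuration")
        blocks.append(np.asarray(contact, dtype=float))
    values = np.concatenate(blocks)
    assert values.shape[0] == config.n_features
    return FeatureVector(values=values, variant=variant, config=config.name)
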