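"""Synthetic alignments, structures and variant tables with planted signal.

The generator emulates the statistical structure the predictor assumes:
homolog alignments with a controllable fraction of conserved columns,
idealized C-alpha chain geometries, and labeled substitution tables whose
disease probability is logistic in the negative relative entropy — variations
at conserved (low-RS) positions are disease-enriched, which is the
conservation premise the entropy feature encodes.  Everything is driven by a
single integer seed and is byte-reproducible.

Scale defaults (20 proteins x 100 residues, 100 variants each) keep a full
train/evaluate round, including a 200-tree model, comfortably inside a couple
of minutes on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .alphabet import AA_ORDER, N_AA
from .io_formats import (
    VariantRecord,
    write_alignment_fasta,
    write_calpha_pdb,
    write_segment_table,
    write_variant_table,
)
from .pipeline import ProteinContext
from .profile_entropy import AlignmentSet
from .structure_features import DomainSegment, StructureModel

CA_SPACING = 3.8  # A, consecutive C-alpha distance in an extended chain
HELIX_RISE = 1.5  # A per residue
HELIX_TWIST = np.deg2rad(100.0)
HELIX_RADIUS = 2.3  # A


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic dataset."""

    n_proteins: int = 20
    length: int = 100
    n_homologs: int = 50
    conserved_fraction: float = 0.5
    substitution_rate: float = 0.5
    variants_per_protein: int = 100
    signal_slope: float = 4.0  # logistic slope on RS; 0 = no signal
    target_ratio: float = 1.0  # neutral/disease per protein, in expectation
    geometry: str = "extended"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_ratio < 0:
            raise ValueError("target neutral/disease ratio must be >= 0")
        if not 0.0 <= self.substitution_rate <= 1.0:
            raise ValueError("substitution_rate must be in [0, 1]")
        if not 0.0 <= self.conserved_fraction <= 1.0:
            raise ValueError("conserved_fraction must be in [0, 1]")
        if self.signal_slope < 0:
            raise ValueError("signal_slope must be >= 0 (0 disables the signal)")


@dataclass
class SyntheticDataset:
    spec: SyntheticSpec
    variants: list[VariantRecord]
    contexts: dict[str, ProteinContext]
    alignments: dict[str, AlignmentSet]
    structures: dict[str, StructureModel]
    segments: list[DomainSegment] = field(default_factory=list)


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(AA_ORDER[i] for i in rng.integers(0, N_AA, size=length))


def make_alignment(
    length: int,
    n_homologs: int,
    conserved_columns: Sequence[int],
    substitution_rate: float,
    seed: int,
    query_id: str = "query",
    query: Optional[str] = None,
) -> AlignmentSet:
    """Query plus homologs; conserved columns are identical across rows.

    At every variable column each homolog independently resamples a uniform
    letter with probability `substitution_rate` (the resampled letter may
    coincide with the query's), so homolog identity to the query lands near
    1 - v * rate * 19/20 for variable-column fraction v — controllable to
    straddle the 35-90% filtering window.
    """
    rng = np.random.default_rng(seed)
    if query is None:
        query = _random_sequence(rng, length)
    conserved = np.zeros(length, dtype=bool)
    for pos in conserved_columns:
        conserved[pos - 1] = True
    rows = [query]
    for _ in range(n_homologs):
        letters = list(query)
        variable = np.flatnonzero(~conserved)
        hit = variable[rng.random(variable.size) < substitution_rate]
        for i in hit:
            letters[i] = AA_ORDER[rng.integers(0, N_AA)]
        rows.append("".join(letters))
    return AlignmentSet(query_id=query_id, rows=rows)


def make_structure(
    length: int,
    geometry: str = "extended",
    seed: int = 0,
    protein_id: str = "synthetic",
    sequence: Optional[str] = None,
) -> StructureModel:
    """Idealized C-alpha chain.

    extended: collinear at 3.8 A spacing, so an interior residue has exactly
    6 neighbors within 12 A (3 * 3.8 = 11.4) and 4 within 8 A.
    helix: ideal alpha-helix (rise 1.5 A, 100 deg twist, radius 2.3 A).
    """
    rng = np.random.default_rng(seed)
    if sequence is None:
        sequence = _random_sequence(rng, length)
    i = np.arange(length, dtype=float)
    if geometry == "extended":
        coords = np.column_stack([CA_SPACING * i, np.zeros(length), np.zeros(length)])
    elif geometry == "helix":
        theta = HELIX_TWIST * i
        coords = np.column_stack(
            [HELIX_RADIUS * np.cos(theta), HELIX_RADIUS * np.sin(theta), HELIX_RISE * i]
        )
    else:
        raise ValueError(f"unknown geometry {geometry!r}")
    return StructureModel(
        protein_id=protein_id,
        positions=np.arange(1, length + 1),
        aas=sequence,
        coords=coords,
    )


def _disease_probability(rs: np.ndarray, slope: float, target_p: float) -> np.ndarray:
    """P(disease) = logistic(-slope * (RS - rs0)), rs0 tuned so E[P] = target_p.

    Low-RS (conserved) positions get high disease probability.  With slope 0
    the probability is the constant target_p (labels independent of features).
    """
    if slope == 0.0:
        return np.full_like(rs, target_p, dtype=float)

    def mean_p(rs0: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(slope * (rs - rs0)))))

    lo, hi = rs.min() - 50.0 / slope, rs.max() + 50.0 / slope
    for _ in range(100):  # bisection; mean_p is increasing in rs0
        mid = 0.5 * (lo + hi)
        if mean_p(mid) < target_p:
            lo = mid
        else:
            hi = mid
    rs0 = 0.5 * (lo + hi)
    return 1.0 / (1.0 + np.exp(slope * (rs - rs0)))


def make_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Generate proteins, homolog alignments, structures, segments and variants.

    Labels are Bernoulli draws from the planted logistic-in-RS signal; the
    per-protein neutral/disease ratio matches spec.target_ratio in
    expectation.  The same seed always reproduces the same dataset.
    """
    master = np.random.default_rng(spec.seed)
    target_p = 1.0 / (1.0 + spec.target_ratio)
    variants: list[VariantRecord] = []
    contexts: dict[str, ProteinContext] = {}
    alignments: dict[str, AlignmentSet] = {}
    structures: dict[str, StructureModel] = {}
    segments: list[DomainSegment] = []
    for p in range(spec.n_proteins):
        pid = f"SYN{p:03d}"
        rng = np.random.default_rng(master.integers(0, 2**31 - 1))
        L = spec.length
        n_cons = int(round(spec.conserved_fraction * L))
        cons_cols = rng.choice(L, size=n_cons, replace=False) + 1
        aln = make_alignment(
            L,
            spec.n_homologs,
            cons_cols,
            spec.substitution_rate,
            seed=int(rng.integers(0, 2**31 - 1)),
            query_id=pid,
        )
        structure = make_structure(
            L, spec.geometry, seed=int(rng.integers(0, 2**31 - 1)),
            protein_id=pid, sequence=aln.rows[0],
        )
        segs = [
            DomainSegment(pid, 1, L // 2),
            DomainSegment(pid, L // 2 + 1, L),
        ]
        ctx = ProteinContext.from_alignment(aln, structure=structure, segments=segs)
        positions = rng.integers(1, L + 1, size=spec.variants_per_protein)
        rs = np.array([ctx.entropy.rs_at(int(pos)) for pos in positions])
        probs = _disease_probability(rs, spec.signal_slope, target_p)
        draws = rng.random(spec.variants_per_protein)
        for pos, prob, u in zip(positions, probs, draws):
            wild = ctx.sequence[int(pos) - 1]
            mutant = wild
            while mutant == wild:
                mutant = AA_ORDER[rng.integers(0, N_AA)]
            variants.append(
                VariantRecord(pid, int(pos), wild, mutant, label=int(u < prob))
            )
        contexts[pid] = ctx
        alignments[pid] = aln
        structures[pid] = structure
        segments.extend(segs)
    return SyntheticDataset(
        spec=spec,
        variants=variants,
        contexts=contexts,
        alignments=alignments,
        structures=structures,
        segments=segments,
    )


def write_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> None:
    """Write the dataset as FASTA/PDB/TSV files consumable by every command."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for pid, aln in dataset.alignments.items():
        write_alignment_fasta(aln, out / f"{pid}.aln.fasta")
    for pid, structure in dataset.structures.items():
        write_calpha_pdb(structure, out / f"{pid}.pdb")
    write_variant_table(dataset.variants, out / "variants.tsv")
    write_segment_table(dataset.segments, out / "segments.tsv")
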