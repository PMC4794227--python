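"""Sequence profiles and relative sequence entropy.

A query protein's homologs (one aligned FASTA, query first) are reduced to a
"35-90" set: every retained homolog has 35-90% identity to the query and at
most 90% to every other retained homolog, which prevents over-representation
of near-duplicate sequences.  Counting amino-acid types per query position and
normalizing by the per-position sequence count gives the frequency profile
f_l; its Shannon entropy in nats,

    S = -sum_l f_l ln f_l,

ranges from 0 (fully conserved) to ln(20) ~ 2.996 (uniform).  The feature
used downstream is the *relative* entropy RS = S - <S>, the per-position
entropy minus the protein-wide mean, which removes protein-level profile-depth
effects (a query-only profile is zero everywhere, not spuriously conserved).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import xlogy

from .alphabet import AA_INDEX, GAP, N_AA

MAX_ENTROPY = float(np.log(N_AA))  # ln(20) ~ 2.996


@dataclass
class AlignmentSet:
    """An alignment in query coordinates: row 0 is the query, gap-free."""

    query_id: str
    rows: list[str]
    identities: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment must contain at least the query row")
        L = len(self.rows[0])
        if any(len(r) != L for r in self.rows):
            raise ValueError("all alignment rows must have the query's length")
        if GAP in self.rows[0]:
            raise ValueError("query row may not contain gaps (query coordinates)")
        if not self.identities:
            self.identities = [
                pairwise_identity(self.rows[0], r) for r in self.rows
            ]

    @property
    def length(self) -> int:
        return len(self.rows[0])

    @property
    def n_rows(self) -> int:
        return len(self.rows)


@dataclass
class Profile:
    """Normalized 20-type frequency matrix, one row per query position."""

    freqs: np.ndarray  # (L, 20)
    coverage: np.ndarray  # (L,) sequences contributing per position

    @property
    def length(self) -> int:
        return self.freqs.shape[0]


@dataclass
class EntropyTrack:
    S: np.ndarray  # per-position entropy, nats
    mean_S: float
    RS: np.ndarray  # S - mean_S

    @property
    def length(self) -> int:
        return self.S.shape[0]

    def rs_at(self, position: int) -> float:
        """RS at a 1-based residue position."""
        if not 1 <= position <= self.length:
            raise ValueError(f"position {position} outside entropy track 1..{self.length}")
        return float(self.RS[position - 1])


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of matching letters over columns where both rows are non-gap.

    Returns 0.0 when the rows share no non-gap column.
    """
    if len(a) != len(b):
        raise ValueError("rows must be aligned (equal length)")
    aligned = matches = 0
    for x, y in zip(a, b):
        if x != GAP and y != GAP:
            aligned += 1
            if x.upper() == y.upper():
                matches += 1
    return matches / aligned if aligned else 0.0


def filter_by_identity(
    aln: AlignmentSet, min_id: float = 0.35, max_id: float = 0.90
) -> AlignmentSet:
    """Greedy 35-90 redundancy filter.

    Non-query rows are scanned in input order; a row is kept iff its identity
    to the query lies in [min_id, max_id] AND its identity to every
    previously kept row is <= max_id.  The query row is always kept.  The
    greedy scan is deterministic given input order.
    """
    kept_rows = [aln.rows[0]]
    kept_ids = [1.0]
    for row, ident in zip(aln.rows[1:], aln.identities[1:]):
        if not (min_id <= ident <= max_id):
            continue
        if any(pairwise_identity(row, other) > max_id for other in kept_rows[1:]):
            continue
        kept_rows.append(row)
        kept_ids.append(ident)
    return AlignmentSet(aln.query_id, kept_rows, kept_ids)


def build_profile(aln: AlignmentSet) -> Profile:
    """Count amino-acid types per column (query included) and normalize.

    Gaps and nonstandard letters are excluded from both the counts and the
    per-position normalization, so each column's frequencies sum to 1 unless
    no sequence contributes there (coverage 0, all-zero column).
    """
    L = aln.length
    counts = np.zeros((L, N_AA))
    for row in aln.rows:
        for i, letter in enumerate(row):
            j = AA_INDEX.get(letter.upper())
            if j is not None:
                counts[i, j] += 1
    coverage = counts.sum(axis=1)
    freqs = np.divide(
        counts, coverage[:, None], out=np.zeros_like(counts), where=coverage[:, None] > 0
    )
    return Profile(freqs=freqs, coverage=coverage.astype(int))


def position_entropy(column_freqs: np.ndarray) -> float:
    """Shannon entropy in nats of one profile column; 0*ln 0 := 0.

    An all-zero (no-coverage) column maps to 0 by convention, matching the
    query-only degenerate case where every position carries zero information.
    """
    f = np.asarray(column_freqs, dtype=float)
    if np.any(f < 0):
        raise ValueError("negative frequency in profile column")
    return float(-xlogy(f, f).sum())


def relative_entropy(profile: Profile) -> EntropyTrack:
    """Per-position S, its protein-wide unweighted mean, and RS = S - <S>."""
    if profile.length == 0:
        raise ValueError("cannot compute entropy of a zero-length profile")
    f = profile.freqs
    if np.any(f < 0):
        raise ValueError("negative frequency in profile")
    S = -xlogy(f, f).sum(axis=1)
    mean_S = float(S.mean())
    return EntropyTrack(S=S, mean_S=mean_S, RS=S - mean_S)
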