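"""Structure-derived feature blocks: domain and contacting compositions.

Both blocks are 20-vectors of amino-acid-type fractions in the fixed
alphabetical order.  The *domain composition* summarizes the segment/domain
containing the mutated position; the *contacting composition* summarizes the
residues whose C-alpha atom lies within a distance cutoff (default 12 A) of
the mutated residue's C-alpha.  A vector of all zeros is the sentinel for "no
neighbors" / "no standard letters in segment"; otherwise entries sum to 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alphabet import AA_INDEX, N_AA, aa_index


@dataclass
class StructureModel:
    """Ordered C-alpha trace: 1-based residue positions, letters, coordinates (A)."""

    protein_id: str
    positions: np.ndarray  # (n,) int, strictly increasing
    aas: str  # one-letter codes, len n
    coords: np.ndarray  # (n, 3) float

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.positions)
        if len(self.aas) != n or self.coords.shape != (n, 3):
            raise ValueError("positions, aas and coords must agree in length")
        if n and np.any(np.diff(self.positions) <= 0):
            raise ValueError("residue positions must be strictly increasing")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite C-alpha coordinate")

    def __len__(self) -> int:
        return len(self.positions)

    def index_of(self, position: int) -> int:
        i = int(np.searchsorted(self.positions, position))
        if i >= len(self.positions) or self.positions[i] != position:
            raise KeyError(f"residue position {position} absent from structure "
                           f"{self.protein_id!r}")
        return i

    def has_position(self, position: int) -> bool:
        try:
            self.index_of(position)
            return True
        except KeyError:
            return False


@dataclass(frozen=True)
class DomainSegment:
    """1-based inclusive segment boundaries of one protein."""

    protein_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid segment [{self.start}, {self.end}]")

    def covers(self, position: int) -> bool:
        return self.start <= position <= self.end


def contact_composition(
    structure: StructureModel, position: int, cutoff: float = 12.0
) -> np.ndarray:
    """Type fractions of residues within `cutoff` A (C-alpha) of `position`.

    The mutated residue itself is excluded; the comparison is boundary
    inclusive (distance <= cutoff).  Returns the all-zero sentinel when the
    residue has no neighbors.  Raises KeyError when the position is absent
    from the structure, which is distinct from "present but isolated".
    """
    i = structure.index_of(position)
    d = np.linalg.norm(structure.coords - structure.coords[i], axis=1)
    neighbors = np.flatnonzero((d <= cutoff) & (np.arange(len(structure)) != i))
    vec = np.zeros(N_AA)
    if neighbors.size == 0:
        return vec
    for j in neighbors:
        vec[aa_index(structure.aas[j])] += 1.0
    return vec / neighbors.size


def domain_composition(sequence: str, segment: DomainSegment) -> np.ndarray:
    """Type fractions over sequence[start..end] (1-based inclusive).

    Nonstandard letters are excluded from numerator and denominator; a
    segment with no standard letters yields the zero sentinel.
    """
    if segment.end > len(sequence):
        raise ValueError(
            f"segment [{segment.start}, {segment.end}] exceeds sequence "
            f"length {len(sequence)}"
        )
    vec = np.zeros(N_AA)
    n = 0
    for letter in sequence[segment.start - 1 : segment.end]:
        j = AA_INDEX.get(letter.upper())
        if j is not None:
            vec[j] += 1.0
            n += 1
    return vec / n if n else vec


def segment_of(
    position: int, segments: list[DomainSegment], sequence_length: int,
    protein_id: str = "",
) -> DomainSegment:
    """The segment covering `position`, else the whole-sequence fallback [1, L]."""
    for seg in segments:
        if seg.covers(position):
            return seg
    return DomainSegment(protein_id, 1, sequence_length)


def check_non_overlapping(segments: list[DomainSegment]) -> None:
    """Raise if any two segments of the same protein overlap."""
    by_protein: dict[str, list[DomainSegment]] = {}
    for seg in segments:
        by_protein.setdefault(seg.protein_id, []).append(seg)
    for pid, segs in by_protein.items():
        ordered = sorted(segs, key=lambda s: s.start)
        for a, b in zip(ordered, ordered[1:]):
            if b.start <= a.end:
                raise ValueError(
                    f"overlapping segments for {pid!r}: "
                    f"[{a.start},{a.end}] and [{b.start},{b.end}]"
                )
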