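"""The 20-letter amino-acid alphabet shared by every feature block.

All composition vectors, one-hot encodings and profile columns are indexed
alphabetically by one-letter code (A, C, D, ..., Y); the index is frozen here
so serialized models remain self-describing.
"""

from __future__ import annotations

from Bio.Data.IUPACData import protein_letters_3to1

AA_ORDER: str = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AA_ORDER)}
N_AA: int = 20

GAP = "-"

# 3-letter -> 1-letter for the 20 standard residues only (SEC/PYL etc. are
# deliberately absent: the feature space is fixed at 20 types).
THREE_TO_ONE: dict[str, str] = {
    name.upper(): one
    for name, one in protein_letters_3to1.items()
    if one in AA_INDEX
}


def is_standard_aa(letter: str) -> bool:
    return letter.upper() in AA_INDEX


def aa_index(letter: str) -> int:
    """Alphabetical index of a standard amino-acid letter (case-insensitive)."""
    try:
        return AA_INDEX[letter.upper()]
    except KeyError:
        raise ValueError(f"unknown amino-acid letter: {letter!r}") from None
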