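"""Readers and writers for every external representation the pipeline touches.

Formats: aligned FASTA (query first), PDB ATOM records (only C-alpha atoms are
consumed), tab-separated variant and domain-segment tables, and a structured
JSON document for trained boosted-tree models.  Positions are 1-based
throughout, matching biological convention.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from Bio import AlignIO
from Bio.PDB import PDBParser

from .alphabet import AA_INDEX, GAP, THREE_TO_ONE
from .profile_entropy import AlignmentSet
from .structure_features import DomainSegment, StructureModel, check_non_overlapping

logger = logging.getLogger(__name__)

MODEL_FORMAT_TAG = "entprise-model-v1"


@dataclass(frozen=True)
class VariantRecord:
    """One amino-acid substitution, optionally labeled.

    label is 1 for disease-associated, 0 for neutral; allele_freq is the
    population allele frequency in [0, 1] when known.
    """

    protein_id: str
    position: int
    wild_aa: str
    mutant_aa: str
    label: Optional[int] = None
    allele_freq: Optional[float] = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        for aa in (self.wild_aa, self.mutant_aa):
            if aa not in AA_INDEX:
                raise ValueError(f"unknown amino-acid letter: {aa!r}")
        if self.wild_aa == self.mutant_aa:
            raise ValueError(
                f"wild equals mutant ({self.wild_aa}) at "
                f"{self.protein_id}:{self.position}"
            )
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")
        if self.allele_freq is not None and not 0.0 <= self.allele_freq <= 1.0:
            raise ValueError(f"allele_freq outside [0,1]: {self.allele_freq}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.protein_id, self.position, self.wild_aa, self.mutant_aa)


def read_variant_table(path: str | Path, require_labels: bool = False) -> list[VariantRecord]:
    """Read a TSV of variants; row order preserved, duplicates retained.

    Required columns: protein_id, position, wild_aa, mutant_aa; optional:
    label, allele_freq.  Malformed rows are rejected with their 1-based file
    row number.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["protein_id", "position", "wild_aa", "mutant_aa"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    records: list[VariantRecord] = []
    for idx, row in enumerate(df.itertuples(index=False)):
        file_row = idx + 2  # 1-based, after the header line
        try:
            pos_text = getattr(row, "position")
            if not pos_text.isdigit():
                raise ValueError(f"malformed position {pos_text!r}")
            label_text = getattr(row, "label", "")
            label = int(label_text) if label_text != "" else None
            if label is None and require_labels:
                raise ValueError("missing label")
            af_text = getattr(row, "allele_freq", "")
            af = float(af_text) if af_text != "" else None
            records.append(
                VariantRecord(
                    protein_id=row.protein_id,
                    position=int(pos_text),
                    wild_aa=row.wild_aa.upper(),
                    mutant_aa=row.mutant_aa.upper(),
                    label=label,
                    allele_freq=af,
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}, row {file_row}: {exc}") from None
    return records


def write_variant_table(records: Iterable[VariantRecord], path: str | Path) -> None:
    rows = [
        {
            "protein_id": r.protein_id,
            "position": r.position,
            "wild_aa": r.wild_aa,
            "mutant_aa": r.mutant_aa,
            "label": "" if r.label is None else r.label,
            "allele_freq": "" if r.allele_freq is None else r.allele_freq,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_segment_table(path: str | Path) -> list[DomainSegment]:
    """TSV with columns protein_id, start, end (1-based inclusive)."""
    df = pd.read_csv(path, sep="\t")
    segments = [
        DomainSegment(str(r.protein_id), int(r.start), int(r.end))
        for r in df.itertuples(index=False)
    ]
    check_non_overlapping(segments)
    return segments


def write_segment_table(segments: Iterable[DomainSegment], path: str | Path) -> None:
    pd.DataFrame(
        [{"protein_id": s.protein_id, "start": s.start, "end": s.end} for s in segments]
    ).to_csv(path, sep="\t", index=False)


def read_calpha_structure(path: str | Path, protein_id: Optional[str] = None) -> StructureModel:
    """Parse the C-alpha trace from a PDB file.

    Only ATOM records with atom name CA are used, first model only, first
    alternate location only.  Residues with names outside the 20 standard
    types are skipped with a warning.  Residue numbering is preserved (gaps
    allowed); residues are ordered by residue sequence number.
    """
    path = Path(path)
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(path.stem, str(path))
    try:
        model = next(structure.get_models())
    except StopIteration:
        raise ValueError(f"{path}: no models in PDB file") from None
    entries: list[tuple[int, str, np.ndarray]] = []
    for chain in model:
        for residue in chain:
            hetflag, resseq, _icode = residue.id
            if hetflag != " " or "CA" not in residue:
                continue
            resname = residue.get_resname().strip().upper()
            one = THREE_TO_ONE.get(resname)
            if one is None:
                logger.warning("%s: skipping non-standard residue %s %d",
                               path, resname, resseq)
                continue
            entries.append((resseq, one, residue["CA"].get_coord()))
    if not entries:
        raise ValueError(f"{path}: no C-alpha atoms found")
    entries.sort(key=lambda e: e[0])
    positions = np.array([e[0] for e in entries])
    if np.any(np.diff(positions) == 0):
        raise ValueError(f"{path}: duplicate residue numbers in C-alpha trace")
    return StructureModel(
        protein_id=protein_id or path.stem,
        positions=positions,
        aas="".join(e[1] for e in entries),
        coords=np.array([e[2] for e in entries], dtype=float),
    )


_ONE_TO_THREE = {one: three for three, one in THREE_TO_ONE.items()}


def write_calpha_pdb(structure: StructureModel, path: str | Path) -> None:
    """Write a minimal PDB file holding only the C-alpha trace."""
    with open(path, "w") as fh:
        for serial, (pos, aa, xyz) in enumerate(
            zip(structure.positions, structure.aas, structure.coords), start=1
        ):
            fh.write(
                f"ATOM  {serial:5d}  CA  {_ONE_TO_THREE[aa]} A{pos:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00           C\n"
            )
        fh.write("END\n")


def read_alignment(path: str | Path) -> AlignmentSet:
    """Read an aligned FASTA whose first record is the query.

    Columns where the query has a gap are dropped, so every retained column is
    indexed by a query residue position and the profile length equals the
    ungapped query length.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            msa = AlignIO.read(str(path), "fasta")
        except ValueError as exc:
            raise ValueError(f"{path}: {exc}") from None
    if len(msa) == 0:
        raise ValueError(f"{path}: empty alignment")
    query = str(msa[0].seq)
    keep = [i for i, c in enumerate(query) if c != GAP]
    rows = ["".join(str(rec.seq)[i] for i in keep).upper() for rec in msa]
    return AlignmentSet(query_id=msa[0].id, rows=rows)


def write_alignment_fasta(aln: AlignmentSet, path: str | Path,
                          homolog_prefix: str = "hom") -> None:
    with open(path, "w") as fh:
        fh.write(f">{aln.query_id}\n{aln.rows[0]}\n")
        for i, row in enumerate(aln.rows[1:], start=1):
            fh.write(f">{aln.query_id}|{homolog_prefix}{i}\n{row}\n")


def serialize_model(model, path: str | Path) -> None:
    """Write a BoostedModel as a structured JSON text document.

    Thresholds and leaf values are JSON doubles, which round-trip exactly, so
    a reloaded model's predictions are bit-identical.
    """
    doc = {
        "format": MODEL_FORMAT_TAG,
        "shrinkage": model.shrinkage,
        "base_score": model.base_score,
        "n_features": model.n_features,
        "feature_config": model.feature_config,
        "trees": [t.root for t in model.trees],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_model(path: str | Path):
    from .gbrt import BoostedModel, RegressionTree

    with open(path) as fh:
        doc = json.load(fh)
    tag = doc.get("format")
    if tag != MODEL_FORMAT_TAG:
        raise ValueError(f"{path}: unsupported model format tag {tag!r}")
    return BoostedModel(
        trees=[RegressionTree(root=r) for r in doc["trees"]],
        shrinkage=doc["shrinkage"],
        base_score=doc["base_score"],
        n_features=doc["n_features"],
        feature_config=doc["feature_config"],
    )
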