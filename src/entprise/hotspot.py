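"""Saturation-mutagenesis scanning and hot-spot analysis.

Every covered position of a protein is scored for all 19 substitutions away
from the reference residue.  A position is a "hot" spot when every one of the
19 scores exceeds the disease cutoff (strictly; default 0.45) — i.e. any
substitution there is predicted disease-associated.  A protein's hot-spot
fraction is |hot| / |covered|, averaged over isoforms when several sequences
share a protein id; positions without features are excluded from both
numerator and denominator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .alphabet import AA_ORDER
from .feature_encoding import FeatureConfig
from .gbrt import BoostedModel, DEFAULT_CUTOFF, predict_score
from .io_formats import VariantRecord
from .pipeline import ProteinContext

logger = logging.getLogger(__name__)


@dataclass
class SaturationScan:
    protein_id: str
    # position -> (wild_aa, 19 mutant letters in alphabetical order, 19 scores)
    scores: dict[int, tuple[str, str, np.ndarray]]

    @property
    def covered_positions(self) -> list[int]:
        return sorted(self.scores)

    @property
    def n_scores(self) -> int:
        return 19 * len(self.scores)


@dataclass
class HotspotProfile:
    protein_id: str
    hot_positions: set[int]
    covered: int
    fraction_hot: float


def saturation_scan(
    context: ProteinContext, model: BoostedModel, config: FeatureConfig
) -> SaturationScan:
    """Score all 19 substitutions at every feature-covered position."""
    scores: dict[int, tuple[str, str, np.ndarray]] = {}
    for pos in range(1, len(context.sequence) + 1):
        wild = context.sequence[pos - 1].upper()
        if wild not in AA_ORDER or not context.covers(pos, config):
            continue
        mutants = "".join(aa for aa in AA_ORDER if aa != wild)
        X = np.vstack(
            [
                context.features_for(
                    VariantRecord(context.protein_id, pos, wild, m), config
                )
                for m in mutants
            ]
        )
        scores[pos] = (wild, mutants, np.asarray(predict_score(model, X)))
    if not scores:
        raise ValueError(f"no covered positions in {context.protein_id!r}")
    return SaturationScan(protein_id=context.protein_id, scores=scores)


def hot_positions(scan: SaturationScan, cutoff: float = DEFAULT_CUTOFF) -> HotspotProfile:
    """Call hot spots: positions where the minimum of the 19 scores > cutoff."""
    hot = {
        pos
        for pos, (_w, _m, s) in scan.scores.items()
        if float(s.min()) > cutoff
    }
    covered = len(scan.scores)
    return HotspotProfile(
        protein_id=scan.protein_id,
        hot_positions=hot,
        covered=covered,
        fraction_hot=len(hot) / covered,
    )


def combine_isoforms(profiles: list[HotspotProfile]) -> float:
    """Protein-level hot-spot fraction: unweighted mean over isoform profiles."""
    if not profiles:
        raise ValueError("no isoform profiles to combine")
    return float(np.mean([p.fraction_hot for p in profiles]))


def threshold_curve(
    per_protein: list[tuple[float, float]],
    thresholds: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Mean attribute among proteins with fraction_hot >= t, per threshold t.

    `per_protein` holds (fraction_hot, attribute) pairs — the attribute may
    be a protein-protein interaction count or a 0/1 disease-association flag
    (whose mean is a cumulative fraction).  Thresholds with no qualifying
    protein are omitted and logged.  Returns (kept thresholds, curve values,
    Pearson r between the two).
    """
    if len(per_protein) < 2:
        raise ValueError("need at least 2 proteins")
    fracs = np.asarray([p[0] for p in per_protein], dtype=float)
    attrs = np.asarray([p[1] for p in per_protein], dtype=float)
    kept_t: list[float] = []
    curve: list[float] = []
    for t in np.asarray(thresholds, dtype=float):
        mask = fracs >= t
        if not mask.any():
            logger.info("threshold %.3f: no qualifying proteins, point omitted", t)
            continue
        kept_t.append(float(t))
        curve.append(float(attrs[mask].mean()))
    t_arr = np.asarray(kept_t)
    c_arr = np.asarray(curve)
    if len(t_arr) >= 2 and np.ptp(t_arr) > 0 and np.ptp(c_arr) > 0:
        r = float(np.corrcoef(t_arr, c_arr)[0, 1])
    else:
        r = float("nan")
    return t_arr, c_arr, r
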