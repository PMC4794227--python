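"""Dataset protocol and evaluation suite.

Training protocol: classify each protein as balanced (neutral/disease ratio
in [0.3, 3.0], with at least one disease variant) or unbalanced; split the
variant table at the variation level; replicate every variation on a balanced
protein to six copies in the training side only, which counters the bias of a
corpus dominated by proteins that carry only one class of variation.

Evaluation: confusion counts with disease as the positive class, the standard
derived metrics (MCC, accuracy, sensitivity, specificity, PPV, NPV), the
rank-formulation AUC, false-positive rate on all-neutral sets, and the
ordinary-least-squares cross-dataset FPR fit used to extrapolate the residual
contamination of a putatively neutral benchmark.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .io_formats import VariantRecord

logger = logging.getLogger(__name__)

BALANCE_LOW = 0.3
BALANCE_HIGH = 3.0
OVERSAMPLE_COPIES = 6
ALLELE_FREQ_CUTOFF = 0.17


@dataclass(frozen=True)
class ProteinBalanceStatus:
    protein_id: str
    n_disease: int
    n_neutral: int

    @property
    def ratio(self) -> float:
        return self.n_neutral / self.n_disease if self.n_disease else math.inf

    @property
    def balanced(self) -> bool:
        return self.n_disease > 0 and BALANCE_LOW <= self.ratio <= BALANCE_HIGH


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class EvaluationReport:
    mcc: float
    acc: float
    sen: Optional[float]
    spe: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]
    fpr: Optional[float]
    auc: Optional[float] = None
    counts: Optional[ConfusionCounts] = None


def balance_status(
    variants: Iterable[VariantRecord],
) -> dict[str, ProteinBalanceStatus]:
    """Per-protein disease/neutral counts and the balanced flag (bounds inclusive)."""
    disease: dict[str, int] = {}
    neutral: dict[str, int] = {}
    for v in variants:
        if v.label is None:
            raise ValueError(f"unlabeled variant {v.key} in balance computation")
        bucket = disease if v.label == 1 else neutral
        bucket[v.protein_id] = bucket.get(v.protein_id, 0) + 1
    return {
        pid: ProteinBalanceStatus(pid, disease.get(pid, 0), neutral.get(pid, 0))
        for pid in {**disease, **neutral}
    }


def oversample_balanced(
    train: Sequence[VariantRecord], copies: int = OVERSAMPLE_COPIES
) -> list[VariantRecord]:
    """Replicate balanced-protein variations to `copies` total copies.

    Balance statuses are computed on the given set itself; variations on
    unbalanced proteins appear once.  Apply to the training side only.
    """
    if copies < 1:
        raise ValueError(f"copies must be >= 1, got {copies}")
    status = balance_status(train)
    out: list[VariantRecord] = []
    for v in train:
        out.extend([v] * (copies if status[v.protein_id].balanced else 1))
    return out


def split_variants(
    variants: Sequence[VariantRecord], fraction: float = 0.5, seed: int = 0
) -> tuple[list[VariantRecord], list[VariantRecord]]:
    """Seeded random partition at the variation level into (TR, TE)."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(variants))
    n_train = int(round(fraction * len(variants)))
    train = [variants[i] for i in sorted(order[:n_train])]
    test = [variants[i] for i in sorted(order[n_train:])]
    return train, test


def grouped_kfold(
    variants: Sequence[VariantRecord],
    group_of: Callable[[str], str],
    k: int = 10,
    seed: int = 0,
) -> list[tuple[list[VariantRecord], list[VariantRecord]]]:
    """k train/test pairs with no group (e.g. protein family) split across folds.

    Groups are shuffled by seed, then assigned largest-first to the currently
    smallest test fold (greedy bin packing), so fold sizes are balanced and
    every variant appears in exactly one test fold.
    """
    group_members: dict[str, list[int]] = {}
    for i, v in enumerate(variants):
        group_members.setdefault(group_of(v.protein_id), []).append(i)
    if k > len(group_members):
        raise ValueError(f"k={k} exceeds the number of groups ({len(group_members)})")
    rng = np.random.default_rng(seed)
    names = sorted(group_members)
    rng.shuffle(names)
    names.sort(key=lambda g: -len(group_members[g]))  # stable: shuffle breaks ties
    fold_of_group: dict[str, int] = {}
    fold_sizes = [0] * k
    for g in names:
        target = int(np.argmin(fold_sizes))
        fold_of_group[g] = target
        fold_sizes[target] += len(group_members[g])
    folds: list[tuple[list[VariantRecord], list[VariantRecord]]] = []
    for fold in range(k):
        test_idx = {
            i
            for g, members in group_members.items()
            if fold_of_group[g] == fold
            for i in members
        }
        folds.append(
            (
                [v for i, v in enumerate(variants) if i not in test_idx],
                [v for i, v in enumerate(variants) if i in test_idx],
            )
        )
    return folds


def allele_frequency_filter(
    variants: Iterable[VariantRecord], threshold: float = ALLELE_FREQ_CUTOFF
) -> list[VariantRecord]:
    """Drop variants with allele frequency >= threshold (assumed neutral).

    Common variants in healthy populations are overwhelmingly benign, so this
    pre-filter shrinks an exome's candidate list before scoring.  Variants
    without an allele frequency are kept.
    """
    return [v for v in variants if v.allele_freq is None or v.allele_freq < threshold]


def _as_binary(values) -> np.ndarray:
    arr = np.asarray(values)
    if arr.dtype.kind in "UO":
        return np.asarray([1 if str(x) == "disease" else 0 for x in arr])
    return arr.astype(int)


def confusion(preds, labels) -> ConfusionCounts:
    """Tally a confusion table; positives are disease-associated.

    Predictions and labels may be 0/1 or the strings "neutral"/"disease".
    """
    p = _as_binary(preds)
    y = _as_binary(labels)
    if p.shape != y.shape:
        raise ValueError("predictions and labels disagree in length")
    return ConfusionCounts(
        tp=int(np.sum((p == 1) & (y == 1))),
        tn=int(np.sum((p == 0) & (y == 0))),
        fp=int(np.sum((p == 1) & (y == 0))),
        fn=int(np.sum((p == 0) & (y == 1))),
    )


def metrics(c: ConfusionCounts) -> EvaluationReport:
    """MCC, ACC, Sen, Spe, PPV, NPV from one confusion table.

    A zero factor in the MCC denominator maps MCC to 0; a ratio with a zero
    denominator (e.g. PPV with no positive predictions) is reported as
    missing (None), never as 0.
    """
    if c.total == 0:
        raise ValueError("empty confusion table")
    tp, tn, fp, fn = c.tp, c.tn, c.fp, c.fn
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom else 0.0
    ratio = lambda a, b: a / b if b else None  # noqa: E731
    spe = ratio(tn, tn + fp)
    return EvaluationReport(
        mcc=mcc,
        acc=(tp + tn) / c.total,
        sen=ratio(tp, tp + fn),
        spe=spe,
        ppv=ratio(tp, tp + fp),
        npv=ratio(tn, tn + fn),
        fpr=None if spe is None else 1.0 - spe,
        counts=c,
    )


def roc_auc(scores, labels) -> tuple[float, np.ndarray]:
    """Rank-formulation AUC and the ROC curve.

    AUC is the probability that a random disease score exceeds a random
    neutral score, ties counted 1/2 (the Mann-Whitney statistic).  The curve
    is returned as an array of (fpr, tpr, threshold) rows, one per distinct
    score, from the strictest threshold down.
    """
    s = np.asarray(scores, dtype=float)
    y = _as_binary(labels)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC/AUC requires both classes present")
    ranks = stats.rankdata(s)
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    order = np.argsort(-s, kind="stable")
    y_sorted = y[order]
    s_sorted = s[order]
    distinct = np.flatnonzero(np.diff(s_sorted, append=-np.inf))
    tps = np.cumsum(y_sorted)[distinct]
    fps = np.cumsum(1 - y_sorted)[distinct]
    curve = np.column_stack([fps / n_neg, tps / n_pos, s_sorted[distinct]])
    return float(auc), curve


def false_positive_rate(preds) -> float:
    """FPR of predictions on an all-neutral set: fraction called disease."""
    p = _as_binary(preds)
    if len(p) == 0:
        raise ValueError("empty prediction set")
    return float(p.mean())


def fpr_cross_regression(
    pairs: Sequence[tuple[float, float]],
) -> tuple[float, float, float]:
    """OLS of FPR(set B) on FPR(set A) across methods: (slope, intercept, r).

    The intercept extrapolates set B's apparent false-positive rate for a
    hypothetical perfect method (FPR(A) = 0), i.e. the residual contamination
    of B by non-neutral variants.
    """
    if len(pairs) < 3:
        raise ValueError("need at least 3 (x, y) pairs")
    x = np.asarray([p[0] for p in pairs], dtype=float)
    y = np.asarray([p[1] for p in pairs], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue)
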