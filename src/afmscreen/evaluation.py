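"""Screen evaluation: ROC/AUC, recall-FDR under controlled N:P ratios,
recall at a fixed FDR, F1 threshold scans, ranking experiments, and paired
rank comparisons.

Conventions (all recorded here because they matter at the boundaries):

* curves are exact step functions over the sorted set of observed scores
  plus endpoints, never binned;
* FDR = FP / (TP + FP) with the convention FDR = 0 when nothing is captured
  above the threshold (no discoveries, no false discoveries);
* recall = TP / P at score >= threshold;
* ranking uses competition ranking with ties resolved at the (floored)
  midrank: rank = 1 + #{strictly better} + floor(#ties / 2);
* a pair with no contact-positive prediction scores 0 and therefore ranks
  behind every scored decoy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateDataError

__all__ = [
    "ScoredPair",
    "RecallFdrCurve",
    "roc_auc",
    "subsample_np",
    "recall_fdr_curve",
    "recall_at_fdr",
    "f1_scan",
    "ranking_experiment",
    "compare_metric_ranks",
]


@dataclass(frozen=True)
class ScoredPair:
    pair_id: str
    score: float
    label: str  # "positive" | "negative"
    metric_name: str = ""

    def __post_init__(self):
        if not np.isfinite(self.score):
            raise ValueError(f"non-finite score for {self.pair_id}")
        if self.label not in ("positive", "negative"):
            raise ValueError(f"label must be positive/negative, got {self.label!r}")


def _split(scored: Sequence[ScoredPair]):
    pos = np.array([s.score for s in scored if s.label == "positive"])
    neg = np.array([s.score for s in scored if s.label == "negative"])
    return pos, neg


def roc_auc(scored: Sequence[ScoredPair]) -> float:
    """Rank-based AUC (concordance probability); ties count 1/2.

    Computed via the Mann-Whitney U relation on midranks, which equals
    exhaustive concordance counting.
    """
    pos, neg = _split(scored)
    if len(pos) == 0 or len(neg) == 0:
        raise DegenerateDataError("AUC undefined: need both classes")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2
    return float(u / (len(pos) * len(neg)))


def subsample_np(
    test: Sequence[ScoredPair],
    ratio: int,
    n_reps: int = 10,
    seed: Optional[int] = None,
) -> list[list[ScoredPair]]:
    """Seeded replicate test sets at a fixed negatives:positives ratio.

    Per replicate: when enough negatives exist, all positives are kept and
    N = P * ratio negatives are sampled without replacement; when negatives
    limit the ratio, all negatives are kept and P = max(1, round(N/ratio))
    positives are sampled.
    """
    if ratio < 1:
        raise ValueError("ratio must be >= 1")
    pos = [s for s in test if s.label == "positive"]
    neg = [s for s in test if s.label == "negative"]
    if not pos or not neg:
        raise DegenerateDataError("subsampling requires both classes")
    rng = np.random.default_rng(seed)
    reps = []
    for _ in range(n_reps):
        if len(neg) >= len(pos) * ratio:
            p_take = list(pos)
            n_take = [neg[i] for i in rng.choice(len(neg), len(pos) * ratio, replace=False)]
        else:
            n_take = list(neg)
            n_pos = max(1, round(len(neg) / ratio))
            p_take = [pos[i] for i in rng.choice(len(pos), n_pos, replace=False)]
        reps.append(p_take + n_take)
    return reps


@dataclass
class RecallFdrCurve:
    ratio: int
    thresholds: np.ndarray
    recall: np.ndarray  # mean over replicates
    fdr: np.ndarray
    n_reps: int


def _recall_fdr_at(scores_pos, scores_neg, thresholds):
    """Step-function recall and FDR at each threshold (score >= t captured)."""
    recall = np.empty(len(thresholds))
    fdr = np.empty(len(thresholds))
    p = len(scores_pos)
    for i, t in enumerate(thresholds):
        tp = int((scores_pos >= t).sum())
        fp = int((scores_neg >= t).sum())
        recall[i] = tp / p if p else 0.0
        fdr[i] = fp / (tp + fp) if (tp + fp) else 0.0
    return recall, fdr


def recall_fdr_curve(
    replicates: list[Sequence[ScoredPair]], ratio: int = 0
) -> RecallFdrCurve:
    """Replicate-averaged recall/FDR over the pooled observed-score grid."""
    if not replicates:
        raise ValueError("no replicates supplied")
    all_scores = np.array([s.score for rep in replicates for s in rep])
    thresholds = np.unique(
        np.concatenate([all_scores, [all_scores.min() - 1e-9, all_scores.max() + 1e-9]])
    )
    recs, fdrs = [], []
    for rep in replicates:
        pos, neg = _split(rep)
        r, f = _recall_fdr_at(pos, neg, thresholds)
        recs.append(r)
        fdrs.append(f)
    return RecallFdrCurve(
        ratio=ratio,
        thresholds=thresholds,
        recall=np.mean(recs, axis=0),
        fdr=np.mean(fdrs, axis=0),
        n_reps=len(replicates),
    )


def recall_at_fdr(curve: RecallFdrCurve, fdr_cap: float = 0.05) -> float:
    """Maximum recall over thresholds whose FDR is <= the cap; 0 when none."""
    ok = curve.fdr <= fdr_cap
    return float(curve.recall[ok].max()) if ok.any() else 0.0


def f1_scan(
    scored: Sequence[ScoredPair], thresholds: Optional[Sequence[float]] = None
) -> tuple[float, np.ndarray, np.ndarray]:
    """F1 = TP / (TP + 0.5 (FP + FN)) at each threshold.

    Returns (argmax threshold, thresholds, f1 array); ties go to the lowest
    threshold.
    """
    pos, neg = _split(scored)
    if len(pos) == 0 or len(neg) == 0:
        raise DegenerateDataError("F1 scan requires both classes")
    if thresholds is None:
        allsc = np.concatenate([pos, neg])
        thresholds = np.unique(np.concatenate([allsc, [allsc.min() - 1e-9]]))
    thresholds = np.asarray(thresholds, dtype=float)
    f1 = np.empty(len(thresholds))
    for i, t in enumerate(thresholds):
        tp = (pos >= t).sum()
        fp = (neg >= t).sum()
        fn = (pos < t).sum()
        denom = tp + 0.5 * (fp + fn)
        f1[i] = tp / denom if denom else 0.0
    best = thresholds[int(np.argmax(f1))]  # argmax returns first (lowest) on ties
    return float(best), thresholds, f1


def ranking_experiment(
    target: ScoredPair, decoys: Sequence[ScoredPair]
) -> tuple[int, Optional[float]]:
    """Rank of the target among its decoys, and its Z-score.

    rank = 1 + #{decoys strictly better} + floor(#{tied decoys} / 2);
    z = (target - mean(decoys)) / sd(decoys), None when sd is 0.
    """
    if not decoys:
        raise ValueError("need at least one decoy")
    d = np.array([s.score for s in decoys])
    greater = int((d > target.score).sum())
    tied = int((d == target.score).sum())
    rank = 1 + greater + tied // 2
    sd = float(d.std(ddof=1)) if len(d) > 1 else 0.0
    if np.all(d == d[0]):  # identical decoys: sd is 0 up to rounding
        sd = 0.0
    z = None if sd == 0 else float((target.score - d.mean()) / sd)
    return rank, z


def compare_metric_ranks(ranks_a: Sequence[int], ranks_b: Sequence[int]):
    """Two-sided Wilcoxon signed-rank p-value on paired rank lists.

    Returns ``(p, degenerate)``; ``degenerate`` is True when every paired
    difference is zero (p reported as 1).
    """
    a = np.asarray(ranks_a, dtype=float)
    b = np.asarray(ranks_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("rank lists must be paired (equal length)")
    diffs = a - b
    if np.all(diffs == 0):
        return 1.0, True
    if np.count_nonzero(diffs) < 5:
        raise DegenerateDataError("need at least 5 non-tied pairs")
    res = stats.wilcoxon(a, b, alternative="two-sided")
    return float(res.pvalue), False
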