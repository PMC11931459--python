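"""ROC/AUC, imbalance subsampling, recall-FDR curves, F1 scans, ranking."""

import itertools

import numpy as np
import pytest

from afmscreen.errors import DegenerateDataError
from afmscreen.evaluation import (
    ScoredPair,
    compare_metric_ranks,
    f1_scan,
    ranking_experiment,
    recall_at_fdr,
    recall_fdr_curve,
    roc_auc,
    subsample_np,
)


def sp(score, label, i=[0]):
    i[0] += 1
    return ScoredPair(f"p{i[0]}", float(score), label)


def brute_force_auc(pairs):
    pos = [p.score for p in pairs if p.label == "positive"]
    neg = [p.score for p in pairs if p.label == "negative"]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


def test_roc_auc_perfect_and_toy():
    perfect = [sp(1.0, "positive"), sp(0.9, "positive"), sp(0.1, "negative")]
    assert roc_auc(perfect) == 1.0
    toy = [sp(0.9, "positive"), sp(0.4, "positive"), sp(0.5, "negative"), sp(0.1, "negative")]
    assert roc_auc(toy) == 0.75  # one inversion among 2P x 2N
    with pytest.raises(DegenerateDataError):
        roc_auc([sp(0.5, "positive")])


def test_roc_auc_matches_brute_force_and_sklearn(rng):
    from sklearn.metrics import roc_auc_score

    for n in (4, 8, 12):
        pairs = [sp(float(rng.integers(0, 5)) / 4, "positive" if rng.random() < 0.5 else "negative")
                 for _ in range(n)]
        labels = {p.label for p in pairs}
        if labels != {"positive", "negative"}:
            continue
        got = roc_auc(pairs)
        assert got == pytest.approx(brute_force_auc(pairs))
        y = [1 if p.label == "positive" else 0 for p in pairs]
        assert got == pytest.approx(roc_auc_score(y, [p.score for p in pairs]))


def test_roc_auc_random_scores_near_half(rng):
    pairs = [sp(float(rng.random()), "positive") for _ in range(2000)]
    pairs += [sp(float(rng.random()), "negative") for _ in range(2000)]
    assert roc_auc(pairs) == pytest.approx(0.5, abs=0.03)


def test_subsample_ratios_and_determinism(rng):
    pos = [sp(1.0, "positive") for _ in range(714)]
    neg = [sp(0.0, "negative") for _ in range(800)]
    reps = subsample_np(pos + neg, 1, n_reps=3, seed=1)
    for rep in reps:
        labels = [p.label for p in rep]
        assert labels.count("positive") == 714 and labels.count("negative") == 714
    # negatives limit the ratio: all negatives, P = max(1, round(N/ratio))
    neg = [sp(0.0, "negative") for _ in range(2912)]
    pos = [sp(1.0, "positive") for _ in range(100)]
    reps = subsample_np(pos + neg, 128, n_reps=2, seed=2)
    for rep in reps:
        labels = [p.label for p in rep]
        assert labels.count("negative") == 2912
        assert labels.count("positive") == 23  # round(2912 / 128)
    a = subsample_np(pos + neg, 4, n_reps=2, seed=9)
    b = subsample_np(pos + neg, 4, n_reps=2, seed=9)
    assert [[p.pair_id for p in r] for r in a] == [[p.pair_id for p in r] for r in b]


def brute_force_curve(pairs, thresholds):
    pos = np.array([p.score for p in pairs if p.label == "positive"])
    neg = np.array([p.score for p in pairs if p.label == "negative"])
    rec, fdr = [], []
    for t in thresholds:
        tp = (pos >= t).sum()
        fp = (neg >= t).sum()
        rec.append(tp / len(pos))
        fdr.append(fp / (tp + fp) if tp + fp else 0.0)
    return np.array(rec), np.array(fdr)


def test_recall_fdr_curve_toy_matches_enumeration():
    pairs = [sp(s, "positive") for s in (0.9, 0.7, 0.4)] + [
        sp(s, "negative") for s in (0.8, 0.3, 0.1)
    ]
    curve = recall_fdr_curve([pairs])
    rec, fdr = brute_force_curve(pairs, curve.thresholds)
    assert np.allclose(curve.recall, rec)
    assert np.allclose(curve.fdr, fdr)
    # recall is non-increasing in threshold
    assert (np.diff(curve.recall) <= 1e-12).all()


def test_recall_fdr_degenerate_cases():
    perfect = [sp(1.0, "positive")] * 3 + [sp(0.0, "negative")] * 3
    c = recall_fdr_curve([perfect])
    assert recall_at_fdr(c, 0.05) == 1.0
    equal = [sp(0.5, "positive")] * 2 + [sp(0.5, "negative")] * 4
    c2 = recall_fdr_curve([equal])
    i = np.where(c2.thresholds == 0.5)[0][0]
    assert c2.recall[i] == 1.0
    assert c2.fdr[i] == pytest.approx(4 / 6)


def test_recall_at_fdr_none_meets_cap():
    # every threshold that captures anything has FDR 0.5
    pairs = [sp(0.9, "positive"), sp(0.9, "negative")]
    c = recall_fdr_curve([pairs])
    assert recall_at_fdr(c, 0.05) == 0.0


def test_f1_formula_and_enumeration():
    # TP=1, FP=1, FN=1 at threshold 0.5
    pairs = [sp(0.9, "positive"), sp(0.2, "positive"), sp(0.7, "negative")]
    _, thr, f1 = f1_scan(pairs, thresholds=[0.5])
    assert f1[0] == pytest.approx(0.5)
    perfect = [sp(0.9, "positive"), sp(0.1, "negative")]
    best, thr, f1 = f1_scan(perfect)
    assert f1.max() == 1.0
    # full scan equals brute force on a toy set
    pairs = [sp(s, "positive") for s in (0.9, 0.6, 0.3)] + [
        sp(s, "negative") for s in (0.7, 0.5, 0.2)
    ]
    best, thr, f1 = f1_scan(pairs)
    pos = [0.9, 0.6, 0.3]
    neg = [0.7, 0.5, 0.2]
    for t, v in zip(thr, f1):
        tp = sum(s >= t for s in pos)
        fp = sum(s >= t for s in neg)
        fn = sum(s < t for s in pos)
        assert v == pytest.approx(tp / (tp + 0.5 * (fp + fn)))
    assert best == thr[np.argmax(f1)]


def test_ranking_experiment_rules():
    decoys = [sp(float(s) / 1000, "negative") for s in range(1000)]
    top = ScoredPair("t", 2.0, "positive")
    rank, z = ranking_experiment(top, decoys)
    assert rank == 1 and z > 0
    # tie rule from the documented midrank convention
    t = ScoredPair("t", 0.9, "positive")
    d = [ScoredPair("a", 0.95, "negative"), ScoredPair("b", 0.9, "negative"),
         ScoredPair("c", 0.1, "negative")]
    rank, z = ranking_experiment(t, d)
    assert rank == 2
    # z = 0 when the target equals the decoy mean
    t2 = ScoredPair("t", 0.5, "positive")
    d2 = [ScoredPair("a", 0.4, "negative"), ScoredPair("b", 0.6, "negative")]
    _, z2 = ranking_experiment(t2, d2)
    assert z2 == pytest.approx(0.0)
    # sd 0 -> z absent
    _, z3 = ranking_experiment(t2, [ScoredPair("a", 0.4, "negative")] * 3)
    assert z3 is None
    rank4, _ = ranking_experiment(ScoredPair("t", -1.0, "positive"), d2)
    assert 1 <= rank4 <= 1 + len(d2)


def test_compare_metric_ranks():
    p, degenerate = compare_metric_ranks([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
    assert p == 1.0 and degenerate
    a = list(range(1, 31))
    b = [x + 1 + (x % 3) for x in a]  # b always worse by >= 1
    p, degenerate = compare_metric_ranks(a, b)
    assert p < 0.01 and not degenerate
    p2, _ = compare_metric_ranks(b, a)
    assert p2 == pytest.approx(p)


def test_recall_invariant_fdr_monotone_in_ratio(rng):
    """Mirrors the qualitative imbalance behavior: at a fixed threshold,
    recall does not depend on the N:P ratio while FDR rises with it."""
    pos = [sp(float(x), "positive") for x in rng.normal(1.5, 1, 200)]
    neg = [sp(float(x), "negative") for x in rng.normal(0, 1, 3000)]
    t = 1.0
    recalls, fdrs = [], []
    for ratio in (1, 4, 16, 64, 128):
        reps = subsample_np(pos + neg, ratio, n_reps=10, seed=100 + ratio)
        curve = recall_fdr_curve(reps, ratio)
        i = int(np.searchsorted(curve.thresholds, t))
        recalls.append(curve.recall[i])
        fdrs.append(curve.fdr[i])
    assert max(recalls) - min(recalls) < 0.1
    assert all(b >= a - 0.02 for a, b in zip(fdrs, fdrs[1:]))
    assert fdrs[-1] > fdrs[0]
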