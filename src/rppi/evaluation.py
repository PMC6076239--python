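"""Prevalence-corrected precision-recall / ROC evaluation and significance tests.

The test sets used for cross-validation are artificially balanced, while a
real interactome is heavily imbalanced (roughly one true interaction per
hundred candidate pairs).  Precision is therefore recomputed from the
estimated sensitivity and specificity for an assumed negative:positive
ratio r:

    precision = Sn / (Sn + r * (1 - Sp))

with r = 100 by default.  Bootstrap resampling with per-iteration
retraining yields AUC distributions whose difference between conditions is
tested with Welch's unequal-variances t-test; a permutation test quantifies
the (small) effect of the arbitrary pair orientation on canonical-mode
features.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import classifier as clf
from . import features as ft
from .curves import KneeEstimate
from .matrix import GlobalThreshold, LabelSet, ScoreMatrix

DEFAULT_PREVALENCE_RATIO = 100.0


@dataclass
class EvaluationReport:
    """Curve point sets and AUC summaries for one condition."""

    condition: str
    prc_points: np.ndarray  # columns (recall, corrected precision)
    roc_points: np.ndarray  # columns (1 - Sp, Sn)
    prc_auc: float
    roc_auc: float
    r: float


@dataclass
class BootstrapResult:
    """Per-iteration AUCs for two conditions plus a Welch comparison."""

    condition_a: str
    condition_b: str
    prc_auc_a: np.ndarray
    prc_auc_b: np.ndarray
    roc_auc_a: np.ndarray
    roc_auc_b: np.ndarray
    welch_prc: tuple[float, float, float]  # (t, df, p)
    welch_roc: tuple[float, float, float]

    @property
    def iterations(self) -> int:
        return len(self.prc_auc_a)

    def summary(self) -> pd.DataFrame:
        """mu +- SE rows per condition and metric (SE = SD / sqrt(iterations))."""
        rows = []
        for cond, prc, roc in (
            (self.condition_a, self.prc_auc_a, self.roc_auc_a),
            (self.condition_b, self.prc_auc_b, self.roc_auc_b),
        ):
            rows.append(
                {
                    "condition": cond,
                    "prc_auc_mean": float(np.mean(prc)),
                    "prc_auc_se": float(np.std(prc, ddof=1) / np.sqrt(len(prc))),
                    "roc_auc_mean": float(np.mean(roc)),
                    "roc_auc_se": float(np.std(roc, ddof=1) / np.sqrt(len(roc))),
                }
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# confusion counts and corrected precision
# ---------------------------------------------------------------------------

def confusion_at_threshold(
    confidences: Sequence[float], labels: Sequence[int], threshold: float
) -> tuple[int, int, int, int]:
    """(TP, FP, TN, FN) with confidence >= threshold predicted positive."""
    c = np.asarray(confidences, dtype=float)
    y = np.asarray(labels, dtype=int)
    if c.size == 0:
        raise ValueError("empty input")
    if c.shape != y.shape:
        raise ValueError("confidences and labels must have equal length")
    pred = c >= threshold
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    tn = int(np.sum(~pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    return tp, fp, tn, fn


def corrected_precision(
    sn: float, sp: float, r: float = DEFAULT_PREVALENCE_RATIO
) -> float:
    """Prevalence-corrected precision Sn / (Sn + r*(1 - Sp)).

    At Sn = 0, Sp = 1 (nothing predicted positive) the value is 1 by
    convention: no predicted positive is wrong in the limit.
    """
    if not (0.0 <= sn <= 1.0 and 0.0 <= sp <= 1.0):
        raise ValueError("sensitivity and specificity must be in [0, 1]")
    if r <= 0:
        raise ValueError("prevalence ratio r must be positive")
    denom = sn + r * (1.0 - sp)
    if denom == 0.0:
        return 1.0
    return sn / denom


def _sweep(confidences, labels) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sn and Sp at every distinct confidence threshold, descending."""
    c = np.asarray(confidences, dtype=float)
    y = np.asarray(labels, dtype=int)
    if c.size == 0:
        raise ValueError("empty input")
    pos = int((y == 1).sum())
    neg = int((y == 0).sum())
    if pos == 0 or neg == 0:
        raise ValueError("both classes must be present")
    order = np.argsort(-c, kind="stable")
    cs, ys = c[order], y[order]
    # last index of each distinct threshold value
    last = np.flatnonzero(np.diff(cs) != 0)
    cut = np.concatenate([last, [cs.size - 1]])
    tps = np.cumsum(ys == 1)[cut]
    fps = np.cumsum(ys == 0)[cut]
    sn = tps / pos
    sp = 1.0 - fps / neg
    return cs[cut], sn, sp


def prc_curve(
    confidences, labels, r: float = DEFAULT_PREVALENCE_RATIO, condition: str = ""
) -> EvaluationReport:
    """Prevalence-corrected precision-recall curve and trapezoidal AUC.

    All distinct thresholds are swept descending; the precision at recall 0
    is carried from the highest-threshold point so recall spans [0, 1].
    """
    _, sn, sp = _sweep(confidences, labels)
    prec = np.array([corrected_precision(s, p, r) for s, p in zip(sn, sp)])
    recall = np.concatenate([[0.0], sn])
    precision = np.concatenate([[prec[0]], prec])
    prc_auc = float(np.trapezoid(precision, recall))
    roc = roc_curve(confidences, labels)
    return EvaluationReport(
        condition=condition,
        prc_points=np.column_stack([recall, precision]),
        roc_points=roc[0],
        prc_auc=prc_auc,
        roc_auc=roc[1],
        r=r,
    )


def roc_curve(confidences, labels) -> tuple[np.ndarray, float]:
    """ROC points (1-Sp, Sn) and trapezoidal AUC.

    With distinct-threshold grouping the trapezoid equals the probability
    that a random positive outranks a random negative, ties counting 1/2.
    """
    _, sn, sp = _sweep(confidences, labels)
    fpr = np.concatenate([[0.0], 1.0 - sp])
    tpr = np.concatenate([[0.0], sn])
    return np.column_stack([fpr, tpr]), float(np.trapezoid(tpr, fpr))


def f1_and_accuracy(confidences, labels, threshold: float = 0.5) -> tuple[float, float]:
    """F1 and accuracy at a fixed confidence threshold."""
    tp, fp, tn, fn = confusion_at_threshold(confidences, labels, threshold)
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
    acc = (tp + tn) / (tp + fp + tn + fn)
    return f1, acc


def welch_t_test(sample_a, sample_b) -> tuple[float, float, float]:
    """Welch's unequal-variances t-test: (t, Welch-Satterthwaite df, two-sided p)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 values")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, float(a.size + b.size - 2), 1.0
        raise ValueError("both samples have zero variance with unequal means")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


# ---------------------------------------------------------------------------
# condition evaluation and bootstrap comparison
# ---------------------------------------------------------------------------

def evaluate_condition(
    dataset: clf.LabeledDataset,
    condition: str,
    t: int = 100,
    seed: int = 0,
    r: float = DEFAULT_PREVALENCE_RATIO,
) -> EvaluationReport:
    """Out-of-fold PRC/ROC evaluation of one ablation condition."""
    conf = clf.train_and_score(dataset, condition=condition, t=t, seed=seed)
    return prc_curve(conf, dataset.labels, r=r, condition=condition)


def bootstrap_compare(
    matrix: ScoreMatrix,
    positives: LabelSet,
    knees: Mapping[str, KneeEstimate],
    global_t: GlobalThreshold,
    condition_a: str = "original",
    condition_b: str = "rp-enhanced",
    iterations: int = 1000,
    seed: int = 0,
    t: int = 100,
    k: int = 5,
    r: float = DEFAULT_PREVALENCE_RATIO,
    subsample: float = 0.8,
    symmetric_mode: bool = False,
) -> BootstrapResult:
    """Bootstrap AUC distributions for two conditions with per-iteration retraining.

    Each iteration draws ``subsample`` of the positives without replacement
    plus a fresh balanced negative sample, reruns the full cross-validated
    training for both conditions, and records out-of-fold PRC/ROC AUCs.
    The two AUC samples are compared with Welch's t-test.
    """
    if iterations < 2:
        raise ValueError("need at least 2 bootstrap iterations")
    full = ft.full_pair_table(matrix, knees, global_t, symmetric_mode=symmetric_mode)
    pos_all = [ft.canonical_pair(*p) for p in positives]
    rng = np.random.default_rng(seed)
    n_take = max(2 * k, int(round(subsample * len(pos_all))))
    n_take = min(n_take, len(pos_all))
    acc = {"a": {"prc": [], "roc": []}, "b": {"prc": [], "roc": []}}
    for it in range(iterations):
        pick = rng.choice(len(pos_all), size=n_take, replace=False)
        pos_iter = [pos_all[i] for i in sorted(pick)]
        it_seed = int(rng.integers(2**31 - 1))
        dataset = clf.build_dataset(
            matrix,
            LabelSet(pos_iter),
            knees,
            global_t,
            seed=it_seed,
            k=k,
            symmetric_mode=symmetric_mode,
            feature_table=full,
        )
        for key, cond in (("a", condition_a), ("b", condition_b)):
            rep = evaluate_condition(dataset, cond, t=t, seed=it_seed, r=r)
            acc[key]["prc"].append(rep.prc_auc)
            acc[key]["roc"].append(rep.roc_auc)
    prc_a = np.array(acc["a"]["prc"])
    prc_b = np.array(acc["b"]["prc"])
    roc_a = np.array(acc["a"]["roc"])
    roc_b = np.array(acc["b"]["roc"])
    return BootstrapResult(
        condition_a=condition_a,
        condition_b=condition_b,
        prc_auc_a=prc_a,
        prc_auc_b=prc_b,
        roc_auc_a=roc_a,
        roc_auc_b=roc_b,
        welch_prc=welch_t_test(prc_a, prc_b),
        welch_roc=welch_t_test(roc_a, roc_b),
    )


# ---------------------------------------------------------------------------
# orientation-symmetry permutation test
# ---------------------------------------------------------------------------

def _swap_orientation(table: pd.DataFrame, rows: np.ndarray) -> pd.DataFrame:
    """Swap complementary X/Y columns for the selected rows (canonical tables)."""
    out = table.copy()
    for col_x, col_y, _ in ft.SYMMETRIC_PAIRS:
        if col_x in out.columns and col_y in out.columns:
            a = out[col_x].to_numpy().copy()
            b = out[col_y].to_numpy().copy()
            out.loc[rows, col_x] = b[rows]
            out.loc[rows, col_y] = a[rows]
    return out


def symmetry_permutation_test(
    matrix: ScoreMatrix,
    positives: LabelSet,
    knees: Mapping[str, KneeEstimate],
    global_t: GlobalThreshold,
    condition: str = "rp-enhanced",
    iterations: int = 1000,
    seed: int = 0,
    t: int = 100,
    k: int = 5,
    r: float = DEFAULT_PREVALENCE_RATIO,
    symmetric_mode: bool = False,
) -> pd.DataFrame:
    """Effect of arbitrary pair orientation on downstream metrics.

    Each iteration flips the orientation of a random half of the rows'
    features, retrains with identical folds/seed, and records the percent
    difference from the canonical run in ROC-AUC, PRC-AUC, F1 (confidence
    0.5) and accuracy.  Returns mean and max percent difference per metric.
    In symmetric mode flipping is a no-op and all differences are exactly 0.
    """
    dataset = clf.build_dataset(
        matrix, positives, knees, global_t, seed=seed, k=k, symmetric_mode=symmetric_mode
    )
    conf0 = clf.train_and_score(dataset, condition=condition, t=t, seed=seed)
    rep0 = prc_curve(conf0, dataset.labels, r=r)
    f1_0, acc0 = f1_and_accuracy(conf0, dataset.labels)
    base = {"roc_auc": rep0.roc_auc, "prc_auc": rep0.prc_auc, "f1": f1_0, "accuracy": acc0}
    rng = np.random.default_rng(seed)
    diffs: dict[str, list[float]] = {m: [] for m in base}
    for _ in range(iterations):
        flip_rows = rng.random(len(dataset.table)) < 0.5
        flipped = clf.LabeledDataset(
            table=_swap_orientation(dataset.table, flip_rows),
            labels=dataset.labels,
            folds=dataset.folds,
            seed=dataset.seed,
        )
        conf = clf.train_and_score(flipped, condition=condition, t=t, seed=seed)
        rep = prc_curve(conf, dataset.labels, r=r)
        f1, acc = f1_and_accuracy(conf, dataset.labels)
        vals = {"roc_auc": rep.roc_auc, "prc_auc": rep.prc_auc, "f1": f1, "accuracy": acc}
        for metric, v in vals.items():
            ref = base[metric]
            diffs[metric].append(100.0 * abs(v - ref) / ref if ref else 0.0)
    return pd.DataFrame(
        {
            "metric": list(base),
            "baseline": [base[m] for m in base],
            "mean_pct_diff": [float(np.mean(diffs[m])) for m in base],
            "max_pct_diff": [float(np.max(diffs[m])) for m in base],
        }
    )


def write_report_points(report: EvaluationReport, path) -> None:
    """TSV of PRC and ROC points for one condition."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#curve\tx\ty\n")
        for x, y in report.prc_points:
            fh.write(f"prc\t{x:.10g}\t{y:.10g}\n")
        for x, y in report.roc_points:
            fh.write(f"roc\t{x:.10g}\t{y:.10g}\n")
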