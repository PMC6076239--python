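import numpy as np
import pytest
from scipy import stats

from rppi import evaluation as ev
from rppi.classifier import build_dataset
from rppi.curves import compute_knees
from rppi.matrix import LabelSet, threshold_at_specificity
from rppi.simulate import SyntheticConfig, generate_interactome


def mw_auc(confidences, labels):
    """Mann-Whitney pair-counting oracle: P(pos > neg) + 0.5 P(tie)."""
    c = np.asarray(confidences, dtype=float)
    y = np.asarray(labels, dtype=int)
    pos, neg = c[y == 1], c[y == 0]
    wins = ties = 0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1
            elif p == q:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestConfusion:
    def test_perfect_classifier(self):
        conf = [1.0] * 5 + [0.0] * 5
        labels = [1] * 5 + [0] * 5
        tp, fp, tn, fn = ev.confusion_at_threshold(conf, labels, 0.5)
        assert (tp, fp, tn, fn) == (5, 0, 5, 0)

    def test_threshold_above_max(self):
        tp, fp, tn, fn = ev.confusion_at_threshold([0.2, 0.8], [1, 0], 0.9)
        assert tp == 0 and fp == 0 and tn == 1 and fn == 1

    def test_matches_brute_force_loop(self):
        rng = np.random.default_rng(7)
        conf = rng.random(20)
        labels = rng.integers(0, 2, 20)
        labels[0], labels[1] = 1, 0  # both classes present
        for thr in np.concatenate([conf, [0.0, 0.5, 1.1]]):
            tp = sum(1 for c, y in zip(conf, labels) if c >= thr and y == 1)
            fp = sum(1 for c, y in zip(conf, labels) if c >= thr and y == 0)
            tn = sum(1 for c, y in zip(conf, labels) if c < thr and y == 0)
            fn = sum(1 for c, y in zip(conf, labels) if c < thr and y == 1)
            assert ev.confusion_at_threshold(conf, labels, thr) == (tp, fp, tn, fn)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            ev.confusion_at_threshold([], [], 0.5)


class TestCorrectedPrecision:
    def test_perfect_case_any_ratio(self):
        for r in (1.0, 100.0):
            assert ev.corrected_precision(1.0, 1.0, r) == 1.0

    def test_operating_point_value(self):
        assert ev.corrected_precision(0.5, 0.9995, 100.0) == pytest.approx(
            0.9091, abs=1e-4
        )

    def test_chance_level(self):
        assert ev.corrected_precision(0.5, 0.5, 100.0) == pytest.approx(
            0.5 / 50.5, abs=1e-6
        )

    def test_empty_positive_limit(self):
        assert ev.corrected_precision(0.0, 1.0, 100.0) == 1.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ev.corrected_precision(1.2, 0.5)
        with pytest.raises(ValueError):
            ev.corrected_precision(0.5, 0.5, r=0.0)

    def test_r_one_equals_empirical_precision_on_balanced_fixture(self):
        rng = np.random.default_rng(11)
        conf = rng.random(60)
        labels = np.array([1, 0] * 30)
        thresholds, sn, sp = ev._sweep(conf, labels)
        for thr, s, p in zip(thresholds, sn, sp):
            tp, fp, _, _ = ev.confusion_at_threshold(conf, labels, thr)
            assert ev.corrected_precision(s, p, r=1.0) == pytest.approx(
                tp / (tp + fp)
            )


class TestCurves:
    def test_perfect_separation_prc_auc_one(self):
        conf = [0.9, 0.8, 0.7, 0.2, 0.1, 0.0]
        labels = [1, 1, 1, 0, 0, 0]
        rep = ev.prc_curve(conf, labels)
        assert rep.prc_auc == pytest.approx(1.0)

    def test_label_independent_scores_give_chance_precision(self):
        rng = np.random.default_rng(5)
        n = 3000
        conf = rng.random(n)
        labels = np.array([1, 0] * (n // 2))
        rep = ev.prc_curve(conf, labels, r=100.0)
        interior = rep.prc_points[
            (rep.prc_points[:, 0] > 0.2) & (rep.prc_points[:, 0] < 0.8)
        ]
        assert np.median(interior[:, 1]) == pytest.approx(1 / 101, rel=0.5)

    def test_prc_auc_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(3)
        conf = np.round(rng.random(20), 2)
        labels = rng.integers(0, 2, 20)
        labels[:2] = [1, 0]
        rep = ev.prc_curve(conf, labels, r=10.0)
        # oracle: enumerate every distinct threshold directly
        pts = []
        pos, neg = (labels == 1).sum(), (labels == 0).sum()
        for thr in sorted(set(conf), reverse=True):
            tp, fp, tn, fn = ev.confusion_at_threshold(conf, labels, thr)
            pts.append((tp / pos, ev.corrected_precision(tp / pos, tn / neg, 10.0)))
        recall = np.array([0.0] + [p[0] for p in pts])
        prec = np.array([pts[0][1]] + [p[1] for p in pts])
        assert rep.prc_auc == pytest.approx(np.trapezoid(prec, recall))

    def test_recall_spans_unit_interval(self):
        rng = np.random.default_rng(9)
        conf = rng.random(40)
        labels = rng.integers(0, 2, 40)
        labels[:2] = [1, 0]
        rep = ev.prc_curve(conf, labels)
        assert rep.prc_points[0, 0] == 0.0
        assert rep.prc_points[-1, 0] == 1.0
        assert np.all(np.diff(rep.prc_points[:, 0]) >= 0)
        assert np.all((rep.prc_points[:, 1] >= 0) & (rep.prc_points[:, 1] <= 1))

    def test_roc_perfect_and_anti_perfect(self):
        labels = [1, 1, 0, 0]
        assert ev.roc_curve([0.9, 0.8, 0.2, 0.1], labels)[1] == 1.0
        assert ev.roc_curve([0.1, 0.2, 0.8, 0.9], labels)[1] == 0.0

    def test_roc_auc_equals_pair_counting_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            n = int(rng.integers(10, 31))
            conf = np.round(rng.random(n), 1)  # force ties
            labels = rng.integers(0, 2, n)
            labels[:2] = [1, 0]
            assert ev.roc_curve(conf, labels)[1] == pytest.approx(
                mw_auc(conf, labels), abs=1e-12
            )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            ev.roc_curve([0.1, 0.2], [1, 1])


class TestWelch:
    def test_identical_constant_samples(self):
        t, df, p = ev.welch_t_test([1.0, 1.0, 1.0], [1.0, 1.0])
        assert t == 0.0 and p == 1.0

    def test_textbook_hand_computation(self):
        a, b = [1.0, 2.0, 3.0], [1.0, 2.0, 3.0, 4.0, 5.0]
        t, df, p = ev.welch_t_test(a, b)
        # independent reference: Welch formulas + t distribution
        va, vb = np.var(a, ddof=1) / 3, np.var(b, ddof=1) / 5
        t_ref = (np.mean(a) - np.mean(b)) / np.sqrt(va + vb)
        df_ref = (va + vb) ** 2 / (va**2 / 2 + vb**2 / 4)
        p_ref = 2 * stats.t.sf(abs(t_ref), df_ref)
        assert t == pytest.approx(t_ref)
        assert df == pytest.approx(df_ref)
        assert p == pytest.approx(p_ref)

    def test_separated_samples_tiny_p(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 30)
        b = rng.normal(5, 1, 30)
        assert ev.welch_t_test(a, b)[2] < 1e-6

    def test_tiny_samples_rejected(self):
        with pytest.raises(ValueError):
            ev.welch_t_test([1.0], [1.0, 2.0])


@pytest.fixture(scope="module")
def tiny_pipeline():
    cfg = SyntheticConfig(n_proteins=50, prevalence=0.05, seed=23)
    matrix, truth = generate_interactome(cfg)
    knees = compute_knees(matrix)
    neg = [s for a, b, s in matrix.iter_pairs() if (a, b) not in truth.positives]
    gt = threshold_at_specificity(neg, 0.9995)
    return matrix, truth, knees, gt


class TestBootstrap:
    def test_null_self_comparison_not_significant(self, tiny_pipeline):
        matrix, truth, knees, gt = tiny_pipeline
        res = ev.bootstrap_compare(
            matrix, truth.positives, knees, gt,
            condition_a="original", condition_b="original",
            iterations=20, seed=1, t=25, k=3,
        )
        assert res.welch_prc[2] > 0.001
        assert res.iterations == 20

    def test_summary_reports_mean_and_se(self, tiny_pipeline):
        matrix, truth, knees, gt = tiny_pipeline
        res = ev.bootstrap_compare(
            matrix, truth.positives, knees, gt,
            iterations=8, seed=2, t=15, k=3,
        )
        summ = res.summary()
        assert list(summ["condition"]) == ["original", "rp-enhanced"]
        expected_se = np.std(res.prc_auc_a, ddof=1) / np.sqrt(8)
        assert summ["prc_auc_se"][0] == pytest.approx(expected_se)

    def test_se_shrinks_with_iterations(self, tiny_pipeline):
        matrix, truth, knees, gt = tiny_pipeline
        ses = []
        for iters in (10, 40, 160):
            res = ev.bootstrap_compare(
                matrix, truth.positives, knees, gt,
                condition_a="original", condition_b="original",
                iterations=iters, seed=3, t=10, k=3,
            )
            ses.append(float(np.std(res.prc_auc_a, ddof=1) / np.sqrt(iters)))
        assert ses[0] > ses[1] > ses[2]
        assert 2.0 < ses[0] / ses[2] < 8.0  # ~4 expected for 16x iterations

    def test_deterministic_under_seed(self, tiny_pipeline):
        matrix, truth, knees, gt = tiny_pipeline
        r1 = ev.bootstrap_compare(matrix, truth.positives, knees, gt,
                                  iterations=4, seed=5, t=10, k=3)
        r2 = ev.bootstrap_compare(matrix, truth.positives, knees, gt,
                                  iterations=4, seed=5, t=10, k=3)
        assert np.array_equal(r1.prc_auc_b, r2.prc_auc_b)

    def test_too_few_iterations_rejected(self, tiny_pipeline):
        matrix, truth, knees, gt = tiny_pipeline
        with pytest.raises(ValueError):
            ev.bootstrap_compare(matrix, truth.positives, knees, gt, iterations=1)


class TestSymmetryPermutation:
    def test_symmetric_mode_differences_exactly_zero(self, tiny_pipeline):
        matrix, truth, knees, gt = tiny_pipeline
        out = ev.symmetry_permutation_test(
            matrix, truth.positives, knees, gt,
            iterations=3, seed=4, t=15, k=3, symmetric_mode=True,
        )
        assert (out["mean_pct_diff"] == 0.0).all()
        assert (out["max_pct_diff"] == 0.0).all()

    def test_canonical_mode_smoke_and_determinism(self, tiny_pipeline):
        matrix, truth, knees, gt = tiny_pipeline
        a = ev.symmetry_permutation_test(
            matrix, truth.positives, knees, gt,
            iterations=4, seed=6, t=15, k=3,
        )
        b = ev.symmetry_permutation_test(
            matrix, truth.positives, knees, gt,
            iterations=4, seed=6, t=15, k=3,
        )
        assert set(a["metric"]) == {"roc_auc", "prc_auc", "f1", "accuracy"}
        assert (a["max_pct_diff"] >= a["mean_pct_diff"] - 1e-12).all()
        assert np.allclose(a["mean_pct_diff"], b["mean_pct_diff"])
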