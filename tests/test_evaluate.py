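import numpy as np
import pytest

from helpers import auprc_brute, auroc_brute, best_specificity_at_sensitivity_brute
from notecast.evaluate import (
    auroc,
    bootstrap_evaluate,
    brier,
    brier_skill,
    calibration_curve,
    pr_curve_and_auprc,
    specificity_at,
    threshold_for_sensitivity,
)


class TestAuroc:
    def test_hand_traced_four_point_example(self):
        assert auroc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)

    def test_perfect_separation(self):
        assert auroc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_label_independent_scores_sit_at_chance(self, rng):
        s = rng.random(10_000)
        y = rng.random(10_000) < 0.3
        assert auroc(s, y) == pytest.approx(0.5, abs=0.02)

    def test_ties_count_one_half(self):
        assert auroc([0.5, 0.5], [0, 1]) == 0.5

    def test_invariant_under_strictly_increasing_transforms(self, rng):
        s = rng.random(200)
        y = rng.random(200) < 0.4
        base = auroc(s, y)
        for f in (lambda x: 3 * x + 1, np.exp, lambda x: x**3):
            assert auroc(f(s), y) == pytest.approx(base, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auroc([0.1, 0.2], [1, 1])


class TestPrCurve:
    def test_perfect_classifier_has_unit_area(self):
        c = pr_curve_and_auprc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert c.auprc == 1.0

    def test_random_scores_converge_to_prevalence(self, rng):
        n, q = 20_000, 0.05
        y = rng.random(n) < q
        c = pr_curve_and_auprc(rng.random(n), y)
        assert c.auprc == pytest.approx(q, abs=0.01)

    def test_six_point_set_matches_exhaustive_enumeration(self):
        s = [0.9, 0.7, 0.7, 0.4, 0.2, 0.1]
        y = [1, 0, 1, 0, 1, 0]
        c = pr_curve_and_auprc(s, y)
        assert c.auprc == pytest.approx(auprc_brute(s, y), abs=1e-12)

    def test_threshold_annotations_report_precision_and_recall(self):
        c = pr_curve_and_auprc([0.9, 0.8, 0.3, 0.1], [1, 0, 1, 0],
                               annotate_thresholds=[0.5])
        thr, prec, rec = c.annotations[0]
        assert (thr, prec, rec) == (0.5, 0.5, 0.5)

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError):
            pr_curve_and_auprc([0.1, 0.2], [0, 0])


class TestSensitivityConstrainedThreshold:
    def test_hand_traced_example(self):
        s = [0.9, 0.8, 0.2, 0.5, 0.1]
        y = [1, 1, 1, 0, 0]
        tau = threshold_for_sensitivity(s, y, 0.95)
        assert tau == 0.2
        assert specificity_at(s, y, tau) == 0.5

    def test_perfectly_separated_scores_reach_full_specificity(self):
        s, y = [0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]
        tau = threshold_for_sensitivity(s, y, 0.95)
        assert specificity_at(s, y, tau) == 1.0

    def test_vacuous_constraint_puts_threshold_above_all_scores(self):
        s, y = [0.3, 0.6, 0.7], [0, 1, 0]
        tau = threshold_for_sensitivity(s, y, 0.0)
        assert tau > max(s)
        assert specificity_at(s, y, tau) == 1.0

    @pytest.mark.parametrize("min_sens", [0.5, 0.8, 0.95, 1.0])
    def test_matches_exhaustive_enumeration_on_random_sets(self, rng, min_sens):
        for _ in range(30):
            n = int(rng.integers(5, 40))
            s = np.round(rng.random(n), 2)  # coarse grid forces ties
            y = (rng.random(n) < 0.4).astype(int)
            if y.sum() in (0, n):
                continue
            tau = threshold_for_sensitivity(s, y, min_sens)
            sens = np.mean(s[y == 1] >= tau)
            assert sens >= min_sens
            assert specificity_at(s, y, tau) == pytest.approx(
                best_specificity_at_sensitivity_brute(s, y, min_sens), abs=1e-12
            )


class TestBrier:
    def test_perfect_hard_predictions_score_zero(self):
        assert brier([0.0, 1.0, 1.0], [0, 1, 1]) == 0.0

    def test_constant_predictor_matches_closed_form(self, rng):
        q = p = 0.0089
        n = 200_000
        y = rng.random(n) < q
        expected = q * (1 - p) ** 2 + (1 - q) * p**2  # = 0.008742...
        # empirical prevalence fluctuates with sd ~2e-4 at this n
        assert brier(np.full(n, p), y) == pytest.approx(expected, abs=1e-3)

    def test_probabilities_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            brier([1.2], [1])

    def test_skill_score_examples(self):
        assert brier_skill(0.01, 0.01) == 0.0
        assert brier_skill(0.0, 0.01) == 1.0
        assert brier_skill(0.0089, 0.0178) == pytest.approx(0.5)
        with pytest.raises(ValueError):
            brier_skill(0.01, 0.0)


class TestCalibration:
    def test_constant_predictor_collapses_to_observed_rate(self, rng):
        n, q = 5000, 0.3
        y = rng.random(n) < q
        curve = calibration_curve(np.full(n, 0.3), y)
        assert np.allclose(curve.predicted, 0.3)
        assert np.allclose(curve.observed, y.mean(), atol=1e-9)

    def test_marker_is_empirical_99th_percentile(self, rng):
        p = rng.random(500)
        y = rng.random(500) < p
        curve = calibration_curve(p, y)
        assert curve.percentile_99 == np.percentile(p, 99)

    def test_too_few_observations_rejected(self, rng):
        with pytest.raises(ValueError):
            calibration_curve(rng.random(10), np.zeros(10))


class TestBootstrap:
    def test_identical_models_have_exactly_zero_paired_differences(self, rng):
        s = rng.random(300)
        y = (rng.random(300) < 0.2).astype(int)
        _, comp = bootstrap_evaluate({"A": s, "B": s.copy()}, y, n_boot=100, seed=3)
        c = comp[("A", "B")]
        assert np.all(c.differences == 0.0)
        assert (c.ci_low, c.ci_high) == (0.0, 0.0)
        assert not c.significant

    def test_strongly_separated_models_differ_significantly(self, rng):
        n = 2000
        y = (rng.random(n) < 0.1).astype(int)
        noise = rng.random(n)
        good = 0.8 * y + 0.2 * noise  # AUROC ~0.95
        rand = rng.random(n)
        summ, comp = bootstrap_evaluate({"good": good, "rand": rand}, y,
                                        n_boot=1000, seed=4)
        c = comp[("good", "rand")]
        assert c.significant and c.ci_low > 0
        assert summ["good"]["auroc"].median > 0.9
        assert summ["rand"]["auroc"].median == pytest.approx(0.5, abs=0.05)

    def test_medians_fall_inside_their_own_intervals(self, rng):
        n = 500
        y = (rng.random(n) < 0.15).astype(int)
        s = 0.5 * y + 0.5 * rng.random(n)
        summ, _ = bootstrap_evaluate({"m": s}, y, n_boot=200, seed=5)
        for ms in summ["m"].values():
            assert ms.ci_low <= ms.median <= ms.ci_high

    def test_single_case_test_set_still_completes_via_redraws(self, rng):
        y = np.zeros(40, dtype=int)
        y[0] = 1
        s = rng.random(40)
        summ, _ = bootstrap_evaluate({"m": s}, y, n_boot=50, seed=6)
        assert np.isfinite(summ["m"]["auroc"].median)

    def test_deterministic_given_seed(self, rng):
        y = (rng.random(200) < 0.2).astype(int)
        s = rng.random(200)
        a, _ = bootstrap_evaluate({"m": s}, y, n_boot=50, seed=7)
        b, _ = bootstrap_evaluate({"m": s}, y, n_boot=50, seed=7)
        assert a["m"]["auroc"].median == b["m"]["auroc"].median


def test_metrics_agree_with_sklearn_reference(rng):
    from sklearn.metrics import average_precision_score, roc_auc_score

    for _ in range(10):
        n = 300
        s = rng.random(n)
        y = (rng.random(n) < 0.3).astype(int)
        assert auroc(s, y) == pytest.approx(roc_auc_score(y, s), abs=1e-12)
        assert pr_curve_and_auprc(s, y).auprc == pytest.approx(
            average_precision_score(y, s), abs=1e-12
        )
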