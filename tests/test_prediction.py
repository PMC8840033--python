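"""Logistic fitting, AUC/ROC machinery, DeLong inference, Youden cutoffs."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats
from sklearn.metrics import roc_auc_score

import leaktraj as lt
from leaktraj.prediction import ConfusionTable, _delong_variance


def brute_force_auc(scores, labels):
    """Independent oracle: enumerate every (positive, negative) pair."""
    scores = np.asarray(scores, float)
    pos = scores[np.asarray(labels) == 1]
    neg = scores[np.asarray(labels) == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def random_fixture(rng, max_n=30):
    """Scores with deliberate ties and at least one patient per class."""
    n = int(rng.integers(4, max_n + 1))
    scores = rng.integers(0, 8, size=n).astype(float)  # coarse grid => ties
    labels = rng.integers(0, 2, size=n)
    labels[0], labels[1] = 0, 1
    return scores, labels


class TestLogisticFit:
    def test_symmetric_design_zero_intercept(self):
        x = np.array([-1.0, 1.0, -1.0, 1.0, -1.0, 1.0])
        y = np.array([0, 1, 0, 1, 1, 0])
        model = lt.fit_logistic(x[:, None], y)
        assert model.converged
        assert model.intercept == pytest.approx(0.0, abs=1e-6)

    def test_matches_grid_search_mle(self):
        x = np.array([-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0, 3.0])
        y = np.array([0, 0, 1, 0, 1, 0, 1, 1])
        model = lt.fit_logistic(x[:, None], y)

        # oracle: nested refinement of a direct log-likelihood grid search
        b0, b1, w = 0.0, 0.0, 4.0
        for _ in range(5):
            b0s = np.linspace(b0 - w, b0 + w, 81)
            b1s = np.linspace(b1 - w, b1 + w, 81)
            ll = np.array(
                [
                    [
                        float(y @ (a + b * x) - np.logaddexp(0, a + b * x).sum())
                        for b in b1s
                    ]
                    for a in b0s
                ]
            )
            i, j = np.unravel_index(np.argmax(ll), ll.shape)
            b0, b1 = b0s[i], b1s[j]
            w = 4 * w / 80
        assert model.coef[0] == pytest.approx(b0, abs=1e-3)
        assert model.coef[1] == pytest.approx(b1, abs=1e-3)
        assert model.loglik == pytest.approx(ll[i, j], abs=1e-6)

    def test_single_class_rejected(self):
        with pytest.raises(lt.SingleClassError):
            lt.fit_logistic(np.arange(4.0)[:, None], np.zeros(4))

    def test_perfect_separation_flagged(self):
        x = np.array([-2.0, -1.0, 1.0, 2.0])
        y = np.array([0, 0, 1, 1])
        with pytest.warns(UserWarning, match="separation"):
            model = lt.fit_logistic(x[:, None], y)
        assert not model.converged

    def test_ridge_penalty_stabilises_separation(self):
        x = np.array([-2.0, -1.0, 1.0, 2.0])
        y = np.array([0, 0, 1, 1])
        model = lt.fit_logistic(x[:, None], y, penalty=1e-2)
        assert model.converged
        assert np.isfinite(model.coef).all()

    def test_loglik_never_positive(self, study_features):
        pct = study_features[study_features.marker == "PCT"].sort_values("patient_id")
        model = lt.fit_logistic(
            pct[["slope"]].to_numpy(), pct["al_label"].to_numpy()
        )
        assert model.loglik <= 0


class TestPredictedScores:
    def test_zero_coefficients_give_half(self):
        model = lt.LogisticModel(np.zeros(3), 0.0, True, 1)
        assert lt.predicted_scores(model, np.ones((4, 2))) == pytest.approx(0.5)

    def test_hand_computed_inverse_logit(self):
        model = lt.LogisticModel(np.array([0.5, 2.0, -1.0]), 0.0, True, 1)
        X = np.array([[0.0, 0.0], [1.0, 1.0], [-1.0, 2.0]])
        eta = np.array([0.5, 1.5, -3.5])
        assert lt.predicted_scores(model, X) == pytest.approx(1 / (1 + np.exp(-eta)))

    def test_monotone_in_positive_coefficient_feature(self):
        model = lt.LogisticModel(np.array([0.0, 1.5]), 0.0, True, 1)
        s = lt.predicted_scores(model, np.array([[0.0], [1.0], [2.0]]))
        assert np.all(np.diff(s) > 0)

    def test_dimension_mismatch(self):
        model = lt.LogisticModel(np.array([0.0, 1.0]), 0.0, True, 1)
        with pytest.raises(lt.ConfigurationError):
            lt.predicted_scores(model, np.ones((3, 4)))


class TestAuc:
    def test_perfect_separation(self):
        assert lt.auc([1, 2, 10, 11], [0, 0, 1, 1]) == 1.0

    def test_tied_fixture_enumerated_by_hand(self):
        # pairs: 5 wins + 1 half-tie out of 6 => 11/12
        assert lt.auc([1, 2, 3, 3, 4], [0, 0, 1, 0, 1]) == pytest.approx(11 / 12)

    def test_single_class_undefined(self):
        with pytest.raises(lt.SingleClassError):
            lt.auc([1.0, 2.0], [1, 1])

    def test_concordance_equals_brute_force_and_sklearn(self, rng):
        for _ in range(50):
            scores, labels = random_fixture(rng)
            a = lt.auc(scores, labels)
            assert a == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)
            assert a == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_concordance_equals_trapezoid_area(self, rng):
        for _ in range(50):
            scores, labels = random_fixture(rng)
            curve = lt.roc_curve(scores, labels)
            assert lt.auc(scores, labels) == pytest.approx(
                lt.trapezoid_auc(curve), abs=1e-12
            )

    def test_label_reversal_complements_auc(self, rng):
        scores, labels = random_fixture(rng)
        assert lt.auc(scores, 1 - labels) == pytest.approx(
            1 - lt.auc(scores, labels), abs=1e-12
        )

    @pytest.mark.parametrize("transform", [np.exp, lambda s: 3.0 * s + 7.0])
    def test_invariant_under_increasing_transform(self, transform, rng):
        scores, labels = random_fixture(rng)
        assert lt.auc(transform(scores), labels) == pytest.approx(
            lt.auc(scores, labels), abs=1e-12
        )

    def test_roc_curve_monotone_from_origin_to_corner(self, rng):
        scores, labels = random_fixture(rng)
        curve = lt.roc_curve(scores, labels)
        assert (curve.fpr[0], curve.tpr[0]) == (0.0, 0.0)
        assert (curve.fpr[-1], curve.tpr[-1]) == (1.0, 1.0)
        assert np.all(np.diff(curve.fpr) >= 0) and np.all(np.diff(curve.tpr) >= 0)


class TestAucInference:
    def test_chance_auc_gives_p_one(self):
        scores = np.tile([1.0, 2.0], 10)
        labels = np.repeat([0, 1, 1, 0], 5)
        a, lo, hi, p = lt.auc_inference(scores, labels)
        assert a == pytest.approx(0.5)
        assert p == pytest.approx(1.0, abs=1e-9)
        assert lo <= a <= hi

    def test_ci_narrows_with_sample_size(self, rng):
        pos = rng.normal(1, 1, 400)
        neg = rng.normal(0, 1, 400)
        widths = []
        for k in (25, 100, 400):
            scores = np.r_[pos[:k], neg[:k]]
            labels = np.r_[np.ones(k), np.zeros(k)]
            _, lo, hi, _ = lt.auc_inference(scores, labels)
            widths.append(hi - lo)
        assert widths[0] > widths[1] > widths[2]

    def test_delong_ci_agrees_with_bootstrap(self, rng):
        scores = np.r_[rng.normal(1.0, 1.0, 12), rng.normal(0.0, 1.0, 18)]
        labels = np.r_[np.ones(12, int), np.zeros(18, int)]
        a, lo, hi, _ = lt.auc_inference(scores, labels)
        boot = []
        for _ in range(2000):
            idx = rng.integers(0, 30, 30)
            if labels[idx].min() == labels[idx].max():
                continue
            boot.append(lt.auc(scores[idx], labels[idx]))
        se = np.std(boot, ddof=1)
        assert lo == pytest.approx(a - 1.96 * se, abs=0.02)
        assert hi == pytest.approx(a + 1.96 * se, abs=0.02)

    def test_hanley_option_close_to_delong(self, rng):
        scores = np.r_[rng.normal(1.2, 1.0, 30), rng.normal(0.0, 1.0, 60)]
        labels = np.r_[np.ones(30, int), np.zeros(60, int)]
        _, lo_d, hi_d, _ = lt.auc_inference(scores, labels, method="delong")
        _, lo_h, hi_h, _ = lt.auc_inference(scores, labels, method="hanley")
        assert lo_h == pytest.approx(lo_d, abs=0.05)
        assert hi_h == pytest.approx(hi_d, abs=0.05)

    def test_delong_variance_positive_and_shrinking(self, rng):
        scores, labels = random_fixture(rng)
        _, var = _delong_variance(scores, labels)
        assert var >= 0


class TestCutoffAndConfusion:
    def test_separated_fixture(self):
        cutoff, table = lt.optimal_cutoff([0.1, 0.2, 0.6, 0.7], [0, 0, 1, 1])
        assert 0.2 < cutoff < 0.6
        assert (table.tp, table.fp, table.fn, table.tn) == (2, 0, 0, 2)
        m = lt.confusion_metrics(table)
        assert m["sn"] == m["sp"] == 100.0

    def test_matches_exhaustive_scan(self, rng):
        for _ in range(100):
            scores, labels = random_fixture(rng)
            _, table = lt.optimal_cutoff(scores, labels)
            m = lt.confusion_metrics(table)
            j = (m["sn"] + m["sp"]) / 100 - 1
            # oracle: J of the best >=threshold dichotomisation, scanned directly
            best = max(
                (np.mean(scores[labels == 1] >= t) + np.mean(scores[labels == 0] < t) - 1)
                for t in np.r_[np.unique(scores), np.inf]
            )
            assert j == pytest.approx(best, abs=1e-12)

    def test_study_pod5_pct_quartet(self):
        m = lt.confusion_metrics(ConfusionTable(tp=17, fp=6, fn=5, tn=177))
        assert lt.round_half_up(m["sn"]) == 77.3
        assert lt.round_half_up(m["sp"]) == 96.7
        assert lt.round_half_up(m["ppv"]) == 73.9
        assert lt.round_half_up(m["npv"]) == 97.3

    def test_degenerate_counts(self):
        all_right = lt.confusion_metrics(ConfusionTable(22, 0, 0, 183))
        assert all(v == 100.0 for v in all_right.values())
        none_called = lt.confusion_metrics(ConfusionTable(0, 0, 22, 183))
        assert none_called["sn"] == 0.0
        assert none_called["sp"] == 100.0
        assert none_called["npv"] == pytest.approx(100 * 183 / 205)
        assert np.isnan(none_called["ppv"])


class TestMarkerPanel:
    def test_raw_model_auc_matches_raw_values(self, study_cohort, study_features):
        spec = [lt.ModelSpec("PCT POD 5", "raw", ("PCT",), day=5)]
        (summary,) = lt.evaluate_marker_panel(study_cohort, study_features, spec)
        sub = study_cohort[(study_cohort.marker == "PCT") & (study_cohort.day == 5)]
        assert summary.auc == pytest.approx(
            lt.auc(sub.value.to_numpy(), sub.al_label.to_numpy()), abs=1e-12
        )

    def test_pct_beats_crp_on_pod5(self, study_cohort, study_features):
        specs = [
            lt.ModelSpec("CRP POD 5", "raw", ("CRP",), day=5),
            lt.ModelSpec("PCT POD 5", "raw", ("PCT",), day=5),
        ]
        crp, pct = lt.evaluate_marker_panel(study_cohort, study_features, specs)
        assert pct.auc > crp.auc

    def test_nested_models_never_lose_likelihood(self, study_features):
        wide = study_features.pivot(index="patient_id", columns="marker", values="slope")
        y = (
            study_features.drop_duplicates("patient_id")
            .sort_values("patient_id")["al_label"]
            .to_numpy()
        )
        ll = {}
        for combo in [("PCT",), ("CRP", "PCT"), ("PCT", "WBC"), ("CRP", "PCT", "WBC")]:
            ll[combo] = lt.fit_logistic(wide[list(combo)].to_numpy(), y).loglik
        assert ll[("CRP", "PCT")] >= ll[("PCT",)] - 1e-6
        assert ll[("PCT", "WBC")] >= ll[("PCT",)] - 1e-6
        assert ll[("CRP", "PCT", "WBC")] >= ll[("CRP", "PCT")] - 1e-6
        assert ll[("CRP", "PCT", "WBC")] >= ll[("PCT", "WBC")] - 1e-6

    def test_binary_rule_auc_is_mean_of_sn_sp(self, study_cohort, study_features):
        spec = [lt.ModelSpec("PCT rise any pair", "rule", ("PCT",))]
        (summary,) = lt.evaluate_marker_panel(study_cohort, study_features, spec)
        assert summary.auc == pytest.approx(
            (summary.sn + summary.sp) / 200.0, abs=1e-12
        )

    def test_default_panel_names_unique(self):
        specs = lt.default_model_specs()
        names = [s.name for s in specs]
        assert len(names) == len(set(names))
        kinds = {s.kind for s in specs}
        assert kinds == {"raw", "trajectory", "rule"}
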