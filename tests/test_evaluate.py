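"""Patient aggregation, AUC, prevalence-adjusted metrics, CIs, strata."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from histobias.evaluate import (MetricsReport, aggregate_patient,
                                aggregate_patients, auc, clopper_pearson_ci,
                                evaluate_fold, logit_ci_predictive,
                                prevalence_adjusted_metrics,
                                stratified_error_rates)

from oracles import auc_pair_counting

# Beta-quantile interval for 87/100 computed independently before the build
CP_87_OF_100 = (0.7879593229125502, 0.9289269538145705)


class TestAggregatePatient:
    @pytest.mark.parametrize("probs,expected", [
        ([0.9, 0.8, 0.7, 0.2, 0.1], "MSI-H"),     # 3 of 5 positive
        ([0.1, 0.2, 0.3], "MSS"),                  # all negative
        ([0.9, 0.8, 0.2, 0.1], "MSI-H"),           # 2 of 4: tie -> MSI-H
    ])
    def test_majority_vote_with_screening_tie_break(self, probs, expected):
        assert aggregate_patient("p", probs).label == expected

    def test_mean_probability_tie_break_option(self):
        assert aggregate_patient("p", [0.8, 0.1], tie_break="mean").label == "MSS"
        assert aggregate_patient("p", [0.9, 0.45], tie_break="mean").label == \
            "MSI-H"

    def test_zero_tiles_rejected(self):
        with pytest.raises(ValueError):
            aggregate_patient("p", [])

    def test_permutation_invariant_and_monotone(self):
        probs = [0.9, 0.8, 0.7, 0.2, 0.1]
        a = aggregate_patient("p", probs)
        b = aggregate_patient("p", probs[::-1])
        assert a.label == b.label
        assert a.mean_probability == pytest.approx(b.mean_probability)
        # duplicating a majority-class tile never flips the call
        c = aggregate_patient("p", probs + [0.9])
        assert c.label == a.label == "MSI-H"

    def test_table_aggregation_matches_scalar_path(self):
        df = pd.DataFrame({"patient": ["a", "a", "b"],
                           "prob": [0.9, 0.2, 0.3]})
        out = aggregate_patients(df)
        assert list(out["patient"]) == ["a", "b"]
        assert out.loc[0, "label"] == "MSI-H"  # 1 of 2: tie rule
        assert out.loc[1, "n_total"] == 1


class TestAuc:
    def test_perfect_separation(self):
        assert auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_four_point_toy_matches_pair_counting(self):
        scores = [0.2, 0.6, 0.4, 0.9]
        labels = [0, 1, 0, 1]
        assert auc(scores, labels) == pytest.approx(
            auc_pair_counting(scores, labels))

    def test_ties_get_midrank_half_credit(self):
        scores = [0.5, 0.5, 0.5, 0.5]
        assert auc(scores, [0, 1, 0, 1]) == 0.5

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(st.integers(0, 100_000))
    def test_random_instances_match_pair_counting(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 30))
        scores = rng.choice(np.linspace(0, 1, 7), n)  # force some ties
        labels = rng.integers(0, 2, n)
        if labels.sum() in (0, n):
            labels[0] = 1 - labels[0]
        assert auc(scores, labels) == pytest.approx(
            auc_pair_counting(scores, labels), abs=1e-12)

    def test_uninformative_scores_near_half(self):
        rng = np.random.default_rng(0)
        assert abs(auc(rng.normal(size=4000),
                       rng.integers(0, 2, 4000)) - 0.5) < 0.03

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([0.1, 0.9], [1, 1])


class TestPrevalenceAdjustedMetrics:
    def test_published_screening_working_point(self):
        """S=87%, E=88.3% at 15% prevalence: accuracy rounds to 88%, and
        the predictive values land at 56.5%/97.3% (printed from unrounded
        inputs; compared at ±0.005)."""
        m = prevalence_adjusted_metrics(0.87, 0.883, 0.15)
        assert round(m["accuracy"] * 100) == 88
        assert m["ppv"] == pytest.approx(0.565, abs=0.005)
        assert m["npv"] == pytest.approx(0.973, abs=0.005)

    def test_perfect_test_saturates(self):
        m = prevalence_adjusted_metrics(1.0, 1.0, 0.15)
        assert (m["accuracy"], m["ppv"], m["npv"]) == (1.0, 1.0, 1.0)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.floats(0.05, 0.99), st.floats(0.05, 0.99), st.floats(0.01, 0.6))
    def test_total_probability_identity(self, S, E, P):
        m = prevalence_adjusted_metrics(S, E, P)
        pred_pos = S * P + (1 - E) * (1 - P)
        pred_neg = E * (1 - P) + (1 - S) * P
        assert m["accuracy"] == pytest.approx(
            m["ppv"] * pred_pos + m["npv"] * pred_neg)
        assert m["balanced_accuracy"] == pytest.approx((S + E) / 2)

    def test_domain_checked(self):
        with pytest.raises(ValueError):
            prevalence_adjusted_metrics(1.2, 0.9)


class TestConfidenceIntervals:
    def test_clopper_pearson_boundaries(self):
        lo, hi = clopper_pearson_ci(10, 10)
        assert hi == 1.0 and 0 < lo < 1
        lo, hi = clopper_pearson_ci(0, 10)
        assert lo == 0.0 and 0 < hi < 1

    def test_clopper_pearson_frozen_beta_quantiles(self):
        lo, hi = clopper_pearson_ci(87, 100)
        assert lo == pytest.approx(CP_87_OF_100[0], abs=1e-12)
        assert hi == pytest.approx(CP_87_OF_100[1], abs=1e-12)

    def test_clopper_pearson_covers_point_estimate(self):
        for k, n in ((3, 17), (40, 80), (1, 2)):
            lo, hi = clopper_pearson_ci(k, n)
            assert lo <= k / n <= hi

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            clopper_pearson_ci(1, 0)
        with pytest.raises(ValueError):
            clopper_pearson_ci(5, 3)

    def test_logit_interval_properties(self):
        comp = {"S": 0.87, "E": 0.883, "n_pos": 100, "n_neg": 1000,
                "kind": "ppv"}
        v = prevalence_adjusted_metrics(0.87, 0.883, 0.15)["ppv"]
        lo, hi = logit_ci_predictive(v, comp)
        assert 0.0 < lo < v < hi < 1.0
        # more data -> tighter interval
        wide = logit_ci_predictive(v, {**comp, "n_pos": 20, "n_neg": 100})
        assert (hi - lo) < (wide[1] - wide[0])
        with pytest.raises(ValueError):
            logit_ci_predictive(1.0, comp)


class TestStratifiedErrorRates:
    def test_all_correct_gives_zero_rates(self):
        df = pd.DataFrame({"tissue": ["TUM", "LYM"] * 4,
                           "prob": [0.9, 0.1] * 4, "y": [1, 0] * 4})
        out = stratified_error_rates(df, "tissue")
        assert (out["fpr"].fillna(0) == 0).all()
        assert (out["fnr"].fillna(0) == 0).all()

    def test_known_confusion_counts(self):
        # one stratum: 2 FP of 4 negatives, 1 FN of 2 positives
        df = pd.DataFrame({
            "tissue": ["TUM"] * 6,
            "y":    [0, 0, 0, 0, 1, 1],
            "prob": [0.9, 0.8, 0.1, 0.2, 0.3, 0.9],
        })
        out = stratified_error_rates(df, "tissue")
        assert out.loc[0, "fpr"] == pytest.approx(0.5)
        assert out.loc[0, "fnr"] == pytest.approx(0.5)

    def test_degenerate_strata_marked_undefined(self):
        df = pd.DataFrame({"tissue": ["MUC"] * 3, "y": [1, 1, 1],
                           "prob": [0.9, 0.2, 0.8]})
        out = stratified_error_rates(df, "tissue")
        assert np.isnan(out.loc[0, "fpr"])
        assert out.loc[0, "fnr"] == pytest.approx(1 / 3)

    def test_per_fold_mean_and_sd(self):
        df = pd.DataFrame({
            "mag": ["x20"] * 8,
            "fold": [0] * 4 + [1] * 4,
            "y": [0, 0, 1, 1] * 2,
            "prob": [0.9, 0.1, 0.8, 0.9, 0.1, 0.1, 0.9, 0.2],
        })
        out = stratified_error_rates(df, "mag", fold_col="fold")
        assert out.loc[0, "fpr_mean"] == pytest.approx((0.5 + 0.0) / 2)
        assert out.loc[0, "fnr_mean"] == pytest.approx((0.0 + 0.5) / 2)
        assert out.loc[0, "fpr_sd"] == pytest.approx(np.std([0.5, 0.0], ddof=1))

    def test_nonspecific_tissues_carry_higher_false_positive_rates(
            self, removable_benchmark):
        """Lymphocyte and mucin tiles carry a weaker class-specific signal
        than tumour epithelium, so the trained models' false-positive rates
        are higher there (mirrors the stratified error analysis)."""
        df = removable_benchmark
        for model in ("baseline", "ablated"):
            tum = df[f"fpr_TUM_{model}"].mean()
            other = (df[f"fpr_LYM_{model}"].mean()
                     + df[f"fpr_MUC_{model}"].mean()) / 2
            assert other > tum


class TestEvaluateFold:
    @staticmethod
    def _tile_frame(seed=0, n_patients=60, tiles=15, flip_sd=0.25):
        """Tile probabilities = patient effect + iid tile noise, so tile
        errors are conditionally independent given the patient."""
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(n_patients):
            lab = "MSI-H" if rng.random() < 0.3 else "MSS"
            centre = 0.72 if lab == "MSI-H" else 0.3
            for _ in range(tiles):
                rows.append((f"p{i:03d}", lab,
                             np.clip(centre + rng.normal(0, flip_sd), 0, 1),
                             rng.choice(["TUM", "LYM", "MUC"]),
                             rng.choice(["x20", "x10"])))
        return pd.DataFrame(rows, columns=["patient", "msi_label", "prob",
                                           "tissue", "magnification"])

    def test_patient_auc_exceeds_tile_auc_by_averaging(self):
        report = evaluate_fold(self._tile_frame())
        assert report.auc_patient >= report.auc_tile
        assert report.n_patients == 60

    def test_report_is_internally_consistent(self):
        report = evaluate_fold(self._tile_frame(seed=1),
                               strata_cols=("tissue", "magnification"))
        m = prevalence_adjusted_metrics(report.sensitivity,
                                        report.specificity,
                                        report.prevalence)
        assert report.accuracy == pytest.approx(m["accuracy"])
        assert set(report.ci) >= {"sensitivity", "specificity", "accuracy"}
        lo, hi = report.ci["sensitivity"]
        assert lo <= report.sensitivity <= hi
        assert set(report.strata) == {"tissue", "magnification"}

    def test_json_roundtrip(self, tmp_path):
        import json

        report = evaluate_fold(self._tile_frame(seed=2))
        report.to_json(tmp_path / "metrics.json")
        loaded = json.loads((tmp_path / "metrics.json").read_text())
        assert loaded["auc_patient"] == report.auc_patient

    def test_metrics_report_validates_ranges(self):
        with pytest.raises(ValueError):
            MetricsReport(auc_tile=1.3, auc_patient=0.5, sensitivity=0.5,
                          specificity=0.5, prevalence=0.15, accuracy=0.5,
                          ppv=0.5, npv=0.5, balanced_accuracy=0.5,
                          n_patients=10, n_tiles=100)
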