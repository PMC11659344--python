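"""Logistic fitting, clinical screening, OR ranking, nested CV models and
the published linear scores."""
import numpy as np
import pandas as pd
import pytest
from scipy.special import logit

from srnapcr.models import (
    CVConfig,
    ModelCoefficients,
    build_nested_models,
    clinical_design,
    fit_logistic,
    linear_score,
    rank_features_by_cv_or,
    screen_clinical,
)
from srnapcr.published import FEATURE_MEDIANS, load_published_model
from srnapcr.quantify import ExpressionMatrix
from srnapcr.selection import LabeledMatrix
from srnapcr.synthetic import table2_patterned_records


def _binary_design_from_2x2(a, b, c, d):
    """Design/outcome realizing a 2x2 table: a=exposed cases, b=exposed
    noncases, c=unexposed cases, d=unexposed noncases."""
    x = [1.0] * (a + b) + [0.0] * (c + d)
    y = [1.0] * a + [0.0] * b + [1.0] * c + [0.0] * d
    return pd.DataFrame({"exposed": x}), np.array(y)


class TestFitLogistic:
    def test_2x2_mle_equals_cross_product_ratio(self):
        """On the cCR 2x2 counts (12,18;15,54) the logistic OR is the
        analytic cross-product ratio, 2.40 to 2 dp."""
        X, y = _binary_design_from_2x2(12, 18, 15, 54)
        fit = fit_logistic(X, y)
        assert np.exp(fit.coefficients["exposed"]) == pytest.approx(2.40, abs=0.005)
        # Wald CI matches the closed form to 6 significant digits
        or_, lo, hi = fit.odds_ratios["exposed"]
        se = np.sqrt(1 / 12 + 1 / 18 + 1 / 15 + 1 / 54)
        assert lo == pytest.approx(or_ * np.exp(-1.959963984540054 * se), rel=1e-6)
        assert hi == pytest.approx(or_ * np.exp(1.959963984540054 * se), rel=1e-6)

    def test_constant_predictor_gives_intercept_only(self):
        X = pd.DataFrame({"flat": [1.0] * 40})
        y = np.array([1.0] * 10 + [0.0] * 30)
        fit = fit_logistic(X, y)
        assert fit.coefficients == {}
        assert fit.intercept == pytest.approx(logit(0.25))

    def test_perfect_separation_is_flagged(self):
        X = pd.DataFrame({"x": np.arange(20, dtype=float)})
        y = np.array([0.0] * 10 + [1.0] * 10)
        fit = fit_logistic(X, y)
        assert fit.separation
        assert np.isnan(fit.intercept)

    def test_firth_fallback_returns_finite_coefficients(self):
        X = pd.DataFrame({"x": np.arange(20, dtype=float)})
        y = np.array([0.0] * 10 + [1.0] * 10)
        fit = fit_logistic(X, y, firth=True)
        assert fit.separation and np.isfinite(fit.coefficients["x"])

    def test_single_class_outcome_raises(self):
        X = pd.DataFrame({"x": np.arange(12, dtype=float)})
        with pytest.raises(ValueError, match="both classes"):
            fit_logistic(X, np.ones(12))


class TestLinearScore:
    def test_published_srpm_intercept_at_zero_inputs(self):
        model = load_published_model("sr")
        zeros = {k: 0.0 for k in model.coefficients}
        assert linear_score(model, zeros) == pytest.approx(-1.7445)

    def test_published_srpm_at_pcr_group_medians(self):
        model = load_published_model("sr")
        inputs = {
            "let7b_isomir": FEATURE_MEDIANS["let7b_isomir"][0],
            "tsrna_gly_group": FEATURE_MEDIANS["tsrna_gly_group"][0],
            "mir93_isomir": FEATURE_MEDIANS["mir93_isomir"][0],
        }
        assert linear_score(model, inputs) == pytest.approx(-0.11728, abs=5e-6)

    def test_published_cpm_intercept_at_reference_inputs(self):
        model = load_published_model("c")
        zeros = {k: 0.0 for k in model.coefficients}
        assert linear_score(model, zeros) == pytest.approx(-1.20176)

    def test_missing_predictor_is_named(self):
        model = load_published_model("cf")
        with pytest.raises(KeyError, match="biopsy_positive"):
            linear_score(model, {"overall_cCR": 1, "pct_delta_suvmax": 70, "post_CEA": 2})

    def test_strictly_increasing_in_positive_coefficient(self):
        model = load_published_model("c")
        base = {k: 10.0 for k in model.coefficients}
        bumped = dict(base, let7b_isomir=11.0)
        assert linear_score(model, bumped) > linear_score(model, base)
        dropped = dict(base, post_CEA=11.0)  # negative coefficient
        assert linear_score(model, dropped) < linear_score(model, base)


class TestScreenClinical:
    def test_table_patterned_cohort_selects_exactly_the_four_cfpm_factors(self):
        records = table2_patterned_records(scale=3)
        assert screen_clinical(records) == [
            "overall_cCR",
            "biopsy_positive",
            "post_CEA",
            "pct_delta_suvmax",
        ]

    def test_alpha_one_returns_every_screenable_factor(self):
        records = table2_patterned_records(scale=1)
        selected = screen_clinical(records, alpha_enter=1.0000001)
        # every factor with >1 level is returned
        assert "age" in selected and "overall_cCR" in selected
        assert len(selected) >= 10

    def test_null_cohort_selection_rate_near_alpha(self):
        """Per-factor selection frequency on label-permuted cohorts is
        within Monte-Carlo error of the 10 % entry threshold."""
        rng = np.random.default_rng(3)
        records = table2_patterned_records(scale=1)
        B = 300
        hits = 0
        trials = 0
        for _ in range(B):
            labels = rng.permutation([r.pcr_label for r in records])
            import dataclasses

            permuted = [dataclasses.replace(r, pcr_label=bool(l)) for r, l in zip(records, labels)]
            sel = screen_clinical(permuted, factors=["post_CEA", "age", "tumor_diameter"])
            trials += 3
            hits += len(sel)
        rate = hits / trials
        se = np.sqrt(0.1 * 0.9 / trials)
        assert abs(rate - 0.1) <= 3 * se


def _matrix_cohort(rng, n_per=60, n_feat=11, effect_feature=0, shift=120.0):
    idx = [f"P{i}" for i in range(n_per)] + [f"N{i}" for i in range(n_per)]
    labels = pd.Series({s: ("pCR" if s.startswith("P") else "non-pCR") for s in idx})
    base = rng.negative_binomial(4, 4 / (4 + 150), size=(2 * n_per, n_feat)).astype(float)
    base[: n_per, effect_feature] += shift
    values = pd.DataFrame(base, index=idx, columns=[f"f{i:02d}" for i in range(n_feat)])
    em = ExpressionMatrix(values=values, raw=values.round().astype(int))
    return LabeledMatrix(matrix=em, labels=labels)


class TestRanking:
    def test_planted_feature_ranks_first_across_seeds(self):
        rng = np.random.default_rng(10)
        lm = _matrix_cohort(rng)
        firsts = 0
        n_seeds = 20
        for seed in range(n_seeds):
            ranked = rank_features_by_cv_or(lm, list(lm.matrix.feature_ids), CVConfig(seed=seed))
            firsts += ranked[0][0] == "f00"
        assert firsts >= int(0.95 * n_seeds)

    def test_identical_columns_tie_lexicographically(self):
        rng = np.random.default_rng(1)
        lm = _matrix_cohort(rng, n_feat=3)
        dup = lm.matrix.values.copy()
        dup["f02"] = dup["f00"]
        lm2 = LabeledMatrix(
            matrix=ExpressionMatrix(values=dup, raw=dup.round().astype(int)),
            labels=lm.labels,
        )
        ranked = rank_features_by_cv_or(lm2, ["f00", "f01", "f02"], CVConfig(seed=0))
        ors = dict(ranked)
        assert ors["f00"] == ors["f02"]
        names = [f for f, _ in ranked]
        assert names.index("f00") < names.index("f02")

    def test_two_fold_cv_on_ten_samples_runs(self):
        rng = np.random.default_rng(2)
        lm = _matrix_cohort(rng, n_per=5, n_feat=4)
        ranked = rank_features_by_cv_or(
            lm, list(lm.matrix.feature_ids), CVConfig(n_folds=2, seed=0)
        )
        assert len(ranked) == 4

    def test_unknown_feature_rejected(self, labeled_matrix):
        with pytest.raises(ValueError, match="not in matrix"):
            rank_features_by_cv_or(labeled_matrix, ["nope"], CVConfig())


class TestNestedModels:
    def test_max_k_one_returns_single_model(self):
        rng = np.random.default_rng(4)
        lm = _matrix_cohort(rng, n_feat=4)
        res = build_nested_models(lm, ["f00", "f01"], max_k=1, cv=CVConfig(seed=1))
        assert len(res.entries) == 1 and res.best_k == 1

    def test_signal_in_two_features_prefers_k_ge_2(self):
        """With signal planted in two features and one pure null, adding
        the second feature helps and the third cannot hurt much."""
        rng = np.random.default_rng(8)
        lm = _matrix_cohort(rng, n_per=120, n_feat=3, effect_feature=0, shift=100.0)
        vals = lm.matrix.values.copy()
        vals.loc[vals.index.str.startswith("P"), "f01"] += 100.0
        lm = LabeledMatrix(
            matrix=ExpressionMatrix(values=vals, raw=vals.round().astype(int)),
            labels=lm.labels,
        )
        res = build_nested_models(lm, ["f00", "f01", "f02"], max_k=3, cv=CVConfig(seed=3))
        aucs = {e.k: e.cv_metrics.auc for e in res.entries}
        assert aucs[2] >= aucs[1] - 0.01
        assert abs(aucs[3] - aucs[2]) < 0.05
        assert res.best_k in (2, 3)

    def test_final_coefficients_are_full_data_refit(self):
        rng = np.random.default_rng(5)
        lm = _matrix_cohort(rng, n_feat=3)
        res = build_nested_models(lm, ["f00"], max_k=1, cv=CVConfig(seed=1))
        y = (lm.labels.loc[lm.matrix.sample_ids] == "pCR").to_numpy(dtype=float)
        direct = fit_logistic(lm.matrix.values[["f00"]].reset_index(drop=True), y, firth=True)
        assert res.final_coefficients.coefficients["f00"] == pytest.approx(
            direct.coefficients["f00"]
        )

    def test_empty_ranking_rejected(self, labeled_matrix):
        with pytest.raises(ValueError, match="non-empty"):
            build_nested_models(labeled_matrix, [], max_k=2)


class TestParameterRecovery:
    def test_refit_recovers_published_cpm_coefficients(self):
        """Cohorts generated with the published combined model as the true
        log-odds model refit to within 3 SE for >= 95 % of coefficients."""
        from srnapcr.synthetic import simulate_from_score_model

        cpm = load_published_model("c")
        within = total = 0
        for rep in range(30):
            X, y = simulate_from_score_model(cpm, n=2000, seed=100 + rep)
            fit = fit_logistic(X, y, firth=True)
            for name, true in cpm.coefficients.items():
                total += 1
                within += abs(fit.coefficients[name] - true) <= 3 * fit.se[name]
        assert within / total >= 0.95
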