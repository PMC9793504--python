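"""Bivariate tests, multinomial regression and stepwise AIC selection."""

import numpy as np
import pandas as pd
import pytest

import caretraj as ct
from caretraj.characterize import (
    MISSING_CATEGORY,
    anova_f,
    backward_stepwise_aic,
    bivariate_screen,
    chi_squared_test,
    fit_multinomial,
    prepare_covariates,
)
from caretraj.model import CovariateTable


class TestChiSquared:
    def test_hand_computed_2x2(self):
        r = chi_squared_test([[30, 10], [10, 30]])
        assert r.statistic == pytest.approx(20.0)
        assert r.df == (1,)
        assert r.p_value < 1e-4

    def test_independent_rows(self):
        r = chi_squared_test([[10, 20, 30], [10, 20, 30]])
        assert r.statistic == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)

    def test_scaling_property(self):
        a = chi_squared_test([[12, 5, 9], [3, 14, 7]])
        b = chi_squared_test([[120, 50, 90], [30, 140, 70]])
        assert b.statistic == pytest.approx(10 * a.statistic)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            chi_squared_test([[0, 0], [5, 5]])


class TestAnova:
    def test_hand_computed(self):
        r = anova_f([[1, 2, 3], [4, 5, 6]])
        assert r.statistic == pytest.approx(13.5)
        assert r.df == (1, 4)

    def test_equal_means(self):
        r = anova_f([[1, 2, 3], [3, 2, 1]])
        assert r.statistic == pytest.approx(0.0)

    def test_within_group_permutation_invariance(self):
        a = anova_f([[1, 5, 2], [7, 3, 4]])
        b = anova_f([[2, 1, 5], [4, 7, 3]])
        assert a.statistic == pytest.approx(b.statistic)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            anova_f([[1, 2, 3]])
        with pytest.raises(ValueError):
            anova_f([[2, 2], [2, 2]])


def make_table(n, missing_share=0.0, seed=0):
    rng = np.random.default_rng(seed)
    sex = rng.choice(["f", "m"], size=n)
    vals = rng.choice(["a", "b", "c"], size=n).astype(object)
    if missing_share:
        vals[rng.random(n) < missing_share] = None
    df = pd.DataFrame(
        {"sex": sex, "edu": vals, "age": rng.integers(65, 71, size=n).astype(float)},
        index=[f"p{i}" for i in range(n)],
    )
    return CovariateTable(df, {"sex": ["f", "m"], "edu": ["a", "b", "c"]}, ["age"])


class TestPrepareCovariates:
    def test_high_missing_gains_category(self):
        table = make_table(1000, missing_share=0.03)
        prep = prepare_covariates(table, 0.005)
        assert MISSING_CATEGORY in prep.categorical["edu"]
        assert len(prep.retained_ids) == 1000  # nobody dropped

    def test_low_missing_drops_rows(self):
        table = make_table(1000, missing_share=0.002)
        n_missing = table.data["edu"].isna().sum()
        assert n_missing > 0
        prep = prepare_covariates(table, 0.005)
        assert MISSING_CATEGORY not in prep.categorical["edu"]
        assert len(prep.dropped_ids) == n_missing

    def test_no_missing_passthrough(self):
        table = make_table(500)
        prep = prepare_covariates(table, 0.005)
        assert prep.retained_ids == list(table.data.index)
        assert prep.categorical["edu"] == ["a", "b", "c"]

    def test_single_category_rejected(self):
        df = pd.DataFrame({"x": ["only"] * 50}, index=[f"p{i}" for i in range(50)])
        table = CovariateTable(df, {"x": ["only"]}, [])
        with pytest.raises(ValueError, match="single category"):
            prepare_covariates(table)

    def test_design_matrix_coding(self):
        prep = prepare_covariates(make_table(100), 0.005)
        X = prep.design_matrix()
        assert "const" in X.columns
        assert "sex[m]" in X.columns and "sex[f]" not in X.columns  # first = ref
        assert "age" in X.columns


class TestMultinomial:
    def test_intercept_only_closed_form(self):
        labels = pd.Series(
            [1] * 80 + [2] * 15 + [3] * 5, index=[f"p{i}" for i in range(100)]
        )
        X = pd.DataFrame({"const": 1.0}, index=labels.index)
        m = fit_multinomial(X, labels)
        assert m.reference == 1
        assert m.params.loc["const", 2] == pytest.approx(np.log(15 / 80), abs=1e-8)
        assert m.params.loc["const", 3] == pytest.approx(np.log(5 / 80), abs=1e-8)

    def test_predicted_shares_match_observed(self):
        labels = pd.Series(
            [1] * 60 + [2] * 30 + [3] * 10, index=[f"p{i}" for i in range(100)]
        )
        X = pd.DataFrame({"const": 1.0}, index=labels.index)
        m = fit_multinomial(X, labels)
        assert np.allclose(m.predict_shares(X), [0.6, 0.3, 0.1], atol=1e-6)

    def test_two_cluster_reduces_to_binary_logit(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(17)
        n = 500
        x = rng.normal(size=n)
        p = 1 / (1 + np.exp(-(-0.5 + 1.2 * x)))
        y = (rng.random(n) < p).astype(int)
        idx = [f"p{i}" for i in range(n)]
        labels = pd.Series(y + 1, index=idx)
        X = pd.DataFrame({"const": 1.0, "x": x}, index=idx)
        m = fit_multinomial(X, labels)
        ref = sm.Logit(y, X.values).fit(disp=False)
        assert np.allclose(m.params[2].values, ref.params, atol=1e-6)

    def test_aic_definition(self):
        labels = pd.Series([1] * 50 + [2] * 30 + [3] * 20,
                           index=[f"p{i}" for i in range(100)])
        X = pd.DataFrame({"const": 1.0}, index=labels.index)
        m = fit_multinomial(X, labels)
        assert m.aic == pytest.approx(-2 * m.llf + 2 * (3 - 1) * 1)

    def test_separation_flagged_not_divergent(self):
        rng = np.random.default_rng(23)
        n = 300
        idx = [f"p{i}" for i in range(n)]
        labels = pd.Series(rng.choice([1, 1, 1, 2, 3], size=n), index=idx)
        dummy = (rng.random(n) < 0.3).astype(float)
        dummy[labels.values == 3] = 0.0  # no category member in cluster 3
        X = pd.DataFrame({"const": 1.0, "g[yes]": dummy}, index=idx)
        m = fit_multinomial(X, labels)
        row = m.or_table[(m.or_table.cluster == 3) & (m.or_table.predictor == "g[yes]")]
        assert bool(row["separated"].iloc[0])
        assert np.isnan(row["odds_ratio"].iloc[0])
        other = m.or_table[(m.or_table.cluster == 2) & (m.or_table.predictor == "g[yes]")]
        assert np.isfinite(other["odds_ratio"].iloc[0])

    def test_empty_reference_category_flags_whole_covariate(self):
        # no "0 illnesses" member in cluster 3: contrasts against the
        # reference category are non-estimable for that cluster
        rng = np.random.default_rng(29)
        n = 400
        idx = [f"p{i}" for i in range(n)]
        labels = pd.Series(rng.choice([1, 1, 1, 2, 3], size=n), index=idx)
        cats = rng.choice(["0", "1", "2+"], size=n).astype(object)
        cats[labels.values == 3] = rng.choice(["1", "2+"], size=(labels.values == 3).sum())
        from caretraj.model import CovariateTable

        table = CovariateTable(
            pd.DataFrame({"chronic": cats}, index=idx), {"chronic": ["0", "1", "2+"]}, []
        )
        prep = prepare_covariates(table)
        m = fit_multinomial(prep.design_matrix(), labels)
        sub = m.or_table[(m.or_table.cluster == 3) & (m.or_table.predictor != "const")]
        assert sub["separated"].all()
        ok = m.or_table[(m.or_table.cluster == 2) & (m.or_table.predictor != "const")]
        assert np.isfinite(ok["odds_ratio"]).all()


class TestStepwise:
    def _simulate(self, n, seed, strong_or=5.0):
        rng = np.random.default_rng(seed)
        idx = [f"p{i}" for i in range(n)]
        strong = rng.choice(["no", "yes"], size=n)
        noise = rng.choice(["u", "v"], size=n)
        beta = np.log(strong_or)
        eta2 = -1.5 + beta * (strong == "yes")
        eta3 = -2.0 + beta * (strong == "yes")
        denom = 1 + np.exp(eta2) + np.exp(eta3)
        u = rng.random(n)
        p2, p3 = np.exp(eta2) / denom, np.exp(eta3) / denom
        y = np.where(u < p2, 2, np.where(u < p2 + p3, 3, 1))
        df = pd.DataFrame({"strong": strong, "noise": noise}, index=idx)
        table = CovariateTable(df, {"strong": ["no", "yes"], "noise": ["u", "v"]}, [])
        return prepare_covariates(table), pd.Series(y, index=idx)

    def test_noise_dropped_strong_kept(self):
        prep, labels = self._simulate(2000, seed=31)
        selected, model, trace = backward_stepwise_aic(
            ["strong", "noise"], prep, labels
        )
        assert selected == ["strong"]
        assert trace[-1]["dropped"] == "noise"

    def test_empty_initial_set(self):
        prep, labels = self._simulate(300, seed=32)
        selected, model, _ = backward_stepwise_aic([], prep, labels)
        assert selected == []
        assert list(model.params.index) == ["const"]

    def test_final_aic_never_worse(self):
        for seed in range(6):
            prep, labels = self._simulate(250, seed=40 + seed, strong_or=2.0)
            _, model, trace = backward_stepwise_aic(["strong", "noise"], prep, labels)
            assert model.aic <= trace[0]["aic"] + 1e-9


class TestScreenAndSigns:
    def test_bivariate_screen_on_synthetic(self):
        cohort, labels = ct.generate_cohort(ct.default_config(n_raw=2500), seed=51)
        kept, retained, _ = ct.filter_min_observations(cohort)
        lab = dict(zip(cohort.ids, labels))
        arch = pd.Series([lab[i] for i in kept.ids], index=kept.ids)
        sizes = arch.value_counts()
        clusters = arch.map({a: r + 1 for r, a in enumerate(sizes.index)})
        prep = prepare_covariates(kept.covariates)
        table, selected = bivariate_screen(prep, clusters, alpha=0.05)
        assert set(table.covariate) == set(prep.covariates)
        assert "sex" in selected  # strong sex contrast across archetypes

    def test_association_signs_match_covariate_model(self):
        """Female membership raises the odds of the high-ambulatory cluster;
        male raises the odds of the early-death cluster (vs the low-use
        reference)."""
        cohort, labels = ct.generate_cohort(ct.default_config(n_raw=3053), seed=52)
        kept, retained, _ = ct.filter_min_observations(cohort)
        lab = dict(zip(cohort.ids, labels))
        arch = pd.Series([lab[i] for i in kept.ids], index=kept.ids)
        sizes = arch.value_counts()
        cluster_of = {a: r + 1 for r, a in enumerate(sizes.index)}
        clusters = arch.map(cluster_of)
        prep = prepare_covariates(kept.covariates)
        m = fit_multinomial(prep.design_matrix(["sex"]), clusters, ["sex"])
        beta_male_hac = m.params.loc["sex[male]", cluster_of["HAC"]]
        beta_male_efe = m.params.loc["sex[male]", cluster_of["EFE"]]
        assert beta_male_hac < 0  # female -> HAC
        assert beta_male_efe > 0  # male -> EFE
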