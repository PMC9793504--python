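"""Cluster characterization: bivariate screens and multinomial regression.

Associations between baseline covariates and cluster membership are first
screened bivariately — Pearson chi-squared tests for categorical covariates,
one-way ANOVA for age — and covariates significant at the entry level are
passed to a multivariable multinomial logistic regression with the largest
cluster as the reference outcome.  Covariates are then discarded one by one
by backward stepwise selection under the Akaike Information Criterion.

Missing covariate values follow the share rule: a covariate whose missing
share exceeds the threshold (default 0.5%) gains an explicit "missing"
category; below the threshold the affected individuals are dropped from the
model sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .model import CovariateTable

MISSING_CATEGORY = "missing"


@dataclass
class BivariateResult:
    covariate: str
    test: str  # "chi_squared" | "anova_f"
    statistic: float
    df: tuple
    p_value: float

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError("p-value outside [0, 1]")


@dataclass
class PreparedCovariates:
    """Model-ready covariates after the missing-share rule.

    ``data`` holds coded categorical columns (pandas Categorical, first
    category = dummy reference) and numeric columns, restricted to the
    retained individuals.
    """

    data: pd.DataFrame
    categorical: dict[str, list[str]]
    numeric: list[str]
    retained_ids: list
    dropped_ids: list

    @property
    def covariates(self) -> list[str]:
        return list(self.categorical) + list(self.numeric)

    def design_matrix(self, covariates: list[str] | None = None) -> pd.DataFrame:
        """Intercept + dummy/numeric columns for the requested covariates."""
        covariates = self.covariates if covariates is None else covariates
        cols = [pd.Series(1.0, index=self.data.index, name="const")]
        for name in covariates:
            if name in self.numeric:
                cols.append(self.data[name].astype(float))
            else:
                cats = self.categorical[name]
                for cat in cats[1:]:  # first category is the reference
                    cols.append(
                        (self.data[name] == cat).astype(float).rename(f"{name}[{cat}]")
                    )
        return pd.concat(cols, axis=1)


def prepare_covariates(
    table: CovariateTable, missing_threshold: float = 0.005
) -> PreparedCovariates:
    """Apply the missing-share rule and code categories for modelling."""
    df = table.data.copy()
    categorical: dict[str, list[str]] = {}
    drop_mask = pd.Series(False, index=df.index)
    for name, cats in table.categorical.items():
        col = df[name]
        share = col.isna().mean()
        if share > missing_threshold:
            cats = list(cats) + [MISSING_CATEGORY]
            df[name] = col.fillna(MISSING_CATEGORY)
        else:
            drop_mask |= col.isna()
            cats = list(cats)
        categorical[name] = cats
    for name in table.numeric:
        drop_mask |= df[name].isna()
    kept = df.loc[~drop_mask]
    for name, cats in categorical.items():
        present = [c for c in cats if (kept[name] == c).any()]
        if len(present) < 2:
            raise ValueError(f"covariate {name!r} has a single category after coding")
        categorical[name] = present
    return PreparedCovariates(
        data=kept,
        categorical=categorical,
        numeric=list(table.numeric),
        retained_ids=list(kept.index),
        dropped_ids=list(df.index[drop_mask]),
    )


def chi_squared_test(counts, covariate: str = "") -> BivariateResult:
    """Pearson chi-squared test of independence on an r x c table.

    No continuity correction is applied (the cluster dimension has more
    than two categories, where the correction never applies anyway).
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise ValueError("zero row or column marginal")
    stat, p, dof, _ = stats.chi2_contingency(counts, correction=False)
    return BivariateResult(covariate, "chi_squared", float(stat), (int(dof),), float(p))


def anova_f(groups, covariate: str = "") -> BivariateResult:
    """One-way fixed-effects ANOVA F test across groups of numeric values."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    pooled = np.concatenate(groups)
    if np.unique(pooled).size < 2:
        raise ValueError("all values identical")
    stat, p = stats.f_oneway(*groups)
    df = (len(groups) - 1, len(pooled) - len(groups))
    return BivariateResult(covariate, "anova_f", float(stat), df, float(p))


def bivariate_screen(
    prepared: PreparedCovariates, labels: pd.Series, alpha: float = 0.05
) -> tuple[pd.DataFrame, list[str]]:
    """Test every covariate against cluster membership.

    Returns the test table and the covariates significant at ``alpha``
    (the entry set for the multivariable model).
    """
    labels = labels.loc[prepared.data.index]
    results = []
    for name in prepared.categorical:
        counts = pd.crosstab(prepared.data[name], labels)
        results.append(chi_squared_test(counts.values, covariate=name))
    for name in prepared.numeric:
        groups = [g.values for _, g in prepared.data[name].groupby(labels)]
        results.append(anova_f(groups, covariate=name))
    table = pd.DataFrame(
        [
            {
                "covariate": r.covariate,
                "test": r.test,
                "statistic": r.statistic,
                "df": r.df,
                "p_value": r.p_value,
            }
            for r in results
        ]
    )
    selected = table.loc[table.p_value < alpha, "covariate"].tolist()
    return table, selected


@dataclass
class MultinomialModel:
    """Fitted multinomial logit with the largest cluster as reference."""

    reference: int
    clusters: list[int]  # non-reference clusters, model row order
    covariates: list[str]
    params: pd.DataFrame  # (predictor, cluster) -> beta
    bse: pd.DataFrame
    llf: float
    aic: float
    n: int
    or_table: pd.DataFrame = field(repr=False, default=None)
    converged: bool = True

    def predict_shares(self, design: pd.DataFrame) -> np.ndarray:
        """Mean predicted membership probabilities (reference first)."""
        eta = design.values @ self.params.values  # (n, k-1)
        eta = np.concatenate([np.zeros((len(design), 1)), eta], axis=1)
        eta -= eta.max(axis=1, keepdims=True)
        p = np.exp(eta)
        p /= p.sum(axis=1, keepdims=True)
        return p.mean(axis=0)


class FitError(RuntimeError):
    """Multinomial fit failed to converge; carries the optimizer trace."""


def _separation_flags(
    design: pd.DataFrame, y: pd.Series, clusters: list[int]
) -> set[tuple[int, str]]:
    """(cluster, predictor) cells with quasi-complete separation.

    A dummy category with zero observations in some outcome cluster makes
    the corresponding log odds ratio diverge; those cells are flagged so the
    odds-ratio table reports them as non-estimable.
    """
    flags = set()
    dummy_cols = [
        c
        for c in design.columns
        if c != "const" and set(np.unique(design[c])) <= {0.0, 1.0}
    ]
    reference = min(y.unique())
    for col in dummy_cols:
        vals = design[col]
        # category empty in the reference cluster: every contrast against
        # it diverges
        if vals[y == reference].sum() == 0:
            flags.update((cl, col) for cl in clusters)
        for cl in clusters:
            if vals[y == cl].sum() == 0:
                flags.add((cl, col))
    # reference category of a covariate empty in a cluster: all of that
    # covariate's dummies diverge for the cluster
    groups: dict[str, list[str]] = {}
    for col in dummy_cols:
        if "[" in col:
            groups.setdefault(col.split("[", 1)[0], []).append(col)
    for name, cols in groups.items():
        in_ref_cat = design[cols].sum(axis=1) == 0
        for cl in [reference] + list(clusters):
            if not (in_ref_cat & (y == cl)).any():
                targets = clusters if cl == reference else [cl]
                for t in targets:
                    flags.update((t, c) for c in cols)
    return flags


def fit_multinomial(
    design: pd.DataFrame,
    labels: pd.Series,
    covariates: list[str] | None = None,
    tol: float = 1e-8,
    maxiter: int = 200,
) -> MultinomialModel:
    """Maximum-likelihood multinomial logit via Newton iterations.

    The reference outcome is the largest cluster (cluster 1 after the size
    renumbering).  Standard errors come from the observed information; odds
    ratios are reported with Wald 95% confidence intervals, with
    quasi-separated cells flagged non-estimable instead of divergent.
    """
    import statsmodels.api as sm

    labels = labels.loc[design.index]
    clusters = sorted(labels.unique())
    reference = min(clusters)  # cluster 1 = largest after renumbering
    order = [reference] + [c for c in clusters if c != reference]
    y = labels.map({c: i for i, c in enumerate(order)})

    flags = _separation_flags(design, labels, order[1:])
    model = sm.MNLogit(y.values, design.values)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(method="newton", maxiter=maxiter, gtol=tol, disp=False)
        except Exception:
            res = None
        if res is None or not np.isfinite(res.llf):
            try:
                res = model.fit(method="lbfgs", maxiter=5 * maxiter, disp=False)
            except Exception as exc:  # pragma: no cover - pathological designs
                raise FitError(f"multinomial fit failed: {exc}") from exc
    if not np.all(np.isfinite(res.params)):
        raise FitError("multinomial fit diverged (non-finite coefficients)")

    try:
        bse_arr = np.asarray(res.bse)
        if not np.all(np.isfinite(bse_arr)):
            raise ValueError
    except Exception:
        # Observed information via pseudo-inverse: under quasi-separation the
        # Hessian is singular and the affected SEs are meaningless anyway
        # (the corresponding cells are flagged non-estimable below).
        hess = model.hessian(np.asarray(res.params).ravel(order="F"))
        cov = np.linalg.pinv(-hess)
        bse_arr = np.sqrt(np.abs(np.diag(cov))).reshape(
            np.asarray(res.params).shape, order="F"
        )
    params = pd.DataFrame(res.params, index=design.columns, columns=order[1:])
    bse = pd.DataFrame(bse_arr, index=design.columns, columns=order[1:])
    k = len(order)
    p_par = (k - 1) * design.shape[1]
    aic = float(-2 * res.llf + 2 * p_par)

    rows = []
    z = stats.norm.ppf(0.975)
    for cl in order[1:]:
        for pred in design.columns:
            beta = params.loc[pred, cl]
            se = bse.loc[pred, cl]
            sep = (cl, pred) in flags
            rows.append(
                {
                    "cluster": cl,
                    "predictor": pred,
                    "beta": beta,
                    "se": se,
                    "odds_ratio": np.nan if sep else float(np.exp(beta)),
                    "ci_low": np.nan if sep else float(np.exp(beta - z * se)),
                    "ci_high": np.nan if sep else float(np.exp(beta + z * se)),
                    "separated": sep,
                }
            )
    or_table = pd.DataFrame(rows)
    return MultinomialModel(
        reference=reference,
        clusters=order[1:],
        covariates=covariates if covariates is not None else [],
        params=params,
        bse=bse,
        llf=float(res.llf),
        aic=aic,
        n=len(design),
        or_table=or_table,
        converged=bool(getattr(res, "mle_retvals", {}).get("converged", True)),
    )


def backward_stepwise_aic(
    initial: list[str],
    prepared: PreparedCovariates,
    labels: pd.Series,
) -> tuple[list[str], MultinomialModel, list[dict]]:
    """Backward covariate elimination under AIC.

    Starting from the entry set, each step refits the model without each
    remaining covariate (all of its dummies at once) and removes the one
    whose absence yields the lowest AIC, provided that improves on the
    current model; stops when no removal improves the criterion.  Returns
    the kept covariates, the final model and the AIC trace.
    """
    current = list(initial)
    model = fit_multinomial(prepared.design_matrix(current), labels, current)
    trace = [{"covariates": list(current), "aic": model.aic, "dropped": None}]
    while current:
        candidates = []
        for name in current:
            reduced = [c for c in current if c != name]
            m = fit_multinomial(prepared.design_matrix(reduced), labels, reduced)
            candidates.append((m.aic, name, m))
        best_aic, best_name, best_model = min(candidates, key=lambda t: t[0])
        if best_aic >= model.aic:
            break
        current = [c for c in current if c != best_name]
        model = best_model
        trace.append({"covariates": list(current), "aic": model.aic, "dropped": best_name})
    return current, model, trace
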