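"""Comet-assay tail-moment statistics.

Subjects are school children with a buccal-cell comet tail moment
(dimensionless DNA-damage index), demographic/lifestyle covariates, and
school-level PAH exposure assignments.  The module provides exposed-vs-
comparative group comparison, covariate-stratified comparisons, ordinary
least squares tail-moment models with backward elimination, and the four
published fixed-coefficient prediction equations.

A Shapiro-Wilk normality gate accompanies every parametric test: the
parametric result is always reported, with a Mann-Whitney / Kruskal-Wallis
fallback alongside whenever normality is rejected at alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted
import statsmodels.api as sm

GROUPS = ("exposed", "comparative")
COVARIATES = ("tobacco_smoke", "grilled_food", "supplement",
              "mosquito_coil", "open_burning")
#: Columns a subject table must provide.
SUBJECT_COLUMNS = ("subject_id", "group", "school", "age", "sex", "bmi",
                   "body_weight_kg", "tail_moment", *COVARIATES)


@dataclass(frozen=True)
class SubjectRecord:
    """One child: tail moment plus covariates and exposure assignment."""

    subject_id: str
    group: str
    school: str
    age: int
    sex: str
    bmi: float
    body_weight_kg: float
    tail_moment: float
    covariates: dict[str, int] = field(default_factory=dict)
    exposure: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.tail_moment < 0:
            raise ValueError("tail moment must be >= 0")
        if not (9 <= self.age <= 11):
            raise ValueError(f"age {self.age} outside the 9-11 study range")
        for k, v in self.covariates.items():
            if v not in (0, 1):
                raise ValueError(f"covariate {k} must be 0/1, got {v}")


def _normality_p(x: np.ndarray) -> float:
    return float(stats.shapiro(x).pvalue) if len(x) >= 3 else 1.0


@dataclass
class GroupComparison:
    summaries: pd.DataFrame        # group, n, mean, sd
    t_stat: float
    p_value: float                 # Welch's t
    normality_p: dict[str, float]
    nonparametric_p: float | None  # Mann-Whitney when normality rejected
    school_anova: pd.DataFrame     # per-group one-way ANOVA across schools


def compare_groups(subjects: pd.DataFrame,
                   value: str = "tail_moment") -> GroupComparison:
    """Exposed vs comparative comparison of a subject-level outcome.

    Welch's two-sample t-test between groups, plus a one-way ANOVA across
    schools within each group.  Requires >= 2 subjects per group.
    """
    groups = {g: subjects.loc[subjects["group"] == g, value].to_numpy(float)
              for g in GROUPS}
    for g, x in groups.items():
        if len(x) < 2:
            raise ValueError(f"group {g!r} has {len(x)} subjects; need >= 2")
    a, b = groups["exposed"], groups["comparative"]
    t_res = stats.ttest_ind(a, b, equal_var=False)
    norm = {g: _normality_p(x) for g, x in groups.items()}
    nonpar = None
    if min(norm.values()) < 0.05:
        nonpar = float(stats.mannwhitneyu(a, b,
                                          alternative="two-sided").pvalue)
    summaries = pd.DataFrame(
        [{"group": g, "n": len(x), "mean": x.mean(), "sd": x.std(ddof=1)}
         for g, x in groups.items()])
    anova_rows = []
    for g in GROUPS:
        sub = subjects[subjects["group"] == g]
        levels = [lv[value].to_numpy(float)
                  for _, lv in sub.groupby("school") if len(lv) >= 2]
        if len(levels) >= 2:
            f = stats.f_oneway(*levels)
            anova_rows.append({"group": g, "n_schools": len(levels),
                               "F": float(f.statistic),
                               "p": float(f.pvalue)})
    return GroupComparison(summaries, float(t_res.statistic),
                           float(t_res.pvalue), norm, nonpar,
                           pd.DataFrame(anova_rows))


def stratified_comparison(subjects: pd.DataFrame, factor: str,
                          value: str = "tail_moment") -> pd.DataFrame:
    """Per-level summaries and tests of a factor, within each group.

    ``factor`` must be a registered covariate, ``age`` or ``sex``.  Levels
    with fewer than 2 subjects are flagged and excluded from the test.
    Two usable levels -> Welch's t; more -> one-way ANOVA; a Mann-Whitney /
    Kruskal-Wallis p accompanies the result when normality is rejected.
    """
    if factor not in (*COVARIATES, "age", "sex"):
        raise ValueError(f"{factor!r} is not a registered stratification "
                         f"factor (choose from {COVARIATES + ('age', 'sex')})")
    rows = []
    for g in GROUPS:
        sub = subjects[subjects["group"] == g]
        levels, excluded = {}, []
        for lv, lv_df in sub.groupby(factor):
            x = lv_df[value].to_numpy(float)
            if len(x) >= 2:
                levels[lv] = x
            else:
                excluded.append(lv)
        if len(levels) < 2:
            raise ValueError(
                f"factor {factor!r} has {len(levels)} usable level(s) in "
                f"group {g!r}: nothing to compare")
        arrays = list(levels.values())
        if len(arrays) == 2:
            test = "welch_t"
            p = float(stats.ttest_ind(*arrays, equal_var=False).pvalue)
            nonpar = float(stats.mannwhitneyu(
                *arrays, alternative="two-sided").pvalue)
        else:
            test = "anova"
            p = float(stats.f_oneway(*arrays).pvalue)
            nonpar = float(stats.kruskal(*arrays).pvalue)
        norm_ok = min(_normality_p(x) for x in arrays) >= 0.05
        for lv, x in levels.items():
            rows.append({"group": g, "factor": factor, "level": lv,
                         "n": len(x), "mean": x.mean(),
                         "sd": x.std(ddof=1), "test": test, "p": p,
                         "nonparametric_p": float("nan") if norm_ok else nonpar,
                         "excluded_levels": ",".join(map(str, excluded))})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# regression models

@dataclass(frozen=True)
class RegressionModel:
    """Affine tail-moment predictor with its fit statistics."""

    intercept: float
    coefficients: dict[str, float]
    adj_r2: float | None = None
    f_stat: float | None = None
    p_value: float | None = None

    def predict(self, covariates: dict[str, float]) -> float:
        missing = [k for k in self.coefficients if k not in covariates]
        if missing:
            raise ValueError(f"missing predictors: {missing}")
        return self.intercept + sum(b * covariates[k]
                                    for k, b in self.coefficients.items())


#: The four published fixed-coefficient prediction equations
#: (tail moment from school-level PAH exposure and open burning).
FIXED_MODELS: dict[str, RegressionModel] = {
    "model1": RegressionModel(12.892, {"total_outdoor_pahs": 0.054,
                                       "open_burning": -2.415}, adj_r2=0.110),
    "model2": RegressionModel(14.120, {"carcinogen_outdoor_pahs": 0.170,
                                       "open_burning": -1.870}, adj_r2=0.124),
    "model3": RegressionModel(13.345, {"total_indoor_pahs": 0.076,
                                       "open_burning": -2.190}, adj_r2=0.115),
    "model4": RegressionModel(15.468, {"carcinogen_indoor_pahs": 0.187,
                                       "open_burning": -2.328}, adj_r2=0.127),
}


def predict_tail_moment(model: RegressionModel | str,
                        covariates: dict[str, float]) -> float:
    """Affine evaluation of a fitted or published fixed-coefficient model."""
    if isinstance(model, str):
        model = FIXED_MODELS[model]
    return model.predict(covariates)


class TailMomentOLS(RegressorMixin, BaseEstimator):
    """Ordinary least squares tail-moment model with backward elimination.

    Parameters
    ----------
    alpha : float, default 0.05
        Predictors with p-value above this are eliminated one at a time
        (worst first) until all survivors are significant.
    backward : bool, default True
        Set False to keep every predictor.
    cond_threshold : float, default 1e8
        Condition number above which the design is declared collinear; the
        error names the most correlated predictor pair.

    Attributes
    ----------
    intercept_, coef_ : fitted affine coefficients (over selected features)
    feature_names_ : surviving predictor names, in coefficient order
    adj_r2_, f_stat_, f_p_value_ : overall fit statistics
    model_ : :class:`RegressionModel` view of the fit
    """

    def __init__(self, alpha: float = 0.05, backward: bool = True,
                 cond_threshold: float = 1e8):
        self.alpha = alpha
        self.backward = backward
        self.cond_threshold = cond_threshold

    def fit(self, X, y):
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float),
                             columns=[f"x{i}" for i in
                                      range(np.asarray(X).shape[1])])
        X = X.astype(float)
        y = np.asarray(y, dtype=float)
        n, p = X.shape
        if n <= p + 1:
            raise ValueError(f"need n > n_predictors + 1 ({n} <= {p + 1}): "
                             "no residual degrees of freedom")
        const = [c for c in X.columns if X[c].nunique() == 1]
        if const:
            raise ValueError(f"constant predictor(s): {const}")
        self._check_collinearity(X)

        cols = list(X.columns)
        while True:
            res = sm.OLS(y, sm.add_constant(X[cols])).fit()
            if not self.backward or len(cols) == 0:
                break
            pvals = res.pvalues.drop("const")
            worst = pvals.idxmax()
            if pvals[worst] <= self.alpha:
                break
            cols.remove(worst)
            if not cols:
                res = sm.OLS(y, np.ones((n, 1))).fit()
                break

        self.results_ = res
        self.feature_names_ = list(cols)
        params = res.params
        self.intercept_ = float(params.iloc[0]) if len(params) else 0.0
        self.coef_ = np.array([params[c] for c in cols], dtype=float)
        self.adj_r2_ = float(res.rsquared_adj) if cols else 0.0
        self.f_stat_ = float(res.fvalue) if cols else float("nan")
        self.f_p_value_ = float(res.f_pvalue) if cols else float("nan")
        self.model_ = RegressionModel(
            self.intercept_, dict(zip(cols, map(float, self.coef_))),
            adj_r2=self.adj_r2_, f_stat=self.f_stat_,
            p_value=self.f_p_value_)
        self.n_features_in_ = p
        return self

    def _check_collinearity(self, X: pd.DataFrame):
        Z = (X - X.mean()) / X.std(ddof=1)
        cond = np.linalg.cond(Z.to_numpy())
        if cond > self.cond_threshold:
            corr = Z.corr().abs().to_numpy()
            np.fill_diagonal(corr, 0.0)
            i, j = np.unravel_index(np.argmax(corr), corr.shape)
            raise ValueError(
                f"collinear design (condition number {cond:.3g}); most "
                f"correlated pair: {X.columns[i]!r} and {X.columns[j]!r}")

    def predict(self, X):
        check_is_fitted(self, "coef_")
        if isinstance(X, pd.DataFrame):
            X = X[self.feature_names_].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        return self.intercept_ + X @ self.coef_


def fit_tail_moment_model(subjects: pd.DataFrame, predictors: list[str],
                          outcome: str = "tail_moment",
                          alpha: float = 0.05) -> RegressionModel:
    """Functional wrapper: backward-eliminated OLS on a subject table."""
    est = TailMomentOLS(alpha=alpha).fit(subjects[predictors],
                                         subjects[outcome])
    return est.model_
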