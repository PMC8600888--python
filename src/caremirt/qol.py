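"""SF-36 handling, cohort descriptives, and the resilience-to-QoL link.

Quality of life enters as eight SF-36 domain scores on the 0-100 scale.
After dichotomizing QoL against a normative cut-off, the association
with resilience is examined three ways: a descriptive stratified table
of the cohort, a penalized-spline logistic GAM testing for a non-linear
dose-response, and logistic regressions giving crude, covariate-adjusted
and per-standard-deviation odds ratios across latent resilience classes.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.gam.api import BSplines, GLMGam

__all__ = [
    "SF36_DOMAINS",
    "TABLE1_STRATIFIED_COUNTS",
    "scale_domain",
    "dichotomize_qol",
    "round_half_up",
    "table1_descriptives",
    "table1_reference_cohort",
    "GAMFitReport",
    "fit_gam_logistic",
    "DoseResponseTable",
    "logistic_dose_response",
]

SF36_DOMAINS = ["pf", "gh", "rp", "bp", "sf", "vt", "re", "mh"]

#: Published stratified cohort counts (cancer type of the care recipient x
#: covariate category), keyed in from the source cohort table (N = 382).
TABLE1_STRATIFIED_COUNTS: dict[str, dict[str, dict[str, int]]] = {
    "sex": {
        "female": {"lung": 65, "gastric": 65, "colorectal": 62, "breast": 37},
        "man": {"lung": 16, "gastric": 43, "colorectal": 30, "breast": 64},
    },
    "age_band": {
        "<40": {"lung": 7, "gastric": 10, "colorectal": 4, "breast": 11},
        "40-50": {"lung": 35, "gastric": 61, "colorectal": 20, "breast": 31},
        "50-60": {"lung": 25, "gastric": 25, "colorectal": 41, "breast": 35},
        ">60": {"lung": 14, "gastric": 12, "colorectal": 27, "breast": 24},
    },
    "education": {
        "middle_or_lower": {"lung": 47, "gastric": 69, "colorectal": 63, "breast": 48},
        "high_or_higher": {"lung": 34, "gastric": 39, "colorectal": 29, "breast": 53},
    },
    "income": {
        "<5000": {"lung": 22, "gastric": 33, "colorectal": 37, "breast": 38},
        "5000-10000": {"lung": 42, "gastric": 48, "colorectal": 27, "breast": 42},
        ">10000": {"lung": 17, "gastric": 27, "colorectal": 28, "breast": 21},
    },
    "relationship": {
        "spouse": {"lung": 61, "gastric": 87, "colorectal": 79, "breast": 61},
        "non_spouse": {"lung": 20, "gastric": 21, "colorectal": 13, "breast": 40},
    },
    "religion": {
        "yes": {"lung": 25, "gastric": 40, "colorectal": 22, "breast": 24},
        "none": {"lung": 56, "gastric": 68, "colorectal": 70, "breast": 77},
    },
    "employment": {
        "employed": {"lung": 29, "gastric": 34, "colorectal": 24, "breast": 59},
        "unemployed": {"lung": 52, "gastric": 74, "colorectal": 68, "breast": 42},
    },
    "months_caregiving": {
        "<6": {"lung": 40, "gastric": 19, "colorectal": 16, "breast": 33},
        "6-12": {"lung": 24, "gastric": 32, "colorectal": 32, "breast": 41},
        "13-24": {"lung": 12, "gastric": 32, "colorectal": 27, "breast": 16},
        ">24": {"lung": 5, "gastric": 25, "colorectal": 17, "breast": 11},
    },
    "comorbidities": {
        "none": {"lung": 47, "gastric": 49, "colorectal": 32, "breast": 56},
        "one": {"lung": 26, "gastric": 45, "colorectal": 36, "breast": 25},
        "two_or_more": {"lung": 8, "gastric": 14, "colorectal": 24, "breast": 20},
    },
}


def scale_domain(raw: float, domain_min: float, domain_range: float) -> float:
    """Affine 0-100 rescaling of a raw domain score."""
    if domain_range <= 0:
        raise ValueError("domain_range must be positive")
    if not domain_min <= raw <= domain_min + domain_range:
        raise ValueError(
            f"raw score {raw} outside [{domain_min}, {domain_min + domain_range}]"
        )
    return 100.0 * (raw - domain_min) / domain_range


def dichotomize_qol(
    profile, cutoffs, rule: str = "composite_mean"
) -> np.ndarray:
    """High/low QoL indicator from SF-36 domain scores and normative cut-offs.

    ``rule="composite_mean"`` (default): the mean of the eight domains is
    compared to the composite cut-off (``cutoffs`` scalar, or the mean of
    a per-domain mapping); scores at or above the cut-off code 1.
    ``rule="domain_majority"``: a person codes 1 when at least half the
    domains sit at or above their own cut-offs.  No normative values are
    shipped — the cut-off is a required input.
    """
    frame = pd.DataFrame(profile)
    if cutoffs is None:
        raise ValueError("a normative cut-off is required; none is shipped by default")
    if ((frame.to_numpy() < 0) | (frame.to_numpy() > 100)).any():
        raise ValueError("domain scores must lie in [0, 100]")
    if rule == "composite_mean":
        composite = frame.mean(axis=1).to_numpy()
        cut = (
            float(np.mean(list(cutoffs.values())))
            if isinstance(cutoffs, dict)
            else float(cutoffs)
        )
        return (composite >= cut).astype(np.int64)
    if rule == "domain_majority":
        if not isinstance(cutoffs, dict):
            cutoffs = {c: float(cutoffs) for c in frame.columns}
        above = np.column_stack(
            [(frame[c].to_numpy() >= cutoffs[c]) for c in frame.columns]
        )
        return (above.mean(axis=1) >= 0.5).astype(np.int64)
    raise ValueError(f"unknown dichotomization rule {rule!r}")


def round_half_up(value: float, decimals: int = 1) -> float:
    """Decimal half-up rounding (the convention of printed cohort tables)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def table1_descriptives(
    covariates: pd.DataFrame, strata: pd.Series | str | None = None
) -> pd.DataFrame:
    """Counts and half-up percentages per covariate category per stratum.

    Returns a tidy frame with one row per (covariate, category, stratum)
    plus ``total`` rows; percentages are within-stratum and rounded
    half-up to one decimal.  Empty strata get a count of 0 and an
    undefined (NaN) percentage.
    """
    covariates = pd.DataFrame(covariates)
    if isinstance(strata, str):
        strata_values = covariates[strata]
        covariates = covariates.drop(columns=[strata])
    elif strata is not None:
        strata_values = pd.Series(strata)
    else:
        strata_values = pd.Series(["all"] * len(covariates), index=covariates.index)
    strat_levels = list(pd.unique(strata_values.astype(str)))
    rows = []
    for cov in covariates.columns:
        col = covariates[cov].astype(str)
        categories = list(pd.unique(col))
        for cat in categories:
            for level in strat_levels + ["total"]:
                if level == "total":
                    denom = len(col)
                    count = int((col == cat).sum())
                else:
                    in_stratum = strata_values.astype(str) == level
                    denom = int(in_stratum.sum())
                    count = int(((col == cat) & in_stratum).sum())
                pct = round_half_up(100.0 * count / denom) if denom else np.nan
                rows.append(
                    {
                        "covariate": cov,
                        "category": cat,
                        "stratum": level,
                        "count": count,
                        "percent": pct,
                    }
                )
    return pd.DataFrame(rows)


def table1_reference_cohort() -> pd.DataFrame:
    """Per-person covariate frame reproducing the published stratified counts.

    Covariate columns are filled independently within each cancer-type
    stratum to match the printed cell counts exactly; the joint
    distribution beyond those margins is synthetic (the source table
    reports margins only).
    """
    strata_sizes = {"lung": 81, "gastric": 108, "colorectal": 92, "breast": 101}
    frames = []
    for stratum, size in strata_sizes.items():
        cols = {"cancer_type": [stratum] * size}
        for cov, cats in TABLE1_STRATIFIED_COUNTS.items():
            values = []
            for cat, per_stratum in cats.items():
                values.extend([cat] * per_stratum[stratum])
            if len(values) != size:
                raise AssertionError(f"counts for {cov}/{stratum} do not sum to {size}")
            cols[cov] = values
        frames.append(pd.DataFrame(cols))
    return pd.concat(frames, ignore_index=True)


@dataclass
class GAMFitReport:
    """Penalized-spline logistic fit of QoL on the resilience score."""

    x_grid: np.ndarray
    fitted_logit: np.ndarray
    edf_smooth: float
    alpha: float
    loglik: float
    loglik_linear: float
    lr_statistic: float
    lr_df: float
    lr_pvalue: float


def fit_gam_logistic(
    x: np.ndarray,
    y: np.ndarray,
    df: int = 10,
    degree: int = 3,
    alphas: np.ndarray | None = None,
    alpha: float | None = None,
) -> GAMFitReport:
    """Penalized B-spline logistic regression of binary y on a smooth of x.

    The smoothing penalty is chosen from a log-spaced candidate grid by
    approximate GCV (deviance over squared residual degrees of freedom),
    unless ``alpha`` fixes it.  Reports the effective degrees of freedom
    of the smooth term and a likelihood-ratio comparison against the
    plain linear-logit submodel (df = EDF of the smooth minus 1, floored
    at 0.5) — EDF near 1 and a non-significant test mean no evidence of
    non-linearity.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y).ravel()
    if len(x) < 50:
        raise ValueError("at least 50 observations required for the smooth fit")
    if len(np.unique(y)) < 2:
        raise ValueError("y must contain both outcome levels")
    if x.std() < 1e-12:
        raise ValueError("x is constant: no spline basis can be built")

    bs = BSplines(x[:, None], df=[df], degree=[degree])
    exog = np.ones((len(x), 1))
    n = len(x)

    def fit_at(a):
        model = GLMGam(y, exog=exog, smoother=bs, alpha=[a], family=sm.families.Binomial())
        return model.fit()

    if alpha is None:
        if alphas is None:
            alphas = np.logspace(0, 7, 8)
        best = None
        for a in alphas:
            try:
                res = fit_at(a)
            except Exception:
                continue
            edf_tot = float(np.sum(res.edf))
            gcv = res.deviance / n / max(1e-8, (1.0 - edf_tot / n) ** 2)
            if best is None or gcv < best[0]:
                best = (gcv, a, res)
        if best is None:
            raise ValueError("smooth fit failed on every candidate penalty")
        _, alpha, res = best
    else:
        res = fit_at(alpha)

    edf_smooth = float(np.sum(res.edf[1:]))  # exclude the free intercept column
    ll_gam = float(res.llf)

    lin = sm.GLM(y, sm.add_constant(x), family=sm.families.Binomial()).fit()
    ll_lin = float(lin.llf)
    lr = max(2.0 * (ll_gam - ll_lin), 0.0)
    lr_df = max(edf_smooth - 1.0, 0.5)
    p = float(stats.chi2.sf(lr, lr_df))
    order = np.argsort(x)
    grid = x[order]
    fitted = res.predict(exog[order], exog_smooth=grid[:, None], which="linear")
    return GAMFitReport(
        x_grid=grid, fitted_logit=np.asarray(fitted, dtype=float),
        edf_smooth=edf_smooth, alpha=float(alpha),
        loglik=ll_gam, loglik_linear=ll_lin,
        lr_statistic=lr, lr_df=lr_df, lr_pvalue=p,
    )


@dataclass
class DoseResponseTable:
    """Crude / adjusted / per-SD odds ratios across resilience classes."""

    table: pd.DataFrame
    covariates_used: list[str]
    monotone_class_ors: bool

    def per_sd_row(self, kind: str = "per_sd_adjusted") -> pd.Series:
        return self.table.set_index("contrast").loc[kind]


def _logit_or_rows(y, X, names, labels):
    model = sm.GLM(y, X, family=sm.families.Binomial())
    res = model.fit()
    rows = []
    for name, label in zip(names, labels):
        i = list(X.columns).index(name)
        beta, se = res.params.iloc[i], res.bse.iloc[i]
        rows.append(
            {
                "contrast": label,
                "or": float(np.exp(beta)),
                "ci_low": float(np.exp(beta - 1.96 * se)),
                "ci_high": float(np.exp(beta + 1.96 * se)),
                "p_value": float(res.pvalues.iloc[i]),
            }
        )
    return rows


def logistic_dose_response(
    classes: np.ndarray,
    total_score: np.ndarray,
    covariates: pd.DataFrame | None,
    y: np.ndarray,
    reference_class=None,
) -> DoseResponseTable:
    """Dose-response odds ratios of high QoL across resilience classes.

    Three fits: crude (class dummies only), adjusted (class dummies plus
    dummy-coded covariates), and per-SD (total score standardized by the
    analysis-sample SD, plus covariates).  Wald 95% intervals
    ``exp(beta +/- 1.96 se)``; monotonicity of the adjusted class ORs is
    reported as the dose-response check.
    """
    if isinstance(classes, pd.Categorical):
        classes = pd.Series(classes)
    elif not isinstance(getattr(classes, "dtype", None), pd.CategoricalDtype):
        classes = pd.Series(np.asarray(classes)).astype("category")
    else:
        classes = pd.Series(classes)
    levels = list(classes.cat.categories)
    if reference_class is None:
        reference_class = levels[0]
    if reference_class not in levels:
        raise ValueError(f"reference class {reference_class!r} not present")
    counts = classes.value_counts()
    empty = [str(lvl) for lvl in levels if counts.get(lvl, 0) == 0]
    if empty:
        raise ValueError(f"class {empty[0]} is empty; cannot estimate its contrast")
    y = np.asarray(y).ravel()
    total = np.asarray(total_score, dtype=float).ravel()

    dummies = pd.get_dummies(classes, prefix="class", dtype=float)
    ref_col = f"class_{reference_class}"
    dummies = dummies.drop(columns=[ref_col])
    contrast_labels = [
        f"{c.removeprefix('class_')} vs {reference_class}" for c in dummies.columns
    ]

    cov_frame = pd.DataFrame(index=dummies.index)
    cov_names: list[str] = []
    if covariates is not None and len(covariates.columns):
        cov_frame = pd.get_dummies(
            pd.DataFrame(covariates).astype(str), drop_first=True, dtype=float
        )
        cov_frame.index = dummies.index
        cov_names = list(pd.DataFrame(covariates).columns)

    const = pd.Series(1.0, index=dummies.index, name="const")

    X_crude = pd.concat([const, dummies], axis=1)
    rows = [
        dict(r, model="crude")
        for r in _logit_or_rows(y, X_crude, dummies.columns, contrast_labels)
    ]

    X_adj = pd.concat([const, dummies, cov_frame], axis=1)
    adj_rows = _logit_or_rows(y, X_adj, dummies.columns, contrast_labels)
    rows += [dict(r, model="adjusted") for r in adj_rows]

    if total.std() > 0:  # per-SD contrasts are undefined for a constant score
        z = (total - total.mean()) / total.std()
        X_sd_crude = pd.concat([const, pd.Series(z, index=dummies.index, name="z")], axis=1)
        rows += [
            dict(r, model="crude")
            for r in _logit_or_rows(y, X_sd_crude, ["z"], ["per_sd_crude"])
        ]
        X_sd = pd.concat(
            [const, pd.Series(z, index=dummies.index, name="z"), cov_frame], axis=1
        )
        rows += [
            dict(r, model="adjusted")
            for r in _logit_or_rows(y, X_sd, ["z"], ["per_sd_adjusted"])
        ]

    table = pd.DataFrame(rows)
    adj_ors = [r["or"] for r in adj_rows]
    monotone = bool(np.all(np.diff(adj_ors) >= 0)) if len(adj_ors) > 1 else True
    return DoseResponseTable(table, cov_names, monotone)
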