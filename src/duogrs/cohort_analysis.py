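"""Association analyses over the scored duo cohort.

Linear models for continuous child BMI within the reference group,
case-cohort logistic models (reference pooled with the overweight-children
group, outcome = case-group membership), exposure-based cohort models
(reference pooled with the overweight-mothers group, outcome = child
overweight, group indicator as covariate, optional group-by-determinant
interaction), the derived ratio statistics comparing genetic and phenotypic
effects, score-validity correlations, and the simple two-group comparison
tests. Determinants are analysed in SD-units so estimates are per
reference-group SD; confidence intervals are Wald-type on the link scale,
exponentiated for odds ratios, and p-values are reported per model without
multiplicity adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

_Z975 = stats.norm.ppf(0.975)
#: |coefficient| on the logit scale beyond which we declare separation
_SEPARATION_NORM = 15.0


class ConvergenceError(RuntimeError):
    """Logistic fit failed to converge (e.g. complete separation)."""


@dataclass
class ModelResult:
    """One fitted determinant: estimate, Wald 95% CI, p, bookkeeping."""

    determinant: str
    n: int
    estimate: float
    ci_low: float
    ci_high: float
    p_value: float
    scale: str  # "linear_beta" | "odds_ratio"
    covariates: list[str] = field(default_factory=list)
    r_squared: float | None = None
    interaction: dict | None = None

    def __post_init__(self) -> None:
        if not self.ci_low <= self.estimate <= self.ci_high:
            raise ValueError("confidence interval does not bracket the estimate")
        if self.scale == "odds_ratio" and min(self.estimate, self.ci_low, self.ci_high) <= 0:
            raise ValueError("odds ratios must be positive")

    def to_row(self) -> dict:
        row = {
            "determinant": self.determinant, "n": self.n, "estimate": self.estimate,
            "ci_low": self.ci_low, "ci_high": self.ci_high, "p": self.p_value,
            "scale": self.scale, "covariates": ",".join(self.covariates) or "none",
        }
        if self.r_squared is not None:
            row["r_squared"] = self.r_squared
        if self.interaction is not None:
            row.update({f"interaction_{k}": v for k, v in self.interaction.items()})
        return row


def results_table(results: list[ModelResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_row() for r in results])


def fit_linear(y, x, covariate=None, *, name: str = "x") -> ModelResult:
    """OLS of y on x (plus one optional covariate), Wald CI on the slope."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    cols = {"x": x}
    covs = []
    if covariate is not None:
        cols["covariate"] = np.asarray(covariate, dtype=float)
        covs = ["covariate"]
    X = pd.DataFrame(cols)
    keep = ~(np.isnan(y) | X.isna().any(axis=1).to_numpy())
    y, X = y[keep], X[keep]
    if len(y) < 3:
        raise ValueError("need at least 3 complete observations")
    if np.ptp(X["x"]) == 0:
        raise ValueError("determinant is constant")
    fit = sm.OLS(y, sm.add_constant(X)).fit()
    beta, se = fit.params["x"], fit.bse["x"]
    return ModelResult(
        determinant=name, n=int(len(y)), estimate=float(beta),
        ci_low=float(beta - _Z975 * se), ci_high=float(beta + _Z975 * se),
        p_value=float(fit.pvalues["x"]), scale="linear_beta",
        covariates=covs, r_squared=float(fit.rsquared))


def fit_logistic(case, x, covariates: pd.DataFrame | None = None,
                 interaction: str | None = None, *, name: str = "x") -> ModelResult:
    """ML logistic fit reporting exp(beta) as OR with Wald 95% CI.

    ``interaction`` names a covariate column; the model then adds an
    x-by-covariate product term, and the result carries per-stratum ORs
    (covariate at 0 and 1) and the interaction p-value. Complete separation
    raises :class:`ConvergenceError` rather than returning huge estimates.
    """
    ycol = np.asarray(case, dtype=float)
    X = pd.DataFrame({"x": np.asarray(x, dtype=float)})
    if covariates is not None:
        for c in covariates.columns:
            X[c] = np.asarray(covariates[c], dtype=float)
    if interaction is not None:
        if interaction not in X.columns:
            raise ValueError(f"interaction covariate {interaction!r} not supplied")
        X["x_inter"] = X["x"] * X[interaction]
    keep = ~(np.isnan(ycol) | X.isna().any(axis=1).to_numpy())
    ycol, X = ycol[keep], X[keep]
    if len(np.unique(ycol)) < 2:
        raise ValueError("outcome has a single class")
    try:
        fit = sm.Logit(ycol, sm.add_constant(X)).fit(
            method="newton", maxiter=100, tol=1e-10, disp=0)
    except Exception as exc:  # statsmodels PerfectSeparation / LinAlg errors
        raise ConvergenceError(f"logistic fit failed: {exc}") from exc
    if not fit.mle_retvals.get("converged", True):
        raise ConvergenceError("logistic fit did not converge")
    if np.abs(fit.params.to_numpy()).max() > _SEPARATION_NORM:
        raise ConvergenceError("diverging coefficients indicate separation")

    beta, se = fit.params["x"], fit.bse["x"]
    inter = None
    if interaction is not None:
        bi, sei = fit.params["x_inter"], fit.bse["x_inter"]
        b1 = beta + bi
        cov = fit.cov_params()
        se1 = float(np.sqrt(cov.loc["x", "x"] + cov.loc["x_inter", "x_inter"]
                            + 2 * cov.loc["x", "x_inter"]))
        inter = {
            "or_group0": float(np.exp(beta)),
            "or_group0_low": float(np.exp(beta - _Z975 * se)),
            "or_group0_high": float(np.exp(beta + _Z975 * se)),
            "or_group1": float(np.exp(b1)),
            "or_group1_low": float(np.exp(b1 - _Z975 * se1)),
            "or_group1_high": float(np.exp(b1 + _Z975 * se1)),
            "p_interaction": float(fit.pvalues["x_inter"]),
        }
    return ModelResult(
        determinant=name, n=int(len(ycol)), estimate=float(np.exp(beta)),
        ci_low=float(np.exp(beta - _Z975 * se)),
        ci_high=float(np.exp(beta + _Z975 * se)),
        p_value=float(fit.pvalues["x"]), scale="odds_ratio",
        covariates=[c for c in X.columns if c not in ("x", "x_inter")],
        interaction=inter)


def run_case_cohort(ref: pd.DataFrame, ch_ow: pd.DataFrame,
                    determinants: list[str],
                    adjusted_pairs: dict[str, str] | None = None) -> list[ModelResult]:
    """Case-cohort analysis: odds of membership in the case group.

    Pools the reference subcohort with the overweight-children group and
    fits one unadjusted logistic model per determinant (SD-unit columns of
    both frames). ``adjusted_pairs`` maps a phenotype determinant to the
    transmitted-score column used as an adjustment covariate (the
    parental-BMI-adjusted-for-transmitted-GRS models).
    """
    overlap = set(ref["duo_id"]) & set(ch_ow["duo_id"])
    if overlap:
        raise ValueError(f"groups overlap: {sorted(overlap)[:3]} ...")
    pooled = pd.concat([ref.assign(_case=0), ch_ow.assign(_case=1)], ignore_index=True)
    if pooled["_case"].nunique() < 2 or ref.equals(ch_ow):
        raise ValueError("no contrast between groups")
    results = []
    for det in determinants:
        results.append(fit_logistic(pooled["_case"], pooled[det], name=det))
    for det, adj in (adjusted_pairs or {}).items():
        res = fit_logistic(pooled["_case"], pooled[det],
                           covariates=pooled[[adj]], name=f"{det}|{adj}")
        results.append(res)
    return results


def run_exposure_cohort(ref: pd.DataFrame, mo_ow: pd.DataFrame,
                        determinants: list[str],
                        with_interaction: bool = False,
                        outcome: str = "child_overweight") -> list[ModelResult]:
    """Exposure-based cohort analysis: odds of child overweight.

    Pools the reference subcohort with the overweight-mothers group; every
    adjusted model includes the group indicator (REF = 0). With
    ``with_interaction`` each model adds a group-by-determinant term and
    reports per-group ORs and the interaction p-value. The unadjusted
    group-indicator OR is reported as the first result.
    """
    overlap = set(ref["duo_id"]) & set(mo_ow["duo_id"])
    if overlap:
        raise ValueError(f"groups overlap: {sorted(overlap)[:3]} ...")
    pooled = pd.concat([ref.assign(_group=0), mo_ow.assign(_group=1)], ignore_index=True)
    y = pooled[outcome].astype(float)
    results = [fit_logistic(y, pooled["_group"], name="group_indicator")]
    for det in determinants:
        results.append(fit_logistic(
            y, pooled[det], covariates=pooled[["_group"]],
            interaction="_group" if with_interaction else None, name=det))
    return results


def effect_ratio(beta_a: float, beta_b: float) -> float:
    """Ratio of two effect sizes, rounded to 2 decimals."""
    if beta_b == 0:
        raise ZeroDivisionError("denominator effect size is zero")
    return round(beta_a / beta_b, 2)


def excess_or_ratio(or_a: float, or_b: float) -> float:
    """Ratio of excess odds ratios (OR - 1), rounded to 2 decimals.

    Requires the denominator OR to exceed 1 so the excess is positive.
    """
    if or_b <= 1:
        raise ValueError("denominator OR must exceed 1")
    return round((or_a - 1) / (or_b - 1), 2)


#: analytic correlation expectations under random mating, no nurture
EXPECTED_CORRELATIONS = {
    ("maternal", "child"): 0.5,
    ("maternal_transmitted", "child"): 1 / np.sqrt(2),
    ("paternal_transmitted", "child"): 1 / np.sqrt(2),
    ("maternal_non_transmitted", "child"): 0.0,
    ("maternal", "maternal_transmitted"): 1 / np.sqrt(2),
    ("maternal", "maternal_non_transmitted"): 1 / np.sqrt(2),
}


@dataclass
class ValidationReport:
    """Observed score correlations against their analytic expectations."""

    correlations: pd.DataFrame  # symmetric matrix over the components
    expected: pd.DataFrame  # pair, observed, expected, flag
    n: int


def validation_correlations(scores: pd.DataFrame, suffix: str = "_count") -> ValidationReport:
    """Pearson correlations among the five scores, with expectation flags.

    Under random mating and no nurture the maternal full score correlates
    0.5 with the child score, each transmitted half-score 1/sqrt(2) with
    the full score containing it, and the non-transmitted score 0 with the
    child score. Pairs deviating by more than 3/sqrt(n) + 0.02 are flagged.
    """
    comps = ["child", "maternal", "maternal_transmitted",
             "paternal_transmitted", "maternal_non_transmitted"]
    cols = [f"{c}{suffix}" for c in comps]
    data = scores[cols].to_numpy(dtype=float)
    n = data.shape[0]
    if n < 30:
        raise ValueError("need at least 30 duos for validation correlations")
    if (data.std(axis=0) == 0).any():
        raise ValueError("degenerate score variance")
    corr = pd.DataFrame(np.corrcoef(data, rowvar=False), index=comps, columns=comps)
    tol = 3 / np.sqrt(n) + 0.02
    rows = []
    for (a, b), exp in EXPECTED_CORRELATIONS.items():
        obs = corr.loc[a, b]
        rows.append({"pair": f"{a}~{b}", "observed": obs, "expected": exp,
                     "tolerance": tol, "flag": bool(abs(obs - exp) > tol)})
    return ValidationReport(correlations=corr, expected=pd.DataFrame(rows), n=n)


def compare_groups(values_a, values_b, binary: bool | None = None) -> tuple[float, float]:
    """Two-group comparison: Welch t-test, or pooled two-proportion z-test.

    ``binary`` is auto-detected from the data when None. Returns
    (statistic, p-value).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty group")
    if binary is None:
        binary = set(np.unique(np.concatenate([a, b]))) <= {0.0, 1.0}
    if binary:
        from statsmodels.stats.proportion import proportions_ztest
        stat, p = proportions_ztest([a.sum(), b.sum()], [len(a), len(b)])
        return float(stat), float(p)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 values per group for the t-test")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)
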