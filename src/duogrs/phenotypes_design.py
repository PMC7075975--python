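"""Phenotype standardization and sampling-group construction.

Parental BMI is standardized by plain internal z-scores; child BMI by sex-
and age-band-specific LMS (lambda-mu-sigma) z-scores. Overweight flags use
an absolute cutoff for adults (25 kg/m2) and a percentile-based z cutoff
for children. The three sampling groups mirror an extreme-sampling design:
a random reference subcohort (REF), a high-maternal-BMI exposure group
(MO-OW) and the children with the highest BMI z-scores (CH-OW), mutually
disjoint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

_L_EPS = 1e-8


def lms_zscore(x, L, M, S):
    """LMS z-score: ((x/M)^L - 1) / (L*S), with the log-limit at L = 0.

    Strictly increasing in x for fixed parameters; x, M, S must be
    positive.
    """
    x = np.asarray(x, dtype=float)
    L = np.asarray(L, dtype=float)
    M = np.asarray(M, dtype=float)
    S = np.asarray(S, dtype=float)
    if np.any(x <= 0) or np.any(M <= 0) or np.any(S <= 0):
        raise ValueError("x, M and S must be positive")
    ratio = x / M
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(np.abs(L) > _L_EPS,
                     (np.power(ratio, np.where(np.abs(L) > _L_EPS, L, 1.0)) - 1)
                     / (np.where(np.abs(L) > _L_EPS, L, 1.0) * S),
                     np.log(ratio) / S)
    return z if z.ndim else float(z)


@dataclass
class LMSReference:
    """Per (sex, age-month band) LMS parameters.

    ``table`` columns: sex, age_lo_months, age_hi_months (inclusive), L, M,
    S. Bands must not overlap within a sex.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        req = {"sex", "age_lo_months", "age_hi_months", "L", "M", "S"}
        if not req <= set(self.table.columns):
            raise ValueError(f"LMS reference missing columns {req - set(self.table.columns)}")
        if (self.table["M"] <= 0).any() or (self.table["S"] <= 0).any():
            raise ValueError("M and S must be positive")
        for sex, grp in self.table.groupby("sex"):
            g = grp.sort_values("age_lo_months")
            if (g["age_hi_months"].to_numpy()[:-1] >= g["age_lo_months"].to_numpy()[1:]).any():
                raise ValueError(f"overlapping age bands for sex {sex}")

    def zscores(self, bmi, sex, age_months) -> np.ndarray:
        bmi = np.asarray(bmi, dtype=float)
        sex = np.asarray(sex)
        age = np.asarray(age_months)
        z = np.full(bmi.shape, np.nan)
        for _, row in self.table.iterrows():
            sel = (sex == row["sex"]) & (age >= row["age_lo_months"]) & (age <= row["age_hi_months"])
            if sel.any():
                z[sel] = lms_zscore(bmi[sel], row["L"], row["M"], row["S"])
        if np.isnan(z).any():
            raise ValueError("some children fall outside the LMS reference age bands")
        return z

    @classmethod
    def fit(cls, bmi, sex, age_months, band_width: int = 3) -> "LMSReference":
        """Moment-matched reference from a (large) sample, with L fixed at 1.

        Per sex and age band, M is the sample mean and S the coefficient of
        variation, so the L=1 transform reduces to (x - M)/(M*S) — a
        transparent, desk-scale stand-in for a fitted growth reference.
        """
        df = pd.DataFrame({"bmi": np.asarray(bmi, float), "sex": np.asarray(sex),
                           "age": np.asarray(age_months)})
        lo_all = (df["age"] // band_width) * band_width
        rows = []
        for (s, lo), grp in df.groupby([df["sex"], lo_all]):
            if len(grp) < 2:
                raise ValueError(f"band (sex={s}, age>={lo}) has fewer than 2 children")
            mu = grp["bmi"].mean()
            sd = grp["bmi"].std(ddof=1)
            rows.append({"sex": s, "age_lo_months": int(lo),
                         "age_hi_months": int(lo + band_width - 1),
                         "L": 1.0, "M": mu, "S": sd / mu})
        return cls(pd.DataFrame(rows))


def internal_zscore(values, strata=None):
    """Per-stratum (x - mean)/SD with sample SD; NaN entries pass through."""
    x = np.asarray(values, dtype=float)
    if strata is None:
        strata = np.zeros(len(x), dtype=int)
    strata = np.asarray(strata)
    z = np.full(x.shape, np.nan)
    for s in pd.unique(strata):
        sel = (strata == s) & ~np.isnan(x)
        if sel.sum() < 2:
            raise ValueError(f"stratum {s!r} has fewer than 2 values")
        sd = x[sel].std(ddof=1)
        if not sd > 0:
            raise ValueError(f"stratum {s!r} has zero variance")
        z[sel] = (x[sel] - x[sel].mean()) / sd
    return z


def overweight_flags(values, rule: dict) -> np.ndarray:
    """Threshold flags: value >= cutoff (inclusive).

    ``rule`` is {"type": "absolute", "cutoff": 25.0} for adult BMI in
    kg/m2, {"type": "zscore", "cutoff": z} for child BMI z-scores, or
    {"type": "percentile", "percentile": 90} which converts the reference
    percentile to the corresponding normal z cutoff.
    """
    x = np.asarray(values, dtype=float)
    kind = rule.get("type")
    if kind == "absolute":
        cutoff = float(rule["cutoff"])
    elif kind == "zscore":
        cutoff = float(rule["cutoff"])
    elif kind == "percentile":
        cutoff = float(stats.norm.ppf(float(rule["percentile"]) / 100.0))
    else:
        raise ValueError(f"unknown overweight rule type {kind!r}")
    return x >= cutoff


ADULT_OVERWEIGHT_RULE = {"type": "absolute", "cutoff": 25.0}
CHILD_OVERWEIGHT_RULE = {"type": "percentile", "percentile": 90}


def sample_design_groups(
    phenotypes: pd.DataFrame,
    sizes: tuple[int, int, int],
    seed: int,
    maternal_bmi_threshold: float = 30.0,
    child_z_column: str = "child_bmi_z",
) -> pd.DataFrame:
    """Assign duos to the REF / MO_OW / CH_OW sampling groups.

    REF is a uniform random sample; MO_OW a random sample among mothers at
    or above ``maternal_bmi_threshold`` (REF members excluded); CH_OW the
    requested number of children with the highest BMI z-scores (REF and
    MO_OW excluded, ties broken by duo_id order). Deterministic given the
    seed. Returns a frame with duo_id and group in
    {REF, MO_OW, CH_OW, unselected}.
    """
    n_ref, n_mo, n_ch = sizes
    df = phenotypes.sort_values("duo_id", kind="stable").reset_index(drop=True)
    n = len(df)
    if n_ref + n_mo + n_ch > n:
        raise ValueError("requested group sizes exceed cohort size")
    rng = np.random.default_rng(seed)
    group = pd.Series("unselected", index=df.index)

    ref_idx = rng.choice(n, size=n_ref, replace=False)
    group.iloc[ref_idx] = "REF"

    eligible = df.index[(df["maternal_bmi"] >= maternal_bmi_threshold)
                        & (group == "unselected")].to_numpy()
    if len(eligible) < n_mo:
        raise ValueError(
            f"only {len(eligible)} mothers at or above BMI {maternal_bmi_threshold}; "
            f"{n_mo} requested")
    group.iloc[rng.choice(eligible, size=n_mo, replace=False)] = "MO_OW"

    free = df.index[group == "unselected"]
    if len(free) < n_ch:
        raise ValueError("not enough remaining duos for the CH_OW group")
    order = df.loc[free].sort_values(
        [child_z_column, "duo_id"], ascending=[False, True], kind="stable").index
    group.loc[order[:n_ch]] = "CH_OW"

    return pd.DataFrame({"duo_id": df["duo_id"].to_numpy(), "group": group.to_numpy()})
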