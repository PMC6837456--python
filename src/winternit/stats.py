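"""Cross-lake statistical synthesis of a winter nitrification survey.

The survey table is a pandas DataFrame in the packaged schema (see
:mod:`winternit.datasets`): one row per lake visit, with a nitrification
rate and its sample-specific LOQ, nutrient concentrations carrying
below-detection flags, and physicochemical covariates. Everything here is
censoring-aware:

* rates below the global quantitation threshold (0.11 µg N L⁻¹ d⁻¹, the
  highest sample LOQ in the survey) are substituted by it before any
  cross-lake statistic;
* ammonium and nitrate below their method detection limits (86 and
  57 µg N L⁻¹) are handled by an explicit per-call policy — substitute
  the MDL, exclude the value, or keep the raw number — because no single
  policy is defensible for every statistic;
* group differences use rank-sum tests (exact enumeration when group
  sizes permit and there are no ties, tie-corrected normal approximation
  otherwise), and regression significance comes from response
  permutation rather than a t reference distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _sstats

from .config import (
    AMMONIUM_MDL,
    DEFAULT_N_PERM,
    GLOBAL_RATE_LOQ,
    NITRATE_MDL,
)
from .tracer import censor_rate

__all__ = [
    "GroupComparison",
    "RegressionResult",
    "PcaResult",
    "MDL_BY_VARIABLE",
    "WINTER_SEASONS",
    "censor_rates",
    "partition_by_rate",
    "group_median",
    "rank_sum_test",
    "compare_rate_groups",
    "permutation_regression",
    "regression_dataset",
    "summarize",
    "pca",
]

#: Variables whose below-detection flags map to a method detection limit.
MDL_BY_VARIABLE: dict[str, float] = {
    "ammonium": AMMONIUM_MDL,
    "nitrate": NITRATE_MDL,
}

WINTER_SEASONS = ("winter_ice", "winter_no_ice")

#: Default variable set for survey summaries (Table-style footer rows).
SUMMARY_VARIABLES = (
    "rate",
    "loq",
    "ammonium",
    "nitrate",
    "oxygen",
    "ph",
    "specific_conductance",
    "n2o_saturation",
    "ch4_saturation",
)


@dataclass(frozen=True)
class GroupComparison:
    """Rank-sum comparison of a variable between rate groups."""

    variable: str
    threshold: float
    high_median: float
    low_median: float
    statistic: float
    p_value: float
    n_high: int
    n_low: int


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit with permutation significance.

    With a centered predictor the intercept equals the mean transformed
    response; the slope is identical to the uncentered fit.
    """

    slope: float
    intercept: float
    r2: float
    adjusted_r2: float
    permutation_p: float
    n: int
    df: int


@dataclass(frozen=True)
class PcaResult:
    """Standardized PCA of the survey covariates.

    ``loadings`` is variables × components (orthonormal columns, sign
    fixed so each component's largest-magnitude loading is positive);
    ``variance_fraction`` sums to 1 over all components.
    """

    loadings: pd.DataFrame
    variance_fraction: np.ndarray
    scores: pd.DataFrame
    n_complete: int


# ----------------------------------------------------------------- censoring


def censor_rates(
    records: pd.DataFrame, threshold: float = GLOBAL_RATE_LOQ
) -> pd.DataFrame:
    """Add ``censored_rate`` and ``censored`` columns; missing rates stay NaN."""
    out = records.copy()
    censored = []
    flags = []
    for rate in out["rate"]:
        if pd.isna(rate):
            censored.append(np.nan)
            flags.append(False)
        else:
            value, flag = censor_rate(float(rate), threshold)
            censored.append(value)
            flags.append(flag)
    out["censored_rate"] = censored
    out["censored"] = flags
    return out


def partition_by_rate(
    records: pd.DataFrame, threshold: float = GLOBAL_RATE_LOQ
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split records into higher-rate (> threshold) and low-rate groups.

    Rates are censored first, so the low group is exactly the rows whose
    censored rate equals the substituted threshold. Rows with missing
    rates are excluded from both groups.
    """
    table = censor_rates(records, threshold)
    table = table[table["censored_rate"].notna()]
    high = table[table["censored_rate"] > threshold]
    low = table[table["censored_rate"] <= threshold]
    return high, low


def _apply_bd_policy(
    group: pd.DataFrame, variable: str, bd_policy: str
) -> np.ndarray:
    """Resolve below-detection flags for one variable; drops missing values."""
    values = group[variable]
    flag_col = f"{variable}_below_mdl"
    if variable in MDL_BY_VARIABLE and flag_col in group.columns:
        mdl = MDL_BY_VARIABLE[variable]
        flagged = group[flag_col].fillna(False).astype(bool)
        if bd_policy == "substitute_mdl":
            values = values.where(~flagged, mdl)
        elif bd_policy == "exclude":
            values = values.where(~flagged, np.nan)
        elif bd_policy != "keep":
            raise ValueError(f"unknown below-detection policy: {bd_policy!r}")
    return values.dropna().to_numpy(dtype=float)


def group_median(
    group: pd.DataFrame, variable: str, bd_policy: str = "substitute_mdl"
) -> float:
    """Median of one variable within a group, after the detection policy.

    Missing values are always excluded; an empty group after the policy is
    an error rather than NaN.
    """
    values = _apply_bd_policy(group, variable, bd_policy)
    if values.size == 0:
        raise ValueError(
            f"no non-missing {variable!r} values after policy {bd_policy!r}"
        )
    return float(np.median(values))


# ---------------------------------------------------------------- rank sums


def rank_sum_test(a, b) -> tuple[float, float]:
    """Two-sided Wilcoxon–Mann–Whitney test; returns (W, p).

    Uses exact null enumeration when there are no ties and the smaller
    group has ≤ 10 observations; otherwise the normal approximation with
    average ranks, tie-corrected variance and continuity correction
    (mirroring R's ``wilcox.test`` defaults). Two identical constant
    samples have no information and return p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return a.size * b.size / 2.0, 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (not has_ties and min(a.size, b.size) <= 10) else "asymptotic"
    res = _sstats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def compare_rate_groups(
    records: pd.DataFrame,
    variable: str,
    threshold: float = GLOBAL_RATE_LOQ,
    bd_policy_high: str = "substitute_mdl",
    bd_policy_low: str = "substitute_mdl",
) -> GroupComparison:
    """Rank-sum comparison of ``variable`` between high- and low-rate groups.

    The below-detection policy is per group because internally consistent
    survey summaries can require different treatments (e.g. excluding a
    single flagged value from a small high-rate group while substituting
    the MDL in a low-rate group dominated by flagged values).
    """
    high, low = partition_by_rate(records, threshold)
    a = _apply_bd_policy(high, variable, bd_policy_high)
    b = _apply_bd_policy(low, variable, bd_policy_low)
    statistic, p = rank_sum_test(a, b)
    return GroupComparison(
        variable=variable,
        threshold=threshold,
        high_median=float(np.median(a)),
        low_median=float(np.median(b)),
        statistic=statistic,
        p_value=p,
        n_high=int(a.size),
        n_low=int(b.size),
    )


# --------------------------------------------------------------- regression


def regression_dataset(
    records: pd.DataFrame,
    subset: str = "all",
    threshold: float = GLOBAL_RATE_LOQ,
    bd_policy: str = "substitute_mdl",
) -> tuple[np.ndarray, np.ndarray]:
    """Assemble (ammonium, rate) pairs for the winter rate regression.

    Winter rows only, complete cases on both variables. Study rates
    (``source == "this_study"``) are censored at the global threshold —
    they carry sample-specific LOQs from this survey's method — while
    literature rates are kept as reported. Below-MDL ammonium follows
    ``bd_policy``. ``subset`` is ``all``, ``no_pasqua`` (drops the
    high-leverage Pasqua Lake record) or ``literature`` (study records
    excluded).
    """
    table = records[records["season"].isin(WINTER_SEASONS)].copy()
    if subset == "no_pasqua":
        table = table[table["location"] != "Pasqua Lake"]
    elif subset == "literature":
        table = table[table["source"] != "this_study"]
    elif subset != "all":
        raise ValueError(f"unknown subset: {subset!r}")
    study = table["source"] == "this_study"
    table.loc[study, "rate"] = [
        censor_rate(r, threshold)[0] if not pd.isna(r) else np.nan
        for r in table.loc[study, "rate"]
    ]
    flagged = table.get("ammonium_below_mdl")
    ammonium = table["ammonium"].copy()
    if flagged is not None:
        flagged = flagged.fillna(False).astype(bool)
        if bd_policy == "substitute_mdl":
            ammonium = ammonium.where(~flagged, MDL_BY_VARIABLE["ammonium"])
        elif bd_policy == "exclude":
            ammonium = ammonium.where(~flagged, np.nan)
        elif bd_policy != "keep":
            raise ValueError(f"unknown below-detection policy: {bd_policy!r}")
    keep = ammonium.notna() & table["rate"].notna()
    return (
        ammonium[keep].to_numpy(dtype=float),
        table.loc[keep, "rate"].to_numpy(dtype=float),
    )


def _transform_response(y: np.ndarray, transform: str) -> np.ndarray:
    if transform == "log10_plus1":
        return np.log10(y + 1.0)
    if transform == "identity":
        return y
    raise ValueError(f"unknown transform: {transform!r}")


def permutation_regression(
    x,
    y_raw,
    transform: str = "log10_plus1",
    center: bool = True,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
) -> RegressionResult:
    """OLS of the transformed response on x, with permutation significance.

    Complete cases only. The permutation p-value is the proportion of
    response permutations whose |slope| is at least the observed |slope|,
    counting the observed arrangement in both numerator and denominator,
    so the smallest attainable p is 1/(n_perm + 1).
    """
    x = np.asarray(x, dtype=float)
    y_raw = np.asarray(y_raw, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y_raw))
    x, y_raw = x[keep], y_raw[keep]
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 complete cases")
    if np.ptp(x) == 0:
        raise ValueError("predictor has zero variance")
    y = _transform_response(y_raw, transform)

    xc = x - x.mean() if center else x
    xd = xc - xc.mean()  # identical to xc when centered; general otherwise
    ssx = float(xd @ xd)
    slope = float(xd @ (y - y.mean())) / ssx
    intercept = float(y.mean() - slope * xc.mean())
    fitted = intercept + slope * xc
    ss_res = float(((y - fitted) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    adjusted = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)

    rng = np.random.default_rng(seed)
    exceed = 0
    yd = y - y.mean()
    for _ in range(n_perm):
        perm_slope = float(xd @ rng.permutation(yd)) / ssx
        if abs(perm_slope) >= abs(slope):
            exceed += 1
    p = (exceed + 1) / (n_perm + 1)

    return RegressionResult(
        slope=slope,
        intercept=intercept,
        r2=r2,
        adjusted_r2=adjusted,
        permutation_p=p,
        n=n,
        df=n - 2,
    )


# ------------------------------------------------------------------ summary


def summarize(
    records: pd.DataFrame,
    variables=SUMMARY_VARIABLES,
    bd_policy: str = "substitute_mdl",
) -> pd.DataFrame:
    """Minimum / median / maximum footer rows over the winter records.

    Inclusion rules per variable: all winter-season rows enter; missing
    values are dropped; below-MDL ammonium/nitrate are handled by
    ``bd_policy`` (default MDL substitution); nitrification rates flagged
    below their sample-specific LOQ (the reported negative values) are
    excluded from the rate column — they are unquantifiable, not small.
    """
    winter = records[records["season"].isin(WINTER_SEASONS)]
    out = {}
    for variable in variables:
        pool = winter
        if variable == "rate" and "rate_below_sample_loq" in pool.columns:
            pool = pool[~pool["rate_below_sample_loq"].fillna(False).astype(bool)]
        values = _apply_bd_policy(pool, variable, bd_policy)
        if values.size == 0:
            out[variable] = (np.nan, np.nan, np.nan)
        else:
            out[variable] = (
                float(values.min()),
                float(np.median(values)),
                float(values.max()),
            )
    return pd.DataFrame(out, index=["minimum", "median", "maximum"])


# ---------------------------------------------------------------------- pca


def pca(
    records: pd.DataFrame, variables, standardize: bool = True
) -> PcaResult:
    """Principal components of the survey covariates over complete cases.

    Each variable is z-scored (sample SD, ddof=1) before the singular
    value decomposition, matching the usual correlation-matrix PCA of
    survey data. Component signs are fixed so the largest-magnitude
    loading of each component is positive.
    """
    variables = list(variables)
    data = records[variables].dropna()
    if len(data) < 2:
        raise ValueError("need at least 2 complete-case records")
    if len(variables) < 2:
        raise ValueError("need at least 2 variables")
    matrix = data.to_numpy(dtype=float)
    centered = matrix - matrix.mean(axis=0)
    if standardize:
        sd = matrix.std(axis=0, ddof=1)
        constant = [v for v, s in zip(variables, sd) if s == 0]
        if constant:
            raise ValueError(f"constant variable(s): {', '.join(constant)}")
        centered = centered / sd
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    # sign convention: largest |loading| positive in every component
    for j in range(vt.shape[0]):
        pivot = np.argmax(np.abs(vt[j]))
        if vt[j, pivot] < 0:
            vt[j] *= -1.0
            u[:, j] *= -1.0
    variance = s**2
    fractions = variance / variance.sum()
    names = [f"PC{i + 1}" for i in range(len(s))]
    loadings = pd.DataFrame(vt.T, index=variables, columns=names)
    scores = pd.DataFrame(u * s, index=data.index, columns=names)
    return PcaResult(
        loadings=loadings,
        variance_fraction=fractions,
        scores=scores,
        n_complete=len(data),
    )
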