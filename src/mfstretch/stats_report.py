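"""Group-level statistics: Welch's t-test, box summaries, same-mouse ratios.

Group tables hold one row per stretched aggregate (group label, mouse id,
Young's modulus, optional covariates).  Because several aggregates come from
the same mouse, group comparisons aggregate to per-mouse means first — the
mouse, not the aggregate, is the independent unit — and then apply Welch's
unequal-variance t-test.  Same-mouse condition ratios (e.g. +W-7 or anti-CD3
versus the PMA+ionomycin reference) are computed per mouse and summarised as
mean +/- SD across mice.  Box summaries follow the median/IQR/1.5*IQR
whisker convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InvalidInputError, InvalidParameterError, PairingError

__all__ = [
    "WelchResult",
    "BoxSummary",
    "PairedRatioResult",
    "CovariateCheck",
    "welch_test",
    "stars_from_p",
    "box_summary",
    "per_mouse_means",
    "paired_ratio",
    "covariate_null_check",
    "group_compare",
]

_STAR_THRESHOLDS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


def stars_from_p(p: float) -> str:
    for threshold, stars in _STAR_THRESHOLDS:
        if p < threshold:
            return stars
    return "ns"


@dataclass(frozen=True)
class WelchResult:
    t_stat: float
    df: float
    p_value: float
    stars: str


def welch_test(a, b) -> WelchResult:
    """Two-sample unequal-variance t-test with Welch-Satterthwaite df."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InvalidInputError("each sample needs at least two observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va <= 0 or vb <= 0:
        raise InvalidInputError("degenerate sample: zero variance")
    se2a, se2b = va / a.size, vb / b.size
    t = (a.mean() - b.mean()) / math.sqrt(se2a + se2b)
    df = (se2a + se2b) ** 2 / (
        se2a**2 / (a.size - 1) + se2b**2 / (b.size - 1)
    )
    p = 2.0 * stats.t.sf(abs(t), df)
    return WelchResult(t_stat=float(t), df=float(df), p_value=float(p),
                       stars=stars_from_p(float(p)))


@dataclass(frozen=True)
class BoxSummary:
    median: float
    q1: float
    q3: float
    whisker_lo: float
    whisker_hi: float
    outliers: tuple


def box_summary(values) -> BoxSummary:
    """Median, quartiles (linear interpolation) and 1.5*IQR whiskers.

    Whiskers sit on the most extreme data points inside the Tukey fences;
    points beyond them are listed as outliers.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise InvalidInputError("empty sample")
    q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75])  # type-7 linear interpolation
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    outliers = tuple(sorted(v[(v < lo_fence) | (v > hi_fence)].tolist()))
    return BoxSummary(
        median=float(med), q1=float(q1), q3=float(q3),
        whisker_lo=float(inside.min()), whisker_hi=float(inside.max()),
        outliers=outliers,
    )


def per_mouse_means(
    table: pd.DataFrame, value_col: str = "E_Pa"
) -> pd.DataFrame:
    """Mean modulus per (group, mouse): the independent unit of analysis."""
    return (
        table.groupby(["group", "mouse_id"], sort=True)[value_col]
        .mean()
        .reset_index()
    )


@dataclass(frozen=True)
class PairedRatioResult:
    mean: float
    sd: float
    n_mice: int
    per_mouse: tuple


def paired_ratio(
    table: pd.DataFrame,
    group_num: str,
    group_den: str,
    value_col: str = "E_Pa",
) -> PairedRatioResult:
    """Same-mouse condition ratio, mean +/- SD across mice.

    Per mouse, the mean modulus in each group is computed and the ratio
    numerator/denominator taken; mice present in only one group are dropped.
    """
    means = per_mouse_means(table, value_col)
    pivot = means.pivot(index="mouse_id", columns="group", values=value_col)
    for g in (group_num, group_den):
        if g not in pivot.columns:
            raise PairingError(f"group {g!r} not present in the table")
    both = pivot[[group_num, group_den]].dropna()
    if len(both) < 2:
        raise PairingError("fewer than two mice shared between the groups")
    ratios = (both[group_num] / both[group_den]).to_numpy()
    return PairedRatioResult(
        mean=float(ratios.mean()),
        sd=float(ratios.std(ddof=1)),
        n_mice=int(ratios.size),
        per_mouse=tuple(ratios.tolist()),
    )


@dataclass(frozen=True)
class CovariateCheck:
    slope: float
    ci_lo: float
    ci_hi: float
    flat: bool


def covariate_null_check(
    table: pd.DataFrame,
    covariate: str,
    value_col: str = "E_Pa",
    alpha: float = 0.05,
) -> CovariateCheck:
    """Least-squares slope of E against a covariate with a 95% CI.

    ``flat`` means the CI contains zero — no detectable dependence of the
    modulus on e.g. aggregate volume, aspirated fraction or time after
    activation.
    """
    sub = table[[covariate, value_col]].dropna()
    if len(sub) < 5:
        raise InvalidInputError("need at least 5 points for a covariate check")
    fit = stats.linregress(sub[covariate].to_numpy(), sub[value_col].to_numpy())
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, len(sub) - 2)
    lo = fit.slope - tcrit * fit.stderr
    hi = fit.slope + tcrit * fit.stderr
    return CovariateCheck(
        slope=float(fit.slope), ci_lo=float(lo), ci_hi=float(hi),
        flat=bool(lo <= 0.0 <= hi),
    )


def group_compare(
    table: pd.DataFrame,
    pairs: list[tuple[str, str]] | None = None,
    value_col: str = "E_Pa",
) -> dict:
    """Figure-style report: per-group box summaries + pairwise Welch tests.

    Welch tests run on per-mouse mean moduli.  ``pairs`` defaults to every
    group against every other (each unordered pair once).  No multiple-
    testing correction is applied, matching pairwise reporting practice.
    """
    groups = sorted(table["group"].unique())
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(groups) for b in groups[i + 1:]]
    means = per_mouse_means(table, value_col)
    report: dict = {"groups": {}, "comparisons": []}
    for g in groups:
        vals = table.loc[table["group"] == g, value_col].to_numpy()
        bs = box_summary(vals)
        report["groups"][g] = {
            "n": int(vals.size),
            "mean": float(vals.mean()),
            "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
            "median": bs.median, "q1": bs.q1, "q3": bs.q3,
            "whisker_lo": bs.whisker_lo, "whisker_hi": bs.whisker_hi,
            "n_outliers": len(bs.outliers),
        }
    for a, b in pairs:
        if a not in groups or b not in groups:
            raise InvalidParameterError(f"unknown group in pair ({a!r}, {b!r})")
        wa = means.loc[means["group"] == a, value_col].to_numpy()
        wb = means.loc[means["group"] == b, value_col].to_numpy()
        res = welch_test(wa, wb)
        report["comparisons"].append(
            {
                "groups": [a, b],
                "t": res.t_stat, "df": res.df,
                "p_value": res.p_value, "stars": res.stars,
            }
        )
    return report
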