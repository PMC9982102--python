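"""Correlating heterosis with its genomic predictors.

Pearson correlation and least-squares regression of MPH/BPH on the
heterozygous-PEUS-SNP count or genetic distance; a paired t-test (on
Fisher-z-transformed coefficients across location x heterosis-type
strata) for deciding which predictor correlates more strongly; and the
top-k cross summary that checks which parents dominate the best crosses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class CorrelationResult:
    r: float
    n: int
    p_value: float
    predictor: str = "x"
    response: str = "y"


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float


@dataclass
class CorrelationComparison:
    pairs: list[tuple[float, float]]
    t_statistic: float
    p_value: float
    transform: str


def _clean_xy(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    return x, y


def pearson(x, y, predictor: str = "x", response: str = "y") -> CorrelationResult:
    """Product-moment correlation with the two-sided t-based p-value."""
    x, y = _clean_xy(x, y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    res = stats.pearsonr(x, y)
    return CorrelationResult(
        r=float(res.statistic), n=len(x), p_value=float(res.pvalue),
        predictor=predictor, response=response,
    )


def regress(x, y) -> RegressionResult:
    """Ordinary least-squares line y = slope*x + intercept with R^2."""
    x, y = _clean_xy(x, y)
    if np.ptp(x) == 0:
        raise ValueError("regression undefined for constant x")
    if np.ptp(y) == 0:
        return RegressionResult(slope=0.0, intercept=float(y[0]), r_squared=0.0)
    fit = stats.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
    )


def compare_correlations(
    pairs: list[tuple[float, float]],
    transform: str = "fisher_z",
    alternative: str = "two-sided",
) -> CorrelationComparison:
    """Paired t-test on per-stratum differences of correlation coefficients.

    Each pair is (r_predictor1, r_predictor2) from one stratum (e.g. one
    location x heterosis-type combination). With transform='fisher_z' the
    coefficients are arctanh-transformed first, the standard
    variance-stabilising step when comparing correlations. A positive t
    means predictor 1 correlates more strongly.
    """
    if len(pairs) < 2:
        raise ValueError("need at least 2 strata pairs")
    if transform not in ("fisher_z", "none"):
        raise ValueError(f"unknown transform {transform!r}")
    a = np.asarray([p[0] for p in pairs], dtype=float)
    b = np.asarray([p[1] for p in pairs], dtype=float)
    if transform == "fisher_z":
        a, b = np.arctanh(a), np.arctanh(b)
    d = a - b
    if np.allclose(d, 0.0):
        t_stat, p = 0.0, 1.0
    else:
        res = stats.ttest_rel(a, b, alternative=alternative)
        t_stat, p = float(res.statistic), float(res.pvalue)
    return CorrelationComparison(
        pairs=list(pairs), t_statistic=t_stat, p_value=p, transform=transform
    )


def top_crosses(
    table: pd.DataFrame, k: int = 10, by: str = "gy"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Top-k crosses by a response column, and parent membership counts.

    ``table`` must carry cross/female/male columns plus the response.
    Returns (top-k rows, counts DataFrame with parent/role/count). Ties at
    the k-th position are broken by stable input order with a warning.
    """
    for col in ("cross", "female", "male", by):
        if col not in table.columns:
            raise ValueError(f"table missing column {col!r}")
    if k > len(table):
        raise ValueError(f"k={k} exceeds number of crosses ({len(table)})")
    ranked = table.sort_values(by, ascending=False, kind="stable")
    top = ranked.head(k)
    if k < len(table) and ranked[by].iloc[k - 1] == ranked[by].iloc[k]:
        logger.warning("top_crosses: tie at rank %d broken by input order", k)
    counts = pd.concat(
        [
            top["female"].value_counts().rename_axis("parent").reset_index(name="count").assign(role="female"),
            top["male"].value_counts().rename_axis("parent").reset_index(name="count").assign(role="male"),
        ],
        ignore_index=True,
    )[["parent", "role", "count"]]
    return top.reset_index(drop=True), counts


def predictor_correlations_per_location(
    scores: pd.DataFrame, het_per_loc: pd.DataFrame
) -> pd.DataFrame:
    """Per-location correlations of n_het_peus and gd with MPH and BPH.

    ``scores`` is the per-cross score table; ``het_per_loc`` the
    per-location heterosis table. Returns one row per location x response
    x predictor with r, n and p — the per-location comparison surface for
    the two predictors.
    """
    merged = het_per_loc.merge(scores[["cross", "n_het_peus", "gd"]], on="cross")
    rows = []
    for loc, sub in merged.groupby("location", sort=True):
        sub = sub[sub["defined"]] if "defined" in sub.columns else sub
        for response in ("mph", "bph"):
            for predictor in ("n_het_peus", "gd"):
                res = pearson(sub[predictor], sub[response], predictor, response)
                rows.append(
                    {
                        "location": loc,
                        "response": response,
                        "predictor": predictor,
                        "r": res.r,
                        "n": res.n,
                        "p_value": res.p_value,
                    }
                )
    return pd.DataFrame(rows)


def compare_predictors_across_locations(per_loc: pd.DataFrame) -> CorrelationComparison:
    """Paired comparison of r(n_het_peus, .) vs r(gd, .) over all strata.

    Strata are the location x {MPH, BPH} combinations of the per-location
    correlation table (3 locations x 2 responses = 6 pairs in the default
    trial layout).
    """
    pairs = []
    for (_, _), sub in per_loc.groupby(["location", "response"], sort=True):
        r_het = float(sub.loc[sub["predictor"] == "n_het_peus", "r"].iloc[0])
        r_gd = float(sub.loc[sub["predictor"] == "gd", "r"].iloc[0])
        pairs.append((r_het, r_gd))
    return compare_correlations(pairs)
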