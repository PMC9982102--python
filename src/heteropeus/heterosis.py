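"""Heterosis, line x tester ANOVA, Fisher's LSD and combining ability.

Plot-level grain yield (t/ha) from a multi-location randomized complete
block trial is reduced to:

* mid-parent heterosis  MPH = 100 * (F1 - MP) / MP, MP = (P1 + P2) / 2
* better-parent heterosis  BPH = 100 * (F1 - BP) / BP, BP = max(P1, P2)
* the fixed-effects line x tester ANOVA
  Y_ijkl = mu + loc_l + rep(loc)_kl + line_i + tester_j + (line.tester)_ij
           + (line.loc)_il + (tester.loc)_jl + (line.tester.loc)_ijl + e_ijkl
  with every F statistic tested against the pooled error mean square
  (lines and testers are deliberately chosen, not sampled)
* Fisher's LSD for separating testcross means
* Kempthorne general/specific combining ability from balanced cross means.

Sums of squares use the balanced orthogonal (cell-mean) decomposition;
unbalanced data is rejected explicitly rather than approximated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .scoring import CrossDesign, cross_id

logger = logging.getLogger(__name__)

ANOVA_SOURCES = [
    "Locations (Loc)",
    "Replications:Loc",
    "Lines",
    "Testers (T)",
    "Lines x T",
    "Lines x Loc",
    "T x Loc",
    "Lines x T x Loc",
    "Error",
]

PLOT_COLUMNS = ["entry_id", "entry_type", "location", "replication", "gy"]


def read_plots_csv(path: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in PLOT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype file missing columns: {missing}")
    if (df["gy"] < 0).any():
        raise ValueError("grain yield must be >= 0")
    dup = df.duplicated(subset=["entry_id", "location", "replication"])
    if dup.any():
        raise ValueError("duplicate (entry, location, replication) plots")
    return df


def compute_heterosis(
    plots: pd.DataFrame, design: CrossDesign, scope: str = "across"
) -> pd.DataFrame:
    """Per-cross F1 mean, MP, BP, MPH and BPH.

    scope='across' averages each entry over all locations and
    replications (one row per cross); scope='per-location' averages
    within each location (one row per cross x location). Crosses whose
    mid- or better-parent mean is <= 0 get NaN heterosis and are flagged
    in the ``defined`` column rather than fabricated.
    """
    if scope not in ("across", "per-location"):
        raise ValueError("scope must be 'across' or 'per-location'")
    f1 = plots[plots["entry_type"] == "F1"]
    par = plots[plots["entry_type"] == "parent"]
    group_cols = ["entry_id"] if scope == "across" else ["entry_id", "location"]
    f1_means = f1.groupby(group_cols)["gy"].mean()
    par_means = par.groupby(group_cols)["gy"].mean()
    locations = ["all"] if scope == "across" else sorted(plots["location"].unique())

    rows = []
    for female, male in design.crosses:
        cid = cross_id(female, male)
        for loc in locations:
            key = cid if scope == "across" else (cid, loc)
            fkey = female if scope == "across" else (female, loc)
            mkey = male if scope == "across" else (male, loc)
            try:
                f1_mean = float(f1_means[key])
                p1 = float(par_means[fkey])
                p2 = float(par_means[mkey])
            except KeyError as e:
                raise ValueError(f"cross {cid}: entry {e.args[0]!r} not phenotyped in scope") from None
            mp = (p1 + p2) / 2.0
            bp = max(p1, p2)
            defined = mp > 0 and bp > 0
            if not defined:
                logger.warning("cross %s at %s: parent mean <= 0, heterosis undefined", cid, loc)
            rows.append(
                {
                    "cross": cid,
                    "female": female,
                    "male": male,
                    "location": loc,
                    "f1_mean": f1_mean,
                    "mp": mp,
                    "bp": bp,
                    "mph": 100.0 * (f1_mean - mp) / mp if defined else np.nan,
                    "bph": 100.0 * (f1_mean - bp) / bp if defined else np.nan,
                    "defined": defined,
                }
            )
    return pd.DataFrame(rows)


def _f1_grid(plots: pd.DataFrame, design: CrossDesign) -> np.ndarray:
    """F1 yields as a (lines, testers, locations, reps) array; balance enforced."""
    lines = design.lines
    testers = design.testers
    id_to_ft = {cross_id(f, m): (f, m) for f, m in design.crosses}
    f1 = plots[plots["entry_type"] == "F1"].copy()
    unknown = set(f1["entry_id"]) - set(id_to_ft)
    if unknown:
        raise ValueError(f"F1 entries not in design: {sorted(unknown)[:5]}")
    locs = sorted(f1["location"].unique())
    reps = sorted(f1["replication"].unique())
    li = {s: i for i, s in enumerate(lines)}
    ti = {s: i for i, s in enumerate(testers)}
    oi = {s: i for i, s in enumerate(locs)}
    ri = {s: i for i, s in enumerate(reps)}
    y = np.full((len(lines), len(testers), len(locs), len(reps)), np.nan)
    for row in f1.itertuples(index=False):
        f, m = id_to_ft[row.entry_id]
        cell = (li[f], ti[m], oi[row.location], ri[row.replication])
        if not np.isnan(y[cell]):
            raise ValueError("duplicate plot for one (cross, location, replication)")
        y[cell] = row.gy
    if np.isnan(y).any():
        raise ValueError(
            "unbalanced design: every cross must be observed once per "
            "(location, replication); balanced data required"
        )
    return y


def anova_line_tester(plots: pd.DataFrame, design: CrossDesign) -> pd.DataFrame:
    """Fixed-effects line x tester ANOVA over locations and replications.

    Returns a table with one row per source (Locations, Replications:Loc,
    Lines, Testers, Lines x T, Lines x Loc, T x Loc, Lines x T x Loc,
    Error) and columns source/df/sum_sq/mean_sq/F/p. All F statistics use
    the Error mean square as denominator.
    """
    y = _f1_grid(plots, design)
    L, T, E, R = y.shape
    grand = y.mean()

    m_l = y.mean(axis=(0, 1, 3))           # per location
    m_lk = y.mean(axis=(0, 1))             # location x rep
    m_i = y.mean(axis=(1, 2, 3))           # per line
    m_j = y.mean(axis=(0, 2, 3))           # per tester
    m_ij = y.mean(axis=(2, 3))
    m_il = y.mean(axis=(1, 3))
    m_jl = y.mean(axis=(0, 3))
    m_ijl = y.mean(axis=3)

    ss = {
        "Locations (Loc)": L * T * R * np.sum((m_l - grand) ** 2),
        "Replications:Loc": L * T * np.sum((m_lk - m_l[:, None]) ** 2),
        "Lines": T * E * R * np.sum((m_i - grand) ** 2),
        "Testers (T)": L * E * R * np.sum((m_j - grand) ** 2),
        "Lines x T": E * R * np.sum((m_ij - m_i[:, None] - m_j[None, :] + grand) ** 2),
        "Lines x Loc": T * R * np.sum((m_il - m_i[:, None] - m_l[None, :] + grand) ** 2),
        "T x Loc": L * R * np.sum((m_jl - m_j[:, None] - m_l[None, :] + grand) ** 2),
        "Lines x T x Loc": R
        * np.sum(
            (
                m_ijl
                - m_ij[:, :, None]
                - m_il[:, None, :]
                - m_jl[None, :, :]
                + m_i[:, None, None]
                + m_j[None, :, None]
                + m_l[None, None, :]
                - grand
            )
            ** 2
        ),
    }
    ss_total = np.sum((y - grand) ** 2)
    ss["Error"] = max(ss_total - sum(ss.values()), 0.0)

    df = {
        "Locations (Loc)": E - 1,
        "Replications:Loc": E * (R - 1),
        "Lines": L - 1,
        "Testers (T)": T - 1,
        "Lines x T": (L - 1) * (T - 1),
        "Lines x Loc": (L - 1) * (E - 1),
        "T x Loc": (T - 1) * (E - 1),
        "Lines x T x Loc": (L - 1) * (T - 1) * (E - 1),
    }
    df["Error"] = y.size - 1 - sum(df.values())

    ms_error = ss["Error"] / df["Error"]
    rows = []
    for source in ANOVA_SOURCES:
        ms = ss[source] / df[source]
        if source == "Error":
            fval, p = np.nan, np.nan
        else:
            fval = ms / ms_error if ms_error > 0 else np.inf
            p = stats.f.sf(fval, df[source], df["Error"])
        rows.append(
            {"source": source, "df": df[source], "sum_sq": ss[source], "mean_sq": ms, "F": fval, "p": p}
        )
    return pd.DataFrame(rows)


def error_row(anova: pd.DataFrame) -> tuple[float, int]:
    """(mean square, df) of the Error source."""
    row = anova.loc[anova["source"] == "Error"]
    if row.empty:
        raise ValueError("ANOVA table has no Error row")
    return float(row["mean_sq"].iloc[0]), int(row["df"].iloc[0])


def lsd(anova: pd.DataFrame, n_per_mean: int, alpha: float = 0.05) -> float:
    """Fisher's least significant difference for separating entry means.

    LSD = t(1 - alpha/2, df_error) * sqrt(2 * MS_error / n_per_mean),
    where n_per_mean is the number of plots averaged into each mean.
    """
    if n_per_mean <= 0:
        raise ValueError("n_per_mean must be positive")
    ms_error, df_error = error_row(anova)
    t_crit = stats.t.ppf(1 - alpha / 2, df_error)
    return float(t_crit * np.sqrt(2 * ms_error / n_per_mean))


@dataclass
class CombiningAbility:
    """Kempthorne combining-ability estimates from balanced cross means.

    gca_line/gca_tester are marginal deviations from the grand cross mean;
    sca is the cross-specific residual. On balanced data each effect set
    sums to zero and grand + gca_line + gca_tester + sca reconstructs
    every cross mean.
    """

    grand_mean: float
    gca_line: pd.Series
    gca_tester: pd.Series
    sca: pd.DataFrame

    def reconstruct(self, line: str, tester: str) -> float:
        return (
            self.grand_mean
            + float(self.gca_line[line])
            + float(self.gca_tester[tester])
            + float(self.sca.loc[line, tester])
        )


def combining_ability(plots: pd.DataFrame, design: CrossDesign) -> CombiningAbility:
    """GCA/SCA from the balanced line x tester F1 table."""
    y = _f1_grid(plots, design)
    cross_means = y.mean(axis=(2, 3))
    grand = float(cross_means.mean())
    gca_l = cross_means.mean(axis=1) - grand
    gca_t = cross_means.mean(axis=0) - grand
    sca = cross_means - grand - gca_l[:, None] - gca_t[None, :]
    return CombiningAbility(
        grand_mean=grand,
        gca_line=pd.Series(gca_l, index=design.lines, name="gca"),
        gca_tester=pd.Series(gca_t, index=design.testers, name="gca"),
        sca=pd.DataFrame(sca, index=design.lines, columns=design.testers),
    )
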