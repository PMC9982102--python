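"""Per-cross PEUS SNP counts and identity-by-state genetic distance.

For each line x tester cross the predictors of heterosis are:

* ``n_het_peus`` — PEUS sites where both inbred parents are homozygous for
  *different* alleles (the F1 is heterozygous there);
* ``n_hom_peus`` — PEUS sites where both parents carry the *same*
  homozygous genotype;
* ``gd`` — genetic distance GD = 1 - IBS, where IBS is the mean shared-
  allele fraction per locus over all jointly observed (by default all
  filtered, not only PEUS) sites.

Sites where either parent is missing or residually heterozygous are
excluded from the het/hom counts: the F1's zygosity there is ambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import PeusAnnotation
from .genotype_io import MISSING, GenotypeMatrix


def cross_id(female: str, male: str) -> str:
    return f"{female}x{male}"


@dataclass
class CrossDesign:
    """A set of crosses plus parent roles and heterotic-group labels."""

    crosses: list[tuple[str, str]]  # (female_id, male_id)
    roles: dict[str, str] = field(default_factory=dict)  # sample -> 'line' | 'tester'
    groups: dict[str, str] = field(default_factory=dict)  # sample -> heterotic group

    def __post_init__(self) -> None:
        if len(set(self.crosses)) != len(self.crosses):
            raise ValueError("duplicate crosses in design")

    @property
    def parents(self) -> list[str]:
        seen: dict[str, None] = {}
        for f, m in self.crosses:
            seen.setdefault(f)
            seen.setdefault(m)
        return list(seen)

    @property
    def lines(self) -> list[str]:
        return [s for s in self.parents if self.roles.get(s) == "line"]

    @property
    def testers(self) -> list[str]:
        return [s for s in self.parents if self.roles.get(s) == "tester"]

    def validate_against(self, gm: GenotypeMatrix) -> None:
        absent = [s for s in self.parents if s not in gm.samples]
        if absent:
            raise KeyError(f"design parents not in genotype matrix: {absent}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "female": [f for f, _ in self.crosses],
                "male": [m for _, m in self.crosses],
                "female_group": [self.groups.get(f, "") for f, _ in self.crosses],
                "male_group": [self.groups.get(m, "") for _, m in self.crosses],
            }
        )


def read_design_csv(path: str) -> CrossDesign:
    """Read a cross-design CSV (columns female, male, optional *_group).

    Females are assigned the 'line' role and males 'tester', matching the
    line x tester convention.
    """
    df = pd.read_csv(path, dtype=str)
    for col in ("female", "male"):
        if col not in df.columns:
            raise ValueError(f"design file missing column {col!r}")
    crosses = list(zip(df["female"], df["male"]))
    roles = {f: "line" for f in df["female"]}
    roles.update({m: "tester" for m in df["male"]})
    groups: dict[str, str] = {}
    if "female_group" in df.columns:
        groups.update(dict(zip(df["female"], df["female_group"].fillna(""))))
    if "male_group" in df.columns:
        groups.update(dict(zip(df["male"], df["male_group"].fillna(""))))
    return CrossDesign(crosses=crosses, roles=roles, groups=groups)


def count_peus(
    gm: GenotypeMatrix, ann: PeusAnnotation, female: str, male: str
) -> tuple[int, int, int]:
    """(n_het_peus, n_hom_peus, n_excluded) over the PEUS sites of a cross.

    Both parents homozygous and different -> het; homozygous and equal ->
    hom; either missing or heterozygous -> excluded. The three counts sum
    to the PEUS site total.
    """
    fi, mi = gm.sample_index(female), gm.sample_index(male)
    f = gm.dosage[fi, ann.is_peus]
    m = gm.dosage[mi, ann.is_peus]
    usable = (f != MISSING) & (m != MISSING) & (f != 1) & (m != 1)
    n_het = int((usable & (f != m)).sum())
    n_hom = int((usable & (f == m)).sum())
    n_excluded = int((~usable).sum())
    return n_het, n_hom, n_excluded


def ibs_distance(gm: GenotypeMatrix, a: str, b: str, site_mask: np.ndarray | None = None) -> float:
    """Genetic distance GD = 1 - IBS between two samples.

    Per-site shared-allele fraction is (2 - |dosage_a - dosage_b|) / 2;
    IBS averages it over sites non-missing in both samples (optionally
    restricted by site_mask). Raises if no jointly observed site exists.
    """
    ai, bi = gm.sample_index(a), gm.sample_index(b)
    da = gm.dosage[ai].astype(np.int16)
    db = gm.dosage[bi].astype(np.int16)
    ok = (da != MISSING) & (db != MISSING)
    if site_mask is not None:
        ok &= np.asarray(site_mask, dtype=bool)
    if not ok.any():
        raise ValueError(f"no jointly observed site between {a!r} and {b!r}: GD undefined")
    ibs = float(np.mean((2 - np.abs(da[ok] - db[ok])) / 2.0))
    return 1.0 - ibs


def score_all(gm: GenotypeMatrix, ann: PeusAnnotation, design: CrossDesign) -> pd.DataFrame:
    """One row per design cross: PEUS counts and GD, in design order."""
    design.validate_against(gm)
    rows = []
    for female, male in design.crosses:
        n_het, n_hom, n_exc = count_peus(gm, ann, female, male)
        gd = ibs_distance(gm, female, male)
        rows.append(
            {
                "cross": cross_id(female, male),
                "female": female,
                "male": male,
                "n_het_peus": n_het,
                "n_hom_peus": n_hom,
                "n_excluded": n_exc,
                "gd": gd,
            }
        )
    return pd.DataFrame(
        rows, columns=["cross", "female", "male", "n_het_peus", "n_hom_peus", "n_excluded", "gd"]
    )


def aggregate_by_parent(
    scores: pd.DataFrame, by: str = "tester", design: CrossDesign | None = None
) -> pd.DataFrame:
    """Mean n_het_peus / n_hom_peus / gd over crosses sharing a parent key.

    ``by`` is 'tester' (group by male), 'line' (group by female) or
    'group' (group by the female parent's heterotic group; requires a
    design with group labels).
    """
    if scores.empty:
        raise ValueError("no scores to aggregate")
    if by == "tester":
        key = scores["male"]
    elif by == "line":
        key = scores["female"]
    elif by == "group":
        if design is None:
            raise ValueError("grouping by heterotic group requires the design")
        key = scores["female"].map(design.groups)
    else:
        raise ValueError(f"unknown aggregation key {by!r}")
    out = (
        scores.assign(key=key)
        .groupby("key", sort=True)[["n_het_peus", "n_hom_peus", "gd"]]
        .mean()
        .reset_index()
        .rename(columns={"key": by})
    )
    return out
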