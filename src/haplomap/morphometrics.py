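"""Wing morphometrics: relative size tables, nested genotype contrasts,
and seta-based cell size / cell number decomposition.

Wing measurements (forewing length, width, area, head width as a body-size
control) come in a nested design: individuals within families within
genotypes.  Genotype contrasts are Tukey HSD tests built on a nested ANOVA
that treats family as the experimental unit -- genotype effects are tested
against the family-within-genotype stratum, not the individual residual --
with a Bonferroni correction across the measurements analysed.

Cell-level effects are inferred from setae, the hair-like projections each
produced by an underlying wing cell.  The area occupied per cell is
estimated from the seta point pattern: for each seta the mean distance to
its four nearest neighbours (nnd4_i) is taken as a diameter, and the
per-seta area is the mean over setae of pi * (nnd4_i / 2)^2.  No edge
correction is applied; the boundary bias is shared by the genotypes being
compared and cancels in their ratio, which is the quantity interpreted.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

#: Canonical measurement columns of a wing table.
MEASUREMENTS = ("length_um", "width_um", "area_um2", "head_width_um")

WING_COLUMNS = ("genotype", "sex", "family", "individual") + MEASUREMENTS

__all__ = [
    "MEASUREMENTS",
    "WING_COLUMNS",
    "SetaPattern",
    "ContrastReport",
    "CellMetrics",
    "relative_table",
    "hsd_contrasts",
    "species_fraction",
    "nnd4_area",
    "cell_metrics",
    "cells_per_seta",
    "mann_whitney",
]


# ---------------------------------------------------------------------------
# Relative measurement tables
# ---------------------------------------------------------------------------


def relative_table(
    table: pd.DataFrame,
    reference: str,
    sex: str,
    measurements: Sequence[str] = MEASUREMENTS,
) -> pd.DataFrame:
    """Per-genotype relative means and SDs, scaled by the reference mean.

    For each genotype and measurement the output row carries the raw mean
    and SD plus ``rel_mean = mean / ref_mean`` and ``rel_sd = sd / ref_mean``
    (both are divided by the *reference mean*, so the reference genotype
    reads 1.00 +/- cv).  ``display`` renders to two decimals; raw values
    are retained at full precision.
    """
    sub = table[table["sex"] == sex]
    if reference not in set(sub["genotype"]):
        raise ValueError(f"reference genotype {reference!r} absent for sex {sex!r}")
    rows = []
    grouped = sub.groupby("genotype", sort=False)
    for meas in measurements:
        ref_mean = float(grouped[meas].mean().loc[reference])
        if ref_mean == 0:
            raise ValueError(f"zero reference mean for {meas!r}")
        for genotype, g in grouped:
            mean = float(g[meas].mean())
            sd = float(g[meas].std(ddof=1)) if len(g) > 1 else 0.0
            rel_mean = mean / ref_mean
            rel_sd = sd / ref_mean
            rows.append(
                {
                    "genotype": genotype,
                    "sex": sex,
                    "measurement": meas,
                    "n": int(len(g)),
                    "mean": mean,
                    "sd": sd,
                    "rel_mean": rel_mean,
                    "rel_sd": rel_sd,
                    "display": f"{rel_mean:.2f}±{rel_sd:.2f}",
                }
            )
    return pd.DataFrame(rows)


def species_fraction(rel_intro: float, rel_species: float) -> float:
    """Percent of the species difference attributable to the introgression.

    Both arguments are relative means (wild-type reference = 1); returns
    100 * (rel_intro - 1) / (rel_species - 1).  Display convention rounds
    to integer percent.
    """
    if rel_species == 1:
        raise ValueError("rel_species must differ from 1")
    return 100.0 * (rel_intro - 1.0) / (rel_species - 1.0)


# ---------------------------------------------------------------------------
# Nested Tukey HSD contrasts with compact letters
# ---------------------------------------------------------------------------


def _compact_letters(names: list[str], sig: np.ndarray) -> dict[str, str]:
    """Compact letter display by insert-and-absorb.

    Genotypes sharing a letter are not significantly different.  ``sig`` is
    the boolean significance matrix of pairwise differences.
    """
    n = len(names)
    groups: list[set[int]] = [set(range(n))]
    for i, j in itertools.combinations(range(n), 2):
        if not sig[i, j]:
            continue
        for g in [g for g in groups if i in g and j in g]:
            groups.remove(g)
            for repl in (g - {i}, g - {j}):
                if repl and not any(repl <= other for other in groups):
                    groups.append(repl)
        groups = [g for g in groups if not any(g < other for other in groups)]
    groups.sort(key=min)
    letters = {k: "" for k in range(n)}
    for letter, g in zip("abcdefghijklmnopqrstuvwxyz", groups):
        for k in sorted(g):
            letters[k] += letter
    return {names[k]: letters[k] for k in range(n)}


@dataclasses.dataclass
class ContrastReport:
    """HSD contrast groups with Bonferroni-adjusted pairwise p-values.

    ``table`` has one row per (measurement, genotype) with relative mean,
    scaled SD and contrast letter; ``pairwise`` one row per
    (measurement, genotype pair) with raw and adjusted p-values.
    """

    table: pd.DataFrame
    pairwise: pd.DataFrame
    alpha: float
    n_tests: int
    error_stratum: str


def hsd_contrasts(
    table: pd.DataFrame,
    sex: str,
    alpha: float = 0.05,
    n_tests: int = 1,
    reference: str | None = None,
    measurements: Sequence[str] = MEASUREMENTS,
    error_stratum: str = "family",
) -> ContrastReport:
    """Tukey HSD genotype contrasts respecting the family nesting.

    With ``error_stratum='family'`` (default) each family contributes its
    mean and the HSD runs on family means, so genotype effects are judged
    against between-family variation; ``'residual'`` runs on individuals.
    If any genotype has a single family the family stratum is unusable and
    the function falls back to individuals with a logged warning.

    Pairwise p-values are multiplied by ``n_tests`` (Bonferroni across the
    measurements analysed) and capped at 1; letters are assigned from the
    adjusted p-values at ``alpha``.
    """
    sub = table[table["sex"] == sex]
    genotypes = list(dict.fromkeys(sub["genotype"]))
    if len(genotypes) < 2:
        raise ValueError("need >= 2 genotypes")
    stratum = error_stratum
    if stratum == "family":
        fam_counts = sub.groupby("genotype")["family"].nunique()
        if (fam_counts < 2).any():
            logger.warning(
                "genotype(s) with a single family: %s; falling back to "
                "one-way ANOVA on individuals",
                list(fam_counts.index[fam_counts < 2]),
            )
            stratum = "residual"

    rel = relative_table(sub, reference or genotypes[0], sex, measurements)
    rel = rel.set_index(["measurement", "genotype"])

    out_rows = []
    pair_rows = []
    for meas in measurements:
        if stratum == "family":
            units = (
                sub.groupby(["genotype", "family"], sort=False)[meas].mean().reset_index()
            )
            samples = [
                units.loc[units["genotype"] == g, meas].to_numpy() for g in genotypes
            ]
        else:
            samples = [
                sub.loc[sub["genotype"] == g, meas].to_numpy() for g in genotypes
            ]
        res = stats.tukey_hsd(*samples)
        k = len(genotypes)
        sig = np.zeros((k, k), dtype=bool)
        for i, j in itertools.combinations(range(k), 2):
            p_raw = float(res.pvalue[i, j])
            p_adj = min(1.0, p_raw * n_tests)
            sig[i, j] = sig[j, i] = p_adj < alpha
            pair_rows.append(
                {
                    "measurement": meas,
                    "genotype_a": genotypes[i],
                    "genotype_b": genotypes[j],
                    "p_raw": p_raw,
                    "p_adj": p_adj,
                }
            )
        letters = _compact_letters(genotypes, sig)
        for g in genotypes:
            r = rel.loc[(meas, g)]
            out_rows.append(
                {
                    "measurement": meas,
                    "genotype": g,
                    "n": int(r["n"]),
                    "rel_mean": float(r["rel_mean"]),
                    "rel_sd": float(r["rel_sd"]),
                    "letter": letters[g],
                }
            )
    return ContrastReport(
        table=pd.DataFrame(out_rows),
        pairwise=pd.DataFrame(pair_rows),
        alpha=alpha,
        n_tests=n_tests,
        error_stratum=stratum,
    )


# ---------------------------------------------------------------------------
# Seta point patterns
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class SetaPattern:
    """Seta (x, y) coordinates, in um, within a wing region of known area."""

    points: np.ndarray
    region_area_um2: float
    wing_id: str = ""
    genotype: str = ""

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array")
        if self.region_area_um2 <= 0:
            raise ValueError("region area must be > 0")

    @property
    def n(self) -> int:
        return int(self.points.shape[0])


def nnd4_area(pattern: SetaPattern | np.ndarray) -> float:
    """Mean area occupied per seta from nearest-4-neighbour distances.

    For each point i, nnd4_i is the mean Euclidean distance to its four
    nearest neighbours (self excluded); the estimate is
    mean_i pi * (nnd4_i / 2)^2 in um^2.  Requires >= 5 points.  Exact under
    coordinate scaling: scaling all coordinates by s scales the output by
    s^2.  Ties in neighbour rank are broken by ascending point index;
    duplicate coordinates are tolerated but logged.
    """
    pts = pattern.points if isinstance(pattern, SetaPattern) else np.asarray(pattern, float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("pattern must be an (n, 2) coordinate array")
    if pts.shape[0] < 5:
        raise ValueError("nnd4 requires >= 5 points")
    if np.unique(pts, axis=0).shape[0] < pts.shape[0]:
        logger.warning("duplicate coordinates in seta pattern")
    tree = cKDTree(pts)
    dist, _ = tree.query(pts, k=5)
    nnd4 = dist[:, 1:5].mean(axis=1)
    return float(np.mean(np.pi * (nnd4 / 2.0) ** 2))


@dataclasses.dataclass(frozen=True)
class CellMetrics:
    """Percent changes of the test pattern relative to the reference.

    ``cell_number_pct`` uses the seta-count ratio; an alternative estimate
    dividing the area ratio by the size ratio is reported alongside, since
    the two need not agree on real (noisy, unevenly sampled) wings.
    """

    cell_size_pct: float
    cell_number_pct: float
    area_pct: float
    cell_number_from_area_pct: float


def cell_metrics(p_ref: SetaPattern, p_test: SetaPattern) -> CellMetrics:
    """Decompose a region-area change into cell size and cell number.

    cell size change = nnd4-area ratio - 1; cell number change =
    seta-count ratio - 1; area change = region-area ratio - 1, all as
    percentages of the reference pattern.
    """
    size_ratio = nnd4_area(p_test) / nnd4_area(p_ref)
    number_ratio = p_test.n / p_ref.n
    area_ratio = p_test.region_area_um2 / p_ref.region_area_um2
    return CellMetrics(
        cell_size_pct=100.0 * (size_ratio - 1.0),
        cell_number_pct=100.0 * (number_ratio - 1.0),
        area_pct=100.0 * (area_ratio - 1.0),
        cell_number_from_area_pct=100.0 * (area_ratio / size_ratio - 1.0),
    )


def cells_per_seta(nuclei: int, setae: int, circle_radius_um: float = 30.0) -> float:
    """Cells (nuclei) per seta within a sampling circle of the pupal wing."""
    if setae < 1:
        raise ValueError("setae must be >= 1")
    if nuclei < 0:
        raise ValueError("nuclei must be >= 0")
    if circle_radius_um <= 0:
        raise ValueError("circle radius must be > 0")
    return nuclei / setae


@dataclasses.dataclass(frozen=True)
class MannWhitneyResult:
    U: float
    p_value: float
    method: str


def mann_whitney(
    group_a: Sequence[float], group_b: Sequence[float], max_exact_n: int = 20
) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test.

    Uses the exact null distribution when both groups have <= 20
    observations and there are no ties; otherwise the tie-corrected normal
    approximation.  When every observation in both groups is identical the
    test is vacuous and p = 1 is returned by convention (logged).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        logger.info("all observations tied across groups; p = 1 by convention")
        return MannWhitneyResult(U=a.size * b.size / 2.0, p_value=1.0, method="all-ties")
    ties = np.unique(pooled).size < pooled.size
    if not ties and max(a.size, b.size) <= max_exact_n:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return MannWhitneyResult(U=float(res.statistic), p_value=float(res.pvalue), method=method)
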