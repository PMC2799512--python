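"""Map-distance estimation and fine-mapping interval algebra.

The estimators here are the deterministic arithmetic of a positional-cloning
effort: map distance in centimorgans from recombinant counts (1 cM = 1%
recombinant gametes), a local recombination rate in cM/Mb obtained by
chaining an outer map distance through the fraction of outer recombinants
that break within an inner physical window, and the minimal causal interval
implied by a panel of recombinant males each typed at ordered markers and
phenotyped for the focal trait.

Interval calling assumes a single causal locus and crossover parsimony:
each recombinant's haplotype carries exactly the breakpoints attested by
its typed markers, with every breakpoint located anywhere within the gap
between the nearest flanking typed markers of differing genotype
(untyped markers are skipped, which widens the gap conservatively).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .cross_sim import MarkerMap

#: Physical span of the cloned candidate region in each species' assembly;
#: indel differences make the same interval 13.5 kb in N. vitripennis
#: coordinates and 10.8 kb in N. giraulti.  vitripennis is canonical here.
WS1_REGION_SPAN_BP = {"vitripennis": 13_500, "giraulti": 10_800}

__all__ = [
    "MapDistance",
    "IntervalCall",
    "ContradictoryPanelError",
    "map_distance_cM",
    "local_rate_cM_per_Mb",
    "minimal_interval",
    "WS1_REGION_SPAN_BP",
]


@dataclasses.dataclass(frozen=True)
class MapDistance:
    """Point estimate and Wilson confidence interval, all in cM."""

    cM: float
    k: int
    n: int
    ci_low_cM: float
    ci_high_cM: float

    def __float__(self) -> float:
        return self.cM


def map_distance_cM(k: int, n: int, ci_alpha: float = 0.05) -> MapDistance:
    """Map distance 100*k/n cM from k recombinants out of n screened.

    A Wilson score interval on the recombinant fraction is attached (the
    interval is reported, never used for downstream interval calling).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError("k must satisfy 0 <= k <= n")
    lo, hi = proportion_confint(k, n, alpha=ci_alpha, method="wilson")
    return MapDistance(
        cM=100.0 * k / n, k=k, n=n, ci_low_cM=100.0 * float(lo), ci_high_cM=100.0 * float(hi)
    )


def local_rate_cM_per_Mb(
    cM_outer: float, n_outer_recombinants: int, k_inner: int, phys_kb: float
) -> float:
    """Local recombination rate in cM/Mb around a fine-mapped locus.

    Chains the outer map distance through the inner breakpoint fraction:
    (cM_outer / n_outer) gives cM per outer recombinant; multiplying by
    (k_inner recombinants / phys_kb) and by 1000 kb/Mb yields cM/Mb for the
    inner physical window.
    """
    if cM_outer <= 0 or n_outer_recombinants <= 0 or phys_kb <= 0:
        raise ValueError("cM_outer, n_outer_recombinants and phys_kb must be > 0")
    if k_inner < 0:
        raise ValueError("k_inner must be >= 0")
    return (cM_outer / n_outer_recombinants) * (k_inner / phys_kb) * 1000.0


class ContradictoryPanelError(ValueError):
    """Raised when no single causal position explains every recombinant.

    Carries the ids of the offending recombinants (possible phenotyping
    error or a two-locus architecture).
    """

    def __init__(self, recombinants: Sequence[str]):
        self.recombinants = list(recombinants)
        super().__init__(
            "contradictory recombinant panel; offending recombinants: "
            + ", ".join(map(str, self.recombinants))
        )


@dataclasses.dataclass(frozen=True)
class IntervalCall:
    """Half-open bp interval containing the causal locus.

    ``start``/``end`` of None denote a bound left open by the panel (no
    recombinant constrains that side).  ``segments`` lists the allowed
    inter-marker segments; a single contiguous run is expected under a
    single-locus model.
    """

    scaffold: str
    start: int | None
    end: int | None
    support: tuple[str, ...]
    segments: tuple[tuple[int | None, int | None], ...]
    double_crossover_ids: tuple[str, ...] = ()

    @property
    def n_support(self) -> int:
        return len(self.support)

    def width_bp(self) -> int | None:
        if self.start is None or self.end is None:
            return None
        return self.end - self.start


def _forced_allele(typed: list[tuple[int, str]], seg: int) -> str | None:
    """Allele forced at inter-marker segment ``seg`` under parsimony.

    ``typed`` holds (marker index, allele) for typed markers, ascending.
    Segment ``seg`` spans markers seg-1 and seg (seg = 0 is the left flank,
    seg = L the right flank).  The genotype is forced when the nearest
    typed markers on both sides agree, or when only one side is typed
    (no extra breakpoint is posited beyond the outermost typed marker).
    """
    left = None
    right = None
    for i, a in typed:
        if i <= seg - 1:
            left = a
        if i >= seg and right is None:
            right = a
    if left is None and right is None:
        return None
    if left is None:
        return right
    if right is None:
        return left
    return left if left == right else None


def _n_breakpoints(typed: list[tuple[int, str]]) -> int:
    alleles = [a for _, a in typed]
    return sum(1 for x, y in zip(alleles, alleles[1:]) if x != y)


def minimal_interval(
    panel: pd.DataFrame,
    rmap: MarkerMap,
    donor_allele: str = "g",
    recipient_allele: str = "v",
    large_phenotype: str = "large",
    id_col: str = "recombinant_id",
    phenotype_col: str = "phenotype",
) -> IntervalCall:
    """Minimal causal interval from a recombinant panel.

    ``panel`` has one row per recombinant male with its id, its wing
    phenotype, and one column per map marker holding the species-origin
    call (donor/recipient allele label, NA for untyped).  A large phenotype
    requires the causal genotype to be the donor allele, a small phenotype
    the recipient allele; the call is the intersection over recombinants of
    the inter-marker segments where the required allele is attainable.

    Raises :class:`ContradictoryPanelError` naming the offending
    recombinants when the intersection is empty.
    """
    for col in (id_col, phenotype_col):
        if col not in panel.columns:
            raise ValueError(f"panel lacks required column {col!r}")
    marker_cols = [m for m in rmap.names if m in panel.columns]
    if len(marker_cols) < 2:
        raise ValueError("panel must type >= 2 map markers")
    marker_idx = {m: rmap.index(m) for m in marker_cols}
    L = len(rmap)
    n_seg = L + 1  # left flank, L-1 gaps, right flank

    allowed_rows: list[np.ndarray] = []
    ids: list[str] = []
    doubles: list[str] = []
    for _, row in panel.iterrows():
        rid = str(row[id_col])
        pheno = str(row[phenotype_col])
        required = donor_allele if pheno == large_phenotype else recipient_allele
        typed = sorted(
            (marker_idx[m], str(row[m]))
            for m in marker_cols
            if not pd.isna(row[m]) and str(row[m]) != "NA"
        )
        for _, a in typed:
            if a not in (donor_allele, recipient_allele):
                raise ValueError(f"recombinant {rid}: unknown genotype call {a!r}")
        if len(typed) < 2:
            raise ValueError(f"recombinant {rid}: fewer than 2 typed markers")
        if _n_breakpoints(typed) >= 2:
            doubles.append(rid)
        mask = np.zeros(n_seg, dtype=bool)
        for seg in range(n_seg):
            forced = _forced_allele(typed, seg)
            mask[seg] = forced is None or forced == required
        if not mask.any():
            raise ContradictoryPanelError([rid])
        allowed_rows.append(mask)
        ids.append(rid)

    if not ids:
        raise ValueError("empty panel")
    joint = np.logical_and.reduce(allowed_rows)
    if not joint.any():
        others = np.ones(n_seg, dtype=bool)
        offending = []
        for rid, mask in zip(ids, allowed_rows):
            rest = np.logical_and.reduce(
                [m for r, m in zip(ids, allowed_rows) if r != rid] or [others]
            )
            if not (mask & rest).any():
                offending.append(rid)
        raise ContradictoryPanelError(offending or ids)

    # contiguous runs of allowed segments -> bp bounds
    seg_bounds: list[tuple[int | None, int | None]] = []
    run_start = None
    for seg in range(n_seg + 1):
        on = seg < n_seg and joint[seg]
        if on and run_start is None:
            run_start = seg
        elif not on and run_start is not None:
            # segment j spans [bp[j-1], bp[j]); segments 0 and L are the
            # open flanks, whose outer bound is None
            lo = None if run_start == 0 else int(rmap.bp[run_start - 1])
            hi = None if seg - 1 == L else int(rmap.bp[seg - 1])
            seg_bounds.append((lo, hi))
            run_start = None
    start = seg_bounds[0][0]
    end = seg_bounds[-1][1]
    return IntervalCall(
        scaffold=rmap.scaffold,
        start=start,
        end=end,
        support=tuple(ids),
        segments=tuple(seg_bounds),
        double_crossover_ids=tuple(doubles),
    )
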