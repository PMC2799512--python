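"""Forward simulation of haplodiploid crosses.

In haplodiploid wasps such as *Nasonia*, virgin females produce exclusively
haploid male offspring, each carrying a single maternal gamete.  This makes
males a direct readout of maternal meiosis: every marker is expressed, and a
recessive lethal carried on one maternal haplotype kills exactly the sons
that inherit it.  A lethal placed in coupling with the donor allele of a
focal locus therefore acts as a selectable filter -- the only surviving sons
that carry the donor focal allele are recombinants between the lethal and
the focal locus, which is the engine of a lethal-enrichment recombinant
screen.

Gametes are simulated marker-to-marker: crossovers occur independently in
each inter-marker interval with that interval's recombination fraction
(no crossover interference).  At the sub-centimorgan distances this package
targets, the linear approximation cM = 100*r is numerically exact; a
Haldane conversion is available for longer maps.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import numpy as np

WILDTYPE = "+"

__all__ = [
    "WILDTYPE",
    "MapError",
    "GenotypeError",
    "EnrichmentUndefinedError",
    "Locus",
    "MarkerMap",
    "DiploidGenotype",
    "ScreenResult",
    "IntrogressionState",
    "r_from_cM",
    "cM_from_r",
    "gen_offspring",
    "simulate_screen",
    "enrichment_factor",
    "simulate_backcross",
]


class MapError(ValueError):
    """Raised for non-monotone or otherwise invalid marker maps."""


class GenotypeError(ValueError):
    """Raised for genotypes inconsistent with the map's allele alphabet."""


class EnrichmentUndefinedError(ValueError):
    """Raised when the enrichment factor is undefined (no recombinants)."""


def r_from_cM(d: float | np.ndarray, mapping: str = "linear"):
    """Convert map distance in cM to a recombination fraction.

    ``linear`` uses r = d/100 (valid for d < 50 cM and exact at the small
    distances of a fine-mapping screen); ``haldane`` uses
    r = (1 - exp(-2d/100)) / 2, which saturates at 0.5.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise MapError("map distances must be non-negative")
    if mapping == "linear":
        if np.any(d >= 50):
            raise MapError(
                "linear cM->r conversion invalid for distances >= 50 cM; "
                "use mapping='haldane'"
            )
        r = d / 100.0
    elif mapping == "haldane":
        r = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    else:
        raise ValueError(f"unknown mapping {mapping!r}")
    return float(r) if r.ndim == 0 else r


def cM_from_r(r: float | np.ndarray, mapping: str = "linear"):
    """Inverse of :func:`r_from_cM`."""
    r = np.asarray(r, dtype=float)
    if np.any((r < 0) | (r >= 0.5)):
        raise MapError("recombination fractions must lie in [0, 0.5)")
    if mapping == "linear":
        d = 100.0 * r
    elif mapping == "haldane":
        d = -50.0 * np.log(1.0 - 2.0 * r)
    else:
        raise ValueError(f"unknown mapping {mapping!r}")
    return float(d) if d.ndim == 0 else d


@dataclasses.dataclass(frozen=True)
class Locus:
    name: str
    bp: int
    cM: float


class MarkerMap:
    """Ordered loci on one scaffold with bp and cM positions.

    Parameters
    ----------
    loci : iterable of (name, bp, cM) or Locus
    scaffold : label of the physical scaffold the bp coordinates refer to
    alleles : optional mapping locus name -> allowed allele labels; when
        given, genotypes are validated against it.
    """

    def __init__(
        self,
        loci: Iterable[Locus | tuple],
        scaffold: str = "scaffold_1",
        alleles: Mapping[str, Sequence[str]] | None = None,
    ):
        loci = [l if isinstance(l, Locus) else Locus(*l) for l in loci]
        if not loci:
            raise MapError("map must contain at least one locus")
        names = [l.name for l in loci]
        if len(set(names)) != len(names):
            raise MapError("duplicate locus names")
        bp = np.array([l.bp for l in loci], dtype=np.int64)
        cm = np.array([l.cM for l in loci], dtype=float)
        if np.any(np.diff(bp) <= 0):
            raise MapError("bp positions must be strictly increasing")
        if np.any(np.diff(cm) < 0):
            raise MapError("cM positions must be non-decreasing")
        self.loci = loci
        self.names = names
        self.bp = bp
        self.cM = cm
        self.scaffold = scaffold
        self.alleles = {k: tuple(v) for k, v in alleles.items()} if alleles else None
        self._index = {n: i for i, n in enumerate(names)}

    def __len__(self) -> int:
        return len(self.loci)

    def index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise MapError(f"locus {name!r} not on map") from None

    def interval_r(self, mapping: str = "linear") -> np.ndarray:
        """Recombination fraction of each inter-marker interval."""
        r = r_from_cM(np.diff(self.cM), mapping=mapping)
        return np.atleast_1d(r)

    def pair_r(self, locus_a: str, locus_b: str, mapping: str = "linear") -> float:
        """Recombination fraction between two (not necessarily adjacent) loci.

        Under independent per-interval crossovers the two-locus fraction is
        the probability of an odd number of crossovers between them:
        r = (1 - prod(1 - 2 r_i)) / 2.
        """
        i, j = sorted((self.index(locus_a), self.index(locus_b)))
        r = self.interval_r(mapping=mapping)[i:j]
        return float(0.5 * (1.0 - np.prod(1.0 - 2.0 * r)))

    def validate_haplotype(self, hap: Sequence[str]) -> tuple[str, ...]:
        hap = tuple(str(a) for a in hap)
        if len(hap) != len(self):
            raise GenotypeError(
                f"haplotype has {len(hap)} alleles for a {len(self)}-locus map"
            )
        if self.alleles is not None:
            for name, a in zip(self.names, hap):
                if a not in self.alleles[name]:
                    raise GenotypeError(
                        f"unknown allele {a!r} at locus {name!r}; "
                        f"declared: {self.alleles[name]}"
                    )
        return hap


@dataclasses.dataclass(frozen=True)
class DiploidGenotype:
    """A mother's two haplotypes, each a tuple of allele labels map-ordered."""

    hap1: tuple[str, ...]
    hap2: tuple[str, ...]

    @classmethod
    def from_haplotypes(cls, rmap: MarkerMap, hap1, hap2) -> "DiploidGenotype":
        return cls(rmap.validate_haplotype(hap1), rmap.validate_haplotype(hap2))

    def heterozygous_loci(self) -> list[int]:
        return [i for i, (a, b) in enumerate(zip(self.hap1, self.hap2)) if a != b]


def _gamete_indices(
    rmap: MarkerMap, n: int, rng: np.random.Generator, mapping: str = "linear"
) -> np.ndarray:
    """(n, L) matrix of parental-haplotype indices (0/1) for n gametes."""
    L = len(rmap)
    start = rng.integers(0, 2, size=n, dtype=np.uint8)
    if L == 1:
        return start[:, None]
    r = rmap.interval_r(mapping=mapping)
    co = (rng.random((n, L - 1)) < r).astype(np.uint8)
    steps = np.concatenate([start[:, None], co], axis=1)
    return np.cumsum(steps, axis=1, dtype=np.uint8) % 2


def gen_offspring(
    rmap: MarkerMap,
    mother: DiploidGenotype,
    n: int,
    seed: int | np.random.Generator,
    mapping: str = "linear",
) -> np.ndarray:
    """Simulate n haploid male offspring (maternal gametes).

    Returns an (n, L) array of allele labels.  Each gamete starts on a
    uniformly chosen maternal haplotype and switches haplotype independently
    in each inter-marker interval with that interval's recombination
    fraction.  Reproducible for a fixed integer seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rmap.validate_haplotype(mother.hap1)
    rmap.validate_haplotype(mother.hap2)
    if not mother.heterozygous_loci():
        raise GenotypeError("mother must be heterozygous at >= 1 locus")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = _gamete_indices(rmap, n, rng, mapping=mapping)
    haps = np.array([mother.hap1, mother.hap2])
    return haps[idx, np.arange(len(rmap))]


@dataclasses.dataclass
class ScreenResult:
    """Outcome of a lethal-enrichment recombinant screen.

    ``n_recombinant_detected`` counts surviving males that carry the donor
    focal allele; by construction of the screen each of them is recombinant
    between the lethal and the focal locus.  ``n_carrier_conceived`` counts
    focal-donor carriers before lethal filtering, which is what one would
    have to genotype absent the lethal.
    """

    r_true: float
    n_conceived: int
    n_surviving: int
    n_carrier_conceived: int
    n_recombinant_detected: int
    class_counts: dict[str, int]
    n_double_crossover: int
    lethal_locus: str
    focal_locus: str
    focal_donor_allele: str

    def __post_init__(self) -> None:
        if self.n_surviving > self.n_conceived:
            raise ValueError("n_surviving exceeds n_conceived")
        if sum(self.class_counts.values()) != self.n_surviving:
            raise ValueError("class counts must sum to n_surviving")


def _screen_batch(rmap, mother, li, fi, donor_hap, n, rng, mapping):
    idx = _gamete_indices(rmap, n, rng, mapping=mapping)
    lethal = idx[:, li] == donor_hap
    carrier = idx[:, fi] == donor_hap
    return idx, ~lethal, carrier


def simulate_screen(
    rmap: MarkerMap,
    mother: DiploidGenotype,
    lethal_locus: str,
    focal_locus: str,
    n: int | None = None,
    seed: int | np.random.Generator = 0,
    survivors_target: int | None = None,
    lethal_allele: str | None = None,
    mapping: str = "linear",
) -> ScreenResult:
    """Run a lethal-enrichment screen on haploid male offspring.

    The mother must be heterozygous lethal.donor / +.+ with the lethal in
    coupling with the donor focal allele.  The lethal is 100% penetrant in
    haploid males: every conceived son carrying it dies.  Either ``n``
    (conceived offspring) or ``survivors_target`` (condition on a fixed
    number of surviving, i.e. screened, males) must be given.

    Surviving males are tallied into phenotype classes keyed by their
    allele combination at all non-lethal loci; gametes whose genotype vector
    implies >= 2 crossovers are counted in ``n_double_crossover``.
    """
    if (n is None) == (survivors_target is None):
        raise ValueError("give exactly one of n or survivors_target")
    li = rmap.index(lethal_locus)
    fi = rmap.index(focal_locus)
    if li == fi:
        raise ValueError("lethal and focal locus must differ")
    if mother.hap1[li] == mother.hap2[li]:
        raise GenotypeError("mother must be heterozygous at the lethal locus")
    rmap.validate_haplotype(mother.hap1)
    rmap.validate_haplotype(mother.hap2)
    if lethal_allele is None:
        cands = [a for a in (mother.hap1[li], mother.hap2[li]) if a != WILDTYPE]
        if len(cands) != 1:
            raise GenotypeError(
                "lethal allele ambiguous; pass lethal_allele explicitly"
            )
        lethal_allele = cands[0]
    donor_hap = 0 if mother.hap1[li] == lethal_allele else 1
    donor = (mother.hap1, mother.hap2)[donor_hap]
    other = (mother.hap2, mother.hap1)[donor_hap]
    if donor[fi] == other[fi]:
        raise GenotypeError("mother must be heterozygous at the focal locus")
    focal_donor_allele = donor[fi]

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    haps = np.array([mother.hap1, mother.hap2])
    visible = [i for i in range(len(rmap)) if i != li]

    n_conceived = 0
    n_carrier_conceived = 0
    n_recombinant = 0
    n_double = 0
    class_counts: dict[str, int] = {}
    collected = 0
    remaining_conceived = n if n is not None else None

    while True:
        if survivors_target is not None:
            batch = max(2 * (survivors_target - collected) + 64, 1024)
        else:
            batch = min(remaining_conceived, 1_000_000)
            if batch == 0:
                break
        idx, survive, carrier = _screen_batch(
            rmap, mother, li, fi, donor_hap, batch, rng, mapping
        )
        if survivors_target is not None and collected + int(survive.sum()) >= survivors_target:
            # truncate at the conceived index of the target-th survivor
            stop = np.searchsorted(np.cumsum(survive), survivors_target - collected)
            idx, survive, carrier = idx[: stop + 1], survive[: stop + 1], carrier[: stop + 1]
            batch = stop + 1
        n_conceived += batch
        n_carrier_conceived += int(carrier.sum())
        surv_idx = idx[survive]
        collected += surv_idx.shape[0]
        n_recombinant += int((survive & carrier).sum())
        n_double += int((np.abs(np.diff(surv_idx.astype(np.int8), axis=1)).sum(axis=1) >= 2).sum())
        labels = haps[surv_idx[:, visible], visible] if visible else np.empty((surv_idx.shape[0], 0))
        if labels.size:
            joined = np.array([" ".join(row) for row in labels])
            uniq, cnt = np.unique(joined, return_counts=True)
            for u, c in zip(uniq, cnt):
                class_counts[str(u)] = class_counts.get(str(u), 0) + int(c)
        if survivors_target is not None:
            if collected >= survivors_target:
                break
        else:
            remaining_conceived -= batch

    return ScreenResult(
        r_true=rmap.pair_r(lethal_locus, focal_locus, mapping=mapping),
        n_conceived=n_conceived,
        n_surviving=collected,
        n_carrier_conceived=n_carrier_conceived,
        n_recombinant_detected=n_recombinant,
        class_counts=class_counts,
        n_double_crossover=n_double,
        lethal_locus=lethal_locus,
        focal_locus=focal_locus,
        focal_donor_allele=focal_donor_allele,
    )


def enrichment_factor(result: ScreenResult) -> float:
    """Fold-enrichment of recombinant discovery conferred by the lethal.

    Defined as 1 / p_hat, where p_hat is the estimated fraction of
    focal-donor-allele carriers that are recombinant absent selection:
    without the lethal one would genotype ~1/p_hat donor-allele males per
    recombinant found, versus 1 with it.  At true recombination fraction r
    this converges to 1/r.  Other definitions (e.g. per male screened)
    differ by a factor of ~2; this one is used consistently throughout.
    """
    if result.n_carrier_conceived == 0 or result.n_recombinant_detected == 0:
        raise EnrichmentUndefinedError(
            "no recombinant carriers observed; enrichment factor undefined"
        )
    p_hat = result.n_recombinant_detected / result.n_carrier_conceived
    return 1.0 / p_hat


# ---------------------------------------------------------------------------
# Backcross introgression with donor-segment tracking
# ---------------------------------------------------------------------------

Segment = tuple[float, float]


@dataclasses.dataclass
class IntrogressionState:
    """Donor-origin segments carried through a repeated backcross.

    ``history_bp[t]`` holds the half-open [start, end) bp segments of donor
    origin on the selected haplotype after generation t+1.  The selected
    locus is always inside a donor segment (selection retains only gametes
    carrying the donor allele there).
    """

    selected_locus: str
    scaffold: str
    history_bp: list[list[tuple[int, int]]]
    history_morgans: list[list[Segment]]

    @property
    def segments_bp(self) -> list[tuple[int, int]]:
        return self.history_bp[-1]


def _intersect_segments(a: list[Segment], b: list[Segment]) -> list[Segment]:
    out: list[Segment] = []
    i = j = 0
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if lo < hi:
            out.append((lo, hi))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def simulate_backcross(
    rmap: MarkerMap,
    selected_locus: str,
    generations: int,
    seed: int | np.random.Generator = 0,
    donor_span_bp: tuple[int, int] | None = None,
    max_tries: int = 10_000,
) -> IntrogressionState:
    """Backcross a donor haplotype into a recurrent background with selection.

    Each generation a gamete is formed from the carried haplotype and the
    (donor-free) recurrent homolog with crossovers as a Poisson process of
    rate 1 per Morgan along the map; only gametes carrying the donor allele
    at ``selected_locus`` are retained (rejection sampling).  Donor segment
    ends erode generation by generation; the per-generation segment history
    is returned in both genetic (Morgan) and physical (bp) coordinates,
    converted by linear interpolation between markers.
    """
    if generations < 1:
        raise ValueError("generations must be >= 1")
    sel = rmap.index(selected_locus)
    morgans = rmap.cM / 100.0
    total = float(morgans[-1] - morgans[0])
    pos0 = float(morgans[sel] - morgans[0])
    m = morgans - morgans[0]
    if total == 0.0:
        # no recombination anywhere: the donor segment is immortal
        span = (int(rmap.bp[0]), int(rmap.bp[-1])) if donor_span_bp is None else (
            int(donor_span_bp[0]),
            int(donor_span_bp[1]),
        )
        return IntrogressionState(
            selected_locus=selected_locus,
            scaffold=rmap.scaffold,
            history_bp=[[span] for _ in range(generations)],
            history_morgans=[[(0.0, 0.0)] for _ in range(generations)],
        )

    if donor_span_bp is None:
        segments: list[Segment] = [(0.0, total)]
    else:
        lo = float(np.interp(donor_span_bp[0], rmap.bp, m))
        hi = float(np.interp(donor_span_bp[1], rmap.bp, m))
        if not lo <= pos0 <= hi:
            raise ValueError("selected locus outside initial donor segment")
        segments = [(lo, hi)]

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    hist_m: list[list[Segment]] = []
    hist_bp: list[list[tuple[int, int]]] = []
    for _ in range(generations):
        for _try in range(max_tries):
            k = rng.poisson(total)
            cuts = np.sort(rng.uniform(0.0, total, size=k))
            phase = int(rng.integers(0, 2))
            bounds = np.concatenate([[0.0], cuts, [total]])
            carried = [
                (float(bounds[i]), float(bounds[i + 1]))
                for i in range(len(bounds) - 1)
                if (i + phase) % 2 == 0
            ]
            new = _intersect_segments(segments, carried)
            if any(lo <= pos0 <= hi for lo, hi in new):
                segments = new
                break
        else:  # pragma: no cover - astronomically unlikely
            raise RuntimeError("selection rejection sampling failed")
        hist_m.append(list(segments))
        hist_bp.append(
            [
                (
                    int(round(float(np.interp(lo, m, rmap.bp)))),
                    int(round(float(np.interp(hi, m, rmap.bp)))),
                )
                for lo, hi in segments
            ]
        )
    return IntrogressionState(
        selected_locus=selected_locus,
        scaffold=rmap.scaffold,
        history_bp=hist_bp,
        history_morgans=hist_m,
    )
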