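"""Seeded generators for every input the pipeline consumes.

The generators emulate the statistical structure of the wet-lab inputs of
a haplodiploid positional-cloning study -- recombining haploid gametes,
family-nested wing measurements, jittered-lattice seta point patterns, and
qPCR Ct triplicates -- so that every downstream stage is testable without
any laboratory data.  Defaults are the study conditions: marker distances
of the fine-mapping screen, the published per-genotype wing means and SDs,
seta densities of the distal forewing, and a wing expression ratio of 2.39.

Design notes
------------
* Wing tables split the configured total variance into a between-family
  and a within-family component (default 30% / 70%); only the total SD is
  an observed quantity, the split is a modelling choice and configurable.
* Seta patterns default to a jittered square lattice: real wing setae are
  over-dispersed (more regular than Poisson).  ``uniform_random`` mode is
  retained for estimator-bias studies.
* Minus-RT wells are emitted with a "no amplification" sentinel (missing
  Ct), never a Ct of 0.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import cross_sim
from .cross_sim import DiploidGenotype, MarkerMap, WILDTYPE, gen_offspring
from .expression import CT_COLUMNS, RT_MINUS, RT_PLUS
from .morphometrics import MEASUREMENTS, SetaPattern

__all__ = [
    "GeneratorConfig",
    "CtParams",
    "TABLE1_MALE_PARAMS",
    "TABLE1_FEMALE_PARAMS",
    "TABLE1_FAMILY_DESIGN",
    "screen_map",
    "screen_mother",
    "gen_offspring",
    "gen_wing_table",
    "gen_seta_pattern",
    "gen_ct_table",
    "PRESETS",
]


def _scale(ref: Mapping[str, tuple[float, float]], rel: Mapping[str, tuple[float, float]]):
    return {
        m: (ref[m][0] * mu, ref[m][0] * sd) for m, (mu, sd) in rel.items()
    }


_REF_MALE = {
    "length_um": (1065.0, 28.0),
    "width_um": (326.0, 11.0),
    "area_um2": (242000.0, 13000.0),
    "head_width_um": (402.0, 9.0),
}
_REF_FEMALE = {
    "length_um": (2006.0, 36.0),
    "width_um": (913.0, 19.0),
    "area_um2": (1175000.0, 43000.0),
    "head_width_um": (495.0, 15.0),
}

#: Per-genotype (mean, SD) of male wing measurements, um / um^2.  The
#: wild-type strain is parameterised absolutely; the introgression and
#: donor-species strains by their relative means and SDs times the
#: wild-type mean.
TABLE1_MALE_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    "ws1_vV": dict(_REF_MALE),
    "ws1_gV_40kb": _scale(
        _REF_MALE,
        {
            "length_um": (1.15, 0.04),
            "width_um": (1.30, 0.05),
            "area_um2": (1.45, 0.09),
            "head_width_um": (0.98, 0.04),
        },
    ),
    "ws1_gG": _scale(
        _REF_MALE,
        {
            "length_um": (1.28, 0.04),
            "width_um": (1.81, 0.05),
            "area_um2": (2.16, 0.13),
            "head_width_um": (1.01, 0.03),
        },
    ),
}

TABLE1_FEMALE_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    "ws1_vV": dict(_REF_FEMALE),
    "ws1_gV_40kb": _scale(
        _REF_FEMALE,
        {
            "length_um": (1.02, 0.02),
            "width_um": (1.02, 0.02),
            "area_um2": (1.03, 0.05),
            "head_width_um": (0.98, 0.02),
        },
    ),
    "ws1_gG": _scale(
        _REF_FEMALE,
        {
            "length_um": (0.86, 0.02),
            "width_um": (0.87, 0.02),
            "area_um2": (0.75, 0.03),
            "head_width_um": (0.98, 0.02),
        },
    ),
}

#: (n_families, n_per_family) per genotype: 5 individuals per family,
#: 8 / 5 / 8 families.
TABLE1_FAMILY_DESIGN: dict[str, tuple[int, int]] = {
    "ws1_vV": (8, 5),
    "ws1_gV_40kb": (5, 5),
    "ws1_gG": (8, 5),
}


@dataclasses.dataclass(frozen=True)
class CtParams:
    """qPCR generating parameters.

    ``true_ratio`` is the generative target/control expression ratio of
    genotype A over genotype B; noiseless tables round-trip it exactly
    through the 2^-ddCt estimator.
    """

    true_ratio: float = 2.39
    base_ct_target: float = 24.0
    base_ct_control: float = 20.0
    noise_sd: float = 0.2
    n_triplicates: int = 3
    n_replicates: int = 7
    tissue: str = "wing"
    genotype_a: str = "ws1_vV"
    genotype_b: str = "ws1_gV_40kb"
    target_gene: str = "dsx"
    control_gene: str = "rp49"

    def __post_init__(self) -> None:
        if self.true_ratio <= 0:
            raise ValueError("true_ratio must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_triplicates < 1 or self.n_replicates < 1:
            raise ValueError("counts must be >= 1")


@dataclasses.dataclass
class GeneratorConfig:
    """All generating parameters, defaulting to the study conditions."""

    seed: int = 0
    n_offspring: int = 15594
    #: (name, bp, cM); the 0.57 cM lethal-to-locus distance over ~4.75 Mb
    #: matches the region's low local rate of ~0.12 cM/Mb.
    marker_map_spec: tuple = (("lethalD4", 0, 0.0), ("ws1", 4_750_000, 0.57))
    family_design: Mapping[str, tuple[int, int]] = dataclasses.field(
        default_factory=lambda: dict(TABLE1_FAMILY_DESIGN)
    )
    wing_params: Mapping[str, Mapping[str, tuple[float, float]]] = dataclasses.field(
        default_factory=lambda: {k: dict(v) for k, v in TABLE1_MALE_PARAMS.items()}
    )
    family_variance_fraction: float = 0.3
    #: points per um^2: 580 setae over a 135000 um^2 distal region
    seta_density: float = 580.0 / 135000.0
    region_area_um2: float = 135000.0
    pattern_mode: str = "lattice_jitter"
    jitter_fraction: float = 0.25
    ct_params: CtParams = dataclasses.field(default_factory=CtParams)

    def __post_init__(self) -> None:
        if self.n_offspring < 1:
            raise ValueError("n_offspring must be >= 1")
        if self.seta_density <= 0 or self.region_area_um2 <= 0:
            raise ValueError("seta density and region area must be > 0")
        if not 0 <= self.family_variance_fraction < 1:
            raise ValueError("family_variance_fraction must be in [0, 1)")
        if self.pattern_mode not in ("lattice_jitter", "uniform_random"):
            raise ValueError(f"unknown pattern_mode {self.pattern_mode!r}")
        if not 0 <= self.jitter_fraction <= 0.25:
            raise ValueError("jitter_fraction must be in [0, 0.25]")
        for g, (nf, npf) in self.family_design.items():
            if nf < 1 or npf < 1:
                raise ValueError(f"family design for {g!r} must be >= 1")
        for g, meas in self.wing_params.items():
            for m, (mu, sd) in meas.items():
                if mu < 0:
                    raise ValueError(f"negative mean for {g}/{m}")
                if sd < 0:
                    raise ValueError(f"negative SD for {g}/{m}")
        cm = [c for _, _, c in self.marker_map_spec]
        bp = [b for _, b, _ in self.marker_map_spec]
        if sorted(cm) != cm or sorted(bp) != bp:
            raise ValueError("marker cM and bp positions must increase together")

    def marker_map(self) -> MarkerMap:
        return MarkerMap(self.marker_map_spec)


def screen_map(r: float = 0.0057, bp_span: int = 4_750_000) -> MarkerMap:
    """Two-locus lethal / focal-locus map at recombination fraction r."""
    return MarkerMap(
        [("lethalD4", 0, 0.0), ("ws1", bp_span, cross_sim.cM_from_r(r))],
        alleles={"lethalD4": ("l", WILDTYPE), "ws1": ("g", "v")},
    )


def screen_mother(rmap: MarkerMap) -> DiploidGenotype:
    """Heterozygous lethal.donor / +.recipient screen mother.

    The lethal is in coupling with the donor (large-wing) allele on the
    first haplotype; loci beyond the two screen loci are donor/wild-type on
    the lethal haplotype.
    """
    hap1 = tuple("l" if n == "lethalD4" else "g" for n in rmap.names)
    hap2 = tuple(WILDTYPE if n == "lethalD4" else "v" for n in rmap.names)
    return DiploidGenotype.from_haplotypes(rmap, hap1, hap2)


def gen_wing_table(
    cfg: GeneratorConfig,
    sex: str = "male",
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Family-nested wing measurement table.

    Each individual value is genotype mean + family effect + residual with
    the family effect carrying ``family_variance_fraction`` of the total
    configured variance, so the marginal per-genotype SD matches the
    configured SD.  Measurements are generated independently of each
    other.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(cfg.seed if seed is None else seed)
    )
    fb = np.sqrt(cfg.family_variance_fraction)
    fw = np.sqrt(1.0 - cfg.family_variance_fraction)
    rows = []
    for genotype, measures in cfg.wing_params.items():
        n_fam, n_per = cfg.family_design[genotype]
        for fam in range(1, n_fam + 1):
            fam_dev = {m: rng.normal(0.0, fb * sd) for m, (_, sd) in measures.items()}
            for ind in range(1, n_per + 1):
                row = {
                    "genotype": genotype,
                    "sex": sex,
                    "family": f"{genotype}_f{fam}",
                    "individual": f"{genotype}_f{fam}_i{ind}",
                }
                for m, (mu, sd) in measures.items():
                    row[m] = mu + fam_dev[m] + rng.normal(0.0, fw * sd)
                rows.append(row)
    cols = ["genotype", "sex", "family", "individual", *MEASUREMENTS]
    df = pd.DataFrame(rows)
    return df[[c for c in cols if c in df.columns]]


def gen_seta_pattern(
    cfg: GeneratorConfig,
    seed: int | np.random.Generator | None = None,
    wing_id: str = "wing_1",
    genotype: str = "ws1_vV",
    max_tries: int = 10,
) -> SetaPattern:
    """Seta point pattern in a square region of the configured area.

    ``lattice_jitter`` places round(density * area) points on a square
    lattice with spacing 1/sqrt(density) and jitters each coordinate
    uniformly within +/- jitter_fraction * spacing (at <= 25% jitter two
    lattice points can never coincide).  ``uniform_random`` scatters the
    same number of points uniformly.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(cfg.seed if seed is None else seed)
    )
    area = cfg.region_area_um2
    n_points = int(round(cfg.seta_density * area))
    if n_points < 1:
        raise ValueError("density * area must round to >= 1 point")
    side = float(np.sqrt(area))
    if cfg.pattern_mode == "uniform_random":
        pts = rng.uniform(0.0, side, size=(n_points, 2))
        return SetaPattern(pts, region_area_um2=area, wing_id=wing_id, genotype=genotype)
    spacing = 1.0 / np.sqrt(cfg.seta_density)
    n_side = int(np.ceil(side / spacing))
    gx, gy = np.meshgrid(np.arange(n_side), np.arange(n_side), indexing="ij")
    lattice = (np.stack([gx.ravel(), gy.ravel()], axis=1) + 0.5) * spacing
    lattice = lattice[np.lexsort((lattice[:, 1], lattice[:, 0]))][:n_points]
    if lattice.shape[0] < n_points:
        raise ValueError("lattice cannot hold the requested point count")
    for _ in range(max_tries):
        jit = rng.uniform(
            -cfg.jitter_fraction * spacing, cfg.jitter_fraction * spacing, size=lattice.shape
        )
        pts = lattice + jit
        if np.unique(pts, axis=0).shape[0] == n_points:
            return SetaPattern(pts, region_area_um2=area, wing_id=wing_id, genotype=genotype)
    raise RuntimeError("could not generate a coincidence-free pattern")


def gen_ct_table(
    cfg: GeneratorConfig, seed: int | np.random.Generator | None = None
) -> pd.DataFrame:
    """Ct table whose noiseless 2^-ddCt estimate equals the true ratio.

    Genotype A's target Ct is offset by -log2(true_ratio) relative to
    genotype B's, control Cts are shared, Gaussian noise of the configured
    SD is added per well, and each cell carries one minus-RT row with a
    missing Ct ("no amplification").
    """
    p = cfg.ct_params
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(cfg.seed if seed is None else seed)
    )
    base = {
        (p.genotype_a, p.target_gene): p.base_ct_target - np.log2(p.true_ratio),
        (p.genotype_a, p.control_gene): p.base_ct_control,
        (p.genotype_b, p.target_gene): p.base_ct_target,
        (p.genotype_b, p.control_gene): p.base_ct_control,
    }
    rows = []
    for rep in range(1, p.n_replicates + 1):
        for (genotype, gene), ct0 in base.items():
            for _ in range(p.n_triplicates):
                rows.append(
                    {
                        "replicate": f"rep{rep}",
                        "genotype": genotype,
                        "tissue": p.tissue,
                        "gene": gene,
                        "ct": float(ct0 + rng.normal(0.0, p.noise_sd)),
                        "rt_flag": RT_PLUS,
                    }
                )
            rows.append(
                {
                    "replicate": f"rep{rep}",
                    "genotype": genotype,
                    "tissue": p.tissue,
                    "gene": gene,
                    "ct": np.nan,
                    "rt_flag": RT_MINUS,
                }
            )
    return pd.DataFrame(rows, columns=list(CT_COLUMNS))


def _preset_table2(**kw) -> GeneratorConfig:
    return GeneratorConfig(
        seta_density=580.0 / 135000.0, region_area_um2=135000.0, **kw
    )


PRESETS = {
    "table1": lambda **kw: GeneratorConfig(**kw),
    "table2": _preset_table2,
    "screen": lambda **kw: GeneratorConfig(
        marker_map_spec=(("lethalD4", 0, 0.0), ("ws1", 4_750_000, 0.57)), **kw
    ),
    "qpcr": lambda **kw: GeneratorConfig(ct_params=CtParams(), **kw),
}
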