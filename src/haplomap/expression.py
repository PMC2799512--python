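"""qPCR relative quantification by the 2^-ddCt method.

A quantitative RT-PCR experiment compares a target transcript with a
reference (control) transcript in two genotypes.  Each biological
replicate contributes four cells -- (genotype A, target), (genotype A,
control), (genotype B, target), (genotype B, control) -- each run in
triplicate wells, with matched minus-RT wells guarding against genomic DNA
contamination.  The per-cell summary is the median of the triplicate.  The
expression ratio is

    ratio = 2 ** -((ctA_target - ctA_control) - (ctB_target - ctB_control))

with an assumed amplification efficiency of exactly 2 per cycle (no
efficiency correction; ratios are therefore approximate in the same sense
as the assay itself).  Ratios > 1 mean more target transcript in genotype
A.  Replicate sets are summarised by their median and interquartile range.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

#: Required columns of a Ct table.
CT_COLUMNS = ("replicate", "genotype", "tissue", "gene", "ct", "rt_flag")

RT_PLUS = "+RT"
RT_MINUS = "-RT"

__all__ = [
    "CT_COLUMNS",
    "RT_PLUS",
    "RT_MINUS",
    "QpcrError",
    "InvalidReplicateError",
    "ExpressionRatio",
    "RatioSummary",
    "ddct_ratio",
    "summarize_ratios",
]


class QpcrError(ValueError):
    """Malformed Ct data."""


class InvalidReplicateError(QpcrError):
    """Replicate rejected, e.g. for minus-RT amplification."""


@dataclasses.dataclass(frozen=True)
class ExpressionRatio:
    """2^-ddCt ratio for one biological replicate.

    ``medians`` maps (genotype, gene) to the triplicate median Ct used.
    """

    replicate: str
    tissue: str
    ratio: float
    medians: dict[tuple[str, str], float]


def _cell_median(sub: pd.DataFrame, genotype: str, gene: str) -> float:
    cell = sub[
        (sub["genotype"] == genotype)
        & (sub["gene"] == gene)
        & (sub["rt_flag"] == RT_PLUS)
    ]
    cts = cell["ct"].dropna()
    if cts.empty:
        raise QpcrError(f"no +RT wells for genotype {genotype!r}, gene {gene!r}")
    if (cts <= 0).any():
        raise QpcrError("Ct values must be positive")
    return float(cts.median())


def ddct_ratio(
    cts: pd.DataFrame,
    genotype_a: str,
    genotype_b: str,
    target_gene: str,
    control_gene: str,
    rt_window_cycles: float = 5.0,
) -> ExpressionRatio:
    """Expression ratio of target/control in genotype A relative to B.

    ``cts`` is the Ct-table slice of a single biological replicate (and
    tissue).  Minus-RT wells are "no amplification" unless they carry a Ct;
    a replicate is rejected when any minus-RT well amplifies within
    ``rt_window_cycles`` of its +RT cell median, i.e. closely enough that
    genomic contamination could contribute materially to the +RT signal.
    """
    missing = [c for c in CT_COLUMNS if c not in cts.columns]
    if missing:
        raise QpcrError(f"Ct table lacks columns: {missing}")
    reps = cts["replicate"].unique()
    if len(reps) != 1:
        raise QpcrError(f"expected a single replicate slice, got {list(reps)}")
    tissues = cts["tissue"].unique()
    if len(tissues) != 1:
        raise QpcrError(f"expected a single tissue slice, got {list(tissues)}")

    medians: dict[tuple[str, str], float] = {}
    for genotype in (genotype_a, genotype_b):
        for gene in (target_gene, control_gene):
            medians[(genotype, gene)] = _cell_median(cts, genotype, gene)
            minus = cts[
                (cts["genotype"] == genotype)
                & (cts["gene"] == gene)
                & (cts["rt_flag"] == RT_MINUS)
            ]["ct"].dropna()
            bad = minus[minus <= medians[(genotype, gene)] + rt_window_cycles]
            if not bad.empty:
                raise InvalidReplicateError(
                    f"replicate {reps[0]!r}: -RT amplification within "
                    f"{rt_window_cycles} cycles of +RT for genotype "
                    f"{genotype!r}, gene {gene!r}"
                )

    ddct = (medians[(genotype_a, target_gene)] - medians[(genotype_a, control_gene)]) - (
        medians[(genotype_b, target_gene)] - medians[(genotype_b, control_gene)]
    )
    return ExpressionRatio(
        replicate=str(reps[0]),
        tissue=str(tissues[0]),
        ratio=float(2.0 ** (-ddct)),
        medians=medians,
    )


@dataclasses.dataclass(frozen=True)
class RatioSummary:
    n: int
    median: float
    iqr: float
    p_value: float


def summarize_ratios(
    ratios: Sequence[ExpressionRatio | float],
    seed: int = 0,
    n_resamples: int = 20_000,
) -> RatioSummary:
    """Median, IQR, and a two-sided location test of ratios against 1.

    The IQR uses linear-interpolation quartiles.  The location test is a
    sign-flip permutation test on the log ratios (statistic: sum of logs):
    under the null of a symmetric log-ratio distribution centred at 0 the
    signs are exchangeable.  Exact enumeration of all 2^n sign patterns is
    used for n <= 16, a seeded Monte Carlo approximation above.
    """
    vals = np.array(
        [r.ratio if isinstance(r, ExpressionRatio) else float(r) for r in ratios],
        dtype=float,
    )
    if vals.size < 1:
        raise ValueError("need >= 1 ratio")
    if (vals <= 0).any():
        raise ValueError("ratios must be > 0")
    median = float(np.median(vals))
    iqr = float(np.percentile(vals, 75) - np.percentile(vals, 25))

    logs = np.log(vals)
    obs = abs(logs.sum())
    mags = np.abs(logs)
    if np.all(mags == 0):
        p = 1.0
    elif vals.size <= 16:
        n = vals.size
        patterns = np.arange(2**n)[:, None] >> np.arange(n) & 1
        signs = patterns * 2 - 1
        perm = np.abs(signs @ mags)
        p = float(np.mean(perm >= obs - 1e-12))
    else:
        rng = np.random.default_rng(seed)
        signs = rng.integers(0, 2, size=(n_resamples, vals.size)) * 2 - 1
        perm = np.abs(signs @ mags)
        p = float((1 + np.sum(perm >= obs - 1e-12)) / (1 + n_resamples))
    return RatioSummary(n=int(vals.size), median=median, iqr=iqr, p_value=p)
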