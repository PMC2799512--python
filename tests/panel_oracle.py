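"""Brute-force oracle and generator for recombinant-panel interval calling.

The oracle enumerates, for each candidate inter-marker segment, every
single-crossover haplotype (orientation x breakpoint gap) consistent with a
recombinant's typed markers and asks whether any of them places the
phenotype-required allele at the candidate position.  It shares no code
with the implementation, which works by a nearest-typed-flanking-marker
rule.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

DONOR = "g"
RECIPIENT = "v"


def _haplotype_allele(first: str, second: str, gap: int, marker: int) -> str:
    """Allele at marker index under a haplotype that switches at ``gap``.

    Markers with index < gap carry ``first``; the rest carry ``second``.
    """
    return first if marker < gap else second


def row_allows_segment(genotypes: list[str], required: str, seg: int) -> bool:
    """True if some single-crossover haplotype matching the typed genotype
    vector carries ``required`` at candidate segment ``seg``.

    Segments are indexed 0..M: 0 is left of the first marker, s in 1..M-1
    lies between markers s-1 and s, M is right of the last.  A candidate in
    the same gap as the crossover may sit on either side of it.
    """
    M = len(genotypes)
    for first, second in ((DONOR, RECIPIENT), (RECIPIENT, DONOR)):
        for gap in range(M + 1):
            ok = all(
                _haplotype_allele(first, second, gap, i) == genotypes[i]
                for i in range(M)
            )
            if not ok:
                continue
            # causal allele at segment seg: before the gap -> first allele,
            # after -> second, same gap -> could be either
            if seg < gap and first == required:
                return True
            if seg > gap and second == required:
                return True
            if seg == gap:
                return True
    return False


def oracle_allowed_segments(panel: pd.DataFrame, marker_names: list[str]) -> np.ndarray:
    M = len(marker_names)
    allowed = np.ones(M + 1, dtype=bool)
    for _, row in panel.iterrows():
        required = DONOR if row["phenotype"] == "large" else RECIPIENT
        genos = [str(row[m]) for m in marker_names]
        mask = np.array(
            [row_allows_segment(genos, required, s) for s in range(M + 1)]
        )
        allowed &= mask
    return allowed


def random_panel(
    rng: np.random.Generator,
    marker_names: list[str],
    n_recombinants: int,
    causal_gap: int | None = None,
) -> tuple[pd.DataFrame, int]:
    """Fully-typed single-crossover panel with a planted causal gap.

    The causal locus sits strictly inside gap ``causal_gap`` (an interior
    gap, 1..M-1).  Each recombinant draws an orientation and a breakpoint
    gap; when breakpoint and causal share a gap, their order within the gap
    is drawn too.  The phenotype is read off the haplotype's allele at the
    causal position.
    """
    M = len(marker_names)
    if causal_gap is None:
        causal_gap = int(rng.integers(1, M))
    rows = []
    for i in range(n_recombinants):
        first, second = (DONOR, RECIPIENT) if rng.integers(2) else (RECIPIENT, DONOR)
        gap = int(rng.integers(0, M + 1))
        genos = [first if j < gap else second for j in range(M)]
        if causal_gap < gap:
            allele = first
        elif causal_gap > gap:
            allele = second
        else:
            allele = first if rng.integers(2) else second
        row = {"recombinant_id": f"rec{i + 1}", "phenotype": "large" if allele == DONOR else "small"}
        row.update(dict(zip(marker_names, genos)))
        rows.append(row)
    return pd.DataFrame(rows), causal_gap
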