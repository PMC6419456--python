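"""acrossCells: TAD pairs occupying identical coordinates in two cell types.

Two TADs form an acrossCells pair when they lie on the same chromosome with
exactly the same start and end. For each pair the package reports the signed
Pearson correlation between the two cell types' fold-enrichment vectors
(signed, unlike the |r| used for clustering: a pair can be functionally
anti-correlated) and the TM-score between their reconstructed structures.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DomainError
from .structsim import tm_score
from .types import FoldEnrichmentVector, GenomicInterval, Structure3D


@dataclass
class AcrossCellPair:
    interval: GenomicInterval
    cell_a: str
    cell_b: str
    state_correlation: float  # signed Pearson; NaN when undefined
    tm: float


def cell_type_pairs(cell_types: list[str]) -> list[tuple[str, str]]:
    """All unordered pairs of cell types (e.g. 6 annotated types -> 15 pairs)."""
    return list(itertools.combinations(cell_types, 2))


def match_across_cells(
    tads_a: list[GenomicInterval], tads_b: list[GenomicInterval]
) -> list[tuple[GenomicInterval, GenomicInterval]]:
    """Pairs with exactly equal (chrom, start, end), ordered by chrom, start."""
    for name, tads in (("a", tads_a), ("b", tads_b)):
        keys = [(t.chrom, t.start, t.end) for t in tads]
        if len(set(keys)) != len(keys):
            raise DomainError(f"duplicate coordinates within TAD list {name}")
    by_coord = {(t.chrom, t.start, t.end): t for t in tads_b}
    matched = [
        (ta, by_coord[(ta.chrom, ta.start, ta.end)])
        for ta in tads_a
        if (ta.chrom, ta.start, ta.end) in by_coord
    ]
    matched.sort(key=lambda p: (p[0].chrom, p[0].start))
    return matched


def across_cell_similarity(
    pair: tuple[GenomicInterval, GenomicInterval],
    fe_a: FoldEnrichmentVector,
    fe_b: FoldEnrichmentVector,
    s_a: Structure3D,
    s_b: Structure3D,
    cell_a: str = "cellA",
    cell_b: str = "cellB",
) -> AcrossCellPair:
    """Signed enrichment correlation and TM-score for one matched pair."""
    va, vb = fe_a.values, fe_b.values
    if va.shape != vb.shape:
        raise DomainError("enrichment vectors must have equal length")
    if np.ptp(va) == 0 or np.ptp(vb) == 0:
        warnings.warn(
            f"constant enrichment vector for {pair[0].id}; correlation undefined",
            stacklevel=2,
        )
        corr = float("nan")
    else:
        corr = float(np.corrcoef(va, vb)[0, 1])
    return AcrossCellPair(
        interval=pair[0],
        cell_a=cell_a,
        cell_b=cell_b,
        state_correlation=corr,
        tm=tm_score(s_a, s_b),
    )
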