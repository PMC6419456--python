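"""Fold enrichment of chromatin states per TAD and functional similarity.

Fold enrichment of state s within region t is the in-region state density
divided by the genome-wide state density:

    F_s = (bp of s overlapping t / length of t) / (bp of s genome-wide / G)

with G the genome size. F_s = 1 means the state occurs in the TAD at exactly
its genome-wide proportion; states absent genome-wide get F_s = 0 by
convention. Bases of t not covered by any segmentation record still count in
the denominator (they dilute every state), but carry no state.

The functional similarity of two TADs is |Pearson r| between their
fold-enrichment vectors (direction of the profile matters for clustering,
not its sign), clipped to [0, 1]; a constant vector has similarity 0.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import DomainError
from .types import (
    FoldEnrichmentVector,
    GenomicInterval,
    Segmentation,
    SimilarityMatrix,
)


def fold_enrichment(
    t: GenomicInterval, seg: Segmentation, genome_size: int
) -> FoldEnrichmentVector:
    """Per-state fold enrichment of one TAD against the genome-wide density."""
    if genome_size < seg.covered_bp():
        raise DomainError("genome_size must be >= bases covered by the segmentation")
    ov = seg.overlap_state_bp(t)
    if ov.sum() == 0:
        warnings.warn(
            f"TAD {t.id} has no overlap with the segmentation; all-zero enrichment",
            stacklevel=2,
        )
        return FoldEnrichmentVector(values=np.zeros(seg.n_states), tad_id=t.id)
    genome = seg.genome_state_bp()
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ov / t.length) / (genome / genome_size)
    f[genome == 0] = 0.0
    return FoldEnrichmentVector(values=f, tad_id=t.id)


def functional_similarity(
    f1: FoldEnrichmentVector | np.ndarray, f2: FoldEnrichmentVector | np.ndarray
) -> float:
    """|Pearson correlation| of two fold-enrichment vectors, in [0, 1]."""
    v1 = f1.values if isinstance(f1, FoldEnrichmentVector) else np.asarray(f1, float)
    v2 = f2.values if isinstance(f2, FoldEnrichmentVector) else np.asarray(f2, float)
    if v1.shape != v2.shape:
        raise DomainError(f"length mismatch: {v1.shape} vs {v2.shape}")
    if v1.shape[0] < 3:
        raise DomainError("need vectors of length >= 3")
    if np.ptp(v1) == 0 or np.ptp(v2) == 0:
        return 0.0
    r = np.corrcoef(v1, v2)[0, 1]
    return float(np.clip(abs(r), 0.0, 1.0))


def functional_similarity_matrix(
    enrichments: list[FoldEnrichmentVector],
) -> SimilarityMatrix:
    """Pairwise |Pearson r| matrix over TAD fold-enrichment vectors."""
    if len(enrichments) < 2:
        raise DomainError("need at least 2 enrichment vectors")
    m = len(enrichments)
    values = np.eye(m)
    for i in range(m):
        for j in range(i + 1, m):
            values[i, j] = values[j, i] = functional_similarity(
                enrichments[i], enrichments[j]
            )
    return SimilarityMatrix(
        values=values, kind="functional", tad_ids=[f.tad_id for f in enrichments]
    )


def cluster_state_enrichment(
    members: list[GenomicInterval], seg: Segmentation, genome_size: int
) -> FoldEnrichmentVector:
    """Pooled fold enrichment over a set of member TADs.

    Overlap bases and region lengths are summed over members before the
    density ratio, i.e. the member set is treated as one region set.
    """
    if not members:
        raise DomainError("members must be non-empty")
    ov = np.zeros(seg.n_states)
    total_len = 0
    for t in members:
        ov += seg.overlap_state_bp(t)
        total_len += t.length
    genome = seg.genome_state_bp()
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ov / total_len) / (genome / genome_size)
    f[genome == 0] = 0.0
    return FoldEnrichmentVector(values=f, tad_id="cluster")


def log2_enrichment(f: FoldEnrichmentVector) -> np.ndarray:
    """log2 fold enrichment for display/scoring; log2(0) -> -inf sentinel."""
    with np.errstate(divide="ignore"):
        return np.log2(f.values)


class FoldEnrichment(BaseEstimator, TransformerMixin):
    """Transformer from TAD intervals to an (m, S) fold-enrichment array.

    Parameters: the segmentation and genome size are fixed at construction;
    ``transform`` maps a list of GenomicInterval to stacked enrichment rows.
    """

    def __init__(self, segmentation: Segmentation, genome_size: int):
        self.segmentation = segmentation
        self.genome_size = genome_size

    def fit(self, X, y=None):
        return self

    def transform(self, X: list[GenomicInterval]) -> np.ndarray:
        return np.vstack(
            [fold_enrichment(t, self.segmentation, self.genome_size).values for t in X]
        )
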