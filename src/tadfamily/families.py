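"""Spectral clustering of similarity matrices and TAD family definition.

TADs are clustered twice — once on the TM-score (structural) similarity
matrix and once on the |Pearson r| fold-enrichment (functional) similarity
matrix — with spectral clustering on the precomputed affinity. A family is
the intersection of one structural cluster with one functional cluster; each
family carries a score (the fraction of chromatin states with log2 fold
enrichment above zero over its pooled members; < 0.5 flags a depleted
family) and a 30 x 30 average contact heatmap.

Cluster indices are relabelled by decreasing size (largest cluster = 1): the
raw spectral labels are arbitrary and not comparable across runs.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import SpectralClustering

from .chromstate import cluster_state_enrichment, log2_enrichment
from .errors import DomainError
from .types import (
    ClusterAssignment,
    ContactMatrix,
    Family,
    FamilyTable,
    FoldEnrichmentVector,
    GenomicInterval,
    Segmentation,
    SimilarityMatrix,
)

#: Predefined cluster-count grids (functional / structural).
K_FUNCTIONAL_GRID = (10, 20, 30)
K_STRUCTURAL_GRID = (2, 3, 5, 10)
HEATMAP_SIZE = 30


def _relabel_by_size(raw: np.ndarray, k: int) -> np.ndarray:
    """Map raw 0-based labels to 1..k ordered by decreasing cluster size;
    ties broken by first occurrence for determinism."""
    sizes = np.bincount(raw, minlength=k)
    first = np.full(k, raw.shape[0])
    for pos, lab in enumerate(raw):
        if pos < first[lab]:
            first[lab] = pos
    order = sorted(range(k), key=lambda c: (-sizes[c], first[c]))
    mapping = {c: rank + 1 for rank, c in enumerate(order)}
    return np.array([mapping[c] for c in raw])


class TADSpectralClustering(ClusterMixin, BaseEstimator):
    """Spectral clustering on a precomputed TAD similarity matrix.

    Normalized-Laplacian spectral embedding into ``n_clusters`` dimensions
    followed by seeded k-means; ``labels_`` are 1..k, size-ordered.
    """

    def __init__(self, n_clusters: int = 2, random_state: int = 0, n_init: int = 10):
        self.n_clusters = n_clusters
        self.random_state = random_state
        self.n_init = n_init

    def fit(self, X, y=None):
        aff = np.asarray(X, dtype=float)
        if aff.ndim != 2 or aff.shape[0] != aff.shape[1]:
            raise DomainError("affinity must be a square matrix")
        if not np.allclose(aff, aff.T, atol=1e-9):
            raise DomainError("affinity must be symmetric")
        m = aff.shape[0]
        if self.n_clusters < 2 or self.n_clusters > m:
            raise DomainError(f"need 2 <= k <= {m}, got k={self.n_clusters}")
        sc = SpectralClustering(
            n_clusters=self.n_clusters,
            affinity="precomputed",
            random_state=self.random_state,
            n_init=self.n_init,
            assign_labels="kmeans",
        )
        with warnings.catch_warnings():
            # disconnected affinity graphs are legitimate (block similarity)
            warnings.simplefilter("ignore")
            raw = sc.fit_predict(aff)
        self.labels_ = _relabel_by_size(raw, self.n_clusters)
        return self


def spectral_cluster(sim: SimilarityMatrix, k: int, seed: int = 0) -> ClusterAssignment:
    """Cluster a similarity matrix into k size-ordered clusters (labels 1..k)."""
    est = TADSpectralClustering(n_clusters=k, random_state=seed)
    est.fit(sim.values)
    labels = {tid: int(lab) for tid, lab in zip(sim.tad_ids, est.labels_)}
    k_eff = len(set(labels.values()))
    if k_eff < k:
        # k-means can leave a cluster empty on degenerate affinities
        labels = {t: min(c, k_eff) for t, c in labels.items()}
        warnings.warn(f"only {k_eff} of {k} clusters are non-empty", stacklevel=2)
        k = k_eff
    return ClusterAssignment(labels=labels, k=k, kind=sim.kind)


def _check_same_ids(a: ClusterAssignment, b: ClusterAssignment) -> None:
    sa, sb = set(a.labels), set(b.labels)
    if sa != sb:
        diff = sorted(sa ^ sb)
        raise DomainError(f"TAD id sets differ; symmetric difference: {diff}")


def overlap_counts(a: ClusterAssignment, b: ClusterAssignment) -> np.ndarray:
    """Contingency counts: entry (i, j) = TADs in cluster i+1 of ``b`` and
    cluster j+1 of ``a`` (k_b rows x k_a columns). By pipeline convention
    ``a`` is the structural and ``b`` the functional clustering."""
    _check_same_ids(a, b)
    counts = np.zeros((b.k, a.k), dtype=int)
    for tid, ca in a.labels.items():
        counts[b.labels[tid] - 1, ca - 1] += 1
    return counts


def overlap_enrichment(
    counts: np.ndarray,
    sizes_a: list[int],
    sizes_b: list[int],
    scale: float = 1000.0,
) -> np.ndarray:
    """Size-normalized overlap: scale * count / (size_b_row * size_a_col).

    Full precision is returned; round to 1 decimal for display (e.g. an
    overlap of 18 between clusters of sizes 167 and 338 displays as 0.3).
    """
    counts = np.asarray(counts, dtype=float)
    sa = np.asarray(sizes_a, dtype=float)
    sb = np.asarray(sizes_b, dtype=float)
    if np.any(sa <= 0) or np.any(sb <= 0):
        raise DomainError("cluster sizes must be positive")
    if counts.shape != (sb.shape[0], sa.shape[0]):
        raise DomainError(
            f"counts shape {counts.shape} inconsistent with sizes "
            f"({sb.shape[0]} x {sa.shape[0]})"
        )
    return scale * counts / np.outer(sb, sa)


def define_families(a: ClusterAssignment, b: ClusterAssignment) -> FamilyTable:
    """One family per non-empty (structural, functional) cluster pair.

    ``a`` is treated as the structural and ``b`` as the functional
    clustering; members are the intersections, families ordered by size
    descending (ties by cluster indices)."""
    _check_same_ids(a, b)
    groups: dict[tuple[int, int], list[str]] = {}
    for tid in a.labels:
        key = (a.labels[tid], b.labels[tid])
        groups.setdefault(key, []).append(tid)
    families = [
        Family(struct_cluster=sc, state_cluster=fc, members=sorted(members))
        for (sc, fc), members in groups.items()
    ]
    families.sort(key=lambda f: (-len(f.members), f.struct_cluster, f.state_cluster))
    return FamilyTable(families=families)


def family_score(cluster_enrichment: FoldEnrichmentVector) -> float:
    """Fraction of states with log2 fold enrichment > 0 (i.e. F_s > 1)."""
    vals = cluster_enrichment.values
    if vals.size == 0:
        raise DomainError("empty enrichment vector")
    return float(np.mean(vals > 1.0))


def score_families(
    table: FamilyTable,
    tads_by_id: dict[str, GenomicInterval],
    seg: Segmentation,
    genome_size: int,
) -> FamilyTable:
    """Attach the depletion score to every family (pooled over its members)."""
    for fam in table:
        fe = cluster_state_enrichment(
            [tads_by_id[t] for t in fam.members], seg, genome_size
        )
        fam.score = family_score(fe)
    return table


def resize_member_matrix(
    m: ContactMatrix, member: GenomicInterval, target: int = HEATMAP_SIZE
) -> tuple[np.ndarray, np.ndarray]:
    """Extract a target x target observed-value matrix for one TAD.

    Members of exactly ``target`` bins yield their submatrix of the
    chromosome matrix ``m``; smaller members are extended evenly into
    flanking bins (odd remainder goes downstream), clipped at chromosome
    bounds with asymmetric completion; larger members have their bins
    partitioned into ``target`` near-equal contiguous groups and
    block-averaged (missing entries excluded). Returns (values, missing).
    """
    if (member.start - m.origin.start) % m.bin_size or (
        member.end - member.start
    ) % m.bin_size:
        raise DomainError(f"member {member.id} is not bin-aligned to the matrix")
    b0 = (member.start - m.origin.start) // m.bin_size
    b1 = (member.end - m.origin.start) // m.bin_size
    n = m.n_bins
    if b0 < 0 or b1 > n:
        raise DomainError(f"member {member.id} outside the chromosome matrix")
    nb = b1 - b0
    if nb < 2:
        raise DomainError(f"member {member.id} has fewer than 2 bins")
    if nb < target:
        extra = target - nb
        left = extra // 2
        right = extra - left  # odd remainder extends downstream
        lo, hi = b0 - left, b1 + right
        if lo < 0 or hi > n:
            warnings.warn(
                f"member {member.id}: flank extension clipped at chromosome bounds",
                stacklevel=2,
            )
            if lo < 0:  # complete asymmetrically on the other side
                hi = min(n, hi - lo)
                lo = 0
            if hi > n:
                lo = max(0, lo - (hi - n))
                hi = n
        vals = m.values[lo:hi, lo:hi]
        miss = m.mask[lo:hi, lo:hi]
        if vals.shape[0] < target:
            # chromosome shorter than the target window: pad as missing
            pad = target - vals.shape[0]
            vals = np.pad(vals, ((0, pad), (0, pad)))
            miss = np.pad(miss, ((0, pad), (0, pad)), constant_values=True)
        return vals.copy(), miss.copy()
    sub = m.values[b0:b1, b0:b1]
    submask = m.mask[b0:b1, b0:b1]
    if nb == target:
        return sub.copy(), submask.copy()
    groups = np.array_split(np.arange(nb), target)
    out = np.zeros((target, target))
    out_missing = np.zeros((target, target), dtype=bool)
    for u, gu in enumerate(groups):
        for v, gv in enumerate(groups):
            block = sub[np.ix_(gu, gv)]
            bmask = submask[np.ix_(gu, gv)]
            obs = ~bmask
            if obs.any():
                out[u, v] = block[obs].mean()
            else:
                out_missing[u, v] = True
    return out, out_missing


def average_family_heatmap(
    members: list[GenomicInterval],
    chrom_matrices: dict[str, ContactMatrix],
    target: int = HEATMAP_SIZE,
) -> np.ndarray:
    """Elementwise mean of member target x target matrices, as log2(mean + 1).

    Missing entries are excluded from the means; cells unobserved in every
    member come out NaN. Members smaller than 2 bins are skipped with a
    warning.
    """
    total = np.zeros((target, target))
    count = np.zeros((target, target))
    used = 0
    for member in members:
        m = chrom_matrices.get(member.chrom)
        if m is None:
            raise DomainError(f"no chromosome matrix for {member.chrom}")
        nb = (member.end - member.start) // m.bin_size
        if nb < 2:
            warnings.warn(f"member {member.id} smaller than 2 bins; skipped", stacklevel=2)
            continue
        vals, miss = resize_member_matrix(m, member, target=target)
        obs = ~miss
        total[obs] += vals[obs]
        count[obs] += 1
        used += 1
    if used == 0:
        raise DomainError("no usable members for the family heatmap")
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(count > 0, total / np.maximum(count, 1), np.nan)
        return np.log2(mean + 1.0)


def gene_density(
    t: GenomicInterval, genes: list[GenomicInterval], bin_size: int
) -> float:
    """Genes overlapping t by >= 1 bp, normalized by t's number of bins."""
    if bin_size <= 0:
        raise DomainError("bin_size must be positive")
    n_bins = -(-t.length // bin_size)  # ceil
    n_genes = sum(1 for g in genes if t.overlaps(g))
    return n_genes / n_bins


def enumerate_heatmap_configurations(
    cell_types: list[str],
    k_functional=K_FUNCTIONAL_GRID,
    k_structural=K_STRUCTURAL_GRID,
) -> list[tuple[str, int, int]]:
    """All (cell type, functional k, structural k) analysis configurations."""
    return [
        (c, kf, ks)
        for c, kf, ks in itertools.product(cell_types, k_functional, k_structural)
    ]
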