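"""Contact matrix -> 3D bead structure, and the two structure statistics.

The conversion chain is: linearly rescale observed contacts of a TAD to
[1, 30] (so the wish-distance law is insensitive to the cell-type-dependent
contact scale), convert to wish distances d = (1/c)^(1/3), and embed in 3D
with metric MDS (stress majorization / SMACOF with per-pair weights, zero on
missing pairs). A t-SNE embedding over a (perplexity, learning-rate) grid can
be produced alternatively; each candidate is rigidly superposed onto a
reference structure and the minimum-RMSD candidate is selected.

Structure statistics: the exponent parameter (log-log slope of mean contact
versus genomic bin separation, a 2D compactness proxy) and the radius of
gyration of the embedded structure (3D compactness). In a well-reconstructed
cohort the two are negatively correlated: slowly decaying contacts (exponent
near 0) produce compact structures with small Rg.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr, spearmanr
from sklearn.base import BaseEstimator
from sklearn.manifold import TSNE

from .errors import (
    ConnectivityError,
    DegenerateInputError,
    DomainError,
    EmptyInputError,
    InsufficientDataError,
    UndefinedCorrelationError,
)
from .structsim import kabsch_superpose
from .types import ContactMatrix, GenomicInterval, Structure3D

RESCALE_LO = 1.0
RESCALE_HI = 30.0
DEFAULT_PERPLEXITIES = (5, 10, 30, 50)
DEFAULT_LEARNING_RATES = (10, 100, 200, 1000)


@dataclass
class WishDistanceMatrix:
    """Target pairwise distances derived from contacts; mask marks missing."""

    values: np.ndarray
    mask: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        n = self.values.shape[0]
        if self.values.shape != (n, n) or self.mask.shape != (n, n):
            raise DomainError("wish distance matrix and mask must be square and equal shape")
        off = ~np.eye(n, dtype=bool)
        obs = off & ~self.mask
        if np.any(self.values[obs] <= 0):
            raise DomainError("observed off-diagonal wish distances must be > 0")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class StructureStats:
    """Per-TAD summary: fitted decay exponent and radius of gyration."""

    tad_id: str
    exponent: float
    rg: float


def rescale_contacts(
    m: ContactMatrix, lo: float = RESCALE_LO, hi: float = RESCALE_HI
) -> ContactMatrix:
    """Affine rescale of observed entries onto [lo, hi], ignoring missing ones."""
    if lo >= hi:
        raise DomainError(f"need lo < hi, got [{lo}, {hi}]")
    obs = m.observed_offdiag()
    if obs.size < 2:
        raise EmptyInputError("need at least two observed off-diagonal contacts")
    cmin, cmax = obs.min(), obs.max()
    if cmax == cmin:
        raise DegenerateInputError(
            "constant contact matrix carries no distance information"
        )
    values = lo + (m.values - cmin) * (hi - lo) / (cmax - cmin)
    values[m.mask] = 0.0
    return ContactMatrix(values=values, mask=m.mask.copy(), bin_size=m.bin_size, origin=m.origin)


def contacts_to_wish_distances(m: ContactMatrix) -> WishDistanceMatrix:
    """d = (1/c)^(1/3) on observed entries; diagonal 0; missing stays missing."""
    off = ~np.eye(m.n_bins, dtype=bool)
    obs = off & ~m.mask
    if np.any(m.values[obs] <= 0):
        raise DomainError("wish distance needs all observed contacts > 0; rescale first")
    d = np.zeros_like(m.values)
    d[obs] = (1.0 / m.values[obs]) ** (1.0 / 3.0)
    mask = m.mask.copy()
    np.fill_diagonal(mask, False)  # self-distance 0 is known, not missing
    np.fill_diagonal(d, 0.0)
    return WishDistanceMatrix(values=d, mask=mask)


def _check_connected(mask: np.ndarray) -> None:
    n = mask.shape[0]
    adj = (~mask) & ~np.eye(n, dtype=bool)
    ncomp, _ = connected_components(csr_matrix(adj), directed=False)
    if ncomp > 1:
        raise ConnectivityError(
            f"observation graph has {ncomp} components; cannot embed"
        )


def _classical_mds_init(delta: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Torgerson classical scaling as a deterministic warm start; missing
    entries are filled with the mean observed distance for the init only."""
    d = delta.copy()
    off = ~np.eye(d.shape[0], dtype=bool)
    missing = mask & off
    if missing.any():
        d[missing] = d[off & ~mask].mean()
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    w, v = np.linalg.eigh(b)
    idx = np.argsort(w)[::-1][:3]
    lam = np.clip(w[idx], 0.0, None)
    return v[:, idx] * np.sqrt(lam)


def smacof_weighted(
    delta: np.ndarray,
    weights: np.ndarray,
    init: np.ndarray,
    max_iter: int = 300,
    tol: float = 1e-10,
) -> tuple[np.ndarray, float]:
    """Stress majorization (SMACOF) with per-pair weights.

    Minimizes sigma(X) = sum_{i<j} w_ij (||x_i - x_j|| - delta_ij)^2 via the
    Guttman transform X <- V^+ B(X) X, where V = diag(W 1) - W. Weights of
    zero remove a pair from the stress entirely (missing data).
    """
    n = delta.shape[0]
    w = weights.copy().astype(float)
    np.fill_diagonal(w, 0.0)
    v = np.diag(w.sum(axis=1)) - w
    vpinv = np.linalg.pinv(v)
    x = init.copy()
    d = squareform(pdist(x))
    old_stress = 0.5 * np.sum(w * (d - delta) ** 2)
    for _ in range(max_iter):
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(d > 0, delta / d, 0.0)
        b = -w * ratio
        np.fill_diagonal(b, 0.0)
        np.fill_diagonal(b, -b.sum(axis=1))
        x = vpinv @ (b @ x)
        d = squareform(pdist(x))
        stress = 0.5 * np.sum(w * (d - delta) ** 2)
        if old_stress - stress < tol * max(old_stress, 1e-30):
            old_stress = stress
            break
        old_stress = stress
    return x, float(old_stress)


class WishDistanceMDS(BaseEstimator):
    """Estimator turning one TAD contact matrix into a 3D bead embedding.

    Parameters
    ----------
    lo, hi : rescale range for observed contacts (default [1, 30]).
    n_init : number of SMACOF starts; the first is a deterministic classical-
        scaling warm start, the rest are seeded Gaussian inits. The embedding
        with lowest final stress wins.
    max_iter, tol : SMACOF iteration controls.
    random_state : seed for the random restarts.

    Attributes (after ``fit``)
    --------------------------
    embedding_ : (n, 3) bead coordinates.
    stress_ : final weighted stress of the selected embedding.
    wish_distances_ : the WishDistanceMatrix that was embedded.
    """

    def __init__(
        self,
        lo: float = RESCALE_LO,
        hi: float = RESCALE_HI,
        n_init: int = 4,
        max_iter: int = 300,
        tol: float = 1e-10,
        random_state: int = 0,
    ):
        self.lo = lo
        self.hi = hi
        self.n_init = n_init
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, X, y=None):
        """X: a ContactMatrix, a WishDistanceMatrix, or a raw array of
        contacts with NaN marking missing entries."""
        if isinstance(X, WishDistanceMatrix):
            w = X
        else:
            if isinstance(X, ContactMatrix):
                m = X
            else:
                arr = np.asarray(X, dtype=float)
                mask = ~np.isfinite(arr)
                np.fill_diagonal(mask, True)
                vals = np.where(mask, 0.0, arr)
                n = arr.shape[0]
                m = ContactMatrix(
                    values=vals,
                    mask=mask,
                    bin_size=1,
                    origin=GenomicInterval("chrX", 0, n, id="X"),
                )
            m = rescale_contacts(m, self.lo, self.hi)
            w = contacts_to_wish_distances(m)
        self.wish_distances_ = w
        self.embedding_, self.stress_ = _embed_mds_arrays(
            w.values,
            w.mask,
            seed=self.random_state,
            n_init=self.n_init,
            max_iter=self.max_iter,
            tol=self.tol,
        )
        return self

    def fit_transform(self, X, y=None):
        return self.fit(X).embedding_


def _embed_mds_arrays(
    delta: np.ndarray,
    mask: np.ndarray,
    seed: int,
    n_init: int,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, float]:
    n = delta.shape[0]
    if n < 3:
        raise DomainError("need at least 3 beads to embed")
    _check_connected(mask)
    weights = (~mask).astype(float)
    np.fill_diagonal(weights, 0.0)
    rng = np.random.default_rng(seed)
    best: tuple[np.ndarray, float] | None = None
    scale = delta[weights > 0].mean() if np.any(weights > 0) else 1.0
    for trial in range(max(1, n_init)):
        if trial == 0:
            init = _classical_mds_init(delta, mask)
        else:
            init = rng.standard_normal((n, 3)) * scale
        x, stress = smacof_weighted(delta, weights, init, max_iter=max_iter, tol=tol)
        if best is None or stress < best[1] - 1e-15:
            best = (x, stress)
    x, stress = best
    return x - x.mean(axis=0), stress


def embed_mds(
    w: WishDistanceMatrix,
    seed: int = 0,
    n_init: int = 4,
    max_iter: int = 300,
    tol: float = 1e-10,
    origin: GenomicInterval | None = None,
) -> Structure3D:
    """Best-of-``n_init`` weighted-SMACOF 3D embedding of the wish distances."""
    coords, _ = _embed_mds_arrays(
        w.values, w.mask, seed=seed, n_init=n_init, max_iter=max_iter, tol=tol
    )
    return Structure3D(coords=coords, source="mds", origin=origin)


def embed_tsne_selected(
    w: WishDistanceMatrix,
    reference: Structure3D,
    perplexities=DEFAULT_PERPLEXITIES,
    learning_rates=DEFAULT_LEARNING_RATES,
    seed: int = 0,
) -> tuple[Structure3D, pd.DataFrame]:
    """t-SNE embedding grid with minimum-RMSD selection against ``reference``.

    One 3-component t-SNE run per (perplexity, learning_rate) pair on the
    precomputed wish distances; each candidate is rigidly superposed onto the
    reference (rotation, translation, reflection allowed; no scaling) and the
    candidate with minimum RMSD is returned with the full selection report.
    """
    n = w.n
    perplexities = [p for p in perplexities]
    learning_rates = [r for r in learning_rates]
    if not perplexities or not learning_rates:
        raise DomainError("parameter grid must be non-empty")
    if any(p >= n for p in perplexities):
        raise DomainError(f"perplexity must be < number of beads ({n})")
    if reference.n_beads != n:
        raise DomainError("reference bead count must match the wish distance matrix")
    dist = w.values.copy()
    off = ~np.eye(n, dtype=bool)
    if (w.mask & off).any():
        # t-SNE needs a complete dissimilarity; fill with the mean observed
        fill = dist[off & ~w.mask].mean()
        dist[w.mask & off] = fill
    rows = []
    candidates = []
    for p in perplexities:
        for lr in learning_rates:
            ts = TSNE(
                n_components=3,
                metric="precomputed",
                perplexity=p,
                learning_rate=lr,
                init="random",
                random_state=seed,
                method="exact",
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                coords = ts.fit_transform(dist)
            res = kabsch_superpose(coords, reference.coords, allow_reflection=True)
            rows.append({"perplexity": p, "learning_rate": lr, "rmsd": res.rmsd})
            candidates.append(coords)
    report = pd.DataFrame(rows)
    best = int(report["rmsd"].idxmin())
    structure = Structure3D(
        coords=candidates[best], source="tsne", origin=reference.origin
    )
    return structure, report


def radius_of_gyration(s: Structure3D | np.ndarray) -> float:
    """Root-mean-square bead distance to the centroid."""
    coords = s.coords if isinstance(s, Structure3D) else np.asarray(s, dtype=float)
    if coords.shape[0] < 2:
        raise DomainError("radius of gyration needs at least 2 beads")
    centered = coords - coords.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum(centered**2, axis=1))))


def exponent_parameter(m: ContactMatrix) -> float:
    """Log-log slope of mean observed contact versus bin separation.

    P(s) is the mean observed contact at separation s = 1..n-1; the slope is
    the unweighted least-squares fit of log P(s) on log s over separations
    with observed data and P(s) > 0.
    """
    n = m.n_bins
    if n < 5:
        raise InsufficientDataError("need at least 5 bins")
    seps, means = [], []
    for s in range(1, n):
        vals = np.diagonal(m.values, offset=s)
        missing = np.diagonal(m.mask, offset=s)
        obs = vals[~missing]
        if obs.size:
            p = obs.mean()
            if p > 0:
                seps.append(s)
                means.append(p)
    if len(seps) < 3:
        raise InsufficientDataError(
            f"only {len(seps)} usable separations; need at least 3"
        )
    slope, _ = np.polyfit(np.log(np.asarray(seps)), np.log(np.asarray(means)), 1)
    return float(slope)


def evaluate_consistency(stats: list[StructureStats]) -> tuple[float, float]:
    """Pearson and Spearman correlation between exponents and Rg over TADs."""
    if len(stats) < 3:
        raise InsufficientDataError("need at least 3 TADs")
    exps = np.array([s.exponent for s in stats])
    rgs = np.array([s.rg for s in stats])
    if np.ptp(exps) == 0 or np.ptp(rgs) == 0:
        raise UndefinedCorrelationError("zero variance in exponent or Rg vector")
    return float(pearsonr(exps, rgs)[0]), float(spearmanr(exps, rgs)[0])


def reconstruct_tad(
    m: ContactMatrix,
    seed: int = 0,
    lo: float = RESCALE_LO,
    hi: float = RESCALE_HI,
    n_init: int = 4,
) -> tuple[Structure3D, StructureStats]:
    """Full per-TAD chain: rescale -> wish distances -> MDS -> statistics.

    The exponent is fitted on the original (pre-rescale) contacts; the Rg on
    the MDS embedding.
    """
    exponent = exponent_parameter(m)
    est = WishDistanceMDS(lo=lo, hi=hi, n_init=n_init, random_state=seed)
    coords = est.fit_transform(m)
    structure = Structure3D(coords=coords, source="mds", origin=m.origin)
    stats = StructureStats(
        tad_id=m.origin.id, exponent=exponent, rg=radius_of_gyration(structure)
    )
    return structure, stats
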