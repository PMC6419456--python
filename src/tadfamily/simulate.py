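"""Synthetic Hi-C cohorts with planted ground truth.

The generators emulate the pipeline's real inputs at desk scale: symmetric
contact matrices with power-law distance decay ``E[c_ij] = scale * |i-j|^alpha``
(alpha < 0, steeper = faster decay = more extended chromatin), chromatin-state
segmentations drawn from per-region state profiles over an S-state model, and
cohorts in which every TAD carries one planted structural class (its decay
exponent) and one planted functional class (its state profile), so that every
downstream stage can be checked against known truth.

Noise is multiplicative log-normal, mean-corrected so the expected contact is
exactly the power law: ``c = E[c] * exp(sd*Z - sd**2/2)`` with ``Z ~ N(0,1)``.
A positive noise model is required because the wish-distance conversion
``d = (1/c)^(1/3)`` needs ``c > 0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError
from .types import ContactMatrix, GenomicInterval, Segmentation, Structure3D

DEFAULT_BIN_SIZE = 50_000
#: 25-state chromatin model labels (Roadmap-style numbering).
DEFAULT_STATE_LABELS = [f"state{i}" for i in range(1, 26)]


def gen_contact_matrix(
    n_bins: int,
    alpha: float,
    scale: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    bin_size: int = DEFAULT_BIN_SIZE,
    chrom: str = "chrSim",
    start: int = 0,
    tad_id: str = "",
) -> ContactMatrix:
    """Power-law decay contact matrix: E[c(i,j)] = scale * |i-j|^alpha, i != j.

    The diagonal is masked (self-contacts are never generated); the matrix is
    symmetric by construction and deterministic given ``seed``.
    """
    if n_bins < 5:
        raise DomainError("n_bins must be >= 5")
    if alpha > 0:
        raise DomainError(f"decay exponent must be <= 0, got {alpha}")
    if scale <= 0:
        raise DomainError("scale must be positive")
    rng = np.random.default_rng(seed)
    sep = np.abs(np.subtract.outer(np.arange(n_bins), np.arange(n_bins))).astype(float)
    np.fill_diagonal(sep, 1.0)  # |i-j| floored at 1; diagonal masked anyway
    values = scale * sep**alpha
    if noise_sd > 0:
        z = rng.standard_normal((n_bins, n_bins))
        z = np.triu(z, 1)
        z = z + z.T  # symmetric noise field
        values = values * np.exp(noise_sd * z - noise_sd**2 / 2.0)
    mask = np.eye(n_bins, dtype=bool)
    values = values.copy()
    values[mask] = 0.0
    origin = GenomicInterval(
        chrom, start, start + n_bins * bin_size, id=tad_id or f"{chrom}:{start}"
    )
    return ContactMatrix(values=values, mask=mask, bin_size=bin_size, origin=origin)


def gen_structure(kind: str, n_beads: int, seed: int = 0) -> Structure3D:
    """Oracle geometries for embedding tests.

    helix: unit radius, 10 beads per turn, pitch (rise per turn) 0.5;
    segment: collinear beads spaced 1.0; random_walk: seeded unit steps.
    """
    if n_beads < 3:
        raise DomainError("n_beads must be >= 3")
    if kind == "segment":
        coords = np.zeros((n_beads, 3))
        coords[:, 0] = np.arange(n_beads, dtype=float)
    elif kind == "helix":
        t = np.arange(n_beads, dtype=float)
        theta = 2.0 * np.pi * t / 10.0
        coords = np.column_stack(
            [np.cos(theta), np.sin(theta), 0.5 * t / 10.0]
        )
    elif kind == "random_walk":
        rng = np.random.default_rng(seed)
        steps = rng.standard_normal((n_beads - 1, 3))
        steps /= np.linalg.norm(steps, axis=1, keepdims=True)
        coords = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
    else:
        raise DomainError(f"unknown structure kind {kind!r}")
    return Structure3D(coords=coords, source=f"gen:{kind}")


def gen_segmentation(
    chrom_length: int,
    state_labels: list[str],
    region_profiles: list[tuple[GenomicInterval, np.ndarray]],
    background: np.ndarray,
    resolution: int = 200,
    seed: int = 0,
    chrom: str = "chrSim",
) -> Segmentation:
    """Tile [0, chrom_length) at ``resolution``; draw each tile's state from
    the profile of the region containing its start, else from ``background``."""
    s = len(state_labels)
    background = np.asarray(background, dtype=float)
    profiles = [(iv, np.asarray(p, dtype=float)) for iv, p in region_profiles]
    for p in [background] + [p for _, p in profiles]:
        if p.shape != (s,):
            raise DomainError(f"profile length {p.shape} != number of states {s}")
        if abs(p.sum() - 1.0) > 1e-9 or np.any(p < 0):
            raise DomainError("profiles must be probability vectors summing to 1")
    rng = np.random.default_rng(seed)
    starts = np.arange(0, chrom_length, resolution)
    ends = np.minimum(starts + resolution, chrom_length)
    which = np.full(starts.shape[0], -1)
    for r, (iv, _) in enumerate(profiles):
        inside = (starts >= iv.start) & (starts < iv.end) & (iv.chrom == chrom)
        which[inside] = r
    # draw all tiles at once via inverse-CDF on stacked profiles
    all_profiles = np.vstack([background] + [p for _, p in profiles])
    cdfs = np.cumsum(all_profiles, axis=1)
    u = rng.random(starts.shape[0])
    states = np.empty(starts.shape[0], dtype=np.int64)
    for r in range(all_profiles.shape[0]):
        sel = which == r - 1
        if sel.any():
            states[sel] = np.searchsorted(cdfs[r], u[sel], side="right")
    states = np.clip(states, 0, s - 1)
    records = [
        (
            GenomicInterval(chrom, int(a), int(b), id=f"tile{k}"),
            state_labels[int(st)],
        )
        for k, (a, b, st) in enumerate(zip(starts, ends, states))
    ]
    return Segmentation(records=records, state_labels=list(state_labels))


def _default_state_profiles(s: int = 25) -> list[np.ndarray]:
    """Three archetypal state-class profiles over an s-state model:
    active (mass on promoter/transcription states), repressed (mass on
    heterochromatin/polycomb states), quiescent (mass on the last state) —
    each mixed with a uniform floor so every state can occur."""
    floor = np.full(s, 0.2 / s)
    active = floor.copy()
    active[0 : min(8, s)] += 0.8 / min(8, s)
    repressed = floor.copy()
    lo, hi = max(0, s - 5), s - 1
    repressed[lo:hi] += 0.8 / max(1, hi - lo)
    quiescent = floor.copy()
    quiescent[s - 1] += 0.8
    return [active / active.sum(), repressed / repressed.sum(), quiescent / quiescent.sum()]


@dataclass
class CohortSpec:
    """Study conditions for a synthetic cohort.

    Defaults model 1.25-Mb TADs at 50 kb resolution (25 bins) with three
    planted structural classes (decay exponents -0.5 / -1.0 / -1.5 spanning
    compact to extended chromatin) and three planted chromatin-state classes
    (active / repressed / quiescent profiles) under moderate measurement
    noise. Bin count is held fixed by default: the per-TAD contact rescale
    makes local bead geometry depend on chain length, so varying TAD size
    plants a second, unintended structural factor that confounds the decay
    classes; a controlled harness keeps the planted factor identifiable.
    Pass a wider ``bins_range`` to study the length effect explicitly.
    """

    n_tads: int = 30
    bins_range: tuple[int, int] = (25, 25)
    struct_classes: tuple[float, ...] = (-0.5, -1.0, -1.5)
    state_classes: list[np.ndarray] = field(default_factory=_default_state_profiles)
    noise_sd: float = 0.1
    seed: int = 0
    bin_size: int = DEFAULT_BIN_SIZE
    state_labels: list[str] = field(default_factory=lambda: list(DEFAULT_STATE_LABELS))
    seg_resolution: int = 200
    gap_bins: int = 2

    def __post_init__(self):
        if self.n_tads < 1:
            raise DomainError("n_tads must be >= 1")
        if self.bins_range[0] < 5 or self.bins_range[0] > self.bins_range[1]:
            raise DomainError("bins_range must satisfy 5 <= min <= max")
        s = len(self.state_labels)
        for p in self.state_classes:
            if np.asarray(p).shape != (s,):
                raise DomainError("every state profile must have one entry per state")


@dataclass
class Cohort:
    matrices: list[ContactMatrix]
    tads: list[GenomicInterval]
    segmentation: Segmentation
    true_struct_labels: np.ndarray
    true_state_labels: np.ndarray
    spec: CohortSpec


def gen_cohort(spec: CohortSpec) -> Cohort:
    """Generate a full cohort with planted structural and functional classes.

    Class assignment is round-robin over the (struct, state) pair grid —
    structural class cycles fastest — so the two planted labelings are
    balanced and mutually independent even for tiny cohorts.
    """
    rng = np.random.default_rng(spec.seed)
    n_s, n_f = len(spec.struct_classes), len(spec.state_classes)
    struct_labels = np.array([i % n_s for i in range(spec.n_tads)])
    state_labels = np.array([(i // n_s) % n_f for i in range(spec.n_tads)])

    matrices: list[ContactMatrix] = []
    tads: list[GenomicInterval] = []
    pos = 0
    for i in range(spec.n_tads):
        n_bins = int(rng.integers(spec.bins_range[0], spec.bins_range[1] + 1))
        tad_id = f"TAD{i:03d}"
        m = gen_contact_matrix(
            n_bins=n_bins,
            alpha=spec.struct_classes[struct_labels[i]],
            scale=1.0,
            noise_sd=spec.noise_sd,
            seed=int(rng.integers(0, 2**31 - 1)),
            bin_size=spec.bin_size,
            start=pos,
            tad_id=tad_id,
        )
        iv = GenomicInterval(
            m.origin.chrom, m.origin.start, m.origin.end, id=tad_id
        )
        matrices.append(m)
        tads.append(iv)
        pos = m.origin.end + spec.gap_bins * spec.bin_size

    region_profiles = [
        (tads[i], spec.state_classes[state_labels[i]]) for i in range(spec.n_tads)
    ]
    background = np.full(len(spec.state_labels), 1.0 / len(spec.state_labels))
    segmentation = gen_segmentation(
        chrom_length=pos,
        state_labels=spec.state_labels,
        region_profiles=region_profiles,
        background=background,
        resolution=spec.seg_resolution,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    return Cohort(
        matrices=matrices,
        tads=tads,
        segmentation=segmentation,
        true_struct_labels=struct_labels,
        true_state_labels=state_labels,
        spec=spec,
    )
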