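"""Core value types shared across the pipeline.

Coordinates follow the BED convention throughout: 0-based, half-open
[start, end). Bin index ``b`` of a matrix with origin ``o`` covers
``[o.start + b*bin_size, o.start + (b+1)*bin_size)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import DomainError, FormatError

VALID_STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval with an identifier and optional strand."""

    chrom: str
    start: int
    end: int
    id: str = ""
    strand: str = "."

    def __post_init__(self):
        if self.start < 0:
            raise DomainError(f"start must be >= 0, got {self.start}")
        if self.start >= self.end:
            raise DomainError(
                f"start must be < end, got [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in VALID_STRANDS:
            raise DomainError(f"strand must be one of {VALID_STRANDS}, got {self.strand!r}")
        if not self.id:
            object.__setattr__(self, "id", f"{self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


def _check_square(values: np.ndarray, name: str) -> int:
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise FormatError(f"{name} must be square, got shape {values.shape}")
    return values.shape[0]


@dataclass
class ContactMatrix:
    """A symmetric non-negative Hi-C contact matrix over one genomic region.

    ``mask`` flags missing entries (True = missing). Observed zeros are kept
    as zeros; only NA tokens / unlisted COO pairs are missing. The diagonal is
    conventionally masked: a bin's self-distance is 0 by definition and never
    derived from its self-contact.
    """

    values: np.ndarray
    mask: np.ndarray
    bin_size: int
    origin: GenomicInterval

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        n = _check_square(self.values, "contact matrix")
        if self.mask.shape != self.values.shape:
            raise FormatError("mask shape must match values shape")
        if self.bin_size <= 0:
            raise DomainError("bin_size must be positive")
        if self.origin.length != n * self.bin_size:
            raise FormatError(
                f"origin spans {self.origin.length} bp but matrix covers "
                f"{n} x {self.bin_size} bp"
            )
        if not np.array_equal(self.mask, self.mask.T):
            raise FormatError("mask must be symmetric")
        both = ~self.mask & ~self.mask.T
        if not np.allclose(
            self.values[both], self.values.T[both], atol=1e-9, equal_nan=True
        ):
            raise FormatError("contact matrix must be symmetric where observed")
        obs = self.values[~self.mask]
        if obs.size and (np.any(~np.isfinite(obs)) or np.any(obs < 0)):
            raise DomainError("observed contacts must be finite and >= 0")

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    def observed_offdiag(self) -> np.ndarray:
        """Observed values strictly off the diagonal."""
        off = ~np.eye(self.n_bins, dtype=bool)
        return self.values[off & ~self.mask]


@dataclass
class Structure3D:
    """An ordered chain of 3D beads, one per genomic bin."""

    coords: np.ndarray
    source: str = ""
    origin: GenomicInterval | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise FormatError(f"coords must be (n, 3), got {self.coords.shape}")
        if self.coords.shape[0] < 3:
            raise DomainError("a structure needs at least 3 beads")
        if not np.all(np.isfinite(self.coords)):
            raise DomainError("coordinates must be finite")

    @property
    def n_beads(self) -> int:
        return self.coords.shape[0]


@dataclass
class Segmentation:
    """A chromatin-state segmentation: labelled, non-overlapping intervals.

    Per-chromosome coordinate/state arrays and genome-wide per-state base
    counts are cached on first use; both are invalidated by constructing a
    new Segmentation rather than by mutation.
    """

    records: list[tuple[GenomicInterval, str]]
    state_labels: list[str]

    def __post_init__(self):
        label_set = set(self.state_labels)
        if len(label_set) != len(self.state_labels):
            raise FormatError("state_labels must be unique")
        for iv, lab in self.records:
            if lab not in label_set:
                raise DomainError(f"unknown state label {lab!r}")
        self.records = sorted(self.records, key=lambda r: (r[0].chrom, r[0].start))
        prev: GenomicInterval | None = None
        for iv, _ in self.records:
            if prev is not None and iv.chrom == prev.chrom and iv.start < prev.end:
                raise FormatError(
                    f"overlapping records on {iv.chrom}: "
                    f"[{prev.start},{prev.end}) and [{iv.start},{iv.end})"
                )
            prev = iv
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] | None = None
        self._genome_state_bp: np.ndarray | None = None

    @property
    def n_states(self) -> int:
        return len(self.state_labels)

    def _index(self) -> None:
        if self._by_chrom is not None:
            return
        label_to_idx = {lab: i for i, lab in enumerate(self.state_labels)}
        by: dict[str, list[tuple[int, int, int]]] = {}
        for iv, lab in self.records:
            by.setdefault(iv.chrom, []).append((iv.start, iv.end, label_to_idx[lab]))
        self._by_chrom = {}
        total = np.zeros(self.n_states)
        for chrom, rows in by.items():
            arr = np.asarray(rows, dtype=np.int64)
            starts, ends, states = arr[:, 0], arr[:, 1], arr[:, 2]
            self._by_chrom[chrom] = (starts, ends, states)
            total += np.bincount(states, weights=ends - starts, minlength=self.n_states)
        self._genome_state_bp = total

    def genome_state_bp(self) -> np.ndarray:
        """Bases covered by each state genome-wide, in state_labels order."""
        self._index()
        return self._genome_state_bp.copy()

    def overlap_state_bp(self, region: GenomicInterval) -> np.ndarray:
        """Bases of each state overlapping ``region``."""
        self._index()
        out = np.zeros(self.n_states)
        entry = self._by_chrom.get(region.chrom)
        if entry is None:
            return out
        starts, ends, states = entry
        ov = np.minimum(ends, region.end) - np.maximum(starts, region.start)
        ov = np.clip(ov, 0, None)
        hit = ov > 0
        if hit.any():
            out += np.bincount(
                states[hit], weights=ov[hit].astype(float), minlength=self.n_states
            )
        return out

    def covered_bp(self) -> int:
        return int(sum(iv.length for iv, _ in self.records))


@dataclass
class FoldEnrichmentVector:
    """Per-state fold enrichment of one TAD (or one pooled region set)."""

    values: np.ndarray
    tad_id: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise FormatError("fold enrichment must be a 1-D vector")
        if np.any(~np.isfinite(self.values)) or np.any(self.values < 0):
            raise DomainError("fold enrichments must be finite and >= 0")

    def __len__(self) -> int:
        return self.values.shape[0]


@dataclass
class SimilarityMatrix:
    """Symmetric pairwise TAD similarity with unit diagonal."""

    values: np.ndarray
    kind: str
    tad_ids: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        m = _check_square(self.values, "similarity matrix")
        if self.kind not in ("structural", "functional"):
            raise DomainError(f"kind must be structural or functional, got {self.kind!r}")
        if len(self.tad_ids) != m:
            raise FormatError("tad_ids length must match matrix size")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise FormatError("similarity matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 1.0, atol=1e-9):
            raise FormatError("similarity diagonal must be 1")
        if np.any(self.values < -1e-12) or np.any(self.values > 1 + 1e-9):
            raise DomainError("similarities must lie in [0, 1]")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class ClusterAssignment:
    """A partition of TAD ids into clusters labelled 1..k (largest first)."""

    labels: dict[str, int]
    k: int
    kind: str

    def __post_init__(self):
        if self.kind not in ("structural", "functional"):
            raise DomainError(f"kind must be structural or functional, got {self.kind!r}")
        got = set(self.labels.values())
        if got != set(range(1, self.k + 1)):
            raise DomainError(
                f"cluster labels must cover 1..{self.k} with no empty cluster, got {sorted(got)}"
            )

    def members(self, cluster: int) -> list[str]:
        return [t for t, c in self.labels.items() if c == cluster]

    def sizes(self) -> list[int]:
        out = [0] * self.k
        for c in self.labels.values():
            out[c - 1] += 1
        return out


@dataclass
class Family:
    """One TAD family: the intersection of a structural and a functional cluster."""

    struct_cluster: int
    state_cluster: int
    members: list[str]
    score: float | None = None
    avg_heatmap: np.ndarray | None = None


@dataclass
class FamilyTable:
    families: list[Family]

    def __iter__(self):
        return iter(self.families)

    def __len__(self):
        return len(self.families)

    def all_members(self) -> list[str]:
        out: list[str] = []
        for f in self.families:
            out.extend(f.members)
        return out
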