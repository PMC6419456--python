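"""Readers and writers for all on-disk formats.

Supported formats are deliberately plain text: dense whitespace-separated
matrices, COO triplets ("i<TAB>j<TAB>value", 0-based bin indices), BED3/4/6
intervals, BED4 chromatin-state segmentations, xyz / PDB-like structure
files, and TSV result tables.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import BoundsError, DomainError, FormatError, RecordError
from .types import (
    ContactMatrix,
    GenomicInterval,
    Segmentation,
    SimilarityMatrix,
    Structure3D,
)

_NA_TOKENS = {"na", "nan", "n/a", "."}


def _is_na(token: str) -> bool:
    return token.lower() in _NA_TOKENS


def read_contact_matrix(
    path, format: str, bin_size: int, origin: GenomicInterval
) -> ContactMatrix:
    """Read a contact matrix from ``path`` in ``dense`` or ``coo`` format.

    Dense: an n x n whitespace-separated grid; NA/nan tokens become masked
    entries, everything else must be a non-negative number. COO: lines
    "i j value"; unlisted pairs are missing, each listed (i, j) also fills
    (j, i). The diagonal is always masked (self-distance is 0 by definition).
    """
    n = origin.length // bin_size
    if origin.length != n * bin_size:
        raise FormatError("bin_size must divide the origin length")
    if format == "dense":
        values, mask = _read_dense(path, n)
    elif format == "coo":
        values, mask = _read_coo(path, n)
    else:
        raise DomainError(f"unknown contact matrix format {format!r}")
    np.fill_diagonal(mask, True)
    values[mask] = 0.0
    # symmetrise tiny asymmetries from text round-trips before validation
    both = ~mask
    values[both] = ((values + values.T) / 2.0)[both]
    return ContactMatrix(values=values, mask=mask, bin_size=bin_size, origin=origin)


def _read_dense(path, n: int) -> tuple[np.ndarray, np.ndarray]:
    rows: list[list[str]] = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                rows.append(line.split())
    if len(rows) != n or any(len(r) != n for r in rows):
        shape = (len(rows), len(rows[0]) if rows else 0)
        raise FormatError(f"dense matrix must be {n} x {n}, got {shape[0]} x {shape[1]}")
    values = np.zeros((n, n))
    mask = np.zeros((n, n), dtype=bool)
    for i, row in enumerate(rows):
        for j, tok in enumerate(row):
            if _is_na(tok):
                mask[i, j] = True
            else:
                v = float(tok)
                if v < 0:
                    raise DomainError(f"negative contact {v} at ({i}, {j})")
                values[i, j] = v
    return values, mask


def _read_coo(path, n: int) -> tuple[np.ndarray, np.ndarray]:
    values = np.zeros((n, n))
    mask = np.ones((n, n), dtype=bool)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 3:
                raise RecordError("COO line must have 3 fields", line=lineno)
            i, j, tok = int(parts[0]), int(parts[1]), parts[2]
            if i < 0 or j < 0 or i >= n or j >= n:
                raise BoundsError(f"line {lineno}: bin index ({i}, {j}) outside 0..{n - 1}")
            if _is_na(tok):
                continue
            v = float(tok)
            if v < 0:
                raise DomainError(f"line {lineno}: negative contact {v}")
            values[i, j] = values[j, i] = v
            mask[i, j] = mask[j, i] = False
    return values, mask


def write_contact_matrix(m: ContactMatrix, path, format: str = "coo") -> None:
    """Write observed entries as COO triplets, or the full grid as dense TSV."""
    if format == "coo":
        with open(path, "w") as fh:
            n = m.n_bins
            for i in range(n):
                for j in range(i, n):
                    if not m.mask[i, j]:
                        fh.write(f"{i}\t{j}\t{m.values[i, j]:.10g}\n")
    elif format == "dense":
        with open(path, "w") as fh:
            for i in range(m.n_bins):
                toks = [
                    "NA" if m.mask[i, j] else f"{m.values[i, j]:.10g}"
                    for j in range(m.n_bins)
                ]
                fh.write("\t".join(toks) + "\n")
    else:
        raise DomainError(f"unknown contact matrix format {format!r}")


def read_intervals(path) -> list[GenomicInterval]:
    """Read BED3+ intervals (optional name col 4, strand col 6), in file order."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise RecordError("BED needs at least 3 columns", line=lineno)
            chrom = cols[0]
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise RecordError(f"bad coordinates: {exc}", line=lineno) from exc
            if start < 0 or start >= end:
                raise RecordError(
                    f"invalid interval [{start}, {end}) on {chrom}", line=lineno
                )
            name = cols[3] if len(cols) > 3 and cols[3] not in ("", ".") else ""
            strand = cols[5] if len(cols) > 5 and cols[5] in ("+", "-") else "."
            out.append(GenomicInterval(chrom, start, end, id=name, strand=strand))
    return out


def write_intervals(intervals: list[GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.id}\t0\t{iv.strand}\n")


def read_segmentation(path, state_labels: list[str]) -> Segmentation:
    """Read a BED4 segmentation (col 4 = state label) into a Segmentation."""
    label_set = set(state_labels)
    records: list[tuple[GenomicInterval, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 4:
                raise RecordError("segmentation needs 4 columns", line=lineno)
            chrom, lab = cols[0], cols[3]
            start, end = int(cols[1]), int(cols[2])
            if start < 0 or start >= end:
                raise RecordError(
                    f"invalid interval [{start}, {end}) on {chrom}", line=lineno
                )
            if lab not in label_set:
                raise DomainError(f"line {lineno}: unknown state label {lab!r}")
            records.append((GenomicInterval(chrom, start, end, id=f"seg{lineno}"), lab))
    return Segmentation(records=records, state_labels=list(state_labels))


def write_segmentation(seg: Segmentation, path) -> None:
    with open(path, "w") as fh:
        for iv, lab in seg.records:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{lab}\n")


def write_structure(s: Structure3D, path, format: str = "xyz") -> None:
    """Write a structure as xyz or PDB-like ATOM records (3 decimals)."""
    if not np.all(np.isfinite(s.coords)):
        raise DomainError("structure contains non-finite coordinates")
    if format == "xyz":
        with open(path, "w") as fh:
            fh.write(f"{s.n_beads}\n")
            comment = s.source or "tadfamily structure"
            if s.origin is not None:
                comment += f" {s.origin.chrom}:{s.origin.start}-{s.origin.end}"
            fh.write(comment + "\n")
            for x, y, z in s.coords:
                fh.write(f"C {x:.3f} {y:.3f} {z:.3f}\n")
    elif format == "pdb_like":
        with open(path, "w") as fh:
            for i, (x, y, z) in enumerate(s.coords, start=1):
                fh.write(
                    f"ATOM  {i:5d}  CA  BED A{i:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n"
                )
            for i in range(1, s.n_beads):
                fh.write(f"CONECT{i:5d}{i + 1:5d}\n")
            fh.write("END\n")
    else:
        raise DomainError(f"unknown structure format {format!r}")


def read_structure(path, format: str = "xyz") -> Structure3D:
    coords: list[list[float]] = []
    with open(path) as fh:
        if format == "xyz":
            lines = fh.read().splitlines()
            n = int(lines[0])
            for line in lines[2 : 2 + n]:
                parts = line.split()
                coords.append([float(parts[1]), float(parts[2]), float(parts[3])])
        elif format == "pdb_like":
            for line in fh:
                if line.startswith("ATOM"):
                    coords.append(
                        [float(line[30:38]), float(line[38:46]), float(line[46:54])]
                    )
        else:
            raise DomainError(f"unknown structure format {format!r}")
    return Structure3D(coords=np.asarray(coords), source=f"read:{format}")


def write_similarity_matrix(sim: SimilarityMatrix, path) -> None:
    """TSV with tad ids as both header row and first column."""
    df = pd.DataFrame(sim.values, index=sim.tad_ids, columns=sim.tad_ids)
    df.to_csv(path, sep="\t", index_label="tad_id", float_format="%.10g")


def read_similarity_matrix(path, kind: str) -> SimilarityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise FormatError("similarity matrix row and column ids must match")
    return SimilarityMatrix(
        values=df.to_numpy(dtype=float), kind=kind, tad_ids=[str(c) for c in df.columns]
    )


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
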