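"""End-to-end pipeline: cohort directory -> structures, similarities,
clusters, families, heatmaps, manifest.

A single global seed is fanned out to per-stage seeds (stage-name hashed via
CRC32) so any stage can be rerun in isolation with the same randomness.
Re-running with an identical config reproduces all outputs byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .chromstate import fold_enrichment, functional_similarity_matrix
from .errors import DomainError, TadFamilyError
from .families import (
    average_family_heatmap,
    define_families,
    overlap_counts,
    overlap_enrichment,
    score_families,
    spectral_cluster,
)
from .io import (
    read_contact_matrix,
    read_intervals,
    read_segmentation,
    write_similarity_matrix,
    write_structure,
    write_table,
)
from .reconstruct import reconstruct_tad
from .structsim import structural_similarity_matrix
from .types import ContactMatrix, GenomicInterval


def stage_seed(seed: int, stage: str) -> int:
    """Derived per-stage seed, deterministic in (seed, stage name)."""
    return (seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class PipelineConfig:
    matrices_dir: str
    tads: str
    segmentation: str
    out_dir: str
    bin_size: int = 50_000
    matrix_format: str = "coo"
    state_labels: list[str] | None = None
    genome_size: int | None = None
    lo: float = 1.0
    hi: float = 30.0
    method: str = "mds"
    k_struct: int = 3
    k_func: int = 3
    seed: int = 0
    n_init: int = 4
    heatmaps: bool = True

    def __post_init__(self):
        if self.lo >= self.hi:
            raise DomainError("rescale range needs lo < hi")
        if self.k_struct < 2 or self.k_func < 2:
            raise DomainError("cluster counts must be >= 2")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def config_hash(self) -> str:
        canon = json.dumps(
            {k: v for k, v in self.__dict__.items()}, sort_keys=True, default=str
        )
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _infer_state_labels(path) -> list[str]:
    labels = set()
    with open(path) as fh:
        for line in fh:
            cols = line.rstrip("\n").split("\t")
            if len(cols) >= 4:
                labels.add(cols[3])
    return sorted(labels)


def _assemble_chrom_matrices(
    tads: list[GenomicInterval],
    matrices: dict[str, ContactMatrix],
    bin_size: int,
) -> dict[str, ContactMatrix]:
    """Block-diagonal whole-chromosome matrices from per-TAD matrices.

    Bins outside TAD blocks are missing; flank extension during heatmap
    extraction then simply finds no observations there.
    """
    out: dict[str, ContactMatrix] = {}
    for chrom in sorted({t.chrom for t in tads}):
        chrom_tads = [t for t in tads if t.chrom == chrom]
        n = max(t.end for t in chrom_tads) // bin_size
        values = np.zeros((n, n))
        mask = np.ones((n, n), dtype=bool)
        for t in chrom_tads:
            m = matrices[t.id]
            b0 = t.start // bin_size
            b1 = t.end // bin_size
            values[b0:b1, b0:b1] = m.values
            mask[b0:b1, b0:b1] = m.mask
        out[chrom] = ContactMatrix(
            values=values,
            mask=mask,
            bin_size=bin_size,
            origin=GenomicInterval(chrom, 0, n * bin_size, id=chrom),
        )
    return out


def run_pipeline(config: PipelineConfig, log=None) -> dict:
    """Execute reconstruct -> similarities -> clustering -> families.

    Returns the run manifest (also written to out_dir/manifest.json).
    """

    def say(msg: str) -> None:
        if log is not None:
            log(msg)

    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "structures").mkdir(exist_ok=True)
    manifest: dict = {
        "tadfamily_version": __version__,
        "numpy_version": np.__version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": {},
    }

    tads = read_intervals(config.tads)
    state_labels = config.state_labels or _infer_state_labels(config.segmentation)
    seg = read_segmentation(config.segmentation, state_labels)
    genome_size = config.genome_size
    if genome_size is None:
        ends: dict[str, int] = {}
        for iv, _ in seg.records:
            ends[iv.chrom] = max(ends.get(iv.chrom, 0), iv.end)
        genome_size = sum(ends.values())

    matrices: dict[str, ContactMatrix] = {}
    for t in tads:
        path = Path(config.matrices_dir) / f"{t.id}.{config.matrix_format}"
        matrices[t.id] = read_contact_matrix(
            path, format=config.matrix_format, bin_size=config.bin_size, origin=t
        )
    manifest["stages"]["load"] = {"n_tads": len(tads), "n_states": seg.n_states}
    say(f"loaded {len(tads)} TADs")

    stage = "reconstruct"
    try:
        structures, stats = [], []
        rec_seed = stage_seed(config.seed, stage)
        for t in tads:
            s, st = reconstruct_tad(
                matrices[t.id],
                seed=rec_seed,
                lo=config.lo,
                hi=config.hi,
                n_init=config.n_init,
            )
            structures.append(s)
            stats.append(st)
            write_structure(s, out / "structures" / f"{t.id}.xyz", format="xyz")
        stats_df = pd.DataFrame(
            {
                "tad_id": [s.tad_id for s in stats],
                "exponent": [s.exponent for s in stats],
                "rg": [s.rg for s in stats],
            }
        )
        write_table(stats_df.round(6), out / "stats.tsv")
        manifest["stages"][stage] = {"n_structures": len(structures)}
        say(f"reconstructed {len(structures)} structures")

        stage = "structsim"
        struct_sim = structural_similarity_matrix(structures)
        write_similarity_matrix(struct_sim, out / "struct_sim.tsv")
        manifest["stages"][stage] = {"shape": list(struct_sim.values.shape)}

        stage = "enrich"
        enrichments = [fold_enrichment(t, seg, genome_size) for t in tads]
        func_sim = functional_similarity_matrix(enrichments)
        write_similarity_matrix(func_sim, out / "func_sim.tsv")
        manifest["stages"][stage] = {"shape": list(func_sim.values.shape)}

        stage = "clustering"
        a = spectral_cluster(
            struct_sim, config.k_struct, seed=stage_seed(config.seed, "cluster_struct")
        )
        b = spectral_cluster(
            func_sim, config.k_func, seed=stage_seed(config.seed, "cluster_func")
        )
        assign = pd.DataFrame(
            {
                "tad_id": [t.id for t in tads],
                "struct_cluster": [a.labels[t.id] for t in tads],
                "func_cluster": [b.labels[t.id] for t in tads],
            }
        )
        write_table(assign, out / "assignments.tsv")
        manifest["stages"][stage] = {"k_struct": a.k, "k_func": b.k}

        stage = "families"
        counts = overlap_counts(a, b)
        enr = overlap_enrichment(counts, a.sizes(), b.sizes())
        pd.DataFrame(
            counts,
            index=[f"func{i + 1}" for i in range(b.k)],
            columns=[f"struct{j + 1}" for j in range(a.k)],
        ).to_csv(out / "counts.tsv", sep="\t", index_label="cluster")
        pd.DataFrame(
            np.round(enr, 1),
            index=[f"func{i + 1}" for i in range(b.k)],
            columns=[f"struct{j + 1}" for j in range(a.k)],
        ).to_csv(out / "enrichment.tsv", sep="\t", index_label="cluster")
        table = define_families(a, b)
        tads_by_id = {t.id: t for t in tads}
        table = score_families(table, tads_by_id, seg, genome_size)
        if config.heatmaps:
            chrom_matrices = _assemble_chrom_matrices(tads, matrices, config.bin_size)
            for fam in table:
                fam.avg_heatmap = average_family_heatmap(
                    [tads_by_id[m] for m in fam.members], chrom_matrices
                )
        fam_rows = []
        for fid, fam in enumerate(table, start=1):
            for member in fam.members:
                fam_rows.append(
                    {
                        "family_id": fid,
                        "struct_cluster": fam.struct_cluster,
                        "state_cluster": fam.state_cluster,
                        "tad_id": member,
                        "score": round(fam.score, 6),
                    }
                )
            if fam.avg_heatmap is not None:
                np.savetxt(
                    out / f"heatmap_family{fid}.tsv",
                    fam.avg_heatmap,
                    delimiter="\t",
                    fmt="%.6g",
                )
        write_table(pd.DataFrame(fam_rows), out / "families.tsv")
        manifest["stages"][stage] = {"n_families": len(table)}
        say(f"{len(table)} families")
    except TadFamilyError as exc:
        offender = getattr(exc, "tad_id", None)
        raise TadFamilyError(
            f"pipeline failed at stage {stage!r}"
            + (f" (TAD {offender})" if offender else "")
            + f": {exc}"
        ) from exc

    manifest["elapsed_s"] = round(time.time() - t0, 3)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
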