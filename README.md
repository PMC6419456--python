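# tadfamily

Classify topologically associating domains (TADs) into **families** by
combining two views of each domain: the 3D shape of its chromatin, and the
chromatin-state (functional) profile of its DNA.

TADs are the structural and functional units of mammalian genomes, yet two
TADs with similar contact maps can carry very different regulatory content —
and vice versa. `tadfamily` implements the full pipeline that makes the two
views comparable and intersects them:

1. **3D reconstruction.** Each TAD's Hi-C contact submatrix `c` is linearly
   rescaled to `[1, 30]` (ignoring missing entries), converted to *wish
   distances* `d = (1/c)^(1/3)`, and embedded in three dimensions with
   metric multidimensional scaling (weighted SMACOF stress majorization;
   missing pairs get zero weight). A t-SNE alternative over a
   (perplexity, learning-rate) grid with minimum-RMSD selection against the
   MDS structure is included.
2. **Structural similarity.** Pairs of reconstructed bead chains are scored
   with a length-normalized **TM-score** in (0, 1], normalized by the
   smaller chain, with `d0(L) = max(0.5, 1.24·(L−15)^(1/3) − 1.8)` and
   reflection allowed.
3. **Functional similarity.** Per TAD, the **fold enrichment**
   `F_s = (in-TAD density of state s) / (genome-wide density of s)` is
   computed over an S-state chromatin segmentation (e.g. the Roadmap
   25-state model); two TADs' similarity is `|Pearson r|` between their
   enrichment vectors.
4. **Clustering and families.** Both similarity matrices are spectrally
   clustered (precomputed affinity, seeded k-means, size-ordered labels).
   A **family** is the intersection of one structural and one functional
   cluster. Each family carries a depletion **score** (fraction of states
   with log2 F > 0), a 30×30 average contact heatmap (smaller members are
   extended into flanking bins, larger ones block-averaged), and overlap
   enrichment `1000 · n_overlap / (size_functional · size_structural)`
   between the parent clusters.

Per-TAD structure statistics (fitted contact-decay exponent, radius of
gyration), same-coordinate TAD matching across cell types, and gene/lncRNA
annotation mapping with catalog-ID unification round out the toolkit. A
seeded synthetic-cohort generator with planted structural and functional
classes makes every stage testable without external downloads.

## Worked example

```python
import numpy as np
from tadfamily import (
    CohortSpec, gen_cohort, reconstruct_tad, structural_similarity_matrix,
    fold_enrichment, functional_similarity_matrix, spectral_cluster,
    define_families, evaluate_consistency,
)

cohort = gen_cohort(CohortSpec(n_tads=12, noise_sd=0.05, seed=0))
genome = sum(iv.length for iv, _ in cohort.segmentation.records)

structures, stats = zip(*(reconstruct_tad(m, seed=1) for m in cohort.matrices))
pearson, spearman = evaluate_consistency(list(stats))
print(f"exponent vs Rg: pearson {pearson:.2f}, spearman {spearman:.2f}")

ssim = structural_similarity_matrix(list(structures))
fes = [fold_enrichment(t, cohort.segmentation, genome) for t in cohort.tads]
fsim = functional_similarity_matrix(fes)
families = define_families(
    spectral_cluster(ssim, 3, seed=0), spectral_cluster(fsim, 3, seed=0)
)
print(f"{len(families)} families, sizes {[len(f.members) for f in families]}")
```

Output:

```
exponent vs Rg: pearson -1.00, spearman -0.90
9 families, sizes [2, 2, 2, 1, 1, 1, 1, 1, 1]
```

The negative exponent–Rg correlation is the expected consistency check:
TADs whose contacts decay slowly with genomic distance (exponent near 0)
reconstruct as compact structures with small radius of gyration. The twelve
TADs carry 3 planted structural × 3 planted functional classes; the families
recover the 9 class intersections.

The same pipeline runs from the shell:

```bash
tadfamily simulate --n-tads 12 --seed 0 --out-dir cohort/
tadfamily run --config pipeline.yaml   # reconstruct → similarities → families
```

writing structures (xyz), per-TAD statistics, both similarity matrices,
cluster assignments, overlap counts/enrichment, the family table and the
per-family 30×30 heatmaps, plus a manifest with seeds and a config hash.

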