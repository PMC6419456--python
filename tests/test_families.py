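"""Clustering, overlap enrichment, family definition, heatmaps, gene density."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from tadfamily import (
    ClusterAssignment,
    CohortSpec,
    FoldEnrichmentVector,
    GenomicInterval,
    SimilarityMatrix,
    average_family_heatmap,
    define_families,
    enumerate_heatmap_configurations,
    family_score,
    gen_cohort,
    gen_contact_matrix,
    gen_segmentation,
    gene_density,
    overlap_counts,
    overlap_enrichment,
    resize_member_matrix,
    spectral_cluster,
    structural_similarity_matrix,
)
from tadfamily.errors import DomainError
from tadfamily.reconstruct import reconstruct_tad
from tadfamily.simulate import DEFAULT_STATE_LABELS, _default_state_profiles


def assignment(labels_list, kind="structural"):
    labels = {f"t{i}": c for i, c in enumerate(labels_list)}
    return ClusterAssignment(labels=labels, k=max(labels_list), kind=kind)


class TestSpectralClustering:
    def test_block_diagonal_recovered_exactly(self):
        values = np.zeros((6, 6))
        values[:3, :3] = 1.0
        values[3:, 3:] = 1.0
        np.fill_diagonal(values, 1.0)
        sim = SimilarityMatrix(values, "structural", [f"t{i}" for i in range(6)])
        a = spectral_cluster(sim, 2, seed=0)
        groups = {a.labels[f"t{i}"] for i in range(3)}
        assert len(groups) == 1
        assert a.labels["t0"] != a.labels["t5"]

    def test_k_bounds_enforced(self):
        values = np.eye(3)
        sim = SimilarityMatrix(values, "structural", ["a", "b", "c"])
        with pytest.raises(DomainError):
            spectral_cluster(sim, 1, seed=0)
        with pytest.raises(DomainError):
            spectral_cluster(sim, 4, seed=0)

    def test_labels_size_ordered(self):
        values = np.full((5, 5), 0.05)
        values[:4, :4] = 1.0
        np.fill_diagonal(values, 1.0)
        sim = SimilarityMatrix(values, "functional", [f"t{i}" for i in range(5)])
        a = spectral_cluster(sim, 2, seed=0)
        sizes = a.sizes()
        assert sizes == sorted(sizes, reverse=True)


class TestOverlapCountsAndEnrichment:
    def test_identical_partitions_give_diagonal_table(self):
        a = assignment([1, 1, 2, 2, 3, 3], kind="structural")
        b = assignment([1, 1, 2, 2, 3, 3], kind="functional")
        counts = overlap_counts(a, b)
        assert np.array_equal(counts, 2 * np.eye(3, dtype=int))

    def test_single_cluster_each(self):
        a = assignment([1, 1, 1], kind="structural")
        b = assignment([1, 1, 1], kind="functional")
        assert overlap_counts(a, b)[0, 0] == 3

    @given(st.lists(st.tuples(st.integers(1, 3), st.integers(1, 4)),
                    min_size=8, max_size=20))
    def test_counts_match_brute_force(self, pairs):
        ka = max(p[0] for p in pairs)
        kb = max(p[1] for p in pairs)
        if set(p[0] for p in pairs) != set(range(1, ka + 1)):
            return
        if set(p[1] for p in pairs) != set(range(1, kb + 1)):
            return
        a = assignment([p[0] for p in pairs], kind="structural")
        b = assignment([p[1] for p in pairs], kind="functional")
        counts = overlap_counts(a, b)
        for i in range(kb):
            for j in range(ka):
                brute = sum(
                    1 for p in pairs if p[1] == i + 1 and p[0] == j + 1
                )
                assert counts[i, j] == brute
        assert counts.sum() == len(pairs)

    def test_worked_enrichment_example(self):
        """Overlap 18 between clusters of sizes 167 (functional) and 338
        (structural), scaled by 1000, displays as 0.3."""
        enr = overlap_enrichment(np.array([[18]]), [338], [167])
        assert round(float(enr[0, 0]), 1) == 0.3
        assert enr[0, 0] == pytest.approx(18_000 / (167 * 338))

    def test_zero_count_gives_zero(self):
        enr = overlap_enrichment(np.array([[0]]), [10], [20])
        assert enr[0, 0] == 0.0

    def test_single_cluster_algebraic_form(self):
        n = 12
        enr = overlap_enrichment(np.array([[n]]), [n], [n])
        assert enr[0, 0] == pytest.approx(1000.0 / n)

    def test_zero_size_rejected(self):
        with pytest.raises(DomainError):
            overlap_enrichment(np.array([[1]]), [0], [5])


class TestDefineFamilies:
    def test_identical_partitions_give_clusters(self):
        a = assignment([1, 1, 2, 2], kind="structural")
        b = assignment([1, 1, 2, 2], kind="functional")
        table = define_families(a, b)
        assert len(table) == 2
        assert sorted(len(f.members) for f in table) == [2, 2]

    def test_orthogonal_partitions_of_eight(self):
        a = assignment([1, 1, 1, 1, 2, 2, 2, 2], kind="structural")
        b = assignment([1, 2, 1, 2, 1, 2, 1, 2], kind="functional")
        table = define_families(a, b)
        assert len(table) == 4
        assert all(len(f.members) == 2 for f in table)

    @given(st.lists(st.tuples(st.integers(1, 3), st.integers(1, 3)),
                    min_size=6, max_size=25))
    def test_families_partition_the_tad_set(self, pairs):
        ka = max(p[0] for p in pairs)
        kb = max(p[1] for p in pairs)
        if set(p[0] for p in pairs) != set(range(1, ka + 1)):
            return
        if set(p[1] for p in pairs) != set(range(1, kb + 1)):
            return
        a = assignment([p[0] for p in pairs], kind="structural")
        b = assignment([p[1] for p in pairs], kind="functional")
        table = define_families(a, b)
        members = table.all_members()
        assert len(members) == len(set(members)) == len(pairs)


class TestFamilyScore:
    def test_all_enriched(self):
        assert family_score(FoldEnrichmentVector(np.full(25, 2.0))) == 1.0

    def test_all_depleted(self):
        assert family_score(FoldEnrichmentVector(np.full(25, 0.5))) == 0.0

    def test_thirteen_of_twentyfive(self):
        vals = np.array([2.0] * 13 + [0.5] * 12)
        assert family_score(FoldEnrichmentVector(vals)) == pytest.approx(0.52)

    def test_zero_counts_as_nonpositive(self):
        vals = np.array([0.0, 2.0, 2.0, 0.5])
        assert family_score(FoldEnrichmentVector(vals)) == pytest.approx(0.5)


class TestHeatmaps:
    def test_exact_target_size_is_identity(self):
        m = gen_contact_matrix(30, alpha=-1.0, noise_sd=0.1, seed=1)
        member = GenomicInterval("chrSim", 0, 30 * m.bin_size, id="m")
        vals, miss = resize_member_matrix(m, member, target=30)
        assert np.array_equal(vals, m.values)
        assert np.array_equal(miss, m.mask)

    def test_sixty_bins_block_average(self):
        m = gen_contact_matrix(60, alpha=-1.0, noise_sd=0.2, seed=2)
        member = GenomicInterval("chrSim", 0, 60 * m.bin_size, id="m")
        vals, _ = resize_member_matrix(m, member, target=30)
        oracle = np.zeros((30, 30))
        for u in range(30):
            for v in range(30):
                block = m.values[2 * u : 2 * u + 2, 2 * v : 2 * v + 2]
                bmask = m.mask[2 * u : 2 * u + 2, 2 * v : 2 * v + 2]
                oracle[u, v] = block[~bmask].mean()
        assert np.allclose(vals, oracle)
        assert np.allclose(vals, vals.T)

    def test_small_member_extended_evenly(self):
        m = gen_contact_matrix(40, alpha=-1.0, noise_sd=0.1, seed=3)
        member = GenomicInterval("chrSim", 5 * m.bin_size, 33 * m.bin_size, id="m")
        vals, _ = resize_member_matrix(m, member, target=30)
        assert np.array_equal(vals, m.values[4:34, 4:34])

    def test_odd_remainder_extends_downstream(self):
        m = gen_contact_matrix(40, alpha=-1.0, noise_sd=0.1, seed=4)
        member = GenomicInterval("chrSim", 5 * m.bin_size, 32 * m.bin_size, id="m")
        vals, _ = resize_member_matrix(m, member, target=30)  # 27 bins, extra 3
        assert np.array_equal(vals, m.values[4:34, 4:34])

    def test_family_mean_is_log2_of_mean_plus_one(self):
        m = gen_contact_matrix(30, alpha=-1.0, noise_sd=0.1, seed=5)
        member = GenomicInterval("chrSim", 0, 30 * m.bin_size, id="m")
        hm = average_family_heatmap([member], {"chrSim": m})
        obs = ~m.mask
        assert np.allclose(hm[obs], np.log2(m.values[obs] + 1.0))
        assert np.allclose(hm, hm.T, equal_nan=True)


class TestGeneDensity:
    def test_three_genes_ten_bins(self):
        t = GenomicInterval("chr1", 0, 500_000, id="t")
        genes = [
            GenomicInterval("chr1", 10_000, 20_000, id=f"g{i}") for i in range(3)
        ]
        assert gene_density(t, genes, bin_size=50_000) == pytest.approx(0.3)

    def test_no_genes(self):
        t = GenomicInterval("chr1", 0, 500_000, id="t")
        assert gene_density(t, [], bin_size=50_000) == 0.0

    def test_straddling_gene_counted(self):
        t = GenomicInterval("chr1", 100_000, 200_000, id="t")
        g = GenomicInterval("chr1", 190_000, 250_000, id="g")
        assert gene_density(t, [g], bin_size=50_000) == pytest.approx(0.5)


class TestConfigurationEnumeration:
    def test_full_grid_size(self):
        cells = ["GM12878", "HMEC", "HUVEC", "IMR90", "K562", "NHEK"]
        assert len(enumerate_heatmap_configurations(cells)) == 72


class TestDepletionLinkage:
    def test_depleted_state_class_concentrates_in_one_structural_cluster(self):
        """A quiescent (state-depleted) functional class whose members share
        one decay class lands >= 80% inside a single structural cluster."""
        profiles = _default_state_profiles(25)
        active, quiescent = profiles[0], profiles[2]
        rng = np.random.default_rng(0)
        n_bins, bin_size = 25, 50_000
        tads, matrices, regions = [], [], []
        truth_func = []
        pos = 0
        for i in range(12):
            depleted = i >= 6
            alpha = -1.5 if depleted else -0.5
            m = gen_contact_matrix(
                n_bins, alpha=alpha, noise_sd=0.05,
                seed=int(rng.integers(0, 2**31 - 1)),
                start=pos, tad_id=f"T{i:02d}",
            )
            iv = GenomicInterval("chrSim", pos, m.origin.end, id=f"T{i:02d}")
            tads.append(iv)
            matrices.append(m)
            regions.append((iv, quiescent if depleted else active))
            truth_func.append(int(depleted))
            pos = m.origin.end + 2 * bin_size
        structs = [reconstruct_tad(m, seed=1)[0] for m in matrices]
        ssim = structural_similarity_matrix(structs)
        a = spectral_cluster(ssim, 2, seed=0)
        depleted_ids = [t.id for t, f in zip(tads, truth_func) if f == 1]
        clusters = [a.labels[t] for t in depleted_ids]
        top_share = max(clusters.count(c) for c in set(clusters)) / len(clusters)
        assert top_share >= 0.8


class TestPlantedFamilyRecovery:
    def test_families_align_with_planted_pairs(self):
        """With mild noise, families recover the planted (struct, state)
        class pairs (ARI >= 0.8 averaged over 3 seeds). Noise 0.02 is the
        regime where three-way structural contrast survives the embedding;
        by noise ~0.05 the MDS optimum shifts enough that TM-score
        similarity no longer separates adjacent decay classes reliably."""
        from sklearn.metrics import adjusted_rand_score

        from tadfamily.chromstate import fold_enrichment, functional_similarity_matrix

        aris = []
        for seed in range(3):
            c = gen_cohort(CohortSpec(n_tads=12, noise_sd=0.02, seed=seed))
            genome = sum(iv.length for iv, _ in c.segmentation.records)
            structs = [reconstruct_tad(m, seed=1)[0] for m in c.matrices]
            ssim = structural_similarity_matrix(structs)
            fes = [fold_enrichment(t, c.segmentation, genome) for t in c.tads]
            fsim = functional_similarity_matrix(fes)
            a = spectral_cluster(ssim, 3, seed=seed)
            b = spectral_cluster(fsim, 3, seed=seed)
            table = define_families(a, b)
            fam_of = {}
            for fid, fam in enumerate(table):
                for m in fam.members:
                    fam_of[m] = fid
            truth = [
                int(c.true_struct_labels[i]) * 3 + int(c.true_state_labels[i])
                for i in range(12)
            ]
            pred = [fam_of[t.id] for t in c.tads]
            aris.append(adjusted_rand_score(truth, pred))
        assert float(np.mean(aris)) >= 0.8
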