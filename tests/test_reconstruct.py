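"""Contact rescaling, wish distances, MDS embedding, structure statistics."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.spatial.distance import pdist, squareform

from tadfamily import (
    GenomicInterval,
    StructureStats,
    WishDistanceMDS,
    WishDistanceMatrix,
    contacts_to_wish_distances,
    embed_mds,
    embed_tsne_selected,
    evaluate_consistency,
    exponent_parameter,
    gen_contact_matrix,
    gen_structure,
    kabsch_superpose,
    radius_of_gyration,
    rescale_contacts,
)
from tadfamily.errors import (
    ConnectivityError,
    DegenerateInputError,
    DomainError,
    UndefinedCorrelationError,
)
from tadfamily.types import ContactMatrix


def matrix_from_values(vals):
    """Symmetric ContactMatrix from an explicit value grid, diagonal masked."""
    vals = np.asarray(vals, dtype=float)
    n = vals.shape[0]
    mask = np.eye(n, dtype=bool)
    vals = vals.copy()
    vals[mask] = 0.0
    return ContactMatrix(
        values=vals,
        mask=mask,
        bin_size=1,
        origin=GenomicInterval("chrT", 0, n, id="toy"),
    )


def exact_wish(structure):
    d = squareform(pdist(structure.coords))
    return WishDistanceMatrix(values=d, mask=np.zeros_like(d, dtype=bool))


class TestRescaleContacts:
    def test_two_values_map_to_endpoints(self):
        m = matrix_from_values([[0, 2, 4], [2, 0, 2], [4, 2, 0]])
        r = rescale_contacts(m)
        obs = sorted(set(r.observed_offdiag()))
        assert obs == pytest.approx([1.0, 30.0])

    def test_midpoint_maps_linearly(self):
        m = matrix_from_values(
            [[0, 2, 3, 4], [2, 0, 4, 3], [3, 4, 0, 2], [4, 3, 2, 0]]
        )
        r = rescale_contacts(m)
        assert sorted(set(np.round(r.observed_offdiag(), 6))) == pytest.approx(
            [1.0, 15.5, 30.0]
        )

    def test_constant_matrix_rejected(self):
        m = matrix_from_values(np.ones((4, 4)))
        with pytest.raises(DegenerateInputError):
            rescale_contacts(m)

    @given(st.integers(0, 2**31 - 1))
    def test_affine_and_strictly_increasing(self, seed):
        m = gen_contact_matrix(8, alpha=-1.0, noise_sd=0.5, seed=seed)
        r = rescale_contacts(m)
        x = m.observed_offdiag()
        y = r.observed_offdiag()
        order = np.argsort(x)
        assert np.all(np.diff(y[order]) >= 0)
        # affine: unique slope
        slope = (30.0 - 1.0) / (x.max() - x.min())
        assert np.allclose(y, 1.0 + (x - x.min()) * slope)


class TestWishDistances:
    @pytest.mark.parametrize(
        "c,d", [(1.0, 1.0), (8.0, 0.5), (30.0, (1.0 / 30.0) ** (1.0 / 3.0))]
    )
    def test_cube_root_law(self, c, d):
        m = matrix_from_values([[0, c, c], [c, 0, c], [c, c, 0]])
        w = contacts_to_wish_distances(m)
        assert w.values[0, 1] == pytest.approx(d, abs=1e-5)

    def test_monotone_decreasing_in_contact(self):
        m = gen_contact_matrix(10, alpha=-1.0, noise_sd=0.2, seed=2)
        r = rescale_contacts(m)
        w = contacts_to_wish_distances(r)
        off = ~np.eye(10, dtype=bool)
        c = r.values[off]
        d = w.values[off]
        order = np.argsort(c)
        assert np.all(np.diff(d[order]) <= 1e-12)

    def test_nonpositive_contact_rejected(self):
        m = matrix_from_values([[0, 0, 1], [0, 0, 1], [1, 1, 0]])
        with pytest.raises(DomainError):
            contacts_to_wish_distances(m)


class TestEmbedMDS:
    def test_segment_recovered_exactly(self):
        truth = gen_structure("segment", 5)
        s = embed_mds(exact_wish(truth), seed=0)
        res = kabsch_superpose(s.coords, truth.coords, allow_reflection=True)
        assert res.rmsd < 1e-3

    def test_helix_recovered(self):
        truth = gen_structure("helix", 20)
        s = embed_mds(exact_wish(truth), seed=0)
        res = kabsch_superpose(s.coords, truth.coords, allow_reflection=True)
        assert res.rmsd < 1e-2

    def test_deterministic_given_seed(self):
        m = gen_contact_matrix(12, alpha=-1.0, noise_sd=0.2, seed=9)
        w = contacts_to_wish_distances(rescale_contacts(m))
        a = embed_mds(w, seed=5)
        b = embed_mds(w, seed=5)
        assert np.array_equal(a.coords, b.coords)

    def test_disconnected_observation_graph_rejected(self):
        n = 6
        d = np.ones((n, n))
        np.fill_diagonal(d, 0.0)
        mask = np.zeros((n, n), dtype=bool)
        mask[:3, 3:] = True
        mask[3:, :3] = True
        w = WishDistanceMatrix(values=d, mask=mask)
        with pytest.raises(ConnectivityError):
            embed_mds(w, seed=0)

    def test_matches_sklearn_smacof_on_complete_matrix(self):
        """Independent cross-check: on a complete distance matrix our
        weighted SMACOF reaches a stress no worse than sklearn's smacof."""
        from sklearn.manifold import smacof

        truth = gen_structure("random_walk", 15, seed=4)
        w = exact_wish(truth)
        ours = embed_mds(w, seed=0)
        d_ours = squareform(pdist(ours.coords))
        _, sk_stress = smacof(
            w.values, n_components=3, random_state=0, n_init=4, metric=True,
            normalized_stress=False,
        )
        our_stress = 0.5 * np.sum((d_ours - w.values) ** 2)
        assert our_stress <= sk_stress + 1e-6


class TestEstimatorInterface:
    def test_fit_transform_from_contact_matrix(self):
        m = gen_contact_matrix(10, alpha=-1.0, noise_sd=0.1, seed=3)
        est = WishDistanceMDS(random_state=1)
        coords = est.fit_transform(m)
        assert coords.shape == (10, 3)
        assert est.stress_ >= 0
        assert est.get_params()["random_state"] == 1

    def test_nan_marks_missing_in_raw_array(self):
        arr = np.abs(np.random.default_rng(0).standard_normal((8, 8))) + 0.5
        arr = (arr + arr.T) / 2
        arr[0, 7] = arr[7, 0] = np.nan
        est = WishDistanceMDS(random_state=0)
        est.fit(arr)
        assert est.wish_distances_.mask[0, 7]


class TestTSNESelection:
    def test_report_covers_grid_and_min_selected(self):
        m = gen_contact_matrix(30, alpha=-1.0, noise_sd=0.1, seed=11)
        w = contacts_to_wish_distances(rescale_contacts(m))
        ref = embed_mds(w, seed=0)
        s, report = embed_tsne_selected(
            w, ref, perplexities=[5, 15], learning_rates=[10, 100], seed=0
        )
        assert len(report) == 4
        best = kabsch_superpose(s.coords, ref.coords, allow_reflection=True)
        assert best.rmsd == pytest.approx(report["rmsd"].min(), abs=1e-9)

    def test_single_configuration_returned_regardless(self):
        m = gen_contact_matrix(20, alpha=-1.0, noise_sd=0.1, seed=12)
        w = contacts_to_wish_distances(rescale_contacts(m))
        ref = embed_mds(w, seed=0)
        s, report = embed_tsne_selected(
            w, ref, perplexities=[5], learning_rates=[100], seed=0
        )
        assert len(report) == 1

    def test_perplexity_bound_enforced(self):
        m = gen_contact_matrix(10, alpha=-1.0, noise_sd=0.1, seed=13)
        w = contacts_to_wish_distances(rescale_contacts(m))
        ref = embed_mds(w, seed=0)
        with pytest.raises(DomainError):
            embed_tsne_selected(w, ref, perplexities=[10], learning_rates=[10], seed=0)
        with pytest.raises(DomainError):
            embed_tsne_selected(w, ref, perplexities=[], learning_rates=[10], seed=0)


class TestStructureStats:
    def test_radius_of_gyration_two_beads(self):
        assert radius_of_gyration(np.array([[0.0, 0, 0], [2.0, 0, 0]])) == 1.0

    def test_radius_of_gyration_identical_beads(self):
        assert radius_of_gyration(np.zeros((4, 3))) == 0.0

    def test_radius_of_gyration_unit_square(self):
        square = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], dtype=float)
        assert radius_of_gyration(square) == pytest.approx(np.sqrt(0.5))

    def test_rigid_invariance(self, rng):
        coords = rng.standard_normal((10, 3))
        q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        moved = coords @ q.T + np.array([3.0, -1.0, 2.0])
        assert radius_of_gyration(moved) == pytest.approx(radius_of_gyration(coords))

    @pytest.mark.parametrize("alpha", [-1.0, -1.5])
    def test_exponent_recovers_exact_power_law(self, alpha):
        m = gen_contact_matrix(20, alpha=alpha, noise_sd=0.0, seed=0)
        assert exponent_parameter(m) == pytest.approx(alpha, abs=1e-9)

    def test_exponent_zero_for_constant_matrix(self):
        m = matrix_from_values(np.full((8, 8), 3.0))
        assert exponent_parameter(m) == pytest.approx(0.0, abs=1e-12)


class TestEvaluateConsistency:
    def test_rank_reversal_gives_spearman_minus_one(self):
        stats = [
            StructureStats("a", -1.5, 3.0),
            StructureStats("b", -1.0, 2.0),
            StructureStats("c", -0.5, 1.0),
        ]
        _, spearman = evaluate_consistency(stats)
        assert spearman == pytest.approx(-1.0)

    def test_identical_vectors_give_pearson_one(self):
        stats = [StructureStats(str(i), v, v) for i, v in enumerate([0.1, 0.5, 0.9])]
        pearson, _ = evaluate_consistency(stats)
        assert pearson == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        stats = [StructureStats(str(i), -1.0, float(i)) for i in range(4)]
        with pytest.raises(UndefinedCorrelationError):
            evaluate_consistency(stats)
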