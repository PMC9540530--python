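"""Weighted Gower dissimilarity, square-root transform, and PCoA."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.spatial.distance import pdist, squareform

import faunadiv as fd
from faunadiv.trait_space import (
    DissimilarityMatrix,
    build_trait_space,
    default_weights,
    trait_matrix,
)


def make_species(sp_id, mass_g, diet, stratum="ground", activity=(True, False, False),
                 habitat=frozenset({"forest"}), volant=False):
    return fd.SpeciesRecord(
        species_id=sp_id, name=sp_id, mass_g=mass_g, diet_pct=diet,
        foraging_stratum=stratum, activity=activity, habitat=habitat, volant=volant,
    )


DIET_A = (100.0, 0, 0, 0, 0, 0, 0)
DIET_B = (0, 100.0, 0, 0, 0, 0, 0)
DIET_AB = (50.0, 50.0, 0, 0, 0, 0, 0)


class TestGower:
    def test_identical_species_have_zero_dissimilarity(self):
        a = make_species("a", 100, DIET_A)
        b = make_species("b", 100, DIET_A)
        c = make_species("c", 300, DIET_B)  # breaks zero ranges
        D = fd.gower([a, b, c])
        assert D.values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_maximally_different_species_score_one(self):
        a = make_species("a", 1.0, DIET_A, stratum="ground",
                         activity=(True, False, False), habitat=frozenset({"forest"}))
        b = make_species("b", 1000.0, DIET_B, stratum="arboreal",
                         activity=(False, True, True), habitat=frozenset({"wetland"}))
        D = fd.gower([a, b])
        assert D.values[0, 1] == pytest.approx(1.0)

    def test_three_species_hand_computation(self):
        """Frozen hand computation of the weighted mean per pair.

        Only mass (weight 1) and the two varying diet axes (weight 1/7
        each) vary; every other variable is constant and dropped, so
        d(i,j) = (w_m |log m_i - log m_j|/R + sum_d |x_i-x_j|/100 / 7)
                 / (1 + 2/7).
        """
        sp = [
            make_species("a", 100.0, DIET_A),
            make_species("b", 200.0, DIET_B),
            make_species("c", 300.0, DIET_AB),
        ]
        D = fd.gower(sp)
        assert D.values[0, 1] == pytest.approx(0.7129453639, abs=1e-9)
        assert D.values[0, 2] == pytest.approx(0.8888888889, abs=1e-9)
        assert D.values[1, 2] == pytest.approx(0.3981657472, abs=1e-9)

    def test_constant_variable_dropped_with_warning(self, caplog):
        sp = [make_species("a", 100, DIET_A), make_species("b", 200, DIET_B)]
        with caplog.at_level("WARNING", logger="faunadiv.trait_space"):
            fd.gower(sp)
        assert any("constant" in r.message for r in caplog.records)

    def test_permutation_equivariance(self):
        sp = [
            make_species("a", 50, DIET_A),
            make_species("b", 500, DIET_B, stratum="arboreal"),
            make_species("c", 5000, DIET_AB, activity=(False, True, False)),
            make_species("d", 20, DIET_AB, habitat=frozenset({"urban"})),
        ]
        D = fd.gower(sp)
        perm = [2, 0, 3, 1]
        Dp = fd.gower([sp[i] for i in perm])
        assert np.allclose(Dp.values, D.values[np.ix_(perm, perm)])

    @given(st.floats(min_value=0.1, max_value=10.0))
    def test_weight_scaling_invariance(self, factor):
        """Multiplying every weight by a constant leaves Gower unchanged."""
        sp = [
            make_species("a", 50, DIET_A),
            make_species("b", 500, DIET_B, stratum="arboreal"),
            make_species("c", 5000, DIET_AB),
        ]
        X, names, _ = trait_matrix(sp)
        base = default_weights(names)
        scaled = {k: v * factor for k, v in base.items()}
        assert np.allclose(
            fd.gower(sp, weights=base).values,
            fd.gower(sp, weights=scaled).values,
            atol=1e-12,
        )

    def test_requires_two_species(self):
        with pytest.raises(ValueError):
            fd.gower([make_species("a", 100, DIET_A)])


class TestSqrtTransform:
    def test_values(self):
        D = DissimilarityMatrix(
            ("a", "b", "c"),
            np.array([[0, 0.25, 1.0], [0.25, 0, 0.0], [1.0, 0.0, 0]]),
        )
        S = fd.sqrt_transform(D)
        assert S.values[0, 1] == pytest.approx(0.5)
        assert S.values[0, 2] == pytest.approx(1.0)
        assert S.values[1, 2] == 0.0

    def test_all_zero_fixed_point(self):
        D = DissimilarityMatrix(("a", "b"), np.zeros((2, 2)))
        assert np.all(fd.sqrt_transform(D).values == 0)


def euclidean_dm(points, ids=None):
    ids = ids or tuple(f"p{i}" for i in range(len(points)))
    return DissimilarityMatrix(ids, squareform(pdist(points)))


class TestPCoA:
    def test_recovers_planar_distances(self):
        """Coordinates of a Euclidean input reproduce its distances."""
        rng = np.random.default_rng(5)
        pts = rng.uniform(0, 0.5, size=(6, 2))
        space = fd.pcoa(euclidean_dm(pts), k=2)
        got = squareform(pdist(space.coordinates))
        want = squareform(pdist(pts))
        assert np.allclose(got, want, atol=1e-8)

    def test_two_points_split_symmetrically(self):
        D = DissimilarityMatrix(("a", "b"), np.array([[0, 0.6], [0.6, 0]]))
        space = fd.pcoa(D, k=1)
        assert sorted(space.coordinates[:, 0]) == pytest.approx([-0.3, 0.3])

    def test_collinear_points_lack_second_axis(self):
        pts = np.array([[0.0], [0.3], [0.7], [1.0]])
        D = euclidean_dm(np.hstack([pts, np.zeros_like(pts)]))
        with pytest.raises(ValueError, match="positive eigenvalues"):
            fd.pcoa(D, k=2)

    def test_strongly_non_euclidean_matrix_rejected(self):
        """Triangle-violating input must fail with transform advice."""
        D = np.array(
            [
                [0.00, 0.05, 0.05, 0.05],
                [0.05, 0.00, 1.00, 1.00],
                [0.05, 1.00, 0.00, 1.00],
                [0.05, 1.00, 1.00, 0.00],
            ]
        )
        with pytest.raises(ValueError, match="square-root"):
            fd.pcoa(DissimilarityMatrix(("a", "b", "c", "d"), D), k=2)

    def test_isometry_on_random_clouds(self):
        """PCoA of Euclidean distances is a rigid motion of the cloud."""
        rng = np.random.default_rng(12)
        for dim in (2, 3, 5):
            pts = rng.normal(size=(12, dim)) * 0.1
            space = fd.pcoa(euclidean_dm(pts), k=dim)
            assert np.allclose(
                squareform(pdist(space.coordinates)), squareform(pdist(pts)), atol=1e-8
            )

    def test_axis_orientation_is_deterministic(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(size=(8, 3)) * 0.5
        a = fd.pcoa(euclidean_dm(pts), k=3)
        b = fd.pcoa(euclidean_dm(pts), k=3)
        assert np.array_equal(a.coordinates, b.coordinates)
        for j in range(3):
            col = a.coordinates[:, j]
            assert col[np.flatnonzero(np.abs(col) > 1e-9)[0]] > 0

    def test_matches_scikit_bio(self):
        """Independent cross-check against scikit-bio's PCoA."""
        skbio = pytest.importorskip("skbio")
        from skbio.stats.ordination import pcoa as skbio_pcoa

        rng = np.random.default_rng(9)
        pts = rng.uniform(size=(10, 4)) * 0.4
        D = euclidean_dm(pts)
        ours = fd.pcoa(D, k=4)
        theirs = skbio_pcoa(skbio.DistanceMatrix(D.values, ids=list(D.species_ids)))
        assert np.allclose(
            np.sort(ours.eigenvalues)[::-1],
            np.sort(theirs.eigvals.values)[::-1][:4],
            atol=1e-8,
        )
        got = squareform(pdist(ours.coordinates))
        want = squareform(pdist(theirs.samples.values[:, :4]))
        assert np.allclose(got, want, atol=1e-8)


class TestFullConstruction:
    def test_synthetic_pool_embeds_cleanly(self):
        """Post-sqrt negative eigenvalue mass stays below tolerance."""
        species = fd.simulate_traits(fd.SimulationConfig(seed=31, n_species=80))
        space = build_trait_space(species, k=5)
        assert space.coordinates.shape == (80, 5)
        assert np.all(space.eigenvalues > 0)
        assert np.all(np.diff(space.eigenvalues) <= 1e-12)
        assert 0 < space.variance_represented <= 1

    def test_variance_grows_with_k(self):
        species = fd.simulate_traits(fd.SimulationConfig(seed=31, n_species=40))
        v3 = build_trait_space(species, k=3).variance_represented
        v5 = build_trait_space(species, k=5).variance_represented
        assert v5 > v3
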