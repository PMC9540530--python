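"""Synthetic generator: determinism, validity, and study-system structure."""

import numpy as np
import pytest

import faunadiv as fd
from faunadiv.data_model import StatusCategory as C
from faunadiv.data_model import Timepoint
from faunadiv.io import write_species_csv, write_status_csv
from faunadiv.simulate import _species_labels


def tip_depths(tree):
    """Root-to-tip path lengths, one per tip."""
    depths = []
    for t in range(tree.n_tips):
        node, depth = t, 0.0
        while node != -1:
            depth += tree.edge_lengths[node]
            node = int(tree.parent[node])
        depths.append(depth)
    return np.array(depths)


class TestSimulateTrees:
    def test_two_species_cherry_is_ultrametric(self):
        config = fd.SimulationConfig(seed=1, n_species=2, n_trees=3)
        for tree in fd.simulate_trees(config):
            depths = tip_depths(tree)
            assert depths[0] == pytest.approx(depths[1])

    def test_same_seed_reproduces_trees(self):
        config = fd.SimulationConfig(seed=5, n_species=10, n_trees=4)
        a = fd.simulate_trees(config)
        b = fd.simulate_trees(config)
        for ta, tb in zip(a, b):
            assert ta.tip_labels == tb.tip_labels
            assert np.array_equal(ta.parent, tb.parent)
            assert np.array_equal(ta.edge_lengths, tb.edge_lengths)

    def test_trees_are_binary_with_n_minus_one_internals(self):
        config = fd.SimulationConfig(seed=2, n_species=50, n_trees=20)
        ensemble = fd.simulate_trees(config)
        assert len(ensemble) == 20
        for tree in ensemble:
            # rooted binary: 50 tips + 49 internal nodes
            assert len(tree.parent) == 2 * 50 - 1
            children = np.bincount(tree.parent[tree.parent >= 0], minlength=99)
            assert set(children[tree.n_tips :]) == {2}

    def test_ensemble_is_ultrametric(self):
        config = fd.SimulationConfig(seed=3, n_species=12, n_trees=5)
        for tree in fd.simulate_trees(config):
            depths = tip_depths(tree)
            assert np.allclose(depths, depths[0], atol=1e-6)


class TestSimulateTraits:
    def test_records_pass_all_invariants(self):
        species = fd.simulate_traits(fd.SimulationConfig(seed=8, n_species=100))
        assert len(species) == 100
        for sp in species:  # construction re-validates every invariant
            assert sum(sp.diet_pct) == pytest.approx(100.0, abs=1e-9)
            assert sp.mass_g > 0
            assert any(sp.activity)

    def test_diet_percentages_are_integers_summing_100(self):
        species = fd.simulate_traits(fd.SimulationConfig(seed=8, n_species=50))
        for sp in species:
            assert all(p == int(p) for p in sp.diet_pct)
            assert sum(sp.diet_pct) == 100.0

    def test_log_mass_mean_recovered(self):
        """Empirical log-mass mean within 3 se of the configured mean."""
        config = fd.SimulationConfig(
            seed=13, n_species=500, volant_fraction=0.0, n_globally_extinct=0,
            n_with_surrogate=0,
        )
        species = fd.simulate_traits(config)
        logm = np.log10([sp.mass_g for sp in species])
        se = config.log_mass_sd / np.sqrt(len(species))
        assert abs(logm.mean() - config.log_mass_mean) < 3 * se

    def test_volant_species_flagged_and_light(self):
        config = fd.SimulationConfig(seed=9, n_species=200)
        species = fd.simulate_traits(config)
        volant = [sp for sp in species if sp.volant]
        assert 0.04 * 200 <= len(volant) <= 0.12 * 200
        rest = [sp for sp in species if not sp.volant]
        assert np.median([sp.mass_g for sp in volant]) < np.median(
            [sp.mass_g for sp in rest]
        )

    def test_extinct_and_surrogate_counts(self):
        config = fd.SimulationConfig(seed=10, n_species=100)
        species = fd.simulate_traits(config)
        extinct = [sp for sp in species if sp.globally_extinct]
        assert len(extinct) == config.n_globally_extinct
        assert sum(sp.surrogate_available for sp in extinct) == config.n_with_surrogate


class TestSimulateStatus:
    def test_islands_are_depauperate(self):
        config = fd.SimulationConfig(seed=21, n_species=120, n_trees=1, n_regions=20)
        species = fd.simulate_traits(config)
        status, regions = fd.simulate_status(config, species)
        richness = {
            r.region_id: len(fd.assemble(status, r.region_id, Timepoint.BP8000))
            for r in regions
        }
        island_mean = np.mean([richness[r.region_id] for r in regions if r.island])
        mainland_mean = np.mean([richness[r.region_id] for r in regions if not r.island])
        assert island_mean < mainland_mean

    def test_no_pressure_means_no_change(self):
        config = fd.SimulationConfig(
            seed=22, n_species=40, n_trees=1, n_regions=6,
            p_extirpated_island=0.0, p_extirpated_continental=0.0,
            p_regained_island=0.0, p_regained_continental=0.0,
            mean_introduced_island=0.0, mean_introduced_continental=0.0,
            mean_colonist_island=0.0, mean_colonist_continental=0.0,
            n_globally_extinct=0, n_with_surrogate=0,
        )
        species = fd.simulate_traits(config)
        status, regions = fd.simulate_status(config, species)
        for r in regions:
            loss, gain = fd.loss_gain_sets(status, r.region_id)
            assert loss == gain == frozenset()

    def test_extinct_species_never_present_in_2020(self):
        config = fd.SimulationConfig(seed=23, n_species=80, n_trees=1, n_regions=10)
        species = fd.simulate_traits(config)
        status, regions = fd.simulate_status(config, species)
        extinct = {sp.species_id for sp in species if sp.globally_extinct}
        for r in regions:
            y2020 = fd.assemble(status, r.region_id, Timepoint.Y2020).species_ids
            assert not y2020 & extinct

    def test_future_candidates_are_restorable(self):
        config = fd.SimulationConfig(seed=24, n_species=80, n_trees=1, n_regions=10)
        species = fd.simulate_traits(config)
        status, _ = fd.simulate_status(config, species)
        by_id = {sp.species_id: sp for sp in species}
        for rec in status:
            if rec.category is C.FUTURE_POTENTIAL:
                sp = by_id[rec.species_id]
                assert not sp.globally_extinct or sp.surrogate_available

    def test_same_seed_gives_identical_csv_bytes(self, tmp_path):
        config = fd.SimulationConfig(seed=25, n_species=30, n_trees=1, n_regions=4)
        outputs = []
        for tag in ("a", "b"):
            species = fd.simulate_traits(config)
            status, _ = fd.simulate_status(config, species)
            write_species_csv(tmp_path / f"species_{tag}.csv", species)
            write_status_csv(tmp_path / f"status_{tag}.csv", status)
            outputs.append(
                (
                    (tmp_path / f"species_{tag}.csv").read_bytes(),
                    (tmp_path / f"status_{tag}.csv").read_bytes(),
                )
            )
        assert outputs[0] == outputs[1]


class TestContinentalFixture:
    def test_counts(self, continental):
        status = continental.status_records
        assert len(fd.assemble(status, "europe", Timepoint.BP8000)) == 198
        assert len(fd.assemble(status, "europe", Timepoint.Y2020)) == 211
        assert len(continental.species) == 228
        extinct = [sp for sp in continental.species if sp.globally_extinct]
        assert len(extinct) == 12
        assert sum(sp.surrogate_available for sp in extinct) == 5

    def test_deterministic(self):
        a = fd.continental_fixture(n_trees=2)
        b = fd.continental_fixture(n_trees=2)
        assert a.species == b.species
        assert a.status_records == b.status_records
        for ta, tb in zip(a.ensemble, b.ensemble):
            assert np.array_equal(ta.edge_lengths, tb.edge_lengths)


class TestDiversityStructure:
    def test_richness_monotone_in_subset_size(self, small_dataset, small_evaluator):
        """Nested random pool subsets: all metrics grow with subset size."""
        rng = np.random.default_rng(33)
        ids = np.array(small_dataset.species_ids)
        perm = rng.permutation(len(ids))
        prev_r = prev_pd = prev_fric = 0.0
        for size in (8, 16, 32, 60):
            tips = set(ids[perm[:size]])
            r = small_evaluator.richness(tips)
            pd_val = small_evaluator.pd(tips)[0]
            fric = small_evaluator.fric(tips)
            assert r >= prev_r and pd_val >= prev_pd - 1e-12
            if fric is not None:
                assert fric >= prev_fric - 1e-12
                prev_fric = fric
            prev_r, prev_pd = r, pd_val

    def test_config_validation(self):
        with pytest.raises(ValueError):
            fd.SimulationConfig(seed=1, n_species=1)
        with pytest.raises(ValueError):
            fd.SimulationConfig(seed=1, island_fraction=1.5)
        with pytest.raises(ValueError):
            fd.SimulationConfig(seed=1, n_globally_extinct=2, n_with_surrogate=3)

    def test_label_format(self):
        assert _species_labels(3) == ["sp0001", "sp0002", "sp0003"]
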