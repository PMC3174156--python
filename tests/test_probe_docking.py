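import math

import numpy as np
import pytest

from bindlev import fixtures
from bindlev.probe_docking import (
    BOND_LENGTH,
    ProbeLocation,
    ProbeState,
    SimulationConfig,
    generate_probe_locations,
    pair_energy,
    run_probe_simulation,
    total_energy,
)
from bindlev.site_catalog import jaccard


class TestPairEnergy:
    @pytest.mark.parametrize(
        "d, expected",
        [
            (6.0, -1.0),  # inside the attractive well
            (5.5, -1.0),
            (8.0, -1.0),
            (5.2, 3.0),
            (4.7, 10.0),
            (4.5, 10.0),
            (9.0, 0.0),
            (8.01, 0.0),
        ],
    )
    def test_values(self, d, expected):
        assert pair_energy(d) == expected

    def test_forbidden_below_hard_core(self):
        assert pair_energy(4.4) == math.inf

    def test_nonpositive_distance(self):
        with pytest.raises(ValueError):
            pair_energy(0.0)


def python_total_energy(probe, protein_coords, box):
    """Independent O(k·N) double-loop oracle with minimum-image distances."""
    total = 0.0
    for a in probe:
        for p in protein_coords:
            delta = a - p
            delta -= box * np.round(delta / box)
            d = float(np.linalg.norm(delta))
            if d < 4.5:
                return math.inf
            if d < 5.0:
                total += 10.0
            elif d < 5.5:
                total += 3.0
            elif d <= 8.0:
                total += -1.0
    return total


class TestTotalEnergy:
    def test_far_probe_zero(self, decoy):
        structure, _ = decoy
        probe = structure.coords.mean(axis=0) + np.array([60.0, 0.0, 0.0])
        probe = np.stack([probe, probe + [BOND_LENGTH, 0, 0]])
        assert total_energy(probe, structure, box_side=400.0) == 0.0

    def test_three_atoms_in_well(self):
        from tests.test_elastic_modes import make_structure

        protein = make_structure([[6.0, 0.0, 0.0], [0.0, 6.0, 0.0], [0.0, 0.0, 6.0]])
        probe = np.zeros((1, 3))
        assert total_energy(probe, protein, box_side=500.0) == -3.0

    def test_oracle_equivalence(self, decoy, rng):
        structure, _ = decoy
        box = 80.0
        center = structure.coords.mean(axis=0)
        for _ in range(50):
            probe = center + rng.uniform(-30, 30, size=(4, 3))
            mine = total_energy(probe, structure, box)
            oracle = python_total_energy(probe, structure.coords, box)
            assert mine == oracle


class TestRunSimulation:
    def test_same_seed_identical(self, decoy):
        structure, _ = decoy
        config = SimulationConfig(probe_size=4, n_steps=5000, n_sims=1, seed=0)
        a = run_probe_simulation(structure, config, seed=99)
        b = run_probe_simulation(structure, config, seed=99)
        assert a.residues == b.residues
        np.testing.assert_array_equal(a.final_probe_coords, b.final_probe_coords)
        assert a.final_energy == b.final_energy

    def test_zero_steps_empty(self, decoy):
        structure, _ = decoy
        config = SimulationConfig(probe_size=4, n_steps=0, n_sims=1, seed=0)
        loc = run_probe_simulation(structure, config, seed=3)
        assert loc.is_empty

    def test_final_state_satisfies_probe_invariants(self, decoy):
        structure, _ = decoy
        config = SimulationConfig(probe_size=5, n_steps=20_000, n_sims=1, seed=0)
        loc = run_probe_simulation(structure, config, seed=11)
        ProbeState(loc.final_probe_coords)  # validates bonds and angles

    def test_box_too_small_errors(self, hinge):
        open_s, _, _ = hinge
        config = SimulationConfig(
            probe_size=4, n_steps=10, n_sims=1, seed=0, box_side=18.0,
            max_init_retries=200,
        )
        with pytest.raises(RuntimeError, match="box"):
            run_probe_simulation(open_s, config, seed=1)

    def test_audit_invariants_short_run(self, decoy):
        structure, _ = decoy
        config = SimulationConfig(probe_size=4, n_steps=50_000, n_sims=1, seed=0)
        loc, audit = run_probe_simulation(structure, config, seed=5, audit=True)
        assert audit["min_clearance"] >= 4.5 - 1e-9
        assert audit["max_bond_deviation"] < 1e-9
        assert audit["max_angle_cos"] <= 1e-9
        assert abs(audit["incremental_energy"] - audit["recomputed_energy"]) < 1e-9
        assert 0.0 < audit["acceptance_rate"] < 1.0


class TestGenerateLocations:
    def test_defaults_follow_heuristics(self, decoy):
        structure, _ = decoy
        config = SimulationConfig(probe_size=4, seed=0).resolve(structure)
        extent = float(
            np.max(structure.coords.max(axis=0) - structure.coords.min(axis=0))
        )
        assert config.box_side == pytest.approx(2.0 * extent)
        assert config.n_sims == 10 * len(structure)
        assert config.n_steps == int(round(1000 * config.box_side))

    def test_master_seed_reproducible(self, decoy):
        structure, _ = decoy
        config = SimulationConfig(probe_size=4, n_sims=8, n_steps=4000, seed=42)
        a = generate_probe_locations(structure, config)
        b = generate_probe_locations(structure, config)
        assert len(a) == len(b)
        for x, y in zip(a, b):
            assert x.residues == y.residues
            np.testing.assert_array_equal(x.final_probe_coords, y.final_probe_coords)

    @pytest.mark.slow
    def test_surface_coverage(self, hinge):
        # at the published sampling density (10 x residues simulations) the
        # union of end-state locations covers nearly the whole surface
        open_s, _, _ = hinge
        config = SimulationConfig(
            probe_size=4, n_sims=10 * len(open_s), n_steps=30_000, seed=7
        )
        locations = generate_probe_locations(open_s, config)
        union = set().union(*(loc.residues for loc in locations))
        assert len(union) >= 0.8 * len(open_s)

    @pytest.mark.slow
    def test_planted_pocket_majority_recovery(self, hinge):
        # deep-cleft fixture: most docking runs should end in the cleft
        open_s, _, truth = hinge
        config = SimulationConfig(probe_size=4, n_sims=50, seed=5)
        locations = generate_probe_locations(open_s, config)
        assert len(locations) >= 40
        overlaps = [jaccard(loc.residues, truth) for loc in locations]
        assert np.mean(np.asarray(overlaps) > 0.3) > 0.5

    @pytest.mark.slow
    def test_deeper_pocket_attracts_more_runs(self):
        # graded truth contact grows from a shallow dent to a deep one
        coverage = []
        for depth in (0.5, 4.5):
            structure, truth = fixtures.make_decoy_with_planted_pocket(
                60, depth, seed=3
            )
            config = SimulationConfig(probe_size=4, n_sims=60, n_steps=120_000, seed=5)
            locations = generate_probe_locations(structure, config)
            coverage.append(
                np.mean([len(l.residues & truth) / len(truth) for l in locations])
            )
        assert coverage[1] > 1.2 * coverage[0]


class TestFreeChainStatistics:
    @pytest.mark.slow
    def test_end_to_end_distribution_matches_direct_sampling(self):
        # with the protein reduced to a remote speck, the probe is a free
        # constrained chain; its end-to-end distance distribution must match
        # direct sampling of uniform hemisphere-constrained bond directions
        from tests.test_elastic_modes import make_structure

        rng = np.random.default_rng(0)
        protein = make_structure([[-140.0, -140.0, -140.0], [-140.0, -140.0, -136.2]])
        config = SimulationConfig(
            probe_size=4, n_steps=2000, n_sims=1, seed=0, box_side=300.0,
            jump_probability=0.0,
        )
        mc_dist = []
        for i in range(400):
            loc = run_probe_simulation(protein, config, seed=1000 + i)
            coords = loc.final_probe_coords
            mc_dist.append(float(np.linalg.norm(coords[-1] - coords[0])))

        direct = []
        for _ in range(4000):
            b = rng.standard_normal(3)
            b /= np.linalg.norm(b)
            pos = [np.zeros(3), BOND_LENGTH * b]
            for _ in range(2):
                while True:
                    c = rng.standard_normal(3)
                    c /= np.linalg.norm(c)
                    if c @ b >= 0.0:
                        break
                pos.append(pos[-1] + BOND_LENGTH * c)
                b = c
            direct.append(float(np.linalg.norm(pos[-1] - pos[0])))

        assert abs(np.mean(mc_dist) - np.mean(direct)) < 0.35
        assert abs(np.std(mc_dist) - np.std(direct)) < 0.35


class TestProbeStateValidation:
    def test_bad_bond_rejected(self):
        with pytest.raises(ValueError, match="bond"):
            ProbeState(np.array([[0.0, 0.0, 0.0], [5.0, 0.0, 0.0]]))

    def test_bad_angle_rejected(self):
        coords = np.array(
            [[0.0, 0.0, 0.0], [3.8, 0.0, 0.0], [0.5, 1.0, 0.0]]
        )
        coords[2] = coords[1] + 3.8 * np.array([-np.cos(0.5), np.sin(0.5), 0.0])
        with pytest.raises(ValueError, match="angle"):
            ProbeState(coords)

    def test_location_is_frozen_set(self):
        loc = ProbeLocation(
            residues=[3, 1, 1],
            final_probe_coords=np.zeros((2, 3)),
            final_energy=0.0,
            sim_seed=0,
        )
        assert loc.residues == frozenset({1, 3})


class TestConfigValidation:
    @pytest.mark.parametrize("size", [1, 9])
    def test_probe_size_bounds(self, size):
        with pytest.raises(ValueError):
            SimulationConfig(probe_size=size)

    def test_with_seed(self):
        config = SimulationConfig(seed=1)
        assert config.with_seed(9).seed == 9
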