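import numpy as np
import pytest

from bindlev.leverage import (
    SpringNetwork,
    binding_leverage,
    build_spring_network,
    delta_u,
    leverage_from_difference,
)
from bindlev.elastic_modes import select_modes
from bindlev.structure_io import DisplacementField
from tests.test_elastic_modes import make_structure


def segment_point_distance(a, b, p):
    ab = b - a
    t = float(np.dot(p - a, ab) / np.dot(ab, ab))
    t = min(max(t, 0.0), 1.0)
    return float(np.linalg.norm(p - (a + t * ab)))


def brute_force_network(coords, probe, cutoff=3.5):
    """O(N²·k) oracle with the exact point-to-segment distance formula."""
    pairs = []
    n = len(coords)
    for i in range(n):
        for j in range(i + 1, n):
            dmin = min(
                segment_point_distance(coords[i], coords[j], p) for p in probe
            )
            if dmin <= cutoff:
                pairs.append((i, j))
    return pairs


def brute_force_delta_u(coords, pairs, lengths, displacement, amplitude):
    moved = coords + amplitude * displacement
    total = 0.0
    for (i, j), d0 in zip(pairs, lengths):
        d1 = float(np.linalg.norm(moved[i] - moved[j]))
        total += 0.5 * (d1 - d0) ** 2
    return total


class TestBuildSpringNetwork:
    def test_midpoint_probe_included(self):
        protein = make_structure([[0.0, 0.0, 0.0], [8.0, 0.0, 0.0]])
        net = build_spring_network(protein, np.array([[4.0, 0.0, 0.0]]))
        assert net.n_springs == 1
        assert net.lengths[0] == pytest.approx(8.0)

    def test_far_probe_excluded(self):
        protein = make_structure([[0.0, 0.0, 0.0], [8.0, 0.0, 0.0]])
        net = build_spring_network(protein, np.array([[4.0, 5.0, 0.0]]))
        assert net.n_springs == 0

    def test_oracle_equivalence_random(self, rng):
        for _ in range(10):
            coords = rng.uniform(-12, 12, size=(15, 3))
            probe = rng.uniform(-12, 12, size=(4, 3))
            protein = make_structure(coords)
            net = build_spring_network(protein, probe)
            expected = brute_force_network(coords, probe)
            assert sorted(map(tuple, net.pairs)) == expected

    def test_hinge_cleft_probe_spans_lobes(self, hinge, hinge_locations):
        open_s, _, truth = hinge
        best = max(
            hinge_locations, key=lambda l: len(l.residues & truth)
        )
        net = build_spring_network(open_s, best.final_probe_coords)
        n_lobe = 36
        cross = np.sum((net.pairs[:, 0] < n_lobe) & (net.pairs[:, 1] >= n_lobe))
        assert cross > 0


class TestDeltaU:
    def test_zero_displacement(self, hinge):
        open_s, _, _ = hinge
        length = float(np.linalg.norm(open_s.coords[0] - open_s.coords[40]))
        net = SpringNetwork(pairs=np.array([[0, 40]]), lengths=np.array([length]))
        field = DisplacementField(vectors=np.zeros((len(open_s), 3)))
        assert delta_u(net, open_s, field) == 0.0

    def test_rigid_translation_invariance(self, hinge, hinge_dx):
        open_s, _, _ = hinge
        ii, jj = np.triu_indices(len(open_s), k=1)
        keep = slice(0, 200)
        pairs = np.stack([ii[keep], jj[keep]], axis=1)
        lengths = np.linalg.norm(
            open_s.coords[pairs[:, 0]] - open_s.coords[pairs[:, 1]], axis=1
        )
        net = SpringNetwork(pairs=pairs, lengths=lengths)
        field = DisplacementField(
            vectors=np.tile([0.3, -0.2, 0.9], (len(open_s), 1))
        )
        assert delta_u(net, open_s, field, amplitude=2.5) < 1e-18

    def test_hand_computed_two_atom_case(self):
        protein = make_structure([[0.0, 0.0, 0.0], [4.0, 0.0, 0.0]])
        net = SpringNetwork(pairs=np.array([[0, 1]]), lengths=np.array([4.0]))
        field = DisplacementField(vectors=np.array([[-1.0, 0, 0], [1.0, 0, 0]]))
        # stretched to 6; (1/2)(6-4)^2 = 2
        assert delta_u(net, protein, field, amplitude=1.0) == pytest.approx(2.0)

    def test_oracle_equivalence(self, rng):
        for _ in range(10):
            coords = rng.uniform(-12, 12, size=(12, 3))
            probe = rng.uniform(-10, 10, size=(3, 3))
            protein = make_structure(coords)
            net = build_spring_network(protein, probe)
            disp = rng.standard_normal((12, 3)) * 0.4
            field = DisplacementField(vectors=disp)
            mine = delta_u(net, protein, field, amplitude=1.3)
            oracle = brute_force_delta_u(
                coords, list(map(tuple, net.pairs)), net.lengths, disp, 1.3
            )
            assert mine == pytest.approx(oracle, abs=1e-9)

    def test_rotation_field_vanishes_quadratically(self, hinge):
        # infinitesimal rotation: ΔU(a)/a² -> 0 as a -> 0
        open_s, _, _ = hinge
        ii, jj = np.triu_indices(len(open_s), k=1)
        pairs = np.stack([ii[:300], jj[:300]], axis=1)
        lengths = np.linalg.norm(
            open_s.coords[pairs[:, 0]] - open_s.coords[pairs[:, 1]], axis=1
        )
        net = SpringNetwork(pairs=pairs, lengths=lengths)
        axis = np.array([0.0, 0.0, 1.0])
        center = open_s.coords.mean(axis=0)
        rot_field = np.cross(axis, open_s.coords - center)
        rot_field /= np.linalg.norm(rot_field.ravel())
        field = DisplacementField(vectors=rot_field)
        ratios = [
            delta_u(net, open_s, field, amplitude=a) / a**2 for a in (1.0, 0.1, 0.01)
        ]
        assert ratios[1] < ratios[0] / 10
        assert ratios[2] < ratios[0] / 1000

    def test_harmonic_limit_for_stretching_field(self, hinge, hinge_dx):
        open_s, _, _ = hinge
        ii, jj = np.triu_indices(len(open_s), k=1)
        pairs = np.stack([ii[:300], jj[:300]], axis=1)
        lengths = np.linalg.norm(
            open_s.coords[pairs[:, 0]] - open_s.coords[pairs[:, 1]], axis=1
        )
        net = SpringNetwork(pairs=pairs, lengths=lengths)
        r1 = delta_u(net, open_s, hinge_dx, amplitude=1e-3) / 1e-6
        r2 = delta_u(net, open_s, hinge_dx, amplitude=1e-4) / 1e-8
        assert r1 == pytest.approx(r2, rel=1e-2)

    def test_monotone_in_amplitude(self, hinge, hinge_dx):
        open_s, _, _ = hinge
        ii, jj = np.triu_indices(len(open_s), k=1)
        pairs = np.stack([ii[:300], jj[:300]], axis=1)
        lengths = np.linalg.norm(
            open_s.coords[pairs[:, 0]] - open_s.coords[pairs[:, 1]], axis=1
        )
        net = SpringNetwork(pairs=pairs, lengths=lengths)
        values = [
            delta_u(net, open_s, hinge_dx, amplitude=a) for a in (0.5, 1.0, 2.0, 4.0)
        ]
        assert np.all(np.diff(values) > 0)


class TestBindingLeverage:
    def test_single_mode_equals_delta_u(self, hinge, hinge_modes, hinge_locations):
        open_s, _, _ = hinge
        loc = hinge_locations[0]
        score = binding_leverage(loc, open_s, hinge_modes, [2])
        net = build_spring_network(open_s, loc.final_probe_coords)
        assert score.value == pytest.approx(
            delta_u(net, open_s, hinge_modes.mode_field(2))
        )

    def test_additivity(self, hinge, hinge_modes, hinge_locations):
        open_s, _, _ = hinge
        loc = hinge_locations[0]
        l12 = binding_leverage(loc, open_s, hinge_modes, [1, 2]).value
        l1 = binding_leverage(loc, open_s, hinge_modes, [1]).value
        l2 = binding_leverage(loc, open_s, hinge_modes, [2]).value
        assert l12 == pytest.approx(l1 + l2)

    def test_empty_subset_errors(self, hinge, hinge_modes, hinge_locations):
        open_s, _, _ = hinge
        with pytest.raises(ValueError):
            binding_leverage(hinge_locations[0], open_s, hinge_modes, [])

    def test_cleft_location_beats_median(self, hinge, hinge_modes, hinge_locations):
        open_s, _, truth = hinge
        lf10 = select_modes(hinge_modes, "LF10")
        scores = [
            binding_leverage(loc, open_s, hinge_modes, lf10).value
            for loc in hinge_locations
        ]
        best = max(range(len(hinge_locations)),
                   key=lambda i: len(hinge_locations[i].residues & truth))
        assert scores[best] > np.median(scores)

    def test_empty_network_warns_and_zero(self, hinge, hinge_modes):
        open_s, _, _ = hinge
        far_probe = open_s.coords.mean(axis=0) + np.array([500.0, 0.0, 0.0])
        with pytest.warns(UserWarning, match="empty spring network"):
            score = binding_leverage(
                far_probe.reshape(1, 3), open_s, hinge_modes, [0]
            )
        assert score.value == 0.0
        assert score.empty_network


class TestLeverageFromDifference:
    def test_mode_as_difference(self, hinge, hinge_modes, hinge_locations):
        open_s, _, _ = hinge
        loc = hinge_locations[0]
        dx = hinge_modes.mode_field(0)
        via_dx = leverage_from_difference(loc, open_s, dx).value
        via_mode = binding_leverage(loc, open_s, hinge_modes, [0]).value
        assert via_dx == pytest.approx(via_mode)

    def test_amplitude_zero(self, hinge, hinge_dx, hinge_locations):
        open_s, _, _ = hinge
        assert (
            leverage_from_difference(
                hinge_locations[0], open_s, hinge_dx, amplitude=0.0
            ).value
            == 0.0
        )

    def test_cleft_beats_lobe_surface(self, hinge, hinge_dx, hinge_locations):
        open_s, _, truth = hinge
        in_cleft = [l for l in hinge_locations if len(l.residues & truth) / len(truth) > 0.5]
        outside = [l for l in hinge_locations if not (l.residues & truth)]
        assert in_cleft and outside
        lev_in = np.median(
            [leverage_from_difference(l, open_s, hinge_dx).value for l in in_cleft]
        )
        lev_out = np.median(
            [leverage_from_difference(l, open_s, hinge_dx).value for l in outside]
        )
        assert lev_in > lev_out
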