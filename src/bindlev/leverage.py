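"""Binding leverage: spring networks through a bound probe and their strain.

For a probe resting in a pocket, springs of natural length d_ij are placed
between every Cα pair (i, j) whose connecting segment passes within 3.5 Å
of any probe atom.  The leverage of the pocket under a motion v is the
harmonic strain ΔU = Σ ½(|x_i + a·v_i − x_j − a·v_j| − d_ij)² summed over
those springs (unit spring constant, amplitude a = 1 on unit-normalized
motions by default); summed over a mode subset this gives L_A, and applied
to a crystal-structure difference vector it gives L_Δ.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from bindlev.elastic_modes import ModeSet
from bindlev.structure_io import CalphaStructure, DisplacementField

__all__ = [
    "SpringNetwork",
    "LeverageScore",
    "build_spring_network",
    "delta_u",
    "binding_leverage",
    "leverage_from_difference",
]

#: A Cα pair is spring-connected when its segment passes this close (Å) to a probe atom.
SEGMENT_CUTOFF = 3.5


@dataclass(frozen=True)
class SpringNetwork:
    """Springs between residue pairs whose connecting segment crosses the probe."""

    pairs: np.ndarray  # (P, 2) int, i < j
    lengths: np.ndarray  # (P,) natural lengths d_ij in Å

    def __post_init__(self) -> None:
        pairs = np.asarray(self.pairs, dtype=int).reshape(-1, 2)
        lengths = np.asarray(self.lengths, dtype=float).reshape(-1)
        if pairs.shape[0] != lengths.shape[0]:
            raise ValueError("pairs/lengths mismatch")
        if pairs.size and np.any(pairs[:, 0] >= pairs[:, 1]):
            raise ValueError("pairs must satisfy i < j")
        object.__setattr__(self, "pairs", pairs)
        object.__setattr__(self, "lengths", lengths)

    @property
    def n_springs(self) -> int:
        return self.pairs.shape[0]


@dataclass(frozen=True)
class LeverageScore:
    """Leverage of one probe location under a named mode set or Δx."""

    mode_set_name: str
    value: float
    n_springs: int
    empty_network: bool = False

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("leverage cannot be negative")


def _segment_point_distances(
    a: np.ndarray, b: np.ndarray, points: np.ndarray
) -> np.ndarray:
    """Min distance from each segment [a_p, b_p] to the nearest of ``points``.

    a, b: (P, 3) segment endpoints; points: (K, 3).  Returns (P,).
    """
    ab = b - a  # (P, 3)
    ab2 = np.einsum("ij,ij->i", ab, ab)  # (P,)
    ap = points[None, :, :] - a[:, None, :]  # (P, K, 3)
    t = np.einsum("pkj,pj->pk", ap, ab) / np.where(ab2 > 0, ab2, 1.0)[:, None]
    t = np.clip(t, 0.0, 1.0)
    closest = a[:, None, :] + t[:, :, None] * ab[:, None, :]
    d = np.linalg.norm(points[None, :, :] - closest, axis=-1)
    return d.min(axis=1)


def build_spring_network(
    protein: CalphaStructure,
    probe_coords: np.ndarray,
    cutoff: float = SEGMENT_CUTOFF,
    max_pair_distance: float | None = None,
) -> SpringNetwork:
    """All Cα pairs whose connecting segment passes within ``cutoff`` of the probe.

    Every residue pair is eligible regardless of sequence separation;
    ``max_pair_distance`` is an optional knob to cap the spanned Cα–Cα
    distance.  The connecting line is the finite segment between the two
    Cα positions, not the infinite line.
    """
    probe = np.asarray(probe_coords, dtype=float).reshape(-1, 3)
    if probe.shape[0] == 0:
        raise ValueError("empty probe")
    coords = protein.coords
    n = coords.shape[0]
    ii, jj = np.triu_indices(n, k=1)
    if max_pair_distance is not None:
        d_pair = np.linalg.norm(coords[ii] - coords[jj], axis=1)
        keep = d_pair <= max_pair_distance
        ii, jj = ii[keep], jj[keep]
    # cheap prefilter: segment can only come near a probe atom if at least one
    # endpoint midpoint-sphere overlaps the probe's bounding sphere
    mid = (coords[ii] + coords[jj]) / 2.0
    half = np.linalg.norm(coords[ii] - coords[jj], axis=1) / 2.0
    centroid = probe.mean(axis=0)
    r_probe = np.max(np.linalg.norm(probe - centroid, axis=1)) if probe.shape[0] else 0.0
    near = np.linalg.norm(mid - centroid, axis=1) <= half + r_probe + cutoff + 1e-9
    ii, jj = ii[near], jj[near]
    if ii.size == 0:
        return SpringNetwork(pairs=np.empty((0, 2), dtype=int), lengths=np.empty(0))
    dmin = _segment_point_distances(coords[ii], coords[jj], probe)
    hit = dmin <= cutoff
    pairs = np.stack([ii[hit], jj[hit]], axis=1)
    lengths = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
    return SpringNetwork(pairs=pairs, lengths=lengths)


def delta_u(
    network: SpringNetwork,
    protein: CalphaStructure,
    displacement: DisplacementField,
    amplitude: float = 1.0,
) -> float:
    """Harmonic spring-strain energy ΔU of a displacement, unit spring constant."""
    if displacement.n_atoms != len(protein):
        raise ValueError("displacement does not match protein")
    if network.n_springs == 0:
        return 0.0
    moved = protein.coords + amplitude * displacement.vectors
    new_len = np.linalg.norm(
        moved[network.pairs[:, 0]] - moved[network.pairs[:, 1]], axis=1
    )
    return float(0.5 * np.sum((new_len - network.lengths) ** 2))


def binding_leverage(
    location,
    protein: CalphaStructure,
    modes: ModeSet,
    subset: np.ndarray,
    amplitude: float = 1.0,
    mode_set_name: str = "custom",
) -> LeverageScore:
    """L_A: summed ΔU over the modes in ``subset`` for one probe location.

    ``location`` may be a ProbeLocation or a raw (k, 3) probe-coordinate
    array; the spring network is built from the final probe configuration.
    """
    subset = np.asarray(subset, dtype=int).reshape(-1)
    if subset.size == 0:
        raise ValueError("empty mode subset")
    probe = getattr(location, "final_probe_coords", location)
    network = build_spring_network(protein, probe)
    if network.n_springs == 0:
        warnings.warn("probe location yields an empty spring network; leverage 0")
        return LeverageScore(
            mode_set_name=mode_set_name, value=0.0, n_springs=0, empty_network=True
        )
    total = 0.0
    for k in subset:
        total += delta_u(network, protein, modes.mode_field(int(k)), amplitude)
    return LeverageScore(
        mode_set_name=mode_set_name, value=total, n_springs=network.n_springs
    )


def leverage_from_difference(
    location,
    protein: CalphaStructure,
    dx: DisplacementField,
    amplitude: float = 1.0,
) -> LeverageScore:
    """L_Δ: the single ΔU of the crystal-structure difference vector."""
    probe = getattr(location, "final_probe_coords", location)
    network = build_spring_network(protein, probe)
    if network.n_springs == 0:
        warnings.warn("probe location yields an empty spring network; leverage 0")
        return LeverageScore(
            mode_set_name="delta", value=0.0, n_springs=0, empty_network=True
        )
    value = delta_u(network, protein, dx, amplitude)
    return LeverageScore(
        mode_set_name="delta", value=value, n_springs=network.n_springs
    )
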