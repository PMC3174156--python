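"""Synthetic test structures with planted ground truth.

Two generators cover the method's needs without any downloads:

* :func:`make_hinge_protein` — a two-lobe Cα chain (coarse helical
  solenoid lobes joined by a linker) whose closed form rotates one lobe
  about the hinge; the cleft between the lobes is the planted pocket and
  couples maximally to the hinge motion.
* :func:`make_decoy_with_planted_pocket` — a compact self-avoiding globule
  with a concave pocket of controllable depth.

Everything is seed-deterministic, satisfies the CalphaStructure invariants
and uses realistic 3.8 Å backbone spacing.
"""

from __future__ import annotations

import numpy as np

from bindlev.structure_io import (
    CalphaStructure,
    HeavyStructure,
    LigandRecord,
    write_calpha_pdb,
)

__all__ = [
    "make_hinge_protein",
    "make_decoy_with_planted_pocket",
    "make_dimer",
    "decorate_heavy",
    "write_fixture_pdb",
]

_BOND = 3.8


def _helix_points(n: int, radius: float, rise: float) -> np.ndarray:
    """n points on a coarse solenoid along +z with exact 3.8 Å chords."""
    chord_xy = np.sqrt(_BOND**2 - rise**2)
    delta = 2.0 * np.arcsin(chord_xy / (2.0 * radius))
    m = np.arange(n)
    return np.stack(
        [
            radius * np.cos(m * delta),
            radius * np.sin(m * delta),
            m * rise,
        ],
        axis=1,
    )


def _frame(axis: np.ndarray) -> np.ndarray:
    """Rotation matrix sending +z to ``axis`` (columns = new frame)."""
    w = axis / np.linalg.norm(axis)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(w @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(w, helper)
    u /= np.linalg.norm(u)
    v = np.cross(w, u)
    return np.stack([u, v, w], axis=1)


def _resample_arc(points: np.ndarray, n_out: int) -> np.ndarray:
    """Evenly respace a polyline to n_out points by arc length."""
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    t = np.linspace(0.0, s[-1], n_out)
    out = np.empty((n_out, 3))
    for c in range(3):
        out[:, c] = np.interp(t, s, points[:, c])
    return out


def _rotation_about_y(angle_rad: float) -> np.ndarray:
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def _as_structure(coords: np.ndarray, source_id: str) -> CalphaStructure:
    n = coords.shape[0]
    return CalphaStructure(
        chain_ids=("A",) * n,
        res_seqs=tuple(range(1, n + 1)),
        icodes=("",) * n,
        res_names=("ALA",) * n,
        coords=coords,
        source_id=source_id,
    )


def make_hinge_protein(
    n_per_lobe: int = 36,
    hinge_angle: float = 15.0,
    seed: int = 0,
    half_opening_deg: float = 32.0,
    lobe_radius: float = 4.5,
    lobe_rise: float = 0.6,
    lobe_offset: float = 6.0,
) -> tuple[CalphaStructure, CalphaStructure, frozenset]:
    """Two-conformation hinge fixture with the inter-lobe cleft as pocket truth.

    The open form is a V of two solenoid lobes joined by a short linker at
    the vertex; the closed form rotates the second lobe (and its half of
    the linker) by ``hinge_angle`` degrees about the hinge axis, narrowing
    the cleft.  Returns ``(open, closed, pocket_truth)`` where pocket truth
    is the set of residue handles lining the cleft.
    """
    if n_per_lobe < 10:
        raise ValueError("n_per_lobe must be >= 10")
    if not 0.0 < hinge_angle <= 60.0:
        raise ValueError("hinge_angle must be in (0, 60] degrees")
    rng = np.random.default_rng(seed)
    gamma = np.radians(half_opening_deg)
    d1 = np.array([np.cos(gamma), 0.0, np.sin(gamma)])
    d2 = np.array([np.cos(gamma), 0.0, -np.sin(gamma)])
    local = _helix_points(n_per_lobe, lobe_radius, lobe_rise)
    lobe1 = (local @ _frame(d1).T) + lobe_offset * d1
    lobe2 = (local @ _frame(d2).T) + lobe_offset * d2
    # chain runs tip -> vertex (lobe 1), linker, vertex -> tip (lobe 2)
    lobe1 = lobe1[::-1]
    p_end, q_start = lobe1[-1], lobe2[0]
    bow = (p_end + q_start) / 2.0
    bow[0] -= 7.0  # bulge the linker away from the cleft (which opens to +x)
    t_dense = np.linspace(0.0, 1.0, 200)[:, None]
    bez = (1 - t_dense) ** 2 * p_end + 2 * t_dense * (1 - t_dense) * bow + t_dense**2 * q_start
    arc = float(np.sum(np.linalg.norm(np.diff(bez, axis=0), axis=1)))
    n_link = max(2, int(round(arc / _BOND)) - 1)
    linker = _resample_arc(bez, n_link + 2)[1:-1]
    coords_open = np.vstack([lobe1, linker, lobe2])
    # tiny deterministic jitter breaks exact symmetries without hurting bonds
    coords_open = coords_open + 0.05 * rng.standard_normal(coords_open.shape)

    n_total = coords_open.shape[0]
    moving = np.zeros(n_total, dtype=bool)
    moving[n_per_lobe + n_link // 2 :] = True  # lobe 2 plus its linker half
    rot = _rotation_about_y(-np.radians(hinge_angle))
    coords_closed = coords_open.copy()
    coords_closed[moving] = coords_closed[moving] @ rot.T

    # cleft truth: the midline region where a probe can sit in the attractive
    # well of both lobes.  Walk out from the vertex to where the cleft opens
    # to >= 6.5 Å and take the residues lining that zone.
    x_c = None
    for x in np.arange(lobe_offset, coords_open[:, 0].max() + 8.0, 0.5):
        gap = np.min(np.linalg.norm(coords_open - np.array([x, 0.0, 0.0]), axis=1))
        if gap >= 6.5:
            x_c = x + 1.5
            break
    if x_c is None:
        raise RuntimeError("hinge fixture has no open cleft; adjust geometry")
    cleft_center = np.array([x_c, 0.0, 0.0])
    dist = np.linalg.norm(coords_open - cleft_center, axis=1)
    pocket_truth = frozenset(int(i) for i in np.flatnonzero(dist < 10.5))

    open_s = _as_structure(coords_open, f"hinge-open-{seed}")
    closed_s = _as_structure(coords_closed, f"hinge-closed-{seed}")
    return open_s, closed_s, pocket_truth


def make_decoy_with_planted_pocket(
    n_residues: int = 60,
    pocket_depth: float = 6.0,
    seed: int = 0,
) -> tuple[CalphaStructure, frozenset]:
    """Compact Cα shell globule with one concave surface pocket.

    The chain winds along a closed spherical spiral (adjacent windings
    ~4.2 Å apart, impenetrable to the probe's 4.5 Å hard core) with a
    Gaussian radial dent of ``pocket_depth`` Å planted on the equator;
    deeper dents are more concave and bind the probe more strongly.
    ``n_residues`` is a lower bound — the closed shell may need a few
    extra residues.  Pocket truth is the set of residues inside the dent's
    angular footprint.
    """
    if n_residues < 30:
        raise ValueError("n_residues must be >= 30")
    if not 0.0 <= pocket_depth <= 5.0:
        raise ValueError("pocket_depth must be in [0, 5] Å (deeper tears the surface)")
    rng = np.random.default_rng(seed)
    sigma = 0.7  # angular half-width of the dent, radians
    pocket_axis = np.array([1.0, 0.0, 0.0])  # dent centered on the equator

    def spiral(radius: float, depth: float) -> np.ndarray:
        """Chain along a spherical spiral with 3.8 Å chords and a radial dent."""
        turns = np.pi * radius / 4.2  # ~4.2 Å between adjacent windings
        points = []
        theta = 1e-3
        while theta < np.pi - 1e-3:
            phi = turns * theta
            unit = np.array(
                [
                    np.sin(theta) * np.cos(phi),
                    np.sin(theta) * np.sin(phi),
                    np.cos(theta),
                ]
            )
            omega = np.arccos(np.clip(unit @ pocket_axis, -1.0, 1.0))
            r = radius - depth * np.exp(-(omega**2) / (2.0 * sigma**2))
            point = r * unit
            if not points or np.linalg.norm(point - points[-1]) >= _BOND:
                if points:  # bisect back to an exact 3.8 Å chord
                    lo, hi = prev_theta, theta
                    for _ in range(40):
                        mid = 0.5 * (lo + hi)
                        phi_m = turns * mid
                        u_m = np.array(
                            [
                                np.sin(mid) * np.cos(phi_m),
                                np.sin(mid) * np.sin(phi_m),
                                np.cos(mid),
                            ]
                        )
                        om = np.arccos(np.clip(u_m @ pocket_axis, -1.0, 1.0))
                        r_m = radius - depth * np.exp(-(om**2) / (2.0 * sigma**2))
                        if np.linalg.norm(r_m * u_m - points[-1]) >= _BOND:
                            hi = mid
                        else:
                            lo = mid
                    phi_m = turns * hi
                    u_m = np.array(
                        [
                            np.sin(hi) * np.cos(phi_m),
                            np.sin(hi) * np.sin(phi_m),
                            np.cos(hi),
                        ]
                    )
                    om = np.arccos(np.clip(u_m @ pocket_axis, -1.0, 1.0))
                    r_m = radius - depth * np.exp(-(om**2) / (2.0 * sigma**2))
                    point = r_m * u_m
                    theta = hi
                points.append(point)
                prev_theta = theta
            theta += 1e-3
        return np.array(points)

    def solid(radius: float) -> tuple[np.ndarray, list[int]]:
        """Concentric dented shells 4.4 Å apart; returns coords and shell sizes.

        Inner shells dent proportionally so layer spacing survives the dent.
        """
        layers = []
        r = radius
        while r > 3.5:
            layers.append(spiral(r, pocket_depth * r / radius))
            r -= 4.4
        coords = np.vstack(layers)
        return coords, [len(l) for l in layers]

    # fit the outer radius so the filled ball holds at least n_residues points
    radius = max(np.sqrt(n_residues * _BOND * 4.2 / (4.0 * np.pi)) * 0.85, 7.5)
    coords, shell_sizes = solid(radius)
    for _ in range(60):
        if coords.shape[0] >= n_residues:
            break
        radius *= 1.02
        coords, shell_sizes = solid(radius)
    else:
        raise RuntimeError("could not fit the requested residue count in the globule")
    # whole closed shells are kept (truncation would puncture the surface);
    # the residue count may somewhat exceed the requested minimum
    coords = coords + 0.03 * rng.standard_normal(coords.shape)  # break symmetry

    # pocket truth: residues lining the dent around the deepest point a
    # hard-core probe atom can actually reach along the dent axis
    anchor = None
    for t in np.arange(radius + 5.0, 0.0, -0.25):
        point = t * pocket_axis
        if np.min(np.linalg.norm(coords - point, axis=1)) < 4.6:
            break
        anchor = point
    if anchor is None:
        raise RuntimeError("decoy dent is not probe-accessible")
    dist = np.linalg.norm(coords - anchor, axis=1)
    pocket_truth = frozenset(int(i) for i in np.flatnonzero(dist < 8.0))

    # one chain per shell, outermost first
    chain_ids = []
    res_seqs = []
    for layer, size in enumerate(shell_sizes):
        chain_ids += [chr(ord("A") + layer)] * size
        res_seqs += list(range(1, size + 1))
    structure = CalphaStructure(
        chain_ids=tuple(chain_ids),
        res_seqs=tuple(res_seqs),
        icodes=("",) * len(chain_ids),
        res_names=("ALA",) * len(chain_ids),
        coords=coords,
        source_id=f"decoy-{seed}",
    )
    return structure, pocket_truth


def make_dimer(structure: CalphaStructure, offset: float = 30.0) -> CalphaStructure:
    """Two-copy assembly: the input plus a translated copy with remapped chains."""
    n = len(structure)
    shift = np.array([offset, 0.0, 0.0])
    n_chains = len(set(structure.chain_ids))
    copy_chains = tuple(chr(ord(c) + n_chains) for c in structure.chain_ids)
    return CalphaStructure(
        chain_ids=structure.chain_ids + copy_chains,
        res_seqs=structure.res_seqs * 2,
        icodes=structure.icodes * 2,
        res_names=structure.res_names * 2,
        coords=np.vstack([structure.coords, structure.coords + shift]),
        source_id=structure.source_id + "-dimer",
    )


_TETRA = np.array(
    [
        [1.0, 1.0, 1.0],
        [1.0, -1.0, -1.0],
        [-1.0, 1.0, -1.0],
        [-1.0, -1.0, 1.0],
    ]
) / np.sqrt(3.0)


def decorate_heavy(
    structure: CalphaStructure, radius: float = 1.8, seed: int = 0
) -> HeavyStructure:
    """Pseudo-heavy-atom decoration: the Cα plus 4 dummy atoms per residue.

    Gives Cα-only fixtures enough atoms to exercise the heavy-atom code
    paths (ligand-contact sites, residue interaction graph).
    """
    rng = np.random.default_rng(seed)
    coords = []
    ridx = []
    for i in range(len(structure)):
        axis = rng.standard_normal(3)
        axis /= np.linalg.norm(axis)
        angle = rng.uniform(0.0, 2.0 * np.pi)
        c, s = np.cos(angle), np.sin(angle)
        k = axis
        rot = (
            c * np.eye(3)
            + s * np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
            + (1 - c) * np.outer(k, k)
        )
        coords.append(structure.coords[i])
        ridx.append(i)
        for d in _TETRA @ rot.T:
            coords.append(structure.coords[i] + radius * d)
            ridx.append(i)
    return HeavyStructure(
        coords=np.array(coords),
        residue_index=np.array(ridx, dtype=int),
        n_residues=len(structure),
    )


def write_fixture_pdb(
    structure: CalphaStructure, ligand: LigandRecord | None = None
) -> str:
    """PDB text that round-trips through load_calpha / extract_ligands."""
    return write_calpha_pdb(structure, ligand=ligand)
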