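"""Metropolis Monte Carlo docking of a flexible Cα-chain probe.

The probe is a chain of 2–8 pseudo-Cα atoms with fixed 3.8 Å bonds and
bond angles restricted to [90°, 180°], moving over a rigid protein Cα
trace in a periodic cubic box (side = twice the protein's maximum extent
by default).  Probe–protein atom pairs interact through a stepped square
well: −1ε for 5.5–8 Å, +3ε for 5.0–5.5 Å, +10ε for 4.5–5.0 Å, hard wall
below 4.5 Å, with ε = 0.75 kT.  Probe atoms do not interact with each
other beyond the geometric constraints.

Each short simulation starts from a random contact-free configuration;
the protein residues within 8 Å of the final probe configuration form a
*probe location*, the unit of site prediction.  The hot loop is JIT
compiled with numba; energies are updated incrementally (only moved atoms
recomputed) and validated against a from-scratch total at run end.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from numba import njit

from bindlev.structure_io import CalphaStructure

__all__ = [
    "BOND_LENGTH",
    "CONTACT_RANGE",
    "HARD_CORE",
    "SimulationConfig",
    "ProbeState",
    "ProbeLocation",
    "pair_energy",
    "total_energy",
    "run_probe_simulation",
    "generate_probe_locations",
]

logger = logging.getLogger(__name__)

BOND_LENGTH = 3.8  # Å, fixed probe Cα–Cα spacing
HARD_CORE = 4.5  # Å, minimum allowed probe–protein distance
CONTACT_RANGE = 8.0  # Å, outer edge of the square well; defines locations
EPSILON_KT = 0.75  # well depth ε in kT

FORBIDDEN = math.inf


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one batch of probe-docking simulations.

    ``n_steps``/``n_sims``/``box_side`` default to the published heuristics
    (1000 × box side in Å, 10 × residue count, 2 × maximum protein extent)
    when left as None.  Move amplitudes are unpublished; the defaults below
    give ~30–60 % acceptance on compact fixtures.
    """

    probe_size: int = 4
    n_steps: int | None = None
    n_sims: int | None = None
    seed: int = 0
    kT: float = 1.0
    epsilon: float = EPSILON_KT
    box_side: float | None = None
    translation_step: float = 1.5  # Å, uniform in a ball
    rotation_step_deg: float = 30.0  # rigid rotations and pivots, uniform ±
    jump_probability: float = 0.1  # chance of a large rigid translation instead
    jump_step: float | None = None  # Å, jump radius; defaults to box_side / 2
    contact_cutoff: float = CONTACT_RANGE
    max_init_retries: int = 10_000

    def __post_init__(self) -> None:
        if not 2 <= self.probe_size <= 8:
            raise ValueError("probe_size must be in [2, 8]")
        if self.n_steps is not None and self.n_steps < 0:
            raise ValueError("n_steps must be >= 0")
        if self.n_sims is not None and self.n_sims < 1:
            raise ValueError("n_sims must be >= 1")
        if self.kT <= 0 or self.epsilon <= 0:
            raise ValueError("kT and epsilon must be positive")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)

    def resolve(self, protein: CalphaStructure) -> "SimulationConfig":
        """Fill in the protein-dependent defaults."""
        extent = float(np.max(protein.coords.max(axis=0) - protein.coords.min(axis=0)))
        box = self.box_side if self.box_side is not None else 2.0 * extent
        steps = self.n_steps if self.n_steps is not None else int(round(1000 * box))
        sims = self.n_sims if self.n_sims is not None else 10 * len(protein)
        return replace(self, box_side=box, n_steps=steps, n_sims=sims)


class ProbeState:
    """Validated probe-chain coordinates (k, 3)."""

    __slots__ = ("coords",)

    def __init__(self, coords: np.ndarray):
        coords = np.asarray(coords, dtype=float).reshape(-1, 3)
        k = coords.shape[0]
        if not 2 <= k <= 8:
            raise ValueError("probe size must be in [2, 8]")
        bonds = np.linalg.norm(np.diff(coords, axis=0), axis=1)
        if np.any(np.abs(bonds - BOND_LENGTH) > 1e-9):
            raise ValueError(f"probe bonds deviate from {BOND_LENGTH} Å: {bonds}")
        for j in range(1, k - 1):
            u = coords[j - 1] - coords[j]
            v = coords[j + 1] - coords[j]
            cosang = float(u @ v) / (BOND_LENGTH * BOND_LENGTH)
            if cosang > 1e-9:  # angle < 90°
                raise ValueError(f"bond angle at probe atom {j} below 90°")
        self.coords = coords

    def __len__(self) -> int:
        return self.coords.shape[0]


@dataclass(frozen=True)
class ProbeLocation:
    """End configuration of one docking run, reduced to contacted residues."""

    residues: frozenset
    final_probe_coords: np.ndarray  # (k, 3)
    final_energy: float  # kT units
    sim_seed: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", frozenset(int(r) for r in self.residues))
        object.__setattr__(
            self,
            "final_probe_coords",
            np.asarray(self.final_probe_coords, dtype=float).reshape(-1, 3),
        )

    @property
    def is_empty(self) -> bool:
        return len(self.residues) == 0


def pair_energy(d: float) -> float:
    """Stepped square-well probe–protein pair energy in ε units.

    −1 in the attractive well [5.5, 8] Å, +3 in [5.0, 5.5), +10 in
    [4.5, 5.0), 0 beyond 8 Å, and ``inf`` (forbidden) below 4.5 Å.
    """
    if d <= 0:
        raise ValueError("distance must be positive")
    if d < HARD_CORE:
        return FORBIDDEN
    if d < 5.0:
        return 10.0
    if d < 5.5:
        return 3.0
    if d <= CONTACT_RANGE:
        return -1.0
    return 0.0


def total_energy(
    probe: ProbeState | np.ndarray,
    protein: CalphaStructure,
    box_side: float,
) -> float:
    """Sum of pair energies over all probe×protein pairs, minimum image.

    Returned in ε units; ``inf`` when any pair violates the hard core.
    """
    coords = probe.coords if isinstance(probe, ProbeState) else np.asarray(probe, float)
    e, forbidden = _energy_range(
        protein.coords, coords.reshape(-1, 3), 0, coords.reshape(-1, 3).shape[0], box_side
    )
    return FORBIDDEN if forbidden else float(e)


# ---------------------------------------------------------------------------
# numba kernels


@njit(cache=True)
def _nint(x):
    return math.floor(x + 0.5)


@njit(cache=True)
def _atom_energy(prot, probe, a, box):
    """Energy (ε units) of probe atom ``a`` against the protein; inf if forbidden."""
    e = 0.0
    for p in range(prot.shape[0]):
        d2 = 0.0
        for c in range(3):
            dx = probe[a, c] - prot[p, c]
            dx -= box * _nint(dx / box)
            d2 += dx * dx
        if d2 < 20.25:  # 4.5^2
            return math.inf
        if d2 < 25.0:  # 5.0^2
            e += 10.0
        elif d2 < 30.25:  # 5.5^2
            e += 3.0
        elif d2 <= 64.0:  # 8.0^2
            e += -1.0
    return e


@njit(cache=True)
def _energy_range(prot, probe, start, end, box):
    """Energy (ε units) of probe atoms [start, end) against the protein."""
    e = 0.0
    for a in range(start, end):
        ea = _atom_energy(prot, probe, a, box)
        if ea == math.inf:
            return 0.0, True
        e += ea
    return e, False


@njit(cache=True)
def _min_clearance2(prot, probe, box):
    best = 1e30
    for a in range(probe.shape[0]):
        for p in range(prot.shape[0]):
            d2 = 0.0
            for c in range(3):
                dx = probe[a, c] - prot[p, c]
                dx -= box * _nint(dx / box)
                d2 += dx * dx
            if d2 < best:
                best = d2
    return best


@njit(cache=True)
def _random_unit_vector():
    while True:
        x = np.random.normal()
        y = np.random.normal()
        z = np.random.normal()
        n2 = x * x + y * y + z * z
        if n2 > 1e-12:
            n = math.sqrt(n2)
            return x / n, y / n, z / n


@njit(cache=True)
def _rotate_range(coords, start, end, ox, oy, oz, ux, uy, uz, angle):
    """Rodrigues rotation of atoms [start, end) about axis u through (ox,oy,oz)."""
    ca = math.cos(angle)
    sa = math.sin(angle)
    for a in range(start, end):
        px = coords[a, 0] - ox
        py = coords[a, 1] - oy
        pz = coords[a, 2] - oz
        dot = px * ux + py * uy + pz * uz
        cx = uy * pz - uz * py
        cy = uz * px - ux * pz
        cz = ux * py - uy * px
        coords[a, 0] = ox + px * ca + cx * sa + ux * dot * (1.0 - ca)
        coords[a, 1] = oy + py * ca + cy * sa + uy * dot * (1.0 - ca)
        coords[a, 2] = oz + pz * ca + cz * sa + uz * dot * (1.0 - ca)


@njit(cache=True)
def _chain_angles_ok(coords, j):
    """Bond angle at interior atom j within [90°, 180°] (cos ≤ 0)."""
    ux = coords[j - 1, 0] - coords[j, 0]
    uy = coords[j - 1, 1] - coords[j, 1]
    uz = coords[j - 1, 2] - coords[j, 2]
    vx = coords[j + 1, 0] - coords[j, 0]
    vy = coords[j + 1, 1] - coords[j, 1]
    vz = coords[j + 1, 2] - coords[j, 2]
    return ux * vx + uy * vy + uz * vz <= 1e-9


@njit(cache=True)
def _initial_probe(prot, k, box, cx, cy, cz, max_retries):
    """Random contact-free probe chain (all clearances > 8 Å), or failure."""
    probe = np.zeros((k, 3))
    for attempt in range(max_retries):
        # build a random chain in a local frame
        probe[0, 0] = 0.0
        probe[0, 1] = 0.0
        probe[0, 2] = 0.0
        bx, by, bz = _random_unit_vector()
        probe[1, 0] = BOND_LENGTH * bx
        probe[1, 1] = BOND_LENGTH * by
        probe[1, 2] = BOND_LENGTH * bz
        for i in range(2, k):
            while True:
                nx, ny, nz = _random_unit_vector()
                if nx * bx + ny * by + nz * bz >= 0.0:  # bond angle >= 90°
                    break
            probe[i, 0] = probe[i - 1, 0] + BOND_LENGTH * nx
            probe[i, 1] = probe[i - 1, 1] + BOND_LENGTH * ny
            probe[i, 2] = probe[i - 1, 2] + BOND_LENGTH * nz
            bx, by, bz = nx, ny, nz
        # random orientation and position inside the box
        ax, ay, az = _random_unit_vector()
        _rotate_range(probe, 0, k, 0.0, 0.0, 0.0, ax, ay, az,
                      np.random.uniform(0.0, 2.0 * math.pi))
        tx = cx + box * (np.random.random() - 0.5)
        ty = cy + box * (np.random.random() - 0.5)
        tz = cz + box * (np.random.random() - 0.5)
        for i in range(k):
            probe[i, 0] += tx
            probe[i, 1] += ty
            probe[i, 2] += tz
        if _min_clearance2(prot, probe, box) > CONTACT_RANGE * CONTACT_RANGE:
            return probe, True
    return probe, False


@njit(cache=True)
def _run_mc(prot, k, n_steps, seed, box, cx, cy, cz, eps, kT,
            tr_step, rot_step, jump_prob, jump_step, max_retries, audit):
    """One full docking run.  Returns (probe, e_incr, e_full, ok, stats).

    stats = [n_accepted, min_clearance, max_bond_dev, max_angle_cos]
    over all accepted (visited) states when ``audit`` is true.
    """
    np.random.seed(seed)
    stats = np.zeros(4)
    stats[1] = 1e30
    stats[3] = -1e30
    probe, ok = _initial_probe(prot, k, box, cx, cy, cz, max_retries)
    if not ok:
        return probe, 0.0, 0.0, False, stats
    e_atom = np.zeros(k)
    for a in range(k):
        e_atom[a] = _atom_energy(prot, probe, a, box)
    e_cur = e_atom.sum()  # contact-free start: cannot be forbidden
    new = probe.copy()
    e_atom_new = np.zeros(k)
    n_move_types = 2
    if k >= 3:
        n_move_types = 3
    if k >= 4:
        n_move_types = 4
    for _step in range(n_steps):
        for i in range(k):
            for c in range(3):
                new[i, c] = probe[i, c]
        m0 = 0
        m1 = k
        angle_check = -1
        if np.random.random() < jump_prob:
            move = -1  # large rigid jump: global relocation between basins
        else:
            move = np.random.randint(n_move_types)
        if move == -1:
            while True:
                dx = np.random.uniform(-1.0, 1.0)
                dy = np.random.uniform(-1.0, 1.0)
                dz = np.random.uniform(-1.0, 1.0)
                if dx * dx + dy * dy + dz * dz <= 1.0:
                    break
            for i in range(k):
                new[i, 0] += jump_step * dx
                new[i, 1] += jump_step * dy
                new[i, 2] += jump_step * dz
        elif move == 0:  # translation in a ball
            while True:
                dx = np.random.uniform(-1.0, 1.0)
                dy = np.random.uniform(-1.0, 1.0)
                dz = np.random.uniform(-1.0, 1.0)
                if dx * dx + dy * dy + dz * dz <= 1.0:
                    break
            for i in range(k):
                new[i, 0] += tr_step * dx
                new[i, 1] += tr_step * dy
                new[i, 2] += tr_step * dz
        elif move == 1:  # rigid rotation about the centroid
            gx = 0.0
            gy = 0.0
            gz = 0.0
            for i in range(k):
                gx += new[i, 0]
                gy += new[i, 1]
                gz += new[i, 2]
            gx /= k
            gy /= k
            gz /= k
            ax, ay, az = _random_unit_vector()
            _rotate_range(new, 0, k, gx, gy, gz, ax, ay, az,
                          np.random.uniform(-rot_step, rot_step))
        elif move == 2:  # bond-angle pivot about an interior atom
            j = 1 + np.random.randint(k - 2)
            ax, ay, az = _random_unit_vector()
            angle = np.random.uniform(-rot_step, rot_step)
            if np.random.random() < 0.5:
                m0 = j + 1
                m1 = k
            else:
                m0 = 0
                m1 = j
            _rotate_range(new, m0, m1, new[j, 0], new[j, 1], new[j, 2],
                          ax, ay, az, angle)
            angle_check = j
        else:  # torsion about an interior bond (j, j+1)
            j = 1 + np.random.randint(k - 3)
            bx = new[j + 1, 0] - new[j, 0]
            by = new[j + 1, 1] - new[j, 1]
            bz = new[j + 1, 2] - new[j, 2]
            bn = math.sqrt(bx * bx + by * by + bz * bz)
            bx /= bn
            by /= bn
            bz /= bn
            angle = np.random.uniform(-rot_step, rot_step)
            if np.random.random() < 0.5:
                m0 = j + 2
                m1 = k
            else:
                m0 = 0
                m1 = j
            _rotate_range(new, m0, m1, new[j, 0], new[j, 1], new[j, 2],
                          bx, by, bz, angle)
        if angle_check >= 0 and not _chain_angles_ok(new, angle_check):
            continue
        e_old_part = 0.0
        for a in range(m0, m1):
            e_old_part += e_atom[a]
        e_new_part = 0.0
        forb = False
        for a in range(m0, m1):
            ea = _atom_energy(prot, new, a, box)
            if ea == math.inf:
                forb = True
                break
            e_atom_new[a] = ea
            e_new_part += ea
        if forb:
            continue
        d_e = eps * (e_new_part - e_old_part)  # kT units
        if d_e <= 0.0 or np.random.random() < math.exp(-d_e / kT):
            for i in range(m0, m1):
                for c in range(3):
                    probe[i, c] = new[i, c]
                e_atom[i] = e_atom_new[i]
            e_cur += e_new_part - e_old_part
            stats[0] += 1.0
            # re-center the probe into the box (rigid shift, minimum image)
            gx = 0.0
            gy = 0.0
            gz = 0.0
            for i in range(k):
                gx += probe[i, 0]
                gy += probe[i, 1]
                gz += probe[i, 2]
            sx = box * _nint((gx / k - cx) / box)
            sy = box * _nint((gy / k - cy) / box)
            sz = box * _nint((gz / k - cz) / box)
            if sx != 0.0 or sy != 0.0 or sz != 0.0:
                for i in range(k):
                    probe[i, 0] -= sx
                    probe[i, 1] -= sy
                    probe[i, 2] -= sz
            if audit:
                c2 = _min_clearance2(prot, probe, box)
                if c2 < stats[1]:
                    stats[1] = c2
                for i in range(k - 1):
                    d2 = 0.0
                    for c in range(3):
                        dd = probe[i + 1, c] - probe[i, c]
                        d2 += dd * dd
                    dev = abs(math.sqrt(d2) - BOND_LENGTH)
                    if dev > stats[2]:
                        stats[2] = dev
                for j in range(1, k - 1):
                    ux = probe[j - 1, 0] - probe[j, 0]
                    uy = probe[j - 1, 1] - probe[j, 1]
                    uz = probe[j - 1, 2] - probe[j, 2]
                    vx = probe[j + 1, 0] - probe[j, 0]
                    vy = probe[j + 1, 1] - probe[j, 1]
                    vz = probe[j + 1, 2] - probe[j, 2]
                    cosang = (ux * vx + uy * vy + uz * vz) / (BOND_LENGTH * BOND_LENGTH)
                    if cosang > stats[3]:
                        stats[3] = cosang
    e_full, _forb = _energy_range(prot, probe, 0, k, box)
    return probe, e_cur, e_full, True, stats


# ---------------------------------------------------------------------------
# Python-level drivers


def _location_residues(
    protein: CalphaStructure, probe: np.ndarray, box: float, cutoff: float
) -> frozenset:
    diff = probe[:, None, :] - protein.coords[None, :, :]
    diff -= box * np.round(diff / box)
    d = np.sqrt(np.sum(diff**2, axis=-1))
    return frozenset(int(i) for i in np.flatnonzero(d.min(axis=0) <= cutoff))


def run_probe_simulation(
    protein: CalphaStructure,
    config: SimulationConfig,
    seed: int | None = None,
    audit: bool = False,
) -> ProbeLocation | tuple[ProbeLocation, dict]:
    """One Metropolis docking run; deterministic in (protein, config, seed).

    With ``audit`` the kernel tracks constraint invariants over every
    visited state and the return value becomes ``(location, audit_dict)``.
    """
    config = config.resolve(protein)
    kernel_seed = int(
        np.random.SeedSequence((config.seed, 0) if seed is None else (seed,)).generate_state(1)[0]
    )
    center = protein.coords.mean(axis=0)
    probe, e_incr, e_full, ok, stats = _run_mc(
        protein.coords,
        config.probe_size,
        config.n_steps,
        kernel_seed,
        config.box_side,
        center[0],
        center[1],
        center[2],
        config.epsilon,
        config.kT,
        config.translation_step,
        math.radians(config.rotation_step_deg),
        config.jump_probability,
        config.jump_step if config.jump_step is not None else config.box_side / 2.0,
        config.max_init_retries,
        audit,
    )
    if not ok:
        raise RuntimeError(
            f"could not place a contact-free probe after {config.max_init_retries} "
            f"retries; box side {config.box_side:.1f} Å is too small"
        )
    if abs(e_incr - e_full) > 1e-9:
        raise AssertionError(
            f"energy bookkeeping drifted: incremental {e_incr} vs recomputed {e_full}"
        )
    residues = _location_residues(protein, probe, config.box_side, config.contact_cutoff)
    location = ProbeLocation(
        residues=residues,
        final_probe_coords=probe,
        final_energy=config.epsilon * e_full,
        sim_seed=kernel_seed,
    )
    if audit:
        info = {
            "n_accepted": int(stats[0]),
            "acceptance_rate": float(stats[0]) / max(config.n_steps, 1),
            "min_clearance": float(math.sqrt(stats[1])) if stats[1] < 1e29 else math.inf,
            "max_bond_deviation": float(stats[2]),
            "max_angle_cos": float(stats[3]),
            "incremental_energy": float(e_incr),
            "recomputed_energy": float(e_full),
        }
        return location, info
    return location


def generate_probe_locations(
    protein: CalphaStructure, config: SimulationConfig
) -> list[ProbeLocation]:
    """Run ``n_sims`` independent docking simulations and keep the non-empty
    probe locations.  Per-simulation seeds derive deterministically from the
    master seed, so the full list is reproducible bit-for-bit.
    """
    config = config.resolve(protein)
    locations: list[ProbeLocation] = []
    n_empty = 0
    children = np.random.SeedSequence(config.seed).spawn(config.n_sims)
    for child in children:
        sim_seed = int(child.generate_state(1)[0])
        loc = run_probe_simulation(protein, config, seed=sim_seed)
        if loc.is_empty:
            n_empty += 1
        else:
            locations.append(loc)
    logger.info(
        "docking: %d/%d simulations produced non-empty locations (%d unbound)",
        len(locations),
        config.n_sims,
        n_empty,
    )
    return locations
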