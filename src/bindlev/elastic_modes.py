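"""Cα elastic-network normal modes and mode/transition comparison measures.

Two spring flavors are exposed:

* ``distance-weighted`` (default): pair force constants follow the Hinsen
  Cα parametrization, k(r) = 8.6e2·r − 2.39e3 for r < 4 Å and
  k(r) = 128e4·r⁻⁶ for r ≥ 4 Å (r in Å, constants in arbitrary energy
  units — only relative mode ordering matters downstream).
* ``cutoff-ANM``: uniform springs between all Cα pairs within a cutoff
  (12 Å default).

Masses are uniform, so geometric and vibrational modes coincide up to the
frequency scale.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np

from bindlev.structure_io import CalphaStructure, DisplacementField

__all__ = [
    "EnmParams",
    "ModeSet",
    "build_hessian",
    "build_modes",
    "overlap",
    "cumulative_overlap",
    "collectivity",
    "select_modes",
    "save_modes",
    "load_modes",
]


@dataclass(frozen=True)
class EnmParams:
    """Elastic-network model parameters.

    model: "distance-weighted" (Hinsen-style, default) or "cutoff-ANM".
    cutoff: interaction cutoff in Å for cutoff-ANM.
    force_constant: overall spring-constant scale (arbitrary units).
    """

    model: str = "distance-weighted"
    cutoff: float = 12.0
    force_constant: float = 1.0

    def __post_init__(self) -> None:
        if self.model not in ("distance-weighted", "cutoff-ANM"):
            raise ValueError(f"unknown ENM model {self.model!r}")
        if self.cutoff <= 3.8:
            raise ValueError("cutoff must exceed the 3.8 Å backbone spacing")
        if self.force_constant <= 0:
            raise ValueError("force_constant must be positive")


@dataclass(frozen=True)
class ModeSet:
    """Orthonormal 3N-dimensional displacement modes, ascending in frequency."""

    vectors: np.ndarray  # (3N, K), one mode per column
    frequencies: np.ndarray  # (K,), sqrt(eigenvalue), arbitrary units
    n_atoms: int
    zero_modes_removed: bool

    def __post_init__(self) -> None:
        vectors = np.asarray(self.vectors, dtype=float)
        freqs = np.asarray(self.frequencies, dtype=float)
        if vectors.shape[0] != 3 * self.n_atoms:
            raise ValueError("mode length != 3N")
        if vectors.shape[1] != freqs.shape[0]:
            raise ValueError("vector/frequency count mismatch")
        if np.any(np.diff(freqs) < -1e-9):
            raise ValueError("frequencies must ascend")
        gram = vectors.T @ vectors
        if not np.allclose(gram, np.eye(vectors.shape[1]), atol=1e-8):
            raise ValueError("modes are not orthonormal")
        object.__setattr__(self, "vectors", vectors)
        object.__setattr__(self, "frequencies", freqs)

    @property
    def n_modes(self) -> int:
        return self.vectors.shape[1]

    def mode_field(self, j: int) -> DisplacementField:
        """Mode ``j`` reshaped to per-residue 3-vectors."""
        return DisplacementField(
            vectors=self.vectors[:, j].reshape(self.n_atoms, 3), normalized=True
        )


def _pair_force_constant(d: np.ndarray, params: EnmParams) -> np.ndarray:
    if params.model == "cutoff-ANM":
        k = np.where(d <= params.cutoff, 1.0, 0.0)
    else:
        # Hinsen Cα pair function, distances in Å.
        near = np.clip(8.6e2 * d - 2.39e3, 0.0, None)
        far = 128e4 * d**-6
        k = np.where(d < 4.0, near, far) / 1e3  # rescale to O(1)
    return params.force_constant * k


def build_hessian(structure: CalphaStructure, params: EnmParams | None = None) -> np.ndarray:
    """Dense 3N×3N elastic-network Hessian for a Cα structure."""
    params = params or EnmParams()
    coords = structure.coords
    n = coords.shape[0]
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt(np.sum(diff**2, axis=-1))
    np.fill_diagonal(dist, np.inf)
    k = _pair_force_constant(dist, params)
    np.fill_diagonal(k, 0.0)
    # off-diagonal 3x3 blocks: -(k_ij / d_ij^2) * (x_i - x_j)(x_i - x_j)^T
    scale = -k / dist**2
    blocks = scale[:, :, None, None] * diff[:, :, :, None] * diff[:, :, None, :]
    blocks[np.arange(n), np.arange(n)] = -blocks.sum(axis=1)
    hessian = blocks.transpose(0, 2, 1, 3).reshape(3 * n, 3 * n)
    return (hessian + hessian.T) / 2.0


def build_modes(
    structure: CalphaStructure,
    params: EnmParams | None = None,
    keep_zero_modes: bool = False,
    zero_mode_gap: float = 1e4,
) -> ModeSet:
    """Eigenmodes of the elastic-network Hessian, ascending by eigenvalue.

    The 6 rigid-body modes are removed by rank unless ``keep_zero_modes``;
    a spectral-gap check (eigenvalue 7 over eigenvalue 6 exceeding
    ``zero_mode_gap``) guards against disconnected networks.
    """
    params = params or EnmParams()
    n = len(structure)
    if n < 3:
        raise ValueError("need at least 3 atoms for a rigid network")
    hessian = build_hessian(structure, params)
    evals, evecs = np.linalg.eigh(hessian)
    evals = np.clip(evals, 0.0, None)  # kill tiny negative round-off
    if keep_zero_modes:
        return ModeSet(
            vectors=evecs,
            frequencies=np.sqrt(evals),
            n_atoms=n,
            zero_modes_removed=False,
        )
    scale = max(float(evals[-1]), 1e-300)
    trivial = float(evals[5]) / scale
    first = float(evals[6]) / scale
    if first <= max(trivial, 1e-14) * zero_mode_gap and first < 1e-8:
        raise ValueError(
            "more than 6 near-zero eigenvalues: elastic network is not rigid "
            f"(model={params.model}, cutoff={params.cutoff} Å); "
            "the structure is likely disconnected at this cutoff"
        )
    return ModeSet(
        vectors=evecs[:, 6:],
        frequencies=np.sqrt(evals[6:]),
        n_atoms=n,
        zero_modes_removed=True,
    )


def overlap(modes: ModeSet, dx: DisplacementField) -> np.ndarray:
    """Normalized projections I_j = Δx·e_j / (|Δx||e_j|) for every mode."""
    if dx.n_atoms != modes.n_atoms:
        raise ValueError("displacement/mode dimension mismatch")
    flat = dx.flattened()
    norm = float(np.linalg.norm(flat))
    if norm < 1e-300:
        raise ValueError("zero displacement has no overlap")
    return modes.vectors.T @ (flat / norm)


def cumulative_overlap(modes: ModeSet, dx: DisplacementField, k: int) -> float:
    """Σ_{j≤k} I_j², the squared cumulative overlap of the first k modes.

    Over a complete basis (zero modes kept) the k = 3N value is exactly 1.
    """
    if not 1 <= k <= modes.n_modes:
        raise ValueError(f"k must be in [1, {modes.n_modes}]")
    i_j = overlap(modes, dx)
    return float(np.sum(i_j[:k] ** 2))


def collectivity(v: DisplacementField) -> float:
    """Brüschweiler collectivity κ ∈ [1/N, 1] of a displacement field.

    κ = (1/N)·exp(−Σ α_i ln α_i) with α_i the normalized per-atom squared
    amplitudes; 1 for rigid-body motion, 1/N for a single moving atom.
    """
    amp2 = np.sum(np.asarray(v.vectors, dtype=float) ** 2, axis=1)
    total = float(amp2.sum())
    if total <= 0.0:
        raise ValueError("zero displacement has no collectivity")
    alpha = amp2 / total
    nz = alpha[alpha > 0]
    entropy = -float(np.sum(nz * np.log(nz)))
    return float(np.exp(entropy) / v.n_atoms)


def select_modes(
    modes: ModeSet, rule: str, dx: DisplacementField | None = None
) -> np.ndarray:
    """Mode index subsets: ``LF10`` (10 lowest-frequency non-trivial modes)
    or ``FM5`` (5 modes with largest |overlap| with dx, ties to lower
    frequency)."""
    if rule == "LF10":
        return np.arange(min(10, modes.n_modes))
    if rule == "FM5":
        if dx is None:
            raise ValueError("FM5 selection requires a displacement field")
        i_j = np.abs(overlap(modes, dx))
        # stable sort on (-|I|, frequency order): lexsort with index tiebreak
        order = np.lexsort((np.arange(modes.n_modes), -i_j))
        return np.sort(order[: min(5, modes.n_modes)])
    raise ValueError(f"unknown selection rule {rule!r} (use 'LF10' or 'FM5')")


def save_modes(modes: ModeSet) -> str:
    """Plain-text matrix dump: header row of frequencies, one mode per column."""
    buf = io.StringIO()
    buf.write(f"# n_atoms {modes.n_atoms} zero_modes_removed {int(modes.zero_modes_removed)}\n")
    buf.write(" ".join(f"{f:.12e}" for f in modes.frequencies) + "\n")
    np.savetxt(buf, modes.vectors, fmt="%.12e")
    return buf.getvalue()


def load_modes(text: str) -> ModeSet:
    lines = text.splitlines()
    header = lines[0].split()
    n_atoms = int(header[2])
    removed = bool(int(header[4]))
    freqs = np.array([float(x) for x in lines[1].split()])
    vectors = np.loadtxt(io.StringIO("\n".join(lines[2:])))
    if vectors.ndim == 1:
        vectors = vectors[:, None]
    return ModeSet(
        vectors=vectors, frequencies=freqs, n_atoms=n_atoms, zero_modes_removed=removed
    )
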