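"""PDB input/output, Cα extraction, superposition and difference vectors.

All downstream stages work on :class:`CalphaStructure`, an ordered list of
Cα records whose index is a stable residue handle.  Heavy atoms are kept
only where they are actually needed (ligand-contact binding sites and the
residue interaction graph) via :class:`HeavyStructure`.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from biotite.structure import AtomArray
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "CalphaStructure",
    "LigandRecord",
    "DisplacementField",
    "HeavyStructure",
    "PdbParseError",
    "load_calpha",
    "load_heavy",
    "extract_ligands",
    "superpose",
    "difference_vector",
    "write_calpha_pdb",
    "write_displacement_table",
]

#: Solvent heteroatom codes excluded from ligand extraction by default.
DEFAULT_SOLVENT = frozenset({"HOH", "WAT", "DOD", "H2O"})


class PdbParseError(ValueError):
    """Raised when a PDB source cannot be interpreted as requested."""


@dataclass(frozen=True)
class CalphaStructure:
    """Ordered Cα records of one or more protein chains.

    The atom order follows the source file, so the integer index of a
    residue is a persistent handle used by every other module.
    """

    chain_ids: tuple[str, ...]
    res_seqs: tuple[int, ...]
    icodes: tuple[str, ...]
    res_names: tuple[str, ...]
    coords: np.ndarray  # (N, 3) float64, Å
    source_id: str = ""

    def __post_init__(self) -> None:
        n = len(self.chain_ids)
        if not (n == len(self.res_seqs) == len(self.icodes) == len(self.res_names)):
            raise ValueError("field lengths disagree")
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (n, 3):
            raise ValueError(f"coords shape {coords.shape} != ({n}, 3)")
        if n < 2:
            raise ValueError("a CalphaStructure needs at least 2 residues")
        if not np.all(np.isfinite(coords)):
            raise ValueError("non-finite coordinates")
        keys = self.residue_keys()
        if len(set(keys)) != n:
            raise ValueError("duplicate (chain, res_seq, icode) residue keys")
        object.__setattr__(self, "coords", coords)

    def __len__(self) -> int:
        return len(self.chain_ids)

    @property
    def n_atoms(self) -> int:
        return len(self.chain_ids)

    def residue_keys(self) -> list[tuple[str, int, str]]:
        """(chain_id, res_seq, icode) triple for every residue, in order."""
        return list(zip(self.chain_ids, self.res_seqs, self.icodes))

    def residue_labels(self) -> list[str]:
        """Human-readable residue ids like ``A12`` or ``A12B``."""
        return [
            f"{c}{s}{i.strip()}"
            for c, s, i in zip(self.chain_ids, self.res_seqs, self.icodes)
        ]

    def subset(self, indices: Sequence[int]) -> "CalphaStructure":
        idx = list(indices)
        return CalphaStructure(
            chain_ids=tuple(self.chain_ids[i] for i in idx),
            res_seqs=tuple(self.res_seqs[i] for i in idx),
            icodes=tuple(self.icodes[i] for i in idx),
            res_names=tuple(self.res_names[i] for i in idx),
            coords=self.coords[idx],
            source_id=self.source_id,
        )

    def with_coords(self, coords: np.ndarray) -> "CalphaStructure":
        return CalphaStructure(
            chain_ids=self.chain_ids,
            res_seqs=self.res_seqs,
            icodes=self.icodes,
            res_names=self.res_names,
            coords=np.asarray(coords, dtype=float),
            source_id=self.source_id,
        )


@dataclass(frozen=True)
class LigandRecord:
    """Heavy atoms of one HETATM group (het code + chain)."""

    het_code: str
    chain_id: str
    heavy_atom_coords: np.ndarray  # (M, 3)

    def __post_init__(self) -> None:
        if not self.het_code:
            raise ValueError("empty het code")
        coords = np.asarray(self.heavy_atom_coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] < 1:
            raise ValueError("ligand needs at least one heavy atom")
        object.__setattr__(self, "heavy_atom_coords", coords)

    @property
    def n_atoms(self) -> int:
        return self.heavy_atom_coords.shape[0]


@dataclass(frozen=True)
class DisplacementField:
    """Per-residue 3-vectors attached to a CalphaStructure (by order)."""

    vectors: np.ndarray  # (N, 3)
    normalized: bool = False

    def __post_init__(self) -> None:
        vectors = np.asarray(self.vectors, dtype=float)
        if vectors.ndim != 2 or vectors.shape[1] != 3:
            raise ValueError("vectors must be (N, 3)")
        if self.normalized:
            norm = float(np.linalg.norm(vectors.ravel()))
            if abs(norm - 1.0) > 1e-10:
                raise ValueError(f"normalized flag set but |v| = {norm}")
        object.__setattr__(self, "vectors", vectors)

    @property
    def n_atoms(self) -> int:
        return self.vectors.shape[0]

    def flattened(self) -> np.ndarray:
        return self.vectors.ravel()


@dataclass(frozen=True)
class HeavyStructure:
    """Protein heavy atoms grouped by residue, aligned to a CalphaStructure.

    ``residue_index[a]`` maps heavy atom ``a`` to the residue handle of the
    companion CalphaStructure parsed from the same source.
    """

    coords: np.ndarray  # (A, 3)
    residue_index: np.ndarray  # (A,) int
    n_residues: int

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        ridx = np.asarray(self.residue_index, dtype=int)
        if coords.shape[0] != ridx.shape[0]:
            raise ValueError("coords / residue_index length mismatch")
        if ridx.size and (ridx.min() < 0 or ridx.max() >= self.n_residues):
            raise ValueError("residue_index out of range")
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "residue_index", ridx)

    def atoms_of_residue(self, i: int) -> np.ndarray:
        return self.coords[self.residue_index == i]


# ---------------------------------------------------------------------------
# Parsing


def _read_first_model(pdb_source) -> AtomArray:
    """Parse PDB text/path into a biotite AtomArray (first model, first altloc)."""
    if isinstance(pdb_source, (str, Path)) and "\n" not in str(pdb_source):
        path = Path(pdb_source)
        if not path.exists():
            raise PdbParseError(f"no such PDB file: {path}")
        text = path.read_text()
    elif isinstance(pdb_source, str):
        text = pdb_source
    elif hasattr(pdb_source, "read"):
        text = pdb_source.read()
    else:
        raise PdbParseError(f"cannot interpret {type(pdb_source)!r} as PDB input")
    try:
        pdb_file = PDBFile.read(io.StringIO(text))
        atoms = pdb_file.get_structure(model=1, altloc="first")
    except Exception as exc:  # biotite raises various error types
        raise PdbParseError(f"could not parse PDB input: {exc}") from exc
    return atoms


def _apply_chain_filter(atoms: AtomArray, chain_filter) -> AtomArray:
    if chain_filter is None:
        return atoms
    wanted = {str(c) for c in chain_filter}
    available = sorted(set(atoms.chain_id))
    missing = wanted - set(available)
    if missing:
        raise PdbParseError(
            f"unknown chain id(s) {sorted(missing)}; available chains: {available}"
        )
    return atoms[np.isin(atoms.chain_id, list(wanted))]


def load_calpha(pdb_source, chain_filter: Iterable[str] | None = None) -> CalphaStructure:
    """Extract the Cα trace of the protein chains in a PDB source.

    HETATM records, waters and non-primary altlocs are excluded; residues
    with insertion codes are retained.  ``pdb_source`` may be PDB text, a
    path, or a readable file object.
    """
    atoms = _apply_chain_filter(_read_first_model(pdb_source), chain_filter)
    mask = (atoms.atom_name == "CA") & ~atoms.hetero & (atoms.element != "CA")
    ca = atoms[mask]
    if ca.array_length() < 2:
        raise PdbParseError(
            "fewer than 2 Cα atoms found after filtering"
            + (f" (chains {sorted(set(chain_filter))})" if chain_filter else "")
        )
    source_id = str(pdb_source)[:40] if isinstance(pdb_source, Path) else ""
    return CalphaStructure(
        chain_ids=tuple(str(c) for c in ca.chain_id),
        res_seqs=tuple(int(r) for r in ca.res_id),
        icodes=tuple(str(i) for i in ca.ins_code),
        res_names=tuple(str(r) for r in ca.res_name),
        coords=np.array(ca.coord, dtype=float),
        source_id=source_id,
    )


def load_heavy(pdb_source, chain_filter: Iterable[str] | None = None) -> HeavyStructure:
    """Protein heavy atoms grouped onto the residue handles of ``load_calpha``.

    Only residues that have a Cα are kept, so the residue indices line up
    one-to-one with the CalphaStructure parsed from the same source.
    """
    atoms = _apply_chain_filter(_read_first_model(pdb_source), chain_filter)
    protein = atoms[~atoms.hetero & (atoms.element != "H") & (atoms.element != "D")]
    ca_mask = protein.atom_name == "CA"
    if not np.any(ca_mask):
        raise PdbParseError("no Cα atoms found; cannot anchor residue handles")
    keys = list(
        zip(
            (str(c) for c in protein.chain_id),
            (int(r) for r in protein.res_id),
            (str(i) for i in protein.ins_code),
        )
    )
    handle_of: dict[tuple[str, int, str], int] = {}
    for key, is_ca in zip(keys, ca_mask):
        if is_ca and key not in handle_of:
            handle_of[key] = len(handle_of)
    keep = [a for a, key in enumerate(keys) if key in handle_of]
    return HeavyStructure(
        coords=np.array(protein.coord[keep], dtype=float),
        residue_index=np.array([handle_of[keys[a]] for a in keep], dtype=int),
        n_residues=len(handle_of),
    )


def extract_ligands(
    pdb_source, exclude_codes: Iterable[str] | None = None
) -> list[LigandRecord]:
    """One LigandRecord per distinct (het_code, chain) HETATM group.

    Waters (and any extra ``exclude_codes``) are dropped; hydrogens are not
    counted as heavy atoms.  Returns an empty list when nothing is found.
    """
    exclude = DEFAULT_SOLVENT if exclude_codes is None else (
        DEFAULT_SOLVENT | {str(c).upper() for c in exclude_codes}
    )
    atoms = _read_first_model(pdb_source)
    het = atoms[atoms.hetero & (atoms.element != "H") & (atoms.element != "D")]
    groups: dict[tuple[str, str], list[np.ndarray]] = {}
    for a in range(het.array_length()):
        code = str(het.res_name[a]).upper()
        if code in exclude:
            continue
        groups.setdefault((code, str(het.chain_id[a])), []).append(het.coord[a])
    return [
        LigandRecord(het_code=code, chain_id=chain, heavy_atom_coords=np.array(xyz))
        for (code, chain), xyz in groups.items()
    ]


# ---------------------------------------------------------------------------
# Superposition and difference vectors


def _match_indices(
    a: CalphaStructure,
    b: CalphaStructure,
    chain_map: Mapping[str, str] | None = None,
) -> tuple[list[int], list[int]]:
    """Indices of residues shared by (chain, res_seq, icode), in a's order.

    ``chain_map`` renames b's chains before matching (b chain -> a chain).
    """
    b_keys = b.residue_keys()
    if chain_map:
        b_keys = [(chain_map.get(c, c), s, i) for c, s, i in b_keys]
    b_index = {key: j for j, key in enumerate(b_keys)}
    ia, ib = [], []
    for i, key in enumerate(a.residue_keys()):
        j = b_index.get(key)
        if j is not None:
            ia.append(i)
            ib.append(j)
    return ia, ib


def _kabsch(p: np.ndarray, q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares proper rotation R and translation t with R @ p + t ≈ q."""
    pc = p.mean(axis=0)
    qc = q.mean(axis=0)
    h = (p - pc).T @ (q - qc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = qc - rot @ pc
    return rot, trans


def superpose(
    mobile: CalphaStructure,
    reference: CalphaStructure,
    chain_map: Mapping[str, str] | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Kabsch superposition of ``mobile`` onto ``reference``.

    Residues are matched by (chain, res_seq, icode); ``chain_map`` maps
    mobile chain ids onto reference chain ids when entries use different
    naming.  Returns ``(rotation, translation, rmsd)`` such that
    ``rotation @ x + translation`` moves mobile coordinates onto the
    reference frame.
    """
    ir, im = _match_indices(reference, mobile, chain_map=chain_map)
    if len(ir) < 3:
        raise ValueError(
            f"only {len(ir)} matched residues between structures; need >= 3"
        )
    p = mobile.coords[im]
    q = reference.coords[ir]
    rot, trans = _kabsch(p, q)
    moved = p @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - q) ** 2, axis=1))))
    return rot, trans, rmsd


def difference_vector(
    a: CalphaStructure,
    b: CalphaStructure,
    normalize: bool = True,
    superpose_first: bool = True,
    chain_map: Mapping[str, str] | None = None,
) -> DisplacementField:
    """Per-residue displacement b_i − a_i over matched residues.

    ``b`` is Kabsch-superposed onto ``a`` first unless disabled.  The two
    structures must match residue-for-residue; unmatched residues are an
    error.  With ``normalize`` the flattened 3N-vector has unit norm; a
    zero difference cannot be normalized and raises instead of emitting NaN.
    """
    ia, ib = _match_indices(a, b, chain_map=chain_map)
    if len(ia) != len(a) or len(ib) != len(b):
        unmatched_a = [a.residue_labels()[i] for i in range(len(a)) if i not in set(ia)]
        unmatched_b = [b.residue_labels()[j] for j in range(len(b)) if j not in set(ib)]
        raise ValueError(
            "structures do not match residue-for-residue; unmatched in first: "
            f"{unmatched_a[:10]}, unmatched in second: {unmatched_b[:10]}"
        )
    b_coords = b.coords[ib]
    if superpose_first:
        rot, trans = _kabsch(b_coords, a.coords[ia])
        b_coords = b_coords @ rot.T + trans
    vectors = b_coords - a.coords[ia]
    if normalize:
        norm = float(np.linalg.norm(vectors.ravel()))
        if norm < 1e-12:
            raise ValueError("zero difference vector has no direction to normalize")
        vectors = vectors / norm
        return DisplacementField(vectors=vectors, normalized=True)
    return DisplacementField(vectors=vectors, normalized=False)


# ---------------------------------------------------------------------------
# Writers


def write_calpha_pdb(
    structure: CalphaStructure,
    bfactors: Sequence[float] | None = None,
    ligand: LigandRecord | None = None,
) -> str:
    """Render a CalphaStructure as minimal PDB text (optionally with B-factors
    for viewer coloring and a HETATM ligand group)."""
    if bfactors is not None and len(bfactors) != len(structure):
        raise ValueError("one B-factor per residue required")
    lines = []
    serial = 1
    for i in range(len(structure)):
        x, y, z = structure.coords[i]
        b = 0.0 if bfactors is None else float(bfactors[i])
        lines.append(
            f"ATOM  {serial:5d}  CA  {structure.res_names[i]:>3s} "
            f"{structure.chain_ids[i][:1]:1s}{structure.res_seqs[i]:4d}"
            f"{structure.icodes[i][:1] or ' ':1s}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{b:6.2f}           C  "
        )
        serial += 1
    lines.append("TER")
    if ligand is not None:
        for j, (x, y, z) in enumerate(ligand.heavy_atom_coords, start=1):
            lines.append(
                f"HETATM{serial:5d}  C{j % 100:<2d} {ligand.het_code:>3s} "
                f"{ligand.chain_id[:1] or 'X':1s}{900 + j // 100:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}           C  "
            )
            serial += 1
        lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


def write_displacement_table(
    structure: CalphaStructure, field_: DisplacementField
) -> str:
    """Whitespace-delimited (chain, res_seq, dx, dy, dz) table."""
    if field_.n_atoms != len(structure):
        raise ValueError("field does not match structure")
    rows = ["# chain res_seq dx dy dz"]
    for i in range(len(structure)):
        dx, dy, dz = field_.vectors[i]
        rows.append(
            f"{structure.chain_ids[i]} {structure.res_seqs[i]} "
            f"{dx:.6e} {dy:.6e} {dz:.6e}"
        )
    return "\n".join(rows) + "\n"
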