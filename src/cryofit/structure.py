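"""Bead/atom structures, PDB I/O, optimal superposition and RMSD.

Coordinates are in Angstrom throughout. A :class:`Structure` is a flat,
ordered list of beads (atoms); for coarse-grained work each bead is the
C-alpha atom of one residue.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "Structure",
    "read_pdb",
    "write_pdb",
    "superpose",
    "rmsd",
    "RESIDUE_MASSES",
]

# Average residue masses in amu (per-residue, i.e. amino-acid minus water).
RESIDUE_MASSES = {
    "ALA": 71.08, "ARG": 156.19, "ASN": 114.10, "ASP": 115.09,
    "CYS": 103.14, "GLN": 128.13, "GLU": 129.12, "GLY": 57.05,
    "HIS": 137.14, "ILE": 113.16, "LEU": 113.16, "LYS": 128.17,
    "MET": 131.19, "PHE": 147.18, "PRO": 97.12, "SER": 87.08,
    "THR": 101.10, "TRP": 186.21, "TYR": 163.18, "VAL": 99.13,
}
_DEFAULT_MASS = 110.0


@dataclass
class Structure:
    """Ordered collection of beads with chain/residue identity.

    Parameters
    ----------
    positions : (n, 3) float array, Angstrom
    residue_ids : (n,) int array, author residue numbers
    chain_ids : (n,) str array
    names : (n,) str array, atom names (e.g. ``"CA"``)
    res_names : (n,) str array, three-letter residue names
    masses : (n,) float array, amu
    icodes : (n,) str array, PDB insertion codes ('' if absent)
    """

    positions: np.ndarray
    residue_ids: np.ndarray
    chain_ids: np.ndarray
    names: np.ndarray
    res_names: np.ndarray
    masses: np.ndarray
    icodes: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.float64).reshape(-1, 3)
        n = len(self.positions)
        self.residue_ids = np.asarray(self.residue_ids, dtype=np.int64)
        self.chain_ids = np.asarray(self.chain_ids, dtype="U4")
        self.names = np.asarray(self.names, dtype="U6")
        self.res_names = np.asarray(self.res_names, dtype="U5")
        self.masses = np.asarray(self.masses, dtype=np.float64)
        if self.icodes is None:
            self.icodes = np.full(n, "", dtype="U2")
        else:
            self.icodes = np.asarray(self.icodes, dtype="U2")
        for arr, label in [
            (self.residue_ids, "residue_ids"), (self.chain_ids, "chain_ids"),
            (self.names, "names"), (self.res_names, "res_names"),
            (self.masses, "masses"), (self.icodes, "icodes"),
        ]:
            if len(arr) != n:
                raise ValueError(f"{label} has length {len(arr)}, expected {n}")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions contain non-finite values")

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    def residue_keys(self) -> list[tuple[str, int, str]]:
        """Per-bead (chain, residue number, insertion code) keys."""
        return list(zip(self.chain_ids.tolist(), self.residue_ids.tolist(),
                        self.icodes.tolist()))

    def select(self, mask) -> "Structure":
        mask = np.asarray(mask)
        return Structure(
            self.positions[mask], self.residue_ids[mask], self.chain_ids[mask],
            self.names[mask], self.res_names[mask], self.masses[mask],
            self.icodes[mask],
        )

    def with_positions(self, positions: np.ndarray) -> "Structure":
        return replace(self, positions=np.array(positions, dtype=np.float64))

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        return self.with_positions(self.positions @ rotation.T + translation)

    def center_of_mass(self) -> np.ndarray:
        w = self.masses / self.masses.sum()
        return w @ self.positions


class PDBParseError(ValueError):
    pass


def _mass_for(res_name: str, atom_name: str) -> float:
    if atom_name.strip() == "CA":
        return RESIDUE_MASSES.get(res_name, _DEFAULT_MASS)
    return RESIDUE_MASSES.get(res_name, _DEFAULT_MASS)


def read_pdb(path, selection: str | None = "CA", model: int = 1) -> Structure:
    """Read a PDB file into a :class:`Structure`.

    Parameters
    ----------
    path : str or Path
    selection : atom-name filter; ``"CA"`` (default) keeps one bead per
        standard residue, ``None`` keeps every atom.
    model : 1-based MODEL number to read.

    Altloc handling keeps the highest-occupancy variant.
    """
    try:
        pdb = PDBFile.read(str(path))
        atoms = pdb.get_structure(
            model=model, altloc="occupancy", extra_fields=["occupancy"]
        )
    except Exception as exc:  # pragma: no cover - message shaping
        raise PDBParseError(f"cannot parse PDB file {path!s}: {exc}") from exc
    mask = ~atoms.hetero
    if selection is not None:
        mask &= atoms.atom_name == selection
    atoms = atoms[mask]
    if atoms.array_length() == 0:
        raise ValueError(
            f"selection {selection!r} matched no atoms in {path!s}"
        )
    masses = np.array(
        [_mass_for(rn, an) for rn, an in zip(atoms.res_name, atoms.atom_name)]
    )
    return Structure(
        positions=atoms.coord.astype(np.float64),
        residue_ids=atoms.res_id,
        chain_ids=atoms.chain_id,
        names=atoms.atom_name,
        res_names=atoms.res_name,
        masses=masses,
        icodes=atoms.ins_code,
    )


def _to_atom_array(s: Structure) -> bst.AtomArray:
    n = len(s)
    arr = bst.AtomArray(n)
    arr.coord = s.positions.astype(np.float32)
    arr.chain_id = s.chain_ids
    arr.res_id = s.residue_ids
    arr.ins_code = s.icodes
    arr.res_name = s.res_names
    arr.atom_name = s.names
    arr.element = np.where(np.char.startswith(s.names.astype("U2"), "C"), "C", "X")
    arr.hetero = np.zeros(n, dtype=bool)
    return arr


def write_pdb(path, s: Structure | list[Structure], remarks: list[str] | None = None):
    """Write one structure, or a multi-MODEL trajectory, as PDB."""
    frames = [s] if isinstance(s, Structure) else list(s)
    if len(frames) == 1:
        atoms = _to_atom_array(frames[0])
    else:
        atoms = bst.stack([_to_atom_array(f) for f in frames])
    pdb = PDBFile()
    pdb.set_structure(atoms)
    if remarks:
        lines = [f"REMARK 250 {r}" for r in remarks]
        pdb.lines = lines + pdb.lines
    pdb.write(str(path))


def superpose(mobile, reference, subset=None):
    """Least-squares optimal rigid superposition (Kabsch).

    Returns ``(rotation, translation, rmsd_after)`` such that
    ``mobile @ rotation.T + translation`` best fits ``reference`` over
    ``subset`` (all beads if None).  ``det(rotation) = +1``.
    """
    xm = mobile.positions if isinstance(mobile, Structure) else np.asarray(mobile, float)
    xr = reference.positions if isinstance(reference, Structure) else np.asarray(reference, float)
    if subset is not None:
        subset = np.asarray(subset, dtype=np.intp)
        xm = xm[subset]
        xr = xr[subset]
    if len(xm) != len(xr):
        raise ValueError(f"subset length mismatch: {len(xm)} vs {len(xr)}")
    if len(xm) < 3:
        raise ValueError("superposition needs at least 3 points")
    cm, cr = xm.mean(axis=0), xr.mean(axis=0)
    am, ar = xm - cm, xr - cr
    h = am.T @ ar
    u, sing, vt = np.linalg.svd(h)
    # Degenerate when the point cloud is (near-)collinear: two singular
    # values of the covariance vanish and the rotation is not unique.
    scale = max(sing[0], 1e-12)
    if sing[1] / scale < 1e-8:
        raise ValueError("degenerate (collinear) subset: superposition not unique")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = cr - rot @ cm
    diff = am @ rot.T - ar
    rmsd_after = float(np.sqrt((diff ** 2).sum() / len(xm)))
    return rot, trans, rmsd_after


def rmsd(a, b, subset=None, fit: bool = True, weights=None) -> float:
    """Root-mean-square deviation between two structures.

    ``fit=True`` computes the RMSD after optimal (Kabsch) superposition;
    ``fit=False`` compares coordinates in place.  Mass-unweighted unless
    explicit ``weights`` are given.
    """
    xa = a.positions if isinstance(a, Structure) else np.asarray(a, float)
    xb = b.positions if isinstance(b, Structure) else np.asarray(b, float)
    if subset is not None:
        subset = np.asarray(subset, dtype=np.intp)
        xa, xb = xa[subset], xb[subset]
    if len(xa) == 0 or len(xb) == 0:
        raise ValueError("empty subset")
    if len(xa) != len(xb):
        raise ValueError(f"length mismatch: {len(xa)} vs {len(xb)}")
    if fit:
        rot, trans, value = superpose(xa, xb)
        if weights is None:
            return value
        xa = xa @ rot.T + trans
    d2 = ((xa - xb) ** 2).sum(axis=1)
    if weights is not None:
        w = np.asarray(weights, float)
        return float(np.sqrt((w * d2).sum() / w.sum()))
    return float(np.sqrt(d2.mean()))


def pair_residues(a: Structure, b: Structure) -> tuple[np.ndarray, np.ndarray]:
    """Indices pairing beads of ``a`` and ``b`` by (chain, residue, icode).

    Unmatched residues are excluded; the count of exclusions is available
    as the difference in lengths.  Order follows ``a``.
    """
    key_b = {k: i for i, k in enumerate(b.residue_keys())}
    ia, ib = [], []
    for i, k in enumerate(a.residue_keys()):
        j = key_b.get(k)
        if j is not None:
            ia.append(i)
            ib.append(j)
    return np.array(ia, dtype=np.intp), np.array(ib, dtype=np.intp)
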