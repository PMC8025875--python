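"""C-alpha structure-based (Go) potential.

One bead per residue at the C-alpha position.  The potential has its
global minimum at the native structure: harmonic pseudo-bonds and angles
at native values, Fourier dihedrals with native phase, a 12-10-6 native
contact well of depth eps_ij at the native pair distance, and a 1/r^12
excluded-volume repulsion between all remaining non-local pairs.  Well
depths are weighted by statistical (Miyazawa-Jernigan-type) contact
energies of the residue-type pair and renormalized so their mean equals
a configurable base depth.

Pair interactions (native and non-native) are switched smoothly to zero
between ``switch_on`` and ``cutoff`` (defaults 18 and 20 Angstrom).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np

from . import _kernels
from .structure import Structure

__all__ = ["GoModelParams", "GoModel", "build_go_model", "combine_chains",
           "scale_contacts", "energy_forces", "ChainBreakWarning"]


class ChainBreakWarning(UserWarning):
    pass


def _load_mj_table() -> dict[str, float]:
    text = (resources.files("cryofit") / "data" / "mj_contact_energies.tsv").read_text()
    table = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, val = line.split()
        table[name] = float(val)
    return table


_MJ = _load_mj_table()


def mj_pair_energy(res_a: str, res_b: str) -> float:
    """Magnitude of the statistical contact energy for a residue pair."""
    missing = [r for r in (res_a, res_b) if r not in _MJ]
    if missing:
        warnings.warn(
            f"unknown residue type(s) {missing}; using mean contact energy",
            UserWarning, stacklevel=2)
    mean = float(np.mean([abs(v) for v in _MJ.values()]))
    ea = abs(_MJ.get(res_a, -mean))
    eb = abs(_MJ.get(res_b, -mean))
    return float(np.sqrt(ea * eb))


@dataclass
class GoModelParams:
    """Tunable Go-model parameters (kcal/mol, Angstrom, radian)."""

    base_epsilon: float = 1.0        # mean native-contact well depth
    mj_weighting: bool = True
    bond_k: float = 100.0            # kcal/mol/A^2 (SHAKE usually active)
    angle_k: float = 20.0            # kcal/mol/rad^2
    dihedral_k1: float = 1.0         # kcal/mol
    dihedral_k3: float = 0.5
    contact_heavy_cutoff: float = 4.5   # heavy-atom contact criterion
    contact_ca_cutoff: float = 6.5      # CA-CA criterion (CA-only input)
    contact_min_separation: int = 4     # |i-j| >= this within a chain
    nonnative_sigma: float = 4.0
    nonnative_eps: float = 0.1
    cutoff: float = 20.0
    switch_on: float = 18.0
    chain_break_distance: float = 4.5
    force_connect: bool = False


def _empty_i():
    return np.empty(0, dtype=np.int64)


def _empty_f():
    return np.empty(0, dtype=np.float64)


@dataclass
class GoModel:
    """Term lists of a C-alpha Go potential over ``n_beads`` beads."""

    n_beads: int
    bond_i: np.ndarray = field(default_factory=_empty_i)
    bond_j: np.ndarray = field(default_factory=_empty_i)
    bond_r0: np.ndarray = field(default_factory=_empty_f)
    bond_k: np.ndarray = field(default_factory=_empty_f)
    ang_i: np.ndarray = field(default_factory=_empty_i)
    ang_j: np.ndarray = field(default_factory=_empty_i)
    ang_k: np.ndarray = field(default_factory=_empty_i)
    ang_t0: np.ndarray = field(default_factory=_empty_f)
    ang_ka: np.ndarray = field(default_factory=_empty_f)
    dih_i: np.ndarray = field(default_factory=_empty_i)
    dih_j: np.ndarray = field(default_factory=_empty_i)
    dih_k: np.ndarray = field(default_factory=_empty_i)
    dih_l: np.ndarray = field(default_factory=_empty_i)
    dih_p0: np.ndarray = field(default_factory=_empty_f)
    dih_k1: np.ndarray = field(default_factory=_empty_f)
    dih_k3: np.ndarray = field(default_factory=_empty_f)
    con_i: np.ndarray = field(default_factory=_empty_i)
    con_j: np.ndarray = field(default_factory=_empty_i)
    con_r0: np.ndarray = field(default_factory=_empty_f)
    con_eps: np.ndarray = field(default_factory=_empty_f)
    nn_i: np.ndarray = field(default_factory=_empty_i)
    nn_j: np.ndarray = field(default_factory=_empty_i)
    nonnative_sigma: float = 4.0
    nonnative_eps: float = 0.1
    cutoff: float = 20.0
    switch_on: float = 18.0

    def __post_init__(self):
        for name in ("bond_i", "bond_j", "ang_i", "ang_j", "ang_k",
                     "dih_i", "dih_j", "dih_k", "dih_l",
                     "con_i", "con_j", "nn_i", "nn_j"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.int64))
        for name in ("bond_r0", "bond_k", "ang_t0", "ang_ka", "dih_p0",
                     "dih_k1", "dih_k3", "con_r0", "con_eps"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.float64))
        if len(self.con_i):
            if np.any(self.con_i >= self.con_j):
                raise ValueError("contacts must have i < j")
            pairs = set(zip(self.con_i.tolist(), self.con_j.tolist()))
            if len(pairs) != len(self.con_i):
                raise ValueError("duplicate contact pairs")
            if np.any(self.con_r0 <= 0) or np.any(self.con_eps <= 0):
                raise ValueError("contact r0 and eps must be positive")

    @property
    def n_contacts(self) -> int:
        return len(self.con_i)

    def copy(self) -> "GoModel":
        kw = {}
        for name, val in self.__dict__.items():
            kw[name] = val.copy() if isinstance(val, np.ndarray) else val
        return GoModel(**kw)

    def kernel_args(self):
        """Positional argument tuple consumed by the numba kernels."""
        return (self.bond_i, self.bond_j, self.bond_r0, self.bond_k,
                self.ang_i, self.ang_j, self.ang_k, self.ang_t0, self.ang_ka,
                self.dih_i, self.dih_j, self.dih_k, self.dih_l,
                self.dih_p0, self.dih_k1, self.dih_k3,
                self.con_i, self.con_j, self.con_r0, self.con_eps,
                self.nn_i, self.nn_j, self.nonnative_sigma, self.nonnative_eps,
                self.cutoff, self.switch_on)

    # -- plain-text serialization -----------------------------------------
    def to_text(self) -> str:
        lines = [f"n_beads {self.n_beads}",
                 f"nonnative sigma={self.nonnative_sigma} eps={self.nonnative_eps}",
                 f"cutoff {self.cutoff} switch_on {self.switch_on}"]
        lines.append(f"[bonds] {len(self.bond_i)}")
        for t in zip(self.bond_i, self.bond_j, self.bond_r0, self.bond_k):
            lines.append("%d %d %.6f %.6f" % t)
        lines.append(f"[angles] {len(self.ang_i)}")
        for t in zip(self.ang_i, self.ang_j, self.ang_k, self.ang_t0, self.ang_ka):
            lines.append("%d %d %d %.8f %.6f" % t)
        lines.append(f"[dihedrals] {len(self.dih_i)}")
        for t in zip(self.dih_i, self.dih_j, self.dih_k, self.dih_l,
                     self.dih_p0, self.dih_k1, self.dih_k3):
            lines.append("%d %d %d %d %.8f %.6f %.6f" % t)
        lines.append(f"[contacts] {len(self.con_i)}")
        for t in zip(self.con_i, self.con_j, self.con_r0, self.con_eps):
            lines.append("%d %d %.6f %.8f" % t)
        lines.append(f"[nonnative_pairs] {len(self.nn_i)}")
        for t in zip(self.nn_i, self.nn_j):
            lines.append("%d %d" % t)
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "GoModel":
        lines = [ln for ln in text.splitlines() if ln.strip()]
        n_beads = int(lines[0].split()[1])
        nn = dict(kv.split("=") for kv in lines[1].split()[1:])
        tok = lines[2].split()
        cutoff, switch_on = float(tok[1]), float(tok[3])
        idx = 3
        sections = {}
        while idx < len(lines):
            name, count = lines[idx].split()
            count = int(count)
            rows = [lines[idx + 1 + r].split() for r in range(count)]
            sections[name.strip("[]")] = rows
            idx += 1 + count
        def col(sec, c, dtype):
            rows = sections.get(sec, [])
            return np.array([dtype(r[c]) for r in rows],
                            dtype=np.int64 if dtype is int else np.float64)
        return cls(
            n_beads=n_beads,
            bond_i=col("bonds", 0, int), bond_j=col("bonds", 1, int),
            bond_r0=col("bonds", 2, float), bond_k=col("bonds", 3, float),
            ang_i=col("angles", 0, int), ang_j=col("angles", 1, int),
            ang_k=col("angles", 2, int), ang_t0=col("angles", 3, float),
            ang_ka=col("angles", 4, float),
            dih_i=col("dihedrals", 0, int), dih_j=col("dihedrals", 1, int),
            dih_k=col("dihedrals", 2, int), dih_l=col("dihedrals", 3, int),
            dih_p0=col("dihedrals", 4, float), dih_k1=col("dihedrals", 5, float),
            dih_k3=col("dihedrals", 6, float),
            con_i=col("contacts", 0, int), con_j=col("contacts", 1, int),
            con_r0=col("contacts", 2, float), con_eps=col("contacts", 3, float),
            nn_i=col("nonnative_pairs", 0, int),
            nn_j=col("nonnative_pairs", 1, int),
            nonnative_sigma=float(nn["sigma"]), nonnative_eps=float(nn["eps"]),
            cutoff=cutoff, switch_on=switch_on,
        )


def _angle(a, b, c) -> float:
    v1, v2 = a - b, c - b
    cs = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.arccos(np.clip(cs, -1.0, 1.0)))


def _dihedral(a, b, c, d) -> float:
    b1, b2, b3 = b - a, c - b, d - c
    m = np.cross(b1, b2)
    n = np.cross(b2, b3)
    x = np.dot(m, n)
    y = np.dot(np.cross(m, n), b2) / np.linalg.norm(b2)
    return float(np.arctan2(y, x))


def _chain_segments(native: Structure, break_distance: float,
                    force_connect: bool):
    """Bead index runs that are covalently connected (per chain, split at
    chain breaks)."""
    segments = []
    start = 0
    n = len(native)
    for i in range(1, n + 1):
        broken = False
        if i == n or native.chain_ids[i] != native.chain_ids[i - 1]:
            broken = True
        else:
            d = np.linalg.norm(native.positions[i] - native.positions[i - 1])
            if d > break_distance and not force_connect:
                warnings.warn(
                    f"chain break between beads {i - 1} and {i} "
                    f"(CA-CA distance {d:.2f} A); pseudo-bond skipped",
                    ChainBreakWarning, stacklevel=3)
                broken = True
        if broken and i < n + 1:
            segments.append((start, i))
            start = i
        if i == n:
            break
    return [s for s in segments if s[1] > s[0]]


def _detect_contacts(native: Structure, all_atom: Structure | None,
                     params: GoModelParams,
                     inter_chain_only: bool = False) -> list[tuple[int, int, float]]:
    """Native-contact pairs by brute-force distance scan.

    Uses the minimum heavy-atom distance per residue pair when an
    all-atom structure is supplied, else the CA-CA distance.
    """
    n = len(native)
    pos = native.positions
    if all_atom is not None and not np.all(all_atom.names == "CA"):
        # group heavy atoms by residue key
        groups: dict[tuple, list[int]] = {}
        for idx, key in enumerate(all_atom.residue_keys()):
            groups.setdefault(key, []).append(idx)
        res_atoms = []
        for key in native.residue_keys():
            idxs = groups.get(key, [])
            res_atoms.append(all_atom.positions[idxs] if idxs else None)
        threshold = params.contact_heavy_cutoff
    else:
        res_atoms = None
        threshold = params.contact_ca_cutoff
    contacts = []
    for i in range(n):
        for j in range(i + 1, n):
            same_chain = native.chain_ids[i] == native.chain_ids[j]
            if inter_chain_only and same_chain:
                continue
            if same_chain and (j - i) < params.contact_min_separation:
                continue
            if res_atoms is not None:
                ai, aj = res_atoms[i], res_atoms[j]
                if ai is None or aj is None:
                    continue
                d2 = ((ai[:, None, :] - aj[None, :, :]) ** 2).sum(-1)
                in_contact = d2.min() < threshold ** 2
            else:
                in_contact = np.linalg.norm(pos[i] - pos[j]) < threshold
            if in_contact:
                r0 = float(np.linalg.norm(pos[i] - pos[j]))
                contacts.append((i, j, r0))
    return contacts


def _contact_eps(native: Structure, pairs, params: GoModelParams) -> np.ndarray:
    if not pairs:
        return np.empty(0)
    if params.mj_weighting:
        w = np.array([mj_pair_energy(native.res_names[i], native.res_names[j])
                      for i, j, _ in pairs])
        return params.base_epsilon * w / w.mean()
    return np.full(len(pairs), params.base_epsilon)


def _nonnative_pairs(native: Structure, contacts, params: GoModelParams):
    """All pairs at sequence separation >= contact_min_separation (or on
    different chains) that are not native contacts."""
    n = len(native)
    contact_set = {(i, j) for i, j, _ in contacts}
    nn = []
    for i in range(n):
        for j in range(i + 1, n):
            same_chain = native.chain_ids[i] == native.chain_ids[j]
            if same_chain and (j - i) < params.contact_min_separation:
                continue
            if (i, j) in contact_set:
                continue
            nn.append((i, j))
    return nn


def build_go_model(native: Structure, all_atom_native: Structure | None = None,
                   params: GoModelParams | None = None) -> GoModel:
    """Build a C-alpha Go model whose minimum is ``native``.

    ``all_atom_native`` provides heavy atoms for contact detection;
    when omitted (or CA-only), a CA-CA distance criterion is used.
    """
    params = params or GoModelParams()
    pos = native.positions
    segments = _chain_segments(native, params.chain_break_distance,
                               params.force_connect)
    bonds, angles, dihedrals = [], [], []
    for lo, hi in segments:
        for i in range(lo, hi - 1):
            bonds.append((i, i + 1, float(np.linalg.norm(pos[i + 1] - pos[i]))))
        for i in range(lo, hi - 2):
            angles.append((i, i + 1, i + 2,
                           _angle(pos[i], pos[i + 1], pos[i + 2])))
        for i in range(lo, hi - 3):
            dihedrals.append((i, i + 1, i + 2, i + 3,
                              _dihedral(pos[i], pos[i + 1], pos[i + 2],
                                        pos[i + 3])))
    contacts = _detect_contacts(native, all_atom_native, params)
    eps = _contact_eps(native, contacts, params)
    nn = _nonnative_pairs(native, contacts, params)
    return GoModel(
        n_beads=len(native),
        bond_i=[b[0] for b in bonds], bond_j=[b[1] for b in bonds],
        bond_r0=[b[2] for b in bonds],
        bond_k=np.full(len(bonds), params.bond_k),
        ang_i=[a[0] for a in angles], ang_j=[a[1] for a in angles],
        ang_k=[a[2] for a in angles], ang_t0=[a[3] for a in angles],
        ang_ka=np.full(len(angles), params.angle_k),
        dih_i=[d[0] for d in dihedrals], dih_j=[d[1] for d in dihedrals],
        dih_k=[d[2] for d in dihedrals], dih_l=[d[3] for d in dihedrals],
        dih_p0=[d[4] for d in dihedrals],
        dih_k1=np.full(len(dihedrals), params.dihedral_k1),
        dih_k3=np.full(len(dihedrals), params.dihedral_k3),
        con_i=[c[0] for c in contacts], con_j=[c[1] for c in contacts],
        con_r0=[c[2] for c in contacts], con_eps=eps,
        nn_i=[p[0] for p in nn], nn_j=[p[1] for p in nn],
        nonnative_sigma=params.nonnative_sigma,
        nonnative_eps=params.nonnative_eps,
        cutoff=params.cutoff, switch_on=params.switch_on,
    )


def combine_chains(models: list[GoModel], complex_structure: Structure | None = None,
                   params: GoModelParams | None = None) -> GoModel:
    """Merge per-chain Go models into one model for the assembly.

    Bead indices of each model are offset by the sizes of the preceding
    models.  When ``complex_structure`` (the assembled complex, bead
    order matching the concatenation) is given, inter-chain native
    contacts are detected on it and added; inter-chain non-native pairs
    are always added.
    """
    params = params or GoModelParams()
    offsets = np.cumsum([0] + [m.n_beads for m in models])
    n_total = int(offsets[-1])
    if complex_structure is not None and len(complex_structure) != n_total:
        raise ValueError("complex structure size does not match models")

    def cat_i(attr):
        return np.concatenate([getattr(m, attr) + off
                               for m, off in zip(models, offsets)]) \
            if models else _empty_i()

    def cat_f(attr):
        return np.concatenate([getattr(m, attr) for m in models]) \
            if models else _empty_f()

    con_i, con_j = cat_i("con_i"), cat_i("con_j")
    con_r0, con_eps = cat_f("con_r0"), cat_f("con_eps")
    nn_i, nn_j = cat_i("nn_i"), cat_i("nn_j")

    if complex_structure is not None and len(models) > 1:
        inter = _detect_contacts(complex_structure, complex_structure, params,
                                 inter_chain_only=True)
        # restrict to pairs crossing a model boundary
        def model_of(idx):
            return np.searchsorted(offsets, idx, side="right") - 1
        inter = [(i, j, r0) for i, j, r0 in inter if model_of(i) != model_of(j)]
        inter_eps = _contact_eps(complex_structure, inter, params)
        con_i = np.concatenate([con_i, [i for i, _, _ in inter]]).astype(np.int64)
        con_j = np.concatenate([con_j, [j for _, j, _ in inter]]).astype(np.int64)
        con_r0 = np.concatenate([con_r0, [r for _, _, r in inter]])
        con_eps = np.concatenate([con_eps, inter_eps])
        # inter-chain non-native pairs (everything not in contact)
        contact_set = set(zip(con_i.tolist(), con_j.tolist()))
        extra_nn = [(i, j)
                    for i in range(n_total) for j in range(i + 1, n_total)
                    if model_of(i) != model_of(j)
                    and (i, j) not in contact_set]
        if extra_nn:
            nn_i = np.concatenate([nn_i, [p[0] for p in extra_nn]]).astype(np.int64)
            nn_j = np.concatenate([nn_j, [p[1] for p in extra_nn]]).astype(np.int64)

    order = np.lexsort((con_j, con_i))
    return GoModel(
        n_beads=n_total,
        bond_i=cat_i("bond_i"), bond_j=cat_i("bond_j"),
        bond_r0=cat_f("bond_r0"), bond_k=cat_f("bond_k"),
        ang_i=cat_i("ang_i"), ang_j=cat_i("ang_j"), ang_k=cat_i("ang_k"),
        ang_t0=cat_f("ang_t0"), ang_ka=cat_f("ang_ka"),
        dih_i=cat_i("dih_i"), dih_j=cat_i("dih_j"), dih_k=cat_i("dih_k"),
        dih_l=cat_i("dih_l"), dih_p0=cat_f("dih_p0"),
        dih_k1=cat_f("dih_k1"), dih_k3=cat_f("dih_k3"),
        con_i=con_i[order], con_j=con_j[order],
        con_r0=con_r0[order], con_eps=con_eps[order],
        nn_i=nn_i, nn_j=nn_j,
        nonnative_sigma=models[0].nonnative_sigma if models else params.nonnative_sigma,
        nonnative_eps=models[0].nonnative_eps if models else params.nonnative_eps,
        cutoff=models[0].cutoff if models else params.cutoff,
        switch_on=models[0].switch_on if models else params.switch_on,
    )


def scale_contacts(m: GoModel, selection_a, selection_b,
                   factor: float) -> GoModel:
    """Multiply eps of contacts with one endpoint in each selection.

    Selections are bead-index sets.  Returns a new model.
    """
    if factor <= 0:
        raise ValueError("factor must be positive")
    sa, sb = set(map(int, selection_a)), set(map(int, selection_b))
    if not sa or not sb:
        warnings.warn("empty selection: no contacts rescaled", UserWarning,
                      stacklevel=2)
        return m.copy()
    out = m.copy()
    for c in range(len(out.con_i)):
        i, j = int(out.con_i[c]), int(out.con_j[c])
        if (i in sa and j in sb) or (i in sb and j in sa):
            out.con_eps[c] *= factor
    return out


def energy_forces(m: GoModel, positions: np.ndarray):
    """Total Go-model energy (kcal/mol) and forces (kcal/mol/A)."""
    positions = np.ascontiguousarray(positions, dtype=np.float64)
    if positions.shape != (m.n_beads, 3):
        raise ValueError(f"positions shape {positions.shape} does not match "
                         f"model with {m.n_beads} beads")
    e, f = _kernels.go_energy_forces(positions, *m.kernel_args())
    if np.isnan(e):
        raise ValueError("coincident beads (pair distance < 1e-6 A)")
    return float(e), f
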