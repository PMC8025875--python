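"""Pairwise C-alpha RMSD benchmark between two conformational states.

Classic open/closed PDB pairs used to validate flexible-fitting inputs:
the RMSD between paired C-alpha atoms of the initial and target
structures after optimal superposition.  Structures are read from a
local directory when present and otherwise fetched from RCSB (network
required).
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .structure import Structure, pair_residues, read_pdb, rmsd

__all__ = ["STATE_PAIRS", "pairwise_ca_rmsd", "fetch_pdb", "load_structure"]


@dataclass(frozen=True)
class StatePair:
    system: str
    initial: str            # pdb id, optionally with :chain suffix
    target: str
    reference_rmsd: float   # published C-alpha RMSD (A)


# Initial -> target conformational pairs with published C-alpha RMSDs.
STATE_PAIRS = (
    StatePair("adenylate kinase", "4ake", "1ake", 7.1),
    StatePair("ribose binding protein", "2dri", "1urp", 4.1),
    StatePair("maltodextrin binding protein", "1omp", "1anf", 3.8),
    StatePair("diphtheria toxin", "1ddt", "1mdt", 15.6),
    StatePair("CO dehydrogenase", "1oao:C", "1oao:D", 7.9),
    StatePair("CorA", "3jcf", "3jcg", 9.7),
)


def fetch_pdb(pdb_id: str, directory: Path, timeout: float = 30.0) -> Path:
    """Download a PDB entry from RCSB into ``directory`` (cached)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / f"{pdb_id.lower()}.pdb"
    if path.exists():
        return path
    import urllib.request
    url = f"https://files.rcsb.org/download/{pdb_id.upper()}.pdb"
    with urllib.request.urlopen(url, timeout=timeout) as resp:
        data = resp.read()
    path.write_bytes(data)
    return path


def load_structure(spec: str, directory: Path, fetch: bool = True) -> Structure:
    """Load C-alpha beads for ``pdbid`` or ``pdbid:CHAIN``."""
    if ":" in spec:
        pdb_id, chain = spec.split(":")
    else:
        pdb_id, chain = spec, None
    directory = Path(directory)
    path = directory / f"{pdb_id.lower()}.pdb"
    if not path.exists():
        if not fetch:
            raise FileNotFoundError(path)
        path = fetch_pdb(pdb_id, directory)
    s = read_pdb(path, selection="CA")
    if chain is not None:
        s = s.select(s.chain_ids == chain)
        if len(s) == 0:
            raise ValueError(f"chain {chain} not found in {pdb_id}")
    return s


def pairwise_ca_rmsd(initial: Structure, target: Structure,
                     by: str = "key") -> float:
    """Best-fit C-alpha RMSD over residues shared by the two structures.

    ``by``: "key" pairs on (chain, residue number, insertion code);
    "resid" pairs on (residue number, insertion code) only, for chain
    pairs within one entry; "order" pairs sequentially.
    """
    if by == "key":
        ia, ib = pair_residues(initial, target)
    elif by == "resid":
        key_b = {}
        for j, (_, rid, ic) in enumerate(target.residue_keys()):
            key_b.setdefault((rid, ic), j)
        ia, ib = [], []
        for i, (_, rid, ic) in enumerate(initial.residue_keys()):
            j = key_b.get((rid, ic))
            if j is not None:
                ia.append(i)
                ib.append(j)
        ia, ib = np.asarray(ia, dtype=np.intp), np.asarray(ib, dtype=np.intp)
    elif by == "order":
        n = min(len(initial), len(target))
        ia = ib = np.arange(n)
    else:
        raise ValueError(f"unknown pairing mode {by!r}")
    if len(ia) < 3:
        raise ValueError("fewer than 3 paired residues")
    return rmsd(initial.positions[ia], target.positions[ib], fit=True)


def run_benchmark(directory, fetch: bool = True) -> dict[str, float]:
    """Compute the C-alpha RMSD for every state pair; returns
    system -> RMSD (A)."""
    out = {}
    for pair in STATE_PAIRS:
        a = load_structure(pair.initial, directory, fetch=fetch)
        b = load_structure(pair.target, directory, fetch=fetch)
        same_entry = pair.initial.split(":")[0] == pair.target.split(":")[0]
        out[pair.system] = pairwise_ca_rmsd(a, b,
                                            by="resid" if same_entry else "key")
    return out
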