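"""Model-quality metrics and best-model selection.

Metrics: map cross-correlation (CC), RMSD to the target structure
(RMSDt) and to the initial structure (RMSDi) over paired C-alpha atoms,
and the secondary-structure score -- the Hamming distance between two
per-residue secondary-structure strings, normalized by length and
expressed as a percentage (0% identical, 100% entirely different).
"""
from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .density import DensityGrid, cross_correlation, simulate_map
from .engine import MapSpec
from .structure import Structure, pair_residues, rmsd

__all__ = ["ss_score", "collapse_to_three_state", "read_dssp_string",
           "FitReport", "evaluate_models"]

DSSP_CODES = set("HGIEBTSC")

_THREE_STATE = {"H": "H", "G": "H", "I": "H", "E": "E", "B": "E",
                "T": "C", "S": "C", "C": "C"}


def _normalize(s: str) -> str:
    out = s.replace(" ", "C").replace("-", "C").upper()
    bad = set(out) - DSSP_CODES
    if bad:
        raise ValueError(f"unknown secondary-structure codes: {sorted(bad)}")
    return out


def collapse_to_three_state(s: str) -> str:
    """Collapse 8-state DSSP codes to helix/strand/coil (H/E/C)."""
    return "".join(_THREE_STATE[c] for c in _normalize(s))


def ss_score(a: str, b: str, three_state: bool = False) -> float:
    """Normalized Hamming distance between two secondary-structure
    strings, as a percentage.

    Blank and '-' are treated as coil before comparison.  Strings must
    have equal, non-zero length.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty secondary-structure string")
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    if three_state:
        a, b = collapse_to_three_state(a), collapse_to_three_state(b)
    else:
        a, b = _normalize(a), _normalize(b)
    mismatches = sum(x != y for x, y in zip(a, b))
    return 100.0 * mismatches / len(a)


def read_dssp_string(path) -> str:
    """Extract the one-letter structure column from a DSSP output file."""
    lines = open(path).read().splitlines()
    try:
        start = next(i for i, ln in enumerate(lines)
                     if ln.lstrip().startswith("#  RESIDUE"))
    except StopIteration:
        raise ValueError(f"not a DSSP file: {path!s}") from None
    codes = []
    for ln in lines[start + 1:]:
        if len(ln) < 17:
            continue
        if ln[13] == "!":  # chain break marker
            continue
        codes.append(ln[16] if ln[16] != " " else "C")
    return "".join(codes)


@dataclass
class FitReport:
    model_id: str
    cc: float
    rmsd_t: float
    rmsd_i: float
    ss_score: float | None
    rank: int

    def as_dict(self):
        return asdict(self)


def evaluate_models(models: list[Structure], target: Structure,
                    target_map: DensityGrid, initial: Structure,
                    ss_target: str | None = None,
                    ss_models: list[str] | None = None,
                    map_spec: MapSpec | None = None,
                    model_ids: list[str] | None = None) -> list[FitReport]:
    """Score candidate models and rank them by CC (descending).

    CC uses a map simulated from each model on the target map's lattice
    with the same resolution/truncation settings as the fitting run.
    RMSDt/RMSDi pair residues by (chain, residue, insertion code).
    """
    map_spec = map_spec or MapSpec()
    if ss_models is not None and ss_target is None:
        raise ValueError("ss_models given without ss_target")
    ids = model_ids or [f"model_{i + 1}" for i in range(len(models))]
    rows = []
    for idx, model in enumerate(models):
        calc = simulate_map(model, resolution=map_spec.resolution,
                            truncate_fraction=map_spec.truncate_fraction,
                            sigma_multiplier=map_spec.sigma_multiplier,
                            lattice=target_map)
        cc = cross_correlation(target_map, calc)
        it, jt = pair_residues(model, target)
        rt = rmsd(model.positions[it], target.positions[jt], fit=True)
        ii, ji = pair_residues(model, initial)
        ri = rmsd(model.positions[ii], initial.positions[ji], fit=True)
        ss = None
        if ss_models is not None and ss_target is not None:
            ss = ss_score(ss_models[idx], ss_target)
        rows.append((ids[idx], cc, rt, ri, ss))
    order = np.argsort([-r[1] for r in rows], kind="stable")
    reports = []
    for rank, pos in enumerate(order, start=1):
        mid, cc, rt, ri, ss = rows[pos]
        reports.append(FitReport(mid, cc, rt, ri, ss, rank))
    reports.sort(key=lambda r: r.rank)
    return reports


def reports_to_frame(reports: list[FitReport]) -> pd.DataFrame:
    return pd.DataFrame([r.as_dict() for r in reports])
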