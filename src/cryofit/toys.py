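"""Deterministic two-state toy proteins for end-to-end testing.

A hinge toy is two idealized C-alpha helical arms (rise 1.5 A/residue,
radius 2.3 A, 100 degrees/residue) joined at a hinge; the two states
differ only by the angle between the arm axes.  Fitting the open state
into a map simulated from the closed state (or vice versa) exercises the
whole pipeline on seconds-scale systems with a known answer structure.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .density import DensityGrid, simulate_map
from .structure import RESIDUE_MASSES, Structure

__all__ = ["ToySystem", "make_hinge_toy", "make_fitting_case"]

HELIX_RISE = 1.5         # A per residue
HELIX_RADIUS = 2.3       # A
HELIX_TWIST = 100.0      # degrees per residue

# repeating sequence for the toy arms: a mix of hydrophobic/polar types
_TOY_SEQUENCE = ("LEU", "ALA", "GLU", "VAL", "LYS", "ILE", "SER", "PHE",
                 "THR", "MET")


@dataclass
class ToySystem:
    state_a: Structure
    state_b: Structure
    hinge_angle_a: float
    hinge_angle_b: float
    n_residues: int
    seed: int


def _helix_arm(n: int, direction: np.ndarray, start: np.ndarray,
               u: np.ndarray, phase: float = 0.0) -> np.ndarray:
    """Ideal C-alpha helix of ``n`` residues along ``direction``; ``u``
    is the zero-phase radial direction (must be unit, perpendicular)."""
    direction = direction / np.linalg.norm(direction)
    v = np.cross(direction, u)
    coords = np.empty((n, 3))
    for i in range(n):
        ang = np.deg2rad(phase + i * HELIX_TWIST)
        coords[i] = (start + direction * (i * HELIX_RISE)
                     + HELIX_RADIUS * (np.cos(ang) * u + np.sin(ang) * v))
    return coords


def _hinge_state(n_per_arm: int, angle_deg: float) -> np.ndarray:
    """Two helical arms meeting at the origin with a given opening angle,
    in the x-z plane, symmetric about the z axis.

    Both arms share the radial frame vector (0,-1,0); the second arm is
    offset by one helical rise and one twist so that the junction CA-CA
    distance equals the ideal helical step (~3.8 A) for any hinge angle.
    """
    half = np.deg2rad(angle_deg) / 2.0
    d1 = np.array([np.sin(half), 0.0, np.cos(half)])
    d2 = np.array([-np.sin(half), 0.0, np.cos(half)])
    u = np.array([0.0, -1.0, 0.0])
    arm1 = _helix_arm(n_per_arm, d1, np.zeros(3), u)
    arm2 = _helix_arm(n_per_arm, d2, d2 * HELIX_RISE, u, phase=HELIX_TWIST)
    # arm1 runs toward the hinge, arm2 away: a continuous chain
    return np.vstack([arm1[::-1], arm2])


def make_hinge_toy(n_per_arm: int = 15, hinge_angle_a: float = 150.0,
                   hinge_angle_b: float = 90.0, seed: int = 0) -> ToySystem:
    """Two-state hinge toy with identical topology in both states."""
    if n_per_arm < 5:
        raise ValueError("need at least 5 residues per arm")
    for ang in (hinge_angle_a, hinge_angle_b):
        if not 0.0 < ang < 180.0:
            raise ValueError("hinge angles must lie in (0, 180) degrees")
    n = 2 * n_per_arm
    res_names = np.array([_TOY_SEQUENCE[i % len(_TOY_SEQUENCE)]
                          for i in range(n)])
    masses = np.array([RESIDUE_MASSES[r] for r in res_names])
    meta = dict(
        residue_ids=np.arange(1, n + 1),
        chain_ids=np.full(n, "A"),
        names=np.full(n, "CA"),
        res_names=res_names,
        masses=masses,
    )
    state_a = Structure(positions=_hinge_state(n_per_arm, hinge_angle_a), **meta)
    state_b = Structure(positions=_hinge_state(n_per_arm, hinge_angle_b), **meta)
    return ToySystem(state_a, state_b, hinge_angle_a, hinge_angle_b, n, seed)


def make_fitting_case(toy: ToySystem, resolution: float = 5.0,
                      voxel: float = 2.0, padding: float = 8.0,
                      truncate_fraction: float = 0.01):
    """(initial structure, target map, answer structure) for one toy.

    The target map is simulated from state B; fitting starts from state A
    and the answer (for RMSDt scoring) is state B.
    """
    target_map = simulate_map(toy.state_b, resolution=resolution, voxel=voxel,
                              padding=padding,
                              truncate_fraction=truncate_fraction)
    return toy.state_a, target_map, toy.state_b
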