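"""Thermostatted coarse-grained dynamics with bond constraints and the
density-fitting bias force.

The integrator is velocity Verlet with SHAKE position constraints on the
pseudo-bonds and a RATTLE velocity correction.  The fitting bias is
V_EM = k * (1 - CC); its force k * dCC/dr is recomputed (together with
the simulated map on the target lattice) at every step by default.
Temperature control is a Berendsen weak-coupling rescale (default
coupling time 0.2 ps); runs are deterministic given the velocity seed,
because no random numbers are drawn during integration.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from ._kernels import KB, KCAL_TO_AKMA
from .density import DensityGrid, sigma_from_resolution, truncation_radius
from .gomodel import GoModel, energy_forces
from .structure import Structure

__all__ = ["SimState", "ThermostatSpec", "MapSpec", "bias_energy",
           "initial_velocities", "step", "run_fitting", "FittingResult"]


def bias_energy(k: float, cc: float) -> float:
    """Fitting bias energy V_EM = k * (1 - CC), kcal/mol."""
    if k < 0:
        raise ValueError("force constant must be non-negative")
    return k * (1.0 - cc)


@dataclass
class ThermostatSpec:
    """Berendsen weak coupling; ``tau_ps <= 0`` disables the thermostat."""

    temperature: float = 200.0
    tau_ps: float = 0.2


@dataclass
class MapSpec:
    """How the calculated map is synthesized on the target lattice."""

    resolution: float = 5.0
    truncate_fraction: float = 0.01
    sigma_multiplier: float = 1.0

    @property
    def sigma(self) -> float:
        return sigma_from_resolution(self.resolution, self.sigma_multiplier)

    @property
    def radius(self) -> float:
        r = truncation_radius(self.sigma, self.truncate_fraction)
        return r if np.isfinite(r) else 20.0 * self.sigma


@dataclass
class SimState:
    """Mutable per-replica simulation state."""

    positions: np.ndarray
    velocities: np.ndarray
    masses: np.ndarray
    time_ps: float = 0.0
    temperature_target: float = 200.0
    force_constant_k: float = 0.0
    rng_seed: int = 0

    def __post_init__(self):
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        self.velocities = np.ascontiguousarray(self.velocities, dtype=np.float64)
        self.masses = np.asarray(self.masses, dtype=np.float64)
        if self.positions.shape != self.velocities.shape:
            raise ValueError("positions/velocities shape mismatch")
        if self.temperature_target <= 0:
            raise ValueError("temperature_target must be positive")
        if self.force_constant_k < 0:
            raise ValueError("force constant must be non-negative")

    def copy(self) -> "SimState":
        return SimState(self.positions.copy(), self.velocities.copy(),
                        self.masses.copy(), self.time_ps,
                        self.temperature_target, self.force_constant_k,
                        self.rng_seed)

    def kinetic_temperature(self, n_constraints: int = 0) -> float:
        ke = _kernels.kinetic_energy(self.velocities, self.masses)
        ndof = max(3 * len(self.masses) - n_constraints, 1)
        return 2.0 * ke / (KB * ndof)


def remove_rigid_momentum(positions, velocities, masses) -> np.ndarray:
    """Remove net linear and angular momentum from a velocity set.

    Standard practice for in-vacuo simulations: without it the molecule
    drifts and tumbles as a rigid body, eventually leaving the density
    grid.  Returns corrected velocities.
    """
    positions = np.asarray(positions, float)
    velocities = np.array(velocities, float)
    masses = np.asarray(masses, float)
    mtot = masses.sum()
    velocities -= (masses @ velocities) / mtot
    com = (masses @ positions) / mtot
    rel = positions - com
    ang_mom = (masses[:, None] * np.cross(rel, velocities)).sum(axis=0)
    inertia = np.zeros((3, 3))
    for m, r in zip(masses, rel):
        inertia += m * ((r @ r) * np.eye(3) - np.outer(r, r))
    omega = np.linalg.solve(inertia, ang_mom)
    velocities -= np.cross(omega, rel)
    return velocities


def initial_velocities(masses, temperature: float, seed: int,
                       positions=None) -> np.ndarray:
    """Maxwell-Boltzmann velocities (A/ps), deterministic given the seed.

    When ``positions`` are supplied, net linear and angular momentum are
    projected out.
    """
    rng = np.random.default_rng(seed)
    masses = np.asarray(masses, dtype=np.float64)
    sd = np.sqrt(KB * temperature * KCAL_TO_AKMA / masses)
    vel = rng.normal(size=(len(masses), 3)) * sd[:, None]
    if positions is not None:
        vel = remove_rigid_momentum(positions, vel, masses)
    return vel


def make_state(s: Structure, temperature: float = 200.0, k: float = 0.0,
               seed: int = 0) -> SimState:
    """SimState for a structure with Maxwell-Boltzmann velocities (net
    linear and angular momentum removed)."""
    return SimState(
        positions=s.positions.copy(),
        velocities=initial_velocities(s.masses, temperature, seed,
                                      positions=s.positions),
        masses=s.masses, temperature_target=temperature,
        force_constant_k=k, rng_seed=seed)


class SimulationError(RuntimeError):
    pass


def _run_segment(state: SimState, model: GoModel, target: DensityGrid | None,
                 map_spec: MapSpec, dt_ps: float, nsteps: int,
                 thermostat: ThermostatSpec | None,
                 use_shake: bool, shake_tol: float, shake_maxiter: int,
                 buf: np.ndarray | None, track_best: bool):
    has_map = target is not None
    if has_map:
        tvals = np.ascontiguousarray(target.values)
        t_sq = float((tvals * tvals).sum())
        origin = target.origin
        spacing = target.spacing
        if buf is None:
            buf = np.zeros_like(tvals)
    else:
        tvals = np.zeros((1, 1, 1))
        t_sq = 1.0
        origin = np.zeros(3)
        spacing = np.ones(3)
        buf = np.zeros((1, 1, 1))
    tau = thermostat.tau_ps if thermostat else 0.0
    temp0 = thermostat.temperature if thermostat else 0.0
    cc_series = np.zeros(nsteps)
    best_pos = np.zeros_like(state.positions)
    status, best_cc = _kernels.md_segment(
        state.positions, state.velocities, state.masses,
        *model.kernel_args(),
        use_shake, shake_tol, shake_maxiter,
        has_map, tvals, t_sq, origin.astype(float), spacing.astype(float),
        map_spec.sigma, map_spec.radius,
        np.ones(model.n_beads), state.force_constant_k, buf,
        dt_ps, nsteps, temp0, tau,
        cc_series, track_best, best_pos)
    if status == 1:
        raise SimulationError("SHAKE failed to converge")
    if status == 2:
        raise SimulationError("non-finite force or zero calculated density")
    state.time_ps += nsteps * dt_ps
    return cc_series, best_cc, best_pos


def step(state: SimState, model: GoModel, target: DensityGrid | None = None,
         dt_fs: float = 20.0, thermostat: ThermostatSpec | None = None,
         map_spec: MapSpec | None = None, n_steps: int = 1,
         use_shake: bool = True, shake_tol: float = 1e-8,
         shake_maxiter: int = 500) -> SimState:
    """Advance ``state`` by ``n_steps`` integration steps (in place).

    Total force is Go forces plus ``k * dCC/dr`` when a target map is
    given.  Returns the state for chaining.
    """
    map_spec = map_spec or MapSpec()
    _run_segment(state, model, target, map_spec, dt_fs * 1e-3, n_steps,
                 thermostat, use_shake, shake_tol, shake_maxiter, None, False)
    return state


@dataclass
class FittingResult:
    frames: list[np.ndarray]
    cc_series: np.ndarray          # CC at every step
    frame_steps: np.ndarray        # step index of each stored frame
    best_positions: np.ndarray
    best_cc: float
    best_step: int
    state: SimState

    def cc_table(self):
        """(step, time_ps, cc, bias_energy) rows for TSV output."""
        import pandas as pd
        steps = np.arange(1, len(self.cc_series) + 1)
        return pd.DataFrame({
            "step": steps,
            "time_ps": steps * self._dt_ps,
            "cc": self.cc_series,
            "bias_energy": self.state.force_constant_k * (1.0 - self.cc_series),
        })

    _dt_ps: float = 0.02


def run_fitting(state: SimState, model: GoModel, target: DensityGrid,
                n_steps: int, dt_fs: float = 20.0,
                thermostat: ThermostatSpec | None = None,
                map_spec: MapSpec | None = None,
                record_every: int = 100,
                use_shake: bool = True, shake_tol: float = 1e-8,
                shake_maxiter: int = 500) -> FittingResult:
    """Flexible-fitting MD: Go forces plus the CC bias at fixed k.

    Returns recorded frames (every ``record_every`` steps, plus the final
    frame), the per-step CC series, and the best (highest-CC) visited
    coordinates with earliest-frame tie-breaking.
    """
    if np.any(target.values < 0):
        raise ValueError("target map must be non-negative (use remove_negative)")
    thermostat = thermostat if thermostat is not None else \
        ThermostatSpec(temperature=state.temperature_target)
    map_spec = map_spec or MapSpec()
    tvals = np.ascontiguousarray(target.values)
    buf = np.zeros_like(tvals)
    cc_all = np.empty(n_steps)
    frames, frame_steps = [], []
    best_cc, best_step = -np.inf, -1
    best_pos = state.positions.copy()
    done = 0
    while done < n_steps:
        chunk = min(record_every, n_steps - done)
        cc_seg, seg_best, seg_best_pos = _run_segment(
            state, model, target, map_spec, dt_fs * 1e-3, chunk, thermostat,
            use_shake, shake_tol, shake_maxiter, buf, True)
        cc_all[done:done + chunk] = cc_seg
        if seg_best > best_cc:  # strict comparison: earliest frame wins ties
            best_cc = seg_best
            best_pos = seg_best_pos.copy()
            best_step = done + int(np.argmax(cc_seg >= seg_best))
        done += chunk
        frames.append(state.positions.copy())
        frame_steps.append(done)
    res = FittingResult(
        frames=frames, cc_series=cc_all,
        frame_steps=np.array(frame_steps, dtype=np.int64),
        best_positions=best_pos, best_cc=float(best_cc),
        best_step=best_step, state=state)
    res._dt_ps = dt_fs * 1e-3
    return res
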