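"""Replica exchange over fitting force constants (REUSfit).

Each replica runs flexible-fitting MD at its own bias force constant k.
Periodically, neighboring replicas on the k ladder attempt to swap force
constants with Metropolis probability on

    Delta = beta * (k_n - k_m) * (CC_j - CC_i),

accepted with probability 1 for Delta <= 0 and exp(-Delta) otherwise.
The rule routes higher force constants to the replicas that currently
fit the map better.  Swaps exchange the force constants (parameters),
not coordinates, so each trajectory stays continuous.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._kernels import KB
from .density import DensityGrid
from .engine import (MapSpec, SimState, ThermostatSpec, _run_segment,
                     make_state)
from .gomodel import GoModel
from .structure import Structure

__all__ = ["default_ladder", "exchange_probability", "ReplicaEnsemble",
           "attempt_exchanges", "run_reusfit", "ReusConfig", "ReusResult"]

# Force-constant ladder used in the original REUSfit protocol:
# 32 values, 500..5000 kcal/mol, geometric-like progression.
_DEFAULT_LADDER = (
    500, 524, 555, 593, 636, 684, 737, 794, 856, 921, 991, 1065, 1144,
    1228, 1318, 1415, 1519, 1632, 1755, 1889, 2035, 2195, 2371, 2564,
    2777, 3011, 3269, 3553, 3865, 4209, 4586, 5000,
)


def default_ladder() -> np.ndarray:
    """The standard 32-replica force-constant ladder (kcal/mol)."""
    return np.array(_DEFAULT_LADDER, dtype=np.float64)


def reduced_ladder(n: int, k_min: float = 500.0, k_max: float = 5000.0) -> np.ndarray:
    """Geometric ladder of ``n`` force constants spanning [k_min, k_max]."""
    if n < 2:
        raise ValueError("need at least 2 replicas")
    return np.geomspace(k_min, k_max, n)


def exchange_probability(beta: float, k_m: float, k_n: float,
                         cc_i: float, cc_j: float) -> float:
    """Metropolis acceptance probability for swapping k_m (replica i)
    with k_n (replica j)."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    delta = beta * (k_n - k_m) * (cc_j - cc_i)
    return 1.0 if delta <= 0 else math.exp(-delta)


@dataclass
class ExchangeAttempt:
    step: int
    pair: tuple[int, int]      # ladder slot indices
    delta: float
    accepted: bool


@dataclass
class ReplicaEnsemble:
    """Replicas plus the k ladder and a shared inverse temperature.

    ``assignment[slot]`` is the replica index currently holding
    ``ladder[slot]``; exchanging two neighboring slots permutes this
    assignment.
    """

    replicas: list[SimState]
    ladder: np.ndarray
    beta: float
    assignment: np.ndarray = None  # type: ignore[assignment]
    attempt_log: list[ExchangeAttempt] = field(default_factory=list)

    def __post_init__(self):
        self.ladder = np.asarray(self.ladder, dtype=np.float64)
        if np.any(np.diff(self.ladder) <= 0):
            raise ValueError("ladder must be strictly increasing")
        if len(self.replicas) != len(self.ladder):
            raise ValueError("one replica per ladder value required")
        if self.assignment is None:
            self.assignment = np.arange(len(self.ladder))
        self.assignment = np.asarray(self.assignment, dtype=np.int64)
        self._sync_k()

    def _sync_k(self):
        for slot, rep in enumerate(self.assignment):
            self.replicas[rep].force_constant_k = float(self.ladder[slot])

    def k_of_replica(self) -> np.ndarray:
        k = np.empty(len(self.ladder))
        for slot, rep in enumerate(self.assignment):
            k[rep] = self.ladder[slot]
        return k


def attempt_exchanges(ens: ReplicaEnsemble, cc: np.ndarray, phase: int,
                      rng: np.random.Generator, step: int = 0) -> ReplicaEnsemble:
    """Attempt neighbor swaps for one phase (0: pairs (0,1),(2,3)...;
    1: pairs (1,2),(3,4)...), given each replica's current CC.

    Mutates and returns ``ens``; every attempt is logged.
    """
    m = len(ens.ladder)
    for lo in range(phase % 2, m - 1, 2):
        hi = lo + 1
        rep_i = ens.assignment[lo]
        rep_j = ens.assignment[hi]
        delta = ens.beta * (ens.ladder[hi] - ens.ladder[lo]) * (cc[rep_j] - cc[rep_i])
        accepted = delta <= 0 or rng.random() < math.exp(-delta)
        if accepted:
            ens.assignment[lo], ens.assignment[hi] = rep_j, rep_i
        ens.attempt_log.append(ExchangeAttempt(step, (lo, hi), float(delta),
                                               bool(accepted)))
    ens._sync_k()
    return ens


def replica_seed(seed: int, replica: int) -> int:
    """Velocity seed used for one replica of a run (deterministic)."""
    return int(np.random.SeedSequence([seed, replica]).generate_state(1)[0] % (2 ** 31))


@dataclass
class ReusConfig:
    ladder: np.ndarray = None  # type: ignore[assignment]
    n_steps: int = 200_000
    dt_fs: float = 20.0
    temperature: float = 200.0
    tau_ps: float = 0.2
    exchange_period_steps: int = 100   # 2 ps at dt = 20 fs
    exchange: bool = True
    map_spec: MapSpec = field(default_factory=MapSpec)
    seed: int = 0
    record_k_trace: bool = True

    def __post_init__(self):
        if self.ladder is None:
            self.ladder = default_ladder()
        self.ladder = np.asarray(self.ladder, dtype=np.float64)
        if self.n_steps % self.exchange_period_steps:
            raise ValueError("n_steps must be a multiple of the exchange period")


@dataclass
class ReusResult:
    best_positions: np.ndarray
    best_cc: float
    best_replica: int
    best_segment: int
    cc_trace: np.ndarray          # (n_segments, n_replicas) CC at segment ends
    k_trace: np.ndarray           # (n_segments, n_replicas) k per replica
    attempt_log: list[ExchangeAttempt]
    final_states: list[SimState]

    def acceptance_rate(self) -> float:
        if not self.attempt_log:
            return float("nan")
        return float(np.mean([a.accepted for a in self.attempt_log]))


def run_reusfit(initial: Structure, model: GoModel, target: DensityGrid,
                config: ReusConfig | None = None) -> ReusResult:
    """Replica-exchange flexible fitting from ``initial`` into ``target``.

    The best model is the highest-CC coordinates over all replicas and
    steps (earliest occurrence wins ties).  With ``exchange=False`` the
    replicas run as independent fixed-k fitting simulations (the ladder
    is still used for the per-replica force constants).
    """
    config = config or ReusConfig()
    if np.any(target.values < 0):
        raise ValueError("target map must be non-negative")
    m = len(config.ladder)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xEC]))
    replicas = [
        make_state(initial, config.temperature, float(config.ladder[r]),
                   seed=replica_seed(config.seed, r))
        for r in range(m)
    ]
    ens = ReplicaEnsemble(replicas, config.ladder, beta=1.0 / (KB * config.temperature))
    thermostat = ThermostatSpec(config.temperature, config.tau_ps)
    tvals = np.ascontiguousarray(target.values)
    buf = np.zeros_like(tvals)
    n_segments = config.n_steps // config.exchange_period_steps
    cc_trace = np.zeros((n_segments, m))
    k_trace = np.zeros((n_segments, m))
    best_cc, best_rep, best_seg = -np.inf, -1, -1
    best_pos = initial.positions.copy()
    cc_now = np.zeros(m)
    for seg in range(n_segments):
        for rep in range(m):
            cc_seg, seg_best, seg_best_pos = _run_segment(
                ens.replicas[rep], model, target, config.map_spec,
                config.dt_fs * 1e-3, config.exchange_period_steps,
                thermostat, True, 1e-8, 500, buf, True)
            cc_now[rep] = cc_seg[-1]
            if seg_best > best_cc:
                best_cc, best_rep, best_seg = seg_best, rep, seg
                best_pos = seg_best_pos.copy()
        cc_trace[seg] = cc_now
        k_trace[seg] = ens.k_of_replica()
        if config.exchange:
            attempt_exchanges(ens, cc_now, phase=seg % 2, rng=rng,
                              step=(seg + 1) * config.exchange_period_steps)
    return ReusResult(
        best_positions=best_pos, best_cc=float(best_cc),
        best_replica=best_rep, best_segment=best_seg,
        cc_trace=cc_trace, k_trace=k_trace,
        attempt_log=ens.attempt_log, final_states=ens.replicas)
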