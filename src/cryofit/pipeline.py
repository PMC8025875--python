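"""Three-step multi-scale fitting protocol and the single-run baseline.

Step 1 runs replica-exchange flexible fitting (REUSfit) with the Go
model and keeps the highest-CC model of each independent run (M1).
Step 2 drives the initial structure to each M1 by targeted MD -- the
density map is not used in this step -- and aligns the result onto its
target (M2).  Step 3 refines each M2 by fixed-k flexible fitting and
ranks the results by CC (M3).  The simple protocol (SP) is the baseline:
independent fixed-k flexible-fitting runs straight from the initial
structure.

This implementation operates at C-alpha/Go-model resolution in every
step; the machinery is resolution-agnostic by contract.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .analysis import FitReport, evaluate_models
from .density import DensityGrid, read_mrc, read_situs, remove_negative, simulate_map
from .engine import MapSpec, make_state, run_fitting
from .gomodel import GoModel, GoModelParams, build_go_model
from .reus import ReusConfig, reduced_ladder, default_ladder, run_reusfit
from .structure import Structure, read_pdb, superpose, write_pdb
from .tmd import TmdSchedule, run_targeted_md

logger = logging.getLogger("cryofit.pipeline")

__all__ = ["ProtocolConfig", "run_multiscale", "run_simple",
           "MultiscaleResult", "SimpleResult"]


@dataclass
class ProtocolConfig:
    """Configuration of the multi-scale and simple protocols.

    Physical quantities carry units in their key names.  Exactly one of
    ``target_map_path`` / ``target_pdb_path`` is required (with a target
    PDB the map is simulated from it).
    """

    initial_pdb_path: str | None = None
    target_pdb_path: str | None = None
    target_map_path: str | None = None

    map_resolution_A: float = 5.0
    map_voxel_A: float = 2.0
    map_padding_A: float = 8.0
    map_truncate_fraction: float = 0.01

    ladder_kcal_mol: list[float] | None = None
    n_replicas: int = 8

    n_runs: int = 5                  # independent step-1 runs
    n_best: int = 5                  # models carried through steps 2-3
    step1_n_steps: int = 200_000
    dt_fs: float = 20.0
    temperature_K: float = 200.0
    exchange_period_steps: int = 100
    exchange: bool = True

    tmd_time_ps: float = 100.0
    tmd_dt_fs: float = 10.0
    tmd_rhof_A: float = 0.1
    tmd_k_rmsd: float = 20000.0

    step3_n_steps: int = 20_000
    step3_k_kcal_mol: float | None = None   # default: ladder median

    simple_n_replicates: int = 5
    simple_n_steps: int = 200_000
    simple_k_kcal_mol: float | None = None

    seed: int = 0
    run_dir: str | None = None

    def __post_init__(self):
        if self.n_best < 1:
            raise ValueError("n_best must be >= 1")
        for path in (self.initial_pdb_path, self.target_pdb_path,
                     self.target_map_path):
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(path)

    @classmethod
    def from_yaml(cls, path) -> "ProtocolConfig":
        raw = yaml.safe_load(open(path)) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def ladder(self) -> np.ndarray:
        if self.ladder_kcal_mol is not None:
            return np.asarray(self.ladder_kcal_mol, dtype=float)
        if self.n_replicas == 32:
            return default_ladder()
        return reduced_ladder(self.n_replicas)

    def map_spec(self) -> MapSpec:
        return MapSpec(resolution=self.map_resolution_A,
                       truncate_fraction=self.map_truncate_fraction)

    def digest(self) -> str:
        payload = {k: v for k, v in asdict(self).items() if k != "run_dir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class StagedModel:
    structure: Structure
    metadata: dict


@dataclass
class MultiscaleResult:
    m1: list[StagedModel]
    m2: list[StagedModel]
    m3: list[StagedModel]
    reports: dict[str, list[FitReport]]


@dataclass
class SimpleResult:
    models: list[StagedModel]
    reports: list[FitReport]


def _load_inputs(config: ProtocolConfig, initial: Structure | None,
                 target_struct: Structure | None,
                 target_map: DensityGrid | None):
    if initial is None:
        if config.initial_pdb_path is None:
            raise ValueError("no initial structure given")
        initial = read_pdb(config.initial_pdb_path, selection="CA")
    if target_map is None:
        if config.target_map_path is not None:
            path = config.target_map_path
            reader = read_situs if str(path).endswith((".sit", ".situs")) else read_mrc
            target_map = remove_negative(reader(path))
        elif config.target_pdb_path is not None or target_struct is not None:
            if target_struct is None:
                target_struct = read_pdb(config.target_pdb_path, selection="CA")
            target_map = simulate_map(
                target_struct, resolution=config.map_resolution_A,
                voxel=config.map_voxel_A, padding=config.map_padding_A,
                truncate_fraction=config.map_truncate_fraction)
        else:
            raise ValueError("need a target map or a target structure")
    elif config.target_pdb_path is not None and target_struct is None:
        target_struct = read_pdb(config.target_pdb_path, selection="CA")
    # superpose the initial structure onto the target before fitting
    if target_struct is not None and len(target_struct) == len(initial):
        rot, trans, _ = superpose(initial, target_struct)
        initial = initial.transformed(rot, trans)
    return initial, target_struct, target_map


def _stage_cached(run_dir: Path | None, stage: str, digest: str):
    if run_dir is None:
        return None
    meta = run_dir / stage / "stage.json"
    if not meta.exists():
        return None
    data = json.loads(meta.read_text())
    if data.get("digest") != digest:
        return None
    return data


def _save_stage(run_dir: Path | None, stage: str, digest: str,
                models: list[StagedModel]):
    if run_dir is None:
        return
    sdir = run_dir / stage
    sdir.mkdir(parents=True, exist_ok=True)
    records = []
    for idx, sm in enumerate(models):
        name = f"{stage}_{idx + 1}.pdb"
        remarks = [f"{k}={v}" for k, v in sm.metadata.items()]
        write_pdb(sdir / name, sm.structure, remarks=remarks)
        records.append({"file": name, **sm.metadata})
    (sdir / "stage.json").write_text(
        json.dumps({"digest": digest, "models": records}, indent=2))


def _load_stage(run_dir: Path, stage: str, template: Structure,
                data) -> list[StagedModel]:
    out = []
    for rec in data["models"]:
        s = read_pdb(run_dir / stage / rec["file"], selection="CA")
        meta = {k: v for k, v in rec.items() if k != "file"}
        out.append(StagedModel(template.with_positions(s.positions), meta))
    return out


def _evaluate(models, target_struct, target_map, initial, map_spec, ids):
    if target_struct is None:
        target_struct = initial  # RMSDt column then reports RMSD to S0
    return evaluate_models([m.structure for m in models], target_struct,
                           target_map, initial, map_spec=map_spec,
                           model_ids=ids)


def run_multiscale(config: ProtocolConfig, initial: Structure | None = None,
                   target_struct: Structure | None = None,
                   target_map: DensityGrid | None = None,
                   model: GoModel | None = None,
                   go_params: GoModelParams | None = None) -> MultiscaleResult:
    """Run the three-step protocol; returns M1/M2/M3 models with reports.

    Structures/maps may be passed directly (tests, library use) or read
    from the paths in ``config``.  With ``config.run_dir`` set, stage
    outputs are written there and completed stages are reused on re-runs
    with an identical configuration.
    """
    initial, target_struct, target_map = _load_inputs(
        config, initial, target_struct, target_map)
    if model is None:
        model = build_go_model(initial, params=go_params)
    run_dir = Path(config.run_dir) if config.run_dir else None
    digest = config.digest()
    ladder = config.ladder()
    map_spec = config.map_spec()

    # ---- step 1: replica-exchange CG fitting ---------------------------
    cached = _stage_cached(run_dir, "m1", digest)
    if cached:
        logger.info("step 1: reusing cached M1 models")
        m1 = _load_stage(run_dir, "m1", initial, cached)
    else:
        m1 = []
        for run in range(config.n_runs):
            rc = ReusConfig(
                ladder=ladder, n_steps=config.step1_n_steps,
                dt_fs=config.dt_fs, temperature=config.temperature_K,
                exchange_period_steps=config.exchange_period_steps,
                exchange=config.exchange, map_spec=map_spec,
                seed=config.seed * 1000 + run)
            res = run_reusfit(initial, model, target_map, rc)
            logger.info("step 1 run %d: best CC %.4f (replica %d)",
                        run + 1, res.best_cc, res.best_replica)
            m1.append(StagedModel(
                initial.with_positions(res.best_positions),
                {"stage": "m1", "run": run + 1, "seed": rc.seed,
                 "cc": round(res.best_cc, 6),
                 "k_at_capture": float(res.k_trace[res.best_segment, res.best_replica]),
                 "segment": res.best_segment}))
        m1.sort(key=lambda sm: -sm.metadata["cc"])
        m1 = m1[:config.n_best]
        _save_stage(run_dir, "m1", digest, m1)

    # ---- step 2: targeted MD back to each M1 (no map) ------------------
    cached = _stage_cached(run_dir, "m2", digest)
    if cached:
        m2 = _load_stage(run_dir, "m2", initial, cached)
    else:
        m2 = []
        for idx, sm in enumerate(m1):
            target_ca = sm.structure
            from ._kernels import fit_reference
            _, rho0 = fit_reference(np.ascontiguousarray(initial.positions),
                                    np.ascontiguousarray(target_ca.positions))
            schedule = TmdSchedule(rho0=float(rho0), rhof=config.tmd_rhof_A,
                                   total_time_ps=config.tmd_time_ps,
                                   dt_fs=config.tmd_dt_fs)
            res = run_targeted_md(
                initial, target_ca, model, schedule,
                k_rmsd=config.tmd_k_rmsd, temperature=config.temperature_K,
                seed=config.seed * 1000 + 500 + idx)
            m2.append(StagedModel(res.final, {
                "stage": "m2", "from_m1": idx + 1,
                "seed": config.seed * 1000 + 500 + idx,
                "final_rmsd_to_m1": round(float(res.rmsd_series[-1]), 4)}))
        _save_stage(run_dir, "m2", digest, m2)

    # ---- step 3: fixed-k refinement against the map ---------------------
    k3 = config.step3_k_kcal_mol or float(np.median(ladder))
    cached = _stage_cached(run_dir, "m3", digest)
    if cached:
        m3 = _load_stage(run_dir, "m3", initial, cached)
    else:
        m3 = []
        for idx, sm in enumerate(m2):
            seed = config.seed * 1000 + 700 + idx
            st = make_state(sm.structure, config.temperature_K, k3, seed)
            res = run_fitting(st, model, target_map, config.step3_n_steps,
                              dt_fs=config.dt_fs, map_spec=map_spec)
            m3.append(StagedModel(
                initial.with_positions(res.best_positions),
                {"stage": "m3", "from_m2": idx + 1, "seed": seed,
                 "k_at_capture": k3, "cc": round(res.best_cc, 6),
                 "frame_step": int(res.best_step)}))
        m3.sort(key=lambda sm: -sm.metadata["cc"])
        _save_stage(run_dir, "m3", digest, m3)

    reports = {}
    for stage, models in (("m1", m1), ("m2", m2), ("m3", m3)):
        ids = [f"{stage}_{i + 1}" for i in range(len(models))]
        reports[stage] = _evaluate(models, target_struct, target_map,
                                   initial, map_spec, ids)
    if run_dir is not None:
        (run_dir / "reports.json").write_text(json.dumps(
            {stage: [r.as_dict() for r in rep] for stage, rep in reports.items()},
            indent=2))
    return MultiscaleResult(m1=m1, m2=m2, m3=m3, reports=reports)


def run_simple(config: ProtocolConfig, initial: Structure | None = None,
               target_struct: Structure | None = None,
               target_map: DensityGrid | None = None,
               model: GoModel | None = None,
               go_params: GoModelParams | None = None) -> SimpleResult:
    """Single-stage baseline: independent fixed-k fitting replicates."""
    initial, target_struct, target_map = _load_inputs(
        config, initial, target_struct, target_map)
    if model is None:
        model = build_go_model(initial, params=go_params)
    run_dir = Path(config.run_dir) if config.run_dir else None
    digest = config.digest()
    ladder = config.ladder()
    map_spec = config.map_spec()
    k = config.simple_k_kcal_mol or float(np.median(ladder))
    cached = _stage_cached(run_dir, "sp", digest)
    if cached:
        models = _load_stage(run_dir, "sp", initial, cached)
    else:
        models = []
        for rep in range(config.simple_n_replicates):
            seed = config.seed * 1000 + 900 + rep
            st = make_state(initial, config.temperature_K, k, seed)
            res = run_fitting(st, model, target_map, config.simple_n_steps,
                              dt_fs=config.dt_fs, map_spec=map_spec)
            models.append(StagedModel(
                initial.with_positions(res.best_positions),
                {"stage": "sp", "replicate": rep + 1, "seed": seed,
                 "k_at_capture": k, "cc": round(res.best_cc, 6),
                 "frame_step": int(res.best_step)}))
        _save_stage(run_dir, "sp", digest, models)
    ids = [f"sp_{i + 1}" for i in range(len(models))]
    reports = _evaluate(models, target_struct, target_map, initial,
                        map_spec, ids)
    return SimpleResult(models=models, reports=reports)
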