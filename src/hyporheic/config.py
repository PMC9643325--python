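"""Run configuration: schema-validated YAML, provenance manifests.

Unknown keys are rejected; units are embedded in key names.  A manifest
(config hash + seed) written next to each run's artifacts allows any
deterministic stage to be regenerated bit-identically.
"""

from __future__ import annotations

import hashlib
import json
from datetime import date
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import hydrology
from .flow import FlowPathGeometry, WaterProperties
from .hydrology import BoundaryChemistry, SeasonScenario
from .reactions import MU_AER_BASE, MU_DEN_BASE, SolidPhases, default_network
from .transport import FlowPathModel

__all__ = ["RunConfig", "load_config", "save_config", "config_hash",
           "write_manifest", "build_model", "build_scenario"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ScenarioConfig(_Strict):
    season_start: date
    season_end: date
    separation_m: float = 58.0
    datum_stage_m: float = 10.0
    stage_amplitude_m: float = 0.3
    start_gradient: float = 0.0066
    snowmelt_peak_day: float = 48.0
    snowmelt_peak_gradient: float = 0.0073
    recession_tau_days: float = 20.0
    baseflow_gradient: float = 0.005643
    dam_build_start: date | None = None
    dam_build_end: date | None = None
    dam_destroy: date | None = None
    dam_peak_gradient: float = 0.0


class GeometryConfig(_Strict):
    length_m: float = 58.0
    dx_m: float = 0.1
    porosity: float = 0.2
    permeability_m2: float = 2.26e-11


class ChemistryConfig(_Strict):
    o2_mol_L: float = 2.5e-4
    no3_mol_L: float = 1.0e-5
    nh4_mol_L: float = 1.0e-6
    acetate_mol_L: float = 1.0e-4
    ca_mol_L: float = 1.0e-3
    dic_mol_L: float = 3.0e-3
    ph: float = 7.8
    tracer_mol_L: float = 0.0


class NetworkConfig(_Strict):
    mu_aer: float = MU_AER_BASE
    mu_den: float = MU_DEN_BASE
    som_amount: float = 100.0
    acetate_eq_mol_L: float = 1.0e-4
    nsom_amount: float = 50.0
    nsom_rate: float = 4.0e-10
    calcite_amount: float = 10.0


class SimulationConfig(_Strict):
    max_dt_h: float = 1.0
    spin_up_hours: float = 7000.0
    snapshot_every_h: float = 24.0


class EnsembleConfig(_Strict):
    mc_draws: int = 200
    mc_gradients: tuple[float, float, float] = (0.0073, 0.0061, 0.017)
    morris_trajectories: int = 10
    morris_levels: int = 4
    sweep_length_step_m: float = 0.5


class RunConfig(_Strict):
    scenario_2018: ScenarioConfig = Field(
        default_factory=lambda: ScenarioConfig(
            **{k: getattr(hydrology.scenario_2018(), k)
               for k in ScenarioConfig.model_fields}))
    scenario_2019: ScenarioConfig = Field(
        default_factory=lambda: ScenarioConfig(
            **{k: getattr(hydrology.scenario_2019(), k)
               for k in ScenarioConfig.model_fields}))
    geometry: GeometryConfig = Field(default_factory=GeometryConfig)
    chemistry: ChemistryConfig = Field(default_factory=ChemistryConfig)
    network: NetworkConfig = Field(default_factory=NetworkConfig)
    simulation: SimulationConfig = Field(default_factory=SimulationConfig)
    ensemble: EnsembleConfig = Field(default_factory=EnsembleConfig)
    seed: int = 0
    output_dir: str = "runs"


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(data)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    data = json.loads(cfg.model_dump_json())
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(json.loads(cfg.model_dump_json()), sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def write_manifest(cfg: RunConfig, outdir: Path, stage: str,
                   artifacts: list[str]) -> Path:
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "stage": stage,
        "config_hash": config_hash(cfg),
        "seed": cfg.seed,
        "artifacts": artifacts,
    }
    path = outdir / f"{stage}_manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path


def build_scenario(sc: ScenarioConfig) -> SeasonScenario:
    return SeasonScenario(**sc.model_dump())


def build_model(cfg: RunConfig, length_m: float | None = None) -> FlowPathModel:
    g = cfg.geometry
    geom = FlowPathGeometry(length_m or g.length_m, g.dx_m, g.porosity,
                            g.permeability_m2)
    c = cfg.chemistry
    chem = BoundaryChemistry(o2=c.o2_mol_L, no3=c.no3_mol_L, nh4=c.nh4_mol_L,
                             acetate=c.acetate_mol_L, ca=c.ca_mol_L,
                             dic=c.dic_mol_L, ph=c.ph, tracer=c.tracer_mol_L)
    n = cfg.network
    solids = SolidPhases(som_amount=n.som_amount,
                         acetate_eq=n.acetate_eq_mol_L,
                         nsom_amount=n.nsom_amount, nsom_rate=n.nsom_rate,
                         calcite_amount=n.calcite_amount)
    net = default_network(mu_aer=n.mu_aer, mu_den=n.mu_den, solids=solids)
    return FlowPathModel(geometry=geom, network=net, chemistry=chem,
                         water=WaterProperties(),
                         max_dt_h=cfg.simulation.max_dt_h)
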