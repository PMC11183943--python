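"""Pipeline configuration: one nested YAML document driving all subcommands.

Exactly one of ``input_csv`` (an existing observation table) or
``simulation`` (a generative specification) drives a run. All blocks are
optional and fall back to package defaults; CLI flags override file values.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .hurdle import ModelSpec, PriorConfig, SamplerConfig
from .synthetic import (
    ConfigError,
    DayPlan,
    DewConfig,
    GroupEffectSDs,
    SimulationConfig,
    SpeciesParams,
    default_config,
)
from .weather import SuitabilityRule

__all__ = ["PipelineConfig", "load_config", "config_hash"]


@dataclass
class PipelineConfig:
    seed: int = 0
    output_dir: Path = Path("nectardep_out")
    input_csv: Path | None = None
    weather_csv: Path | None = None
    simulation: SimulationConfig | None = None
    model: ModelSpec = field(default_factory=ModelSpec)
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    levels: tuple[float, float] = (0.66, 0.95)
    weather_rule: SuitabilityRule = field(default_factory=SuitabilityRule)
    raw: dict = field(default_factory=dict)

    def validate_source(self) -> None:
        if (self.input_csv is None) == (self.simulation is None):
            raise ConfigError(
                "exactly one of input_csv or the simulation block must drive the run")


def _simulation_from_dict(d: dict) -> SimulationConfig:
    if d.get("preset") == "default" or not d.get("species"):
        cfg = default_config(seed=int(d.get("seed", 0)))
        if "depletion_schedule" in d:
            cfg.depletion_schedule = {int(k): float(v)
                                      for k, v in d["depletion_schedule"].items()}
        for key in ("zero_prob_bagged", "flowers_per_treatment_per_tree",
                    "depletion_split_hurdle"):
            if key in d:
                setattr(cfg, key, type(getattr(cfg, key))(d[key]))
        return cfg.validate()
    species = {name: SpeciesParams(float(sp["mean_volume_uL"]), float(sp["gamma_shape"]))
               for name, sp in d["species"].items()}
    days = [DayPlan(date=str(day["date"]),
                    trees_per_species={k: int(v) for k, v in day["trees"].items()},
                    rounds=tuple(day["rounds"]) if "rounds" in day else None,
                    dew=bool(day.get("dew", False)))
            for day in d["days"]]
    hierarchy = {g: GroupEffectSDs(**{k: float(v) for k, v in sds.items()})
                 for g, sds in d.get("hierarchy_sds", {}).items()}
    sched = {int(k): float(v) for k, v in d.get("depletion_schedule", {}).items()}
    dew = DewConfig(**d["dew"]) if "dew" in d else None
    return SimulationConfig(
        species=species,
        days=days,
        rounds=tuple(d.get("rounds", (9, 11, 13, 15))),
        flowers_per_treatment_per_tree=int(d.get("flowers_per_treatment_per_tree", 5)),
        zero_prob_bagged=float(d.get("zero_prob_bagged", 0.15)),
        depletion_schedule=sched,
        hierarchy_sds=hierarchy,
        depletion_split_hurdle=float(d.get("depletion_split_hurdle", 0.5)),
        dew=dew,
        seed=int(d.get("seed", 0)),
    ).validate()


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> PipelineConfig:
    """Load a pipeline config file, applying flat key overrides on top."""
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    if overrides:
        raw.update({k: v for k, v in overrides.items() if v is not None})

    cfg = PipelineConfig(raw=raw)
    cfg.seed = int(raw.get("seed", 0))
    cfg.output_dir = Path(raw.get("output_dir", "nectardep_out"))
    if raw.get("input_csv"):
        cfg.input_csv = Path(raw["input_csv"])
    if raw.get("weather_csv"):
        cfg.weather_csv = Path(raw["weather_csv"])
    if "simulation" in raw and raw["simulation"] is not None:
        sim = dict(raw["simulation"])
        sim.setdefault("seed", cfg.seed)
        cfg.simulation = _simulation_from_dict(sim)

    m = raw.get("model", {}) or {}
    priors = PriorConfig(**(m.get("priors", {}) or {}))
    cfg.model = ModelSpec(
        rounds=tuple(m.get("rounds", (9, 11, 13, 15))),
        group_factors=tuple(m.get("group_factors", ("tree", "species", "date"))),
        correlated=bool(m.get("correlated", True)),
        priors=priors,
    )
    s = raw.get("sampler", {}) or {}
    cfg.sampler = SamplerConfig(
        chains=int(s.get("chains", 4)),
        warmup=int(s.get("warmup", 1000)),
        draws=int(s.get("draws", 1000)),
        target_accept=float(s.get("target_accept", 0.8)),
        max_leapfrog=int(s.get("max_leapfrog", 48)),
    )
    if "levels" in raw:
        lv = sorted(float(x) for x in raw["levels"])
        if len(lv) != 2 or not all(0 < x < 1 for x in lv):
            raise ConfigError("levels must be two probabilities in (0, 1)")
        cfg.levels = (lv[0], lv[1])
    w = raw.get("weather", {}) or {}
    cfg.weather_rule = SuitabilityRule(
        temp_min_C=float(w.get("temp_min_C", 10.0)),
        precip_max_mm=float(w.get("precip_max_mm", 0.0)),
        daylight_window=tuple(w.get("daylight_window", (7, 19))),
    )
    return cfg


def config_hash(cfg: PipelineConfig) -> str:
    """Stable short hash of the raw config document, for manifests."""
    blob = json.dumps(cfg.raw, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
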