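"""Synthetic bagged-vs-open nectar standing-crop datasets with known truth.

The generator mirrors the statistical structure the downstream analysis
assumes: a hurdle process for empty flowers (zero volume) and gamma-
distributed positive volumes, with hierarchical variation by tree, species
and date on the link scales (log for the positive-volume mean, logit for the
empty probability). Depletion by foragers acts only on open flowers and only
on the *unconditional* cell mean: a true depletion ``d`` shrinks
``E[V_open] = E[V_bagged] * (1 - d)``, split between a higher empty
probability and smaller positive volumes.

Every run also records :class:`TrueParameters` — the exact per-cell expected
volumes actually used — so that parameter-recovery tests compare posterior
estimates against generative cell means, never against noisy per-flower
ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_io import OBSERVATION_COLUMNS

__all__ = [
    "SpeciesParams",
    "GroupEffectSDs",
    "DewConfig",
    "DayPlan",
    "SimulationConfig",
    "TrueParameters",
    "ConfigError",
    "default_config",
    "simulate_dataset",
    "apply_dew_dilution",
    "evaporate",
    "simulate_weather",
]


class ConfigError(ValueError):
    """The simulation configuration violates one of its invariants."""


@dataclass(frozen=True)
class SpeciesParams:
    """Per-species baseline: mean positive volume μ_s (μL) and gamma shape α_s."""

    mean_volume_uL: float
    gamma_shape: float


@dataclass(frozen=True)
class GroupEffectSDs:
    """SDs of one grouping factor's random deviations on the link scales.

    ``log_*`` act on the gamma submodel's log mean, ``logit_*`` on the hurdle
    submodel's logit empty-probability; intercepts shift both treatments,
    slopes shift the open (treatment) contrast only.
    """

    log_intercept: float = 0.0
    log_slope: float = 0.0
    logit_intercept: float = 0.0
    logit_slope: float = 0.0


@dataclass(frozen=True)
class DewConfig:
    """Morning dew scenario for the concentration trajectory.

    ``dew_volume_uL`` of water is mixed into each flower's nectar before the
    first round; water then evaporates at ``evaporation_rate_per_hour``
    (geometric decay), so concentration climbs back through the day.
    """

    dew_volume_uL: float = 9.0
    base_concentration_brix: float = 30.0
    evaporation_rate_per_hour: float = 0.3


@dataclass(frozen=True)
class DayPlan:
    """One sampling day: which species are sampled and with how many trees."""

    date: str
    trees_per_species: Mapping[str, int]
    rounds: tuple[int, ...] | None = None  # None → config default rounds
    dew: bool = False


@dataclass
class SimulationConfig:
    """Full generative specification of a simulated exclusion experiment."""

    species: Mapping[str, SpeciesParams]
    days: Sequence[DayPlan]
    rounds: tuple[int, ...] = (9, 11, 13, 15)
    flowers_per_treatment_per_tree: int = 5
    zero_prob_bagged: float = 0.15
    #: true depletion d in [0,1): keyed by (date, round_hour), falling back
    #: to round_hour alone.
    depletion_schedule: Mapping = field(default_factory=dict)
    hierarchy_sds: Mapping[str, GroupEffectSDs] = field(default_factory=dict)
    #: fraction of each cell's depletion realized by raising the empty
    #: probability (the rest shrinks positive volumes); on the ratio scale:
    #: (1-π_open)/(1-π_bagged) = (1-d)^f and μ_open/μ_bagged = (1-d)^(1-f).
    depletion_split_hurdle: float = 0.5
    dew: DewConfig | None = None
    seed: int = 0

    def depletion(self, date: str, round_hour: int) -> float:
        sched = self.depletion_schedule
        if (date, round_hour) in sched:
            return float(sched[(date, round_hour)])
        if round_hour in sched:
            return float(sched[round_hour])
        return 0.0

    def validate(self) -> "SimulationConfig":
        if not self.species:
            raise ConfigError("species list is empty")
        if not self.days:
            raise ConfigError("no sampling days configured")
        for name, sp in self.species.items():
            if sp.mean_volume_uL <= 0 or sp.gamma_shape <= 0:
                raise ConfigError(f"species {name!r}: mean volume and shape must be > 0")
        if not 0 <= self.zero_prob_bagged < 1:
            raise ConfigError("zero_prob_bagged must lie in [0, 1)")
        if not 0 <= self.depletion_split_hurdle <= 1:
            raise ConfigError("depletion_split_hurdle must lie in [0, 1]")
        if self.flowers_per_treatment_per_tree < 1:
            raise ConfigError("flowers_per_treatment_per_tree must be ≥ 1")
        for d in self.depletion_schedule.values():
            if not 0 <= float(d) < 1:
                raise ConfigError(f"depletion {d} outside [0, 1)")
        for g, sds in self.hierarchy_sds.items():
            if g not in ("tree", "species", "date"):
                raise ConfigError(f"unknown grouping factor {g!r}")
            for v in (sds.log_intercept, sds.log_slope, sds.logit_intercept, sds.logit_slope):
                if v < 0:
                    raise ConfigError("hierarchy SDs must be ≥ 0")
        for day in self.days:
            if not day.trees_per_species:
                raise ConfigError(f"day {day.date}: no species sampled")
            for sp, n in day.trees_per_species.items():
                if sp not in self.species:
                    raise ConfigError(f"day {day.date}: species {sp!r} not configured")
                if n < 1:
                    raise ConfigError(f"day {day.date}: zero trees for {sp!r}")
        return self


@dataclass
class TrueParameters:
    """Ground truth realized by one simulation run.

    ``cells`` has one row per species × date × round with the exact
    unconditional expected volumes E_bagged and E_open (averaged over the
    cell's trees with their realized deviations) and the implied true
    depletion D_true = 1 − E_open/E_bagged.
    """

    cells: pd.DataFrame
    species_effects: pd.DataFrame
    date_effects: pd.DataFrame
    tree_effects: pd.DataFrame

    def d_true(self, species: str, date: str, round_hour: int) -> float:
        c = self.cells
        m = c[
            (c["species"] == species)
            & (c["date"] == date)
            & (c["round_hour"] == round_hour)
        ]
        if m.empty:
            raise KeyError((species, date, round_hour))
        return float(m["D_true"].iloc[0])

    def to_csv(self, path) -> None:
        self.cells.to_csv(path, index=False)


def default_config(seed: int = 0, depletion_schedule: Mapping | None = None) -> SimulationConfig:
    """Configuration emulating the spring fruit-tree study design.

    Four rosaceous species sampled over nine days following their flowering
    phenology (plum → blackthorn → plum + cherry → pear), 3–5 trees per
    species-day, rounds at 9:00–15:00 every 2 h with one extra 17:00 round
    on the final day, five bagged + five open flowers per tree per round,
    and a diel schedule of rising true depletion.
    """
    if depletion_schedule is None:
        depletion_schedule = {9: 0.1, 11: 0.3, 13: 0.5, 15: 0.6, 17: 0.6}
    species = {
        "plum": SpeciesParams(0.6, 1.5),
        "blackthorn": SpeciesParams(0.3, 1.5),
        "cherry": SpeciesParams(1.0, 1.8),
        "pear": SpeciesParams(0.7, 1.5),
    }
    days = [
        DayPlan("2023-03-20", {"plum": 1}),
        DayPlan("2023-03-22", {"plum": 3}),
        DayPlan("2023-03-25", {"blackthorn": 5}),
        DayPlan("2023-03-29", {"plum": 3, "blackthorn": 5}),
        DayPlan("2023-04-03", {"blackthorn": 5}),
        DayPlan("2023-04-10", {"plum": 3, "cherry": 2}),
        DayPlan("2023-04-14", {"cherry": 2, "pear": 1}),
        DayPlan("2023-04-19", {"plum": 2, "pear": 2}),
        DayPlan("2023-04-21", {"pear": 2}, rounds=(9, 11, 13, 15, 17), dew=True),
    ]
    hierarchy = {
        "tree": GroupEffectSDs(0.3, 0.1, 0.3, 0.1),
        "species": GroupEffectSDs(0.2, 0.1, 0.2, 0.1),
        "date": GroupEffectSDs(0.3, 0.1, 0.3, 0.1),
    }
    return SimulationConfig(
        species=species,
        days=days,
        depletion_schedule=dict(depletion_schedule),
        hierarchy_sds=hierarchy,
        dew=DewConfig(),
        seed=seed,
    )


def _logit(p: float) -> float:
    if p <= 0.0:
        return -math.inf
    if p >= 1.0:
        return math.inf
    return math.log(p) - math.log1p(-p)


def _expit(x: float) -> float:
    if x < -700:
        return 0.0
    if x > 700:
        return 1.0
    return 1.0 / (1.0 + math.exp(-x))


def _draw_effects(rng: np.random.Generator, sds: GroupEffectSDs) -> np.ndarray:
    scale = [sds.log_intercept, sds.log_slope, sds.logit_intercept, sds.logit_slope]
    return rng.normal(0.0, 1.0, size=4) * np.asarray(scale)


def simulate_dataset(config: SimulationConfig) -> tuple[pd.DataFrame, TrueParameters]:
    """Generate one observation table plus its ground truth.

    Deterministic given ``config.seed``: repeated calls with the same config
    produce byte-identical tables.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    sds = {g: config.hierarchy_sds.get(g, GroupEffectSDs()) for g in ("tree", "species", "date")}
    f = config.depletion_split_hurdle

    species_eff = {sp: _draw_effects(rng, sds["species"]) for sp in config.species}
    date_eff = {day.date: _draw_effects(rng, sds["date"]) for day in config.days}

    rows: list[dict] = []
    cell_sums: dict[tuple, list[float]] = {}
    tree_rows, sp_rows, dt_rows = [], [], []

    for sp, eff in species_eff.items():
        sp_rows.append({"species": sp, "log_intercept": eff[0], "log_slope": eff[1],
                        "logit_intercept": eff[2], "logit_slope": eff[3]})
    for dt, eff in date_eff.items():
        dt_rows.append({"date": dt, "log_intercept": eff[0], "log_slope": eff[1],
                        "logit_intercept": eff[2], "logit_slope": eff[3]})

    n_fl = config.flowers_per_treatment_per_tree
    for day_i, day in enumerate(config.days):
        rounds = day.rounds if day.rounds is not None else config.rounds
        for sp, n_trees in day.trees_per_species.items():
            base = config.species[sp]
            for k in range(n_trees):
                tree_id = f"{sp}-{day.date}-T{k + 1}"
                tree = _draw_effects(rng, sds["tree"])
                tree_rows.append({"species": sp, "tree_id": tree_id, "date": day.date,
                                  "log_intercept": tree[0], "log_slope": tree[1],
                                  "logit_intercept": tree[2], "logit_slope": tree[3]})
                log_m = (math.log(base.mean_volume_uL)
                         + species_eff[sp][0] + date_eff[day.date][0] + tree[0])
                logit_p0 = (_logit(config.zero_prob_bagged)
                            + species_eff[sp][2] + date_eff[day.date][2] + tree[2])
                p0 = _expit(logit_p0)
                m0 = math.exp(log_m)
                slope_log = species_eff[sp][1] + date_eff[day.date][1] + tree[1]
                slope_logit = species_eff[sp][3] + date_eff[day.date][3] + tree[3]
                for r in rounds:
                    d = config.depletion(day.date, r)
                    # open arm: hurdle share of depletion on the survival
                    # ratio, gamma share on the positive mean, then the
                    # tree/species/date treatment-slope deviations
                    surv1 = (1.0 - p0) * (1.0 - d) ** f
                    p1 = _expit(_logit(1.0 - surv1) + slope_logit)
                    m1 = m0 * (1.0 - d) ** (1.0 - f) * math.exp(slope_log)
                    # foragers never add nectar: slope deviations may damp or
                    # amplify depletion but cannot invert the treatment
                    # ordering, so the open unconditional mean caps at the
                    # bagged one (keeps true depletion in [0, 1))
                    cap = (1.0 - p0) * m0
                    if (1.0 - p1) * m1 > cap:
                        m1 = cap / (1.0 - p1)
                    conc = _dew_concentration(config, day, r, m0) if day.dew else None
                    for treatment, p, m in (("bagged", p0, m0), ("open", p1, m1)):
                        key = (sp, day.date, r)
                        cell_sums.setdefault(key, [0.0, 0.0, 0])
                        acc = cell_sums[key]
                        if treatment == "bagged":
                            acc[0] += (1.0 - p0) * m0
                            acc[2] += 1
                        else:
                            acc[1] += (1.0 - p1) * m1
                        empty = rng.random(n_fl) < p
                        vol = rng.gamma(base.gamma_shape, m / base.gamma_shape, size=n_fl)
                        vol[empty] = 0.0
                        for j in range(n_fl):
                            rows.append({
                                "date": day.date,
                                "round_hour": r,
                                "species": sp,
                                "tree_id": tree_id,
                                "treatment": treatment,
                                "flower_id": f"F{j + 1}",
                                "volume_uL": float(vol[j]),
                                "concentration_brix": conc,
                                "concentration_pooled": (True if conc is not None else pd.NA),
                            })

    cells = []
    for (sp, date, r), (sb, so, n_tr) in sorted(cell_sums.items()):
        e_b, e_o = sb / n_tr, so / n_tr
        cells.append({"species": sp, "date": date, "round_hour": r,
                      "E_bagged": e_b, "E_open": e_o,
                      "D_true": 1.0 - e_o / e_b})
    truth = TrueParameters(
        cells=pd.DataFrame(cells),
        species_effects=pd.DataFrame(sp_rows),
        date_effects=pd.DataFrame(dt_rows),
        tree_effects=pd.DataFrame(tree_rows),
    )
    df = pd.DataFrame(rows, columns=OBSERVATION_COLUMNS)
    df["concentration_brix"] = pd.to_numeric(df["concentration_brix"])
    df["concentration_pooled"] = df["concentration_pooled"].astype("boolean")
    return df, truth


def _dew_concentration(config: SimulationConfig, day: DayPlan, round_hour: int,
                       nectar_volume: float) -> float | None:
    """Concentration trajectory on a dew morning: dilute at 9:00, then evaporate."""
    if config.dew is None:
        return None
    dew = config.dew
    v, c = apply_dew_dilution(nectar_volume, dew.base_concentration_brix, dew.dew_volume_uL)
    _, c = evaporate(v, c, dew.evaporation_rate_per_hour, max(0.0, round_hour - 9.0))
    return c


def apply_dew_dilution(volume_uL: float, concentration_brix: float,
                       dew_volume_uL: float) -> tuple[float, float]:
    """Mix dew water into nectar, conserving sugar mass.

    Uses the volume-fraction approximation to °Brix mixing: the sugar
    "volume" v·c/100 is invariant, so concentration scales by
    v / (v + dew). Returns (new volume, new concentration).
    """
    if volume_uL < 0 or dew_volume_uL < 0:
        raise ValueError("volumes must be non-negative")
    if not 0 <= concentration_brix <= 100:
        raise ValueError("concentration must lie in [0, 100]")
    if dew_volume_uL == 0:
        return volume_uL, concentration_brix
    v_new = volume_uL + dew_volume_uL
    if v_new == 0:
        return 0.0, 0.0
    return v_new, concentration_brix * volume_uL / v_new


def evaporate(volume_uL: float, concentration_brix: float, rate_per_hour: float,
              hours: float) -> tuple[float, float]:
    """Evaporate water from nectar, conserving sugar mass.

    The water fraction decays geometrically at ``rate_per_hour`` (fraction of
    remaining water lost per hour); sugar stays, so concentration rises,
    capped at 100 °Brix when all water is gone.
    """
    if volume_uL < 0 or hours < 0:
        raise ValueError("volume and hours must be non-negative")
    if not 0 <= rate_per_hour < 1:
        raise ValueError("rate_per_hour must lie in [0, 1)")
    if not 0 <= concentration_brix <= 100:
        raise ValueError("concentration must lie in [0, 100]")
    if volume_uL == 0:
        return 0.0, 0.0
    sugar = volume_uL * concentration_brix / 100.0
    water = volume_uL - sugar
    water *= (1.0 - rate_per_hour) ** hours
    v_new = water + sugar
    c_new = 100.0 if v_new == 0 else min(100.0, 100.0 * sugar / v_new)
    return v_new, c_new


def simulate_weather(days: int, *, mean_temp_C: float = 8.0, amplitude_C: float = 5.0,
                     noise_sd_C: float = 1.0, precip_prob: float = 0.3,
                     precip_mean_mm: float = 0.5, start_date: str = "2023-03-20",
                     seed: int = 0) -> pd.DataFrame:
    """Hourly weather with a sinusoidal diel temperature cycle.

    Temperature peaks mid-afternoon (14:00); precipitation is Bernoulli per
    hour with exponential amounts. Defaults approximate erratic early spring
    in central Germany (cool mornings, frequent showers), where a large
    share of daylight hours falls below honey bee foraging thresholds.
    Deterministic given ``seed``.
    """
    if days < 1:
        raise ConfigError("days must be ≥ 1")
    if not 0 <= precip_prob <= 1:
        raise ConfigError("precip_prob must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    ts = pd.date_range(start=start_date, periods=24 * days, freq="h")
    hours = ts.hour.to_numpy()
    temp = (mean_temp_C
            + amplitude_C * np.cos(2 * np.pi * (hours - 14) / 24.0)
            + rng.normal(0.0, noise_sd_C, size=len(ts)))
    wet = rng.random(len(ts)) < precip_prob
    precip = np.where(wet, rng.exponential(precip_mean_mm, size=len(ts)), 0.0)
    return pd.DataFrame({
        "timestamp": ts,
        "temperature_C": np.round(temp, 2),
        "precipitation_mm": np.round(precip, 2),
    })
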