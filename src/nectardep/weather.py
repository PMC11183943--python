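"""Foraging-weather suitability for honey bees.

Honey bees forage very little below about 10 °C or in any appreciable
precipitation, so an hour is classified suitable when it is a daylight hour
at or above the temperature threshold with precipitation at or below the
cutoff. The headline quantity is the fraction of daylight hours that
qualify over a study period.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "SuitabilityRule",
    "classify_hours",
    "fraction_suitable",
    "estimated_forager_population",
]


@dataclass(frozen=True)
class SuitabilityRule:
    """Thresholds defining suitable foraging weather.

    The temperature bound is inclusive (exactly 10.0 °C is suitable; only
    *below* 10 °C disqualifies); the precipitation cutoff defaults to 0 mm —
    any appreciable precipitation disqualifies — but is configurable for
    noisy station data. Daylight is a fixed clock window,
    [start, end) hours, since the rule is operational rather than
    astronomical.
    """

    temp_min_C: float = 10.0
    precip_max_mm: float = 0.0
    daylight_window: tuple[int, int] = (7, 19)

    def __post_init__(self):
        lo, hi = self.daylight_window
        if not lo < hi:
            raise ValueError("daylight window must be non-empty")
        if self.precip_max_mm < 0:
            raise ValueError("precip_max_mm must be ≥ 0")


def classify_hours(records: pd.DataFrame,
                   rule: SuitabilityRule = SuitabilityRule()) -> pd.Series:
    """Boolean suitability per record.

    True iff temperature ≥ temp_min_C, precipitation ≤ precip_max_mm and the
    hour lies within the daylight window.
    """
    ts = pd.to_datetime(records["timestamp"])
    hour = ts.dt.hour
    lo, hi = rule.daylight_window
    daylight = (hour >= lo) & (hour < hi)
    return (daylight
            & (records["temperature_C"] >= rule.temp_min_C)
            & (records["precipitation_mm"] <= rule.precip_max_mm))


def fraction_suitable(records: pd.DataFrame,
                      rule: SuitabilityRule = SuitabilityRule()) -> float:
    """Suitable daylight hours divided by all daylight hours."""
    ts = pd.to_datetime(records["timestamp"])
    hour = ts.dt.hour
    lo, hi = rule.daylight_window
    daylight = (hour >= lo) & (hour < hi)
    n_day = int(daylight.sum())
    if n_day == 0:
        raise ValueError("no daylight records in the period")
    return float(classify_hours(records, rule).sum()) / n_day


def estimated_forager_population(n_colonies: int, foragers_per_colony: int) -> int:
    """Back-of-envelope foraging force of the local managed honey bee stock.

    Simply colonies × foragers per colony — e.g. 55 colonies at a
    conservative 5000 foragers each put 275,000 potential nectar foragers in
    the landscape.
    """
    if n_colonies < 0 or foragers_per_colony < 0:
        raise ValueError("counts must be non-negative")
    return int(n_colonies) * int(foragers_per_colony)
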