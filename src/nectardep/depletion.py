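"""The censored depletion statistic D and its point-interval summaries.

Depletion is the proportional difference between the expected standing crop
of bagged (pollinator-excluded) and open flowers,

    D = 1 − V_open / V_bagged,

applied draw-by-draw to the posterior of the two cell expectations. Draws
where the open expectation exceeds the bagged one produce negative D with
no substantive meaning (there is no "negative depletion"), so the posterior
is censored by mapping negative values to zero before summarization. The
result is the posterior of the *mean* depletion rate for the cell — not the
distribution of observed per-flower depletion.

Summaries follow the point-interval convention: posterior median with
nested equal-tailed 66% and 95% credible intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hurdle import PosteriorDraws, posterior_cell_expectation

__all__ = [
    "DEFAULT_LEVELS",
    "DepletionEstimate",
    "depletion_draws",
    "summarize",
    "depletion_table",
    "estimates_to_frame",
]

DEFAULT_LEVELS = (0.66, 0.95)


@dataclass
class DepletionEstimate:
    """Censored posterior of D for one species × date × round cell."""

    species: str
    date: str
    round_hour: int
    d_draws: np.ndarray
    median: float
    inner_interval: tuple[float, float]
    outer_interval: tuple[float, float]
    levels: tuple[float, float] = DEFAULT_LEVELS


def depletion_draws(v_bagged_draws: np.ndarray, v_open_draws: np.ndarray) -> np.ndarray:
    """Element-wise censored depletion D = max(0, 1 − V_open/V_bagged).

    Draws are paired by posterior draw index; bagged draws must be strictly
    positive.
    """
    vb = np.asarray(v_bagged_draws, dtype=float)
    vo = np.asarray(v_open_draws, dtype=float)
    if vb.shape != vo.shape:
        raise ValueError(f"draw vectors differ in length: {vb.shape} vs {vo.shape}")
    if (vb <= 0).any():
        raise ValueError("bagged expected volumes must be strictly positive")
    if (vo < 0).any():
        raise ValueError("open expected volumes must be non-negative")
    return np.maximum(0.0, 1.0 - vo / vb)


def summarize(d_draws: np.ndarray,
              levels: tuple[float, float] = DEFAULT_LEVELS) -> tuple[float, tuple, tuple]:
    """Median and nested equal-tailed credible intervals of censored D draws.

    Returns (median, inner interval, outer interval) at the two requested
    probability levels (inner first).
    """
    d = np.asarray(d_draws, dtype=float)
    if d.size == 0:
        raise ValueError("no depletion draws to summarize")
    if (d < 0).any() or (d > 1).any():
        raise ValueError("censored depletion draws must lie in [0, 1]")
    inner, outer = sorted(levels)
    med = float(np.median(d))
    qi = np.quantile(d, [(1 - inner) / 2, (1 + inner) / 2])
    qo = np.quantile(d, [(1 - outer) / 2, (1 + outer) / 2])
    return med, (float(qi[0]), float(qi[1])), (float(qo[0]), float(qo[1]))


def depletion_table(draws: PosteriorDraws, cells: list[tuple[str, str, int]],
                    levels: tuple[float, float] = DEFAULT_LEVELS) -> list[DepletionEstimate]:
    """Censored depletion estimates for a list of (species, date, round) cells.

    Each cell's bagged and open expectations are evaluated per posterior draw
    (tree deviations marginalized to zero), differenced via D, censored at
    zero and summarized. Output is sorted by species, date, round.
    """
    if not cells:
        raise ValueError("empty cell list")
    out = []
    for cell in sorted(cells):
        species, date, round_hour = cell
        vb = posterior_cell_expectation(draws, cell, "bagged")
        vo = posterior_cell_expectation(draws, cell, "open")
        d = depletion_draws(vb, vo)
        med, inner, outer = summarize(d, levels)
        out.append(DepletionEstimate(
            species=species, date=date, round_hour=int(round_hour),
            d_draws=d, median=med, inner_interval=inner, outer_interval=outer,
            levels=tuple(sorted(levels)),
        ))
    return out


def estimates_to_frame(estimates: list[DepletionEstimate]) -> pd.DataFrame:
    """Tabular view: one row per cell with median and interval bounds."""
    rows = []
    for e in estimates:
        inner_pct = int(round(e.levels[0] * 100))
        outer_pct = int(round(e.levels[1] * 100))
        rows.append({
            "species": e.species, "date": e.date, "round_hour": e.round_hour,
            "d_median": e.median,
            f"d_l{inner_pct}": e.inner_interval[0], f"d_u{inner_pct}": e.inner_interval[1],
            f"d_l{outer_pct}": e.outer_interval[0], f"d_u{outer_pct}": e.outer_interval[1],
            "n_draws": len(e.d_draws),
        })
    return pd.DataFrame(rows)
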