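"""Cell-wise normalization of nectar volumes.

Each reading is divided by the mean volume of the *bagged* flowers within
its species × round × date cell (zeros included, since the depletion
statistic is defined on unconditional standing-crop means). Cells whose
bagged mean is zero or that have no bagged observations carry no
information about relative depletion; both arms of such cells are excluded
and reported.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["CELL_KEY", "bagged_cell_means", "normalize"]

#: the stratum at which normalization and depletion are computed
CELL_KEY = ["species", "date", "round_hour"]


def bagged_cell_means(obs: pd.DataFrame) -> pd.Series:
    """Arithmetic mean bagged volume per cell, zeros included.

    Returns a Series indexed by (species, date, round_hour); cells without
    any bagged observation are absent from the result.
    """
    bagged = obs[obs["treatment"] == "bagged"]
    return bagged.groupby(CELL_KEY)["volume_uL"].mean()


def normalize(obs: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Scale every volume by its cell's bagged mean.

    Returns ``(normalized, excluded)`` where ``normalized`` carries two new
    columns — ``bagged_cell_mean_uL`` and ``v_norm = volume_uL / mean`` —
    and ``excluded`` lists the cell keys dropped in full, with a reason
    (``no_bagged`` or ``zero_bagged_mean``). Retained + excluded row counts
    equal the input row count; by construction the mean of bagged ``v_norm``
    within every retained cell is exactly 1.
    """
    if len(obs) == 0:
        empty = obs.copy()
        empty["bagged_cell_mean_uL"] = pd.Series(dtype=float)
        empty["v_norm"] = pd.Series(dtype=float)
        return empty, pd.DataFrame(columns=CELL_KEY + ["reason"])

    means = bagged_cell_means(obs)
    keyed = obs.set_index(CELL_KEY, drop=False)
    cell_mean = means.reindex(keyed.index)

    all_cells = keyed.index.unique()
    excluded_rows = []
    for cell in all_cells:
        if cell not in means.index:
            excluded_rows.append((*cell, "no_bagged"))
        elif means.loc[cell] == 0.0:
            excluded_rows.append((*cell, "zero_bagged_mean"))
    excluded = pd.DataFrame(excluded_rows, columns=CELL_KEY + ["reason"])
    excluded = excluded.sort_values(CELL_KEY).reset_index(drop=True)

    keep = cell_mean.notna() & (cell_mean > 0)
    out = keyed[keep.to_numpy()].reset_index(drop=True)
    out["bagged_cell_mean_uL"] = cell_mean[keep.to_numpy()].to_numpy()
    out["v_norm"] = out["volume_uL"] / out["bagged_cell_mean_uL"]
    return out, excluded
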