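"""Shared fixtures: small observation tables and the replicate recovery study.

The recovery study (constant-depletion replicates plus one diel and one null
replicate) is expensive, so it runs once per session and is shared by every
test that checks estimator calibration.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import nectardep as nd
from nectardep.depletion import depletion_table, estimates_to_frame
from nectardep.hurdle import ModelSpec, SamplerConfig, fit
from nectardep.synthetic import (
    DayPlan,
    GroupEffectSDs,
    SimulationConfig,
    SpeciesParams,
    simulate_dataset,
)

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("suite")

#: replicate count of the recovery study
N_RECOVERY_REPLICATES = 20

#: sampler used for all replicate fits: single chain, short adaptive run —
#: cell medians are stable at this length while keeping the study tractable
REPLICATE_SAMPLER = SamplerConfig(chains=1, warmup=350, draws=350)

RECOVERY_SPEC = ModelSpec(rounds=(9, 11, 13, 15))


def recovery_config(seed: int, schedule: dict) -> SimulationConfig:
    """Reduced study design for replicate recovery runs.

    Two species × three dates × three trees per species-date, four rounds,
    twenty flowers per treatment per tree. Slope SDs are zero so the true
    depletion is exactly the scheduled value in every cell; intercept SDs
    keep realistic tree/species/date heterogeneity in baseline volumes.
    """
    return SimulationConfig(
        species={"plum": SpeciesParams(0.6, 1.5), "pear": SpeciesParams(0.8, 1.5)},
        days=[DayPlan(f"2023-04-{10 + i:02d}", {"plum": 3, "pear": 3}) for i in range(3)],
        depletion_schedule=dict(schedule),
        hierarchy_sds={
            "tree": GroupEffectSDs(0.3, 0.0, 0.3, 0.0),
            "species": GroupEffectSDs(0.2, 0.0, 0.2, 0.0),
            "date": GroupEffectSDs(0.3, 0.0, 0.3, 0.0),
        },
        zero_prob_bagged=0.15,
        flowers_per_treatment_per_tree=20,
        seed=seed,
    )


def fit_and_summarize(obs: pd.DataFrame, seed: int,
                      sampler: SamplerConfig = REPLICATE_SAMPLER) -> pd.DataFrame:
    """Normalize, fit, and return the per-cell depletion summary table."""
    normalized, _ = nd.normalize(obs)
    draws = fit(normalized, RECOVERY_SPEC, sampler, seed=seed)
    cells = sorted(set(zip(obs["species"], obs["date"], obs["round_hour"])))
    return estimates_to_frame(depletion_table(draws, cells))


@pytest.fixture(scope="session")
def recovery_study():
    """Replicated recovery study under three generative regimes.

    Returns a dict with
      - ``constant``: per-cell summaries across replicates generated with
        true D = 0.5 in every cell, with columns ``err`` (|median − 0.5|)
        and ``cover95`` (does the 95% interval contain 0.5);
      - ``diel``: one replicate with d = (0.1, 0.3, 0.5, 0.7) across rounds;
      - ``null``: one replicate with d ≡ 0.
    """
    import warnings

    constant_tabs = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for rep in range(N_RECOVERY_REPLICATES):
            cfg = recovery_config(1000 + rep, {9: 0.5, 11: 0.5, 13: 0.5, 15: 0.5})
            obs, truth = simulate_dataset(cfg)
            assert np.allclose(truth.cells["D_true"], 0.5)
            tab = fit_and_summarize(obs, seed=2000 + rep)
            tab["replicate"] = rep
            tab["err"] = (tab["d_median"] - 0.5).abs()
            tab["cover95"] = (tab["d_l95"] <= 0.5) & (0.5 <= tab["d_u95"])
            constant_tabs.append(tab)

        diel_cfg = recovery_config(4242, {9: 0.1, 11: 0.3, 13: 0.5, 15: 0.7})
        diel_obs, _ = simulate_dataset(diel_cfg)
        diel_tab = fit_and_summarize(diel_obs, seed=4243)

        null_cfg = recovery_config(5151, {9: 0.0, 11: 0.0, 13: 0.0, 15: 0.0})
        null_obs, _ = simulate_dataset(null_cfg)
        null_tab = fit_and_summarize(null_obs, seed=5152)

    return {
        "constant": pd.concat(constant_tabs, ignore_index=True),
        "diel": diel_tab,
        "null": null_tab,
    }


def make_observations(rows: list[dict]) -> pd.DataFrame:
    """Small observation table from compact row dicts with defaults."""
    defaults = dict(date="2023-03-29", round_hour=9, species="plum", tree_id="T1",
                    treatment="bagged", volume_uL=0.4,
                    concentration_brix=None, concentration_pooled=None)
    out = []
    for i, row in enumerate(rows):
        r = {**defaults, **row}
        r.setdefault("flower_id", f"F{i + 1}")
        out.append(r)
    df = pd.DataFrame(out)
    df["concentration_brix"] = pd.to_numeric(df["concentration_brix"])
    return df


@pytest.fixture
def single_cell_data():
    """One cell, both treatments: bagged {1, 2, 3}, open {1, 1} μL."""
    rows = [
        {"treatment": "bagged", "flower_id": f"B{i}", "volume_uL": v}
        for i, v in enumerate([1.0, 2.0, 3.0])
    ] + [
        {"treatment": "open", "flower_id": f"O{i}", "volume_uL": v}
        for i, v in enumerate([1.0, 1.0])
    ]
    return make_observations(rows)
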