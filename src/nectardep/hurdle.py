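"""Hierarchical Bayesian hurdle-gamma regression for nectar standing crop.

The response is a normalized nectar volume that is continuously non-negative
with exact zeros (empty flowers). The likelihood has two parts:

* a **binomial (hurdle) submodel** on the logit scale for the probability π
  that a flower is empty, and
* a **gamma submodel** on the log scale for the mean μ of positive volumes,
  with a single shape parameter α shared across observations.

Treatment (bagged/open) and sampling round interact as fixed effects via
cell-means coding: one coefficient per treatment × round cell on each
submodel. Tree, species and date enter as varying (partially pooled)
intercepts and treatment slopes on both submodels, with per-factor scale
parameters and, optionally, a modelled intercept–slope correlation. Random
effects are parameterized non-centered (deviations = diag(σ)·L·z with
z ~ N(0,1)), which keeps the posterior geometry tractable for gradient-based
MCMC.

Priors are regularizing and weakly informative: normal(0, 1) on fixed
effects on the link scales, half-normal(1) on group SDs, LKJ(2) on the 2×2
intercept–slope correlation, and an exponential prior with median 1 on the
gamma shape. All are overridable via :class:`PriorConfig`.

The unconditional expected volume implied by one parameter draw is
``E[V] = (1 − π) · μ``; :func:`posterior_cell_expectation` evaluates it per
cell and treatment with tree deviations marginalized to zero (the
typical-tree cell mean), which is the quantity the depletion statistic is
built from.
"""

from __future__ import annotations

import math
import re
import warnings as _warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln, digamma

from . import sampler as _sampler
from .sampler import SamplerConfig

__all__ = [
    "PriorConfig",
    "ModelSpec",
    "ModelParameters",
    "PosteriorDraws",
    "SamplerConfig",
    "UnidentifiableError",
    "ConvergenceWarning",
    "log_likelihood",
    "log_prior",
    "sample_prior",
    "fit",
    "posterior_cell_expectation",
    "diagnostics",
    "load_draws_csv",
]

SUBMODELS = ("gamma", "hurdle")


class UnidentifiableError(ValueError):
    """The data cannot identify the model (e.g. no bagged observations)."""


class ConvergenceWarning(UserWarning):
    """MCMC diagnostics exceeded their thresholds; inspect before use."""


@dataclass(frozen=True)
class PriorConfig:
    """Hyperparameters of the regularizing, weakly informative priors."""

    gamma_coef_mean: float = 0.0
    gamma_coef_sd: float = 1.0
    hurdle_coef_mean: float = 0.0
    hurdle_coef_sd: float = 1.0
    #: half-normal scale of every group-level SD
    sd_scale: float = 1.0
    #: LKJ shape for the 2×2 intercept–slope correlation
    lkj_eta: float = 2.0
    #: exponential rate on the gamma shape α; ln 2 puts the prior median at 1
    shape_rate: float = math.log(2.0)


@dataclass(frozen=True)
class ModelSpec:
    """Structure of the regression: levels, grouping factors, priors."""

    rounds: tuple[int, ...] = (9, 11, 13, 15)
    treatments: tuple[str, str] = ("bagged", "open")
    group_factors: tuple[str, ...] = ("tree", "species", "date")
    correlated: bool = True
    priors: PriorConfig = field(default_factory=PriorConfig)

    def cells(self) -> list[tuple[str, int]]:
        """Treatment × round cells in fixed-effect index order."""
        return [(t, r) for t in self.treatments for r in self.rounds]

    def cell_index(self, treatment: str, round_hour: int) -> int:
        try:
            t = self.treatments.index(treatment)
            r = self.rounds.index(int(round_hour))
        except ValueError as exc:
            raise KeyError((treatment, round_hour)) from exc
        return t * len(self.rounds) + r


@dataclass
class ModelParameters:
    """One point in parameter space (e.g. a single posterior draw).

    ``u`` maps (factor, submodel) to a per-level mapping of
    (intercept deviation, treatment-slope deviation) pairs; ``sigma`` and
    ``rho`` hold the corresponding group scales and correlations.
    """

    b_gamma: Mapping[tuple[str, int], float]
    b_hurdle: Mapping[tuple[str, int], float]
    shape: float
    u: Mapping[tuple[str, str], Mapping[str, Sequence[float]]] = field(default_factory=dict)
    sigma: Mapping[tuple[str, str], Sequence[float]] = field(default_factory=dict)
    rho: Mapping[tuple[str, str], float] = field(default_factory=dict)

    def validate(self) -> "ModelParameters":
        if not self.shape > 0:
            raise ValueError("gamma shape must be > 0")
        for key, s in self.sigma.items():
            if min(s) < 0:
                raise ValueError(f"sigma{key} must be ≥ 0")
        for key, r in self.rho.items():
            if not -1 < r < 1:
                raise ValueError(f"rho{key} must lie in (-1, 1)")
        return self


def _factor_values(data: pd.DataFrame, factor: str) -> pd.Series:
    """Level labels of one grouping factor; trees are nested within species."""
    if factor == "tree":
        return data["species"].astype(str) + "/" + data["tree_id"].astype(str)
    if factor in ("species", "date"):
        return data[factor].astype(str)
    raise KeyError(f"unknown grouping factor {factor!r}")


def _linear_predictors(params: ModelParameters, data: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """η_gamma and η_hurdle per row, from explicit parameter mappings."""
    trt = data["treatment"].to_numpy()
    rnd = data["round_hour"].to_numpy()
    eta_g = np.array([params.b_gamma[(t, int(r))] for t, r in zip(trt, rnd)], dtype=float)
    eta_h = np.array([params.b_hurdle[(t, int(r))] for t, r in zip(trt, rnd)], dtype=float)
    t01 = (trt == "open").astype(float)
    for (factor, sub), dev in params.u.items():
        labels = _factor_values(data, factor)
        contrib = np.empty(len(data))
        for i, lab in enumerate(labels):
            d0, d1 = dev[lab]
            contrib[i] = d0 + t01[i] * d1
        if sub == "gamma":
            eta_g += contrib
        else:
            eta_h += contrib
    return eta_g, eta_h


def log_likelihood(params: ModelParameters, data: pd.DataFrame,
                   spec: ModelSpec | None = None) -> float:
    """Hurdle-gamma log likelihood of a normalized observation table.

    Each zero response contributes log π_i; each positive response
    contributes log(1 − π_i) plus the gamma log density with shape α and
    mean μ_i, where logit π_i and log μ_i are the linear predictors.
    """
    if len(data) == 0:
        raise ValueError("data is empty")
    params.validate()
    v = data["v_norm"].to_numpy(dtype=float)
    if (v < 0).any():
        raise ValueError("v_norm must be non-negative")
    eta_g, eta_h = _linear_predictors(params, data)
    zero = v == 0
    # stable Bernoulli: z·logπ + (1−z)·log(1−π) with logit π = η
    sign = np.where(zero, 1.0, -1.0)
    ll = float(np.sum(-np.logaddexp(0.0, -sign * eta_h)))
    a = params.shape
    vp = v[~zero]
    eg = eta_g[~zero]
    ll += float(np.sum(a * math.log(a) - gammaln(a) + (a - 1.0) * np.log(vp)
                       - a * eg - a * vp * np.exp(-eg)))
    return ll


def _half_normal_logpdf(x: float, scale: float) -> float:
    if x < 0:
        return -math.inf
    return 0.5 * math.log(2.0 / math.pi) - math.log(scale) - 0.5 * (x / scale) ** 2


def _lkj2_logpdf(rho: float, eta: float) -> float:
    # 2×2 LKJ: (1-ρ²)^(η-1) / (2^(2η-1)·B(η, η))
    if not -1 < rho < 1:
        return -math.inf
    log_norm = (2 * eta - 1) * math.log(2.0) + 2 * float(gammaln(eta)) - float(gammaln(2 * eta))
    return (eta - 1.0) * math.log1p(-rho * rho) - log_norm


def log_prior(params: ModelParameters, spec: ModelSpec) -> float:
    """Joint log prior density at one parameter point.

    Random-effect deviations are evaluated on the centered scale: each
    level's (intercept, slope) pair is bivariate normal with covariance
    diag(σ)·R·diag(σ). Returns −inf off the support (α ≤ 0, σ < 0, |ρ| ≥ 1).
    """
    pr = spec.priors
    if params.shape <= 0:
        return -math.inf
    lp = math.log(pr.shape_rate) - pr.shape_rate * params.shape

    def _normal(x, m, sd):
        return -0.5 * math.log(2 * math.pi) - math.log(sd) - 0.5 * ((x - m) / sd) ** 2

    for b in params.b_gamma.values():
        lp += _normal(b, pr.gamma_coef_mean, pr.gamma_coef_sd)
    for b in params.b_hurdle.values():
        lp += _normal(b, pr.hurdle_coef_mean, pr.hurdle_coef_sd)

    for key, dev in params.u.items():
        sig = np.asarray(params.sigma[key], dtype=float)
        if (sig < 0).any():
            return -math.inf
        rho = float(params.rho.get(key, 0.0))
        if not -1 < rho < 1:
            return -math.inf
        cov = np.array([[sig[0] ** 2, rho * sig[0] * sig[1]],
                        [rho * sig[0] * sig[1], sig[1] ** 2]])
        det = cov[0, 0] * cov[1, 1] - cov[0, 1] ** 2
        if det <= 0:
            return -math.inf
        inv = np.array([[cov[1, 1], -cov[0, 1]], [-cov[0, 1], cov[0, 0]]]) / det
        for pair in dev.values():
            x = np.asarray(pair, dtype=float)
            lp += -math.log(2 * math.pi) - 0.5 * math.log(det) - 0.5 * float(x @ inv @ x)
        lp += sum(_half_normal_logpdf(s, pr.sd_scale) for s in sig)
        if spec.correlated and key in params.rho:
            lp += _lkj2_logpdf(rho, pr.lkj_eta)
    return lp


def sample_prior(spec: ModelSpec, rng: np.random.Generator) -> ModelParameters:
    """Draw one parameter point from the prior (for prior predictive checks)."""
    pr = spec.priors
    b_g = {c: rng.normal(pr.gamma_coef_mean, pr.gamma_coef_sd) for c in spec.cells()}
    b_h = {c: rng.normal(pr.hurdle_coef_mean, pr.hurdle_coef_sd) for c in spec.cells()}
    shape = rng.exponential(1.0 / pr.shape_rate)
    return ModelParameters(b_gamma=b_g, b_hurdle=b_h, shape=shape)


# ---------------------------------------------------------------------------
# design / parameter layout / log posterior for the sampler


class _Design:
    """Index arrays binding one observation table to the model structure."""

    def __init__(self, data: pd.DataFrame, spec: ModelSpec):
        if "v_norm" not in data.columns:
            raise KeyError("data must carry a v_norm column (run normalize first)")
        v = data["v_norm"].to_numpy(dtype=float)
        if (v < 0).any() or not np.isfinite(v).all():
            raise ValueError("v_norm must be finite and non-negative")
        if not (data["treatment"] == "bagged").any():
            raise UnidentifiableError("no bagged observations anywhere in the data")
        extra_rounds = set(map(int, data["round_hour"])) - set(spec.rounds)
        if extra_rounds:
            raise ValueError(f"data contains rounds {sorted(extra_rounds)} outside the spec")
        both = data.groupby(["species", "date", "round_hour"])["treatment"].nunique()
        if not (both >= 2).any():
            raise UnidentifiableError("no cell contains both treatments")

        self.v = v
        self.zero = (v == 0).astype(float)
        self.pos = v > 0
        self.n_pos = int(self.pos.sum())
        self.vpos = v[self.pos]
        self.sum_log_vpos = float(np.log(self.vpos).sum())
        self.t01 = (data["treatment"].to_numpy() == "open").astype(float)
        self.t01_pos = self.t01[self.pos]
        cell = np.array([spec.cell_index(t, r) for t, r in
                         zip(data["treatment"], data["round_hour"])])
        self.cell = cell
        self.cell_pos = cell[self.pos]
        self.n_cells = len(spec.cells())
        self.levels: dict[str, list[str]] = {}
        self.codes: dict[str, np.ndarray] = {}
        for factor in spec.group_factors:
            vals = _factor_values(data, factor)
            levels = sorted(vals.unique())
            self.levels[factor] = levels
            code = vals.map({l: i for i, l in enumerate(levels)}).to_numpy()
            self.codes[factor] = code.astype(int)


@dataclass(frozen=True)
class _Block:
    factor: str
    submodel: str
    n_levels: int
    sl_z: slice
    sl_logsig: slice
    sl_rho: slice | None


class _Layout:
    """Packing of all unconstrained parameters into one flat vector."""

    def __init__(self, design: _Design, spec: ModelSpec):
        K = design.n_cells
        self.sl_bg = slice(0, K)
        self.sl_bh = slice(K, 2 * K)
        self.i_alpha = 2 * K
        pos = 2 * K + 1
        self.blocks: list[_Block] = []
        for factor in spec.group_factors:
            n = len(design.levels[factor])
            for sub in SUBMODELS:
                sl_z = slice(pos, pos + 2 * n)
                pos += 2 * n
                sl_s = slice(pos, pos + 2)
                pos += 2
                if spec.correlated:
                    sl_c = slice(pos, pos + 1)
                    pos += 1
                else:
                    sl_c = None
                self.blocks.append(_Block(factor, sub, n, sl_z, sl_s, sl_c))
        self.size = pos
        self.n_cells = K


def _make_log_posterior(design: _Design, layout: _Layout, spec: ModelSpec):
    pr = spec.priors
    K = layout.n_cells
    cell, cell_pos = design.cell, design.cell_pos
    t01, t01_pos = design.t01, design.t01_pos
    zero = design.zero
    vpos, n_pos, sum_log_vpos = design.vpos, design.n_pos, design.sum_log_vpos
    codes = design.codes

    def logp_and_grad(theta: np.ndarray) -> tuple[float, np.ndarray]:
        with np.errstate(over="ignore", invalid="ignore"):
            lp, g = _logp_grad_inner(theta)
        if not np.isfinite(lp):
            return -np.inf, g
        return lp, g

    def _logp_grad_inner(theta: np.ndarray) -> tuple[float, np.ndarray]:
        g = np.zeros_like(theta)
        b_g = theta[layout.sl_bg]
        b_h = theta[layout.sl_bh]
        th_a = theta[layout.i_alpha]
        alpha = math.exp(th_a)

        eta_h = b_h[cell]
        eta_g = b_g[cell_pos]
        cache = []
        for blk in layout.blocks:
            z = theta[blk.sl_z].reshape(blk.n_levels, 2)
            sig = np.exp(theta[blk.sl_logsig])
            if blk.sl_rho is not None:
                # tanh saturates to ±1.0 in floats; keep |rho| < 1 strictly
                rho = max(-1.0 + 1e-9, min(1.0 - 1e-9, math.tanh(theta[blk.sl_rho][0])))
            else:
                rho = 0.0
            s = math.sqrt(max(1.0 - rho * rho, 1e-12))
            u0 = sig[0] * z[:, 0]
            u1 = sig[1] * (rho * z[:, 0] + s * z[:, 1])
            lev = codes[blk.factor]
            if blk.submodel == "gamma":
                lev_p = lev[design.pos]
                eta_g = eta_g + u0[lev_p] + t01_pos * u1[lev_p]
            else:
                eta_h = eta_h + u0[lev] + t01 * u1[lev]
            cache.append((z, sig, rho, s))

        # Bernoulli hurdle, numerically stable
        sign = np.where(zero == 1.0, 1.0, -1.0)
        ll = float(np.sum(-np.logaddexp(0.0, -sign * eta_h)))
        g_eta_h = zero - expit(eta_h)

        # gamma density on positives, mean exp(eta_g), shape alpha
        w = vpos * np.exp(-eta_g)
        sum_eta = float(eta_g.sum())
        sum_w = float(w.sum())
        ll += (n_pos * (alpha * th_a - float(gammaln(alpha)))
               + (alpha - 1.0) * sum_log_vpos - alpha * sum_eta - alpha * sum_w)
        g_eta_g = alpha * (w - 1.0)
        dll_da = (n_pos * (th_a + 1.0 - float(digamma(alpha)))
                  + sum_log_vpos - sum_eta - sum_w)
        g[layout.i_alpha] = alpha * dll_da

        g[layout.sl_bg] = np.bincount(cell_pos, weights=g_eta_g, minlength=K)
        g[layout.sl_bh] = np.bincount(cell, weights=g_eta_h, minlength=K)

        for blk, (z, sig, rho, s) in zip(layout.blocks, cache):
            lev = codes[blk.factor]
            if blk.submodel == "gamma":
                ge, lv, tt = g_eta_g, lev[design.pos], t01_pos
            else:
                ge, lv, tt = g_eta_h, lev, t01
            gu0 = np.bincount(lv, weights=ge, minlength=blk.n_levels)
            gu1 = np.bincount(lv, weights=ge * tt, minlength=blk.n_levels)
            gz = np.empty((blk.n_levels, 2))
            gz[:, 0] = sig[0] * gu0 + sig[1] * rho * gu1
            gz[:, 1] = sig[1] * s * gu1
            g[blk.sl_z] = gz.ravel()
            gsig0 = float(np.dot(z[:, 0], gu0))
            gsig1 = float(np.dot(rho * z[:, 0] + s * z[:, 1], gu1))
            g[blk.sl_logsig] = [sig[0] * gsig0, sig[1] * gsig1]
            if blk.sl_rho is not None:
                grho = sig[1] * float(np.dot(z[:, 0] - (rho / s) * z[:, 1], gu1))
                g[blk.sl_rho] = (1.0 - rho * rho) * grho

        # priors (unnormalized where the constant does not matter)
        lp = ll
        db = (b_g - pr.gamma_coef_mean) / pr.gamma_coef_sd
        lp += -0.5 * float(db @ db)
        g[layout.sl_bg] -= db / pr.gamma_coef_sd
        db = (b_h - pr.hurdle_coef_mean) / pr.hurdle_coef_sd
        lp += -0.5 * float(db @ db)
        g[layout.sl_bh] -= db / pr.hurdle_coef_sd
        # alpha ~ Exponential(rate), theta = log(alpha), + Jacobian
        lp += -pr.shape_rate * alpha + th_a
        g[layout.i_alpha] += -pr.shape_rate * alpha + 1.0
        for blk, (z, sig, rho, s) in zip(layout.blocks, cache):
            zf = theta[blk.sl_z]
            lp += -0.5 * float(zf @ zf)
            g[blk.sl_z] -= zf
            # sigma ~ HalfNormal(scale), theta = log(sigma), + Jacobian
            lp += float(np.sum(-0.5 * (sig / pr.sd_scale) ** 2 + theta[blk.sl_logsig]))
            g[blk.sl_logsig] += -(sig / pr.sd_scale) ** 2 + 1.0
            if blk.sl_rho is not None:
                # LKJ(eta) + tanh Jacobian
                lp += pr.lkj_eta * math.log1p(-rho * rho)
                g[blk.sl_rho] += -2.0 * pr.lkj_eta * rho
        return lp, g

    return logp_and_grad


# ---------------------------------------------------------------------------
# posterior container


@dataclass
class PosteriorDraws:
    """Posterior samples with structure-aware accessors and diagnostics.

    Fixed-effect arrays have shape (chains, draws, n_cells); random-effect
    deviations are stored on the centered scale, shape
    (chains, draws, n_levels, 2) with columns (intercept, slope).
    """

    b_gamma: np.ndarray
    b_hurdle: np.ndarray
    alpha: np.ndarray
    u: dict[tuple[str, str], np.ndarray]
    sigma: dict[tuple[str, str], np.ndarray]
    rho: dict[tuple[str, str], np.ndarray]
    cells: list[tuple[str, int]]
    levels: dict[str, list[str]]
    stats: dict = field(default_factory=dict)
    diagnostics: pd.DataFrame | None = None
    warnings: list[str] = field(default_factory=list)

    @property
    def n_chains(self) -> int:
        return self.b_gamma.shape[0]

    @property
    def n_draws(self) -> int:
        return self.b_gamma.shape[1]

    def cell_index(self, treatment: str, round_hour: int) -> int:
        try:
            return self.cells.index((treatment, int(round_hour)))
        except ValueError as exc:
            raise KeyError((treatment, round_hour)) from exc

    def named_arrays(self) -> dict[str, np.ndarray]:
        """Flat name → (chains, draws) mapping of every stored parameter."""
        out: dict[str, np.ndarray] = {"alpha": self.alpha}
        for k, (trt, rnd) in enumerate(self.cells):
            out[f"b_gamma[{trt},{rnd}]"] = self.b_gamma[:, :, k]
            out[f"b_hurdle[{trt},{rnd}]"] = self.b_hurdle[:, :, k]
        for (factor, sub), arr in self.sigma.items():
            out[f"sigma_{sub}[{factor},intercept]"] = arr[:, :, 0]
            out[f"sigma_{sub}[{factor},slope]"] = arr[:, :, 1]
        for (factor, sub), arr in self.rho.items():
            out[f"rho_{sub}[{factor}]"] = arr
        for (factor, sub), arr in self.u.items():
            for j, level in enumerate(self.levels[factor]):
                out[f"u_{sub}[{factor}:{level},intercept]"] = arr[:, :, j, 0]
                out[f"u_{sub}[{factor}:{level},slope]"] = arr[:, :, j, 1]
        return out

    def to_frame(self) -> pd.DataFrame:
        """Columnar (chain, draw, parameter, value) long format."""
        named = self.named_arrays()
        C, S = self.n_chains, self.n_draws
        chains = np.repeat(np.arange(C), S)
        draws = np.tile(np.arange(S), C)
        frames = [
            pd.DataFrame({"chain": chains, "draw": draws,
                          "parameter": name, "value": arr.reshape(-1)})
            for name, arr in named.items()
        ]
        return pd.concat(frames, ignore_index=True)

    def save_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def load_draws_csv(path) -> PosteriorDraws:
    """Rebuild a :class:`PosteriorDraws` from its columnar CSV."""
    df = pd.read_csv(path)
    C = int(df["chain"].max()) + 1
    S = int(df["draw"].max()) + 1
    pivot: dict[str, np.ndarray] = {}
    for name, grp in df.groupby("parameter", sort=False):
        grp = grp.sort_values(["chain", "draw"])
        pivot[str(name)] = grp["value"].to_numpy().reshape(C, S)

    cells: list[tuple[str, int]] = []
    for name in pivot:
        m = re.match(r"^b_gamma\[(\w+),(\d+)\]$", name)
        if m:
            cells.append((m.group(1), int(m.group(2))))
    cells.sort(key=lambda c: (c[0] != "bagged", c[1]))
    K = len(cells)
    b_g = np.stack([pivot[f"b_gamma[{t},{r}]"] for t, r in cells], axis=-1)
    b_h = np.stack([pivot[f"b_hurdle[{t},{r}]"] for t, r in cells], axis=-1)

    levels: dict[str, list[str]] = {}
    u_names: dict[tuple[str, str], dict[str, str]] = {}
    sigma: dict[tuple[str, str], np.ndarray] = {}
    rho: dict[tuple[str, str], np.ndarray] = {}
    for name in pivot:
        m = re.match(r"^u_(gamma|hurdle)\[(\w+):(.+),(intercept|slope)\]$", name)
        if m:
            sub, factor, level = m.group(1), m.group(2), m.group(3)
            levels.setdefault(factor, [])
            if level not in levels[factor]:
                levels[factor].append(level)
        m = re.match(r"^sigma_(gamma|hurdle)\[(\w+),intercept\]$", name)
        if m:
            sub, factor = m.group(1), m.group(2)
            sigma[(factor, sub)] = np.stack(
                [pivot[f"sigma_{sub}[{factor},intercept]"],
                 pivot[f"sigma_{sub}[{factor},slope]"]], axis=-1)
        m = re.match(r"^rho_(gamma|hurdle)\[(\w+)\]$", name)
        if m:
            rho[(m.group(2), m.group(1))] = pivot[name]
    for factor in levels:
        levels[factor] = sorted(levels[factor])
    u: dict[tuple[str, str], np.ndarray] = {}
    for (factor, sub) in sigma:
        if factor not in levels:
            continue
        arr = np.empty((C, S, len(levels[factor]), 2))
        for j, level in enumerate(levels[factor]):
            arr[:, :, j, 0] = pivot[f"u_{sub}[{factor}:{level},intercept]"]
            arr[:, :, j, 1] = pivot[f"u_{sub}[{factor}:{level},slope]"]
        u[(factor, sub)] = arr
    return PosteriorDraws(
        b_gamma=b_g, b_hurdle=b_h, alpha=pivot["alpha"],
        u=u, sigma=sigma, rho=rho, cells=cells, levels=levels,
    )


# ---------------------------------------------------------------------------
# fitting


def fit(data: pd.DataFrame, spec: ModelSpec,
        sampler_config: SamplerConfig | None = None, seed: int = 0,
        rhat_max: float = 1.01, ess_min: float = 400.0,
        max_divergence_frac: float = 0.02) -> PosteriorDraws:
    """Fit the hurdle-gamma model by adaptive HMC.

    Deterministic given ``seed`` and the sampler configuration. Convergence
    problems (R-hat above ``rhat_max`` or bulk ESS below ``ess_min`` on a
    fixed effect, or too many divergent trajectories) are surfaced as a
    :class:`ConvergenceWarning` and recorded on ``result.warnings`` — never
    silently ignored.
    """
    cfg = sampler_config or SamplerConfig()
    design = _Design(data, spec)
    layout = _Layout(design, spec)
    logp = _make_log_posterior(design, layout, spec)
    theta, chain_stats = _sampler.sample(logp, layout.size, cfg, seed)

    C, S = cfg.chains, cfg.draws
    b_g = theta[:, :, layout.sl_bg]
    b_h = theta[:, :, layout.sl_bh]
    alpha = np.exp(theta[:, :, layout.i_alpha])
    u, sigma, rho = {}, {}, {}
    for blk in layout.blocks:
        key = (blk.factor, blk.submodel)
        z = theta[:, :, blk.sl_z].reshape(C, S, blk.n_levels, 2)
        sig = np.exp(theta[:, :, blk.sl_logsig])
        sigma[key] = sig
        if blk.sl_rho is not None:
            r = np.tanh(theta[:, :, blk.sl_rho][:, :, 0])
            rho[key] = r
        else:
            r = np.zeros((C, S))
        s = np.sqrt(np.maximum(1.0 - r * r, 1e-12))
        dev = np.empty_like(z)
        dev[..., 0] = sig[..., 0][..., None] * z[..., 0]
        dev[..., 1] = sig[..., 1][..., None] * (r[..., None] * z[..., 0] + s[..., None] * z[..., 1])
        u[key] = dev

    draws = PosteriorDraws(
        b_gamma=b_g, b_hurdle=b_h, alpha=alpha, u=u, sigma=sigma, rho=rho,
        cells=spec.cells(), levels=dict(design.levels),
        stats={
            "seed": int(seed),
            "warmup": cfg.warmup,
            "draws": cfg.draws,
            "chains": cfg.chains,
            "accept_rate": [r.accept_rate for r in chain_stats],
            "divergences": [r.divergences for r in chain_stats],
            "step_size": [r.step_size for r in chain_stats],
        },
    )

    if cfg.chains >= 2:
        diag = diagnostics(draws, rhat_max=rhat_max, ess_min=ess_min)
        draws.diagnostics = diag
        fixed = diag[diag["parameter"].str.startswith(("b_gamma", "b_hurdle"))]
        bad_rhat = fixed[fixed["r_hat"] > rhat_max]
        bad_ess = fixed[fixed["ess_bulk"] < ess_min]
        if len(bad_rhat):
            draws.warnings.append(
                f"{len(bad_rhat)} fixed effect(s) with R-hat > {rhat_max}: "
                + ", ".join(bad_rhat["parameter"].head(5)))
        if len(bad_ess):
            draws.warnings.append(
                f"{len(bad_ess)} fixed effect(s) with bulk ESS < {ess_min:g}: "
                + ", ".join(bad_ess["parameter"].head(5)))
    n_div = sum(r.divergences for r in chain_stats)
    if n_div > max_divergence_frac * C * S:
        draws.warnings.append(
            f"{n_div} divergent transitions out of {C * S} draws "
            f"(threshold {max_divergence_frac:.0%})")
    for w in draws.warnings:
        _warnings.warn(w, ConvergenceWarning, stacklevel=2)
    return draws


def posterior_cell_expectation(draws: PosteriorDraws, cell: tuple[str, str, int],
                               treatment: str) -> np.ndarray:
    """Per-draw unconditional expected volume E[V] = (1 − π)·μ for one cell.

    ``cell`` is (species, date, round_hour). The cell's species and date
    deviations (intercept, and slope if the treatment is open) are included;
    tree deviations are marginalized to zero, so this is the typical-tree
    cell expectation. Returns a flat vector of length chains × draws.
    """
    species, date, round_hour = cell
    k = draws.cell_index(treatment, round_hour)
    t = 1.0 if treatment == "open" else 0.0
    eta_g = draws.b_gamma[:, :, k].astype(float).copy()
    eta_h = draws.b_hurdle[:, :, k].astype(float).copy()
    for factor, label in (("species", str(species)), ("date", str(date))):
        for sub, eta in (("gamma", eta_g), ("hurdle", eta_h)):
            key = (factor, sub)
            if key not in draws.u:
                continue
            if label not in draws.levels[factor]:
                raise KeyError(f"{factor} level {label!r} not among fitted levels")
            j = draws.levels[factor].index(label)
            eta += draws.u[key][:, :, j, 0] + t * draws.u[key][:, :, j, 1]
    return (expit(-eta_h) * np.exp(eta_g)).reshape(-1)


def diagnostics(draws: PosteriorDraws, rhat_max: float = 1.01,
                ess_min: float = 400.0) -> pd.DataFrame:
    """Split-R-hat and effective sample sizes per stored parameter.

    Uses rank-normalized split R-hat and bulk/tail ESS. Requires at least
    two chains; flags parameters breaching the thresholds, plus degenerate
    (zero-variance) chains.
    """
    if draws.n_chains < 2:
        raise ValueError("R-hat requires at least two chains")
    import arviz as az

    named = draws.named_arrays()
    degenerate = {name for name, arr in named.items()
                  if np.allclose(arr.var(axis=1), 0.0)}
    live = {name.replace("[", "(").replace("]", ")"): arr
            for name, arr in named.items() if name not in degenerate}
    display = {name.replace("[", "(").replace("]", ")"): name for name in named}
    rows = []
    if live:
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            ds = az.convert_to_dataset(live)
            rhat = az.rhat(ds)
            ess_b = az.ess(ds, method="bulk")
            ess_t = az.ess(ds, method="tail")
        for key in live:
            r = float(rhat[key].values)
            eb = float(ess_b[key].values)
            et = float(ess_t[key].values)
            flag = "rhat" if r > rhat_max else ("ess" if eb < ess_min else "")
            rows.append({"parameter": display[key], "r_hat": r,
                         "ess_bulk": eb, "ess_tail": et, "flag": flag})
    for name in degenerate:
        rows.append({"parameter": name, "r_hat": np.nan, "ess_bulk": np.nan,
                     "ess_tail": np.nan, "flag": "degenerate"})
    order = {name: i for i, name in enumerate(named)}
    return pd.DataFrame(rows).sort_values("parameter", key=lambda s: s.map(order)).reset_index(drop=True)
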