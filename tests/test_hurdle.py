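"""Hurdle-gamma model: likelihood/prior oracles, sampler correctness, recovery."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

from nectardep.hurdle import (
    ModelParameters,
    ModelSpec,
    PosteriorDraws,
    PriorConfig,
    SamplerConfig,
    UnidentifiableError,
    diagnostics,
    fit,
    load_draws_csv,
    log_likelihood,
    log_prior,
    posterior_cell_expectation,
    sample_prior,
)
from nectardep.oracle import grid_posterior_single_cell

from conftest import make_observations


def simple_params(b_g=0.0, b_h=0.0, shape=1.0):
    return ModelParameters(
        b_gamma={("bagged", 9): b_g, ("open", 9): b_g},
        b_hurdle={("bagged", 9): b_h, ("open", 9): b_h},
        shape=shape,
    )


def scipy_hurdle_loglik(v, pi, shape, mu):
    """Independent density sum from textbook scipy distributions."""
    total = 0.0
    for vi, p, m in zip(v, pi, mu):
        if vi == 0:
            total += st.bernoulli.logpmf(1, p)
        else:
            total += st.bernoulli.logpmf(0, p)
            total += st.gamma.logpdf(vi, a=shape, scale=m / shape)
    return total


def test_zero_observation_contributes_log_pi():
    data = make_observations([{"volume_uL": 0.0}]).assign(v_norm=0.0)
    ll = log_likelihood(simple_params(b_h=0.0), data)  # logit 0 → π = 0.5
    assert ll == pytest.approx(math.log(0.5))


def test_exponential_density_closed_form():
    # α = 1, μ = 1 is Exponential(1); at v = 1 the log density is −1, and a
    # strongly negative hurdle coefficient makes π ≈ 0 exactly in floats
    data = make_observations([{"volume_uL": 1.0}]).assign(v_norm=1.0)
    ll = log_likelihood(simple_params(b_g=0.0, b_h=-750.0, shape=1.0), data)
    assert ll == pytest.approx(-1.0)


def test_likelihood_matches_independent_scipy_sum():
    rng = np.random.default_rng(17)
    n = 20
    rows = []
    for i in range(n):
        v = 0.0 if rng.random() < 0.3 else float(rng.gamma(2.0, 0.5))
        rows.append({
            "species": rng.choice(["plum", "pear"]),
            "tree_id": rng.choice(["T1", "T2"]),
            "treatment": rng.choice(["bagged", "open"]),
            "round_hour": int(rng.choice([9, 11])),
            "flower_id": f"F{i}",
            "volume_uL": v,
        })
    data = make_observations(rows).assign(v_norm=lambda d: d["volume_uL"])
    b_g = {(t, r): rng.normal() for t in ("bagged", "open") for r in (9, 11)}
    b_h = {(t, r): rng.normal() for t in ("bagged", "open") for r in (9, 11)}
    u_sp = {"plum": (0.3, -0.1), "pear": (-0.2, 0.2)}
    params = ModelParameters(
        b_gamma=b_g, b_hurdle=b_h, shape=1.7,
        u={("species", "gamma"): u_sp},
        sigma={("species", "gamma"): (0.5, 0.5)},
    )
    t01 = (data["treatment"] == "open").astype(float).to_numpy()
    eta_g = np.array([
        b_g[(t, r)] + u_sp[s][0] + t01[i] * u_sp[s][1]
        for i, (t, r, s) in enumerate(zip(data["treatment"], data["round_hour"], data["species"]))
    ])
    eta_h = np.array([b_h[(t, r)] for t, r in zip(data["treatment"], data["round_hour"])])
    expected = scipy_hurdle_loglik(
        data["v_norm"].to_numpy(), st.logistic.cdf(eta_h), 1.7, np.exp(eta_g))
    got = log_likelihood(params, data)
    assert got == pytest.approx(expected, rel=1e-10)


def test_likelihood_additive_over_partitions():
    rng = np.random.default_rng(5)
    rows = [{"treatment": t, "flower_id": f"F{i}",
             "volume_uL": 0.0 if rng.random() < 0.25 else float(rng.gamma(2, 0.4))}
            for i, t in enumerate(rng.choice(["bagged", "open"], 30))]
    data = make_observations(rows).assign(v_norm=lambda d: d["volume_uL"])
    params = simple_params(b_g=0.2, b_h=-0.5, shape=2.0)
    whole = log_likelihood(params, data)
    parts = log_likelihood(params, data.iloc[:11]) + log_likelihood(params, data.iloc[11:])
    assert whole == pytest.approx(parts, rel=1e-12)


def test_negative_response_is_domain_error():
    data = make_observations([{"volume_uL": 1.0}]).assign(v_norm=-0.5)
    with pytest.raises(ValueError, match="non-negative"):
        log_likelihood(simple_params(), data)


def test_log_prior_matches_scipy_density_sum():
    spec = ModelSpec(rounds=(9,), correlated=True)
    pr = spec.priors
    params = ModelParameters(
        b_gamma={("bagged", 9): 0.4, ("open", 9): -0.3},
        b_hurdle={("bagged", 9): 0.0, ("open", 9): 1.1},
        shape=1.3,
        u={("species", "gamma"): {"plum": (0.2, -0.1), "pear": (-0.4, 0.3)}},
        sigma={("species", "gamma"): (0.6, 0.4)},
        rho={("species", "gamma"): 0.25},
    )
    expected = st.expon.logpdf(1.3, scale=1.0 / pr.shape_rate)
    for b in (0.4, -0.3):
        expected += st.norm.logpdf(b, pr.gamma_coef_mean, pr.gamma_coef_sd)
    for b in (0.0, 1.1):
        expected += st.norm.logpdf(b, pr.hurdle_coef_mean, pr.hurdle_coef_sd)
    sig, rho = np.array([0.6, 0.4]), 0.25
    cov = np.diag(sig) @ np.array([[1, rho], [rho, 1]]) @ np.diag(sig)
    for dev in ((0.2, -0.1), (-0.4, 0.3)):
        expected += st.multivariate_normal.logpdf(dev, mean=[0, 0], cov=cov)
    expected += st.halfnorm.logpdf(sig, scale=pr.sd_scale).sum()
    # 2×2 LKJ(η) equals Beta(η, η) on (ρ+1)/2 with a factor 1/2 Jacobian
    expected += st.beta.logpdf((rho + 1) / 2, pr.lkj_eta, pr.lkj_eta) - math.log(2.0)
    assert log_prior(params, spec) == pytest.approx(expected, rel=1e-12)


def test_log_prior_out_of_support():
    spec = ModelSpec(rounds=(9,))
    params = simple_params()
    params.shape = -1.0
    assert log_prior(params, spec) == -math.inf


def test_prior_ensemble_quantiles():
    spec = ModelSpec(rounds=(9,))
    rng = np.random.default_rng(8)
    draws = [sample_prior(spec, rng) for _ in range(4000)]
    shapes = np.array([d.shape for d in draws])
    coefs = np.array([d.b_gamma[("bagged", 9)] for d in draws])
    q = [0.25, 0.5, 0.75]
    np.testing.assert_allclose(
        np.quantile(shapes, q), st.expon.ppf(q, scale=1 / spec.priors.shape_rate), atol=0.08)
    np.testing.assert_allclose(np.quantile(coefs, q), st.norm.ppf(q), atol=0.08)
    assert abs(np.median(shapes) - 1.0) < 0.08  # prior median near 1


def test_internal_gradient_matches_finite_differences():
    from nectardep.hurdle import _Design, _Layout, _make_log_posterior

    rng = np.random.default_rng(0)
    n = 40
    df = make_observations([
        {"species": rng.choice(["plum", "pear"]),
         "date": rng.choice(["2023-03-20", "2023-03-22"]),
         "round_hour": int(rng.choice([9, 11])),
         "tree_id": rng.choice(["T1", "T2"]),
         "treatment": rng.choice(["bagged", "open"]),
         "flower_id": f"F{i}",
         "volume_uL": 0.0 if rng.random() < 0.3 else float(rng.gamma(2, 0.5))}
        for i in range(n)
    ]).assign(v_norm=lambda d: d["volume_uL"])
    spec = ModelSpec(rounds=(9, 11))
    design = _Design(df, spec)
    layout = _Layout(design, spec)
    logp = _make_log_posterior(design, layout, spec)
    theta = rng.normal(0, 0.4, layout.size)
    _, grad = logp(theta)
    eps = 1e-6
    for i in rng.choice(layout.size, size=25, replace=False):
        tp, tm = theta.copy(), theta.copy()
        tp[i] += eps
        tm[i] -= eps
        num = (logp(tp)[0] - logp(tm)[0]) / (2 * eps)
        assert grad[i] == pytest.approx(num, rel=1e-4, abs=1e-6)


def _single_cell_frame(rng, n_per_arm, pi, mu, shape, mu_open=None, pi_open=None):
    rows = []
    for trt, p, m in (("bagged", pi, mu), ("open", pi_open or pi, mu_open or mu)):
        v = rng.gamma(shape, m / shape, n_per_arm)
        v[rng.random(n_per_arm) < p] = 0.0
        rows += [{"treatment": trt, "flower_id": f"{trt}{i}", "volume_uL": float(x)}
                 for i, x in enumerate(v)]
    return make_observations(rows).assign(v_norm=lambda d: d["volume_uL"])


def test_single_cell_recovery_within_posterior_uncertainty():
    """Non-hierarchical instance: posterior brackets the generating values."""
    rng = np.random.default_rng(31)
    data = _single_cell_frame(rng, 200, pi=0.3, mu=1.0, shape=4.0)
    spec = ModelSpec(rounds=(9,), group_factors=())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        draws = fit(data, spec, SamplerConfig(chains=2, warmup=400, draws=400), seed=13)
    k = draws.cell_index("bagged", 9)
    mu_d = np.exp(draws.b_gamma[:, :, k]).ravel()
    pi_d = st.logistic.cdf(draws.b_hurdle[:, :, k]).ravel()
    assert abs(mu_d.mean() - 1.0) < 3 * mu_d.std()
    assert abs(pi_d.mean() - 0.3) < 3 * pi_d.std()
    assert abs(draws.alpha.mean() - 4.0) < 3 * draws.alpha.std()


def test_fit_is_deterministic_given_seed(single_cell_data):
    data, _ = __import__("nectardep").normalize(single_cell_data)
    spec = ModelSpec(rounds=(9,), group_factors=())
    cfg = SamplerConfig(chains=2, warmup=100, draws=100)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        a = fit(data, spec, cfg, seed=99)
        b = fit(data, spec, cfg, seed=99)
    np.testing.assert_array_equal(a.b_gamma, b.b_gamma)
    np.testing.assert_array_equal(a.alpha, b.alpha)


def test_unidentifiable_without_bagged_rows():
    df = make_observations([
        {"treatment": "open", "volume_uL": 0.5, "flower_id": "F1"},
        {"treatment": "open", "volume_uL": 0.7, "flower_id": "F2"},
    ]).assign(v_norm=lambda d: d["volume_uL"])
    with pytest.raises(UnidentifiableError, match="bagged"):
        fit(df, ModelSpec(rounds=(9,), group_factors=()))


def _toy_draws(b_g, b_h, n_draws=10, alpha=2.0):
    shape = (1, n_draws, 1)
    return PosteriorDraws(
        b_gamma=np.full(shape, b_g), b_hurdle=np.full(shape, b_h),
        alpha=np.full((1, n_draws), alpha), u={}, sigma={}, rho={},
        cells=[("bagged", 9)], levels={},
    )


def test_cell_expectation_closed_forms():
    # π = 0.5, μ = 2 → E[V] = 1
    d = _toy_draws(b_g=math.log(2.0), b_h=0.0)
    e = posterior_cell_expectation(d, ("plum", "2023-03-29", 9), "bagged")
    np.testing.assert_allclose(e, 1.0, rtol=1e-12)
    # π ≈ 0 → E[V] = μ
    d = _toy_draws(b_g=math.log(2.0), b_h=-750.0)
    e = posterior_cell_expectation(d, ("plum", "2023-03-29", 9), "bagged")
    np.testing.assert_allclose(e, 2.0, rtol=1e-12)
    with pytest.raises(KeyError):
        posterior_cell_expectation(d, ("plum", "2023-03-29", 11), "bagged")


def test_draws_csv_round_trip(single_cell_data):
    import nectardep as nd

    data, _ = nd.normalize(single_cell_data)
    spec = ModelSpec(rounds=(9,))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        draws = fit(data, spec, SamplerConfig(chains=2, warmup=80, draws=60), seed=3)
    import io

    buf = io.StringIO()
    draws.to_frame().to_csv(buf, index=False)
    buf.seek(0)
    back = load_draws_csv(buf)
    np.testing.assert_allclose(back.b_gamma, draws.b_gamma)
    np.testing.assert_allclose(back.alpha, draws.alpha)
    assert back.cells == draws.cells
    assert back.levels["species"] == draws.levels["species"]
    cell = ("plum", "2023-03-29", 9)
    np.testing.assert_allclose(
        posterior_cell_expectation(back, cell, "open"),
        posterior_cell_expectation(draws, cell, "open"), rtol=1e-9)


def test_diagnostics_flags():
    rng = np.random.default_rng(2)
    # well-mixed: independent draws from one distribution
    good = _toy_draws(0.0, 0.0, n_draws=800)
    good.b_gamma = rng.standard_normal((4, 800, 1))
    good.b_hurdle = rng.standard_normal((4, 800, 1))
    good.alpha = np.exp(rng.standard_normal((4, 800)) * 0.1)
    diag = diagnostics(good)
    b_row = diag[diag["parameter"] == "b_gamma[bagged,9]"].iloc[0]
    assert 0.99 <= b_row["r_hat"] <= 1.01

    # two chains stuck at different values: strong non-convergence
    bad = _toy_draws(0.0, 0.0, n_draws=400)
    bad.b_gamma = np.concatenate([
        rng.standard_normal((1, 400, 1)), 5.0 + rng.standard_normal((1, 400, 1))], axis=0)
    bad.b_hurdle = rng.standard_normal((2, 400, 1))
    bad.alpha = np.exp(rng.standard_normal((2, 400)) * 0.1)
    diag = diagnostics(bad)
    assert diag.loc[diag["parameter"] == "b_gamma[bagged,9]", "r_hat"].iloc[0] > 1.1
    assert (diag.loc[diag["parameter"] == "b_gamma[bagged,9]", "flag"] == "rhat").all()

    # constant chains: degenerate, not spuriously "converged"
    const = _toy_draws(1.0, 0.0, n_draws=50)
    const.b_gamma = np.ones((2, 50, 1))
    const.b_hurdle = np.ones((2, 50, 1))
    const.alpha = np.ones((2, 50))
    diag = diagnostics(const)
    assert (diag["flag"] == "degenerate").all()

    single = _toy_draws(0.0, 0.0)
    with pytest.raises(ValueError, match="two chains"):
        diagnostics(single)


def test_hierarchical_shrinkage_with_tight_scale_prior():
    """As the group-SD prior collapses, group deviations shrink to zero."""
    rng = np.random.default_rng(44)
    rows = []
    for sp, m in (("plum", 0.4), ("pear", 1.6)):
        for trt in ("bagged", "open"):
            v = rng.gamma(2.0, m / 2.0, 40)
            v[rng.random(40) < 0.2] = 0.0
            rows += [{"species": sp, "treatment": trt, "tree_id": "T1",
                      "flower_id": f"{sp}{trt}{i}", "volume_uL": float(x)}
                     for i, x in enumerate(v)]
    data = make_observations(rows).assign(v_norm=lambda d: d["volume_uL"])
    cfg = SamplerConfig(chains=1, warmup=300, draws=300)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        loose = fit(data, ModelSpec(rounds=(9,), group_factors=("species",)),
                    cfg, seed=6)
        tight = fit(data, ModelSpec(rounds=(9,), group_factors=("species",),
                                    priors=PriorConfig(sd_scale=1e-3)), cfg, seed=6)
    dev_loose = np.abs(loose.u[("species", "gamma")][..., 0]).mean()
    dev_tight = np.abs(tight.u[("species", "gamma")][..., 0]).mean()
    assert dev_tight < 0.05 * dev_loose  # deviations collapse
    # cell expectations for the two species approach a common population mean
    def spread(d):
        e = [posterior_cell_expectation(d, (sp, "2023-03-29", 9), "bagged").mean()
             for sp in ("plum", "pear")]
        return abs(e[0] - e[1])
    assert spread(tight) < 0.2 * spread(loose)


def test_degenerate_limit_matches_plain_gamma_regression():
    """No zeros + hurdle prior pinned at π ≈ 0 reduces to a gamma fit."""
    rng = np.random.default_rng(77)
    data = _single_cell_frame(rng, 150, pi=0.0, mu=1.5, shape=3.0)
    assert (data["v_norm"] > 0).all()
    priors = PriorConfig(hurdle_coef_mean=-8.0, hurdle_coef_sd=0.01)
    spec = ModelSpec(rounds=(9,), group_factors=(), priors=priors)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        draws = fit(data, spec, SamplerConfig(chains=2, warmup=400, draws=400), seed=23)
    g = grid_posterior_single_cell(
        data.loc[data["treatment"] == "bagged", "v_norm"].to_numpy(),
        data.loc[data["treatment"] == "open", "v_norm"].to_numpy())
    mu_mcmc = np.exp(draws.b_gamma[:, :, draws.cell_index("bagged", 9)]).mean()
    assert mu_mcmc == pytest.approx(g["mu_bagged_mean"], rel=0.02)


def test_fixed_effect_coverage_across_replicates():
    """95% intervals cover the generating fixed effects in ≥80% of replicates."""
    true = {"b_g": math.log(1.2), "b_h": st.logistic.ppf(0.3),
            "b_g_open": math.log(0.8), "b_h_open": st.logistic.ppf(0.4)}
    spec = ModelSpec(rounds=(9,), group_factors=())
    cfg = SamplerConfig(chains=1, warmup=250, draws=250)
    cover = {k: 0 for k in true}
    n_rep = 20
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for rep in range(n_rep):
            rng = np.random.default_rng(600 + rep)
            data = _single_cell_frame(rng, 120, pi=0.3, mu=1.2, shape=2.0,
                                      mu_open=0.8, pi_open=0.4)
            draws = fit(data, spec, cfg, seed=700 + rep)
            kb = draws.cell_index("bagged", 9)
            ko = draws.cell_index("open", 9)
            for key, arr in (("b_g", draws.b_gamma[:, :, kb]),
                             ("b_h", draws.b_hurdle[:, :, kb]),
                             ("b_g_open", draws.b_gamma[:, :, ko]),
                             ("b_h_open", draws.b_hurdle[:, :, ko])):
                lo, hi = np.quantile(arr, [0.025, 0.975])
                cover[key] += int(lo <= true[key] <= hi)
    for key, n_cov in cover.items():
        assert n_cov >= 0.8 * n_rep, f"{key}: {n_cov}/{n_rep} covered"
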