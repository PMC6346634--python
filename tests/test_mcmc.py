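"""Sampler correctness: determinism, oracle equivalence, diagnostics, metrics."""

import numpy as np
import pandas as pd
import pytest

from seedshadow.errors import DiagnosticError, UnidentifiableError
from seedshadow.kernel import kernel_density
from seedshadow.mcmc import (PosteriorSamples, SamplerConfig, SpeciesData,
                             convergence_summary, fit_metrics, rmspe, run_chain)
from seedshadow.model import FIXED_EFFECT_NAMES, PriorSpec
from seedshadow import io as ssio


def _small_chain(one_plot_dataset, seed=3, **kw):
    trees, traps, counts, _, _ = one_plot_dataset
    data = SpeciesData(trees, traps, counts)
    cfg = SamplerConfig(n_iter=kw.pop("n_iter", 1200), burn_in=kw.pop("burn_in", 200),
                        thin=kw.pop("thin", 2), rng_seed=seed, **kw)
    return data, run_chain(data, cfg)


def test_seeded_determinism(one_plot_dataset):
    _, s1 = _small_chain(one_plot_dataset, seed=5)
    _, s2 = _small_chain(one_plot_dataset, seed=5)
    np.testing.assert_array_equal(s1.u, s2.u)
    np.testing.assert_array_equal(s1.beta, s2.beta)
    np.testing.assert_array_equal(s1.deviance, s2.deviance)
    assert s1.n_draws == (1200 - 200) // 2


def test_chain_invariant_to_tree_ordering(one_plot_dataset):
    trees, traps, counts, _, _ = one_plot_dataset
    cfg = SamplerConfig(n_iter=600, burn_in=100, thin=2, rng_seed=9)
    s1 = run_chain(SpeciesData(trees, traps, counts), cfg)
    rng = np.random.default_rng(0)
    perm = rng.permutation(len(trees))
    s2 = run_chain(SpeciesData(trees.iloc[perm].reset_index(drop=True), traps, counts), cfg)
    np.testing.assert_array_equal(s1.u, s2.u)
    np.testing.assert_array_equal(s1.beta, s2.beta)


def test_u_sampler_matches_grid_quadrature_oracle(one_plot_dataset):
    """Single-unknown toy: posterior of u from the chain vs dense-grid
    quadrature of the same Poisson likelihood (total variation < 0.05)."""
    trees, traps, counts, _, truth = one_plot_dataset
    data = SpeciesData(trees, traps, counts)
    order = trees.sort_values(["plot_id", "tree_id"], kind="mergesort").index.to_numpy()
    f_true = truth.f[order]
    init = dict(u=truth.u["protected"],
                log_psi=np.log(np.clip(f_true, 1e-12, None)),
                rho=np.ones(len(trees), dtype=np.int8))
    cfg = SamplerConfig(n_iter=21000, burn_in=1000, thin=1, rng_seed=9,
                        update_psi=False, update_rho=False, update_beta=False,
                        update_effects=False, update_sigmas=False)
    draws = run_chain(data, cfg, init=init).u[:, 0]
    assert draws.size == 20000

    pr = PriorSpec()
    edges = np.linspace(pr.u_min, pr.u_max, 801)
    mid = 0.5 * (edges[:-1] + edges[1:])
    ll = np.empty(mid.size)
    for j, u in enumerate(mid):
        lam = np.clip(kernel_density(data.dist, u) @ f_true, 1e-300, None)
        ll[j] = np.sum(data.y * np.log(data.A[:, None] * lam) - data.A[:, None] * lam)
    w = np.exp(ll - ll.max())
    w /= w.sum()
    hist, _ = np.histogram(draws, bins=edges)
    tv = 0.5 * np.abs(hist / hist.sum() - w).sum()
    assert tv < 0.05


def test_single_tree_single_trap_fecundity_matches_analytic_gamma():
    """With an effectively flat prior on f, the posterior is Gamma(y+1, A*S)
    with mean (y+1)/(A*S); the chain's posterior-mean f approaches it."""
    trees = pd.DataFrame({
        "plot_id": "P1", "tree_id": ["T1"], "species": "X", "x_m": [50.0],
        "y_m": [50.0], "dbh_cm": [40.0], "regime": "protected"})
    traps = pd.DataFrame([("P1", "S1", 60.0, 50.0, 1.0, 1.0)],
                         columns=ssio.TRAP_COLUMNS)
    counts = pd.DataFrame([("P1", "S1", "X", 1, 3)], columns=ssio.COUNT_COLUMNS)
    data = SpeciesData(trees, traps, counts)
    u = 100.0
    S = kernel_density(10.0, u)
    # prior on log f ~ N(eta, sig2) with eta = sig2 approximates density ~ f,
    # i.e. a flat prior on f itself, over the region the posterior occupies
    sig2 = 400.0
    init = dict(u=u, rho=np.ones(1, dtype=np.int8), a=np.array([sig2]),
                log_psi=np.full((1, 1), np.log(3.0 / S)), sigma_e2=sig2,
                beta=np.zeros(4))
    cfg = SamplerConfig(n_iter=60000, burn_in=2000, thin=1, rng_seed=17,
                        update_rho=False, update_beta=False,
                        update_effects=False, update_sigmas=False,
                        update_u=False)
    s = run_chain(data, cfg, init=init)
    assert s.mean_f[0, 0] == pytest.approx(4.0 / S, rel=0.08)


def test_refuses_all_zero_species(one_plot_dataset):
    trees, traps, counts, _, _ = one_plot_dataset
    zero = counts.copy()
    zero["count"] = 0
    with pytest.raises(UnidentifiableError, match="Synthetica"):
        SpeciesData(trees, traps, zero)


def test_acceptance_rates_in_window_after_adaptation(one_plot_dataset):
    _, s = _small_chain(one_plot_dataset, n_iter=2500, burn_in=1000, seed=21)
    assert 0.1 <= s.acceptance["psi"] <= 0.6
    for r, rate in s.acceptance["u"].items():
        assert 0.1 <= rate <= 0.6


def test_fit_metrics_values(one_plot_dataset):
    assert rmspe([0, 2], [1, 1]) == pytest.approx(1.0)
    assert rmspe([3, 5], [3, 5]) == 0.0
    data, s = _small_chain(one_plot_dataset, n_iter=1300, burn_in=200, thin=2)
    m = fit_metrics(s, data)
    assert m["p_D"] > 0
    assert m["DIC"] == pytest.approx(m["mean_deviance"] + m["p_D"])
    assert m["RMSPE"] > 0
    # degenerate posterior: every draw identical -> zero effective parameters
    frozen = PosteriorSamples(
        species=s.species, regimes=s.regimes, years=s.years,
        beta_names=FIXED_EFFECT_NAMES, u=np.tile(s.u[:1], (150, 1)),
        beta=np.tile(s.beta[:1], (150, 1)), sigma_a2=np.zeros(150),
        sigma_g2=np.zeros(150), sigma_e2=np.zeros(150),
        deviance=np.full(150, s.deviance[0]), mean_rho=s.mean_rho,
        mean_f=s.mean_f, mean_lambda=s.mean_lambda, acceptance={},
        center_log_dbh=s.center_log_dbh)
    # deviance at the posterior-mean intensity equals each draw's deviance
    from seedshadow.model import log_likelihood
    frozen.deviance[:] = -2.0 * log_likelihood(data.y, data.A[:, None], s.mean_lambda)
    assert fit_metrics(frozen, data)["p_D"] == pytest.approx(0.0, abs=1e-9)


def test_convergence_summary_cases():
    rng = np.random.default_rng(1)
    good = {"x": rng.standard_normal(4000)}
    rep = convergence_summary(good)
    assert rep.loc[0, "rhat"] == pytest.approx(1.0, abs=0.05)
    assert not rep.loc[0, "flagged"]

    split = {"x": np.stack([rng.standard_normal(500), rng.standard_normal(500) + 10])}
    rep = convergence_summary(split)
    assert rep.loc[0, "rhat"] > 1.1 and rep.loc[0, "flagged"]

    const = {"x": np.ones(1000)}
    rep = convergence_summary(const)
    assert rep.loc[0, "ess"] == 0.0 and rep.loc[0, "flagged"]

    with pytest.raises(DiagnosticError):
        convergence_summary({"x": np.arange(4.0)})


def test_posterior_samples_round_trip(one_plot_dataset, tmp_path):
    _, s = _small_chain(one_plot_dataset, n_iter=700, burn_in=100)
    s.save(tmp_path)
    df = pd.read_csv(tmp_path / "posterior_samples.csv")
    back = df[df["parameter"] == "u[protected]"]["value"].to_numpy()
    np.testing.assert_allclose(back, s.u[:, 0])
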