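"""Metropolis-within-Gibbs inference for the seed-shadow model.

One sweep updates, in order: (1) each tree-year log conditional fecundity
log psi by adaptive random-walk Metropolis; (2) maturation indicators rho
from their Bernoulli full conditional; (3) fixed effects beta by conjugate
Gaussian draw (the psi layer is lognormal, so given log psi the regression
is exactly Gaussian); (4) individual effects a_i and year-by-regime effects
gamma_tg by conjugate Gaussian draws; (5) variance components by conjugate
inverse-gamma draws; (6) each regime's kernel scale u by random-walk
Metropolis on log u against the Poisson trap likelihood.

Proposal scales adapt by Robbins-Monro only during burn-in, so the
post-burn-in chain targets the exact posterior.  Everything is deterministic
given ``rng_seed``; trees and traps are canonically ordered at assembly so
the chain is invariant to input row order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from numba import njit
from scipy.special import gammaln

from .errors import DiagnosticError, InitializationError, UnidentifiableError
from .kernel import kernel_density, u_from_mean
from .model import (FIXED_EFFECT_NAMES, MaturationModel, PriorSpec, design_matrix,
                    log_likelihood, maturation_probability)

__all__ = [
    "SamplerConfig",
    "SpeciesData",
    "PosteriorSamples",
    "run_chain",
    "fit_species",
    "fit_metrics",
    "rmspe",
    "convergence_summary",
]


@dataclass
class SamplerConfig:
    n_iter: int = 50_000
    burn_in: int = 1_000
    thin: int = 10
    rng_seed: int = 0
    step_log_psi: float = 0.5
    step_log_u: float = 0.15
    #: latent-fecundity sub-sweeps per Gibbs scan; the psi field mixes slowly
    #: under single-site proposals, so extra sub-sweeps speed convergence
    latent_sweeps: int = 2
    #: scale of the joint beta/psi translation moves that walk along the
    #: fecundity-dispersal ridge (beta_j and the whole log-psi field move
    #: together, leaving the psi-layer residuals untouched)
    step_ridge: float = 0.1
    adapt_window: int = 100
    adapt_target: float = 0.35
    # which blocks to update; fixing a block keeps it at its initial value
    update_psi: bool = True
    update_rho: bool = True
    update_beta: bool = True
    update_effects: bool = True
    update_sigmas: bool = True
    update_u: bool = True

    def __post_init__(self):
        if self.n_iter <= self.burn_in or self.burn_in < 0:
            raise ValueError("need n_iter > burn_in >= 0")
        if self.step_log_psi <= 0 or self.step_log_u <= 0:
            raise ValueError("proposal scales must be positive")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


class SpeciesData:
    """Flat arrays for one species' fit, canonically ordered.

    Trees are sorted by (plot, tree id) and traps by (plot, trap id); years
    ascending.  Cross-plot tree-trap distances are set to +inf so the kernel
    assigns them zero seed density.
    """

    def __init__(self, trees: pd.DataFrame, traps: pd.DataFrame, counts: pd.DataFrame,
                 species: str | None = None):
        if species is not None:
            trees = trees[trees["species"] == species]
            counts = counts[counts["species"] == species]
        elif trees["species"].nunique() != 1:
            raise ValueError("pass species= when tables contain several species")
        self.species = trees["species"].iloc[0] if len(trees) else species
        trees = trees.sort_values(["plot_id", "tree_id"], kind="mergesort").reset_index(drop=True)
        plots = list(pd.unique(trees["plot_id"]))
        traps = traps[traps["plot_id"].isin(plots)]
        traps = traps.sort_values(["plot_id", "trap_id"], kind="mergesort").reset_index(drop=True)
        self.trees, self.traps = trees, traps
        self.plots = plots
        plot_idx = {p: i for i, p in enumerate(plots)}
        self.tree_plot = trees["plot_id"].map(plot_idx).to_numpy(np.int64)
        self.trap_plot = traps["plot_id"].map(plot_idx).to_numpy(np.int64)
        # traps grouped by plot -> pointer array used by the numba sweeps
        order = np.argsort(self.trap_plot, kind="stable")
        self.traps = traps.iloc[order].reset_index(drop=True)
        self.trap_plot = self.trap_plot[order]
        self.trap_ptr = np.searchsorted(self.trap_plot, np.arange(len(plots) + 1))

        plot_regime = trees.drop_duplicates("plot_id").set_index("plot_id")["regime"]
        from .io import REGIMES
        self.regimes = [r for r in REGIMES if r in set(plot_regime)]
        reg_idx = {r: g for g, r in enumerate(self.regimes)}
        self.plot_regime = np.array([reg_idx[plot_regime[p]] for p in plots])
        self.tree_regime = self.plot_regime[self.tree_plot]
        self.trap_regime = self.plot_regime[self.trap_plot]

        self.years = np.array(sorted(counts["year"].unique()))
        if self.years.size == 0:
            raise UnidentifiableError(f"no seed-count records for species {self.species!r}")
        key = pd.MultiIndex.from_arrays([self.traps["plot_id"], self.traps["trap_id"]])
        pivot = counts.pivot_table(index=["plot_id", "trap_id"], columns="year",
                                   values="count", aggfunc="sum", fill_value=0)
        pivot = pivot.reindex(index=key, columns=self.years, fill_value=0).fillna(0)
        self.y = pivot.to_numpy(dtype=np.float64)
        if self.y.sum() <= 0:
            raise UnidentifiableError(
                f"species {self.species!r} has no positive trap count; "
                "its fecundity and dispersal are unidentifiable"
            )
        self.A = (self.traps["area_m2"] * self.traps["season_fraction"]).to_numpy(
            dtype=np.float64)
        if "effort_A" in counts.columns:
            eff = counts.drop_duplicates(["plot_id", "trap_id"]).set_index(
                ["plot_id", "trap_id"])["effort_A"].reindex(key).to_numpy(np.float64)
            self.A = np.where(np.isnan(eff), self.A, eff)
        if np.any(~(self.A > 0)):
            raise UnidentifiableError("non-positive sampling effort A")

        txy = trees[["x_m", "y_m"]].to_numpy(dtype=np.float64)
        sxy = self.traps[["x_m", "y_m"]].to_numpy(dtype=np.float64)
        diff = sxy[:, None, :] - txy[None, :, :]
        dist = np.hypot(diff[..., 0], diff[..., 1])
        cross = self.trap_plot[:, None] != self.tree_plot[None, :]
        self.dist = np.where(cross, np.inf, dist)

        self.center_log_dbh = float(np.log(trees["dbh_cm"]).mean())
        self.X = design_matrix(trees, center_log_dbh=self.center_log_dbh)
        self.dbh = trees["dbh_cm"].to_numpy(dtype=np.float64)

    @property
    def n_trees(self):
        return len(self.trees)

    @property
    def n_traps(self):
        return len(self.traps)

    @property
    def n_years(self):
        return len(self.years)


@njit(cache=True)
def _psi_sweep(log_psi, rho, f, lam, S, y, A, eta, sigma_e2, trap_ptr, tree_plot,
               step, z, logu):
    n, T = log_psi.shape
    acc = 0
    for i in range(n):
        s0 = trap_ptr[tree_plot[i]]
        s1 = trap_ptr[tree_plot[i] + 1]
        for t in range(T):
            cur = log_psi[i, t]
            prop = cur + step * z[i, t]
            dlp = -0.5 * ((prop - eta[i, t]) ** 2 - (cur - eta[i, t]) ** 2) / sigma_e2
            dll = 0.0
            if rho[i] == 1:
                df = np.exp(prop) - f[i, t]
                for s in range(s0, s1):
                    lo = lam[s, t]
                    ln = lo + S[s, i] * df
                    if ln < 1e-300:
                        ln = 1e-300
                    if lo < 1e-300:
                        lo = 1e-300
                    dll += y[s, t] * (np.log(ln) - np.log(lo)) - A[s] * (ln - lo)
            if logu[i, t] < dll + dlp:
                if rho[i] == 1:
                    df = np.exp(prop) - f[i, t]
                    for s in range(s0, s1):
                        lam[s, t] += S[s, i] * df
                    f[i, t] = np.exp(prop)
                log_psi[i, t] = prop
                acc += 1
    return acc


@njit(cache=True)
def _rho_sweep(log_psi, rho, f, lam, S, y, A, p_mat, forced, trap_ptr, tree_plot, uu):
    n, T = log_psi.shape
    for i in range(n):
        if forced[i] == 1:
            continue
        s0 = trap_ptr[tree_plot[i]]
        s1 = trap_ptr[tree_plot[i] + 1]
        ll1m0 = 0.0
        for t in range(T):
            fi = np.exp(log_psi[i, t])
            for s in range(s0, s1):
                base = lam[s, t] - f[i, t] * S[s, i]
                if base < 0.0:
                    base = 0.0
                l1 = base + fi * S[s, i]
                l0 = base
                if l1 < 1e-300:
                    l1 = 1e-300
                if l0 < 1e-300:
                    l0 = 1e-300
                ll1m0 += y[s, t] * (np.log(l1) - np.log(l0)) - A[s] * (l1 - l0)
        p = p_mat[i]
        if p < 1e-12:
            p = 1e-12
        if p > 1.0 - 1e-12:
            p = 1.0 - 1e-12
        logit = np.log(p / (1.0 - p)) + ll1m0
        if logit > 35.0:
            p1 = 1.0
        elif logit < -35.0:
            p1 = 0.0
        else:
            p1 = 1.0 / (1.0 + np.exp(-logit))
        new = 1 if uu[i] < p1 else 0
        if new != rho[i]:
            for t in range(T):
                fnew = np.exp(log_psi[i, t]) if new == 1 else 0.0
                df = fnew - f[i, t]
                for s in range(s0, s1):
                    lam[s, t] += S[s, i] * df
                f[i, t] = fnew
            rho[i] = new


@dataclass
class PosteriorSamples:
    """Retained draws plus running posterior-mean summaries of latents."""

    species: str
    regimes: list
    years: np.ndarray
    beta_names: tuple
    u: np.ndarray            # (n_draws, n_regimes)
    beta: np.ndarray         # (n_draws, p)
    sigma_a2: np.ndarray
    sigma_g2: np.ndarray
    sigma_e2: np.ndarray
    deviance: np.ndarray
    mean_rho: np.ndarray
    mean_f: np.ndarray
    mean_lambda: np.ndarray
    acceptance: dict
    center_log_dbh: float
    config: SamplerConfig = field(repr=False, default=None)

    @property
    def n_draws(self):
        return self.u.shape[0]

    def scalar_draws(self) -> dict:
        out = {f"u[{r}]": self.u[:, g] for g, r in enumerate(self.regimes)}
        for j, name in enumerate(self.beta_names):
            out[f"beta[{name}]"] = self.beta[:, j]
        out["sigma_a2"] = self.sigma_a2
        out["sigma_g2"] = self.sigma_g2
        out["sigma_e2"] = self.sigma_e2
        return out

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for name, arr in self.scalar_draws().items():
            rows.append(pd.DataFrame({
                "iteration": np.arange(arr.size), "parameter": name, "value": arr}))
        return pd.concat(rows, ignore_index=True)

    def save(self, out_dir):
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.to_dataframe().to_csv(out_dir / "posterior_samples.csv", index=False)
        with open(out_dir / "acceptance.json", "w") as fh:
            json.dump(self.acceptance, fh, indent=1)


def _initial_state(data: SpeciesData, prior: PriorSpec, maturation: MaturationModel):
    n, T = data.n_trees, data.n_years
    rho = (data.dbh >= np.median(data.dbh)).astype(np.int8)
    # a plot with seeds needs at least one mature tree; the largest qualifies
    plot_pos = np.zeros(len(data.plots), dtype=bool)
    for p in range(len(data.plots)):
        s0, s1 = data.trap_ptr[p], data.trap_ptr[p + 1]
        plot_pos[p] = data.y[s0:s1].sum() > 0
        if plot_pos[p]:
            members = np.where(data.tree_plot == p)[0]
            if members.size == 0:
                raise InitializationError(
                    f"plot {data.plots[p]!r} has seeds but no censused conspecific tree")
            if rho[members].sum() == 0:
                rho[members[np.argmax(data.dbh[members])]] = 1
    # trees that are the sole conspecific in a plot with seeds are known mature
    forced = np.zeros(n, dtype=np.int8)
    for p in np.where(plot_pos)[0]:
        members = np.where(data.tree_plot == p)[0]
        if members.size == 1:
            forced[members[0]] = 1
            rho[members[0]] = 1

    u0 = u_from_mean(25.0)
    S = kernel_density(data.dist, u0)
    # method-of-moments psi: attribute each plot-year total to its mature
    # trees proportional to basal area (the standard fecundity allometry),
    # solving sum_s A_s sum_i S_si f_i = total for the shared scale
    log_psi = np.empty((n, T))
    for p in range(len(data.plots)):
        s0, s1 = data.trap_ptr[p], data.trap_ptr[p + 1]
        members = np.where(data.tree_plot == p)[0]
        mature = members[rho[members] == 1]
        w = data.dbh[members] ** 2
        exposure = data.A[s0:s1] @ S[s0:s1][:, members]   # per-tree trap mass
        w_mat = w * (rho[members] == 1)
        for t in range(T):
            denom = float(w_mat @ exposure)
            total = data.y[s0:s1, t].sum()
            scale = total / denom if denom > 0 else 1.0 / max(float(w.mean()), 1.0)
            log_psi[members, t] = np.log(np.clip(scale * w, 1e-3, 1e6))
    # deterministic least-squares guess for beta from the moment-matched psi
    vbar = log_psi.mean(axis=1)
    beta, *_ = np.linalg.lstsq(data.X, vbar, rcond=None)
    return rho, forced, log_psi, beta


def run_chain(data: SpeciesData, config: SamplerConfig | None = None,
              prior: PriorSpec | None = None,
              maturation: MaturationModel | None = None,
              init: dict | None = None) -> PosteriorSamples:
    """Run one Metropolis-within-Gibbs chain and return retained draws.

    ``init`` overrides any subset of the deterministic initial state
    (keys: u, beta, log_psi, rho, a, gamma, sigma_a2, sigma_g2, sigma_e2);
    combined with the ``update_*`` flags in :class:`SamplerConfig` this also
    supports reduced problems where some blocks are held fixed.
    """
    cfg = config or SamplerConfig()
    prior = prior or PriorSpec()
    maturation = maturation or MaturationModel()
    rng = np.random.default_rng(cfg.rng_seed)
    n, T, G = data.n_trees, data.n_years, len(data.regimes)
    p = data.X.shape[1]

    rho, forced, log_psi, beta = _initial_state(data, prior, maturation)
    u = np.full(G, np.clip(u_from_mean(25.0), prior.u_min, prior.u_max))
    a = np.zeros(n)
    gamma = np.zeros((T, G))
    sigma_a2 = sigma_g2 = sigma_e2 = prior.ig_scale
    init = init or {}
    if "u" in init:
        u = np.broadcast_to(np.asarray(init["u"], dtype=float), (G,)).copy()
    if "beta" in init:
        beta = np.asarray(init["beta"], dtype=float).copy()
    if "log_psi" in init:
        log_psi = np.broadcast_to(np.asarray(init["log_psi"], dtype=float), (n, T)).copy()
    if "rho" in init:
        rho = np.broadcast_to(np.asarray(init["rho"], dtype=np.int8), (n,)).copy()
    if "a" in init:
        a = np.asarray(init["a"], dtype=float).copy()
    if "gamma" in init:
        gamma = np.broadcast_to(np.asarray(init["gamma"], dtype=float), (T, G)).copy()
    sigma_a2 = float(init.get("sigma_a2", sigma_a2))
    sigma_g2 = float(init.get("sigma_g2", sigma_g2))
    sigma_e2 = float(init.get("sigma_e2", sigma_e2))

    u_tree = u[data.tree_regime]
    S = kernel_density(data.dist, u_tree[None, :])
    f = rho.astype(float)[:, None] * np.exp(log_psi)
    lam = S @ f
    eta = (data.X @ beta + a)[:, None] + gamma[:, data.tree_regime].T
    p_mat = maturation_probability(data.dbh, maturation)

    ll0 = log_likelihood(data.y, data.A[:, None], lam)
    if not np.isfinite(ll0):
        raise InitializationError("non-finite log-posterior at the initial state")

    n_ret = (cfg.n_iter - cfg.burn_in) // cfg.thin
    out_u = np.empty((n_ret, G))
    out_beta = np.empty((n_ret, p))
    out_s = np.empty((n_ret, 3))
    out_dev = np.empty(n_ret)
    mean_rho = np.zeros(n)
    mean_f = np.zeros((n, T))
    mean_lam = np.zeros((data.n_traps, T))

    step_psi = cfg.step_log_psi
    step_u = np.full(G, cfg.step_log_u)
    step_ridge = np.full(p, cfg.step_ridge)
    acc_psi = tot_psi = 0
    acc_u = np.zeros(G)
    tot_u = np.zeros(G)
    acc_ridge = np.zeros(p)
    tot_ridge = np.zeros(p)
    win_acc_psi = win_tot_psi = 0
    win_acc_u = np.zeros(G)
    win_tot_u = np.zeros(G)
    win_acc_ridge = np.zeros(p)
    loggam_const = float(np.sum(gammaln(data.y + 1.0)))
    ypos = data.y > 0
    ig_a, ig_b = prior.ig_shape, prior.ig_scale
    tau2 = prior.beta_sd ** 2
    XtX = data.X.T @ data.X
    regime_members = [np.where(data.tree_regime == g)[0] for g in range(G)]
    regime_traps = [np.where(data.trap_regime == g)[0] for g in range(G)]
    kept = 0

    for it in range(cfg.n_iter):
        if cfg.update_psi:
            for _ in range(cfg.latent_sweeps):
                z = rng.standard_normal((n, T))
                lu = np.log(rng.uniform(size=(n, T)))
                acc = _psi_sweep(log_psi, rho, f, lam, S, data.y, data.A, eta,
                                 sigma_e2, data.trap_ptr, data.tree_plot,
                                 step_psi, z, lu)
                acc_psi += acc
                tot_psi += n * T
                win_acc_psi += acc
                win_tot_psi += n * T
        if cfg.update_rho:
            _rho_sweep(log_psi, rho, f, lam, S, data.y, data.A, p_mat, forced,
                       data.trap_ptr, data.tree_plot, rng.uniform(size=n))
        if cfg.update_beta:
            v = log_psi - a[:, None] - gamma[:, data.tree_regime].T
            prec = (T / sigma_e2) * XtX + np.eye(p) / tau2
            rhs = data.X.T @ v.sum(axis=1) / sigma_e2
            L = np.linalg.cholesky(prec)
            mean = np.linalg.solve(prec, rhs)
            beta = mean + np.linalg.solve(L.T, rng.standard_normal(p))
        if cfg.update_effects:
            base = data.X @ beta
            r = log_psi - base[:, None] - gamma[:, data.tree_regime].T
            prec_a = T / sigma_e2 + 1.0 / sigma_a2
            a = r.sum(axis=1) / sigma_e2 / prec_a + rng.standard_normal(n) / np.sqrt(prec_a)
            r2 = log_psi - (base + a)[:, None]
            for g in range(G):
                members = regime_members[g]
                if members.size == 0:
                    gamma[:, g] = rng.standard_normal(T) * np.sqrt(sigma_g2)
                    continue
                prec_g = members.size / sigma_e2 + 1.0 / sigma_g2
                mg = r2[members].sum(axis=0) / sigma_e2 / prec_g
                gamma[:, g] = mg + rng.standard_normal(T) / np.sqrt(prec_g)
        if cfg.update_sigmas:
            sse = float(np.sum((log_psi - (data.X @ beta + a)[:, None]
                                - gamma[:, data.tree_regime].T) ** 2))
            sigma_e2 = 1.0 / rng.gamma(ig_a + 0.5 * n * T, 1.0 / (ig_b + 0.5 * sse))
            sigma_a2 = 1.0 / rng.gamma(ig_a + 0.5 * n, 1.0 / (ig_b + 0.5 * float(a @ a)))
            sigma_g2 = 1.0 / rng.gamma(ig_a + 0.5 * T * G,
                                       1.0 / (ig_b + 0.5 * float(np.sum(gamma ** 2))))
        if cfg.update_beta:
            # joint translation moves: beta_j -> beta_j + delta with
            # log psi -> log psi + delta * X[:, j]; the psi-layer residuals are
            # invariant, so only the Poisson likelihood and the beta prior enter
            for j in range(p):
                tot_ridge[j] += 1
                delta = step_ridge[j] * rng.standard_normal()
                logacc = np.log(rng.uniform())
                shift = delta * data.X[:, j]
                f_new = f * np.exp(shift)[:, None]
                lam_new = S @ f_new
                ln = np.clip(lam_new, 1e-300, None)
                lo = np.clip(lam, 1e-300, None)
                dll = float(np.sum(data.y * (np.log(ln) - np.log(lo))
                                   - data.A[:, None] * (lam_new - lam)))
                dlp = -0.5 * ((beta[j] + delta) ** 2 - beta[j] ** 2) / tau2
                if logacc < dll + dlp:
                    beta[j] += delta
                    log_psi += shift[:, None]
                    f = f_new
                    lam = lam_new
                    acc_ridge[j] += 1
                    win_acc_ridge[j] += 1
        eta = (data.X @ beta + a)[:, None] + gamma[:, data.tree_regime].T
        if cfg.update_u:
            for g in range(G):
                tot_u[g] += 1
                win_tot_u[g] += 1
                lognew = np.log(u[g]) + step_u[g] * rng.standard_normal()
                unew = np.exp(lognew)
                logacc_u = np.log(rng.uniform())
                if not (prior.u_min <= unew <= prior.u_max):
                    continue
                rows = regime_traps[g]
                cols = regime_members[g]
                if rows.size == 0:
                    u[g] = unew
                    continue
                Sb = kernel_density(data.dist[np.ix_(rows, cols)], unew)
                lam_new = Sb @ f[cols]
                lo = np.clip(lam[rows], 1e-300, None)
                ln = np.clip(lam_new, 1e-300, None)
                yb = data.y[rows]
                dll = float(np.sum(yb * (np.log(ln) - np.log(lo))
                                   - data.A[rows][:, None] * (lam_new - lam[rows])))
                if logacc_u < dll + (lognew - np.log(u[g])):
                    u[g] = unew
                    S[np.ix_(rows, cols)] = Sb
                    lam[rows] = lam_new
                    acc_u[g] += 1
                    win_acc_u[g] += 1
        if (it + 1) % 200 == 0:
            lam = S @ f   # kill accumulated drift from incremental updates
        if it < cfg.burn_in and (it + 1) % cfg.adapt_window == 0:
            if win_tot_psi:
                rate = win_acc_psi / win_tot_psi
                step_psi *= np.exp(0.66 * (rate - cfg.adapt_target))
                win_acc_psi = win_tot_psi = 0
            for g in range(G):
                if win_tot_u[g]:
                    rate = win_acc_u[g] / win_tot_u[g]
                    step_u[g] *= np.exp(0.66 * (rate - cfg.adapt_target))
            win_acc_u[:] = 0
            win_tot_u[:] = 0
            if cfg.update_beta:
                rate = win_acc_ridge / cfg.adapt_window
                step_ridge *= np.exp(0.66 * (rate - cfg.adapt_target))
                win_acc_ridge[:] = 0
        if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0 and kept < n_ret:
            out_u[kept] = u
            out_beta[kept] = beta
            out_s[kept] = (sigma_a2, sigma_g2, sigma_e2)
            mu = data.A[:, None] * np.clip(lam, 1e-300, None)
            dev = -2.0 * (float(np.sum(data.y[ypos] * np.log(mu[ypos])))
                          - float(np.sum(mu)) - loggam_const)
            out_dev[kept] = dev
            mean_rho += rho
            mean_f += f
            mean_lam += lam
            kept += 1

    acceptance = {
        "psi": acc_psi / tot_psi if tot_psi else None,
        "u": {r: (acc_u[g] / tot_u[g] if tot_u[g] else None)
              for g, r in enumerate(data.regimes)},
        "ridge": {name: (acc_ridge[j] / tot_ridge[j] if tot_ridge[j] else None)
                  for j, name in enumerate(FIXED_EFFECT_NAMES[:p])},
        "step_psi_final": float(step_psi),
        "step_u_final": [float(s) for s in step_u],
    }
    return PosteriorSamples(
        species=data.species, regimes=list(data.regimes), years=data.years,
        beta_names=FIXED_EFFECT_NAMES, u=out_u[:kept], beta=out_beta[:kept],
        sigma_a2=out_s[:kept, 0], sigma_g2=out_s[:kept, 1], sigma_e2=out_s[:kept, 2],
        deviance=out_dev[:kept], mean_rho=mean_rho / max(kept, 1),
        mean_f=mean_f / max(kept, 1), mean_lambda=mean_lam / max(kept, 1),
        acceptance=acceptance, center_log_dbh=data.center_log_dbh, config=cfg,
    )


def fit_species(trees, traps, counts, species=None, config=None, prior=None,
                maturation=None) -> PosteriorSamples:
    """Assemble one species' data and run the sampler (convenience wrapper)."""
    data = SpeciesData(trees, traps, counts, species=species)
    return run_chain(data, config=config, prior=prior, maturation=maturation)


def from_analysis_config(cfg) -> tuple[SamplerConfig, PriorSpec, MaturationModel]:
    """Expand an :class:`seedshadow.io.AnalysisConfig` into sampler, prior and
    maturation settings."""
    sampler = SamplerConfig(
        n_iter=cfg.n_iter, burn_in=cfg.burn_in, thin=cfg.thin,
        rng_seed=cfg.rng_seed, step_log_psi=cfg.proposal_scale_log_psi,
        step_log_u=cfg.proposal_scale_log_u)
    prior = PriorSpec(u_min=cfg.u_min, u_max=cfg.u_max,
                      ig_shape=cfg.ig_shape, ig_scale=cfg.ig_scale)
    maturation = MaturationModel(mu_log_cm=cfg.maturation_mu_log_cm,
                                 sigma_log=cfg.maturation_sigma_log)
    return sampler, prior, maturation


def rmspe(y, predicted) -> float:
    """Root mean squared prediction error between observed and predicted counts."""
    y = np.asarray(y, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    return float(np.sqrt(np.mean((y - predicted) ** 2)))


def fit_metrics(samples: PosteriorSamples, data: SpeciesData) -> dict:
    """DIC (mean deviance + p_D) and RMSPE at the posterior-mean intensity."""
    if samples.n_draws < 100:
        raise DiagnosticError("need at least 100 retained draws for fit metrics")
    mean_dev = float(samples.deviance.mean())
    dev_hat = -2.0 * log_likelihood(data.y, data.A[:, None], samples.mean_lambda)
    p_d = mean_dev - dev_hat
    pred = data.A[:, None] * samples.mean_lambda
    return {"DIC": mean_dev + p_d, "p_D": p_d, "mean_deviance": mean_dev,
            "RMSPE": rmspe(data.y, pred)}


def convergence_summary(draws, rhat_threshold: float = 1.1) -> pd.DataFrame:
    """Split-chain R-hat and effective sample size per scalar parameter.

    ``draws`` is a PosteriorSamples, or a mapping name -> array of shape
    (n_draws,) (a single chain, split in half) or (n_chains, n_draws).
    Constant chains get ESS 0 and a flag rather than an exception.
    """
    import arviz as az

    if isinstance(draws, PosteriorSamples):
        draws = draws.scalar_draws()
    rows = []
    for name, arr in draws.items():
        arr = np.asarray(arr, dtype=float)
        if arr.ndim == 1:
            if arr.size < 8:
                raise DiagnosticError(f"too few draws for diagnostics on {name!r}")
            half = arr.size // 2
            arr = np.stack([arr[:half], arr[half:2 * half]])
        if arr.shape[1] < 4:
            raise DiagnosticError(f"too few draws for diagnostics on {name!r}")
        if np.allclose(arr, arr.flat[0]):
            rows.append((name, np.nan, 0.0, True))
            continue
        with np.errstate(all="ignore"):
            r = float(np.ravel(az.rhat(az.convert_to_dataset(arr[..., None]))["x"].values)[0])
            e = float(np.ravel(az.ess(az.convert_to_dataset(arr[..., None]))["x"].values)[0])
        rows.append((name, r, e, bool(np.isnan(r) or r > rhat_threshold)))
    return pd.DataFrame(rows, columns=["parameter", "rhat", "ess", "flagged"])
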