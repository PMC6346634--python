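"""Synthetic stands, trap layouts and seed rain with known ground truth.

The generator emulates the field design the analysis assumes: 1-ha square
plots censused down to 10 cm DBH at a median density of 155 stems/ha, 21
one-m^2 traps on three transects (all >=20 m from any border), three years of
counts, and three disturbance regimes.  Counts are drawn from the package's
own data-generating model (conditionally Poisson, marginally overdispersed
through individual random effects and regime-coherent year effects), and the
full latent state is returned so parameter-recovery tests can score coverage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as ssio
from .errors import GeometryError
from .kernel import shadow_matrix, u_from_mean
from .model import MaturationModel, design_matrix, maturation_probability, trap_intensity

__all__ = [
    "StandConfig",
    "GroundTruth",
    "generate_stand",
    "layout_traps",
    "simulate_seed_rain",
    "simulate_dataset",
    "make_fixture_suite",
]

REGIME_INDEX = {r: g for g, r in enumerate(ssio.REGIMES)}


@dataclass
class StandConfig:
    """One plot's geometry and stem population."""

    plot_id: str = "P1"
    regime: str = "protected"
    plot_side_m: float = 100.0
    stem_density_per_ha: float = 155.0
    dbh_meanlog: float = float(np.log(20.0))   # lognormal DBH, cm
    dbh_sdlog: float = 0.6
    dbh_min_cm: float = 10.0
    species: str = "Synthetica exemplaris"


@dataclass
class GroundTruth:
    """True model parameters (and, after simulation, latent states)."""

    u: dict = field(default_factory=lambda: {r: u_from_mean(30.0) for r in ssio.REGIMES})
    beta: np.ndarray = field(default_factory=lambda: np.array([-0.7, 2.0, 0.0, 0.0]))
    sigma_a2: float = 0.3 ** 2
    sigma_g2: float = 0.3 ** 2
    sigma_e2: float = 0.2 ** 2
    maturation: MaturationModel = field(default_factory=MaturationModel)
    # filled in by generate_stand / simulate_seed_rain, aligned with tree rows
    a: np.ndarray | None = None
    rho: np.ndarray | None = None
    gamma: dict | None = None          # (year, regime) -> effect
    psi: np.ndarray | None = None      # (n_trees, n_years)
    f: np.ndarray | None = None

    def to_jsonable(self) -> dict:
        out = {
            "u": {k: float(v) for k, v in self.u.items()},
            "beta": [float(b) for b in self.beta],
            "sigma_a2": self.sigma_a2,
            "sigma_g2": self.sigma_g2,
            "sigma_e2": self.sigma_e2,
            "maturation": {"mu_log_cm": self.maturation.mu_log_cm,
                           "sigma_log": self.maturation.sigma_log},
        }
        if self.a is not None:
            out["a"] = [float(v) for v in self.a]
            out["rho"] = [int(v) for v in self.rho]
        if self.gamma is not None:
            out["gamma"] = {f"{t}:{g}": float(v) for (t, g), v in self.gamma.items()}
        if self.psi is not None:
            out["psi"] = np.asarray(self.psi).tolist()
            out["f"] = np.asarray(self.f).tolist()
        return out


def _truncated_lognormal(meanlog, sdlog, lo, size, rng):
    # rejection sampling; acceptance is ~80% at the defaults
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.lognormal(meanlog, sdlog, size=2 * (size - filled) + 8)
        draw = draw[draw >= lo]
        take = min(draw.size, size - filled)
        out[filled:filled + take] = draw[:take]
        filled += take
    return out


def generate_stand(cfg: StandConfig, rng: np.random.Generator,
                   truth: GroundTruth | None = None) -> tuple[pd.DataFrame, dict]:
    """Homogeneous-Poisson stand: N ~ Poisson(density x area), uniform
    locations, truncated-lognormal DBH.  Returns the census table and the
    per-tree latent truth (random effect a_i, maturation rho_i)."""
    truth = truth or GroundTruth()
    area_ha = (cfg.plot_side_m / 100.0) ** 2
    n = rng.poisson(cfg.stem_density_per_ha * area_ha)
    xy = rng.uniform(0.0, cfg.plot_side_m, size=(n, 2))
    dbh = _truncated_lognormal(cfg.dbh_meanlog, cfg.dbh_sdlog, cfg.dbh_min_cm, n, rng)
    trees = pd.DataFrame({
        "plot_id": cfg.plot_id,
        "tree_id": [f"{cfg.plot_id}-T{i + 1:03d}" for i in range(n)],
        "species": cfg.species,
        "x_m": xy[:, 0],
        "y_m": xy[:, 1],
        "dbh_cm": dbh,
        "regime": cfg.regime,
    })
    a = rng.normal(0.0, np.sqrt(truth.sigma_a2), size=n)
    p_mat = maturation_probability(dbh, truth.maturation)
    rho = (rng.uniform(size=n) < p_mat).astype(np.int8)
    return trees, {"a": a, "rho": rho}


def layout_traps(plot_side_m: float = 100.0, plot_id: str = "P1") -> pd.DataFrame:
    """Three transects at x = 25, 50, 75 m; seven 1-m^2 traps per transect at
    y = 20, 30, ..., 80 m; every trap >= 20 m from all borders."""
    if plot_side_m < 40.0:
        raise GeometryError(
            f"plot side {plot_side_m} m cannot keep traps 20 m from all borders"
        )
    xs = np.array([0.25, 0.50, 0.75]) * plot_side_m
    y0, y1 = 20.0, plot_side_m - 20.0
    ys = np.arange(y0, y1 + 1e-9, 10.0)
    rows = []
    k = 0
    for x in xs:
        for y in ys:
            k += 1
            rows.append((plot_id, f"{plot_id}-S{k:02d}", x, y, 1.0, 1.0))
    return pd.DataFrame(rows, columns=ssio.TRAP_COLUMNS)


def simulate_seed_rain(trees: pd.DataFrame, traps: pd.DataFrame, truth: GroundTruth,
                       years, rng: np.random.Generator,
                       stand_truth: dict | None = None) -> tuple[pd.DataFrame, GroundTruth]:
    """Forward-simulate trap counts y ~ Poisson(A * lambda) for each year.

    Year effects gamma_tg are drawn per (year, regime); latent fecundity
    f_it = rho_i * exp(X beta + a_i + gamma_tg + eps_it).  Returns the count
    table (all trap x year cells, zeros included) and a GroundTruth carrying
    every latent draw.
    """
    years = list(years)
    n = len(trees)
    if stand_truth is None:
        stand_truth = {
            "a": rng.normal(0.0, np.sqrt(truth.sigma_a2), size=n),
            "rho": (rng.uniform(size=n)
                    < maturation_probability(trees["dbh_cm"], truth.maturation)).astype(np.int8),
        }
    a, rho = np.asarray(stand_truth["a"]), np.asarray(stand_truth["rho"])
    X = design_matrix(trees)
    eta0 = X @ truth.beta + a

    plot_regime = trees.drop_duplicates("plot_id").set_index("plot_id")["regime"]
    regimes_present = sorted(set(plot_regime), key=REGIME_INDEX.get)
    gamma = {(t, g): rng.normal(0.0, np.sqrt(truth.sigma_g2))
             for t in years for g in regimes_present}

    tree_regime = np.asarray(trees["regime"])
    u_tree = np.array([truth.u[g] for g in tree_regime])
    plot_codes = {p: i for i, p in enumerate(pd.unique(trees["plot_id"]))}
    S = shadow_matrix(
        trees[["x_m", "y_m"]].to_numpy(), traps[["x_m", "y_m"]].to_numpy(), u_tree,
        tree_plot=trees["plot_id"].map(plot_codes).to_numpy(),
        trap_plot=traps["plot_id"].map(plot_codes).fillna(-1).astype(int).to_numpy(),
    )
    A = (traps["area_m2"] * traps["season_fraction"]).to_numpy()

    psi = np.empty((n, len(years)))
    f = np.empty_like(psi)
    recs = []
    for j, t in enumerate(years):
        g_t = np.array([gamma[(t, g)] for g in tree_regime])
        eps = rng.normal(0.0, np.sqrt(truth.sigma_e2), size=n)
        psi[:, j] = np.exp(eta0 + g_t + eps)
        f[:, j] = rho * psi[:, j]
        lam = trap_intensity(S, f[:, j])
        y = rng.poisson(A * lam)
        for (trap, count) in zip(traps.itertuples(), y):
            recs.append((trap.plot_id, trap.trap_id, trees["species"].iloc[0] if n else "none",
                         t, int(count)))
    counts = pd.DataFrame(recs, columns=ssio.COUNT_COLUMNS)
    out = GroundTruth(u=truth.u, beta=truth.beta, sigma_a2=truth.sigma_a2,
                      sigma_g2=truth.sigma_g2, sigma_e2=truth.sigma_e2,
                      maturation=truth.maturation, a=a, rho=rho, gamma=gamma,
                      psi=psi, f=f)
    return counts, out


def simulate_dataset(seed: int, truth: GroundTruth | None = None,
                     n_plots_per_regime: int = 2, years=(1, 2, 3),
                     regimes=ssio.REGIMES, stand_cfg: StandConfig | None = None):
    """Full multi-plot study: stands, traps and seed rain for every regime.

    Returns (trees, traps, counts, traits, truth).  Defaults follow the study
    conditions the generator emulates: 2 plots per regime, 3 years.
    """
    rng = np.random.default_rng(seed)
    base = stand_cfg or StandConfig()
    all_trees, all_traps = [], []
    stand_a, stand_rho = [], []
    truth = truth or GroundTruth()
    for regime in regimes:
        for k in range(n_plots_per_regime):
            cfg = StandConfig(
                plot_id=f"{regime[:4].upper()}{k + 1}", regime=regime,
                plot_side_m=base.plot_side_m,
                stem_density_per_ha=base.stem_density_per_ha,
                dbh_meanlog=base.dbh_meanlog, dbh_sdlog=base.dbh_sdlog,
                dbh_min_cm=base.dbh_min_cm, species=base.species,
            )
            trees, st = generate_stand(cfg, rng, truth)
            all_trees.append(trees)
            all_traps.append(layout_traps(cfg.plot_side_m, cfg.plot_id))
            stand_a.append(st["a"])
            stand_rho.append(st["rho"])
    trees = pd.concat(all_trees, ignore_index=True)
    traps = pd.concat(all_traps, ignore_index=True)
    stand_truth = {"a": np.concatenate(stand_a), "rho": np.concatenate(stand_rho)}
    counts, full_truth = simulate_seed_rain(trees, traps, truth, years, rng, stand_truth)
    traits = pd.DataFrame({"species": [base.species], "vector": ["animal"]})
    return trees, traps, counts, traits, full_truth


def make_fixture_suite(out_dir, seed: int = 1) -> dict:
    """Write a small (1 plot, 1 species) and a full (3 regimes x 2 plots)
    dataset in the package's CSV schemas, plus the ground truth as JSON."""
    out_dir = Path(out_dir)
    written = {}
    specs = {
        "small": dict(n_plots_per_regime=1, regimes=("protected",)),
        "full": dict(n_plots_per_regime=2, regimes=ssio.REGIMES),
    }
    for name, kw in specs.items():
        d = out_dir / name
        d.mkdir(parents=True, exist_ok=True)
        trees, traps, counts, traits, truth = simulate_dataset(seed=seed, **kw)
        ssio.write_table(trees, d / "trees.csv")
        ssio.write_table(traps, d / "traps.csv")
        ssio.write_table(counts, d / "seed_counts.csv")
        ssio.write_table(traits, d / "traits.csv")
        with open(d / "truth.json", "w") as fh:
            json.dump(truth.to_jsonable(), fh, indent=1)
        written[name] = d
    return written
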