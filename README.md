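# seedshadow

Hierarchical Bayesian inverse modelling of seed dispersal and tree fecundity
from mapped forest stands and seed-trap counts.

## The problem

In a mapped stand, every censused tree is a potential seed source and every
seed trap a detector.  Observed trap counts mix two confounded processes —
how many seeds each tree produces (fecundity) and how far they travel
(dispersal).  `seedshadow` fits both jointly from tree censuses, trap
locations and per-trap seed counts, the design used to ask how disturbances
such as selective logging and hunting reshape dispersal and fecundity in
tropical forests: 1-ha plots under protected, logged, and hunted+logged
regimes, ~155 mapped stems ≥ 10 cm DBH per plot, 21 one-m² traps on three
transects, multi-year counts.

## The model

Counts are conditionally Poisson,

    y_s ~ Poisson(A λ_s),    λ_s = Σ_i S_si f_i,

where `A` is sampling effort (trap area × fraction of the fruiting season,
m² yr), `S_si` the 2Dt dispersal kernel evaluated at the tree–trap distance,

    S(r; u) = 1 / (π u (1 + r²/u)²),   mean dispersal distance (π/2)√u,

with a single per-species × regime scale `u` (no shape parameter), and
`f_it = ρ_it ψ_it` the fecundity of tree `i` in year `t`: a latent
maturation status `ρ ∈ {0,1}` (probit in log DBH) times conditional
fecundity `ψ > 0` with

    log ψ_it = β₀ + β_D log DBH_i + β_L [logged] + β_HL [hunted+logged]
               + a_i + γ_tg + ε_it,

individual random effects `a_i ~ N(0, σ_a²)`, year effects `γ_tg` shared
within a disturbance regime, and tree-year residuals `ε`.  The random layers
make marginal counts overdispersed while the observation layer stays
Poisson.  Inference is Metropolis-within-Gibbs: random-walk updates for the
latent `ψ` field and each regime's `u` (flat prior on `u`), Bernoulli full
conditionals for `ρ`, conjugate Gaussian/inverse-gamma draws for effects and
variances, plus joint β/ψ translation moves along the fecundity–dispersal
ridge.  Dispersal is reported as the posterior mean and 95% credible
interval of the kernel's mean distance; disturbance effects are classified
by credible-interval overlap against the protected regime.

## Worked example

`examples/simulate_and_fit.py` simulates the default study design (three
regimes × two 1-ha stands, 3 years, truth: mean dispersal 30 m in every
regime, diameter elasticity β_D = 2.0) and refits it:

```
simulated 997 trees, 126 traps, 2503 seeds over 3 years; validation errors: 0

mean dispersal distance by regime:
  protected       35.9 m [26.5, 49.0]  (truth 30.0 m)
  logged          30.1 m [23.7, 38.7]  (truth 30.0 m)
  hunted_logged   53.0 m [22.3, 142.2]  (truth 30.0 m)
diameter effect on log fecundity: 1.80 [1.29, 2.33]  (truth 2.0)
posterior mean mature fraction: 0.57 (truth 0.59)

fit: DIC 1766.9 (p_D 35.1), RMSPE 2.32 seeds/trap/yr
parameters flagged by split-chain R-hat > 1.1: 1/10
```

Every 95% interval here covers its generating value; the hunted+logged
interval is wide because interior traps weakly constrain the kernel's upper
range — the characteristic uncertainty of inverse seed-shadow estimation.
`examples/kernel_basics.py` walks through the kernel's closed forms, and
`examples/printed_tables.py` runs the credible-interval-overlap
classification on the packaged 33-species dispersal table (22/33 species
affected by disturbance; group means 51.4 / 41.1 / 34.4 m by dispersal
vector and 38.9 / 39.6 / 40.5 m by regime).

## Layout

- `src/seedshadow/io.py` — CSV/YAML readers, validation, schemas
- `src/seedshadow/kernel.py` — 2Dt kernel mathematics and shadow matrices
- `src/seedshadow/model.py` — likelihood, priors, maturation, design matrix
- `src/seedshadow/mcmc.py` — sampler, DIC/RMSPE, convergence diagnostics
- `src/seedshadow/posterior.py` — tables, CI-overlap classification, group means
- `src/seedshadow/simulate.py` — synthetic stands/traps/seed rain with truth
- `docs/methods.md` — model, assumptions, numerical choices, limitations
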