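# Methods

## The model

`plastlife` simulates the coevolution of reversible phenotypic plasticity
and life history in a population of fixed size N with overlapping
generations. Time is discrete. Each individual carries an asexually
inherited two-locus genotype: an updating schedule `u > 0` and a
reproductive effort `r > 0`, plus a phenotype `x` and a clock `T_u`
counting steps since its last phenotype update.

**Environment.** A scalar optimum follows the AR(1) recursion
`E_t = p E_{t-1} + (1 - p) z_t` with `z_t ~ N(0, 1)`; `p` in [0, 1) sets
the autocorrelation. The stationary variance is `(1-p)/(1+p)`, so
autocorrelation and variance are confounded in this recursion; the
ARMA(2,1) generator decouples them by solving for the AR(1)-lag coefficient
that hits a target lag-1 autocorrelation at fixed shape coefficients
(`ar2`, `ma1`) and rescaling the innovation sd to hit a target variance
(moments via the autocovariance of the ARMA lag polynomials; root finding
by bisection on the stationarity interval). By default `E_0` is drawn from
the stationary distribution so there is no burn-in transient; it can be
pinned to 0.

**Within one time step**, in order:

1. Ages and update clocks advance.
2. Each individual updates its phenotype with probability
   `1 - exp(-u * T_u)`; newborns (undefined `T_u`) update with probability
   1 regardless of `u`. An update sets `x = E_t + N(0, eps)` and resets
   `T_u = 0`; `eps` is the updating error sd (`eps = 0` removes mismatch
   exactly). Non-updaters keep their phenotype.
3. Mismatch `m = |x - E_t|`.
4. Expected clutch size `c = min(10, r) * exp(-m^2) * (1 - kappa * U)`,
   where `U = 1` for updaters; `kappa` (default 0.4) is the fecundity cost
   of updating. Newborns pay it for their forced first update.
5. Each adult dies with probability `clamp(alpha0 + m + rho * r^2, 0, 1)`
   (`alpha0 = 0.05`, `rho = 0.01` by default). The printed sum can exceed
   1, so it is clamped to keep probability semantics.
6. Dead adults leave vacancies filled by recruits: parents are drawn with
   replacement with probability proportional to `c` (continuous weights,
   not integer clutches), each draw producing one newborn with genotype
   `u_child = u_parent * e^mu`, `r_child = r_parent * e^mu'`,
   `mu, mu' ~ N(0, 0.01)` independently. In `N(mu, s)` the second argument
   is always a standard deviation.

**Recruitment pool.** Clutch weights are computed before mortality
(reproduction precedes death), but the lottery draws from parents that
survived the mortality phase. Consequently, if every adult dies in one
step the run ends with status `extinct` — a real outcome of the model at
high reproduction cost (`rho = 0.05` with high effort pushes everyone's
death probability to 1). The alternative convention, in which dead parents
of the current step remain eligible, is available as
`LifeHistoryParams(recruit_pool="all_parents")`; under it a population
whose adults all die is simply replaced by their offspring in the same
step and extinction is unreachable. We default to the survivors pool
because complete die-off is a documented behaviour of the system being
modelled; the choice has no visible effect on the comparative patterns at
the default parameters, where per-step die-off of all N adults has
negligible probability.

**Clock convention.** `T_u` resets to 0 at an update and increments at the
start of every subsequent step before the update decision, so the first
opportunity after an update uses `T_u = 1` (probability `1 - e^{-u}`).
With `T_u = 0` the formula gives 0, so an individual can never update
twice in one step; this convention makes `u` a per-step updating
intensity. Founders are newborns, so the whole founding population updates
at step 1.

**Variants.** `mismatch_mode` controls which vital rates mismatch
penalises: `both` (main model), `mortality_only` (the `exp(-m^2)` fecundity
term dropped; the `1 - kappa U` updating cost is retained, since the
variant targets mismatch effects, not updating costs), `fecundity_only`
(the `m` mortality term dropped), and `none` (both dropped). `none` exists
for neutrality controls: with `kappa = 0`, `rho = 0` and mode `none`,
fitness is flat in `u`, and the mean log genotype must drift as a
driftless random walk — a property the test suite checks.

## Parameters and defaults

| parameter | meaning | default |
|---|---|---|
| `N` | population capacity (constant when recruitment succeeds) | 2000 |
| `t_max` | simulated steps per run | 50 000 |
| `p` | AR(1) environmental autocorrelation | scenario-dependent |
| `eps` | updating error sd | scenario-dependent |
| `kappa` | fecundity cost of an update | 0.4 |
| `rho` | mortality cost coefficient of effort (`rho r^2`) | 0.01 |
| `alpha0` | baseline per-step mortality | 0.05 |
| `r_cap` | fecundity cap on effort | 10 |
| mutation sd | sd of the additive log-scale mutation | 0.01 |
| `u_init` grid | founding updating schedules | 10^{-2 .. 1}, 7 log-spaced values |
| `r_init` grid | founding efforts | 1, 4, 7 |
| `record_every` | trajectory stride (steps) | 50 |
| `record_last` | final steps kept as individual panels | 10 |

Each run consumes one integer seed; the environment and the demography use
independent child streams of it, so an environment realisation can be held
fixed while life-history variants change. Grid runs derive per-cell seeds
from the master seed and the cell index, making sweeps reproducible as a
whole yet statistically independent across cells.

## Summary statistics

- **Lifespan proxy**: cross-sectional mean age of the standing population
  at the end of the run (not mean age at death), read from the
  reproduction-time cross-section of the final step.
- **Evolved gene values**: cross-sectional means of `u` and `r` at the end.
- **Senescence slope**: OLS slope of individual mismatch on individual age,
  pooling all individual-step records of the final 10 steps (an individual
  alive throughout contributes 10 rows; no within-individual clustering
  correction). Undefined (reported missing) when all ages coincide.
- **Pattern report**: Spearman correlations of evolved effort and of
  lifespan against evolved plasticity across runs; 1-D k-means clustering
  of log10 evolved `u` into 2–3 regimes; per-scenario alternative-equilibria
  flags raised when evolved `u` within one scenario splits into groups more
  than an order of magnitude apart.

When scenarios are compared on evolved plasticity we use the mean of
log10 `u`. The gene is multiplicative — mutation acts on log `u`, the
founding grid is log-spaced, and evolved values span 3+ orders of
magnitude — so the arithmetic mean across a scenario's runs is dominated
by whichever replicate drifted highest and is not a meaningful scenario
summary.

## Scaled-down study sizes

Full-scale runs use N = 2000 and t_max = 50 000 (under a minute on one
CPU for a single run; the CLI `simulate` command handles it). The test
suite and the acceptance script run the same machinery at N = 500 and
t_max = 5000 with 3 replicates per grid cell, sizes at which all the
comparative patterns (effort–plasticity trade-off, lifespan–plasticity
association, senescence contrast, plasticity loss under updating error,
updating-cost and variant contrasts) are already directional and stable.
At these sizes plasticity has typically not converged from the most
displaced inits — which is itself informative, since effort evolves much
faster than plasticity — so the pattern checks are directional, not
point predictions.

## What the simulator does and does not emulate

The model generates its own data; there is no external input. It captures
fluctuating selection with tunable autocorrelation, a fecundity/survival
trade-off, senescence as phenotype–environment mismatch, and drift in a
finite population. It deliberately ignores sexual reproduction, diploidy
and recombination, age-dependent updating schedules (updating depends on
`T_u` only), juvenile life stages (the recruitment lottery stands in for
juvenile survival), density dependence beyond the fixed-capacity lottery,
and spatial or multidimensional environments. Passing tests therefore
demonstrate properties of this idealised system, not of any empirical
population.

## Numerical notes

- Update probabilities `1 - exp(-u T_u)` are computed with `expm1`; for
  large `u T_u` they saturate to 1.0 in floating point (mathematically the
  value is < 1).
- Death probabilities are clamped to [0, 1].
- The recruitment lottery inverts the cumulative clutch weights with one
  uniform draw per vacancy (equivalent to a multinomial draw with
  replacement).
- If the total eligible clutch weight is 0 (possible only when every
  survivor's weight is exactly 0, e.g. `kappa = 1` with all updaters),
  vacancies stay unfilled and the population shrinks.
- Ties and degenerate inputs in the summaries (empty panels, constant
  ages, fewer than 5 completed runs) return missing values or a
  diagnostics-only report instead of raising.

## Known limitations

- The ARMA(2,1) shape coefficients default to `ar2 = 0.2`, `ma1 = 0.3`;
  targets very close to ±1 in lag-1 autocorrelation can be infeasible at a
  given shape and raise a diagnostic error.
- At scaled-down sizes, runs started far from an attractor may still be in
  transit at t_max; summaries describe the population at t_max, as
  recorded, with no convergence test.
- `status="extinct"` depends on the survivors recruitment pool (above);
  with `recruit_pool="all_parents"` high-mortality populations persist as
  annuals instead.
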