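# Methods

`socped` estimates genetic, maternal, and environmental contributions to
repeatable individual differences in sociality for a pedigreed wild
population observed by monthly scan sampling. This note documents the models,
the numerical choices, and what the synthetic validation does and does not
show.

## Phenotypes and inclusion rules

Scan records (subject, date, identities within ~4 m) are pooled into
subject-months carrying two responses: the number of scans with at least one
partner out of `n_scans` (binomial trait, "time spent social") and the total
number of partners summed over scans (Poisson trait, "gregariousness", with
ln `n_scans` as a sampling-effort offset). Months with fewer than five scans
are dropped, then subjects with fewer than six surviving months. Infants
under one year are excluded as subjects and removed from their own mother's
partner lists (mother–infant proximity would otherwise inflate heritability,
since the pair shares both genes and space). Both thresholds are inclusive.

Fixed effects: cubic age (raw powers of the z-scored age) and a male
indicator with all three age×sex interactions; z-scored group size; one
annual sine/cosine harmonic of calendar month (angle `2π·month/12`; the
phase is configurable); and ENSO-phase indicators derived from the bimonthly
MEI.v2 climate index (warm ≥ 0.5, cool ≤ −0.5, inclusive; neutral is the
reference). Z-scores use population (ddof 0) moments of the filtered
dataset, recorded on the design spec so the same scaling can be replayed on
new data. The fixed-effect variance `V_FE = Var_records(Xβ)` uses the same
ddof, so the two are consistent.

## The generalized animal models

For subject-month `j` of subject `i`:

    η_j = x_j'β + u_ID[i] + u_ID:Year + u_M[mother(i)] + u_M:GroupAlpha:Year
          + a_i + u_Year + u_Month:Year + u_GroupAlpha + u_GroupAlpha:Year + e_j

    binomial:  y_j ~ Binomial(n_j, logistic(η_j))
    Poisson:   y_j ~ Poisson(exp(η_j + ln n_j))

The animal term `a ~ N(0, V_A·A)` has covariance proportional to the
additive relationship matrix computed from the pedigree by the tabular
method (`a_ii = 1 + F_i`); all other grouping terms are iid; `e` is a latent
overdispersion residual. The ten variance components (nine grouping terms
plus the residual) define `V_P` and the reported ratios: `h² = V_A/V_P`,
`m² = V_M/V_P`, `pe² = V_ID/V_P`, `R_long = (V_ID+V_M+V_A)/V_P`, and
`R_short` adding `V_ID:Year` and `V_M:GroupAlpha:Year` to the numerator.
All ratios are computed draw-wise and only then summarized (posterior mode
via a Gaussian KDE with Silverman bandwidth on a 512-point grid; 95% HPD as
the shortest interval containing ⌈0.95·n⌉ sorted draws). The residual is
estimated by default (overdispersion is identifiable with ≥5 trials per
row); `ModelSpec(residual=1.0)` reproduces the fixed-residual reading.

Priors: each G-side variance gets a parameter-expanded prior
(V = 1, ν = 1, α_μ = 0, α_V = 1000) by default — the implied marginal on the
effective variance is a scaled F(1, ν) with scale α_V·V — with inverse-
Wishart alternatives (V = 1, ν = 0.002 and ν = 0.02) selectable per
component for prior-sensitivity checks. Fixed effects get zero-mean
Gaussians with variance 1e10; the residual an IW(1, 0.002).

## Sampler

A blocked MCMC scheme, one chain per seed, bitwise-reproducible (records are
canonically sorted by subject/year/month before any random number is drawn,
so row order cannot change results):

1. **Latent residuals** — vectorized single-site random-walk Metropolis on
   each `η_j`, per-record step sizes adapted toward 0.44 acceptance during
   burn-in only.
2. **Fixed effects** — one Gaussian conditional draw.
3. **Subject-keyed pair (ID, animal)** — these two compete for the same
   among-individual variance, and conditional conjugate updates have an
   absorbing ridge (whichever component first explains the subject means
   pins the other near zero). They are updated by a partially collapsed
   move: a 2-D log-scale Metropolis step (two proposals, scale 0.8) on the
   two *effective* variances with both effect blocks integrated out — the
   sufficient statistic is the vector of per-subject residual means, with
   covariance `V_ID·I + V_A·A_obs + V_R·diag(1/c_s)` — followed by an exact
   joint Gaussian redraw of both blocks, factored through the Schur
   complement of the diagonal ID block. The prior density used in the move
   is the parameter-expanded prior's implied scaled-F marginal.
4. **Other grouping terms** — per-block Gaussian conditionals (diagonal
   posteriors for iid terms), a working-scale multiplier update when the
   prior is parameter-expanded, and conjugate scaled-inverse-χ² variance
   draws.
5. **Residual variance** — conjugate draw unless fixed.

Variances initialize at 0.1 (residual 0.3), typical latent-GLMM scales,
which shortens the burn-in transient; `A⁻¹` and its Cholesky factor are
computed once per fit, with a 1e−8 diagonal jitter (logged) if A is
singular. A variance draw above 1e12 aborts with a diagnostics dump.
Deviance (−2 log-likelihood of the counts given the latents, constants
included) is stored per retained draw, and again at the posterior-mean
latents for `DIC = 2·mean(D) − D(η̄)`.

Diagnostics follow the conventions common in this literature: a univariate
PSRF with the Brooks–Gelman df correction (pooled variance `W + (1+1/m)·b`,
so identical chains give exactly 1.0); initial-positive-sequence
(Geyer-paired) effective sample size, capped at n; and the
Heidelberger–Welch stationarity test (Cramér–von Mises statistic of the
standardized cumulative bridge, spectral density at zero from an
AIC-selected Yule–Walker AR fit capped at order 3 — the low cap keeps the
estimator short-memory so slow trends inflate the statistic instead of the
variance; p-values from the 4-term series expansion of the CvM limit
distribution, clamped to 1 above q = 2).

## Latent-to-data-scale transforms

Latent variances are converted to the observed scale by integrating the
inverse link over the latent Gaussian. Poisson-log has closed forms
(`λ = exp(μ + v_P/2)`, `var = λ + λ²(exp(v_P)−1)`, focal additive variance
`λ²·v_focal`, ICC `λ²(exp(v_focal)−1)/var`). Binomial-logit uses 64-node
Gauss–Hermite quadrature (refined at 128 nodes; per-trial disagreement above
1e−8 raises an error): `mean = n·E[p]`, `var = n·E[p(1−p)] + n²·Var(p)`,
best-linear-predictor additive variance `n²·Ψ²·v_focal` with
`Ψ = E[p(1−p)]`, and a nested-quadrature ICC. `n_obs = 32` mirrors the mean
scans per subject-month. Per-draw transforms over a chain use the model
intercept as the latent mean by default (`mu_mode="average_predictor"`
averages the full fixed predictor instead — both readings of "population
mean" are legitimate and exposed); the binomial ICC path is slow, so a
seeded posterior subsample (typically 1000 draws) is supported.

## The synthetic population

The generator emulates the study system rather than an abstract mixed
model: 4 social groups followed for 10 years (25 burn-in years build a
multi-generation pedigree), density-regulated births (capacity parameter;
equilibrium group size ≈ 25, matching the study's 24.7 ± 7.9), alpha-male
tenures with geometric lengths (mean 7 years, capped at 14 — long tenures
and the 0.73 paternity skew are what create the large cross-group paternal
sibships this study design relies on), inbreeding avoidance (the alpha is
not the sire when the dam is his daughter or granddaughter; a non-alpha
resident male is drawn instead), male dispersal at maturity with sibling
co-migration, and a male-immigration fallback for male-less groups.
Observations: ~47% of present subject-months are sampled (≈40 records per
subject over the window), scans per month truncated-Poisson with mean 32
(min 5), MEI as an AR(1) with φ = 0.8 and stationary SD 0.435 (≈25% of
months leave the neutral band). Breeding values follow the pedigree exactly
(founders N(0, σ²_A); midparent plus Mendelian sampling deflated by parental
inbreeding, unknown parents contributing compensating variance), so
`Cov(a) = σ²_A·A` holds by construction.

Default truth mirrors the study's binomial-trait variance partition
(proportions of a unit V_P): ID 0.050, ID:Year 0.091, M 0.005,
M:GroupAlpha:Year 0.045, animal 0.152, Year 0.110, Month:Year 0.208,
GroupAlpha 0.108, GroupAlpha:Year 0.061, residual 0.170. Fixed-effect truth
follows the qualitative study pattern (sociality declines with age, juvenile
males exceed females with the gap closing, larger groups more social, both
ENSO extremes depress sociality, weak seasonality). `with_h2(x)` moves
variance between the animal term and the residual, keeping V_P fixed.

What the generator does **not** emulate: observer effects, within-month
scan-time autocorrelation, group fissions, age-dependent scan density, and
real MEI dynamics. Passing recovery tests therefore show the estimator is
correct and calibrated *under the assumed latent decomposition at desk
scale*; they do not show the model is well-specified for real field data.

## Validation design and problem sizes

Test-suite experiments are sized for a single CPU: recovery runs 20
replicate populations per heritability cell (h² ∈ {0, 0.15, 0.3}) at the
default scale (~130–160 subjects, ~5–6k records) with 3,500-iteration
chains (1,000 burn-in, thin 3); production analyses should use the long
defaults (60k/10k/25, four chains), which satisfy the ESS ≥ 1000 target.
At desk scale the ID/animal split is weakly identified: the exact Gaussian
likelihood evaluated at the *true* latent effects misattributes the split
in a nontrivial fraction of replicates, so per-replicate HPD coverage of
the nominal h² is a demanding check — the null cell is judged by its own
criterion (HPD lower bound < 0.02), since variance posteriors are strictly
positive. Oracle checks: the tabular A-matrix is compared with an
independent recursive kinship oracle to 1e−12; data-scale transforms with
10⁷-draw Monte-Carlo integration to 1%; diagnostics with analytic AR(1)
autocorrelation times and iid calibration runs.

## Known limitations

- Single-trait models only; no indirect genetic effects (phenotypes of
  social partners are not modelled).
- The latent Metropolis step adapts per record; very sparse rows (n_scans
  near the minimum) mix more slowly than dense ones.
- The collapsed variance move covers the subject-keyed pair; exchanges
  between the animal term and group-tenure terms rely on ordinary Gibbs
  and dominate the remaining autocorrelation.
- `heidelberger_welch` follows the low-order-AR convention described above;
  implementations that estimate s(0) with high-order AR fits can absorb
  slow trends and reach different verdicts on strongly drifting chains.
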