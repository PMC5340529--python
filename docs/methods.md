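# Methods

## Model structure

The population is described, at the start of each season, by an abundance
and a normal distribution of breeding values for female dry weight
(`N(b̄, V_A)`).  An individual with breeding value `x` expresses phenotype
`z = x + y`, where the environmental effect `y ~ N(e, V_E)` is redrawn
each season — phenotype is not inherited across seasons, only breeding
values are.  The mean environmental effect declines linearly with
density: breeding-season phenotypes carry `e = −λ_Y · Y_prev` (crowding in
the parental non-breeding season carries over into offspring condition),
non-breeding phenotypes carry `e = −λ_X · X_cur` (the breeding density the
cohort developed under).  Both variances are held constant across
generations; the model therefore represents strong selection acting on a
standing distribution whose variance is continuously replenished, not
allele-frequency dynamics.

A generation is one breeding season followed by one non-breeding season.
Each season performs the same two operations over the phenotype
distribution truncated to the trait domain `[z_min, z_max]`:

- abundance is multiplied by the mean of the season's kernel
  (`Y₀ = X₀·E[f]`, next `X₀ = Y₀·E[s]`);
- the mean breeding value is replaced by the kernel-weighted mean
  breeding value, which is how phenotypic selection is transmitted
  across generations at rate `h²`.

The fecundity kernel rises as `z⁴` (large females are far more fecund)
but decays exponentially with an effective density combining current
breeding abundance, the previous non-breeding abundance and their
product (the carry-over term), with a decay rate that itself grows as
`z⁴` — large flies are hit harder by crowding.  The survival kernel's
numerator carries the delayed density dependence (a linear penalty in
`z` times the abundances one and two generations back) and its
denominator the interaction of current non-breeding density with size.
The numerator can go negative at extreme size-density combinations, so
survival is clipped to [0, 1]; clipping is logged.  The printed form of
the size-interaction exponential is ambiguous between `exp(z)·υ₄`
(default) and `exp(z·υ₄)`; both parses are available via
`survival_kernel(..., exp_parse=)`, and the default was validated
against the scenario outcomes below.

### Parameters

Defaults (also shipped as `ecocycles/data/default_params.yaml`):
fecundity constants `φ₁ = 1.5`, `φ₂ = 2.8`, `φ₃ = 7e-5`, `φ₄ = 0.04588`,
`φ₅ = 1`, `φ₆ = 0.001`; survival constants `υ₁ = 0.005`, `υ₂ = 0.0026`,
`υ₃ = 0.7`, `υ₄ = 0.7`, `υ₅ = 6`, `υ₆ = 350`; environmental slopes
`λ_X = 1e-5`, `λ_Y = 2.5e-4` mg per individual; variances `V_A = 0.003`,
`V_E = 0.007` mg² (`h² = 0.30`).  The logistic survival curve used by
stop-selection regimes has half-survival abundance `v = 375.22`
individuals and shape `w = 1.83`.

## Numerical implementation

The two seasonal expectations `E[w(z)]` and `E[x·w(z)]/E[w(z)]` are 2-D
trapezoid integrals in the variables (breeding value `x`, phenotype `z`),
a change of variables from `(x, y)` with unit Jacobian that puts the
size-dependent kernel on a fixed phenotype grid.  The phenotype axis uses
`n_grid = 201` uniform nodes on `[0, 1]` mg; the breeding-value axis uses
201 nodes on `b̄ ± 10·√V_A` intersected with the domain, so the integrand
stays resolved even at near-zero heritability (at `V_A = 0` exactly, the
breeding-value distribution is treated as a point mass and the mean is
conserved by construction).  Doubling the grid changes updates by less
than 1e-6 relative where the kernels are smooth; where the survival
numerator crosses zero, the clip introduces a kink that limits trapezoid
accuracy to about 1e-5 relative — both regimes are pinned by tests, and
both updates are verified against a brute-force individual-based Monte
Carlo simulation of the same kernels (3 MC standard errors, five states).

Truncation to the trait domain is part of the model: at the default
variances a 0.30 mg mean loses ~0.3% of mass below `z = 0`, and heavily
crowded states (strongly negative environmental means) lose up to ~15%.
Because truncation removes small phenotypes preferentially, it acts as a
weak selective filter of its own; the selection-free conservation
property (`b̄` unchanged under a constant kernel) is therefore exact only
for distributions away from the boundary.  The captured mass is checked
on every update: below 0.95 a warning is logged, below 0.5 the update
raises rather than silently renormalizing a distribution that has
escaped the domain.

## Scenarios and the calibrated initial state

`run_scenario` provides: `full`; `no_viability` (survival evaluated at
the mean phenotype for every individual — density dependence including
lags intact, no selection on size); `no_delay` (`υ₁ = υ₂ = φ₅ = φ₆ = 0`,
selection intact); `low_h2` (heritability rescaled to 1e-5 at constant
phenotypic variance, so only the transmissible fraction changes);
and `stop_selection` (full rules to the switch generation, then logistic
size-independent survival of current density, survival lags zeroed and
carry-over constants `φ₅, φ₆` reduced by 25%, continuing from the final
full-model state).  A run terminates as crashed when any season-start
abundance falls below one individual; within a generation the breeding
season wins ties.

Initial conditions are a genuinely open choice.  The packaged state (all
lagged abundances 130 individuals, mean breeding value 0.34 mg,
environmental means implied by those densities) was found by a coarse
grid search over a common starting abundance and breeding value,
targeting the joint qualitative behaviour — the full model cycles while
the no-viability variant destabilizes and crashes at generation 10 — and
then frozen.  Neighbouring states (±10 individuals, +0.01 mg) give the
same qualitative outcomes.  At these defaults the full model's
oscillations have a period near 6 generations and damp slowly toward an
equilibrium around 90 breeding adults; over a 40-generation horizon the
classifier reports them as cycles, which is the relevant regime for
comparison with experiments of that length.

## Cycle documentation

Series are analysed one value per generation (breeding-season start for
model output; experimental series may be interleaved two steps per
generation).  The first three generations are discarded as transient,
a fitted linear trend is removed by OLS, and the biased-normalized
sample ACF is estimated to `min(n/2, 20)` lags with the white-noise band
`±1.96/√n`.  "Oscillatory decay" is formalized as: some lag with
autocorrelation significantly below the band followed by a larger lag
significantly above it; the period estimate is the first significant
positive peak after the first significant trough, ties broken toward
smaller lags.  The whole pipeline is invariant to affine transforms of
the series and the ACF matches a double-loop reference implementation to
1e-12.

## Selection and density-dependence statistics

Selection differentials standardize each population-generation's pooled
before+after weight sample to zero mean and unit variance (sample SD),
then take `S = mean(after) − mean(before)`; `S` is thus in within-
generation phenotypic SD units and invariant to affine rescaling of raw
weights.  An external standardization pool can be supplied instead.
Welch's t-test (`t = (m_after − m_before)/√(s²_a/n_a + s²_b/n_b)`,
Welch–Satterthwaite df, two-sided p) assesses the overall weight change.

The logistic survival curve is fit by unweighted nonlinear least squares
(`scipy.optimize.curve_fit`) on observed survival fractions, with
standard errors from the Jacobian-based covariance; the fit is
scale-consistent (rescaling all abundances by `c` rescales `v` by `c`
and leaves `w` unchanged).

Density-dependent selection and delayed density dependence use linear
mixed models with a population random intercept (statsmodels `MixedLM`,
REML).  Responses (fecundity = breeding-season end/start counts;
survival = non-breeding end/start) are log-transformed, with exact zeros
offset by half the smallest positive value; predictors are standardized
to mean 0, SD 1 before interactions are formed.  Fixed-effect inference
uses large-sample Wald statistics — at the designs generated here
(hundreds to thousands of records) the difference from small-sample df
corrections is negligible, and a single population falls back to OLS
with a logged warning.  Variance explained is reported as marginal and
conditional R² from the standard variance-partition definitions.

## The synthetic-data generator

The generator simulates discrete flies sharing the projection model's
kernels: 45 replicate populations for 58 generations from 10 founders
(1:1 sex ratio), random pairing with male siring success weighted by the
same fecundity kernel (so fecundity selection acts through both sexes,
as in the projection model), per-female Poisson broods at twice the
per-capita kernel rate, mid-parent inheritance with segregation variance
`V_A/2`, and a 5% weighing subsample of females rounded to 0.001 mg
before and after each non-breeding season.  With viability selection on,
each individual survives the non-breeding season with the kernel
probability; off, survivor counts follow the logistic curve (binomial by
default, deterministic rounding available) and survivors are drawn
without regard to size.  The stop-selection emulator additionally
reduces the carry-over constants by 25%.

Two features depart from the pure kernels.  First, phenotypes below a
minimum viable size (default 0.10 mg) never recruit: the kernels impose
selection that is purely downward at small sizes, so without a floor,
drift in finite populations eventually crosses into a dwarf-fly/high-
density regime the vial experiments never exhibited.  The floor is the
generator's stand-in for the physiological limits of real flies and is
configurable.  Second, demographic stochasticity from 10 founders can
extinguish the occasional population; extinctions are logged and
flagged, and remaining populations continue.

At the defaults the generator realizes mean non-breeding survival of
about 0.6–0.7, mean weights near 0.30 mg, heritability recoverable from
midparent–offspring regression, a significantly negative S-vs-density
slope with selection on and a null slope with selection off, and lagged
survival coefficients that are significant with the kernel and null
under the stop-selection rule.  Because S is computed from a 5%
subsample, its sampling variance shrinks with density; this
heteroskedasticity makes single-fit null-slope p-values mildly
anticonservative, which is why the null is asserted on a seed-ensemble
mean in the tests.  What passing these tests shows is that the analysis
chain recovers truth built into data of the experiment's shape; it does
not validate the kernels against real fly biology beyond the qualitative
ranges above.

## Known limitations

- The IPM is deterministic and one-sex with constant variances; no
  demographic noise, mutation, or evolving genetic architecture.
- Trait-domain truncation interacts with selection near the boundary
  (see above); trait means approaching the domain edge raise rather
  than silently renormalize.
- Mixed-model inference is asymptotic (Wald); small designs should not
  lean on its p-values.
- The generator collapses egg-to-adult stages into one draw and fixes
  the sex ratio at 1:1; vial-level environmental covariates are not
  modelled.
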