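# Methods

This note documents the models implemented in `soahia`, the choices made
where the design was genuinely open, and what the synthetic data do and
do not establish about real-world performance.

## Scope and data model

The analysis estimates the US public-health burden of the PM₂.₅ formed
from single-ring aromatic hydrocarbons in gasoline, for a 2006 baseline.
The geographic unit is an abstract "county-like" unit carrying a state
code, a census-based analysis region, an urban/rural flag and an
annual-average aromatic-SOA concentration (μg/m³). Units are coarser
than the 12-km grid of a chemical-transport model but sufficient for all
downstream arithmetic, and the unit count is configurable. States map to
three regions: census Northeast and Midwest are merged into
`MidwestEast` (their model-bias behavior is indistinguishable in the
reference coefficients), census South and West map through unchanged;
Alaska and Hawaii are outside the domain.

## Synthetic inputs

Real inputs (gridded model output, a tracer-based monitor campaign,
census and mortality tables) are not redistributable, so
`soahia.synthetic_data` generates statistically faithful stand-ins with
their generating parameters recorded for parameter-recovery testing.

**Concentration fields.** Per-state lognormal draws (lognormality
guarantees positivity and the right skew of county-level data). Default
state means are obtained by inverting the published regional adjustment
equations at the published adjusted statewide means (0.03–0.23 μg/m³),
so the default field sits on the *unadjusted* model scale — its national
mean comes out at ≈0.045 μg/m³ — and maps back onto the published
statewide table when the adjustment is applied. Within-state spread is
relative (`field_cv`, default 0.2): an absolute spread would be two
thirds of the smallest state means yet a tenth of the largest. A
region-mean mode with absolute spread (`field_mean`/`field_sd`) exists
for controlled experiments; `field_sd = 0` degenerates to constant
values.

**Monitor campaigns.** Monitor pairs are monthly samples at sites drawn
from the field. The model value is the unit's annual mean times a
lognormal seasonal factor with mean 1 and cv `monitor_month_cv`
(default 0.5): photochemical SOA peaks strongly in summer, and cv 0.5
reproduces the roughly 2.5–3× max/median spread seen in co-located
monthly model values. The observation is
`a + (b + u_region)·model + ε` truncated at zero, with ε Gaussian. The
default noise sd, 0.046 μgC/m³, is ~33% of the median observed
concentration, matching the quoted accuracy of the tracer-based
measurement method. The μgC (observation) versus μg (model) unit
mismatch of the underlying data is represented by an explicit
`model_scale` factor, default 1.0 — the package does not silently
convert between organic-carbon and organic-matter mass.

**Emissions inventory.** The packaged default is the published national
inventory of single-ring aromatic VOC exactly (gasoline 2,491,313;
solvent 518,334; diesel 25,436; other 573,679 tons/yr). Overrides merge
into the default; `replace=True` substitutes the whole inventory.

**Population tables.** Lognormal populations (default mean 100,000/unit)
and a single all-cause baseline mortality rate per unit, Gaussian
clipped to [0,1] around a default 0.008 deaths/person-year. No age
structure is modeled: the reference analysis's age stratification is not
published, so synthetic populations are calibration devices, not
demographic reconstructions.

## Bias-correction mixed model

Observed concentration regressed on the co-located model value with a
fixed line and a region-specific random slope; random intercepts are
constrained to zero, reproducing the structure of the published fit
(regional intercept effects are exactly zero there, and the grouping
term acts on the slope).

Estimation is REML, profiled over the variance ratio λ = σᵤ²/σₑ². For
fixed λ the GLS fixed effects, the residual variance and the BLUP slope
deviations have closed forms; the per-region covariance
I + λ·x xᵀ is rank-one structured, so Sherman–Morrison identities give
exact O(n) evaluations. A bounded scalar optimizer (tolerance 1e-8,
search over log λ in [1e-10, 1e8]) maximizes the restricted likelihood,
with an explicit check of the λ = 0 boundary (no regional
heterogeneity). Variance components are floored at zero; an exact-fit
campaign (zero residual) is kept finite by flooring σₑ² inside the log
only. This is deterministic, auditable, and exact for a three-group,
two-fixed-effect model — no iterative matrix factorizations whose
convergence could vary across platforms.

Standard errors: fixed effects from the GLS covariance; composed slopes
(b + uⱼ) from the inverse of Henderson's mixed-model-equation
coefficient matrix, which accounts for the covariance between the fixed
slope and each BLUP. Degenerate designs: one region falls back to
ordinary least squares with a logged warning and zero random effects;
constant model values raise a singular-design error. Input rows are
canonicalized (sorted by site and month) so the fit is permutation
invariant. Negative composed slopes are allowed but logged; adjusted
concentrations are clamped at zero.

The test suite cross-checks the fit against two independent routes: a
dense grid search on the restricted likelihood using explicit n×n
covariance matrices, and statsmodels' MixedLM.

## Source attribution

The gasoline-attributable fraction equals gasoline's share of aromatic
VOC emissions, computed from the inventory at run time (69.0% on the
default inventory) rather than hard-coded, so alternative inventories
propagate automatically. The uniform scenario scales every unit by that
share. The urban/rural sensitivity scenario assigns 100% of urban
aromatic SOA to gasoline (urban aromatic sources — gasoline, solvent
use, refineries — co-locate spatially) and scales only rural units.
Shares are carried at full precision; "69%" appears only in rounded
report output.

## Health impact functions

`cases = y₀ · (1 − exp(−β·ΔC)) · Pop`, the standard log-linear health
impact function of regulatory PM₂.₅ benefit assessment. ΔC is the full
attributable concentration (a rollback-to-zero counterfactual). At this
analysis's exposure scale (ΔC ≤ ~0.6 μg/m³, β ≤ 0.015 per μg/m³) the
form is within 0.5% of linear, so the functional-form choice cannot
materially change results; the exponential form is kept because it is
exactly bounded by baseline deaths y₀·Pop.

The default β set spans the published range: 0.006 (two cohort
configurations with different confidence widths), 0.011 (expert
elicitation, the recommended central basis) and 0.015. Published
sources give only the resulting national 5th/95th-percentile case
counts, so each β's percentile bounds are back-solved by near-linear
inversion (β_p5 ≈ β · cases_p5 / cases_central); the standard error is
then (p95 − p5)/(2·z₀.₉₅). Downstream logic keys on β values, not study
labels, because the published label-to-β assignment is internally
inconsistent.

Uncertainty propagation draws β from a normal truncated at zero
(triangular also supported), recomputes the national total per draw, and
reports empirical type-7 5th/95th percentiles next to the point-β
central estimate. Only β uncertainty is propagated — concentration and
baseline-rate uncertainty are not — matching the uncertainty scope of
the reference analysis. Zero-variance and point distributions collapse
the percentiles to the central value exactly. Draws are chunked to bound
peak memory; results are bit-reproducible under a fixed seed. Note that
truncation at zero pulls the 5th percentile up slightly relative to an
untruncated normal when σ/β is large (e.g. the β = 0.011 elicitation
distribution).

## Valuation and reports

Dollars are exactly cases × VSL at every percentile, with the VSL
defaulting to $7.4M (2006 USD; no inflation or income-growth
adjustment). Rounding happens only in report formatting: billions to one
decimal, millions and cases to integers. State tables sort by descending
central cases with alphabetical tie-breaks. The nationwide adjustment
factor is reported by the formatter as the one-decimal ratio of adjusted
to unadjusted national means (0.17/0.045 → 3.8).

## Pipeline, calibration and determinism

`run_all` executes simulate → fit → adjust → attribute → impact → value,
writing plain CSV per stage plus a manifest (config echo, seed, package
version, per-stage row counts — deliberately no timestamps, so identical
config and seed give byte-identical output directories). Every stage is
re-runnable from its serialized inputs; package CSV readers parse floats
in round-trip mode so write→read is bit-exact.

The default configuration calibrates the synthetic population scale so
that the expected national estimate at β = 0.011 equals 3,816 cases —
the published central estimate — making the default run a worked
demonstration of the valuation chain ($28.2B central). This calibration
is a demonstration device: recovery and property tests never use it, and
disabling it (`target_cases=None`) yields the uncalibrated synthetic
burden.

Problem sizes used in tests and the acceptance script — 980-unit fields
(20 per state), 300–1500-pair campaigns, 200 recovery replicates, 10⁴
Monte-Carlo draws — were chosen so each statistical check has adequate
power while the whole suite runs in well under a minute of compute.

## What the synthetic tests do and do not show

Passing tests establish that the estimation machinery is correct: the
REML fit matches independent oracles, recovers known generating
parameters at the expected coverage, and the downstream arithmetic is
exact. They do not validate the scientific inputs themselves — the real
monitor network's spatial representativeness, the true regional bias
structure, the equal-proportionality assumption between emission shares
and SOA shares, or the transferability of cohort β values to this PM₂.₅
component. The synthetic generator also omits spatial autocorrelation,
true monthly time structure (months are labels on independent draws),
and demographic heterogeneity; conclusions about real-world magnitudes
rest on the published inputs, not on these tests.

## Known limitations

* Morbidity endpoints, life-table accounting and cessation lags are out
  of scope; only premature mortality is quantified.
* The published nationwide adjusted mean (0.17 μg/m³) is not an
  equal-weight mean of the published statewide table (≈0.12); the
  weighting behind it is unstated. The package reproduces the published
  factor through its report formatter and treats the printed statewide
  table as authoritative for field calibration.
* The μgC/μg unit ambiguity of the underlying regression is surfaced as
  a configuration scale factor rather than resolved.
* County-level concentration extremes (up to ~0.6 μg/m³) are
  underdispersed by the default within-state cv of 0.2; raise `field_cv`
  to study heavier-tailed exposure distributions.
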