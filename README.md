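# soahia

**S**econdary **o**rganic **a**erosol **h**ealth **i**mpact **a**ssessment:
premature mortality and social cost attributable to the PM₂.₅ formed from
aromatic hydrocarbons (benzene, toluene, xylenes) in gasoline.

Gasoline is ~20% single-ring aromatics by volume. Once emitted, these
oxidize in the atmosphere and condense into secondary organic aerosol
(SOA), a component of fine particulate matter (PM₂.₅) with well-established
mortality effects. Chemical-transport models underpredict aromatic SOA —
by roughly a factor of two nationwide, with strong regional differences —
so raw model fields must be bias-corrected against tracer-based monitor
observations before they can drive a health impact assessment. This
package implements that full chain as a tested, offline-reproducible
pipeline for exposure/risk analysts:

1. **synthetic data** — county-like concentration fields, monitor
   campaigns with known regional bias, a speciated aromatic-VOC emissions
   inventory, and population/baseline-mortality tables, all with recorded
   generating truth (`soahia.synthetic_data`);
2. **bias correction** — a random-slope linear mixed model of observed on
   modeled concentrations, fit by REML, composing one adjustment equation
   per region (`soahia.bias_model`);
3. **source attribution** — scaling the adjusted field by gasoline's share
   of aromatic-VOC emissions, uniformly or with an urban/rural sensitivity
   scenario (`soahia.attribution`);
4. **health impacts** — log-linear concentration-response functions with
   Monte-Carlo propagation of β uncertainty (`soahia.health_impact`);
5. **valuation** — monetization at the EPA value of mortality risk and
   report assembly (`soahia.valuation`).

## The models

**Bias correction.** For observation *i* in census-based region *j*
(Midwest/East, South, West):

```
yᵢⱼ = a + (b + uⱼ)·xᵢⱼ + εᵢⱼ,   uⱼ ~ N(0, σᵤ²),  εᵢⱼ ~ N(0, σₑ²)
```

where *y* is the tracer-derived aromatic-SOA observation (μgC/m³) and *x*
the co-located monthly model value. Random intercepts are constrained to
zero; the REML fit profiles the restricted likelihood over λ = σᵤ²/σₑ²
with a bounded scalar optimizer (Sherman–Morrison algebra makes each
evaluation exact and O(n)). The fitted model composes per-region
adjustment equations `SOA = a + (b + uⱼ)·x`; on the published reference
coefficients these are slopes 3.016, 1.627 and 1.04.

**Health impact function.** With baseline mortality rate y₀, exposed
population Pop, and concentration increment ΔC:

```
cases = y₀ · (1 − exp(−β·ΔC)) · Pop
```

β is the log-linear concentration-response coefficient per μg/m³ (default
set: 0.006, 0.006, 0.011, 0.015). 5th/95th percentiles come from
Monte-Carlo draws of β (normal, truncated at zero). Social cost is
cases × VSL at $7.4M per statistical life (2006 USD).

## Worked example

```
$ soahia run-all --out out --seed 1
wrote 16 artifacts to out
$ soahia validate
...
[ok] share_of_pm25_burden_pct: 1.4 (expected 1.4)
all 11 checks passed
```

Or from Python:

```python
import soahia as sa

truth = sa.SyntheticTruth(obs_noise_sd=0.02, seed=7)   # published slopes as truth
field = sa.generate_field(truth, 980)                  # unadjusted model scale
monitors = sa.generate_monitors(field, truth, 300, 8)
fit = sa.fit(monitors)
for eq in sa.compose_equations(fit):
    print(f"{eq.region}: SOA = {eq.intercept:.5f} + {eq.slope:.3f}*model")
```

```
MidwestEast: SOA = 0.01820 + 3.007*model
South: SOA = 0.01820 + 1.668*model
West: SOA = 0.01820 + 1.072*model
```

The fit recovers the generating coefficients (intercept 0.01875, slopes
3.016/1.627/1.04) within sampling error. Applying the equations to the
field raises the national mean from ≈0.045 to the adjusted scale, the
inventory attributes 69% of it to gasoline, and the default calibrated
pipeline reports 3,816 premature deaths/yr at β = 0.011, i.e. $28.2B in
social cost ($13.6B–$34.9B across the β set).

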