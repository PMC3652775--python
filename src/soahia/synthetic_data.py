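"""Synthetic inputs for the pipeline, with recorded ground truth.

The upstream data of the real analysis — a chemical-transport model's
gridded aromatic-SOA field, a tracer-based monitor campaign, a speciated
emissions inventory and census population/mortality tables — are not
redistributable at desk scale. This module generates statistically
faithful stand-ins with their generating parameters recorded in a
:class:`SyntheticTruth`, so every downstream stage can be tested by
parameter recovery.

The default configuration encodes the study conditions: per-state
lognormal concentration fields whose state means invert the published
regional adjustment equations (so the field sits on the unadjusted model
scale and maps back onto the published statewide table under
adjustment), monitor observations built from the published fixed and
regional random slopes with additive Gaussian noise truncated at zero,
and the published emissions inventory.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import reference
from .field import ConcentrationField
from .regions import REGIONS, STATES, STATE_TO_REGION

MONTHS = ("Jan", "Feb", "Mar", "Apr", "May", "Jun",
          "Jul", "Aug", "Sep", "Oct", "Nov", "Dec")


def _inverse_adjusted_state_means() -> dict[str, float]:
    """State means on the unadjusted model scale.

    Obtained by inverting the regional adjustment equations at the
    published adjusted statewide means: m = (M − a) / b_region.
    """
    out = {}
    for state, adj in reference.STATE_MEAN_UGM3.items():
        slope = reference.COMPOSED_SLOPES[STATE_TO_REGION[state]]
        out[state] = (adj - reference.FIXED_INTERCEPT) / slope
    return out


def _regional_means(state_means: Mapping[str, float]) -> dict[str, float]:
    sums: dict[str, list[float]] = {r: [] for r in REGIONS}
    for s, m in state_means.items():
        sums[STATE_TO_REGION[s]].append(m)
    return {r: float(np.mean(v)) for r, v in sums.items()}


_DEFAULT_STATE_MEANS = _inverse_adjusted_state_means()


@dataclass(frozen=True)
class SyntheticTruth:
    """Generating parameters of a synthetic campaign.

    The regression truth (``fixed_intercept``, ``fixed_slope``,
    ``region_slopes``) defaults to the published adjustment
    coefficients, so the default campaign emulates the observed
    region-dependent model underprediction. ``obs_noise_sd`` defaults to
    ~33% of the median observed concentration (0.14 μgC/m³), matching
    the quoted error of the tracer-based measurement method.
    """

    fixed_intercept: float = reference.FIXED_INTERCEPT  # μg/m³
    fixed_slope: float = reference.FIXED_SLOPE  # dimensionless
    region_slopes: Mapping[str, float] = field(
        default_factory=lambda: dict(reference.RANDOM_SLOPES))
    obs_noise_sd: float = 0.046  # μgC/m³
    field_mean: Mapping[str, float] = field(
        default_factory=lambda: _regional_means(_DEFAULT_STATE_MEANS))  # μg/m³
    field_sd: float = 0.02  # within-region sd, μg/m³ (region-mean mode)
    field_cv: float = 0.2  # within-state coefficient of variation (state-mean mode)
    state_means: Mapping[str, float] | None = field(
        default_factory=lambda: dict(_DEFAULT_STATE_MEANS))  # μg/m³
    model_scale: float = 1.0  # monitor model-value scale (μgC vs μg ambiguity)
    monitor_month_cv: float = 0.5  # seasonal spread of monthly model values
    urban_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.obs_noise_sd < 0:
            raise ValueError("obs_noise_sd must be >= 0")
        if self.field_sd < 0:
            raise ValueError("field_sd must be >= 0")
        if self.field_cv < 0:
            raise ValueError("field_cv must be >= 0")
        missing = [r for r in REGIONS if r not in self.region_slopes]
        if missing:
            raise ValueError(f"region_slopes missing regions {missing}")

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d["region_slopes"] = dict(d["region_slopes"])
        d["field_mean"] = dict(d["field_mean"])
        if d["state_means"] is not None:
            d["state_means"] = dict(d["state_means"])
        Path(path).write_text(json.dumps(d, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        return cls(**json.loads(Path(path).read_text()))


def statewide_mean_truth(**overrides) -> SyntheticTruth:
    """Truth whose state means are the published adjusted statewide table.

    Generates fields directly on the adjusted scale (0.03–0.23 μg/m³
    statewide means); used to emulate final exposure surfaces without
    running the bias-correction stage.
    """
    kw = dict(state_means=dict(reference.STATE_MEAN_UGM3))
    kw.update(overrides)
    return SyntheticTruth(**kw)


def _lognormal(rng: np.random.Generator, mean, sd) -> np.ndarray:
    """Lognormal draws with given arithmetic means and sds (sd may be 0)."""
    mean = np.asarray(mean, dtype=float)
    sd = np.broadcast_to(np.asarray(sd, dtype=float), mean.shape)
    out = mean.copy()
    pos = sd > 0
    if pos.any():
        sigma2 = np.log1p((sd[pos] / mean[pos]) ** 2)
        mu = np.log(mean[pos]) - sigma2 / 2.0
        out[pos] = rng.lognormal(mean=mu, sigma=np.sqrt(sigma2))
    return out


def _assign_states(n_units: int) -> np.ndarray:
    """Deterministic round-robin state assignment over the lower 48 + DC."""
    reps = -(-n_units // len(STATES))
    return np.tile(np.array(STATES), reps)[:n_units]


def generate_field(truth: SyntheticTruth, n_units: int) -> ConcentrationField:
    """Generate a synthetic annual-average concentration field.

    Units cycle deterministically through the lower-48 states (+DC);
    concentrations are lognormal per state with arithmetic mean from
    ``truth.state_means`` and coefficient of variation ``truth.field_cv``
    (or per region with mean ``truth.field_mean`` and absolute sd
    ``truth.field_sd`` when ``state_means`` is None). Regeneration with
    the same truth is bit-identical.
    """
    if n_units < 1:
        raise ValueError(f"n_units must be >= 1, got {n_units}")
    rng = np.random.default_rng(truth.seed)
    states = _assign_states(n_units)
    regions = np.array([STATE_TO_REGION[s] for s in states])
    if truth.state_means is not None:
        means = np.array([truth.state_means[s] for s in states])
        sd = truth.field_cv * means  # spread scales with the state level
    else:
        means = np.array([truth.field_mean[r] for r in regions])
        sd = truth.field_sd
    if np.any(means <= 0):
        raise ValueError("configured field means must be positive")
    conc = _lognormal(rng, means, sd)
    urban = rng.random(n_units) < truth.urban_fraction
    df = pd.DataFrame({
        "unit_id": [f"U{i:05d}" for i in range(n_units)],
        "state": states,
        "region": regions,
        "urban": urban,
        "conc_ugm3": conc,
    })
    return ConcentrationField(df, ("simulated",))


def generate_monitors(field: ConcentrationField, truth: SyntheticTruth,
                      n_sites: int, seed: int) -> pd.DataFrame:
    """Generate paired monitor observations with known regional bias.

    Sites are sampled from the field's units. Pairs are monthly samples:
    the co-located model value is the unit's annual mean times
    ``truth.model_scale`` and a lognormal seasonal factor (mean 1, cv
    ``truth.monitor_month_cv`` — photochemical SOA peaks strongly in
    summer, so monthly values spread far wider than annual means). The
    observation is ``intercept + (fixed_slope + region_slope)·model + ε``
    with ε ~ N(0, obs_noise_sd), truncated at zero. Columns:
    ``site_id``, ``month``, ``region``, ``model_ugCm3``, ``obs_ugCm3``.
    """
    if len(field) == 0:
        raise ValueError("cannot place monitors on an empty field")
    if n_sites < 1:
        raise ValueError(f"n_sites must be >= 1, got {n_sites}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(field), size=n_sites, replace=n_sites > len(field))
    rows = field.data.iloc[idx].reset_index(drop=True)
    seasonal = _lognormal(rng, np.ones(n_sites), truth.monitor_month_cv)
    model = rows["conc_ugm3"].to_numpy() * truth.model_scale * seasonal
    slopes = np.array([truth.fixed_slope + truth.region_slopes[r]
                       for r in rows["region"]])
    noise = rng.normal(0.0, truth.obs_noise_sd, n_sites) if truth.obs_noise_sd > 0 \
        else np.zeros(n_sites)
    obs = np.maximum(0.0, truth.fixed_intercept + slopes * model + noise)
    return pd.DataFrame({
        "site_id": [f"S{i:04d}" for i in range(n_sites)],
        "month": [MONTHS[i % 12] for i in range(n_sites)],
        "region": rows["region"],
        "model_ugCm3": model,
        "obs_ugCm3": obs,
    })


def generate_inventory(overrides: Mapping[str, float] | None = None,
                       replace: bool = False) -> pd.DataFrame:
    """Aromatic-VOC emissions inventory by source category, tons/yr.

    With no overrides, returns the published national inventory exactly.
    ``overrides`` merge into it by default; with ``replace=True`` the
    inventory consists of the overrides alone.
    """
    if overrides is not None:
        for src, tons in overrides.items():
            if tons < 0:
                raise ValueError(f"negative tonnage for {src!r}: {tons}")
    if replace:
        entries = dict(overrides or {})
    else:
        entries = dict(reference.INVENTORY_TONS)
        entries.update(overrides or {})
    return pd.DataFrame({"source": list(entries),
                         "tons_per_year": [float(v) for v in entries.values()]})


@dataclass(frozen=True)
class PopulationConfig:
    """Distributional parameters for synthetic population tables.

    Baseline mortality is a single all-cause annual rate per unit;
    0.008 deaths/person-year is a round national all-ages figure.
    """

    population_mean: float = 100_000.0  # persons per unit
    population_sd: float = 80_000.0
    baseline_rate_mean: float = 0.008  # deaths per person-year
    baseline_rate_sd: float = 0.001
    urban_fraction: float = 0.3

    def __post_init__(self) -> None:
        if not 0.0 <= self.baseline_rate_mean <= 1.0:
            raise ValueError("baseline_rate_mean must lie in [0, 1]")
        if self.baseline_rate_sd < 0:
            raise ValueError("baseline_rate_sd must be >= 0")
        if not 0.0 <= self.urban_fraction <= 1.0:
            raise ValueError("urban_fraction must lie in [0, 1]")


def generate_population(n_units: int, seed: int,
                        config: PopulationConfig | None = None) -> pd.DataFrame:
    """Synthetic population and baseline-mortality table.

    Unit ids and states follow the same deterministic scheme as
    :func:`generate_field`, so the tables join one-to-one. Populations
    are lognormal rounded to integers; rates are Gaussian clipped to
    [0, 1] (a zero ``baseline_rate_sd`` yields a constant rate).
    """
    if n_units < 1:
        raise ValueError(f"n_units must be >= 1, got {n_units}")
    cfg = config or PopulationConfig()
    rng = np.random.default_rng(seed)
    pops = np.rint(_lognormal(rng, np.full(n_units, cfg.population_mean),
                              cfg.population_sd)).astype(int)
    if cfg.baseline_rate_sd > 0:
        rates = np.clip(rng.normal(cfg.baseline_rate_mean, cfg.baseline_rate_sd,
                                   n_units), 0.0, 1.0)
    else:
        rates = np.full(n_units, cfg.baseline_rate_mean)
    urban = rng.random(n_units) < cfg.urban_fraction
    states = _assign_states(n_units)
    return pd.DataFrame({
        "unit_id": [f"U{i:05d}" for i in range(n_units)],
        "state": states,
        "population": pops,
        "baseline_rate": rates,
        "urban": urban,
    })
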