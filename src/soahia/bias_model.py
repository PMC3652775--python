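"""Bias correction of modeled aromatic-SOA fields against monitor data.

Chemical-transport models systematically underpredict anthropogenic
secondary organic aerosol, and the size of the bias varies by region
(photochemical regime, NOx levels, temperature). The correction model
regresses observed tracer-based concentrations y on co-located model
values x with a common fixed line and a region-specific random slope:

    y_ij = a + (b + u_j) x_ij + e_ij,   u_j ~ N(0, σu²),  e_ij ~ N(0, σe²)

for observation i in region j. Random intercepts are constrained to
zero: the grouping acts on the slope only, so regions share the
fixed intercept. Estimation is restricted maximum likelihood (REML),
profiled over the variance ratio λ = σu²/σe²: for fixed λ the GLS fixed
effects and σe² have closed forms, leaving a one-dimensional restricted
likelihood that a bounded scalar optimizer maximizes. The per-region
covariance V_j = σe²(I + λ x_j x_jᵀ) is rank-one structured, so all
linear algebra uses Sherman–Morrison identities and the fit is exact,
deterministic and fast at any group count.

The fitted model composes one linear adjustment equation per region,
slope = b + u_j, which :func:`apply` uses to rescale concentration
fields (clamped at zero) before health-impact estimation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .field import ConcentrationField
from .regions import REGIONS

logger = logging.getLogger(__name__)


class SingularDesignError(ValueError):
    """Raised when the monitor design cannot identify a slope."""


class MissingEquationError(KeyError):
    """Raised when a field unit's region has no adjustment equation."""


@dataclass(frozen=True)
class MixedModelFit:
    """REML estimates of the random-slope bias model."""

    fixed_intercept: float  # μg/m³
    fixed_slope: float  # dimensionless
    region_random_slopes: Mapping[str, float]  # BLUP slope deviations u_j
    slope_variance: float  # σu²
    residual_variance: float  # σe², μg²/m⁶
    standard_errors: Mapping[str, float]  # keys "intercept", "slope"
    composed_slope_se: Mapping[str, float] = field(default_factory=dict)
    n_obs: int = 0
    method: str = "reml"

    def composed_slope(self, region: str) -> float:
        return self.fixed_slope + self.region_random_slopes.get(region, 0.0)

    def to_csv(self, path: str | Path) -> None:
        rows = [("intercept", self.fixed_intercept, self.standard_errors["intercept"]),
                ("slope", self.fixed_slope, self.standard_errors["slope"])]
        for r, u in self.region_random_slopes.items():
            rows.append((f"random_slope[{r}]", u, self.composed_slope_se.get(r, np.nan)))
        rows.append(("slope_variance", self.slope_variance, np.nan))
        rows.append(("residual_variance", self.residual_variance, np.nan))
        rows.append(("n_obs", float(self.n_obs), np.nan))
        pd.DataFrame(rows, columns=["term", "estimate", "se"]) \
            .assign(method=self.method).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "MixedModelFit":
        df = pd.read_csv(path, float_precision="round_trip").set_index("term")
        est = df["estimate"]
        random = {}
        composed_se = {}
        for term in df.index:
            if term.startswith("random_slope["):
                region = term[len("random_slope["):-1]
                random[region] = float(est[term])
                se = df.loc[term, "se"]
                if np.isfinite(se):
                    composed_se[region] = float(se)
        return cls(
            fixed_intercept=float(est["intercept"]),
            fixed_slope=float(est["slope"]),
            region_random_slopes=random,
            slope_variance=float(est["slope_variance"]),
            residual_variance=float(est["residual_variance"]),
            standard_errors={"intercept": float(df.loc["intercept", "se"]),
                             "slope": float(df.loc["slope", "se"])},
            composed_slope_se=composed_se,
            n_obs=int(est["n_obs"]),
            method=str(df["method"].iloc[0]),
        )


@dataclass(frozen=True)
class AdjustmentEquation:
    """Linear adjustment y = intercept + slope·x for one region."""

    region: str
    intercept: float  # μg/m³
    slope: float  # dimensionless


# ---------------------------------------------------------------------------
# REML machinery
# ---------------------------------------------------------------------------

def _group_arrays(pairs: pd.DataFrame):
    """Canonically ordered (region, x, y) triples."""
    order = {r: i for i, r in enumerate(REGIONS)}
    groups = []
    for region, sub in pairs.groupby("region", sort=False):
        groups.append((region, sub["model_ugCm3"].to_numpy(float),
                       sub["obs_ugCm3"].to_numpy(float)))
    groups.sort(key=lambda g: order.get(g[0], len(order)))
    return groups


def _profile(lam: float, groups) -> dict:
    """GLS fit and REML criterion at a fixed variance ratio λ.

    Uses W_j = I + λ x_j x_jᵀ per region with Sherman–Morrison:
    W_j⁻¹ = I − (λ/d_j) x_j x_jᵀ, d_j = 1 + λ‖x_j‖², log|W_j| = log d_j.
    """
    XtWX = np.zeros((2, 2))
    XtWy = np.zeros(2)
    logdet_w = 0.0
    n = 0
    for _, x, y in groups:
        n += x.size
        X = np.column_stack([np.ones_like(x), x])
        s = float(x @ x)
        d = 1.0 + lam * s
        Xtx = X.T @ x  # [Σx, Σx²]
        XtWX += X.T @ X - (lam / d) * np.outer(Xtx, Xtx)
        XtWy += X.T @ y - (lam / d) * Xtx * float(x @ y)
        logdet_w += np.log(d)
    beta = np.linalg.solve(XtWX, XtWy)
    q = 0.0
    u = {}
    for region, x, y in groups:
        r = y - beta[0] - beta[1] * x
        xr = float(x @ r)
        d = 1.0 + lam * float(x @ x)
        q += float(r @ r) - lam * xr * xr / d
        u[region] = lam * xr / d  # BLUP of the slope deviation
    p = 2
    sigma2e = max(q, 0.0) / (n - p)  # clamp tiny negative roundoff
    sign, logdet_xwx = np.linalg.slogdet(XtWX)
    if sign <= 0:
        raise SingularDesignError("X'V⁻¹X is singular; check the monitor design")
    # -2 × restricted log-likelihood, dropping λ-free constants; the floor
    # keeps exact-fit data (zero residual) finite for the optimizer
    crit = (n - p) * np.log(max(sigma2e, 1e-300)) + logdet_w + logdet_xwx
    return {"beta": beta, "sigma2e": sigma2e, "u": u, "crit": crit,
            "XtWX": XtWX, "n": n}


def _mme_covariance(groups, lam: float, sigma2e: float) -> np.ndarray:
    """Prediction covariance of (â, b̂, û − u) from the mixed-model equations."""
    G = len(groups)
    M = np.zeros((2 + G, 2 + G))
    for j, (_, x, y) in enumerate(groups):
        X = np.column_stack([np.ones_like(x), x])
        M[:2, :2] += X.T @ X
        Xtx = X.T @ x
        M[:2, 2 + j] = Xtx
        M[2 + j, :2] = Xtx
        M[2 + j, 2 + j] = float(x @ x) + 1.0 / lam
    return sigma2e * np.linalg.inv(M)


def _ols(x: np.ndarray, y: np.ndarray):
    """Plain least-squares line with coefficient standard errors."""
    X = np.column_stack([np.ones_like(x), x])
    XtX = X.T @ X
    if np.linalg.matrix_rank(XtX) < 2:
        raise SingularDesignError("constant model values: slope unidentifiable")
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    dof = max(x.size - 2, 1)
    s2 = float(resid @ resid) / dof
    cov = s2 * np.linalg.inv(XtX)
    return beta, s2, np.sqrt(np.diag(cov))


def fit(pairs: pd.DataFrame, *, fixed_lambda: float | None = None,
        lambda_bounds: tuple[float, float] = (1e-10, 1e8),
        tol: float = 1e-8) -> MixedModelFit:
    """Fit the random-slope bias model by REML.

    ``pairs`` needs columns ``site_id``, ``month``, ``region``,
    ``model_ugCm3``, ``obs_ugCm3``; rows are canonicalized (sorted by
    site and month) before fitting so the result is permutation
    invariant. With a single region the model degenerates and an
    ordinary least-squares line is returned with zero random effects
    (logged). ``fixed_lambda`` pins the variance ratio σu²/σe² instead
    of profiling it (0 forces the pooled OLS solution).
    """
    required = {"site_id", "month", "region", "model_ugCm3", "obs_ugCm3"}
    missing = required - set(pairs.columns)
    if missing:
        raise ValueError(f"monitor table missing columns {sorted(missing)}")
    pairs = pairs.sort_values(["site_id", "month"], kind="mergesort").reset_index(drop=True)
    if not np.isfinite(pairs[["model_ugCm3", "obs_ugCm3"]].to_numpy()).all():
        raise ValueError("non-finite monitor values")
    if (pairs[["model_ugCm3", "obs_ugCm3"]].to_numpy() < 0).any():
        raise ValueError("negative monitor values")

    counts = pairs.groupby("region").size()
    if (counts < 3).any():
        small = counts[counts < 3].index.tolist()
        raise ValueError(f"need >= 3 monitor pairs per region; too few in {small}")
    x_all = pairs["model_ugCm3"].to_numpy(float)
    y_all = pairs["obs_ugCm3"].to_numpy(float)
    if np.ptp(x_all) == 0:
        raise SingularDesignError("constant model values: slope unidentifiable")

    groups = _group_arrays(pairs)
    if len(groups) == 1:
        region = groups[0][0]
        logger.warning("single region %s: falling back to ordinary least squares",
                       region)
        beta, s2, se = _ols(x_all, y_all)
        return MixedModelFit(
            fixed_intercept=float(beta[0]), fixed_slope=float(beta[1]),
            region_random_slopes={region: 0.0}, slope_variance=0.0,
            residual_variance=s2,
            standard_errors={"intercept": float(se[0]), "slope": float(se[1])},
            composed_slope_se={region: float(se[1])},
            n_obs=len(pairs), method="ols-single-region")

    if fixed_lambda is not None:
        lam = float(fixed_lambda)
    else:
        lo, hi = np.log(lambda_bounds[0]), np.log(lambda_bounds[1])
        res = minimize_scalar(lambda t: _profile(np.exp(t), groups)["crit"],
                              bounds=(lo, hi), method="bounded",
                              options={"xatol": tol})
        lam = float(np.exp(res.x))
        # boundary check: a variance ratio of exactly zero may beat the
        # interior optimum (no regional heterogeneity)
        if _profile(0.0, groups)["crit"] <= res.fun:
            lam = 0.0

    prof = _profile(lam, groups)
    beta, sigma2e = prof["beta"], prof["sigma2e"]
    cov_beta = sigma2e * np.linalg.inv(prof["XtWX"])
    se = np.sqrt(np.diag(cov_beta))
    if lam > 0:
        u = prof["u"]
        C = _mme_covariance(groups, lam, sigma2e)
        composed_se = {region: float(np.sqrt(max(
            C[1, 1] + C[2 + j, 2 + j] + 2.0 * C[1, 2 + j], 0.0)))
            for j, (region, _, _) in enumerate(groups)}
    else:
        u = {region: 0.0 for region, _, _ in groups}
        composed_se = {region: float(se[1]) for region, _, _ in groups}
    return MixedModelFit(
        fixed_intercept=float(beta[0]), fixed_slope=float(beta[1]),
        region_random_slopes={r: float(v) for r, v in u.items()},
        slope_variance=float(lam * sigma2e), residual_variance=float(sigma2e),
        standard_errors={"intercept": float(se[0]), "slope": float(se[1])},
        composed_slope_se=composed_se, n_obs=len(pairs), method="reml")


# ---------------------------------------------------------------------------
# Adjustment equations
# ---------------------------------------------------------------------------

def compose_equations(fit_result: MixedModelFit) -> list[AdjustmentEquation]:
    """One linear adjustment equation per region: a + (b + u_j)·x.

    Regions absent from the fit receive a zero random slope (logged);
    non-positive composed slopes are allowed but flagged.
    """
    equations = []
    for region in REGIONS:
        if region not in fit_result.region_random_slopes:
            logger.warning("region %s absent from fit; using random slope 0", region)
        slope = fit_result.composed_slope(region)
        if slope <= 0:
            logger.warning("non-positive composed slope %.4g for region %s",
                           slope, region)
        equations.append(AdjustmentEquation(region, fit_result.fixed_intercept, slope))
    return equations


def equations_to_csv(equations: Sequence[AdjustmentEquation], path: str | Path) -> None:
    pd.DataFrame([(e.region, e.intercept, e.slope) for e in equations],
                 columns=["region", "intercept", "slope"]).to_csv(path, index=False)


def equations_from_csv(path: str | Path) -> list[AdjustmentEquation]:
    df = pd.read_csv(path, float_precision="round_trip")
    return [AdjustmentEquation(str(r.region), float(r.intercept), float(r.slope))
            for r in df.itertuples()]


def apply(field: ConcentrationField,
          equations: Sequence[AdjustmentEquation]) -> ConcentrationField:
    """Apply regional adjustment equations to a concentration field.

    Each unit's concentration becomes max(0, intercept + slope·c); the
    returned field carries an ``adjusted`` provenance stage.
    """
    by_region = {e.region: e for e in equations}
    regions = field.data["region"]
    unmapped = sorted(set(regions) - set(by_region))
    if unmapped:
        offenders = field.data.loc[regions.isin(unmapped), "unit_id"].head(5).tolist()
        raise MissingEquationError(
            f"no adjustment equation for region(s) {unmapped} (e.g. units {offenders})")
    intercepts = regions.map(lambda r: by_region[r].intercept).to_numpy(float)
    slopes = regions.map(lambda r: by_region[r].slope).to_numpy(float)
    adjusted = np.maximum(0.0, intercepts + slopes * field.data["conc_ugm3"].to_numpy(float))
    return field.with_concentrations(adjusted, "adjusted")
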