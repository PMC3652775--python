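"""REML bias model: estimation, composition, application."""

import numpy as np
import pandas as pd
import pytest

import soahia as sa
from soahia import bias_model, reference
from soahia.regions import MIDWEST_EAST, REGIONS, SOUTH, WEST

from conftest import make_pairs


# ---------------------------------------------------------------------------
# Independent oracle: dense grid search on the restricted likelihood using
# explicit n×n covariance matrices (no Sherman–Morrison shortcuts).
# ---------------------------------------------------------------------------

def reml_criterion_bruteforce(lam, pairs):
    regions = sorted(pairs["region"].unique(), key=list(REGIONS).index)
    n = len(pairs)
    X = np.column_stack([np.ones(n), pairs["model_ugCm3"].to_numpy()])
    y = pairs["obs_ugCm3"].to_numpy()
    Z = np.zeros((n, len(regions)))
    for j, r in enumerate(regions):
        mask = (pairs["region"] == r).to_numpy()
        Z[mask, j] = pairs.loc[mask, "model_ugCm3"]
    W = np.eye(n) + lam * Z @ Z.T
    Wi = np.linalg.inv(W)
    beta = np.linalg.solve(X.T @ Wi @ X, X.T @ Wi @ y)
    r = y - X @ beta
    s2 = float(r @ Wi @ r) / (n - 2)
    _, ldw = np.linalg.slogdet(W)
    _, ldx = np.linalg.slogdet(X.T @ Wi @ X)
    crit = (n - 2) * np.log(s2) + ldw + ldx
    u = lam * Z.T @ Wi @ r
    return crit, beta, s2, dict(zip(regions, u))


def grid_search_reml(pairs):
    """Two-stage dense grid over the variance ratio."""
    grid = np.concatenate([[0.0], np.logspace(-6, 8, 3000)])
    crits = [reml_criterion_bruteforce(l, pairs)[0] for l in grid]
    k = int(np.argmin(crits))
    lo, hi = grid[max(k - 1, 1)], grid[min(k + 1, len(grid) - 1)]
    fine = np.linspace(lo, hi, 4000)
    crits = [reml_criterion_bruteforce(l, pairs)[0] for l in fine]
    lam = float(fine[int(np.argmin(crits))])
    _, beta, s2, u = reml_criterion_bruteforce(lam, pairs)
    return lam, beta, s2, u


def sig3(a, b):
    """Agreement to 3 significant figures."""
    return abs(a - b) <= 5e-4 * max(abs(a), abs(b))


class TestFit:
    def test_identity_data_yields_unit_line(self, identity_pairs):
        fit = sa.fit(identity_pairs)
        assert abs(fit.fixed_slope - 1.0) < 1e-6
        assert abs(fit.fixed_intercept) < 1e-6
        assert all(abs(u) < 1e-6 for u in fit.region_random_slopes.values())
        assert fit.residual_variance < 1e-6

    def test_matches_grid_search_oracle_on_toy_set(self, toy_pairs):
        """Profiled REML agrees with a brute-force restricted-likelihood
        grid search to 3 significant figures on 12 observations."""
        fit = sa.fit(toy_pairs)
        lam, beta, s2, u = grid_search_reml(toy_pairs)
        assert sig3(fit.fixed_intercept, beta[0])
        assert sig3(fit.fixed_slope, beta[1])
        assert sig3(fit.residual_variance, s2)
        assert sig3(fit.slope_variance, lam * s2)
        for region in u:
            assert sig3(fit.region_random_slopes[region], u[region])

    def test_matches_statsmodels_mixedlm(self, small_campaign):
        """Cross-check against an established REML implementation."""
        smf = pytest.importorskip("statsmodels.formula.api")
        _, mon = small_campaign
        df = mon.rename(columns={"model_ugCm3": "x", "obs_ugCm3": "y"})
        sm_fit = smf.mixedlm("y ~ x", df, groups=df["region"],
                             re_formula="0 + x").fit(reml=True)
        fit = sa.fit(mon)
        assert abs(fit.fixed_intercept - sm_fit.fe_params.iloc[0]) < 1e-3
        assert abs(fit.fixed_slope - sm_fit.fe_params.iloc[1]) < 1e-2
        for region, re in sm_fit.random_effects.items():
            assert abs(fit.region_random_slopes[region] - float(re.iloc[0])) < 1e-2
        assert fit.residual_variance == pytest.approx(sm_fit.scale, rel=0.05)

    def test_recovers_generating_slopes(self, small_campaign, low_noise_truth):
        _, mon = small_campaign
        fit = sa.fit(mon)
        for region in REGIONS:
            truth_slope = (low_noise_truth.fixed_slope
                           + low_noise_truth.region_slopes[region])
            assert abs(fit.composed_slope(region) - truth_slope) \
                <= 2 * fit.composed_slope_se[region]

    def test_zero_variance_ratio_collapses_to_pooled_ols(self, toy_pairs):
        fit = sa.fit(toy_pairs, fixed_lambda=0.0)
        x = toy_pairs["model_ugCm3"].to_numpy()
        y = toy_pairs["obs_ugCm3"].to_numpy()
        slope, intercept = np.polyfit(x, y, 1)
        assert abs(fit.fixed_slope - slope) < 1e-6
        assert abs(fit.fixed_intercept - intercept) < 1e-6
        composed = {r: fit.composed_slope(r) for r in REGIONS}
        assert all(abs(c - slope) < 1e-6 for c in composed.values())

    def test_random_slopes_sum_to_zero_for_balanced_design(self):
        """With identical within-region designs the BLUP deviations are
        centred exactly (shrinkage-centering of the estimator)."""
        rng = np.random.default_rng(17)
        x = [0.02, 0.04, 0.06, 0.08, 0.10, 0.12]
        slopes = {MIDWEST_EAST: 3.0, SOUTH: 1.6, WEST: 1.0}
        y = {r: [0.02 + s * xi + rng.normal(0, 0.01) for xi in x]
             for r, s in slopes.items()}
        fit = sa.fit(make_pairs({r: x for r in slopes}, y))
        assert abs(sum(fit.region_random_slopes.values())) < 1e-8

    def test_shrinkage_vanishes_with_many_monitors(self):
        """Composed slopes approach per-region OLS slopes as the
        per-region sample grows: the gap shrinks and becomes small."""
        truth = sa.SyntheticTruth(obs_noise_sd=0.02, seed=31)
        field = sa.generate_field(truth, 2000)

        def max_gap(n_sites):
            mon = sa.generate_monitors(field, truth, n_sites, 32)
            fit = sa.fit(mon)
            gaps = []
            for region in REGIONS:
                sub = mon[mon.region == region]
                slope_ols = np.polyfit(sub["model_ugCm3"], sub["obs_ugCm3"], 1)[0]
                gaps.append(abs(fit.composed_slope(region) - slope_ols))
            return max(gaps)

        small, large = max_gap(300), max_gap(6000)
        assert large < small
        assert large < 0.05

    def test_permutation_invariance(self, toy_pairs):
        shuffled = toy_pairs.sample(frac=1.0, random_state=8).reset_index(drop=True)
        a, b = sa.fit(toy_pairs), sa.fit(shuffled)
        assert a.fixed_slope == b.fixed_slope
        assert a.region_random_slopes == b.region_random_slopes

    def test_single_region_falls_back_to_ols(self, toy_pairs, caplog):
        sub = toy_pairs[toy_pairs.region == SOUTH]
        with caplog.at_level("WARNING"):
            fit = sa.fit(sub)
        assert fit.method == "ols-single-region"
        assert fit.slope_variance == 0.0
        assert fit.region_random_slopes == {SOUTH: 0.0}
        assert "single region" in caplog.text

    def test_constant_model_values_raise_singular_design(self):
        pairs = make_pairs({r: [0.05] * 4 for r in REGIONS},
                           {r: [0.1, 0.2, 0.15, 0.12] for r in REGIONS})
        with pytest.raises(sa.SingularDesignError):
            sa.fit(pairs)

    def test_too_few_pairs_per_region_rejected(self, toy_pairs):
        with pytest.raises(ValueError, match="3 monitor pairs"):
            sa.fit(toy_pairs.drop(toy_pairs.index[:3]))

    def test_fit_roundtrips_through_csv(self, toy_pairs, tmp_path):
        fit = sa.fit(toy_pairs)
        fit.to_csv(tmp_path / "fit.csv")
        back = sa.MixedModelFit.from_csv(tmp_path / "fit.csv")
        assert back == fit


class TestComposeEquations:
    def test_published_fixed_and_random_effects_compose_exactly(self):
        """The published fixed slope plus regional random slopes yield the
        published final adjustment slopes 3.016 / 1.627 / 1.04."""
        fit = sa.MixedModelFit(
            fixed_intercept=reference.FIXED_INTERCEPT,
            fixed_slope=reference.FIXED_SLOPE,
            region_random_slopes=reference.RANDOM_SLOPES,
            slope_variance=1.0, residual_variance=0.001,
            standard_errors={"intercept": 0.16, "slope": 2.34})
        eqs = {e.region: e for e in sa.compose_equations(fit)}
        for region, slope in reference.COMPOSED_SLOPES.items():
            assert eqs[region].slope == pytest.approx(slope, abs=1e-12)
            assert eqs[region].intercept == reference.FIXED_INTERCEPT

    def test_zero_random_slopes_reduce_to_fixed_line(self):
        fit = sa.MixedModelFit(0.01, 2.0, {r: 0.0 for r in REGIONS}, 0.0, 0.001,
                               {"intercept": 0.0, "slope": 0.0})
        assert all(e.slope == 2.0 and e.intercept == 0.01
                   for e in sa.compose_equations(fit))

    def test_nonpositive_composed_slope_flagged(self, caplog):
        fit = sa.MixedModelFit(0.0, 2.0, {MIDWEST_EAST: -2.0, SOUTH: 0.0,
                                          WEST: 0.0}, 1.0, 0.001,
                               {"intercept": 0.0, "slope": 0.0})
        with caplog.at_level("WARNING"):
            eqs = {e.region: e for e in sa.compose_equations(fit)}
        assert eqs[MIDWEST_EAST].slope == 0.0
        assert "non-positive" in caplog.text

    def test_equations_roundtrip_through_csv(self, tmp_path):
        eqs = [sa.AdjustmentEquation(r, 0.01875, s)
               for r, s in reference.COMPOSED_SLOPES.items()]
        bias_model.equations_to_csv(eqs, tmp_path / "eq.csv")
        assert bias_model.equations_from_csv(tmp_path / "eq.csv") == eqs


def published_equations():
    return [sa.AdjustmentEquation(r, reference.FIXED_INTERCEPT, s)
            for r, s in reference.COMPOSED_SLOPES.items()]


class TestApply:
    def test_published_equation_arithmetic(self):
        """A Midwest/East unit at the median modeled value 0.052 μg/m³
        adjusts to 0.01875 + 3.016·0.052 = 0.17558 μg/m³."""
        df = pd.DataFrame({"unit_id": ["U00000"], "state": ["OH"],
                           "region": [MIDWEST_EAST], "urban": [True],
                           "conc_ugm3": [0.052]})
        out = sa.apply(sa.ConcentrationField(df), published_equations())
        assert out.data["conc_ugm3"].iloc[0] == pytest.approx(0.175582, abs=1e-6)
        assert out.stage == "adjusted"

    def test_zero_concentration_floors_at_intercept(self):
        df = pd.DataFrame({"unit_id": ["U00000"], "state": ["TX"],
                           "region": [SOUTH], "urban": [False],
                           "conc_ugm3": [0.0]})
        out = sa.apply(sa.ConcentrationField(df), published_equations())
        assert out.data["conc_ugm3"].iloc[0] == 0.01875

    def test_tuned_regional_mix_reproduces_nationwide_factor(self):
        """With the published equations, a regional mix tuned to an
        unadjusted unit-weighted mean of ~0.045 μg/m³ yields a
        state-averaged adjusted mean ~3.8× larger (1-decimal)."""
        region_mean = {MIDWEST_EAST: 0.08, SOUTH: 0.055, WEST: 0.02}
        n_by_region = {MIDWEST_EAST: 80, SOUTH: 109, WEST: 211}
        rows = []
        i = 0
        from soahia.regions import STATE_TO_REGION
        states_by_region = {r: [s for s, rr in STATE_TO_REGION.items() if rr == r]
                            for r in REGIONS}
        for region, n in n_by_region.items():
            for k in range(n):
                rows.append({"unit_id": f"U{i:05d}",
                             "state": states_by_region[region][k % len(states_by_region[region])],
                             "region": region, "urban": False,
                             "conc_ugm3": region_mean[region]})
                i += 1
        field = sa.ConcentrationField(pd.DataFrame(rows))
        adjusted = sa.apply(field, published_equations())
        factor = sa.adjustment_factor(adjusted.state_means().mean(),
                                      field.national_mean())
        assert factor == 3.8

    def test_monotonicity_within_region(self):
        rng = np.random.default_rng(5)
        conc = np.sort(rng.uniform(0, 0.3, 30))
        df = pd.DataFrame({"unit_id": [f"U{i:05d}" for i in range(30)],
                           "state": "GA", "region": SOUTH, "urban": False,
                           "conc_ugm3": conc})
        out = sa.apply(sa.ConcentrationField(df), published_equations())
        assert (np.diff(out.data["conc_ugm3"]) >= 0).all()

    def test_unmapped_region_names_offending_units(self, flat_field):
        eqs = [e for e in published_equations() if e.region != WEST]
        with pytest.raises(sa.MissingEquationError, match="West"):
            sa.apply(flat_field, eqs)

    def test_negative_adjustment_clamped_at_zero(self, flat_field):
        eqs = [sa.AdjustmentEquation(r, -1.0, 0.5) for r in REGIONS]
        out = sa.apply(flat_field, eqs)
        assert (out.data["conc_ugm3"] == 0.0).all()
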