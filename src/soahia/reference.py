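"""Published reference values for the 2006 US baseline analysis.

These constants are the worked-example inputs of the pipeline: the 2005
National Emissions Inventory aggregation of single-ring aromatic VOC by
source category, the regional mixed-model adjustment coefficients, the
statewide annual-average aromatic-SOA concentrations, the EPA value of
mortality risk, and the headline national mortality estimates. They are
used by the validation command, by the default synthetic-data
configuration, and by tests; the pipeline itself recomputes everything
downstream of them.
"""

from __future__ import annotations

from .regions import MIDWEST_EAST, SOUTH, WEST

# ---------------------------------------------------------------------------
# Emissions inventory: single-ring aromatic VOC, tons/yr (2005 NEI, speciated)
# ---------------------------------------------------------------------------
INVENTORY_TONS: dict[str, float] = {
    "Gasoline": 2_491_313.0,
    "Solvent usage": 518_334.0,
    "Diesel": 25_436.0,
    "Other": 573_679.0,
}
INVENTORY_TOTAL_TONS = 3_608_762.0

# ---------------------------------------------------------------------------
# Mixed-model adjustment of modeled aromatic SOA against monitor observations
# ---------------------------------------------------------------------------
FIXED_INTERCEPT = 0.01875  # μg/m³
FIXED_SLOPE = 1.896  # dimensionless
RANDOM_SLOPES: dict[str, float] = {MIDWEST_EAST: 1.12, SOUTH: -0.269, WEST: -0.856}
#: fixed slope + regional random slope, the final adjustment slopes
COMPOSED_SLOPES: dict[str, float] = {MIDWEST_EAST: 3.016, SOUTH: 1.627, WEST: 1.04}

#: national annual-average aromatic-SOA concentration, μg/m³
NATIONAL_MEAN_UNADJUSTED = 0.045
NATIONAL_MEAN_ADJUSTED = 0.17

#: median monitor observation (μgC/m³) and co-located monthly model value
MEDIAN_OBSERVED = 0.14
MEDIAN_MODELED = 0.052

# ---------------------------------------------------------------------------
# Statewide annual-average adjusted concentrations, μg/m³ (lower 48 + DC)
# ---------------------------------------------------------------------------
STATE_MEAN_UGM3: dict[str, float] = {
    "CT": 0.23, "RI": 0.23, "OH": 0.21, "NY": 0.21, "NJ": 0.20, "IN": 0.20,
    "MA": 0.19, "NH": 0.18, "IL": 0.17, "PA": 0.17, "MO": 0.17, "MI": 0.16,
    "SC": 0.16, "NC": 0.16, "GA": 0.16, "VT": 0.15, "IA": 0.15, "WI": 0.15,
    "ME": 0.14, "KY": 0.14, "DE": 0.14, "TN": 0.14, "AL": 0.14, "WV": 0.13,
    "VA": 0.13, "MS": 0.13, "KS": 0.12, "DC": 0.12, "MD": 0.12, "AR": 0.11,
    "MN": 0.11, "NE": 0.11, "OK": 0.09, "LA": 0.09, "SD": 0.09, "TX": 0.08,
    "ND": 0.08, "FL": 0.08, "NV": 0.05, "AZ": 0.05, "CA": 0.04, "ID": 0.04,
    "MT": 0.03, "UT": 0.03, "WY": 0.03, "OR": 0.03, "WA": 0.03, "NM": 0.03,
    "CO": 0.03,
}

# ---------------------------------------------------------------------------
# Health impact and valuation
# ---------------------------------------------------------------------------
#: EPA value of mortality risk ("value of a statistical life"), 2006 USD
VSL_2006_USD = 7_400_000.0

#: national premature-mortality central estimates (lower 48, 2006 baseline)
HEADLINE_CASES: dict[str, float] = {
    "central": 3816.0,  # expert-elicitation C-R function, β = 0.011
    "high": 4714.0,     # β = 0.015 cohort function
    "low": 1833.0,      # β = 0.006 cohort functions
}

#: nationwide PM2.5-attributable premature mortalities (all sources, 2005)
#: used as the denominator of the "share of total PM2.5 burden" comparison
TOTAL_PM25_MORTALITY_REFERENCE = 130_000.0
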