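"""Monetization of mortality estimates and report-table assembly.

Premature mortality is valued at the EPA value of mortality risk
(historically "value of a statistical life"): $7.4M per statistical
death in 2006 USD. Dollars are exactly cases × VSL at every percentile;
rounding happens only in report formatting (billions to one decimal,
millions and cases to integers), with unrounded values carried in the
stored tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import reference
from .health_impact import ImpactEstimate


@dataclass(frozen=True)
class ValuationConfig:
    vsl: float = reference.VSL_2006_USD  # dollars per statistical life
    currency_year: str = "2006"

    def __post_init__(self) -> None:
        if self.vsl <= 0:
            raise ValueError("vsl must be > 0")


def monetize(estimate: ImpactEstimate, config: ValuationConfig) -> dict:
    """One social-cost report row: cases and dollars, central and percentiles."""
    row = {
        "geography": estimate.label,
        "crf_label": estimate.crf_label,
        "cases_central": estimate.cases_central,
        "cases_p5": estimate.cases_p5,
        "cases_p95": estimate.cases_p95,
        "dollars_central": estimate.cases_central * config.vsl,
        "dollars_p5": None if estimate.cases_p5 is None
        else estimate.cases_p5 * config.vsl,
        "dollars_p95": None if estimate.cases_p95 is None
        else estimate.cases_p95 * config.vsl,
        "currency_year": config.currency_year,
    }
    return row


def compare_to_reference(cases: float, reference_total: float) -> float:
    """Percent share of a reference mortality total (e.g. all-PM2.5 burden)."""
    if reference_total <= 0:
        raise ValueError("reference_total must be > 0")
    return 100.0 * cases / reference_total


def build_state_report(state_estimates: pd.DataFrame,
                       config: ValuationConfig) -> pd.DataFrame:
    """State-level social-cost table, ranked by descending central cases.

    ``state_estimates`` needs columns ``state`` and ``cases`` (optional
    ``cases_p5``/``cases_p95``); ties in cases break alphabetically.
    """
    out = state_estimates.copy()
    out["dollars"] = out["cases"] * config.vsl
    for col in ("cases_p5", "cases_p95"):
        if col in out.columns:
            out[col.replace("cases", "dollars")] = out[col] * config.vsl
    out = out.sort_values(["cases", "state"], ascending=[False, True],
                          kind="mergesort").reset_index(drop=True)
    out["rank"] = range(1, len(out) + 1)
    return out


# ---------------------------------------------------------------------------
# Report formatting (the only place rounding happens)
# ---------------------------------------------------------------------------

def billions(dollars: float, ndigits: int = 1) -> float:
    """Dollars expressed in billions, rounded for reports ($28.2B style)."""
    return round(dollars / 1e9, ndigits)


def millions(dollars: float) -> int:
    """Dollars in integer millions, the per-state table convention."""
    return int(round(dollars / 1e6))


def format_billions(dollars: float) -> str:
    return f"${billions(dollars):.1f}B"


def adjustment_factor(adjusted_mean: float, unadjusted_mean: float,
                      ndigits: int = 1) -> float:
    """Ratio of adjusted to unadjusted national mean, report-rounded."""
    if unadjusted_mean <= 0:
        raise ValueError("unadjusted_mean must be > 0")
    return round(adjusted_mean / unadjusted_mean, ndigits)


def percent(share: float, ndigits: int = 1) -> float:
    """Report-rounded percentage."""
    return round(share, ndigits)
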