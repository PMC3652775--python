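"""Census-based analysis regions for the lower 48 states.

The bias-correction regression groups monitor sites into three regions.
US census Northeast and Midwest divisions are merged into a single
``MidwestEast`` region (their model-bias slopes are statistically
indistinguishable and both sit in the cool, high-biomass part of the
domain); census South and West map through unchanged. Alaska and Hawaii
are outside the modeling domain and are not mapped.
"""

from __future__ import annotations

MIDWEST_EAST = "MidwestEast"
SOUTH = "South"
WEST = "West"

#: canonical region ordering used everywhere (tables, fits, reports)
REGIONS: tuple[str, ...] = (MIDWEST_EAST, SOUTH, WEST)

_NORTHEAST = ("CT", "ME", "MA", "NH", "RI", "VT", "NJ", "NY", "PA")
_MIDWEST = ("IL", "IN", "MI", "OH", "WI", "IA", "KS", "MN", "MO", "NE", "ND", "SD")
_SOUTH = (
    "DE", "DC", "FL", "GA", "MD", "NC", "SC", "VA", "WV",
    "AL", "KY", "MS", "TN", "AR", "LA", "OK", "TX",
)
_WEST = ("AZ", "CO", "ID", "MT", "NV", "NM", "UT", "WY", "CA", "OR", "WA")

STATE_TO_REGION: dict[str, str] = {}
for _s in _NORTHEAST + _MIDWEST:
    STATE_TO_REGION[_s] = MIDWEST_EAST
for _s in _SOUTH:
    STATE_TO_REGION[_s] = SOUTH
for _s in _WEST:
    STATE_TO_REGION[_s] = WEST

#: all mapped state codes, alphabetical — the deterministic assignment order
STATES: tuple[str, ...] = tuple(sorted(STATE_TO_REGION))


def region_of(state: str) -> str:
    """Return the analysis region for a 2-letter state code.

    Raises ``KeyError`` for states outside the lower-48 + DC domain.
    """
    return STATE_TO_REGION[state]
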