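"""The gridded-concentration container shared by every pipeline stage."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

#: required columns of the underlying table
FIELD_COLUMNS = ("unit_id", "state", "region", "urban", "conc_ugm3")


@dataclass(frozen=True)
class ConcentrationField:
    """Per-geographic-unit annual-average aromatic-SOA concentrations.

    ``data`` holds one row per geographic unit with columns ``unit_id``,
    ``state``, ``region``, ``urban`` (bool) and ``conc_ugm3`` (μg/m³, ≥ 0).
    ``provenance`` records the stages the field has passed through, e.g.
    ``("simulated", "adjusted", "attributed:uniform")``.
    """

    data: pd.DataFrame
    provenance: tuple[str, ...] = ("simulated",)

    def __post_init__(self) -> None:
        missing = [c for c in FIELD_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"concentration field missing columns {missing}")
        if (self.data["conc_ugm3"] < 0).any():
            raise ValueError("concentration field contains negative values")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def stage(self) -> str:
        return self.provenance[-1]

    def with_concentrations(self, conc, stage: str) -> "ConcentrationField":
        """Return a new field with replaced concentrations and appended stage."""
        out = self.data.copy()
        out["conc_ugm3"] = conc
        return ConcentrationField(out, self.provenance + (stage,))

    def national_mean(self) -> float:
        """Unit-weighted national mean concentration, μg/m³."""
        return float(self.data["conc_ugm3"].mean())

    def state_means(self) -> pd.Series:
        """Per-state mean concentration, μg/m³, indexed by state code."""
        return self.data.groupby("state")["conc_ugm3"].mean()

    def to_csv(self, path: str | Path) -> None:
        out = self.data.copy()
        out["stage"] = self.stage
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ConcentrationField":
        df = pd.read_csv(path, float_precision="round_trip")
        stage = str(df["stage"].iloc[0]) if "stage" in df.columns else "loaded"
        df = df.drop(columns=[c for c in ("stage",) if c in df.columns])
        df["urban"] = df["urban"].astype(bool)
        return cls(df, (stage,))
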