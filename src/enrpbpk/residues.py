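"""Tissue residue-depletion datasets (real or synthetic).

A residue study records, per slaughtered animal, the concentration of each
analyte in each edible tissue at its slaughter time (days after the last
administration).  Concentrations are in µg/kg; values below the assay's
limit of quantitation (LOQ) are flagged rather than dropped, so downstream
consumers choose their own LOQ policy.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .parameters import ParameterError

COLUMNS = (
    "animal_id",
    "tissue",
    "time_days",
    "analyte",
    "conc_ug_per_kg",
    "below_loq",
)

DEFAULT_LOQ_UG_PER_KG = 20.0  # 0.02 µg/mL at tissue density 1 g/mL


@dataclass
class ResidueDataset:
    """Long-format residue records plus assay metadata.

    ``records`` columns: animal_id, tissue, time_days (post last dose),
    analyte, conc_ug_per_kg, below_loq.
    """

    records: pd.DataFrame
    loq_ug_per_kg: float = DEFAULT_LOQ_UG_PER_KG

    def __post_init__(self) -> None:
        missing = set(COLUMNS) - set(self.records.columns)
        if missing:
            raise ParameterError(f"residue records missing columns: {sorted(missing)}")
        if self.loq_ug_per_kg <= 0:
            raise ParameterError("LOQ must be positive")
        if (self.records["time_days"] < 0).any():
            raise ParameterError("time_days must be >= 0")
        if (self.records["conc_ug_per_kg"] < 0).any():
            raise ParameterError("concentrations must be >= 0")
        self.records = self.records.reset_index(drop=True)

    def subset(self, tissue: str | None = None, analyte: str | None = None) -> "ResidueDataset":
        df = self.records
        if tissue is not None:
            df = df[df["tissue"] == tissue]
        if analyte is not None:
            df = df[df["analyte"] == analyte]
        return ResidueDataset(df.copy(), self.loq_ug_per_kg)

    def marker_total(self) -> "ResidueDataset":
        """Sum ENR + CIP per (animal, tissue, time) into marker records.

        A marker record is below the LOQ only when every component is.
        """
        g = self.records.groupby(["animal_id", "tissue", "time_days"], sort=True)
        out = g.agg(
            conc_ug_per_kg=("conc_ug_per_kg", "sum"),
            below_loq=("below_loq", "all"),
        ).reset_index()
        out["analyte"] = "ENR+CIP"
        return ResidueDataset(out[list(COLUMNS)], self.loq_ug_per_kg)

    def to_csv(self, path: str | Path) -> None:
        self.records.to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls, path: str | Path, loq_ug_per_kg: float = DEFAULT_LOQ_UG_PER_KG
    ) -> "ResidueDataset":
        df = pd.read_csv(path)
        df["below_loq"] = df["below_loq"].astype(bool)
        return cls(df, loq_ug_per_kg)
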