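"""Tidy container for longitudinal HMO concentration measurements."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

FLAGS = ("quantified", "below_loq", "below_lod")

COLUMNS = ["sample_id", "month", "analyte", "conc_mg_per_L", "flag"]


@dataclass
class HMOTable:
    """Long-format table of (sample, month, analyte) concentration records.

    ``conc_mg_per_L`` is non-negative; ``flag`` marks left-censoring:
    ``quantified`` (>= LoQ), ``below_loq`` (value drawn/reported but under
    the LoQ) or ``below_lod`` (stored as 0 mg/L).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"HMOTable missing columns: {missing}")
        if (self.df["conc_mg_per_L"] < 0).any():
            raise ValueError("negative concentrations")
        bad = set(self.df["flag"].unique()) - set(FLAGS)
        if bad:
            raise ValueError(f"unknown censoring flags: {sorted(bad)}")
        dup = self.df.duplicated(subset=["sample_id", "month", "analyte"])
        if dup.any():
            raise ValueError("duplicate (sample, month, analyte) records")

    @property
    def analytes(self) -> list[str]:
        return sorted(self.df["analyte"].unique())

    @property
    def months(self) -> list[int]:
        return sorted(self.df["month"].unique())

    @property
    def sample_ids(self) -> list[str]:
        return sorted(self.df["sample_id"].unique())

    def wide(self, month: int | None = None, values: str = "conc_mg_per_L") -> pd.DataFrame:
        """Pivot to a sample x analyte matrix, optionally for one month."""
        df = self.df if month is None else self.df[self.df["month"] == month]
        return df.pivot_table(
            index="sample_id", columns="analyte", values=values, aggfunc="first"
        )

    def sample_row(self, sample_id: str, month: int) -> dict[str, tuple[float, str]]:
        """analyte -> (concentration, flag) for one sample at one month."""
        sub = self.df[(self.df["sample_id"] == sample_id) & (self.df["month"] == month)]
        return {
            r.analyte: (r.conc_mg_per_L, r.flag) for r in sub.itertuples(index=False)
        }

    def to_csv(self, path) -> None:
        self.df[COLUMNS].to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "HMOTable":
        df = pd.read_csv(path)
        df["month"] = df["month"].astype(int)
        return cls(df[COLUMNS].copy())
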