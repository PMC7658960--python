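"""Variant metadata and the sample x variant minor-allele dosage matrix."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .reference import VARIANT_PANEL

_CONSEQUENCES = {"missense", "synonymous", "stop-gained", "intron", "3'UTR"}
_STATUS_DEFINING = {"yes", "no", "unknown"}


@dataclass
class VariantSpec:
    """Identity and annotation of one exonic SNP.

    ``maf`` is the cohort minor-allele frequency; ``status_defining`` marks
    SNPs with a known functional effect on secretor or Lewis status.
    """

    rsid: str
    gene: str
    chrom_pos: int
    ref_allele: str
    alt_allele: str
    maf: float
    consequence: str
    status_defining: str = "unknown"
    aa_change: Optional[str] = None
    protein_position: Optional[int] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.maf <= 0.5):
            raise ValueError(f"{self.rsid}: MAF {self.maf} outside [0, 0.5]")
        if self.consequence not in _CONSEQUENCES:
            raise ValueError(f"{self.rsid}: unknown consequence {self.consequence!r}")
        if self.status_defining not in _STATUS_DEFINING:
            raise ValueError(
                f"{self.rsid}: status_defining must be one of {_STATUS_DEFINING}"
            )


def reference_variants() -> list[VariantSpec]:
    """The FUT2/FUT3 coding-variant panel with cohort MAFs."""
    return [VariantSpec(**row) for row in VARIANT_PANEL]


@dataclass
class GenotypeMatrix:
    """Sample x variant matrix of minor-allele dosages {0, 1, 2, missing}.

    Dosages count copies of the *minor* allele (0 = homozygous major,
    1 = heterozygous, 2 = homozygous minor); missing genotypes are NaN.
    Backed by a pandas DataFrame with sample ids as index and rsids as
    columns.
    """

    dosages: pd.DataFrame
    variants: dict[str, VariantSpec] = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = self.dosages.to_numpy(dtype=float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            bad = np.unique(vals[~ok])
            raise ValueError(f"dosages outside {{0,1,2,missing}}: {bad}")
        if self.dosages.index.has_duplicates or self.dosages.columns.has_duplicates:
            raise ValueError("duplicate sample ids or rsids")
        extra = set(self.variants) - set(self.dosages.columns)
        if extra:
            raise ValueError(f"variant specs without dosage column: {sorted(extra)}")

    # -- basic accessors ----------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.dosages.index)

    @property
    def rsids(self) -> list[str]:
        return list(self.dosages.columns)

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def dosage(self, sample_id: str, rsid: str) -> float:
        return float(self.dosages.at[sample_id, rsid])

    def sample_dosages(self, sample_id: str) -> dict[str, float]:
        """Per-SNP dosage map for one sample (NaN where missing)."""
        return self.dosages.loc[sample_id].to_dict()

    def subset(
        self,
        samples: Optional[Iterable[str]] = None,
        rsids: Optional[Iterable[str]] = None,
    ) -> "GenotypeMatrix":
        df = self.dosages
        if samples is not None:
            df = df.loc[list(samples)]
        if rsids is not None:
            df = df[list(rsids)]
        specs = {r: self.variants[r] for r in df.columns if r in self.variants}
        return GenotypeMatrix(df.copy(), specs)

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(self.dosages.copy(), dict(self.variants))

    def equals(self, other: "GenotypeMatrix") -> bool:
        return self.dosages.equals(other.dosages)
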