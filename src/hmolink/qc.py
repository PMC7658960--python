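"""Genotype-matrix quality control: missingness and MAF filters.

The filters mirror standard plink-style QC applied at the genotype-matrix
level, in the tool order: (1) drop samples with more than
``sample_missing_max`` of their genotypes missing, (2) drop variants missing
in more than ``variant_missing_max`` of the retained samples, (3) drop
variants with minor-allele frequency below ``maf_min``, with MAF recomputed
on the post-sample-filter data.  "More than" is strict: a sample at exactly
the threshold is retained.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .variants import GenotypeMatrix

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = {
    "sample_missing_max": 0.05,
    "variant_missing_max": 0.05,
    "maf_min": 0.01,
}


class EmptyResultError(ValueError):
    """All samples or all variants were removed by QC."""


def compute_maf(matrix: GenotypeMatrix, rsid: str) -> float:
    """Minor-allele frequency of one variant over non-missing genotypes.

    The dosage column counts one designated allele; the MAF is the folded
    frequency ``min(f, 1 - f)`` so it is always <= 0.5 even if sample
    filtering has flipped which allele is rarer.

    Raises
    ------
    KeyError
        If ``rsid`` is not in the matrix.
    ValueError
        If every genotype at the variant is missing.
    """
    col = matrix.dosages[rsid].to_numpy(dtype=float)
    n_obs = int(np.sum(~np.isnan(col)))
    if n_obs == 0:
        raise ValueError(f"MAF undefined for {rsid}: all genotypes missing")
    f = float(np.nansum(col)) / (2.0 * n_obs)
    return min(f, 1.0 - f)


@dataclass
class QCReport:
    """Per-stage removal counts from :func:`apply_qc`."""

    thresholds: dict
    n_samples_in: int
    n_variants_in: int
    samples_removed: list[str] = field(default_factory=list)
    variants_removed_missingness: list[str] = field(default_factory=list)
    variants_removed_maf: list[str] = field(default_factory=list)

    @property
    def n_samples_out(self) -> int:
        return self.n_samples_in - len(self.samples_removed)

    @property
    def n_variants_out(self) -> int:
        return (
            self.n_variants_in
            - len(self.variants_removed_missingness)
            - len(self.variants_removed_maf)
        )

    def to_dict(self) -> dict:
        return {
            "thresholds": self.thresholds,
            "n_samples_in": self.n_samples_in,
            "n_variants_in": self.n_variants_in,
            "samples_removed": self.samples_removed,
            "n_samples_removed": len(self.samples_removed),
            "variants_removed_missingness": self.variants_removed_missingness,
            "variants_removed_maf": self.variants_removed_maf,
            "n_samples_out": self.n_samples_out,
            "n_variants_out": self.n_variants_out,
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)

    def summary(self) -> str:
        return (
            f"QC: {len(self.samples_removed)} sample(s) removed "
            f"(missingness > {self.thresholds['sample_missing_max']:.0%}); "
            f"{len(self.variants_removed_missingness)} variant(s) removed "
            f"(missingness > {self.thresholds['variant_missing_max']:.0%}); "
            f"{len(self.variants_removed_maf)} variant(s) removed "
            f"(MAF < {self.thresholds['maf_min']:g}); "
            f"{self.n_samples_out} samples x {self.n_variants_out} variants retained."
        )


def apply_qc(
    matrix: GenotypeMatrix,
    thresholds: dict | None = None,
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply sample-missingness, variant-missingness and MAF filters in order.

    MAF is computed on the post-sample-filter matrix, so a borderline variant
    can change fate depending on which samples survive stage 1.

    Raises
    ------
    EmptyResultError
        If no samples or no variants survive.
    """
    if matrix.n_samples == 0 or matrix.n_variants == 0:
        raise EmptyResultError("input matrix is empty")
    th = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        th.update(thresholds)

    report = QCReport(
        thresholds=th,
        n_samples_in=matrix.n_samples,
        n_variants_in=matrix.n_variants,
    )
    df = matrix.dosages

    # stage 1: sample missingness (fraction over all input variants)
    sample_miss = df.isna().mean(axis=1)
    keep_samples = sample_miss <= th["sample_missing_max"]
    report.samples_removed = list(df.index[~keep_samples])
    df = df.loc[keep_samples]
    if df.shape[0] == 0:
        raise EmptyResultError("all samples removed by missingness filter")

    # stage 2: variant missingness over retained samples
    var_miss = df.isna().mean(axis=0)
    keep_var = var_miss <= th["variant_missing_max"]
    report.variants_removed_missingness = list(df.columns[~keep_var])
    df = df.loc[:, keep_var]

    # stage 3: MAF on the post-sample-filter data
    interim = GenotypeMatrix(df, {r: matrix.variants[r] for r in df.columns
                                  if r in matrix.variants})
    maf_fail = [r for r in df.columns if compute_maf(interim, r) < th["maf_min"]]
    report.variants_removed_maf = maf_fail
    df = df.drop(columns=maf_fail)
    if df.shape[1] == 0:
        raise EmptyResultError("all variants removed by QC")

    out = GenotypeMatrix(
        df.copy(), {r: matrix.variants[r] for r in df.columns if r in matrix.variants}
    )
    logger.info(report.summary())
    return out, report
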