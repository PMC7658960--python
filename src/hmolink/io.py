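"""Reading and writing genotype matrices (VCF / dosage TSV).

VCF handling is GT-only (unphased) through pysam.  On read, the minor allele
is re-derived from the cohort allele frequencies rather than taken from the
file or from dbSNP: if the ALT frequency exceeds 0.5 the dosage column is
flipped so it counts the rarer allele (ties keep ALT as minor).  Written
VCFs place the minor allele in ALT, so a write -> read round trip preserves
dosages exactly.
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
import pandas as pd
import pysam

from .variants import GenotypeMatrix, VariantSpec

logger = logging.getLogger(__name__)


class MultiAllelicError(ValueError):
    """A VCF record with more than one ALT allele was encountered."""


def read_genotypes(
    path,
    fmt: str = "vcf",
    variants: Optional[dict[str, VariantSpec]] = None,
) -> GenotypeMatrix:
    """Read a genotype matrix from a VCF or a dosage TSV.

    Parameters
    ----------
    path : path-like
        Input file.
    fmt : {"vcf", "dosage-tsv"}
        ``vcf``: VCFv4.x with GT fields, one bi-allelic SNP per record.
        ``dosage-tsv``: rows = samples, columns = rsIDs, cells 0/1/2/NA.
    variants : dict, optional
        rsid -> :class:`VariantSpec` metadata to attach.
    """
    if fmt == "vcf":
        return _read_vcf(path, variants or {})
    if fmt == "dosage-tsv":
        return _read_dosage_tsv(path, variants or {})
    raise ValueError(f"unknown genotype format {fmt!r}")


def _read_vcf(path, variants: dict[str, VariantSpec]) -> GenotypeMatrix:
    try:
        vf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise ValueError(f"cannot parse VCF {path}: {exc}") from exc
    samples = list(vf.header.samples)
    cols: dict[str, np.ndarray] = {}
    for i, rec in enumerate(vf.fetch() if vf.index is not None else vf):
        rsid = rec.id or f"{rec.chrom}:{rec.pos}"
        alts = rec.alts or ()
        if len(alts) != 1:
            raise MultiAllelicError(
                f"record {i + 1} ({rsid}): {len(alts)} ALT alleles; "
                "only bi-allelic SNPs are supported"
            )
        alt_dosage = np.full(len(samples), np.nan)
        for j, s in enumerate(samples):
            gt = rec.samples[s].get("GT")
            if gt is None or any(a is None for a in gt):
                continue
            alt_dosage[j] = float(sum(1 for a in gt if a == 1))
        # orient to the minor allele from cohort frequency (tie -> ALT minor)
        n_obs = np.sum(~np.isnan(alt_dosage))
        if n_obs > 0:
            f_alt = np.nansum(alt_dosage) / (2.0 * n_obs)
            if f_alt > 0.5:
                alt_dosage = 2.0 - alt_dosage
                logger.info("%s: ALT is the major allele; dosages flipped", rsid)
        cols[rsid] = alt_dosage
    vf.close()
    df = pd.DataFrame(cols, index=samples)
    specs = {r: variants[r] for r in df.columns if r in variants}
    return GenotypeMatrix(df, specs)


def _read_dosage_tsv(path, variants: dict[str, VariantSpec]) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df = df.apply(pd.to_numeric, errors="coerce")
    df.index = df.index.astype(str)
    specs = {r: variants[r] for r in df.columns if r in variants}
    return GenotypeMatrix(df, specs)


def write_dosage_tsv(matrix: GenotypeMatrix, path, seed: int | None = None) -> None:
    """Write rsID x sample dosage TSV (rows = samples); NA for missing."""
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        matrix.dosages.to_csv(fh, sep="\t", na_rep="NA", index_label="sample_id")


def write_vcf(matrix: GenotypeMatrix, path, seed: int | None = None) -> None:
    """Write a minimal VCFv4.2 (GT only, unphased), minor allele as ALT.

    Variants without a :class:`VariantSpec` get placeholder coordinates in
    record order and N/A alleles replaced by A/C.
    """
    header = pysam.VariantHeader()
    header.add_meta("source", "hmolink")
    if seed is not None:
        header.add_meta("hmolink_seed", str(seed))
    header.contigs.add("19")
    header.formats.add("GT", 1, "String", "Genotype")
    for s in matrix.sample_ids:
        header.add_sample(s)

    records = []
    for k, rsid in enumerate(matrix.rsids):
        spec = matrix.variants.get(rsid)
        pos = spec.chrom_pos if spec else 1000 + k
        ref = spec.ref_allele if spec else "A"
        alt = spec.alt_allele if spec else "C"
        records.append((pos, rsid, ref, alt))

    out = pysam.VariantFile(str(path), "w", header=header)
    for (pos, rsid, ref, alt), col in zip(records, matrix.rsids):
        rec = out.new_record(contig="19", start=pos - 1, stop=pos,
                             alleles=(ref, alt), id=rsid)
        rec.qual = None
        rec.filter.add("PASS")
        for s in matrix.sample_ids:
            d = matrix.dosages.at[s, col]
            if np.isnan(d):
                rec.samples[s]["GT"] = (None, None)
            else:
                d = int(d)
                rec.samples[s]["GT"] = (0, 0) if d == 0 else (0, 1) if d == 1 else (1, 1)
            rec.samples[s].phased = False
        out.write(rec)
    out.close()
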