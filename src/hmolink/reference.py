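"""Published reference parameters for the FUT2/FUT3–HMO analysis.

The study cohort behind these numbers is a European (Leipzig) cohort of 156
lactating mothers whose *FUT2* and *FUT3* exons were amplicon-sequenced and
whose milk was profiled for 24 HMOs at 3, 6 and 12 months post partum.  The
constants here are the printed summary parameters of that cohort: the coding
variant panel with cohort minor-allele frequencies, the per-HMO lactation
slopes (median regression of natural-log concentration on month), the pooled
HMO-class slopes, and the fitted coefficients of the polygenic 2'FL score.
They parameterise the synthetic cohort generator and serve as the reference
model for the score module.
"""

from __future__ import annotations

# ---------------------------------------------------------------------------
# Coding variant panel (rsid, gene, position, cohort MAF, consequence,
# ref>alt, amino-acid change, protein position, secretor/Lewis relevance).
# consequence codes: missense / synonymous / stop-gained / intron / 3'UTR.
# status_defining: "yes" / "no" / "unknown".
# Multi-allelic dbSNP records are reduced to the first alternate allele.
# ---------------------------------------------------------------------------

VARIANT_PANEL: list[dict] = [
    {"rsid": "rs3894326", "gene": "FUT3", "chrom_pos": 5843773, "maf": 0.07895,
     "consequence": "missense", "ref_allele": "A", "alt_allele": "C",
     "aa_change": "I>K", "protein_position": 356, "status_defining": "yes"},
    {"rsid": "rs28362465", "gene": "FUT3", "chrom_pos": 5844228, "maf": 0.01316,
     "consequence": "synonymous", "ref_allele": "T", "alt_allele": "C",
     "aa_change": "S>S", "protein_position": None, "status_defining": "no"},
    {"rsid": "rs3745635", "gene": "FUT3", "chrom_pos": 5844332, "maf": 0.02961,
     "consequence": "missense", "ref_allele": "G", "alt_allele": "A",
     "aa_change": "G>S", "protein_position": 170, "status_defining": "yes"},
    {"rsid": "rs778986", "gene": "FUT3", "chrom_pos": 5844526, "maf": 0.1908,
     "consequence": "missense", "ref_allele": "A", "alt_allele": "G",
     "aa_change": "T>M", "protein_position": 105, "status_defining": "yes"},
    {"rsid": "rs812936", "gene": "FUT3", "chrom_pos": 5844638, "maf": 0.2007,
     "consequence": "missense", "ref_allele": "G", "alt_allele": "A",
     "aa_change": "W>R", "protein_position": 68, "status_defining": "yes"},
    {"rsid": "rs28362459", "gene": "FUT3", "chrom_pos": 5844781, "maf": 0.125,
     "consequence": "missense", "ref_allele": "A", "alt_allele": "C",
     "aa_change": "L>R", "protein_position": 20, "status_defining": "yes"},
    {"rsid": "rs145362171", "gene": "FUT3", "chrom_pos": 5844793, "maf": 0.01645,
     "consequence": "missense", "ref_allele": "C", "alt_allele": "G",
     "aa_change": "C>S", "protein_position": 16, "status_defining": "unknown"},
    {"rsid": "rs516316", "gene": "FUT2", "chrom_pos": 48702888, "maf": 0.3553,
     "consequence": "intron", "ref_allele": "G", "alt_allele": "C",
     "aa_change": None, "protein_position": None, "status_defining": "unknown"},
    {"rsid": "rs516246", "gene": "FUT2", "chrom_pos": 48702915, "maf": 0.3553,
     "consequence": "intron", "ref_allele": "C", "alt_allele": "T",
     "aa_change": None, "protein_position": None, "status_defining": "unknown"},
    {"rsid": "rs492602", "gene": "FUT2", "chrom_pos": 48703160, "maf": 0.352,
     "consequence": "synonymous", "ref_allele": "A", "alt_allele": "G",
     "aa_change": "A>A", "protein_position": 68, "status_defining": "no"},
    {"rsid": "rs681343", "gene": "FUT2", "chrom_pos": 48703205, "maf": 0.3553,
     "consequence": "stop-gained", "ref_allele": "C", "alt_allele": "T",
     "aa_change": "Y>*", "protein_position": 83, "status_defining": "yes"},
    {"rsid": "rs281377", "gene": "FUT2", "chrom_pos": 48703346, "maf": 0.4507,
     "consequence": "synonymous", "ref_allele": "C", "alt_allele": "T",
     "aa_change": "N>N", "protein_position": 130, "status_defining": "no"},
    {"rsid": "rs1800022", "gene": "FUT2", "chrom_pos": 48703368, "maf": 0.01645,
     "consequence": "missense", "ref_allele": "C", "alt_allele": "T",
     "aa_change": "R>C", "protein_position": 138, "status_defining": "no"},
    {"rsid": "rs601338", "gene": "FUT2", "chrom_pos": 48703417, "maf": 0.3553,
     "consequence": "stop-gained", "ref_allele": "G", "alt_allele": "A",
     "aa_change": "W>*", "protein_position": 154, "status_defining": "yes"},
    {"rsid": "rs1800027", "gene": "FUT2", "chrom_pos": 48703469, "maf": 0.102,
     "consequence": "missense", "ref_allele": "C", "alt_allele": "G",
     "aa_change": "H>Q", "protein_position": 171, "status_defining": "yes"},
    {"rsid": "rs602662", "gene": "FUT2", "chrom_pos": 48703728, "maf": 0.4046,
     "consequence": "missense", "ref_allele": "G", "alt_allele": "A",
     "aa_change": "G>S", "protein_position": 258, "status_defining": "yes"},
    {"rsid": "rs141630650", "gene": "FUT2", "chrom_pos": 48703844, "maf": 0.02303,
     "consequence": "synonymous", "ref_allele": "A", "alt_allele": "G",
     "aa_change": "A>A", "protein_position": 296, "status_defining": "no"},
    {"rsid": "rs485186", "gene": "FUT2", "chrom_pos": 48703949, "maf": 0.4046,
     "consequence": "synonymous", "ref_allele": "A", "alt_allele": "G",
     "aa_change": "T>T", "protein_position": 331, "status_defining": "yes"},
    {"rsid": "rs485073", "gene": "FUT2", "chrom_pos": 48703998, "maf": 0.4046,
     "consequence": "3'UTR", "ref_allele": "A", "alt_allele": "G",
     "aa_change": None, "protein_position": None, "status_defining": "unknown"},
    {"rsid": "rs603985", "gene": "FUT2", "chrom_pos": 48704000, "maf": 0.4046,
     "consequence": "3'UTR", "ref_allele": "T", "alt_allele": "C",
     "aa_change": None, "protein_position": None, "status_defining": "unknown"},
]

#: Rule SNPs whose homozygous-minor genotype abolishes FUT2 (secretor) activity.
SECRETOR_RULE_SNPS = ("rs601338", "rs1047781", "rs200157007")

#: Rule SNPs whose homozygous-minor genotype abolishes FUT3 (Lewis) activity.
LEWIS_RULE_SNPS = ("rs3745635", "rs28362459", "rs3894326", "rs812936")

# ---------------------------------------------------------------------------
# Lactation dynamics: median-regression slopes of ln(concentration, mg/L)
# on month post partum, per (analyte, milk group).  Milk groups: 1 = Se+Le+,
# 2 = Se-Le+, 3 = Se+Le-, 4 = Se-Le-.  Only strata reported at q < 0.1 in the
# reference cohort appear here; the generator falls back to the pooled class
# slope for any other stratum.
# ---------------------------------------------------------------------------

LACTATION_SLOPES: dict[tuple[str, int], float] = {
    ("2'FL", 1): -0.167,
    ("3FL", 1): 0.204,
    ("6'SL", 2): -0.960,
    ("6'SL", 3): -0.888,
    ("6'SL", 1): -1.049,
    ("DFLNHa", 1): -0.777,
    ("LNDFH-I", 1): -0.212,
    ("LNFP-I", 1): -0.408,
    ("LNFP-III", 1): -0.203,
    ("LNH", 3): -0.571,
    ("LNH", 1): -0.580,
    ("Hex4HexNAc2", 1): -0.693,
    ("LNnDFH", 1): 0.370,
    ("LNnFP-V", 2): -0.480,
    ("LNnFP-V", 1): -0.470,
    ("LNnT", 1): -0.604,
    ("LNT", 1): -0.283,
    ("LSTc", 2): -1.269,
    ("LSTc", 3): -1.352,
    ("LSTc", 1): -1.263,
    ("MFLNH-III", 1): -0.836,
}

#: Pooled per-class slopes of ln(class sum) on month (all milk groups).
CLASS_SLOPES: dict[str, float] = {
    "core": -0.070,
    "fucosylated": -0.073,
    "sialylated": -0.122,
}

# ---------------------------------------------------------------------------
# Polygenic 2'FL score: GLM coefficients (ln mg/L per minor-allele copy) and
# standard errors fitted on secretor mothers of the reference cohort.
# ---------------------------------------------------------------------------

SCORE_BETAS: dict[str, float] = {
    "rs601338": -0.56304,
    "rs28362459": 0.39504,
    "rs778986": 0.18314,
    "rs1800022": -0.36211,
    "rs281377": 0.10313,
}

SCORE_SE: dict[str, float] = {
    "rs601338": 0.06936,
    "rs28362459": 0.06534,
    "rs778986": 0.04536,
    "rs1800022": 0.14316,
    "rs281377": 0.05702,
}

#: Reported cohort status counts (152 QC-passing samples).
COHORT_COUNTS = {
    "n_samples": 152,
    "secretor_pos": 134,
    "secretor_neg": 18,
    "lewis_neg": 9,
    "rs812936_hom_minor": 7,
    "rs28362459_hom_minor": 2,
}
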