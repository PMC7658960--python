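"""Synthetic genotype + HMO cohort generator.

The generator emulates the statistical structure the downstream analysis
assumes:

* Hardy-Weinberg diploid genotypes at the reference-panel MAFs, with
  within-gene linkage disequilibrium produced by shared haplotype pools
  (pairwise r^2 above a configurable target for SNPs sharing a block);
* milk-group-conditional lognormal HMO concentrations, with FUT2-dependent
  analytes absent below the limit of detection for genetic non-secretors,
  FUT3-dependent analytes absent or suppressed for Lewis-negative mothers,
  A-tetra present only for secretors of blood group A, and attenuated
  ("intermediate") levels for heterozygous carriers of the inactivating
  alleles;
* per-analyte, per-milk-group log-linear time trends over months 3 - 12,
  falling back to the pooled structural-class trend where no per-analyte
  slope is given;
* a five-SNP linear generative model for log 2'FL in secretor mothers.

A deterministic 152-sample fixture reproduces the reference cohort's printed
genotype counts exactly.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .hmotable import COLUMNS, HMOTable
from .panel import (
    ALL_ANALYTES,
    DEFAULT_PANEL,
    FUT2_DEPENDENT,
    FUT3_DEPENDENT,
    HMOPanel,
)
from .reference import CLASS_SLOPES, LACTATION_SLOPES, SCORE_BETAS
from .status import DEFAULT_RULES, RuleSet, call_statuses
from .variants import GenotypeMatrix, VariantSpec, reference_variants

# ---------------------------------------------------------------------------
# Baseline concentration medians (mg/L) at month 3 for a Se+Le+ mother.
# These are representative literature-scale values for a European cohort;
# the reference study does not print per-analyte medians.
# ---------------------------------------------------------------------------
BASELINE_MEDIANS: dict[str, float] = {
    "2'FL": 2500.0, "3FL": 400.0, "LDFT": 300.0, "LNFP-I": 1200.0,
    "LNFP-II": 300.0, "LNFP-III": 80.0, "LNFP-V": 60.0, "LNnFP-V": 40.0,
    "LNnDFH": 40.0, "LNDFH-I": 300.0, "DFLNHa": 150.0, "MFLNH-III": 80.0,
    "A-tetra": 100.0, "LNT": 1000.0, "LNnT": 300.0, "LNH": 60.0,
    "Hex4HexNAc2": 50.0, "3'GL": 15.0, "6'GL": 20.0, "3'SL": 200.0,
    "6'SL": 400.0, "LSTb": 80.0, "LSTc": 200.0, "DSLNT": 400.0,
}

#: Fold change of FUT3-dependent analytes in non-secretor milk (substrate
#: not consumed by FUT2).
_SE_NEG_FUT3_BOOST = 3.0
#: Residual fraction of 3FL in Lewis-negative milk (FUT3-independent
#: alpha-1,3 fucosylation).
_LE_NEG_3FL_RESIDUAL = 0.15
#: FUT3-dependent analytes fully absent (below LoD) in Lewis-negative milk.
_LE_NEG_ABSENT = ("LNFP-II", "LNnDFH", "LNFP-III", "LNnFP-V")


def default_milk_group_log_medians(
    panel: HMOPanel = DEFAULT_PANEL,
) -> dict[tuple[str, int], float]:
    """ln(median mg/L) per (analyte, milk group) at month 3.

    Absence gates (FUT2-dependent for Se-, fully FUT3-dependent for Le-)
    are applied by the generator, not encoded here; this map carries the
    levels of the analytes that are present.
    """
    out: dict[tuple[str, int], float] = {}
    for analyte, med in BASELINE_MEDIANS.items():
        for group in (1, 2, 3, 4):
            se_neg = group in (2, 4)
            le_neg = group in (3, 4)
            m = med
            if analyte in FUT3_DEPENDENT and se_neg:
                m *= _SE_NEG_FUT3_BOOST
            if analyte == "3FL" and le_neg:
                m *= _LE_NEG_3FL_RESIDUAL
            out[(analyte, group)] = math.log(m)
    return out


@dataclass
class CohortSimParams:
    """Parameters of the synthetic cohort generator.

    The defaults reproduce the reference-cohort conditions: panel MAFs,
    within-gene LD target r^2 = 0.8, the printed per-HMO and per-class
    lactation slopes, halved-on-average heterozygote levels and the printed
    five-SNP 2'FL score coefficients.
    """

    n_samples: int = 152
    variant_specs: list[VariantSpec] = field(default_factory=reference_variants)
    ld_r2_target: float = 0.8
    blocks: Optional[dict[str, list[list[str]]]] = None  # gene -> rsid blocks
    milk_group_log_medians: dict[tuple[str, int], float] = field(
        default_factory=default_milk_group_log_medians
    )
    time_slopes: dict[tuple[str, int], float] = field(
        default_factory=lambda: dict(LACTATION_SLOPES)
    )
    class_slopes: dict[str, float] = field(default_factory=lambda: dict(CLASS_SLOPES))
    uniform_class_slopes: bool = False  # force every analyte to its class slope
    dosage_effect: float = 0.5
    panel: HMOPanel = field(default_factory=lambda: DEFAULT_PANEL)
    score_betas: dict[str, float] = field(default_factory=lambda: dict(SCORE_BETAS))
    score_intercept: float = math.log(2500.0)
    residual_sd: float = 0.5
    bloodgroup_A_prob: float = 0.4
    timepoint_sizes: Optional[dict[int, int]] = None  # month -> n, None = all
    months: tuple[int, ...] = (3, 6, 12)
    seed: int = 0
    discordance_spec: Optional[dict[str, int]] = None
    rules: RuleSet = field(default_factory=lambda: DEFAULT_RULES)

    def __post_init__(self) -> None:
        for v in self.variant_specs:
            if not (0.0 < v.maf <= 0.5):
                raise ValueError(f"{v.rsid}: simulation MAF must be in (0, 0.5]")
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be non-negative")
        if not (0.0 <= self.dosage_effect <= 1.0):
            raise ValueError("dosage_effect must be in [0, 1]")
        if not (0.0 <= self.ld_r2_target <= 1.0):
            raise ValueError("ld_r2_target must be in [0, 1]")
        for k, s in {**self.time_slopes, **self.class_slopes}.items():
            if not math.isfinite(s):
                raise ValueError(f"non-finite slope for {k}")
        if self.timepoint_sizes is not None:
            for m, n in self.timepoint_sizes.items():
                if not (0 <= n <= self.n_samples):
                    raise ValueError(f"timepoint size for month {m} out of range")

    def hash(self) -> str:
        return hashlib.sha256(repr(self).encode()).hexdigest()[:12]


@dataclass
class SyntheticCohort:
    """Genotypes, HMO table and ground truth for one simulated cohort."""

    genotypes: GenotypeMatrix
    hmo: HMOTable
    truth: pd.DataFrame  # sample_id, secretor, lewis, milk_group, blood_group
    provenance: dict


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def max_attainable_r2(p: float, q: float) -> float:
    """Maximum r^2 between two loci with MAFs p, q under nested haplotypes.

    With the rarer minor allele occurring only on haplotypes that also carry
    the commoner one, D = p(1-q) for p <= q and r^2 = p(1-q) / (q(1-p)).
    """
    p, q = min(p, q), max(p, q)
    return (p * (1.0 - q)) / (q * (1.0 - p))


def _auto_blocks(specs: Sequence[VariantSpec], r2_target: float) -> list[list[str]]:
    """Greedy grouping of one gene's SNPs into MAF-compatible LD blocks."""
    order = sorted(specs, key=lambda v: -v.maf)
    blocks: list[list[VariantSpec]] = []
    for v in order:
        placed = False
        for blk in blocks:
            if all(max_attainable_r2(v.maf, w.maf) >= r2_target for w in blk):
                blk.append(v)
                placed = True
                break
        if not placed:
            blocks.append([v])
    return [[v.rsid for v in blk] for blk in blocks]


def simulate_genotypes(params: CohortSimParams) -> GenotypeMatrix:
    """Draw diploid minor-allele dosages with within-gene LD blocks.

    SNPs sharing a block are sampled from a common haplotype pool: each
    haplotype draws one latent uniform U and carries the minor allele of
    SNP i iff U < MAF_i, which makes the rarer allele nested inside the
    commoner one and realises the maximum attainable pairwise r^2 for the
    given MAFs.  Blocks are auto-formed per gene so that every within-block
    pair can reach ``ld_r2_target``; user-forced blocks that cannot raise a
    diagnostic error.
    """
    spec_by_rsid = {v.rsid: v for v in params.variant_specs}
    genes: dict[str, list[VariantSpec]] = {}
    for v in params.variant_specs:
        genes.setdefault(v.gene, []).append(v)

    if params.blocks is not None:
        blocks = []
        for gene, blks in params.blocks.items():
            for blk in blks:
                for a in blk:
                    for b in blk:
                        if a >= b:
                            continue
                        r2 = max_attainable_r2(spec_by_rsid[a].maf, spec_by_rsid[b].maf)
                        if r2 < params.ld_r2_target:
                            raise ValueError(
                                f"LD target {params.ld_r2_target} unreachable for "
                                f"{a} (MAF {spec_by_rsid[a].maf}) and "
                                f"{b} (MAF {spec_by_rsid[b].maf}) in {gene}: "
                                f"max attainable r^2 = {r2:.3f}"
                            )
                blocks.append(blk)
        covered = {r for blk in blocks for r in blk}
        blocks += [[v.rsid] for v in params.variant_specs if v.rsid not in covered]
    else:
        blocks = []
        for gene_specs in genes.values():
            blocks += _auto_blocks(gene_specs, params.ld_r2_target)

    rng = np.random.default_rng(params.seed)
    n = params.n_samples
    cols: dict[str, np.ndarray] = {}
    for blk in blocks:
        u = rng.random((n, 2))  # one latent uniform per haplotype
        for rsid in blk:
            maf = spec_by_rsid[rsid].maf
            cols[rsid] = (u < maf).sum(axis=1).astype(float)

    order = [v.rsid for v in params.variant_specs]
    sample_ids = [f"S{i:04d}" for i in range(n)]
    df = pd.DataFrame({r: cols[r] for r in order}, index=sample_ids)
    return GenotypeMatrix(df, spec_by_rsid)


# ---------------------------------------------------------------------------
# Ground truth and HMO profiles
# ---------------------------------------------------------------------------

def _derive_truth(
    genotypes: GenotypeMatrix, params: CohortSimParams
) -> pd.DataFrame:
    calls = call_statuses(genotypes, params.rules)
    rng = np.random.default_rng(params.seed + 104729)  # independent stream
    blood_a = rng.random(len(calls)) < params.bloodgroup_A_prob
    return pd.DataFrame(
        {
            "sample_id": [c.sample_id for c in calls],
            "secretor": [c.secretor for c in calls],
            "lewis": [c.lewis for c in calls],
            "milk_group": [c.milk_group for c in calls],
            "blood_group": np.where(blood_a, "A", "O"),
        }
    )


def _analyte_slope(analyte: str, group: int, params: CohortSimParams) -> float:
    cls = params.panel.class_map[analyte]
    if params.uniform_class_slopes:
        return params.class_slopes[cls]
    return params.time_slopes.get((analyte, group), params.class_slopes[cls])


def simulate_hmo_profiles(
    genotypes: GenotypeMatrix,
    params: CohortSimParams,
    truth: Optional[pd.DataFrame] = None,
) -> HMOTable:
    """Generate the longitudinal HMO table for simulated genotypes.

    Per sample, analyte and month the log concentration is
    ``group log-median + slope * (month - 3) + heterozygote shift + noise``;
    FUT2-dependent analytes are drawn below LoD for genetic non-secretors,
    fully FUT3-dependent analytes for Lewis negatives, and A-tetra for
    everyone who is not a secretor of blood group A.  Heterozygous carriers
    of an inactivating allele have their dependent analytes attenuated by
    the factor ``2 ** -dosage_effect`` (intermediate levels).
    """
    missing_rules = [
        r for r in (params.rules.secretor_snps[0],) if r not in genotypes.rsids
    ]
    if missing_rules:
        raise ValueError(f"status-defining SNPs absent from genotypes: {missing_rules}")
    for a in params.panel.analytes:
        if a not in ALL_ANALYTES:
            raise ValueError(f"analyte {a!r} not on the panel")

    if truth is None:
        truth = _derive_truth(genotypes, params)
    truth = truth.set_index("sample_id")

    rng = np.random.default_rng(params.seed + 15485863)
    het_shift = -params.dosage_effect * math.log(2.0)

    # per-sample heterozygosity at the rule loci
    dos = genotypes.dosages
    se_het = np.zeros(genotypes.n_samples, dtype=bool)
    if "rs601338" in dos.columns:
        se_het = (dos["rs601338"].to_numpy() == 1.0)
    le_het = np.zeros(genotypes.n_samples, dtype=bool)
    for rsid in params.rules.lewis_snps:
        if rsid in dos.columns:
            le_het |= (dos[rsid].to_numpy() == 1.0)

    months = list(params.months)
    sizes = params.timepoint_sizes or {m: genotypes.n_samples for m in months}
    sample_ids = genotypes.sample_ids
    month_members: dict[int, list[str]] = {}
    for m in months:
        k = sizes.get(m, 0)
        if k == genotypes.n_samples:
            month_members[m] = list(sample_ids)
        else:
            idx = rng.choice(genotypes.n_samples, size=k, replace=False)
            month_members[m] = [sample_ids[i] for i in sorted(idx)]

    records: list[tuple] = []
    sid_pos = {s: i for i, s in enumerate(sample_ids)}
    for m in months:
        dt = m - months[0]
        for sid in month_members[m]:
            i = sid_pos[sid]
            t = truth.loc[sid]
            group = t["milk_group"]
            se_pos = t["secretor"] == "Se+"
            le_pos = t["lewis"] == "Le+"
            for analyte in params.panel.analytes:
                absent = (
                    (analyte in FUT2_DEPENDENT and not se_pos)
                    or (analyte in _LE_NEG_ABSENT and not le_pos)
                    or (analyte == "A-tetra" and not (se_pos and t["blood_group"] == "A"))
                )
                if absent:
                    records.append((sid, m, analyte, 0.0, "below_lod"))
                    continue
                mu = params.milk_group_log_medians[(analyte, group)]
                mu += _analyte_slope(analyte, group, params) * dt
                if analyte in FUT2_DEPENDENT and se_het[i]:
                    mu += het_shift
                if analyte in FUT3_DEPENDENT and le_het[i]:
                    mu += het_shift
                noise = rng.normal(0.0, params.residual_sd) if params.residual_sd else 0.0
                v = math.exp(mu + noise)
                if v < params.panel.lod(analyte):
                    records.append((sid, m, analyte, 0.0, "below_lod"))
                elif v < params.panel.loq(analyte):
                    records.append((sid, m, analyte, v, "below_loq"))
                else:
                    records.append((sid, m, analyte, v, "quantified"))

    df = pd.DataFrame(records, columns=COLUMNS)
    table = HMOTable(df)
    if params.discordance_spec:
        table = _inject_discordance(table, truth.reset_index(), params)
    return table


def _inject_discordance(
    table: HMOTable, truth: pd.DataFrame, params: CohortSimParams
) -> HMOTable:
    """Overwrite a few samples' key analytes to create genotype/phenotype
    mismatches mirroring those seen in real cohorts (off by default)."""
    spec = params.discordance_spec or {}
    df = table.df.copy()
    panel = params.panel

    def set_value(sid: str, analyte: str, conc: float, flag: str) -> None:
        mask = (df["sample_id"] == sid) & (df["analyte"] == analyte)
        df.loc[mask, ["conc_mg_per_L", "flag"]] = [conc, flag]

    se_pos = truth.loc[truth["secretor"] == "Se+", "sample_id"].tolist()
    se_neg = truth.loc[truth["secretor"] == "Se-", "sample_id"].tolist()
    le_pos = truth.loc[truth["lewis"] == "Le+", "sample_id"].tolist()

    for sid in se_pos[: spec.get("se_pos_censored", 0)]:
        # secretor genotype but 2'FL (and LNFP-I) below LoQ, near their LoD
        set_value(sid, "2'FL", panel.lod("2'FL"), "below_loq")
        set_value(sid, "LNFP-I", panel.lod("LNFP-I"), "below_loq")
    for sid in se_neg[: spec.get("se_neg_quantified", 0)]:
        set_value(sid, "2'FL", 5.0 * panel.loq("2'FL"), "quantified")
    for sid in le_pos[: spec.get("le_pos_no_lnfp2", 0)]:
        set_value(sid, "LNFP-II", 0.0, "below_lod")
    return HMOTable(df)


def simulate_cohort(params: CohortSimParams) -> SyntheticCohort:
    """Full cohort draw: genotypes, ground truth and HMO table."""
    genotypes = simulate_genotypes(params)
    truth = _derive_truth(genotypes, params)
    hmo = simulate_hmo_profiles(genotypes, params, truth)
    return SyntheticCohort(
        genotypes=genotypes,
        hmo=hmo,
        truth=truth,
        provenance={"seed": params.seed, "params_hash": params.hash()},
    )


# ---------------------------------------------------------------------------
# Five-SNP generative model for log 2'FL (secretor mothers)
# ---------------------------------------------------------------------------

def simulate_score_cohort(
    n: int,
    seed: int,
    betas: Optional[dict[str, float]] = None,
    intercept: float = math.log(2500.0),
    residual_sd: float = 0.2,
    mafs: Optional[dict[str, float]] = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Simulate secretor-mother dosages and log 2'FL from the linear score model.

    Dosages at the score SNPs are drawn independently at the panel MAFs under
    Hardy-Weinberg; rs601338 is conditioned on not being homozygous minor
    (the score is defined on secretor mothers).  The response is
    ``intercept + sum(beta * dosage) + N(0, residual_sd)`` on the natural-log
    mg/L scale.
    """
    betas = dict(betas or SCORE_BETAS)
    if mafs is None:
        mafs = {v.rsid: v.maf for v in reference_variants()}
    rng = np.random.default_rng(seed)
    cols = {}
    for rsid in betas:
        p = mafs[rsid]
        d = rng.binomial(2, p, size=n).astype(float)
        if rsid == "rs601338":
            while True:  # rejection: secretor mothers carry at most one copy
                hom = d == 2.0
                if not hom.any():
                    break
                d[hom] = rng.binomial(2, p, size=int(hom.sum())).astype(float)
        cols[rsid] = d
    X = pd.DataFrame(cols, index=[f"S{i:04d}" for i in range(n)])
    eta = intercept + X.to_numpy() @ np.array([betas[r] for r in X.columns])
    y = eta + rng.normal(0.0, residual_sd, size=n)
    return X, pd.Series(y, index=X.index, name="log_2FL")


# ---------------------------------------------------------------------------
# Deterministic fixture matching the reference cohort's printed counts
# ---------------------------------------------------------------------------

def _fixture_genotypes() -> GenotypeMatrix:
    n = 152
    total_alleles = 2 * n
    specs = {v.rsid: v for v in reference_variants()}
    sample_ids = [f"F{i:03d}" for i in range(n)]
    df = pd.DataFrame(0.0, index=sample_ids, columns=list(specs))

    def fill(rsid: str, n_hom: int, hom_start: int, het_start: int,
             n_het: Optional[int] = None) -> None:
        m = round(specs[rsid].maf * total_alleles)
        if n_het is None:
            n_het = m - 2 * n_hom
        assert n_het >= 0 and hom_start + n_hom <= n
        df.iloc[hom_start:hom_start + n_hom, df.columns.get_loc(rsid)] = 2.0
        # wrap heterozygotes around the cohort, skipping the homozygotes
        pool = [i for i in range(n) if not (hom_start <= i < hom_start + n_hom)]
        start = pool.index(het_start) if het_start in pool else 0
        for k in range(n_het):
            df.iloc[pool[(start + k) % len(pool)], df.columns.get_loc(rsid)] = 1.0

    # secretor locus: 18 homozygous minor (Se-), 72 heterozygous -> 108 minor
    # alleles, MAF 108/304
    fill("rs601338", 18, 0, 18)
    # perfect-LD FUT2 partners of rs601338 (same MAF)
    for rsid in ("rs516316", "rs516246", "rs681343"):
        df[rsid] = df["rs601338"]
    # rs492602 (MAF 0.352): one minor allele fewer -> 18 hom + 71 het
    fill("rs492602", 18, 0, 18, n_het=71)

    # Lewis locus: exactly 7 rs812936 and 2 rs28362459 homozygotes, disjoint
    fill("rs812936", 7, 20, 40)
    fill("rs28362459", 2, 27, 60)
    fill("rs3894326", 0, 0, 90)    # 24 heterozygotes, no homozygotes
    fill("rs3745635", 0, 0, 100)   # 9 heterozygotes
    fill("rs778986", 0, 0, 30)     # 58 heterozygotes (no Le- contribution)
    fill("rs28362465", 0, 0, 110)
    fill("rs145362171", 0, 0, 120)

    # remaining FUT2 variants: Hardy-Weinberg-rounded homozygote counts
    for rsid, hom_start, het_start in (
        ("rs281377", 100, 10), ("rs1800022", 140, 50), ("rs1800027", 130, 70),
        ("rs602662", 60, 95), ("rs141630650", 145, 80), ("rs485186", 60, 95),
        ("rs485073", 60, 95), ("rs603985", 60, 95),
    ):
        maf = specs[rsid].maf
        n_hom = round(maf * maf * n)
        fill(rsid, n_hom, hom_start, het_start)

    return GenotypeMatrix(df, specs)


def make_fixture_cohort() -> SyntheticCohort:
    """Deterministic 152-sample cohort matching the printed status counts.

    Exactly 18 samples are homozygous minor at rs601338 (non-secretors), 7 at
    rs812936 and 2 at rs28362459 (disjoint; 9 Lewis negatives); all minor
    allele totals round to the panel MAFs.  HMO profiles are generated from
    the genotypes under a fixed internal seed with the visit sizes of the
    reference cohort.
    """
    genotypes = _fixture_genotypes()
    params = CohortSimParams(
        n_samples=152,
        timepoint_sizes={3: 152, 6: 122, 12: 28},
        seed=20201029,
    )
    truth = _derive_truth(genotypes, params)
    hmo = simulate_hmo_profiles(genotypes, params, truth)
    return SyntheticCohort(
        genotypes=genotypes,
        hmo=hmo,
        truth=truth,
        provenance={"seed": params.seed, "params_hash": params.hash(), "fixture": True},
    )
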