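"""Secretor/Lewis classification and milk-group assignment.

Genetic rule: a mother is non-Secretor (Se-) when any secretor-rule SNP
(rs601338, rs1047781, rs200157007) is homozygous for its minor allele, and
Lewis negative (Le-) when any Lewis-rule SNP (rs3745635, rs28362459,
rs3894326, rs812936) is homozygous minor.  Heterozygotes keep the positive
status.  Milk groups cross the two statuses: 1 = Se+Le+, 2 = Se-Le+,
3 = Se+Le-, 4 = Se-Le-.

Phenotypic (milk-based) classification calls Se+ when 2'FL or LNFP-I is
quantifiable (>= LoQ) and Le+ when LNFP-II is quantifiable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import math

import pandas as pd

from .hmotable import HMOTable
from .panel import DEFAULT_PANEL, HMOPanel
from .reference import LEWIS_RULE_SNPS, SECRETOR_RULE_SNPS
from .variants import GenotypeMatrix

logger = logging.getLogger(__name__)
_warned_absent: set[str] = set()

MILK_GROUP_MAP = {
    ("Se+", "Le+"): 1,
    ("Se-", "Le+"): 2,
    ("Se+", "Le-"): 3,
    ("Se-", "Le-"): 4,
}


@dataclass
class RuleSet:
    """The status-defining SNP sets for the two fucosyltransferase loci."""

    secretor_snps: tuple[str, ...] = SECRETOR_RULE_SNPS
    lewis_snps: tuple[str, ...] = LEWIS_RULE_SNPS

    def __post_init__(self) -> None:
        if set(self.secretor_snps) & set(self.lewis_snps):
            raise ValueError("secretor and Lewis rule SNP sets must be disjoint")


DEFAULT_RULES = RuleSet()


@dataclass
class StatusCall:
    """Per-sample secretor/Lewis status and milk group with its genotype basis."""

    sample_id: str
    secretor: str = "unknown"
    lewis: str = "unknown"
    milk_group: int | str = "unknown"
    basis: list[tuple[str, int]] = field(default_factory=list)


def _classify_axis(
    dosages: Mapping[str, float], rule_snps: Sequence[str], positive: str, negative: str
) -> tuple[str, list[tuple[str, int]]]:
    basis: list[tuple[str, int]] = []
    any_missing = False
    for rsid in rule_snps:
        if rsid not in dosages:
            # rule SNP absent from the matrix: treated as homozygous major
            if rsid not in _warned_absent:
                _warned_absent.add(rsid)
                logger.warning(
                    "rule SNP %s absent from input; treated as dosage 0", rsid
                )
            continue
        d = dosages[rsid]
        if d is None or (isinstance(d, float) and math.isnan(d)):
            any_missing = True
            continue
        if int(d) == 2:
            basis.append((rsid, 2))
    if basis:
        return negative, basis
    if any_missing:
        return "unknown", []
    return positive, []


def classify_secretor(
    dosages: Mapping[str, float], rules: RuleSet = DEFAULT_RULES
) -> tuple[str, list[tuple[str, int]]]:
    """Secretor status from the rule-SNP dosages.

    Returns ``("Se-", basis)`` if any secretor-rule SNP is homozygous minor,
    ``("Se+", [])`` if none is and none is missing, otherwise
    ``("unknown", [])``.
    """
    return _classify_axis(dosages, rules.secretor_snps, "Se+", "Se-")


def classify_lewis(
    dosages: Mapping[str, float], rules: RuleSet = DEFAULT_RULES
) -> tuple[str, list[tuple[str, int]]]:
    """Lewis status from the rule-SNP dosages (analogous to secretor)."""
    return _classify_axis(dosages, rules.lewis_snps, "Le+", "Le-")


def assign_milk_group(secretor: str, lewis: str) -> int | str:
    """Milk group from the (secretor, lewis) pair; unknown propagates."""
    return MILK_GROUP_MAP.get((secretor, lewis), "unknown")


def call_statuses(
    matrix: GenotypeMatrix, rules: RuleSet = DEFAULT_RULES
) -> list[StatusCall]:
    """Genetic status calls for every sample of a genotype matrix."""
    calls = []
    for sid in matrix.sample_ids:
        dosages = matrix.sample_dosages(sid)
        se, se_basis = classify_secretor(dosages, rules)
        le, le_basis = classify_lewis(dosages, rules)
        calls.append(
            StatusCall(
                sample_id=sid,
                secretor=se,
                lewis=le,
                milk_group=assign_milk_group(se, le),
                basis=se_basis + le_basis,
            )
        )
    return calls


def phenotypic_milk_group(
    hmo_row: Mapping[str, tuple[float, str]], panel: HMOPanel = DEFAULT_PANEL
) -> int | str:
    """Milk group from HMO presence/absence in one sample's profile.

    Se+ iff 2'FL or LNFP-I is at/above its LoQ; Le+ iff LNFP-II is at/above
    its LoQ.  A censoring flag other than ``quantified`` counts as absent
    regardless of the stored value.
    """
    for a in ("2'FL", "LNFP-I", "LNFP-II"):
        if a not in hmo_row:
            raise ValueError(f"analyte {a!r} missing from HMO row")

    def present(analyte: str) -> bool:
        conc, flag = hmo_row[analyte]
        return flag == "quantified" and conc >= panel.loq(analyte)

    se = "Se+" if (present("2'FL") or present("LNFP-I")) else "Se-"
    le = "Le+" if present("LNFP-II") else "Le-"
    return assign_milk_group(se, le)


def phenotypic_milk_groups(
    hmo: HMOTable, month: int | None = None, panel: HMOPanel = DEFAULT_PANEL
) -> dict[str, int | str]:
    """Phenotypic milk group per sample (first available month by default)."""
    groups: dict[str, int | str] = {}
    for sid in hmo.sample_ids:
        months = sorted(hmo.df.loc[hmo.df["sample_id"] == sid, "month"].unique())
        m = month if month is not None else months[0]
        groups[sid] = phenotypic_milk_group(hmo.sample_row(sid, m), panel)
    return groups


def concordance_report(
    genetic: Sequence[StatusCall], phenotypic: Mapping[str, int | str]
) -> pd.DataFrame:
    """Samples whose genetic and phenotypic milk groups disagree.

    Returns a DataFrame (sample_id, genetic_group, phenotypic_group), empty
    when fully concordant.

    Raises
    ------
    ValueError
        If the two sample sets differ.
    """
    genetic_map = {c.sample_id: c.milk_group for c in genetic}
    if set(genetic_map) != set(phenotypic):
        raise ValueError("genetic and phenotypic sample sets differ")
    rows = [
        {"sample_id": sid, "genetic_group": genetic_map[sid],
         "phenotypic_group": phenotypic[sid]}
        for sid in sorted(genetic_map)
        if genetic_map[sid] != phenotypic[sid]
    ]
    return pd.DataFrame(rows, columns=["sample_id", "genetic_group", "phenotypic_group"])


def status_table(
    calls: Sequence[StatusCall], phenotypic: Optional[Mapping[str, int | str]] = None
) -> pd.DataFrame:
    """Tabular status report (one row per sample)."""
    rows = []
    for c in calls:
        row = {
            "sample_id": c.sample_id,
            "secretor": c.secretor,
            "lewis": c.lewis,
            "milk_group_genetic": c.milk_group,
            "basis": ";".join(f"{r}:{d}" for r, d in c.basis),
        }
        if phenotypic is not None:
            row["milk_group_phenotypic"] = phenotypic.get(c.sample_id, "unknown")
        rows.append(row)
    return pd.DataFrame(rows)
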