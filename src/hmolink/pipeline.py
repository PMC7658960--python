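"""End-to-end pipeline: simulate/ingest -> QC -> status -> statistics ->
dynamics -> clustering -> predictors -> genetic score."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import io as gio
from .cluster import multiscale_bootstrap_clusters, supported_clusters
from .dynamics import dynamics_table
from .hmotable import HMOTable
from .mlp import train_milkgroup_mlp
from .panel import DEFAULT_PANEL
from .qc import apply_qc
from .score import GeneticScore2FL, categorize_secretor_level
from .simulate import CohortSimParams, SyntheticCohort, simulate_cohort
from .spls import SPLSSelector
from .stats import class_sums, correlation_matrix, log_concentration_matrix
from .status import (
    call_statuses,
    concordance_report,
    phenotypic_milk_groups,
    status_table,
)
from .variants import reference_variants

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run (inputs XOR simulation)."""

    outdir: str = "hmolink_out"
    seed: int = 0
    genotypes_path: Optional[str] = None
    genotypes_format: str = "vcf"
    hmo_path: Optional[str] = None
    simulate: Optional[dict] = None  # CohortSimParams overrides
    qc_thresholds: dict = field(default_factory=dict)
    censoring_policy: str = "half_loq"
    cluster_n_boot: int = 1000
    cluster_alpha: float = 0.05
    spls_components: int = 2
    spls_keep: int = 8
    mlp_hidden: int = 16
    mlp_split: float = 0.7
    score_criterion: str = "aic"

    def __post_init__(self) -> None:
        has_inputs = self.genotypes_path is not None or self.hmo_path is not None
        if has_inputs and self.simulate is not None:
            raise ValueError("set either input paths or simulation params, not both")
        if not has_inputs and self.simulate is None:
            self.simulate = {}

    def to_yaml(self) -> str:
        return yaml.safe_dump(vars(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        return cls(**(yaml.safe_load(text) or {}))


def _load_or_simulate(cfg: PipelineConfig):
    if cfg.simulate is not None:
        params = CohortSimParams(seed=cfg.seed, **cfg.simulate)
        cohort = simulate_cohort(params)
        return cohort.genotypes, cohort.hmo, cohort
    specs = {v.rsid: v for v in reference_variants()}
    if cfg.genotypes_path is None or cfg.hmo_path is None:
        raise PipelineError("input", "both genotypes_path and hmo_path are required")
    for p in (cfg.genotypes_path, cfg.hmo_path):
        if not Path(p).exists():
            raise PipelineError("input", f"input file not found: {p}")
    genotypes = gio.read_genotypes(cfg.genotypes_path, cfg.genotypes_format, specs)
    hmo = HMOTable.read_csv(cfg.hmo_path)
    return genotypes, hmo, None


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage and write the report bundle under ``cfg.outdir``.

    Returns a dict of output paths plus headline numbers; deterministic for
    a fixed config + seed.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    summary_lines: list[str] = [f"hmolink pipeline (seed={cfg.seed})"]

    def save(name: str, text: str) -> None:
        p = out / name
        p.write_text(text)
        paths[name] = str(p)

    # --- ingest / simulate -------------------------------------------------
    genotypes, hmo, cohort = _load_or_simulate(cfg)
    if cohort is not None:
        gio.write_dosage_tsv(genotypes, out / "genotypes.tsv", seed=cfg.seed)
        gio.write_vcf(genotypes, out / "genotypes.vcf", seed=cfg.seed)
        hmo.to_csv(out / "hmo.csv")
        cohort.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        for n in ("genotypes.tsv", "genotypes.vcf", "hmo.csv", "truth.tsv"):
            paths[n] = str(out / n)
    summary_lines.append(
        f"cohort: {genotypes.n_samples} samples x {genotypes.n_variants} variants"
    )

    # --- QC ----------------------------------------------------------------
    try:
        genotypes, qc_report = apply_qc(genotypes, cfg.qc_thresholds)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("qc", str(exc)) from exc
    save("qc_report.json", qc_report.to_json())
    summary_lines.append(qc_report.summary())

    # --- status ------------------------------------------------------------
    calls = call_statuses(genotypes)
    pheno = phenotypic_milk_groups(hmo)
    stat = status_table(calls, pheno)
    save("status.tsv", stat.to_csv(sep="\t", index=False))
    n_se = int((stat["secretor"] == "Se+").sum())
    n_le_neg = int((stat["lewis"] == "Le-").sum())
    summary_lines.append(
        f"status: {n_se} Se+ / {int((stat['secretor'] == 'Se-').sum())} Se- ; "
        f"{n_le_neg} Le-"
    )
    try:
        disc = concordance_report(calls, pheno)
        save("discordance.tsv", disc.to_csv(sep="\t", index=False))
        summary_lines.append(f"genetic/phenotypic discordance: {len(disc)} sample(s)")
    except ValueError as exc:
        logger.warning("concordance skipped: %s", exc)

    # --- statistics --------------------------------------------------------
    sums = class_sums(hmo, DEFAULT_PANEL, policy="zero")
    save("class_sums.tsv", sums.to_csv(sep="\t", index=False))
    logm = log_concentration_matrix(hmo, cfg.censoring_policy, month=3)
    r, q, mask = correlation_matrix(logm)
    save("correlation_r.csv", r.to_csv())
    save("correlation_q.csv", q.to_csv())

    nodes = multiscale_bootstrap_clusters(
        logm, n_boot=cfg.cluster_n_boot, seed=cfg.seed,
        au_threshold=cfg.cluster_alpha,
    )
    clusters = supported_clusters(nodes, cfg.cluster_alpha)
    save("clusters.json", json.dumps([n.to_dict() for n in nodes], indent=2))
    summary_lines.append(f"clusters with AU >= {1 - cfg.cluster_alpha}: {len(clusters)}")

    # --- dynamics ----------------------------------------------------------
    group_map = {c.sample_id: c.milk_group for c in calls}
    dyn = dynamics_table(hmo, group_map, DEFAULT_PANEL, cfg.censoring_policy)
    save("dynamics.tsv", dyn.to_csv(sep="\t", index=False))
    if len(dyn):
        summary_lines.append(
            f"dynamics: {int(dyn['significant'].sum())} of {len(dyn)} strata at q < 0.1"
        )

    # --- predictors --------------------------------------------------------
    groups = np.array([group_map[s] for s in genotypes.sample_ids])
    known = np.array([g in (1, 2, 3, 4) for g in groups])
    X = genotypes.dosages.loc[known]
    labels = groups[known]
    logm_all = log_concentration_matrix(hmo, cfg.censoring_policy, month=3)
    common = [s for s in X.index if s in logm_all.index]
    try:
        sel = SPLSSelector(n_components=cfg.spls_components, keep_x=cfg.spls_keep)
        sel.fit(X.loc[common], logm_all.loc[common])
        mlp = train_milkgroup_mlp(
            sel.transform(X), labels, split=cfg.mlp_split, seed=cfg.seed,
            hidden_layer_size=cfg.mlp_hidden,
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("predict", str(exc)) from exc
    imp = pd.DataFrame(
        sorted(mlp.importances_.items(), key=lambda kv: -kv[1]),
        columns=["rsid", "importance"],
    )
    save("mlp_importance.tsv", imp.to_csv(sep="\t", index=False))
    save("mlp_model.json", json.dumps({
        "selected_snps": sel.selected_,
        "hidden_layer_size": cfg.mlp_hidden,
        "test_accuracy": mlp.test_accuracy_,
        "seed": cfg.seed,
    }, indent=2))
    summary_lines.append(
        f"milk-group MLP: {sel.n_selected_} SNPs selected, "
        f"test accuracy {mlp.test_accuracy_:.3f}"
    )

    # --- genetic score -----------------------------------------------------
    se_pos = [c.sample_id for c in calls if c.secretor == "Se+"]
    twofl = (
        hmo.df[(hmo.df["analyte"] == "2'FL") & (hmo.df["month"] == hmo.months[0])]
        .set_index("sample_id")["conc_mg_per_L"]
    )
    usable = [s for s in se_pos if s in twofl.index and twofl[s] > 0]
    score_out = {}
    if len(usable) >= 20:
        est = GeneticScore2FL(criterion=cfg.score_criterion, random_state=cfg.seed)
        est.fit(genotypes.dosages.loc[usable], np.log(twofl[usable].to_numpy()))
        scores = est.scores_
        pred = pd.DataFrame({
            "sample_id": usable,
            "score": scores,
            "category": [categorize_secretor_level(s) for s in scores],
        })
        save("score_predictions.tsv", pred.to_csv(sep="\t", index=False))
        save("score_model.json", est.model_.to_json())
        score_out = {"snps": est.model_.snps, "adjusted_r2": est.adjusted_r2_}
        summary_lines.append(
            f"genetic score: {len(est.model_.snps)} SNPs, "
            f"held-out adjusted R^2 {est.adjusted_r2_:.2f}"
        )
    else:
        summary_lines.append("genetic score: skipped (too few quantified secretors)")

    save("config.yaml", cfg.to_yaml())
    save("summary.txt", "\n".join(summary_lines) + "\n")
    return {
        "paths": paths,
        "qc": qc_report.to_dict(),
        "secretor_pos": n_se,
        "lewis_neg": n_le_neg,
        "mlp_accuracy": mlp.test_accuracy_,
        "score": score_out,
    }
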