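"""Reference evaluation protocols.

Each function re-runs one of the package's headline analyses under its
reference study conditions — the fixture status counts, coefficient
recovery of the polygenic score GLM, held-out milk-group MLP accuracy, and
median-regression recovery of the printed lactation trends — and returns
the measured quantities.  They are used by the acceptance checks and are
convenient entry points for calibration experiments.
"""

from __future__ import annotations

import numpy as np

from .dynamics import median_regression
from .mlp import train_milkgroup_mlp
from .panel import DEFAULT_PANEL
from .score import stepwise_glm_select
from .simulate import (
    CohortSimParams,
    make_fixture_cohort,
    simulate_cohort,
    simulate_score_cohort,
)
from .spls import SPLSSelector
from .stats import class_sums, log_concentration_matrix
from .status import call_statuses


def fixture_status_counts() -> dict[str, int]:
    """Secretor/Lewis counts of the deterministic 152-sample fixture."""
    cohort = make_fixture_cohort()
    calls = call_statuses(cohort.genotypes)
    return {
        "n_samples": len(calls),
        "secretor_pos": sum(c.secretor == "Se+" for c in calls),
        "secretor_neg": sum(c.secretor == "Se-" for c in calls),
        "lewis_neg": sum(c.lewis == "Le-" for c in calls),
    }


def glm_coefficient_recovery(
    n: int = 2000,
    n_seeds: int = 50,
    residual_sd: float = 0.2,
    base_seed: int = 0,
    rsids: tuple[str, ...] = ("rs601338", "rs28362459"),
) -> dict[str, dict[str, float]]:
    """Refit the score GLM on simulated secretor cohorts and summarise the
    recovered coefficients (mean and Monte-Carlo SE across seeds)."""
    coefs: dict[str, list[float]] = {r: [] for r in rsids}
    for k in range(n_seeds):
        X, y = simulate_score_cohort(n, seed=base_seed + k, residual_sd=residual_sd)
        _, betas, _ = stepwise_glm_select(X, y)
        for r in rsids:
            if r in betas:
                coefs[r].append(betas[r])
    out = {}
    for r, vals in coefs.items():
        arr = np.asarray(vals)
        out[r] = {
            "mean": float(arr.mean()),
            "mc_se": float(arr.std(ddof=1) / np.sqrt(len(arr))),
            "n_selected": len(arr),
        }
    return out


def mlp_accuracy_protocol(
    n: int = 500, n_seeds: int = 10, base_seed: int = 0
) -> list[float]:
    """Held-out milk-group accuracies of the sPLS+MLP pipeline on cohorts
    whose labels follow deterministically from the genotype rules."""
    accs = []
    for k in range(n_seeds):
        cohort = simulate_cohort(CohortSimParams(n_samples=n, seed=base_seed + k))
        logm = log_concentration_matrix(cohort.hmo, month=3)
        X = cohort.genotypes.dosages.loc[logm.index]
        y = cohort.truth.set_index("sample_id").loc[logm.index, "milk_group"]
        sel = SPLSSelector().fit(X, logm)
        model = train_milkgroup_mlp(
            sel.transform(X), y.to_numpy(), split=0.7, seed=base_seed + k
        )
        accs.append(model.test_accuracy_)
    return accs


def class_slope_recovery(
    n: int = 1000,
    n_seeds: int = 20,
    residual_sd: float = 0.3,
    base_seed: int = 0,
    classes: tuple[str, ...] = ("sialylated", "core"),
) -> dict[str, dict[str, float]]:
    """Median-regression recovery of the pooled class trends.

    Cohorts are generated with every analyte following its class slope
    (months 3/6/12, ``n`` samples per month, log-scale noise) and censoring
    disabled so the regression sees the full dynamic range.
    """
    slopes: dict[str, list[float]] = {c: [] for c in classes}
    for k in range(n_seeds):
        params = CohortSimParams(
            n_samples=n, seed=base_seed + k, residual_sd=residual_sd,
            uniform_class_slopes=True, panel=DEFAULT_PANEL.without_censoring(),
        )
        cohort = simulate_cohort(params)
        sums = class_sums(cohort.hmo, params.panel, policy="zero")
        months = sums["month"].to_numpy(dtype=float)
        for cls in classes:
            slope, _, _ = median_regression(months, np.log(sums[cls].to_numpy()))
            slopes[cls].append(slope)
    return {
        c: {
            "mean": float(np.mean(v)),
            "mc_se": float(np.std(v, ddof=1) / np.sqrt(len(v))),
        }
        for c, v in slopes.items()
    }


def hmo_slope_recovery(
    analytes: tuple[str, ...] = ("6'SL", "3FL"),
    milk_group: int = 1,
    n_per_month: int = 500,
    n_seeds: int = 20,
    residual_sd: float = 0.3,
    base_seed: int = 0,
) -> dict[str, dict[str, float]]:
    """Median-regression recovery of printed per-analyte trends within one
    milk group (censoring disabled; cohorts over-sampled so the stratum
    holds ``n_per_month`` mothers)."""
    # group 1 is ~70% of mothers at the panel MAFs
    n_total = int(np.ceil(n_per_month / 0.6))
    slopes: dict[str, list[float]] = {a: [] for a in analytes}
    for k in range(n_seeds):
        params = CohortSimParams(
            n_samples=n_total, seed=base_seed + k, residual_sd=residual_sd,
            panel=DEFAULT_PANEL.without_censoring(),
        )
        cohort = simulate_cohort(params)
        members = cohort.truth.loc[
            cohort.truth["milk_group"] == milk_group, "sample_id"
        ].head(n_per_month)
        df = cohort.hmo.df
        for analyte in analytes:
            sub = df[(df["analyte"] == analyte) & df["sample_id"].isin(members)]
            slope, _, _ = median_regression(
                sub["month"].to_numpy(dtype=float),
                np.log(sub["conc_mg_per_L"].to_numpy()),
            )
            slopes[analyte].append(slope)
    return {
        a: {
            "mean": float(np.mean(v)),
            "mc_se": float(np.std(v, ddof=1) / np.sqrt(len(v))),
        }
        for a, v in slopes.items()
    }
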