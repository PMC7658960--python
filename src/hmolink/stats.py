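"""Panel statistics: censoring substitution, class sums, group comparisons
and the correlation matrix with FDR control."""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .hmotable import HMOTable
from .panel import DEFAULT_PANEL, HMOPanel

#: Offset added before log-transforming when the substitution policy can
#: produce exact zeros.
LOG_OFFSET_MG_PER_L = 1.0

_POLICIES = ("zero", "half_loq", "loq_over_sqrt2")


def substitute_censored(
    table: HMOTable, policy: str = "half_loq", panel: HMOPanel = DEFAULT_PANEL
) -> pd.DataFrame:
    """Replace left-censored values for downstream numeric analysis.

    Policies act on records flagged ``below_loq`` or ``below_lod``:
    ``zero`` -> 0 mg/L, ``half_loq`` -> LoQ/2, ``loq_over_sqrt2`` ->
    LoQ/sqrt(2).  Quantified records are untouched.  Returns a copy of the
    tidy table with a ``value`` column holding the substituted concentration.
    """
    if policy not in _POLICIES:
        raise ValueError(f"unknown censoring policy {policy!r}; use one of {_POLICIES}")
    df = table.df.copy()
    loq = df["analyte"].map(panel.loq_map).astype(float)
    censored = df["flag"] != "quantified"
    value = df["conc_mg_per_L"].astype(float).copy()
    if policy == "zero":
        value[censored] = 0.0
    elif policy == "half_loq":
        value[censored] = loq[censored] / 2.0
    else:
        value[censored] = loq[censored] / np.sqrt(2.0)
    df["value"] = value
    return df


def log_transform(values: pd.Series | np.ndarray) -> np.ndarray:
    """Natural log, with exact zeros replaced by a 1 mg/L floor.

    Only the zero entries are floored so quantified values keep their exact
    log concentration (an additive offset on every value would distort
    fitted time trends).
    """
    v = np.asarray(values, dtype=float)
    if (v < 0).any():
        raise ValueError("negative concentrations cannot be log-transformed")
    return np.log(np.where(v == 0.0, LOG_OFFSET_MG_PER_L, v))


def log_concentration_matrix(
    table: HMOTable, policy: str = "half_loq", panel: HMOPanel = DEFAULT_PANEL,
    month: int | None = None,
) -> pd.DataFrame:
    """Sample x analyte matrix of log concentrations after substitution."""
    df = substitute_censored(table, policy, panel)
    if month is not None:
        df = df[df["month"] == month]
    wide = df.pivot_table(index="sample_id", columns="analyte", values="value",
                          aggfunc="first")
    return pd.DataFrame(
        log_transform(wide.to_numpy()), index=wide.index, columns=wide.columns
    )


def class_sums(
    table: HMOTable, panel: HMOPanel = DEFAULT_PANEL, policy: str = "zero"
) -> pd.DataFrame:
    """Per-(sample, month) sums of core / fucosylated / sialylated / total.

    Censored records contribute per the substitution ``policy`` (default:
    zero, i.e. absent analytes add nothing).  Total is the sum of the three
    class sums.

    Raises
    ------
    ValueError
        If any panel analyte is missing for a (sample, month) cell.
    """
    df = substitute_censored(table, policy, panel)
    counts = df.groupby(["sample_id", "month"])["analyte"].nunique()
    incomplete = counts[counts < len(panel.analytes)]
    if len(incomplete):
        sid, month = incomplete.index[0]
        have = set(df[(df["sample_id"] == sid) & (df["month"] == month)]["analyte"])
        missing = sorted(set(panel.analytes) - have)
        raise ValueError(
            f"sample {sid} month {month} missing analytes: {missing[:5]}"
        )
    df["hmo_class"] = df["analyte"].map(panel.class_map)
    out = (
        df.pivot_table(index=["sample_id", "month"], columns="hmo_class",
                       values="value", aggfunc="sum")
        .reindex(columns=["core", "fucosylated", "sialylated"])
    )
    out["total"] = out.sum(axis=1)
    return out.reset_index()


def mann_whitney(
    group_a: Sequence[float], group_b: Sequence[float], mode: str = "auto"
) -> tuple[float, float]:
    """Mann-Whitney U (statistic of group A) with a two-sided p-value.

    ``mode='exact'`` enumerates the exact null distribution (valid without
    ties), ``'normal_approx'`` uses the tie-corrected normal approximation
    with continuity correction, ``'auto'`` picks exact for
    ``min(n_a, n_b) <= 8`` with no ties and the approximation otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    if mode == "auto":
        mode = "exact" if (min(a.size, b.size) <= 8 and not has_ties) else "normal_approx"
    if mode == "exact":
        if has_ties:
            raise ValueError("exact Mann-Whitney p-value is undefined with ties")
        method = "exact"
    elif mode == "normal_approx":
        method = "asymptotic"
    else:
        raise ValueError(f"unknown mode {mode!r}")
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def benjamini_hochberg(pvals: Sequence[float]) -> np.ndarray:
    """BH step-up adjusted p-values (q-values)."""
    return multipletests(np.asarray(pvals, dtype=float), method="fdr_bh")[1]


def correlation_matrix(
    log_table: pd.DataFrame, display_alpha: float = 0.001
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations with BH-adjusted p-values.

    Parameters
    ----------
    log_table : DataFrame
        Sample x analyte log concentrations.
    display_alpha : float
        Threshold for the boolean display mask (adjusted p < alpha).

    Returns
    -------
    (r, q, mask)
        Symmetric correlation matrix with unit diagonal, BH-adjusted
        p-value matrix (adjustment over the strict upper triangle), and the
        display mask.  Constant columns yield NaN correlations and a
        False mask.
    """
    cols = list(log_table.columns)
    k = len(cols)
    r = np.eye(k)
    p = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            x = log_table.iloc[:, i].to_numpy(dtype=float)
            y = log_table.iloc[:, j].to_numpy(dtype=float)
            ok = ~(np.isnan(x) | np.isnan(y))
            if ok.sum() < 3 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
                r[i, j] = r[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
                continue
            rr, pp = sps.pearsonr(x[ok], y[ok])
            r[i, j] = r[j, i] = rr
            p[i, j] = p[j, i] = pp
    iu = np.triu_indices(k, 1)
    raw = p[iu]
    q = np.full((k, k), np.nan)
    finite = ~np.isnan(raw)
    adj = np.full(raw.shape, np.nan)
    if finite.any():
        adj[finite] = benjamini_hochberg(raw[finite])
    q[iu] = adj
    q.T[iu] = adj
    np.fill_diagonal(q, 0.0)
    mask = np.zeros((k, k), dtype=bool)
    with np.errstate(invalid="ignore"):
        mask[~np.isnan(q)] = q[~np.isnan(q)] < display_alpha
    np.fill_diagonal(mask, True)
    rf = pd.DataFrame(r, index=cols, columns=cols)
    qf = pd.DataFrame(q, index=cols, columns=cols)
    mf = pd.DataFrame(mask, index=cols, columns=cols)
    return rf, qf, mf


def group_comparison_table(
    table: HMOTable,
    groups: dict[str, int | str],
    panel: HMOPanel = DEFAULT_PANEL,
    month: int = 3,
    alpha: float = 0.0001,
    policy: str = "half_loq",
) -> pd.DataFrame:
    """Pairwise Mann-Whitney comparisons of each analyte across milk groups.

    Only significant comparisons (two-sided p below ``alpha``) are retained,
    mirroring the reference analysis protocol.
    """
    df = substitute_censored(table, policy, panel)
    df = df[df["month"] == month].copy()
    df["group"] = df["sample_id"].map(groups)
    rows = []
    levels = sorted(g for g in df["group"].dropna().unique())
    for analyte, sub in df.groupby("analyte"):
        for i, g1 in enumerate(levels):
            for g2 in levels[i + 1:]:
                a = sub.loc[sub["group"] == g1, "value"].to_numpy()
                b = sub.loc[sub["group"] == g2, "value"].to_numpy()
                if len(a) == 0 or len(b) == 0:
                    continue
                u, pval = mann_whitney(a, b, mode="normal_approx")
                if pval < alpha:
                    rows.append({"analyte": analyte, "group_a": g1, "group_b": g2,
                                 "U": u, "p": pval,
                                 "median_a": float(np.median(a)),
                                 "median_b": float(np.median(b))})
    return pd.DataFrame(rows, columns=["analyte", "group_a", "group_b", "U", "p",
                                       "median_a", "median_b"])
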