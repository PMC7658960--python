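"""Multiscale-bootstrap cluster support for HMO correlation structure.

Analytes are clustered by complete linkage on the distance ``1 - r``
(Pearson correlation of log concentrations).  Support for every internal
node of the dendrogram is assessed by multiscale bootstrap: samples
(mothers) are resampled with replacement at several sizes ``n' = rho * n``,
the clustering is recomputed per replicate, and the bootstrap probability
(BP) of the node is recorded per scale.  The approximately unbiased (AU)
p-value is obtained from the scale dependence of BP by weighted least
squares on the probit scale: with ``sigma = sqrt(n / n')``,

    Phi^-1(1 - BP(sigma)) = v * sigma + c / sigma,      AU = 1 - Phi(v - c),

where ``v`` and ``c`` estimate the signed distance and curvature of the
cluster's region boundary.  Clusters with ``AU >= 1 - alpha`` are reported
as supported at level ``alpha``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.stats import norm

DEFAULT_SCALES = tuple(np.round(np.arange(0.5, 1.45, 0.1), 2))


@dataclass
class ClusterNode:
    """One internal dendrogram node with its bootstrap support."""

    members: tuple[str, ...]
    height: float
    bp: dict[float, float] = field(default_factory=dict)
    au: float = float("nan")
    is_root: bool = False

    def to_dict(self) -> dict:
        return {
            "members": list(self.members),
            "height": self.height,
            "bp": {str(k): v for k, v in self.bp.items()},
            "au": self.au,
        }


def _correlation_distance(x: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x, rowvar=False)
    r = np.nan_to_num(r, nan=0.0)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    return d


def _node_sets(x: np.ndarray, method: str) -> list[frozenset[int]]:
    """Member-index sets of every internal node of the dendrogram of x."""
    d = _correlation_distance(x)
    k = d.shape[0]
    iu = np.triu_indices(k, 1)
    z = linkage(d[iu], method=method)
    sets: list[frozenset[int]] = [frozenset([i]) for i in range(k)]
    out = []
    for a, b, _, _ in z:
        merged = sets[int(a)] | sets[int(b)]
        sets.append(merged)
        out.append(merged)
    return out


def _au_from_bp(bps: dict[float, float], n_boot: int) -> float:
    """Probit-curve extrapolation of multiscale bootstrap probabilities."""
    lo, hi = 1.0 / (2 * n_boot), 1.0 - 1.0 / (2 * n_boot)
    clipped = {s: min(max(bp, lo), hi) for s, bp in bps.items()}
    if all(bp >= hi for bp in bps.values()):
        return 1.0
    if all(bp <= lo for bp in bps.values()):
        return 0.0
    sigmas = np.array([np.sqrt(1.0 / s) for s in clipped])  # sqrt(n / n')
    z = norm.ppf(1.0 - np.array(list(clipped.values())))
    bp_arr = np.array(list(clipped.values()))
    w = n_boot * norm.pdf(z) ** 2 / (bp_arr * (1.0 - bp_arr))
    X = np.column_stack([sigmas, 1.0 / sigmas])
    W = np.diag(w)
    try:
        beta = np.linalg.solve(X.T @ W @ X, X.T @ W @ z)
    except np.linalg.LinAlgError:
        return float("nan")
    v, c = beta
    return float(1.0 - norm.cdf(v - c))


def multiscale_bootstrap_clusters(
    log_table: pd.DataFrame,
    n_boot: int = 1000,
    scales: tuple[float, ...] = DEFAULT_SCALES,
    linkage_method: str = "complete",
    au_threshold: float = 0.05,
    seed: int | None = None,
) -> list[ClusterNode]:
    """Dendrogram nodes of the analyte clustering with BP and AU support.

    Parameters
    ----------
    log_table : DataFrame
        Sample x analyte log concentrations (columns are sorted
        lexicographically internally so dendrogram ties break by analyte
        name).
    n_boot : int
        Bootstrap replicates per scale (>= 100).
    scales : tuple of float
        Resampling ratios ``n'/n``.
    au_threshold : float
        Significance level alpha; clusters with ``AU >= 1 - alpha`` are
        flagged supported.
    seed : int, optional
        RNG seed for the resampling.

    Returns
    -------
    list of ClusterNode
        One entry per internal node, in merge order; the root carries
        ``au = 1`` by convention.
    """
    if log_table.shape[1] < 2:
        raise ValueError("need at least two analytes to cluster")
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    cols = sorted(log_table.columns)
    x = log_table[cols].to_numpy(dtype=float)
    n = x.shape[0]

    observed = _node_sets(x, linkage_method)
    d = _correlation_distance(x)
    iu = np.triu_indices(len(cols), 1)
    heights = linkage(d[iu], method=linkage_method)[:, 2]

    rng = np.random.default_rng(seed)
    counts = {s: np.zeros(len(observed)) for s in scales}
    obs_index = {node: i for i, node in enumerate(observed)}
    for s in scales:
        m = max(3, int(round(s * n)))
        for _ in range(n_boot):
            idx = rng.integers(0, n, size=m)
            for node in _node_sets(x[idx], linkage_method):
                j = obs_index.get(node)
                if j is not None:
                    counts[s][j] += 1

    nodes = []
    for i, members in enumerate(observed):
        bps = {s: counts[s][i] / n_boot for s in scales}
        is_root = len(members) == len(cols)
        au = 1.0 if is_root else _au_from_bp(bps, n_boot)
        nodes.append(
            ClusterNode(
                members=tuple(sorted(cols[j] for j in members)),
                height=float(heights[i]),
                bp=bps,
                au=au,
                is_root=is_root,
            )
        )
    return nodes


def supported_clusters(
    nodes: list[ClusterNode], au_threshold: float = 0.05
) -> list[ClusterNode]:
    """Non-root nodes whose AU support rejects at the given level."""
    return [nd for nd in nodes if not nd.is_root and nd.au >= 1.0 - au_threshold]
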