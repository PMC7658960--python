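"""Sparse partial least squares (sPLS) selection of SNPs against the HMO matrix.

Each component takes the dominant singular pair of the column-centred
cross-covariance ``X^T Y``, soft-thresholds the SNP-side weight vector so a
fixed number of SNPs keeps nonzero loading, and deflates both matrices on
the component score before extracting the next component.  The selected set
is the union of SNPs with nonzero loading on any component.  With the
keep-count equal to the number of SNP columns no thresholding occurs and
the loadings coincide with dense PLS-SVD weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted


def _soft_threshold_keep(u: np.ndarray, keep: int) -> np.ndarray:
    """Soft-threshold ``u`` so at most ``keep`` entries stay nonzero."""
    if keep >= u.size:
        return u.copy()
    mags = np.sort(np.abs(u))[::-1]
    lam = mags[keep]  # the (keep+1)-th largest magnitude
    out = np.sign(u) * np.maximum(np.abs(u) - lam, 0.0)
    return out


class SPLSSelector(BaseEstimator, TransformerMixin):
    """sPLS-based SNP selection transformer.

    Parameters
    ----------
    n_components : int
        Number of sparse components to extract.
    keep_x : int
        SNPs retained (nonzero loading) per component.
    max_iter, tol : int, float
        Alternating power-iteration controls per component.

    Attributes
    ----------
    x_loadings_ : ndarray of shape (p, n_components)
        Sparse SNP-side weight vectors (unit norm over nonzero support).
    y_loadings_ : ndarray of shape (q, n_components)
    selected_ : list of str
        SNP names with nonzero loading on any component, in column order.
    n_selected_ : int
    """

    def __init__(self, n_components: int = 2, keep_x: int = 8,
                 max_iter: int = 200, tol: float = 1e-10):
        self.n_components = n_components
        self.keep_x = keep_x
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, Y):
        Xd = pd.DataFrame(X)
        Yd = pd.DataFrame(Y)
        if Xd.shape[0] != Yd.shape[0]:
            raise ValueError("X and Y must have matching samples")
        if self.keep_x > Xd.shape[1]:
            raise ValueError(
                f"keep_x={self.keep_x} exceeds the {Xd.shape[1]} SNP columns"
            )
        self.feature_names_in_ = np.asarray(Xd.columns.astype(str))
        Xc = Xd.to_numpy(dtype=float)
        Yc = Yd.to_numpy(dtype=float)
        Xc = Xc - Xc.mean(axis=0)
        Yc = Yc - Yc.mean(axis=0)

        p, q = Xc.shape[1], Yc.shape[1]
        U = np.zeros((p, self.n_components))
        V = np.zeros((q, self.n_components))
        for k in range(self.n_components):
            M = Xc.T @ Yc
            uu, _, vv = np.linalg.svd(M, full_matrices=False)
            u, v = uu[:, 0], vv[0, :]
            for _ in range(self.max_iter):
                u_new = _soft_threshold_keep(M @ v, self.keep_x)
                nrm = np.linalg.norm(u_new)
                if nrm == 0:
                    break
                u_new /= nrm
                v_new = M.T @ u_new
                v_new /= np.linalg.norm(v_new) or 1.0
                if np.linalg.norm(u_new - u) < self.tol:
                    u, v = u_new, v_new
                    break
                u, v = u_new, v_new
            U[:, k], V[:, k] = u, v
            t = Xc @ u
            tt = float(t @ t)
            if tt > 0:  # deflate both blocks on the component score
                Xc = Xc - np.outer(t, (t @ Xc) / tt)
                Yc = Yc - np.outer(t, (t @ Yc) / tt)

        self.x_loadings_ = U
        self.y_loadings_ = V
        mask = (np.abs(U) > 0).any(axis=1)
        self.selected_ = [str(c) for c, m in zip(self.feature_names_in_, mask) if m]
        self.n_selected_ = len(self.selected_)
        return self

    def transform(self, X):
        check_is_fitted(self)
        Xd = pd.DataFrame(X)
        return Xd[[c for c in Xd.columns.astype(str) if c in set(self.selected_)]]


@dataclass
class SelectionResult:
    """Outcome of one sPLS selection run."""

    selected_snps: list[str]
    component_loadings: np.ndarray
    n_selected: int


def spls_select(
    snp_matrix: pd.DataFrame,
    hmo_matrix: pd.DataFrame,
    n_components: int = 2,
    keep_per_component: int = 8,
) -> SelectionResult:
    """Functional wrapper over :class:`SPLSSelector`."""
    sel = SPLSSelector(n_components=n_components, keep_x=keep_per_component)
    sel.fit(snp_matrix, hmo_matrix)
    return SelectionResult(
        selected_snps=sel.selected_,
        component_loadings=sel.x_loadings_,
        n_selected=sel.n_selected_,
    )
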