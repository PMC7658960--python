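"""Polygenic score for 2'FL concentration in secretor milk.

SNP selection is bidirectional stepwise search over Gaussian GLMs
(identity link on natural-log 2'FL, equivalent to OLS), starting from the
intercept-only model and minimising an information criterion (AIC by
default).  The genetic score of a mother is the *signed allele sum*
``sum_s sign(beta_s) * dosage_s`` over the selected SNPs: alleles that
increase 2'FL count +1 per copy and alleles that decrease it count -1, so
the score of an all-major-homozygote is 0, positive scores predict high and
zero-or-negative scores moderate 2'FL.  A beta-weighted variant
(``sum beta_s * dosage_s``) is available through ``score_mode``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)

#: SNPs of the published reference score model, in reported order.
REFERENCE_SCORE_SNPS = ("rs601338", "rs28362459", "rs778986", "rs1800022", "rs281377")


def _ic(model, criterion: str) -> float:
    return model.aic if criterion == "aic" else model.bic


def stepwise_glm_select(
    dosages: pd.DataFrame,
    response: pd.Series | np.ndarray,
    criterion: str = "aic",
) -> tuple[list[str], dict[str, float], dict[str, float]]:
    """Bidirectional stepwise OLS selection from the intercept-only model.

    Returns ``(selected_rsids, betas, standard_errors)``.  Perfectly
    collinear (duplicated) columns are dropped up front, keeping the
    earlier-ordered one.
    """
    if criterion not in ("aic", "bic"):
        raise ValueError("criterion must be 'aic' or 'bic'")
    X = dosages.astype(float).copy()
    y = np.asarray(response, dtype=float)

    # drop later-ordered duplicates (perfect collinearity)
    drop = []
    cols = list(X.columns)
    for i, a in enumerate(cols):
        for b in cols[:i]:
            if b not in drop and np.allclose(X[a], X[b]):
                drop.append(a)
                logger.warning("dropping %s: perfectly collinear with %s", a, b)
                break
    X = X.drop(columns=drop)

    def fit(cols: Sequence[str]):
        design = sm.add_constant(X[list(cols)], has_constant="add")
        return sm.OLS(y, design).fit()

    included: list[str] = []
    current = fit(included)
    current_ic = _ic(current, criterion)
    while True:
        moves = []
        for c in X.columns:
            if c not in included:
                m = fit(included + [c])
                moves.append((_ic(m, criterion), "add", c, m))
        for c in included:
            m = fit([k for k in included if k != c])
            moves.append((_ic(m, criterion), "drop", c, m))
        if not moves:
            break
        best_ic, action, col, model = min(moves, key=lambda t: t[0])
        if best_ic >= current_ic - 1e-9:
            break
        if action == "add":
            included.append(col)
        else:
            included.remove(col)
        current, current_ic = model, best_ic

    betas = {c: float(current.params[c]) for c in included}
    ses = {c: float(current.bse[c]) for c in included}
    return included, betas, ses


def compute_genetic_score(
    dosages: Mapping[str, float] | pd.Series,
    betas: Mapping[str, float],
    score_mode: str = "signed_sum",
) -> float:
    """Genetic score of one sample from its dosages at the model SNPs.

    ``signed_sum`` (default) counts each minor-allele copy with the sign of
    its coefficient, yielding an integer; ``beta_weighted`` returns
    ``sum beta_s * dosage_s``.

    Raises
    ------
    KeyError
        If a model SNP is missing from the dosage map.
    """
    if score_mode not in ("signed_sum", "beta_weighted"):
        raise ValueError(f"unknown score_mode {score_mode!r}")
    total = 0.0
    for rsid, beta in betas.items():
        if rsid not in dosages:
            raise KeyError(f"dosage for model SNP {rsid} missing")
        d = float(dosages[rsid])
        total += (np.sign(beta) * d) if score_mode == "signed_sum" else beta * d
    return float(total)


def categorize_secretor_level(score: float) -> str:
    """``high`` for a positive score, ``moderate`` for zero or negative."""
    return "high" if score > 0 else "moderate"


def adjusted_r2(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Adjusted R^2 of a one-regressor prediction on held-out data."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    n = len(y_true)
    ss_res = float(np.sum((y_true - y_pred) ** 2))
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    return 1.0 - (1.0 - r2) * (n - 1) / (n - 2)


def fit_score_regression(
    scores: Sequence[float],
    log_conc: Sequence[float],
    split: float = 0.7,
    seed: int = 0,
) -> dict:
    """OLS of log 2'FL on the genetic score with held-out evaluation.

    Fits on a random ``split`` fraction and reports the adjusted R^2 of the
    predictions on the remaining test samples.

    Raises
    ------
    ValueError
        For a constant score vector or fewer than 10 training samples.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(log_conc, dtype=float)
    if np.unique(s).size < 2:
        raise ValueError("constant score vector; regression undefined")
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(s))
    n_train = int(round(split * len(s)))
    tr, te = idx[:n_train], idx[n_train:]
    if len(tr) < 10:
        raise ValueError("need at least 10 training samples")
    design = sm.add_constant(s[tr])
    ols = sm.OLS(y[tr], design).fit()
    intercept, slope = float(ols.params[0]), float(ols.params[1])
    pred = intercept + slope * s[te]
    return {
        "intercept": intercept,
        "slope": slope,
        "adjusted_r2": adjusted_r2(y[te], pred) if len(te) > 2 else float("nan"),
        "n_train": int(len(tr)),
        "n_test": int(len(te)),
    }


def cross_validate_score_regression(
    scores: Sequence[float],
    log_conc: Sequence[float],
    repeats: int = 20,
    folds: int = 10,
    seed: int = 0,
) -> float:
    """Mean held-out R^2 of the score regression over repeated K-fold CV."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(log_conc, dtype=float)
    rng = np.random.default_rng(seed)
    r2s = []
    for _ in range(repeats):
        perm = rng.permutation(len(s))
        for fold in range(folds):
            te = perm[fold::folds]
            tr = np.setdiff1d(perm, te)
            if np.unique(s[tr]).size < 2 or len(te) < 3:
                continue
            design = sm.add_constant(s[tr])
            ols = sm.OLS(y[tr], design).fit()
            pred = ols.params[0] + ols.params[1] * s[te]
            ss_res = np.sum((y[te] - pred) ** 2)
            ss_tot = np.sum((y[te] - y[te].mean()) ** 2)
            if ss_tot > 0:
                r2s.append(1.0 - ss_res / ss_tot)
    return float(np.mean(r2s))


@dataclass
class ScoreModel:
    """Selected SNPs, coefficients and the score -> log 2'FL regression."""

    snps: list[str]
    betas: dict[str, float]
    standard_errors: dict[str, float] = field(default_factory=dict)
    score_mode: str = "signed_sum"
    regression: Optional[dict] = None

    @property
    def signs(self) -> dict[str, int]:
        return {r: int(np.sign(b)) for r, b in self.betas.items()}

    def score(self, dosages: Mapping[str, float]) -> float:
        return compute_genetic_score(dosages, self.betas, self.score_mode)

    def categorize(self, dosages: Mapping[str, float]) -> str:
        return categorize_secretor_level(self.score(dosages))

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(
            {
                "snps": self.snps,
                "betas": self.betas,
                "standard_errors": self.standard_errors,
                "score_mode": self.score_mode,
                "regression": self.regression,
            },
            indent=indent,
        )

    @classmethod
    def from_json(cls, text: str) -> "ScoreModel":
        d = json.loads(text)
        return cls(
            snps=d["snps"],
            betas=d["betas"],
            standard_errors=d.get("standard_errors", {}),
            score_mode=d.get("score_mode", "signed_sum"),
            regression=d.get("regression"),
        )


class GeneticScore2FL(BaseEstimator, RegressorMixin):
    """End-to-end estimator: stepwise SNP selection, signed-allele-sum score
    and score regression predicting log 2'FL for secretor mothers.

    Parameters
    ----------
    criterion : {"aic", "bic"}
        Information criterion of the stepwise search.
    score_mode : {"signed_sum", "beta_weighted"}
    split : float
        Training fraction for the internal score-regression evaluation.
    random_state : int

    Attributes
    ----------
    model_ : ScoreModel
    adjusted_r2_ : float
        Held-out adjusted R^2 of the score regression.
    """

    def __init__(self, criterion: str = "aic", score_mode: str = "signed_sum",
                 split: float = 0.7, random_state: int = 0):
        self.criterion = criterion
        self.score_mode = score_mode
        self.split = split
        self.random_state = random_state

    def fit(self, X, y):
        Xd = pd.DataFrame(X)
        snps, betas, ses = stepwise_glm_select(Xd, y, self.criterion)
        scores = np.array(
            [compute_genetic_score(row, betas, self.score_mode)
             for _, row in Xd.iterrows()]
        ) if snps else np.zeros(len(Xd))
        reg = None
        if snps and np.unique(scores).size > 1:
            reg = fit_score_regression(scores, np.asarray(y, dtype=float),
                                       self.split, self.random_state)
        self.model_ = ScoreModel(snps, betas, ses, self.score_mode, reg)
        self.scores_ = scores
        self.adjusted_r2_ = reg["adjusted_r2"] if reg else float("nan")
        self.n_features_in_ = Xd.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        Xd = pd.DataFrame(X)
        reg = self.model_.regression
        if reg is None:
            raise ValueError("score regression unavailable (empty model)")
        s = np.array([self.model_.score(row) for _, row in Xd.iterrows()])
        return reg["intercept"] + reg["slope"] * s
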