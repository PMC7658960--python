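"""Milk-group prediction with a single-hidden-layer perceptron and
weight-based (Garson) variable importance."""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import accuracy_score
from sklearn.neural_network import MLPClassifier
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)

#: rsID named in the reference analysis that is not on the variant panel;
#: accepted when present, otherwise ignored.
OPTIONAL_SNPS = ("rs3760776",)


class MilkGroupMLP(BaseEstimator, ClassifierMixin):
    """Single-hidden-layer softmax network over SNP dosages.

    Dosage thresholds (homozygous minor vs carrier) are sharp decision
    boundaries, and the rarer milk groups contribute only a handful of
    training genotype patterns, so the defaults favour robust
    generalisation: 16 ReLU hidden units trained full-batch with L-BFGS
    under moderate L2 decay (alpha = 0.01), which smooths the fitted
    thresholds across unseen dosage combinations.  Fixed seeds give
    bit-identical weights.

    Parameters
    ----------
    hidden_layer_size : int
        Units in the single hidden layer.
    activation : str
        Hidden-unit nonlinearity.
    alpha : float
        L2 weight decay.
    max_iter : int
        Iteration cap for the solver.
    random_state : int

    Attributes
    ----------
    classes_ : ndarray
        Milk-group labels.
    importances_ : dict
        Garson importance fraction per input SNP (sums to 1).
    """

    def __init__(self, hidden_layer_size: int = 16, activation: str = "relu",
                 alpha: float = 1e-2, max_iter: int = 20000,
                 random_state: int = 0):
        self.hidden_layer_size = hidden_layer_size
        self.activation = activation
        self.alpha = alpha
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y):
        Xd = pd.DataFrame(X)
        self.feature_names_in_ = np.asarray(Xd.columns.astype(str))
        self.net_ = MLPClassifier(
            hidden_layer_sizes=(self.hidden_layer_size,),
            activation=self.activation,
            solver="lbfgs",
            alpha=self.alpha,
            max_iter=self.max_iter,
            random_state=self.random_state,
        )
        self.net_.fit(Xd.to_numpy(dtype=float), np.asarray(y))
        self.classes_ = self.net_.classes_
        self.importances_ = dict(
            zip(self.feature_names_in_,
                garson_importance(self.net_.coefs_[0], self.net_.coefs_[1]))
        )
        return self

    def predict(self, X):
        check_is_fitted(self, "net_")
        return self.net_.predict(pd.DataFrame(X).to_numpy(dtype=float))

    def predict_proba(self, X):
        check_is_fitted(self, "net_")
        return self.net_.predict_proba(pd.DataFrame(X).to_numpy(dtype=float))

    @property
    def input_to_hidden_(self) -> np.ndarray:
        return self.net_.coefs_[0]

    @property
    def hidden_to_output_(self) -> np.ndarray:
        return self.net_.coefs_[1]


def garson_importance(w_in: np.ndarray, w_out: np.ndarray) -> np.ndarray:
    """Garson variable importance from network weight products.

    ``importance_i = sum_h sum_o |w_ih * w_ho|``, normalised to sum to 1.

    Raises
    ------
    ValueError
        If the weights are degenerate (all zero).
    """
    contrib = np.abs(w_in) @ np.abs(w_out)  # (p, o)
    raw = contrib.sum(axis=1)
    total = raw.sum()
    if total == 0:
        raise ValueError("degenerate zero-weight network: importance undefined")
    return raw / total


def stratified_split(
    labels: Sequence, train_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Per-class split keeping at least one sample of each class in training.

    Classes with a single member go entirely to training (they cannot be
    stratified).
    """
    y = np.asarray(labels)
    train_idx, test_idx = [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        if len(idx) == 1:
            train_idx.extend(idx)
            continue
        k = max(1, int(round(train_fraction * len(idx))))
        k = min(k, len(idx) - 1)  # keep at least one test sample
        train_idx.extend(idx[:k])
        test_idx.extend(idx[k:])
    return np.sort(np.array(train_idx)), np.sort(np.array(test_idx))


def train_milkgroup_mlp(
    genotypes: pd.DataFrame,
    labels: Sequence,
    split: float = 0.7,
    seed: int = 0,
    hidden_layer_size: int = 16,
    extra_snps: Optional[pd.DataFrame] = None,
) -> MilkGroupMLP:
    """Train the milk-group MLP on a stratified split and score held-out data.

    Parameters
    ----------
    genotypes : DataFrame
        Sample x SNP dosage matrix (typically the sPLS-selected SNPs).
    labels : sequence
        Milk-group label per sample.
    split : float
        Training fraction of the stratified split.
    seed : int
        Seed for the split and the network initialisation.
    extra_snps : DataFrame, optional
        Additional optional dosage columns to append when supplied.

    Returns
    -------
    MilkGroupMLP
        Fitted model with ``test_accuracy_`` on the held-out split.
    """
    X = genotypes.copy()
    if extra_snps is not None:
        for c in extra_snps.columns:
            if c in OPTIONAL_SNPS:
                X[c] = extra_snps[c]
            else:
                logger.warning("ignoring unrecognised optional SNP column %s", c)
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("need at least two milk-group classes to train")
    rng = np.random.default_rng(seed)
    tr, te = stratified_split(y, split, rng)
    if len(te) == 0:
        raise ValueError("stratified split left no test samples")
    model = MilkGroupMLP(hidden_layer_size=hidden_layer_size, random_state=seed)
    model.fit(X.iloc[tr], y[tr])
    model.test_accuracy_ = float(
        accuracy_score(y[te], model.predict(X.iloc[te]))
    )
    model.train_index_ = tr
    model.test_index_ = te
    return model
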