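"""Embedded feature selection with L1-penalized (multinomial) logistic regression.

The penalty strength is chosen by cross-validated deviance over a log-spaced
path; features are then ranked by the largest absolute coefficient across
classes at the selected penalty and the top ``k`` kept.  If fewer than ``k``
features survive with nonzero coefficients, all nonzero ones are kept and the
effective ``k`` is reduced -- recorded in the returned report rather than
raised, since an all-noise table is a legitimate input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LogisticRegressionCV

from .radiomics import FeatureTable

__all__ = ["SelectionReport", "lasso_select", "LassoFeatureSelector"]


@dataclass
class SelectionReport:
    requested_k: int
    effective_k: int
    n_nonzero: int
    penalty_C: float

    @property
    def reduced(self) -> bool:
        return self.effective_k < self.requested_k


def _fit_l1_path(X: np.ndarray, y: np.ndarray, cv: int, seed: int):
    model = LogisticRegressionCV(
        penalty="l1",
        solver="saga",
        Cs=np.logspace(-2.5, 1.5, 9),  # ascending C: ties resolve to the sparser fit
        cv=cv,
        scoring="neg_log_loss",
        max_iter=2000,
        tol=1e-3,
        random_state=seed,
        n_jobs=1,
    )
    with warnings.catch_warnings():
        # scikit-learn 1.9 deprecation chatter for the penalty/attribute API
        # transition; the l1 path itself is unaffected
        warnings.simplefilter("ignore", FutureWarning)
        model.fit(X, y)
    return model


def lasso_select(table: FeatureTable, labels: np.ndarray, k: int,
                 cv: int = 5, seed: int = 0) -> tuple[np.ndarray, SelectionReport]:
    """Select the ``k`` strongest features under an L1 logistic path.

    Returns ``(indices, report)`` where ``indices`` are column indices into the
    table ordered by decreasing maximum absolute coefficient.  The table should
    be standardized on the fitting split (the penalty is scale-sensitive).
    """
    labels = np.asarray(labels)
    n_features = table.values.shape[1]
    if k < 1 or k > n_features:
        raise ValueError(f"k must be in [1, {n_features}], got {k}")
    if len(np.unique(labels)) < 2:
        raise ValueError("labels must contain at least two classes")
    model = _fit_l1_path(table.values, labels, cv=cv, seed=seed)
    strength = np.max(np.abs(model.coef_), axis=0)
    nonzero = np.flatnonzero(strength > 1e-8)
    order = nonzero[np.argsort(strength[nonzero])[::-1]]
    effective_k = min(k, len(order))
    indices = order[:effective_k]
    report = SelectionReport(
        requested_k=k,
        effective_k=effective_k,
        n_nonzero=len(nonzero),
        penalty_C=float(np.atleast_1d(model.C_)[0]),
    )
    return indices, report


class LassoFeatureSelector:
    """Sklearn-style selector wrapping :func:`lasso_select`.

    Fitted attributes: ``selected_idx_`` (ordered kept indices), ``report_``.
    """

    def __init__(self, k: int = 100, cv: int = 5, random_state: int = 0):
        self.k = k
        self.cv = cv
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {"k": self.k, "cv": self.cv, "random_state": self.random_state}

    def set_params(self, **params) -> "LassoFeatureSelector":
        for key, value in params.items():
            setattr(self, key, value)
        return self

    def fit(self, X, y) -> "LassoFeatureSelector":
        X = np.asarray(X, dtype=float)
        table = FeatureTable(
            values=X,
            feature_names=[f"f{i}" for i in range(X.shape[1])],
            standardized=True,
        )
        k = min(self.k, X.shape[1])
        self.selected_idx_, self.report_ = lasso_select(
            table, y, k, cv=self.cv, seed=self.random_state
        )
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return X[:, self.selected_idx_]

    def fit_transform(self, X, y):
        return self.fit(X, y).transform(X)

    def get_support(self) -> np.ndarray:
        mask = np.zeros(self.n_features_in_, dtype=bool)
        mask[self.selected_idx_] = True
        return mask
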