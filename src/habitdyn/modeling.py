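"""Probabilistic next-day non-brushing classifier.

Plain maximum-likelihood logistic regression — the same learner for every
feature set, so that model comparisons reflect the features and nothing
else.  A small ridge penalty can be switched on explicitly to stabilize
perfectly separable inner-fold fits during hyperparameter search; it is off
by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

__all__ = [
    "FittedClassifier",
    "DegenerateFitError",
    "SchemaError",
    "fit_logistic",
    "predict_proba",
    "feature_importance",
]


class DegenerateFitError(ValueError):
    """Raised when the target contains a single class."""


class SchemaError(ValueError):
    """Raised when prediction-time features do not match the fit."""


@dataclass
class FittedClassifier:
    """Coefficients (log-odds units) plus fit diagnostics."""

    feature_names: list[str]
    coef: np.ndarray
    intercept: float
    converged: bool
    n_iter: int
    ridge: float = 0.0

    def to_dict(self) -> dict:
        return {
            "feature_names": list(self.feature_names),
            "coef": [float(c) for c in self.coef],
            "intercept": float(self.intercept),
            "converged": bool(self.converged),
            "n_iter": int(self.n_iter),
            "ridge": float(self.ridge),
        }


def _split_rows(
    rows: pd.DataFrame | np.ndarray, y: np.ndarray | None, feature_names
) -> tuple[np.ndarray, np.ndarray | None, list[str]]:
    if isinstance(rows, pd.DataFrame):
        if feature_names is None:
            drop = [c for c in ("participant_id", "day", "fold", "target") if c in rows.columns]
            feature_names = [c for c in rows.columns if c not in drop]
        x = rows[feature_names].to_numpy(dtype=float)
        if y is None and "target" in rows.columns:
            y = rows["target"].to_numpy(dtype=int)
        return x, y, list(feature_names)
    x = np.asarray(rows, dtype=float)
    if feature_names is None:
        feature_names = [f"x{i}" for i in range(x.shape[1])]
    return x, y, list(feature_names)


def fit_logistic(
    rows: pd.DataFrame | np.ndarray,
    y: np.ndarray | None = None,
    feature_names: list[str] | None = None,
    ridge: float = 0.0,
    max_iter: int = 500,
    tol: float = 1e-10,
) -> FittedClassifier:
    """Maximum-likelihood logistic fit.

    ``rows`` may be a feature table (with a ``target`` column) or a plain
    design matrix with ``y`` given separately.  Deterministic given the
    input.  A single-class target raises :class:`DegenerateFitError`;
    perfect separation returns a fit flagged ``converged=False``.
    """
    x, y, names = _split_rows(rows, y, feature_names)
    if y is None:
        raise ValueError("no target column found and y not given")
    y = np.asarray(y, dtype=int)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 rows to fit")
    classes = np.unique(y)
    if len(classes) < 2:
        raise DegenerateFitError(f"target contains only class {classes[0]}")
    if ridge < 0:
        raise ValueError("ridge must be >= 0")
    if ridge == 0:
        lr = LogisticRegression(penalty=None, solver="lbfgs", max_iter=max_iter, tol=tol)
    else:
        lr = LogisticRegression(
            penalty="l2", C=1.0 / ridge, solver="lbfgs", max_iter=max_iter, tol=tol
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # separation warnings become the converged flag
        lr.fit(x, y)
    n_iter = int(np.max(lr.n_iter_))
    coef = lr.coef_[0].copy()
    # under (quasi-)separation the ML optimum does not exist and coefficients
    # diverge; flag fits that ran out of iterations or drifted to absurd
    # log-odds scales
    diverged = bool(np.max(np.abs(coef)) > 1e2) and ridge == 0
    return FittedClassifier(
        feature_names=names,
        coef=coef,
        intercept=float(lr.intercept_[0]),
        converged=n_iter < max_iter and not diverged,
        n_iter=n_iter,
        ridge=ridge,
    )


def predict_proba(
    model: FittedClassifier, rows: pd.DataFrame | np.ndarray
) -> np.ndarray:
    """P(positive) per row: sigmoid of the linear predictor."""
    if isinstance(rows, pd.DataFrame):
        missing = [c for c in model.feature_names if c not in rows.columns]
        if missing:
            raise SchemaError(f"missing feature column(s): {missing}")
        x = rows[model.feature_names].to_numpy(dtype=float)
    else:
        x = np.asarray(rows, dtype=float)
        if x.shape[1] != len(model.feature_names):
            raise SchemaError(
                f"expected {len(model.feature_names)} features, got {x.shape[1]}"
            )
    z = x @ model.coef + model.intercept
    return 1.0 / (1.0 + np.exp(-z))


def feature_importance(
    model: FittedClassifier, rows: pd.DataFrame | np.ndarray
) -> dict[str, float]:
    """Standardized-coefficient importance: |coef| x feature SD over ``rows``.

    A dimensionless magnitude comparable across features on different
    scales; usually reported as ratios (e.g. habit strength vs
    accessibility).  Zero-variance features get importance 0 with a warning.
    """
    if isinstance(rows, pd.DataFrame):
        x = rows[model.feature_names].to_numpy(dtype=float)
    else:
        x = np.asarray(rows, dtype=float)
    sd = x.std(axis=0)
    if np.any(sd == 0):
        flat = [n for n, s in zip(model.feature_names, sd) if s == 0]
        warnings.warn(f"zero-variance feature(s) {flat}: importance set to 0", stacklevel=2)
    return {
        name: float(abs(c) * s)
        for name, c, s in zip(model.feature_names, model.coef, sd)
    }
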