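"""Feature standardization and L2-importance feature selection.

Selection fits one multinomial logistic regression with an L2 (ridge)
penalty on the standardized feature matrix. The L2 penalty shrinks
extreme weights and spreads weight evenly over correlated features
instead of dropping them, which suits small, noisy datasets. A
feature's importance is the mean absolute coefficient across classes;
features at or above the mean importance are kept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LogisticRegression


@dataclass
class StandardizationParams:
    """Per-feature location/scale learned from a training set.

    Zero-variance features keep ``sd = 1`` (so they pass through
    centred but unscaled) and are flagged.
    """

    mean: np.ndarray
    sd: np.ndarray
    zero_variance: np.ndarray  # boolean mask


@dataclass
class SelectionResult:
    """Importances, mean-importance threshold and the resulting mask."""

    importances: np.ndarray
    threshold: float
    mask: np.ndarray  # boolean
    names: list[str] | None = None

    @property
    def selected_names(self) -> list[str]:
        if self.names is None:
            raise ValueError("selection was run without feature names")
        return [n for n, keep in zip(self.names, self.mask) if keep]

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "n_selected": int(self.mask.sum()),
            "importances": {
                (self.names[j] if self.names else str(j)): float(v)
                for j, v in enumerate(self.importances)
            },
            "selected": self.selected_names if self.names else self.mask.tolist(),
        }


def standardize_fit(X: np.ndarray) -> StandardizationParams:
    """Learn per-column mean and (population) sd; n >= 2 required."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("standardization needs a 2-D matrix with n >= 2 rows")
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    zero_variance = sd == 0.0
    sd = np.where(zero_variance, 1.0, sd)
    return StandardizationParams(mean=mean, sd=sd, zero_variance=zero_variance)


def standardize_apply(X: np.ndarray, params: StandardizationParams) -> np.ndarray:
    """Centre and scale ``X`` with training-set parameters."""
    X = np.asarray(X, dtype=float)
    if X.shape[-1] != params.mean.shape[0]:
        raise ValueError("feature count does not match standardization params")
    return (X - params.mean) / params.sd


def l2_importances(
    X_std: np.ndarray,
    y: np.ndarray,
    C: float = 1.0,
    aggregation: str = "mean_abs",
    tol: float = 1e-8,
    max_iter: int = 5000,
) -> np.ndarray:
    """Per-feature importance from an L2-penalized logistic regression.

    One multinomial model is fit on the standardized matrix; importance
    of feature j aggregates ``|coef[class, j]|`` over classes by mean
    (default) or max. The lbfgs solver is deterministic for a fixed
    tolerance, so importances are reproducible.
    """
    X_std = np.asarray(X_std, dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("feature selection needs at least 2 classes")
    if aggregation not in ("mean_abs", "max_abs"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    # L2 penalty is the LogisticRegression default
    model = LogisticRegression(C=C, solver="lbfgs", tol=tol, max_iter=max_iter)
    model.fit(X_std, y)
    coefs = np.abs(model.coef_)
    return coefs.mean(axis=0) if aggregation == "mean_abs" else coefs.max(axis=0)


def select(importances: np.ndarray, names: list[str] | None = None) -> SelectionResult:
    """Keep every feature whose importance is >= the mean importance.

    Ties at the threshold are kept (so equal importances select
    everything rather than nothing).
    """
    importances = np.asarray(importances, dtype=float)
    if importances.size == 0:
        raise ValueError("empty importance vector")
    threshold = float(importances.mean())
    mask = importances >= threshold
    return SelectionResult(
        importances=importances, threshold=threshold, mask=mask, names=names
    )
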