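"""Gaussian naive Bayes, written out explicitly.

The classifier models each feature independently per class as a
Gaussian with the class's sample mean and (population) variance, and
empirical class frequencies as priors. The unnormalized log posterior
of class c for a feature vector x is

    log pi_c + sum_j [ -0.5 log(2 pi sigma_cj^2)
                       - (x_j - mu_cj)^2 / (2 sigma_cj^2) ]

and prediction is the arg-max over classes, ties broken by label
order. Variances are floored at a small fraction of the largest total
feature variance so a class that happens to be constant on one feature
cannot produce infinite densities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

VAR_SMOOTHING = 1e-9


@dataclass
class GNBModel:
    """Fitted per-class priors and per-(class, feature) moments."""

    labels: list
    priors: np.ndarray  # (c,)
    mu: np.ndarray  # (c, k)
    var: np.ndarray  # (c, k) floored
    eps: float

    def __post_init__(self) -> None:
        if abs(float(self.priors.sum()) - 1.0) > 1e-12:
            raise ValueError("class priors must sum to 1")
        if self.eps <= 0 or np.any(self.var < self.eps):
            raise ValueError("variances must be floored at a positive eps")

    @property
    def n_features(self) -> int:
        return self.mu.shape[1]

    def to_dict(self) -> dict:
        return {
            "labels": [str(lab) for lab in self.labels],
            "priors": self.priors.tolist(),
            "mu": self.mu.tolist(),
            "var": self.var.tolist(),
            "eps": self.eps,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_dict(cls, d: dict) -> "GNBModel":
        return cls(
            labels=list(d["labels"]),
            priors=np.asarray(d["priors"], dtype=float),
            mu=np.asarray(d["mu"], dtype=float),
            var=np.asarray(d["var"], dtype=float),
            eps=float(d["eps"]),
        )

    @classmethod
    def load(cls, path: str | Path) -> "GNBModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def gnb_fit(
    X: np.ndarray,
    y: np.ndarray,
    labels: list | None = None,
    var_smoothing: float = VAR_SMOOTHING,
) -> GNBModel:
    """Fit per-class Gaussians by sample moments.

    ``labels`` fixes the class order (defaults to sorted unique labels);
    every class present must have at least 2 samples so a variance can
    be estimated.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y)
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y lengths differ")
    present = list(np.unique(y))
    if labels is None:
        labels = present
    else:
        labels = [lab for lab in labels if lab in set(present)]
        missing = set(present) - set(labels)
        if missing:
            raise ValueError(f"labels argument omits observed classes: {sorted(map(str, missing))}")

    n, k = X.shape
    c = len(labels)
    priors = np.empty(c)
    mu = np.empty((c, k))
    var = np.empty((c, k))
    for i, lab in enumerate(labels):
        rows = X[y == lab]
        if rows.shape[0] < 2:
            raise ValueError(f"class {lab!r} has fewer than 2 samples")
        priors[i] = rows.shape[0] / n
        mu[i] = rows.mean(axis=0)
        var[i] = rows.var(axis=0)

    total_var = X.var(axis=0)
    eps = var_smoothing * float(total_var.max()) if total_var.max() > 0 else var_smoothing
    var = np.maximum(var, eps)
    return GNBModel(labels=list(labels), priors=priors, mu=mu, var=var, eps=eps)


def gnb_log_posterior(model: GNBModel, X: np.ndarray) -> np.ndarray:
    """Unnormalized per-class log posterior scores, shape (n, c)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"expected {model.n_features} features, got {X.shape[1]}"
        )
    if not np.all(np.isfinite(X)):
        raise ValueError("query matrix contains non-finite values")
    diff = X[:, None, :] - model.mu[None, :, :]  # (n, c, k)
    log_lik = -0.5 * np.sum(
        np.log(2 * np.pi * model.var)[None, :, :] + diff**2 / model.var[None, :, :],
        axis=2,
    )
    return log_lik + np.log(model.priors)[None, :]


def gnb_predict(model: GNBModel, X: np.ndarray) -> np.ndarray:
    """Arg-max of the log posterior; ties resolve to the first label."""
    scores = gnb_log_posterior(model, X)
    idx = np.argmax(scores, axis=1)
    return np.asarray([model.labels[i] for i in idx])
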