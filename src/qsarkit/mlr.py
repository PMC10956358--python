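"""Ordinary least-squares multiple linear regression and fit statistics.

The least-squares problem is solved through ``numpy.linalg.lstsq`` (SVD-based,
no explicit inversion of X'X) on the intercept-augmented design; rank
deficiency is detected before solving and reported with the offending columns
identified by pivoted QR.

Statistics reported by :func:`fit_metrics`:

* ``r2``      : 1 - SSE/SST
* ``r2_adj``  : ((n-1)*r2 - p) / (n-1-p)
* ``mse``     : SSE/n   (and ``rmse = sqrt(mse)``)
* ``f_stat``  : [SSReg/SSE] * (n-p-1)/p  (+inf at a perfect fit)
* ``s``       : residual standard deviation sqrt(SSE/(n-p-1))
* ``bic``     : Gaussian-likelihood form n*ln(SSE/n) + (p+1)*ln(n)
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np
import scipy.linalg

__all__ = ["MLRModel", "FitMetrics", "SingularDesignError", "fit_mlr", "predict", "fit_metrics"]


class SingularDesignError(ValueError):
    """Raised when the (augmented) design matrix is rank-deficient."""


@dataclass
class MLRModel:
    """Fitted linear model ``y = intercept + sum_j coef_j * x_j``."""

    intercept: float
    coefficients: dict[str, float]
    n_train: int

    def __post_init__(self) -> None:
        vals = [self.intercept, *self.coefficients.values()]
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("model parameters must be finite")

    @property
    def descriptor_names(self) -> list[str]:
        return list(self.coefficients)

    def to_json(self, path=None) -> str:
        payload = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload

    @classmethod
    def from_json(cls, source) -> "MLRModel":
        if hasattr(source, "read"):
            data = json.load(source)
        else:
            try:
                data = json.loads(source)
            except (json.JSONDecodeError, TypeError):
                with open(source) as fh:
                    data = json.load(fh)
        return cls(**data)


@dataclass
class FitMetrics:
    r2: float
    r2_adj: float
    mse: float
    rmse: float
    mae: float
    f_stat: float
    s: float
    bic: float
    n: int
    p: int

    def to_dict(self) -> dict:
        return asdict(self)


def _augment(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError(f"X must be 2-D, got shape {X.shape}")
    return np.column_stack([np.ones(X.shape[0]), X])


def _check_rank(Xa: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(Xa)
    if rank < Xa.shape[1]:
        # pivoted QR points at the dependent columns
        _, _, piv = scipy.linalg.qr(Xa, pivoting=True)
        dependent = sorted(piv[rank:].tolist())
        labels = ["<intercept>" if j == 0 else names[j - 1] for j in dependent]
        raise SingularDesignError(
            f"design matrix is rank-deficient (rank {rank} < {Xa.shape[1]}); "
            f"linearly dependent columns: {labels}"
        )


def fit_mlr(
    X: np.ndarray, y: np.ndarray, descriptor_names: list[str] | None = None
) -> MLRModel:
    """Fit OLS with intercept; requires ``n >= p + 2`` and a full-rank design."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if len(y) != n:
        raise ValueError(f"X has {n} rows but y has {len(y)} values")
    if n < p + 2:
        raise ValueError(f"need at least p+2={p + 2} observations to fit, got {n}")
    if descriptor_names is None:
        descriptor_names = [f"x{j + 1}" for j in range(p)]
    if len(descriptor_names) != p:
        raise ValueError("descriptor_names length must match X columns")
    Xa = _augment(X)
    _check_rank(Xa, descriptor_names)
    beta, *_ = np.linalg.lstsq(Xa, y, rcond=None)
    return MLRModel(
        intercept=float(beta[0]),
        coefficients={d: float(b) for d, b in zip(descriptor_names, beta[1:])},
        n_train=n,
    )


def predict(model: MLRModel, X, descriptor_names: list[str] | None = None) -> np.ndarray:
    """Evaluate ``intercept + X @ coefs``; columns must match the model order."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X.reshape(1, -1)
    expected = model.descriptor_names
    if descriptor_names is not None and list(descriptor_names) != expected:
        raise ValueError(
            f"descriptor mismatch: model expects {expected}, got {list(descriptor_names)}"
        )
    if X.shape[1] != len(expected):
        raise ValueError(
            f"descriptor mismatch: model expects {len(expected)} columns "
            f"{expected}, got {X.shape[1]}"
        )
    coefs = np.array([model.coefficients[d] for d in expected])
    return model.intercept + X @ coefs


def fit_metrics(y_obs, y_cal, n: int | None = None, p: int = 1) -> FitMetrics:
    """Fit statistics for observed vs calculated activities (see module doc)."""
    y_obs = np.asarray(y_obs, dtype=float).ravel()
    y_cal = np.asarray(y_cal, dtype=float).ravel()
    if len(y_obs) != len(y_cal):
        raise ValueError("y_obs and y_cal must have equal length")
    if len(y_obs) < 3:
        raise ValueError("need at least 3 observations")
    if n is None:
        n = len(y_obs)
    if p < 1:
        raise ValueError("p must be >= 1")
    if n - 1 - p <= 0:
        raise ValueError(f"n-1-p must be positive, got n={n}, p={p}")
    ybar = y_obs.mean()
    sst = float(np.sum((y_obs - ybar) ** 2))
    if sst == 0:
        raise ValueError("y_obs has zero variance; r2 undefined")
    sse = float(np.sum((y_obs - y_cal) ** 2))
    ssreg = float(np.sum((y_cal - ybar) ** 2))
    r2 = 1.0 - sse / sst
    r2_adj = ((n - 1) * r2 - p) / (n - 1 - p)
    mse = sse / n
    mae = float(np.mean(np.abs(y_obs - y_cal)))
    f_stat = math.inf if sse == 0 else (ssreg / sse) * (n - p - 1) / p
    s = math.sqrt(sse / (n - p - 1))
    bic = -math.inf if sse == 0 else n * math.log(sse / n) + (p + 1) * math.log(n)
    return FitMetrics(
        r2=r2,
        r2_adj=r2_adj,
        mse=mse,
        rmse=math.sqrt(mse),
        mae=mae,
        f_stat=f_stat,
        s=s,
        bic=bic,
        n=int(n),
        p=int(p),
    )
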