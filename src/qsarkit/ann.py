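"""Single-hidden-layer feed-forward regressor (sigmoid hidden, identity output).

Inputs and the target are z-scored on training statistics; weights start from
a seeded uniform draw on [-0.5, 0.5]; the mean-squared-error objective is
minimized with a nonlinear conjugate-gradient routine (analytic gradients).
Training is fully deterministic for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

__all__ = ["MLPModel", "TrainConfig", "train_mlp", "predict_mlp"]


@dataclass
class TrainConfig:
    """``algorithm`` is "cg" (nonlinear conjugate gradient, the default) or
    "bfgs" when machine-precision convergence matters more than fidelity to
    the conjugate-gradient family.  ``tol`` is the gradient-norm stopping
    tolerance."""

    seed: int = 0
    max_iter: int = 500
    tol: float = 1e-10
    hidden_units: int = 3
    algorithm: str = "cg"

    def __post_init__(self) -> None:
        if self.hidden_units < 1:
            raise ValueError("hidden_units must be >= 1")
        if self.algorithm not in ("cg", "bfgs"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")


@dataclass
class MLPModel:
    """Trained network plus the standardization needed to predict in
    original units."""

    descriptor_names: list[str]
    hidden_units: int
    w1: np.ndarray  # (p, h)
    b1: np.ndarray  # (h,)
    w2: np.ndarray  # (h,)
    b2: float
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float
    y_sd: float
    final_loss: float = float("nan")
    n_iter: int = 0
    loss_history: list[float] = field(default_factory=list)

    @property
    def n_parameters(self) -> int:
        p, h = self.w1.shape
        return p * h + h + h + 1

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {
                "descriptor_names": self.descriptor_names,
                "hidden_units": self.hidden_units,
                "w1": self.w1.tolist(),
                "b1": self.b1.tolist(),
                "w2": self.w2.tolist(),
                "b2": self.b2,
                "x_mean": self.x_mean.tolist(),
                "x_sd": self.x_sd.tolist(),
                "y_mean": self.y_mean,
                "y_sd": self.y_sd,
                "final_loss": self.final_loss,
                "n_iter": self.n_iter,
            },
            indent=2,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload

    @classmethod
    def from_json(cls, source) -> "MLPModel":
        if hasattr(source, "read"):
            data = json.load(source)
        else:
            try:
                data = json.loads(source)
            except (json.JSONDecodeError, TypeError):
                with open(source) as fh:
                    data = json.load(fh)
        return cls(
            descriptor_names=data["descriptor_names"],
            hidden_units=data["hidden_units"],
            w1=np.array(data["w1"], dtype=float),
            b1=np.array(data["b1"], dtype=float),
            w2=np.array(data["w2"], dtype=float),
            b2=float(data["b2"]),
            x_mean=np.array(data["x_mean"], dtype=float),
            x_sd=np.array(data["x_sd"], dtype=float),
            y_mean=float(data["y_mean"]),
            y_sd=float(data["y_sd"]),
            final_loss=float(data.get("final_loss", float("nan"))),
            n_iter=int(data.get("n_iter", 0)),
        )


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _unpack(theta: np.ndarray, p: int, h: int):
    i = 0
    w1 = theta[i : i + p * h].reshape(p, h); i += p * h
    b1 = theta[i : i + h]; i += h
    w2 = theta[i : i + h]; i += h
    b2 = theta[i]
    return w1, b1, w2, b2


def _loss_grad(theta: np.ndarray, Xs: np.ndarray, ys: np.ndarray, p: int, h: int):
    w1, b1, w2, b2 = _unpack(theta, p, h)
    n = Xs.shape[0]
    a = _sigmoid(Xs @ w1 + b1)           # (n, h)
    yhat = a @ w2 + b2                   # (n,)
    err = yhat - ys
    loss = float(np.mean(err**2))
    # gradients of mean squared error
    gy = 2.0 * err / n                   # (n,)
    g_w2 = a.T @ gy
    g_b2 = float(np.sum(gy))
    ga = np.outer(gy, w2) * a * (1.0 - a)  # (n, h)
    g_w1 = Xs.T @ ga
    g_b1 = ga.sum(axis=0)
    grad = np.concatenate([g_w1.ravel(), g_b1, g_w2, [g_b2]])
    if not np.isfinite(loss):
        raise FloatingPointError("non-finite training loss")
    return loss, grad


def train_mlp(
    X,
    y,
    config: TrainConfig | None = None,
    descriptor_names: list[str] | None = None,
) -> MLPModel:
    """Train the network; deterministic given ``config.seed``."""
    config = config or TrainConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n < 8:
        raise ValueError(f"need at least 8 training rows, got {n}")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("X and y must be finite")
    if descriptor_names is None:
        descriptor_names = [f"x{j + 1}" for j in range(p)]

    x_mean = X.mean(axis=0)
    x_sd = X.std(axis=0, ddof=0)
    x_sd[x_sd == 0] = 1.0
    y_mean = float(y.mean())
    y_sd = float(y.std(ddof=0)) or 1.0
    Xs = (X - x_mean) / x_sd
    ys = (y - y_mean) / y_sd

    h = config.hidden_units
    rng = np.random.default_rng(config.seed)
    theta0 = rng.uniform(-0.5, 0.5, size=p * h + h + h + 1)

    history: list[float] = []

    def callback(theta):
        history.append(_loss_grad(theta, Xs, ys, p, h)[0])

    res = minimize(
        _loss_grad,
        theta0,
        args=(Xs, ys, p, h),
        jac=True,
        method="CG" if config.algorithm == "cg" else "BFGS",
        options={"maxiter": config.max_iter, "gtol": config.tol},
        callback=callback,
    )
    w1, b1, w2, b2 = _unpack(res.x, p, h)
    return MLPModel(
        descriptor_names=list(descriptor_names),
        hidden_units=h,
        w1=w1,
        b1=b1,
        w2=w2,
        b2=float(b2),
        x_mean=x_mean,
        x_sd=x_sd,
        y_mean=y_mean,
        y_sd=y_sd,
        final_loss=float(res.fun),
        n_iter=int(res.nit),
        loss_history=history,
    )


def predict_mlp(model: MLPModel, X, descriptor_names: list[str] | None = None) -> np.ndarray:
    """Forward pass, destandardized to original activity units."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X.reshape(1, -1)
    if descriptor_names is not None and list(descriptor_names) != model.descriptor_names:
        raise ValueError(
            f"descriptor mismatch: model expects {model.descriptor_names}, "
            f"got {list(descriptor_names)}"
        )
    if X.shape[1] != len(model.descriptor_names):
        raise ValueError(
            f"descriptor mismatch: model expects {len(model.descriptor_names)} "
            f"columns, got {X.shape[1]}"
        )
    Xs = (X - model.x_mean) / model.x_sd
    a = _sigmoid(Xs @ model.w1 + model.b1)
    ys = a @ model.w2 + model.b2
    return ys * model.y_sd + model.y_mean
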