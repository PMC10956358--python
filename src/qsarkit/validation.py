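"""The QSAR validation battery.

* :func:`loocv_q2` — leave-one-out cross-validated Q2 (refit per fold; a
  model-factory hook lets any regressor be validated the same way).
* :func:`golbraikh_tropsha` — external-set criteria with through-origin
  regressions and slopes, plus Lin's concordance.
* :func:`y_randomization` — permutation test with the cRp2 penalty
  ``r * sqrt(max(r2 - avg_r2_perm, 0))``.
* :func:`applicability_domain` — leverage on the intercept-augmented design,
  warning threshold ``h* = 3(k+1)/n``, standardized-residual cutoff +-3, and
  the Williams-plot table.

Through-origin conventions (the literature-standard forms): ``k`` is the
slope of observed~predicted through the origin (``sum(y*yhat)/sum(yhat^2)``)
and ``k'`` the converse; ``r0^2`` scores the through-origin fit of predicted
on observed, ``r0'^2`` the converse.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from qsarkit.mlr import MLRModel, fit_mlr, predict

__all__ = [
    "LOOCVResult",
    "ExternalValidationReport",
    "YRandomizationResult",
    "DomainResult",
    "loocv_q2",
    "golbraikh_tropsha",
    "y_randomization",
    "applicability_domain",
    "warning_leverage",
]


# ---------------------------------------------------------------------------
# LOOCV


@dataclass
class LOOCVResult:
    q2: float
    press: float
    per_compound_loo_prediction: dict[str, float]
    predictive_flag: bool

    def to_dict(self) -> dict:
        return {
            "q2": self.q2,
            "press": self.press,
            "per_compound_loo_prediction": self.per_compound_loo_prediction,
            "predictive_flag": self.predictive_flag,
        }


def _default_fit(X, y):
    model = fit_mlr(X, y)
    return lambda Xq: predict(model, Xq)


def loocv_q2(
    X,
    y,
    ids: Sequence[str] | None = None,
    fit_fn: Callable[[np.ndarray, np.ndarray], Callable[[np.ndarray], np.ndarray]] | None = None,
    q2_threshold: float = 0.5,
) -> LOOCVResult:
    """Leave-one-out Q2 = 1 - PRESS / sum((y - ybar)^2), ybar over the full set.

    ``fit_fn(X, y)`` must return a predictor callable; it defaults to OLS.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if fit_fn is None and n < p + 3:
        raise ValueError(f"LOOCV needs n >= p+3 ({p + 3}), got {n}")
    if ids is None:
        ids = [str(i) for i in range(n)]
    fit_fn = fit_fn or _default_fit
    loo_pred = np.empty(n)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        try:
            predictor = fit_fn(X[mask], y[mask])
        except Exception as exc:  # surface which fold failed
            raise RuntimeError(f"LOOCV refit failed for fold {i} (id {ids[i]!r}): {exc}") from exc
        loo_pred[i] = float(np.asarray(predictor(X[i : i + 1])).ravel()[0])
        mask[i] = True
    press = float(np.sum((y - loo_pred) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        raise ValueError("y has zero variance; Q2 undefined")
    q2 = 1.0 - press / sst
    return LOOCVResult(
        q2=q2,
        press=press,
        per_compound_loo_prediction={str(ids[i]): float(loo_pred[i]) for i in range(n)},
        predictive_flag=q2 > q2_threshold,
    )


# ---------------------------------------------------------------------------
# Golbraikh-Tropsha external criteria


@dataclass
class ExternalValidationReport:
    q2_ext: float
    r2: float
    r0_sq: float
    r0_prime_sq: float
    k: float
    k_prime: float
    delta1: float
    delta2: float
    abs_diff_r0: float
    ccc: float
    criterion_flags: dict[str, bool]

    @property
    def all_pass(self) -> bool:
        return all(self.criterion_flags.values())

    def to_dict(self) -> dict:
        return {
            "q2_ext": self.q2_ext,
            "r2": self.r2,
            "r0_sq": self.r0_sq,
            "r0_prime_sq": self.r0_prime_sq,
            "k": self.k,
            "k_prime": self.k_prime,
            "delta1": self.delta1,
            "delta2": self.delta2,
            "abs_diff_r0": self.abs_diff_r0,
            "ccc": self.ccc,
            "criterion_flags": self.criterion_flags,
            "all_pass": self.all_pass,
        }


def _through_origin_r2(y: np.ndarray, x: np.ndarray) -> float:
    """R2 of regressing y on x through the origin, scored around mean(y)."""
    slope = float(np.sum(x * y) / np.sum(x * x))
    resid = y - slope * x
    return 1.0 - float(np.sum(resid**2)) / float(np.sum((y - y.mean()) ** 2))


def golbraikh_tropsha(y_test, y_pred, y_train_mean: float) -> ExternalValidationReport:
    """External-validation criteria for a test set against its predictions."""
    y = np.asarray(y_test, dtype=float).ravel()
    yh = np.asarray(y_pred, dtype=float).ravel()
    if len(y) != len(yh):
        raise ValueError("y_test and y_pred must have equal length")
    if len(y) < 3:
        raise ValueError("need at least 3 test compounds")
    if np.ptp(y) == 0:
        raise ValueError("y_test is constant; external validation undefined")

    q2_ext = 1.0 - float(np.sum((yh - y) ** 2)) / float(np.sum((y - y_train_mean) ** 2))
    # squared Pearson correlation of observed vs predicted
    if np.ptp(yh) == 0:
        r2 = 0.0
    else:
        r2 = float(np.corrcoef(y, yh)[0, 1]) ** 2
    k = float(np.sum(y * yh) / np.sum(yh * yh))
    k_prime = float(np.sum(y * yh) / np.sum(y * y))
    r0_sq = _through_origin_r2(yh, y)        # predicted regressed on observed
    r0_prime_sq = _through_origin_r2(y, yh)  # observed regressed on predicted
    if r2 == 0:
        delta1 = delta2 = math.nan
    else:
        delta1 = (r2 - r0_sq) / r2
        delta2 = (r2 - r0_prime_sq) / r2
    abs_diff_r0 = abs(r0_sq - r0_prime_sq)

    # Lin's concordance correlation coefficient (population moments)
    my, mh = y.mean(), yh.mean()
    vy = float(np.mean((y - my) ** 2))
    vh = float(np.mean((yh - mh) ** 2))
    cov = float(np.mean((y - my) * (yh - mh)))
    ccc = 2 * cov / (vy + vh + (my - mh) ** 2)

    flags = {
        "q2_ext>0.5": q2_ext > 0.5,
        "r2>0.6": r2 > 0.6,
        "|r0^2-r0'^2|<0.3": abs_diff_r0 < 0.3,
        "(r2-r0^2)/r2<0.1": (not math.isnan(delta1)) and delta1 < 0.1,
        "(r2-r0'^2)/r2<0.1": (not math.isnan(delta2)) and delta2 < 0.1,
        "0.85<k<1.15": 0.85 < k < 1.15,
        "0.85<k'<1.15": 0.85 < k_prime < 1.15,
    }
    return ExternalValidationReport(
        q2_ext=q2_ext,
        r2=r2,
        r0_sq=r0_sq,
        r0_prime_sq=r0_prime_sq,
        k=k,
        k_prime=k_prime,
        delta1=delta1,
        delta2=delta2,
        abs_diff_r0=abs_diff_r0,
        ccc=ccc,
        criterion_flags=flags,
    )


# ---------------------------------------------------------------------------
# Y-randomization


@dataclass
class YRandomizationResult:
    original: tuple[float, float, float]  # (r, r2, q2)
    permuted_runs: list[tuple[float, float, float]]
    avg_r: float
    avg_r2: float
    avg_q2: float
    crp2: float
    seed: int | None
    valid: bool
    clamped: bool = False  # crp2 radicand was negative and clamped to 0

    def to_dict(self) -> dict:
        return {
            "original": {"r": self.original[0], "r2": self.original[1], "q2": self.original[2]},
            "permuted_runs": [
                {"r": r, "r2": r2, "q2": q2} for r, r2, q2 in self.permuted_runs
            ],
            "avg_r": self.avg_r,
            "avg_r2": self.avg_r2,
            "avg_q2": self.avg_q2,
            "crp2": self.crp2,
            "seed": self.seed,
            "valid": self.valid,
            "clamped": self.clamped,
        }


def _fit_stats(X: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    model = fit_mlr(X, y)
    yh = predict(model, X)
    r = float(np.corrcoef(y, yh)[0, 1]) if np.ptp(yh) > 0 else 0.0
    sse = float(np.sum((y - yh) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / sst
    q2 = loocv_q2(X, y).q2
    return r, r2, q2


def y_randomization(
    X, y, n_perm: int = 10, seed: int | None = None
) -> YRandomizationResult:
    """Permutation test: refit after shuffling activities ``n_perm`` times.

    The model is judged valid when every permuted R2 is below the original R2
    and ``cRp2 = r * sqrt(r2 - avg permuted r2)`` exceeds 0.5 (radicand
    clamped at 0 with a ``clamped`` warning flag).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if np.ptp(y) == 0:
        raise ValueError("y is constant; Y-randomization undefined")
    rng = np.random.default_rng(seed)
    original = _fit_stats(X, y)
    runs = []
    for _ in range(n_perm):
        y_perm = rng.permutation(y)
        runs.append(_fit_stats(X, y_perm))
    avg_r = float(np.mean([r for r, _, _ in runs]))
    avg_r2 = float(np.mean([r2 for _, r2, _ in runs]))
    avg_q2 = float(np.mean([q2 for _, _, q2 in runs]))
    radicand = original[1] - avg_r2
    clamped = radicand < 0
    crp2 = 0.0 if clamped else original[0] * math.sqrt(radicand)
    valid = all(r2 < original[1] for _, r2, _ in runs) and crp2 > 0.5
    return YRandomizationResult(
        original=original,
        permuted_runs=runs,
        avg_r=avg_r,
        avg_r2=avg_r2,
        avg_q2=avg_q2,
        crp2=crp2,
        seed=seed,
        valid=valid,
        clamped=clamped,
    )


# ---------------------------------------------------------------------------
# Applicability domain (leverage)


@dataclass
class DomainResult:
    leverages: dict[str, float]
    h_star: float
    std_residuals: dict[str, float]
    outliers: list[tuple[str, str]]
    williams_table: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "h_star": self.h_star,
            "leverages": self.leverages,
            "std_residuals": self.std_residuals,
            "outliers": [{"id": i, "reason": r} for i, r in self.outliers],
            "williams_table": self.williams_table,
        }


def warning_leverage(k: int, n: int) -> float:
    """Warning leverage threshold ``h* = 3(k+1)/n``."""
    if n <= 0 or k < 0:
        raise ValueError("need k >= 0 and n > 0")
    return 3.0 * (k + 1) / n


def applicability_domain(
    X_train,
    residuals_train,
    X_test=None,
    residuals_test=None,
    train_ids: Sequence[str] | None = None,
    test_ids: Sequence[str] | None = None,
    k: int | None = None,
    n: int | None = None,
    std_resid_cutoff: float = 3.0,
) -> DomainResult:
    """Leverage/residual applicability domain with a Williams-plot table.

    Leverages are the diagonal ``x_i'(X'X)^-1 x_i`` of the intercept-augmented
    hat matrix, so training leverages sum to k+1.  ``k`` and ``n`` default to
    the training design dimensions but can be overridden (the threshold is a
    pure function of them).  Residuals are standardized by the training
    residual standard deviation ``sqrt(SSE/(n-k-1))``.
    """
    X_train = np.asarray(X_train, dtype=float)
    e_train = np.asarray(residuals_train, dtype=float).ravel()
    n_train, p = X_train.shape
    if len(e_train) != n_train:
        raise ValueError("residuals_train length must match X_train rows")
    k = p if k is None else k
    n = n_train if n is None else n
    h_star = warning_leverage(k, n)

    Xa = np.column_stack([np.ones(n_train), X_train])
    gram = Xa.T @ Xa
    if np.linalg.matrix_rank(gram) < gram.shape[0]:
        raise ValueError("X'X is singular; leverage undefined")
    gram_inv = np.linalg.inv(gram)
    h_train = np.einsum("ij,jk,ik->i", Xa, gram_inv, Xa)

    dof = n_train - p - 1
    s = math.sqrt(float(np.sum(e_train**2)) / dof) if dof > 0 else float("nan")

    if train_ids is None:
        train_ids = [f"train_{i}" for i in range(n_train)]
    leverages = {str(i): float(h) for i, h in zip(train_ids, h_train)}
    std_res = {str(i): float(e / s) for i, e in zip(train_ids, e_train)}
    rows = [
        {"id": str(i), "h": float(h), "std_residual": float(e / s), "set": "train"}
        for i, h, e in zip(train_ids, h_train, e_train)
    ]

    if X_test is not None:
        X_test = np.asarray(X_test, dtype=float)
        Xta = np.column_stack([np.ones(X_test.shape[0]), X_test])
        h_test = np.einsum("ij,jk,ik->i", Xta, gram_inv, Xta)
        if test_ids is None:
            test_ids = [f"test_{i}" for i in range(X_test.shape[0])]
        e_test = (
            np.asarray(residuals_test, dtype=float).ravel()
            if residuals_test is not None
            else np.full(X_test.shape[0], np.nan)
        )
        for i, h, e in zip(test_ids, h_test, e_test):
            leverages[str(i)] = float(h)
            std_res[str(i)] = float(e / s)
            rows.append(
                {"id": str(i), "h": float(h), "std_residual": float(e / s), "set": "test"}
            )

    outliers: list[tuple[str, str]] = []
    for row in rows:
        if row["h"] > h_star:
            outliers.append((row["id"], "leverage"))
        if math.isfinite(row["std_residual"]) and abs(row["std_residual"]) > std_resid_cutoff:
            outliers.append((row["id"], "residual"))

    return DomainResult(
        leverages=leverages,
        h_star=h_star,
        std_residuals=std_res,
        outliers=outliers,
        williams_table=rows,
    )
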