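"""Regression methods and leave-one-out cross-validation.

PLSR is a from-scratch single-response NIPALS decomposition on mean-centred
data (no variance scaling).  The number of latent factors is chosen by the
parsimony rule: a factor is added only while it reduces the cross-validated
RMSE by more than 2%.  The linear epsilon-SVR wraps the libsvm solver behind
a min-max feature scaler re-derived inside every fold; the cost parameter is
chosen as the smallest grid value whose LOOCV RMSE is within 2% of the grid
minimum.

All data-dependent quantities (centring, scaling, MSC references passed as
preprocessors) are recomputed inside each cross-validation fold, so the
out-of-fold predictions never see the held-out sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Protocol, Sequence

import numpy as np
from sklearn.svm import SVR as _LibSVR

DEFAULT_EPSILON = 0.1
DEFAULT_C_GRID: tuple[float, ...] = tuple(float(2.0**k) for k in range(-10, 4))
PARSIMONY_REL = 0.02  # ">2%" RMSE-reduction rule


class ModelError(ValueError):
    """Invalid input for model fitting or validation."""


class Preprocessor(Protocol):
    """Fold-safe transformation fitted on training rows only."""

    def fit(self, wavelengths: np.ndarray, X: np.ndarray) -> "Preprocessor": ...

    def transform(
        self, wavelengths: np.ndarray, X: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]: ...


# ---------------------------------------------------------------------------
# Accuracy statistics
# ---------------------------------------------------------------------------


def accuracy_stats(
    y: np.ndarray, yhat: np.ndarray, center: str = "mean"
) -> tuple[float, float, float]:
    """(R2, RMSE, %RMSE) of predictions against observations.

    R2 is the explained-variance form 1 - SSE/SStot (can be negative);
    %RMSE is 100 * RMSE over the mean or median of the observations.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ModelError("y and yhat lengths differ")
    if y.size < 2:
        raise ModelError("need at least 2 observations")
    sse = float(np.sum((y - yhat) ** 2))
    sstot = float(np.sum((y - y.mean()) ** 2))
    if sstot <= 0:
        raise ModelError("response has zero variance")
    rmse = float(np.sqrt(sse / y.size))
    r2 = 1.0 - sse / sstot
    if center == "mean":
        c = float(y.mean())
    elif center == "median":
        c = float(np.median(y))
    else:
        raise ModelError(f"unknown center {center!r}")
    if c == 0:
        raise ModelError("%RMSE undefined: centre of response is zero")
    return r2, rmse, 100.0 * rmse / c


@dataclass
class CVResult:
    """Cross-validated accuracy of one model."""

    predictions: np.ndarray
    r2: float
    rmse: float
    pct_rmse: float
    complexity: float
    rmse_cal: float = float("nan")

    @property
    def cal_cv_gap_ok(self) -> bool:
        """True when calibration and CV RMSE agree within 2% (overfit check)."""
        if not np.isfinite(self.rmse_cal) or self.rmse <= 0:
            return False
        return abs(self.rmse_cal - self.rmse) / self.rmse <= PARSIMONY_REL


def _cv_result(
    y: np.ndarray, preds: np.ndarray, complexity: float, center: str, rmse_cal: float
) -> CVResult:
    r2, rmse, pct = accuracy_stats(y, preds, center)
    return CVResult(preds, r2, rmse, pct, complexity, rmse_cal)


# ---------------------------------------------------------------------------
# PLSR (NIPALS, single response)
# ---------------------------------------------------------------------------


@dataclass
class PLSRModel:
    """Mean-centred NIPALS PLS1 decomposition.

    ``coefs[:, a]`` are the regression coefficients using the first ``a+1``
    factors, on the original (uncentred) predictor scale.
    """

    n_factors: int
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray  # p x F
    loadings: np.ndarray  # p x F
    scores: np.ndarray  # n x F
    q: np.ndarray  # F
    coefs: np.ndarray  # p x F (cumulative over factors)

    def predict(self, X: np.ndarray, n_factors: int | None = None) -> np.ndarray:
        F = self.n_factors if n_factors is None else n_factors
        if not 1 <= F <= self.n_factors:
            raise ModelError(f"n_factors must be in [1, {self.n_factors}]")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        b = self.coefs[:, F - 1]
        return (X - self.x_mean) @ b + self.y_mean


def fit_plsr(X: np.ndarray, y: np.ndarray, n_factors: int) -> PLSRModel:
    """Fit a PLS1 model with the NIPALS algorithm (no variance scaling)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2:
        raise ModelError("X must be 2-D")
    n, p = X.shape
    if n < 3:
        raise ModelError("PLSR requires at least 3 samples")
    if y.shape != (n,):
        raise ModelError("y length must match X rows")
    if float(y.std()) == 0.0:
        raise ModelError("response has zero variance")
    if n_factors < 1:
        raise ModelError("n_factors must be >= 1")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    E = X - x_mean
    f = y - y_mean
    max_factors = min(n - 1, p)
    if n_factors > max_factors:
        raise ModelError(
            f"n_factors={n_factors} exceeds min(n-1, p)={max_factors}"
        )
    W = np.zeros((p, n_factors))
    P = np.zeros((p, n_factors))
    T = np.zeros((n, n_factors))
    q = np.zeros(n_factors)
    actual = 0
    for a in range(n_factors):
        w = E.T @ f
        wnorm = float(np.linalg.norm(w))
        if wnorm < 1e-13 * max(1.0, float(np.abs(y).max())):
            break  # residual covariance exhausted (rank limit)
        w /= wnorm
        t = E @ w
        tt = float(t @ t)
        if tt < 1e-300:
            break
        pvec = E.T @ t / tt
        qa = float(f @ t) / tt
        E = E - np.outer(t, pvec)
        f = f - qa * t
        W[:, a], P[:, a], T[:, a], q[a] = w, pvec, t, qa
        actual += 1
    if actual == 0:
        raise ModelError("no PLSR factor could be extracted (X has no variance)")
    W, P, T, q = W[:, :actual], P[:, :actual], T[:, :actual], q[:actual]
    # B_a = W_a (P_a' W_a)^{-1} q_a for every factor count a
    coefs = np.zeros((p, actual))
    for a in range(actual):
        coefs[:, a] = W[:, : a + 1] @ np.linalg.solve(
            P[:, : a + 1].T @ W[:, : a + 1], q[: a + 1]
        )
    return PLSRModel(actual, x_mean, y_mean, W, P, T, q, coefs)


# ---------------------------------------------------------------------------
# OLSR
# ---------------------------------------------------------------------------


@dataclass
class OLSRModel:
    intercept: float
    coefficients: np.ndarray

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return X @ self.coefficients + self.intercept


def fit_olsr(X: np.ndarray, y: np.ndarray) -> OLSRModel:
    """Ordinary least squares with intercept; rank-deficient designs error out."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < p + 1:
        raise ModelError(f"OLSR requires n >= p + 1 (n={n}, p={p})")
    design = np.column_stack([np.ones(n), X])
    rank = np.linalg.matrix_rank(design)
    if rank < p + 1:
        raise ModelError(f"rank-deficient design (rank {rank} < {p + 1})")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return OLSRModel(float(beta[0]), beta[1:])


# ---------------------------------------------------------------------------
# Linear epsilon-SVR
# ---------------------------------------------------------------------------


@dataclass
class SVRModel:
    """Linear epsilon-insensitive SVR behind a min-max feature scaler."""

    C: float
    epsilon: float
    feature_min: np.ndarray
    feature_range: np.ndarray
    weights: np.ndarray
    intercept: float
    n_support: int

    def _scale(self, X: np.ndarray) -> np.ndarray:
        return (X - self.feature_min) / self.feature_range

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return self._scale(X) @ self.weights + self.intercept


def _fit_svr_single(X: np.ndarray, y: np.ndarray, C: float, epsilon: float) -> SVRModel:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    fmin = X.min(axis=0)
    frange = X.max(axis=0) - fmin
    frange = np.where(frange > 0, frange, 1.0)  # constant features map to 0
    Xs = (X - fmin) / frange
    est = _LibSVR(kernel="linear", C=C, epsilon=epsilon, tol=1e-8, max_iter=-1)
    est.fit(Xs, y)
    w = est.coef_.ravel().astype(float)
    return SVRModel(
        C, epsilon, fmin, frange, w, float(est.intercept_[0]), int(est.n_support_.sum())
    )


def fit_svr(
    X: np.ndarray,
    y: np.ndarray,
    C_grid: Sequence[float] | None = None,
    epsilon: float = DEFAULT_EPSILON,
    center: str = "mean",
) -> tuple[SVRModel, CVResult]:
    """Grid search over C under LOOCV, with the 2% parsimony rule.

    The chosen C is the smallest grid value whose LOOCV RMSE is within 2% of
    the grid minimum.  Feature scaling is re-derived inside every fold.
    """
    grid = tuple(C_grid) if C_grid is not None else DEFAULT_C_GRID
    if not grid:
        raise ModelError("empty C grid")
    if any(c <= 0 for c in grid):
        raise ModelError("C values must be positive")
    y = np.asarray(y, dtype=float)
    results: list[tuple[float, CVResult]] = []
    for C in sorted(grid):
        cv = loocv(lambda Xtr, ytr, C=C: _fit_svr_single(Xtr, ytr, C, epsilon), X, y,
                   center=center)
        results.append((C, cv))
    best_rmse = min(cv.rmse for _, cv in results)
    for C, cv in results:  # sorted ascending: first within tolerance is smallest C
        if cv.rmse <= (1.0 + PARSIMONY_REL) * best_rmse:
            chosen_C, chosen_cv = C, cv
            break
    model = _fit_svr_single(X, y, chosen_C, epsilon)
    chosen_cv.complexity = chosen_C
    chosen_cv.rmse_cal = float(
        np.sqrt(np.mean((y - model.predict(np.atleast_2d(X))) ** 2))
    )
    return model, chosen_cv


# ---------------------------------------------------------------------------
# Leave-one-out cross-validation
# ---------------------------------------------------------------------------


def loocv(
    fit: Callable[[np.ndarray, np.ndarray], object],
    X: np.ndarray,
    y: np.ndarray,
    center: str = "mean",
    preprocess: Preprocessor | None = None,
    wavelengths: np.ndarray | None = None,
    complexity: float = float("nan"),
) -> CVResult:
    """Leave-one-out CV of an arbitrary ``fit(X, y) -> model`` procedure.

    ``preprocess`` (e.g. an MSC reference) is refitted on each fold's
    training rows and applied to both partitions, so no information leaks
    from the held-out sample.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if n < 3:
        raise ModelError("LOOCV requires at least 3 samples")
    wl = (
        np.asarray(wavelengths, dtype=float)
        if wavelengths is not None
        else np.arange(X.shape[1], dtype=float)
    )
    preds = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        Xtr, ytr = X[keep], y[keep]
        Xte = X[i : i + 1]
        try:
            if preprocess is not None:
                preprocess.fit(wl, Xtr)
                _, Xtr = preprocess.transform(wl, Xtr)
                _, Xte = preprocess.transform(wl, Xte)
            model = fit(Xtr, ytr)
            preds[i] = float(np.asarray(model.predict(Xte)).ravel()[0])
        except Exception as exc:  # noqa: BLE001 - re-raise with fold context
            raise ModelError(f"LOOCV fold {i} failed: {exc}") from exc
    return _cv_result(y, preds, complexity, center, float("nan"))


# ---------------------------------------------------------------------------
# PLSR factor selection
# ---------------------------------------------------------------------------


def parsimony_select(rmse_seq: Sequence[float], atol: float = 0.0) -> int:
    """Number of factors under the strict >2% RMSE-reduction rule.

    Starting from one factor, the next is accepted only while
    ``rmse[F+1] < 0.98 * rmse[F]`` (an exactly-2% reduction is rejected).
    Selection stops early once the RMSE reaches the absolute floor ``atol``
    (a perfect fit cannot be improved by 2%).
    """
    if not rmse_seq:
        raise ModelError("empty RMSE sequence")
    F = 1
    while F < len(rmse_seq):
        if rmse_seq[F - 1] <= atol:
            break
        if rmse_seq[F] < (1.0 - PARSIMONY_REL) * rmse_seq[F - 1]:
            F += 1
        else:
            break
    return F


def select_plsr_factors(
    X: np.ndarray,
    y: np.ndarray,
    f_max: int = 10,
    center: str = "mean",
    preprocess: Preprocessor | None = None,
    wavelengths: np.ndarray | None = None,
) -> tuple[int, CVResult]:
    """Choose the PLSR factor count by LOOCV and the >2% parsimony rule.

    Each fold fits a single model with the maximum feasible factor count and
    yields out-of-fold predictions for every smaller count, from which the
    per-count RMSE curve and the selected model's CV statistics follow.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if n < 3:
        raise ModelError("factor selection requires at least 3 samples")
    if f_max < 1:
        raise ModelError("f_max must be >= 1")
    wl = (
        np.asarray(wavelengths, dtype=float)
        if wavelengths is not None
        else np.arange(X.shape[1], dtype=float)
    )
    cap = min(f_max, n - 2, X.shape[1])
    pred_paths = np.full((n, cap), np.nan)
    for i in range(n):
        keep = np.arange(n) != i
        Xtr, ytr = X[keep], y[keep]
        Xte = X[i : i + 1]
        try:
            if preprocess is not None:
                preprocess.fit(wl, Xtr)
                _, Xtr = preprocess.transform(wl, Xtr)
                _, Xte = preprocess.transform(wl, Xte)
            model = fit_plsr(Xtr, ytr, min(cap, Xtr.shape[0] - 1, Xtr.shape[1]))
        except Exception as exc:  # noqa: BLE001
            raise ModelError(f"LOOCV fold {i} failed: {exc}") from exc
        for a in range(cap):
            f_use = min(a + 1, model.n_factors)
            pred_paths[i, a] = float(model.predict(Xte, n_factors=f_use)[0])
    rmse_curve = np.sqrt(np.mean((pred_paths - y[:, None]) ** 2, axis=0))
    atol = 1e-8 * float(y.std())
    F = parsimony_select(list(rmse_curve), atol=atol)
    cv = _cv_result(y, pred_paths[:, F - 1], float(F), center, float("nan"))
    # calibration RMSE of the selected model on the full data
    Xc = X
    if preprocess is not None:
        preprocess.fit(wl, X)
        _, Xc = preprocess.transform(wl, X)
    full = fit_plsr(Xc, y, min(F, Xc.shape[0] - 1, Xc.shape[1]))
    cal = full.predict(Xc, n_factors=min(F, full.n_factors))
    cv.rmse_cal = float(np.sqrt(np.mean((y - cal) ** 2)))
    return F, cv
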