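"""Partial least squares regression (univariate response) with LOO-CV.

The extraction is NIPALS with deflation of the predictor block only; with a
single response the weight vector has a closed form per component, so no
inner iteration is needed.  The number of latent components (at most
``MAX_COMPONENTS`` = 7 by default) is chosen as the global minimiser of the
leave-one-out cross-validation RMSE, with ties broken toward fewer
components; an optional one-standard-error rule picks the most parsimonious
model within one SE of the minimum.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "PLSRModel",
    "PredictionStats",
    "fit_plsr",
    "predict",
    "prediction_stats",
    "save_model",
    "load_model",
    "MAX_COMPONENTS",
]

MAX_COMPONENTS = 7

_SERIAL_VERSION = 1


@dataclass
class PLSRModel:
    """Centered latent-variable regression model.

    ``weights`` (A x p), ``x_loadings`` (A x p) and ``y_loadings`` (A,) hold
    the extracted components; prediction for a row x uses components
    1..``n_components``.  ``cv_rmse_by_components`` maps each candidate count
    to its leave-one-out RMSE (% SSC).  A model fitted to a zero-variance
    response is ``degenerate`` and predicts the training mean everywhere.
    """

    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    n_components: int
    cv_rmse_by_components: dict[int, float]
    wavelengths: np.ndarray | None = None
    degenerate: bool = False
    training_years: tuple = ()
    n_train: int = 0

    def coefficients(self, n_components: int | None = None) -> np.ndarray:
        """Equivalent linear regression vector b with y = y_mean + (x - x_mean) @ b."""
        if self.degenerate or self.weights.shape[0] == 0:
            return np.zeros_like(self.x_mean)
        a = self.n_components if n_components is None else n_components
        W = self.weights[:a].T  # p x a
        P = self.x_loadings[:a].T
        q = self.y_loadings[:a]
        # R = W (P^T W)^{-1}: maps X-space to scores for the deflated sequence
        R = W @ np.linalg.inv(P.T @ W)
        return R @ q


@dataclass
class PredictionStats:
    """Validation diagnostics: RMSEP, adjusted R2, and the bias line."""

    rmsep: float
    adjusted_r2: float
    bias_slope: float
    bias_intercept: float
    n: int


def _extract_components(Xc: np.ndarray, yc: np.ndarray, max_components: int):
    """PLS1 extraction; returns (W, P, q) possibly shorter than requested."""
    n, p = Xc.shape
    X = Xc.copy()
    W = np.empty((0, p))
    P = np.empty((0, p))
    q: list[float] = []
    ynorm = np.linalg.norm(yc)
    scale = max(np.linalg.norm(X), 1.0)
    for _ in range(max_components):
        w = X.T @ yc
        nw = np.linalg.norm(w)
        if nw <= 1e-12 * max(ynorm, 1.0) * scale:
            break
        w = w / nw
        t = X @ w
        tt = t @ t
        if tt <= 1e-24 * scale**2:
            break
        pvec = (X.T @ t) / tt
        qa = (yc @ t) / tt
        X = X - np.outer(t, pvec)
        W = np.vstack([W, w])
        P = np.vstack([P, pvec])
        q.append(qa)
    return W, P, np.array(q)


def _extract_components_gram(A: np.ndarray, b: np.ndarray, max_components: int):
    """PLS1 extraction from the Gram matrix A = Xc'Xc and b = Xc'yc.

    Algebraically identical to :func:`_extract_components` (deflating X by
    t p' maps to A <- A - (t't) p p' and b <- b - (t't) q p), but every step
    is O(p^2), independent of the sample count — this is what makes
    leave-one-out over large calibration sets affordable.
    """
    p_dim = A.shape[0]
    A = A.copy()
    b = b.copy()
    scale_b = max(np.linalg.norm(b), 1.0)
    scale_a = max(np.trace(A), 1.0)
    W = np.empty((0, p_dim))
    P = np.empty((0, p_dim))
    q: list[float] = []
    for _ in range(max_components):
        nb = np.linalg.norm(b)
        if nb <= 1e-12 * scale_b:
            break
        w = b / nb
        Aw = A @ w
        tt = float(w @ Aw)
        if tt <= 1e-14 * scale_a:
            break
        pvec = Aw / tt
        qa = float(w @ b) / tt
        A -= tt * np.outer(pvec, pvec)
        b -= (tt * qa) * pvec
        W = np.vstack([W, w])
        P = np.vstack([P, pvec])
        q.append(qa)
    return W, P, np.array(q)


def _predict_scores(x_rows: np.ndarray, W: np.ndarray, P: np.ndarray) -> np.ndarray:
    """Per-component scores of new rows (already centered), with deflation."""
    x = x_rows.copy()
    T = np.empty((x.shape[0], W.shape[0]))
    for a in range(W.shape[0]):
        t = x @ W[a]
        T[:, a] = t
        x = x - np.outer(t, P[a])
    return T


def fit_plsr(
    X: np.ndarray,
    y: np.ndarray,
    max_components: int = MAX_COMPONENTS,
    wavelengths: np.ndarray | None = None,
    training_years: tuple = (),
    select: str = "min",
    cv: str = "loo",
    n_components: int | None = None,
) -> PLSRModel:
    """Fit a PLS1 model and choose the component count by cross-validation.

    Parameters
    ----------
    X, y:
        Predictor matrix (n x p, e.g. second-derivative spectra) and response
        vector (% SSC).
    max_components:
        Largest candidate count (capped at min(n - 1, p)).
    select:
        ``"min"`` (global CV minimum, ties to fewer components) or
        ``"one_se"`` (fewest components within one standard error of the
        minimum).
    cv:
        ``"loo"`` or ``"none"``.  With ``"none"``, ``n_components`` must be
        given and no cross-validation is run (used by the Monte Carlo driver
        when the component count is fixed up front).
    n_components:
        Fixed component count, bypassing selection.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.size:
        raise ValueError("X must be n x p and y length n")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("missing or non-finite values in X or y")
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least two samples")
    max_components = int(min(max_components, n - 1, p))
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    yc = y - y_mean

    if np.allclose(yc, 0.0):
        return PLSRModel(
            x_mean=x_mean,
            y_mean=y_mean,
            weights=np.empty((0, p)),
            x_loadings=np.empty((0, p)),
            y_loadings=np.empty(0),
            n_components=0,
            cv_rmse_by_components={},
            wavelengths=None if wavelengths is None else np.asarray(wavelengths, float),
            degenerate=True,
            training_years=tuple(training_years),
            n_train=n,
        )

    Xc = X - x_mean
    W, P, q = _extract_components(Xc, yc, max_components)
    n_extracted = W.shape[0]

    cv_rmse: dict[int, float] = {}
    if n_components is not None:
        chosen = int(min(n_components, n_extracted)) if n_extracted else 0
    elif cv == "none":
        raise ValueError("cv='none' requires an explicit n_components")
    elif cv == "loo":
        # leave-one-out: each fold refits via rank-one downdates of the Gram
        # matrix, yielding hold-out predictions for every candidate count
        S = X.T @ X
        s = X.sum(axis=0)
        Txy = X.T @ y
        sy = y.sum()
        sq_err = np.zeros((n, n_extracted))
        for i in range(n):
            xi = X[i]
            m = (s - xi) / (n - 1)
            ym = (sy - y[i]) / (n - 1)
            A = S - np.outer(xi, xi) - (n - 1) * np.outer(m, m)
            b = Txy - xi * y[i] - m * (sy - y[i])
            Wi, Pi, qi = _extract_components_gram(A, b, n_extracted)
            Ti = _predict_scores((xi - m)[None, :], Wi, Pi)[0]
            preds = ym + np.cumsum(Ti * qi)
            if preds.size < n_extracted:  # rank fell when sample i was dropped
                preds = np.concatenate(
                    [preds, np.full(n_extracted - preds.size, preds[-1] if preds.size else ym)]
                )
            sq_err[i] = (preds - y[i]) ** 2
        rmse = np.sqrt(sq_err.mean(axis=0))
        cv_rmse = {a + 1: float(rmse[a]) for a in range(n_extracted)}
        if select == "one_se":
            se = np.sqrt(sq_err.var(axis=0, ddof=1) / n) / (2.0 * np.maximum(rmse, 1e-12))
            best = int(np.argmin(rmse))
            thresh = rmse[best] + se[best]
            chosen = int(np.nonzero(rmse <= thresh)[0][0]) + 1
        else:
            chosen = int(np.argmin(rmse)) + 1  # argmin takes the first minimum
    else:
        raise ValueError(f"unknown cv scheme {cv!r}")

    return PLSRModel(
        x_mean=x_mean,
        y_mean=y_mean,
        weights=W,
        x_loadings=P,
        y_loadings=q,
        n_components=chosen,
        cv_rmse_by_components=cv_rmse,
        wavelengths=None if wavelengths is None else np.asarray(wavelengths, float),
        degenerate=False,
        training_years=tuple(training_years),
        n_train=n,
    )


def predict(model: PLSRModel, X: np.ndarray, n_components: int | None = None) -> np.ndarray:
    """Predict the response for rows of ``X`` on the training wavelength grid."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.x_mean.size:
        raise ValueError(
            f"wavelength mismatch: model has {model.x_mean.size} channels, X has {X.shape[1]}"
        )
    if model.degenerate:
        return np.full(X.shape[0], model.y_mean)
    b = model.coefficients(n_components)
    return model.y_mean + (X - model.x_mean) @ b


def prediction_stats(y_hat: np.ndarray, y: np.ndarray, n_predictors: int) -> PredictionStats:
    """RMSEP, adjusted R2 and the modelled-vs-laboratory bias line.

    ``adjusted_r2 = 1 - (1 - R2) (n - 1) / (n - n_predictors - 1)`` with
    ``n_predictors`` the number of latent components; the bias line is the
    ordinary least squares fit of the laboratory values on the predictions
    (slope 1, intercept 0 for an unbiased model).
    """
    y_hat = np.asarray(y_hat, dtype=float)
    y = np.asarray(y, dtype=float)
    if y_hat.size != y.size or y.size < 3:
        raise ValueError("need equal-length vectors with at least 3 values")
    n = y.size
    resid = y - y_hat
    rmsep = float(np.sqrt(np.mean(resid**2)))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else np.nan
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - n_predictors - 1)
    var_hat = np.var(y_hat)
    if var_hat <= 0:
        raise ValueError("zero variance in predictions: bias line undefined")
    slope = float(np.cov(y_hat, y, ddof=1)[0, 1] / np.var(y_hat, ddof=1))
    intercept = float(y.mean() - slope * y_hat.mean())
    return PredictionStats(
        rmsep=rmsep, adjusted_r2=float(adj), bias_slope=slope, bias_intercept=intercept, n=n
    )


def save_model(model: PLSRModel, path: str | Path) -> None:
    """Serialize to a self-describing versioned JSON text artifact."""
    doc = {
        "format": "orchardssc-plsr",
        "version": _SERIAL_VERSION,
        "x_mean": model.x_mean.tolist(),
        "y_mean": model.y_mean,
        "weights": model.weights.tolist(),
        "x_loadings": model.x_loadings.tolist(),
        "y_loadings": model.y_loadings.tolist(),
        "n_components": model.n_components,
        "cv_rmse_by_components": {str(k): v for k, v in model.cv_rmse_by_components.items()},
        "wavelengths": None if model.wavelengths is None else model.wavelengths.tolist(),
        "degenerate": model.degenerate,
        "training_years": list(model.training_years),
        "n_train": model.n_train,
    }
    Path(path).write_text(json.dumps(doc))


def load_model(path: str | Path) -> PLSRModel:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "orchardssc-plsr":
        raise ValueError("not a PLSR model artifact")
    if doc.get("version") != _SERIAL_VERSION:
        raise ValueError(f"unsupported model version {doc.get('version')}")
    p = len(doc["x_mean"])
    weights = np.array(doc["weights"], dtype=float).reshape(-1, p)
    return PLSRModel(
        x_mean=np.array(doc["x_mean"], dtype=float),
        y_mean=float(doc["y_mean"]),
        weights=weights,
        x_loadings=np.array(doc["x_loadings"], dtype=float).reshape(-1, p),
        y_loadings=np.array(doc["y_loadings"], dtype=float),
        n_components=int(doc["n_components"]),
        cv_rmse_by_components={int(k): float(v) for k, v in doc["cv_rmse_by_components"].items()},
        wavelengths=None if doc["wavelengths"] is None else np.array(doc["wavelengths"], float),
        degenerate=bool(doc["degenerate"]),
        training_years=tuple(doc["training_years"]),
        n_train=int(doc["n_train"]),
    )
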