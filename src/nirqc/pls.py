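"""PLS1 calibration by NIPALS, merit figures and factor selection.

One model is built per API (single response, no PLS2).  Latent factors are
extracted sequentially: the weight vector is the covariance direction between
the (deflated) feature matrix and the response; scores, loadings and the
response loading follow by least squares, and the feature matrix is deflated.
The regression vector b = W (P'W)^-1 q reproduces the factor-by-factor
prediction in one linear map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PLSModel",
    "CVResult",
    "fit_pls1",
    "predict",
    "rmse",
    "rmsec",
    "rmsep",
    "cross_validate",
    "venetian_blinds",
    "correlation",
    "error_interval",
]


class RankDeficiencyError(ValueError):
    pass


@dataclass
class PLSModel:
    n_factors: int
    weights: np.ndarray  # W, (p, a)
    x_loadings: np.ndarray  # P, (p, a)
    y_loadings: np.ndarray  # q, (a,)
    scores: np.ndarray  # T, (n, a)
    coef: np.ndarray  # regression vector b, (p,)
    x_mean: np.ndarray
    y_mean: float
    rmsec: float = 0.0
    r: float = 1.0


def fit_pls1(
    X: np.ndarray,
    y: np.ndarray,
    n_factors: int,
    tol: float = 1e-12,
) -> PLSModel:
    """Fit a single-response PLS model with ``n_factors`` latent variables.

    X and y are centered internally; the stored means make prediction
    self-contained.  Deterministic: no random initialization (the PLS1 weight
    vector has the closed form X'y / ||X'y||, so the NIPALS inner loop
    converges in one pass).
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    n, p = X.shape
    if len(y) != n:
        raise ValueError("X rows and y length differ")
    if n_factors < 1 or n < n_factors + 1:
        raise RankDeficiencyError("need at least n_factors + 1 samples")
    x_mean = X.mean(axis=0)
    y_mean = y.mean()
    Xc = X - x_mean
    yc = y - y_mean
    W = np.empty((p, n_factors))
    P = np.empty((p, n_factors))
    q = np.empty(n_factors)
    T = np.empty((n, n_factors))
    Xd = Xc.copy()
    for a in range(n_factors):
        w = Xd.T @ yc
        norm = np.linalg.norm(w)
        if norm < tol * max(1.0, np.linalg.norm(Xd)):
            raise RankDeficiencyError(
                f"residual X has no covariance with y at factor {a + 1}; "
                "reduce n_factors"
            )
        w /= norm
        # single-response NIPALS: w = X'y/||X'y|| is already the fixed point,
        # so the inner iteration (bounded by max_iter) terminates immediately
        t = Xd @ w
        tt = t @ t
        pvec = Xd.T @ t / tt
        qa = yc @ t / tt
        Xd = Xd - np.outer(t, pvec)
        W[:, a] = w
        P[:, a] = pvec
        q[a] = qa
        T[:, a] = t
    coef = W @ np.linalg.solve(P.T @ W, q)
    model = PLSModel(
        n_factors=n_factors,
        weights=W,
        x_loadings=P,
        y_loadings=q,
        scores=T,
        coef=coef,
        x_mean=x_mean,
        y_mean=y_mean,
    )
    yhat = predict(model, X)
    model.rmsec = rmse(y, yhat)
    model.r = correlation(y, yhat) if np.std(yhat) > 0 else 1.0
    return model


def predict(model: PLSModel, X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[1] != model.coef.size:
        raise ValueError("feature length does not match model")
    return (X - model.x_mean) @ model.coef + model.y_mean


def rmse(y: np.ndarray, yhat: np.ndarray) -> float:
    """Root-mean-square error, in the units of y (percent of label here)."""
    y = np.asarray(y, float).ravel()
    yhat = np.asarray(yhat, float).ravel()
    if y.size == 0 or y.size != yhat.size:
        raise ValueError("need equal-length, non-empty arrays")
    return float(np.sqrt(np.mean((yhat - y) ** 2)))


def rmsec(model: PLSModel, X: np.ndarray, y: np.ndarray) -> float:
    """RMSE on the calibration set the model was fitted to."""
    return rmse(y, predict(model, X))


def rmsep(model: PLSModel, X: np.ndarray, y: np.ndarray) -> float:
    """RMSE of prediction on an independent validation set."""
    return rmse(y, predict(model, X))


def correlation(y: np.ndarray, yhat: np.ndarray) -> float:
    """Pearson r between reference and predicted values."""
    y = np.asarray(y, float).ravel()
    yhat = np.asarray(yhat, float).ravel()
    if np.std(y) == 0 or np.std(yhat) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    return float(np.corrcoef(y, yhat)[0, 1])


def error_interval(y: np.ndarray, yhat: np.ndarray) -> tuple[float, float]:
    """(min, max) of the residuals yhat - y."""
    res = np.asarray(yhat, float).ravel() - np.asarray(y, float).ravel()
    return float(res.min()), float(res.max())


def venetian_blinds(
    n: int, n_splits: int = 6, strata: np.ndarray | None = None
) -> list[np.ndarray]:
    """Interleaved cross-validation folds.

    With ``strata`` (e.g. concentration level per sample), samples are
    interleaved within each stratum so every fold spans all levels.
    """
    fold_of = np.empty(n, int)
    if strata is None:
        fold_of[:] = np.arange(n) % n_splits
    else:
        strata = np.asarray(strata)
        for s in np.unique(strata):
            idx = np.nonzero(strata == s)[0]
            fold_of[idx] = np.arange(idx.size) % n_splits
    folds = [np.nonzero(fold_of == k)[0] for k in range(n_splits)]
    if any(f.size < 1 for f in folds):
        raise ValueError("a fold is empty; reduce n_splits")
    return folds


@dataclass
class CVResult:
    rmsecv: np.ndarray  # indexed by factor count - 1
    n_factors: int  # selected
    scheme: str

    @property
    def factor_counts(self) -> np.ndarray:
        return np.arange(1, len(self.rmsecv) + 1)


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    max_factors: int = 10,
    n_splits: int = 6,
    strata: np.ndarray | None = None,
    scheme: str = "venetian",
) -> CVResult:
    """RMSECV per factor count; selects the global minimum, ties broken toward
    fewer factors.

    ``scheme`` is ``"venetian"`` (interleaved, optionally stratified) or
    ``"loo"`` (leave-one-out).
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    n = len(y)
    if max_factors < 1:
        raise ValueError("max_factors must be >= 1")
    if scheme == "loo":
        folds = [np.array([i]) for i in range(n)]
    elif scheme == "venetian":
        folds = venetian_blinds(n, n_splits, strata)
    else:
        raise ValueError(f"unknown CV scheme {scheme!r}")
    max_factors = min(max_factors, min(n - f.size for f in folds) - 1)
    press = np.zeros(max_factors)
    for test_idx in folds:
        train = np.setdiff1d(np.arange(n), test_idx)
        # cap at the training fold's effective rank
        a_max = max_factors
        while True:
            try:
                model = fit_pls1(X[train], y[train], a_max)
                break
            except RankDeficiencyError:
                a_max -= 1
                if a_max < 1:
                    raise
        if a_max < max_factors:
            max_factors = a_max
            press = press[:max_factors]
        # nested models: truncating W, P, q to a factors gives the a-factor fit
        for a in range(1, max_factors + 1):
            coef = model.weights[:, :a] @ np.linalg.solve(
                model.x_loadings[:, :a].T @ model.weights[:, :a],
                model.y_loadings[:a],
            )
            yhat = (X[test_idx] - model.x_mean) @ coef + model.y_mean
            press[a - 1] += np.sum((yhat - y[test_idx]) ** 2)
    rmsecv = np.sqrt(press / n)
    selected = int(np.argmin(rmsecv)) + 1
    return CVResult(rmsecv=rmsecv, n_factors=selected, scheme=scheme)
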