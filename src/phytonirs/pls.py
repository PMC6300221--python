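"""PLS1 regression by NIPALS.

One latent factor at a time: the weight vector maximizes covariance between
the (deflated) spectral matrix X and the concentration vector y; scores are
projections of X on the weights; X is deflated by the score-loading outer
product after each factor.  X is column-centered only (no autoscaling —
absorbance columns share units), y is centered.

The fitted model carries both the factor expansion (W, P, q) and the folded
regression-coefficient vector; the two prediction routes agree to 1e-10 and
the invariant is asserted at fit time.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .preprocess import MscFit, PreprocessSpec

__all__ = ["PLSModel", "fit_pls", "pls_predict", "explained_x_variance",
           "save_model", "load_model", "PLSError"]

MODEL_FORMAT_VERSION = 1

NIPALS_TOL = 1e-12
NIPALS_MAX_ITER = 500


class PLSError(ValueError):
    pass


@dataclass
class PLSModel:
    """Fitted PLS1 calibration for one analyte."""

    x_mean: np.ndarray            # column means of the preprocessed training X
    y_mean: float                 # mean training concentration, µM
    weights: np.ndarray           # W, (p, A) orthonormal columns
    x_loadings: np.ndarray        # P, (p, A)
    y_loadings: np.ndarray        # q, (A,)
    n_factors: int
    coef: np.ndarray              # folded regression coefficients B, (p,)
    x_scores: np.ndarray | None = None   # T, (n, A); kept for variance decomposition
    x_total_ss: float = 0.0       # ||X_centered||_F^2 of the training set
    preprocess: PreprocessSpec | None = None
    msc_reference: np.ndarray | None = None
    analyte: str | None = None

    def predict(self, X_new: np.ndarray) -> np.ndarray:
        return pls_predict(self, X_new)


def _nipals_factor(X: np.ndarray, y: np.ndarray):
    """One NIPALS factor on deflated (X, y); returns (w, t, p, q) or None.

    For a single response the weight iteration is stationary after one
    pass; the loop is kept as a guard for numerically degenerate input.
    """
    w = X.T @ y
    nw = np.linalg.norm(w)
    if nw < 1e-14:
        return None
    w = w / nw
    for _ in range(NIPALS_MAX_ITER):
        t = X @ w
        tt = t @ t
        if tt < 1e-30:
            return None
        q = (y @ t) / tt
        if abs(q) < 1e-30:
            return None
        w_new = X.T @ (y * 1.0)
        n_new = np.linalg.norm(w_new)
        if n_new < 1e-14:
            return None
        w_new = w_new / n_new
        if np.linalg.norm(w_new - w) < NIPALS_TOL:
            w = w_new
            break
        w = w_new
    else:
        warnings.warn("NIPALS weight iteration did not converge; using last vector")
    t = X @ w
    tt = t @ t
    p = X.T @ t / tt
    q = (y @ t) / tt
    return w, t, p, q


def fit_pls(
    X: np.ndarray,
    y: np.ndarray,
    n_factors: int,
    *,
    preprocess: PreprocessSpec | None = None,
    msc_reference: np.ndarray | None = None,
    analyte: str | None = None,
) -> PLSModel:
    """Fit a PLS1 model with up to ``n_factors`` latent factors.

    Stops extracting early (with the achieved count recorded) if X deflates
    to numerical zero.  ``n_factors`` beyond min(n_samples-1, n_variables)
    is reduced with a warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n < 2:
        raise PLSError("need at least 2 samples")
    if y.shape != (n,):
        raise PLSError("y length must match rows of X")
    if np.ptp(y) == 0:
        raise PLSError("constant response y: nothing to calibrate")
    if n_factors < 0:
        raise PLSError("n_factors must be >= 0")
    max_f = min(n - 1, p)
    if n_factors > max_f:
        warnings.warn(f"n_factors {n_factors} reduced to maximum {max_f}")
        n_factors = max_f

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    yc = y - y_mean
    x_total_ss = float(np.sum(Xc * Xc))

    Ws, Ts, Ps, qs = [], [], [], []
    Xd, yd = Xc.copy(), yc.copy()
    y_ss = float(yc @ yc)
    for _ in range(n_factors):
        # stop once X or the y-covariance has deflated to numerical zero
        # (relative to the original scales) — avoids garbage factors on
        # exactly low-rank data
        if np.sum(Xd * Xd) <= 1e-20 * max(x_total_ss, 1e-300):
            break
        if float(yd @ yd) <= 1e-20 * max(y_ss, 1e-300):
            break
        fac = _nipals_factor(Xd, yd)
        if fac is None:
            break  # X (or its covariance with y) deflated to zero
        w, t, pl, q = fac
        Ws.append(w)
        Ts.append(t)
        Ps.append(pl)
        qs.append(q)
        Xd = Xd - np.outer(t, pl)
        yd = yd - q * t

    A = len(Ws)
    if A == 0:
        W = np.zeros((p, 0))
        P = np.zeros((p, 0))
        T = np.zeros((n, 0))
        q = np.zeros(0)
        coef = np.zeros(p)
    else:
        W = np.column_stack(Ws)
        P = np.column_stack(Ps)
        T = np.column_stack(Ts)
        q = np.asarray(qs)
        # folded coefficients: B = W (P'W)^{-1} q
        coef = W @ np.linalg.solve(P.T @ W, q)

    model = PLSModel(
        x_mean=x_mean, y_mean=y_mean, weights=W, x_loadings=P, y_loadings=q,
        n_factors=A, coef=coef, x_scores=T, x_total_ss=x_total_ss,
        preprocess=preprocess, msc_reference=msc_reference, analyte=analyte,
    )
    if A:
        # invariant: factor-expansion and folded-coefficient predictions agree
        y_fold = Xc @ coef + y_mean
        y_fact = _predict_by_factors(model, X)
        if np.max(np.abs(y_fold - y_fact)) > 1e-10 * max(1.0, np.max(np.abs(y))):
            raise PLSError("internal inconsistency between prediction routes")
    return model


def _predict_by_factors(model: PLSModel, X_new: np.ndarray) -> np.ndarray:
    """Predict by sequential score extraction with deflation (slow route)."""
    Xd = np.asarray(X_new, dtype=float) - model.x_mean
    yhat = np.full(Xd.shape[0], model.y_mean)
    for a in range(model.n_factors):
        t = Xd @ model.weights[:, a]
        yhat = yhat + model.y_loadings[a] * t
        Xd = Xd - np.outer(t, model.x_loadings[:, a])
    return yhat


def pls_predict(model: PLSModel, X_new: np.ndarray) -> np.ndarray:
    """ŷ = (X_new − x̄)·B + ȳ on preprocessed spectra."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.x_mean.shape[0]:
        raise PLSError(
            f"X has {X_new.shape[1]} variables; model expects {model.x_mean.shape[0]}"
        )
    return (X_new - model.x_mean) @ model.coef + model.y_mean


def explained_x_variance(model: PLSModel) -> np.ndarray:
    """Percent of centered-X sum of squares captured per factor.

    Because scores are mutually orthogonal the per-factor contributions
    ||t_a p_a'||^2 add, and their cumulative sum cannot exceed 100%.
    """
    if model.x_scores is None:
        raise PLSError("model was saved without training scores")
    if model.x_total_ss <= 0:
        return np.zeros(model.n_factors)
    out = np.empty(model.n_factors)
    for a in range(model.n_factors):
        t = model.x_scores[:, a]
        pl = model.x_loadings[:, a]
        out[a] = 100.0 * (t @ t) * (pl @ pl) / model.x_total_ss
    return out


def save_model(model: PLSModel, path) -> None:
    """Serialize a model (JSON text; includes preprocessing and MSC reference)."""
    d = {
        "format_version": MODEL_FORMAT_VERSION,
        "analyte": model.analyte,
        "x_mean": model.x_mean.tolist(),
        "y_mean": model.y_mean,
        "weights": model.weights.tolist(),
        "x_loadings": model.x_loadings.tolist(),
        "y_loadings": model.y_loadings.tolist(),
        "n_factors": model.n_factors,
        "coef": model.coef.tolist(),
        "x_scores": None if model.x_scores is None else model.x_scores.tolist(),
        "x_total_ss": model.x_total_ss,
        "preprocess": None if model.preprocess is None else model.preprocess.to_dict(),
        "msc_reference": None if model.msc_reference is None
        else np.asarray(model.msc_reference).tolist(),
    }
    Path(path).write_text(json.dumps(d))


def load_model(path) -> PLSModel:
    d = json.loads(Path(path).read_text())
    if d.get("format_version") != MODEL_FORMAT_VERSION:
        raise PLSError(f"unsupported model format {d.get('format_version')!r}")
    return PLSModel(
        x_mean=np.asarray(d["x_mean"], dtype=float),
        y_mean=float(d["y_mean"]),
        weights=np.asarray(d["weights"], dtype=float).reshape(len(d["x_mean"]), -1),
        x_loadings=np.asarray(d["x_loadings"], dtype=float).reshape(len(d["x_mean"]), -1),
        y_loadings=np.asarray(d["y_loadings"], dtype=float),
        n_factors=int(d["n_factors"]),
        coef=np.asarray(d["coef"], dtype=float),
        x_scores=None if d["x_scores"] is None else np.asarray(d["x_scores"], dtype=float),
        x_total_ss=float(d["x_total_ss"]),
        preprocess=None if d["preprocess"] is None
        else PreprocessSpec.from_dict(d["preprocess"]),
        msc_reference=None if d["msc_reference"] is None
        else np.asarray(d["msc_reference"], dtype=float),
        analyte=d["analyte"],
    )
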