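"""Calibration design, error metrics and model selection.

Standards are split 70/30 into calibration and external-validation sets,
stratified by concentration with the extreme levels forced into training.
For each candidate preprocessing recipe the latent-factor count is chosen
by minimum cross-validation error (RMSECV, parsimony on ties), the model is
refit on the full training set, and external prediction error (RMSEP) is
measured on the held-out 30% with all preprocessing statistics (window, MSC
reference, centering) frozen from training.

The selection rule over candidates: discard candidates whose prediction R²
is not positive (a model that predicts worse than the test-set mean is
invalid no matter how small its nominal error), then take minimal RMSEP,
breaking ties by fewer factors, then by smaller calibration error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pls import PLSModel, fit_pls, pls_predict
from .preprocess import PreprocessSpec, apply_preprocess
from .spectra import SpectraSet

__all__ = [
    "SplitDesign",
    "CandidateReport",
    "split_standards",
    "rmse",
    "r_squared",
    "cross_validate",
    "evaluate_candidate",
    "select_model",
    "default_grid",
    "calibrate_analyte",
    "reports_frame",
    "predict_preprocessed",
    "CalibrationError",
]

REPORT_COLUMNS = ["analyte", "method", "window_low", "window_high",
                  "rmsec", "r2_cal", "rmsecv", "rmsep", "r2_pred", "n_factors"]


class CalibrationError(ValueError):
    pass


@dataclass
class SplitDesign:
    train_ids: list[str]
    test_ids: list[str]
    seed: int

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise CalibrationError("train/test overlap")


@dataclass
class CandidateReport:
    """Metrics for one (preprocessing, window) candidate — one report row."""

    spec: PreprocessSpec
    rmsec: float
    r2_cal: float
    rmsecv: float
    rmsep: float
    r2_pred: float
    n_factors: int
    analyte: str | None = None
    model: PLSModel | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        for name in ("rmsec", "rmsecv", "rmsep"):
            v = getattr(self, name)
            if np.isfinite(v) and v < 0:
                raise CalibrationError(f"{name} must be >= 0")


def standards_for(standards: SpectraSet, analyte: str) -> SpectraSet:
    ids = [s.sample_id for s in standards.spectra
           if standards.meta[s.sample_id].role == "standard"
           and standards.meta[s.sample_id].analyte == analyte]
    if not ids:
        raise CalibrationError(f"no standards for analyte {analyte!r}")
    return standards.subset(ids)


def split_standards(standards: SpectraSet, analyte: str,
                    fraction: float = 0.7, seed: int = 0) -> SplitDesign:
    """Concentration-stratified 70/30 split with extremes forced into train.

    Standards are sorted by concentration and cut into as many consecutive
    blocks as test samples; one sample per block (never the global minimum
    or maximum level) goes to the test set.  Train size is round-half-up of
    fraction*n.  Deterministic for a given seed.
    """
    if not 0.0 < fraction < 1.0:
        raise CalibrationError("fraction must be in (0, 1)")
    sub = standards_for(standards, analyte)
    n = len(sub)
    if n < 5:
        raise CalibrationError(f"need >= 5 standards, got {n}")
    conc = sub.concentrations()
    order = np.lexsort((np.array(sub.sample_ids, dtype=object), conc))
    ids_sorted = [sub.sample_ids[i] for i in order]

    n_train = int(np.floor(fraction * n + 0.5))
    n_test = n - n_train
    if n_test < 1:
        raise CalibrationError("fraction leaves no test samples")
    rng = np.random.default_rng(seed)
    test_idx: list[int] = []
    for block in np.array_split(np.arange(n), n_test):
        allowed = [int(i) for i in block if i not in (0, n - 1)]
        if not allowed:
            raise CalibrationError("stratified split block has no eligible sample")
        test_idx.append(int(rng.choice(allowed)))
    test_ids = [ids_sorted[i] for i in test_idx]
    train_ids = [i for i in ids_sorted if i not in set(test_ids)]
    return SplitDesign(train_ids=train_ids, test_ids=test_ids, seed=seed)


def rmse(y_true, y_pred) -> float:
    """Root mean squared error: sqrt(mean((y - yhat)^2))."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.size == 0:
        raise CalibrationError("rmse needs equal, nonzero-length inputs")
    return float(np.sqrt(np.mean((y_true - y_pred) ** 2)))


def r_squared(y_true, y_pred) -> float:
    """1 - SSres/SStot; negative when predictions are worse than the mean."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.size == 0:
        raise CalibrationError("r_squared needs equal, nonzero-length inputs")
    sstot = float(np.sum((y_true - y_true.mean()) ** 2))
    if sstot == 0:
        raise CalibrationError("constant y_true: R² undefined")
    return 1.0 - float(np.sum((y_true - y_pred) ** 2)) / sstot


def _fit_on(train: SpectraSet, spec: PreprocessSpec, n_factors: int,
            analyte: str | None = None) -> PLSModel:
    """Preprocess a training set (fitting the MSC reference) and fit PLS."""
    proc, fit = apply_preprocess(train, spec)
    model = fit_pls(
        proc.as_matrix(), train.concentrations(), n_factors,
        preprocess=spec,
        msc_reference=None if fit is None else fit.reference,
        analyte=analyte,
    )
    return model


def predict_preprocessed(model: PLSModel, sset: SpectraSet) -> np.ndarray:
    """Apply a model's frozen preprocessing to a raw set, then predict."""
    if model.preprocess is None:
        raise CalibrationError("model carries no preprocessing recipe")
    proc, _ = apply_preprocess(sset, model.preprocess,
                               msc_reference=model.msc_reference)
    return pls_predict(model, proc.as_matrix())


def _coef_for(model: PLSModel, a: int) -> np.ndarray:
    W = model.weights[:, :a]
    P = model.x_loadings[:, :a]
    q = model.y_loadings[:a]
    return W @ np.linalg.solve(P.T @ W, q)


def _folds(n: int, scheme: str, k: int | None, seed: int) -> list[np.ndarray]:
    if scheme == "loo":
        return [np.array([i]) for i in range(n)]
    if scheme == "kfold":
        k = min(k or 10, n)
        if k < 2 or k > n:
            raise CalibrationError(f"k={k} invalid for n={n}")
        perm = np.random.default_rng(seed).permutation(n)
        return [np.sort(f) for f in np.array_split(perm, k)]
    raise CalibrationError(f"unknown CV scheme {scheme!r}")


def _cv_predictions(train: SpectraSet, spec: PreprocessSpec, max_factors: int,
                    folds: list[np.ndarray]) -> np.ndarray:
    """Left-out predictions, one column per factor count 1..max_factors.

    Preprocessing-dependent statistics (MSC reference, centering) are refit
    inside each fold; the factor counts share one NIPALS fit per fold since
    PLS factors are nested.
    """
    n = len(train)
    ids = train.sample_ids
    y = train.concentrations()
    preds = np.full((n, max_factors), np.nan)
    for fold in folds:
        hold = set(int(i) for i in fold)
        tr_ids = [ids[i] for i in range(n) if i not in hold]
        te = train.subset([ids[i] for i in sorted(hold)])
        model = _fit_on(train.subset(tr_ids), spec, max_factors)
        proc_te, _ = apply_preprocess(te, model.preprocess,
                                      msc_reference=model.msc_reference)
        Xte = proc_te.as_matrix() - model.x_mean
        for a in range(1, max_factors + 1):
            aa = min(a, model.n_factors)
            yhat = (Xte @ _coef_for(model, aa) + model.y_mean
                    if aa else np.full(len(fold), model.y_mean))
            preds[sorted(hold), a - 1] = yhat
    assert not np.isnan(preds).any()
    return preds


def cross_validate(train: SpectraSet, spec: PreprocessSpec, n_factors: int,
                   scheme: str = "kfold", k: int = 10, seed: int = 0) -> float:
    """RMSECV over all left-out predictions for one factor count."""
    if n_factors < 1:
        raise CalibrationError("n_factors must be >= 1")
    folds = _folds(len(train), scheme, k, seed)
    preds = _cv_predictions(train, spec, n_factors, folds)
    return rmse(train.concentrations(), preds[:, n_factors - 1])


def evaluate_candidate(standards: SpectraSet, design: SplitDesign,
                       spec: PreprocessSpec, max_factors: int = 7,
                       scheme: str = "kfold", k: int = 10,
                       seed: int = 0, analyte: str | None = None) -> CandidateReport:
    """Full metrics for one candidate recipe.

    Factor count = argmin RMSECV over 1..max_factors (ties -> fewer);
    RMSEC/R²cal on the training set; RMSEP/R²pred on the external test set
    with training-frozen preprocessing.
    """
    train = standards.subset(design.train_ids)
    test = standards.subset(design.test_ids)
    y_tr = train.concentrations()
    y_te = test.concentrations()

    folds = _folds(len(train), scheme, k, seed)
    cap = min(max_factors, len(design.train_ids) - 1 -
              int(np.ceil(len(train) / max(len(folds), 1))))
    cap = max(cap, 1)
    preds = _cv_predictions(train, spec, cap, folds)
    rmsecvs = [rmse(y_tr, preds[:, a - 1]) for a in range(1, cap + 1)]
    best_a = 1 + int(np.argmin(rmsecvs))  # argmin takes the first (fewest) on ties

    model = _fit_on(train, spec, best_a, analyte=analyte)
    yhat_tr = predict_preprocessed(model, train)
    yhat_te = predict_preprocessed(model, test)
    return CandidateReport(
        spec=spec,
        rmsec=rmse(y_tr, yhat_tr),
        r2_cal=r_squared(y_tr, yhat_tr),
        rmsecv=rmsecvs[best_a - 1],
        rmsep=rmse(y_te, yhat_te),
        r2_pred=r_squared(y_te, yhat_te),
        n_factors=model.n_factors,
        analyte=analyte,
        model=model,
    )


def select_model(candidates: list[CandidateReport],
                 r2_min: float = 0.0) -> CandidateReport:
    """Pick the best candidate: valid (r2_pred > r2_min), minimal RMSEP,
    ties by fewer factors then smaller RMSEC.

    A candidate that predicts the external set worse than its mean
    (r2_pred <= 0) is rejected however small its nominal RMSEP; if no
    candidate survives the filter, the overall-minimum-RMSEP candidate is
    returned with a warning.
    """
    if not candidates:
        raise CalibrationError("no candidates to select from")
    valid = [c for c in candidates if c.r2_pred > r2_min]
    pool = valid
    if not pool:
        warnings.warn("no candidate passed the validity filter; "
                      "returning overall minimum RMSEP")
        pool = candidates
    return min(pool, key=lambda c: (c.rmsep, c.n_factors, c.rmsec))


# Reduced windows as used in the published candidate grid, per hormone and
# pre-treatment (the derivative rows use different ranges for IAA/kinetin).
_REDUCED_WINDOWS: dict[str, dict[str, tuple[float, float]]] = {
    "IAA": {"none": (4000, 6000), "msc": (4000, 6000), "sg1d": (4000, 5000)},
    "GA": {"none": (4000, 7000), "msc": (4000, 7000), "sg1d": (4000, 7000)},
    "SA": {"none": (4000, 6000), "msc": (4000, 6000), "sg1d": (4000, 6000)},
    "kinetin": {"none": (4000, 6000), "msc": (4000, 6000), "sg1d": (4000, 7000)},
}


def default_grid(analyte: str) -> list[PreprocessSpec]:
    """Six candidates per hormone: {none, msc, sg1d} x {full, reduced window}."""
    if analyte not in _REDUCED_WINDOWS:
        raise CalibrationError(f"unknown analyte {analyte!r}")
    specs = []
    for method in ("none", "msc", "sg1d"):
        specs.append(PreprocessSpec(method=method, window_low=4000, window_high=10000))
        lo, hi = _REDUCED_WINDOWS[analyte][method]
        specs.append(PreprocessSpec(method=method, window_low=lo, window_high=hi))
    return specs


def calibrate_analyte(standards: SpectraSet, analyte: str, seed: int = 0,
                      grid: list[PreprocessSpec] | None = None,
                      fraction: float = 0.7, max_factors: int = 7,
                      scheme: str = "kfold", k: int = 10,
                      ) -> tuple[CandidateReport, list[CandidateReport], SplitDesign]:
    """Run the full candidate grid for one hormone and select the winner."""
    sub = standards_for(standards, analyte)
    design = split_standards(sub, analyte, fraction=fraction, seed=seed)
    reports = [
        evaluate_candidate(sub, design, spec, max_factors=max_factors,
                           scheme=scheme, k=k, seed=seed, analyte=analyte)
        for spec in (grid or default_grid(analyte))
    ]
    return select_model(reports), reports, design


def reports_frame(reports: list[CandidateReport]) -> pd.DataFrame:
    """Candidate reports as a table with the canonical report columns."""
    rows = []
    for c in reports:
        rows.append({
            "analyte": c.analyte or "",
            "method": c.spec.method,
            "window_low": c.spec.window_low,
            "window_high": c.spec.window_high,
            "rmsec": c.rmsec,
            "r2_cal": c.r2_cal,
            "rmsecv": c.rmsecv,
            "rmsep": c.rmsep,
            "r2_pred": c.r2_pred,
            "n_factors": c.n_factors,
        })
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)
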