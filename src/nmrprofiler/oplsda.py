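"""OPLS-DA for a two-class response, written from scratch.

Orthogonal projections to latent structures discriminant analysis splits the
X-variation into one class-predictive component and a configurable number of
orthogonal (class-uncorrelated) components.  For a single centered response
``y`` the predictive weight direction is ``w ∝ Xᵀy`` (fixed once, from the
undeflated matrix); each orthogonal component is extracted from the current
loading ``p`` as ``w_o ∝ p − (wᵀp)w``, its score/loading pair is removed from
X, and the predictive component is finally computed on the deflated matrix.

Model quality is summarized by R²X(cum) and R²Y(cum) on the training data and
by Q²(cum) = 1 − PRESS/SS from stratified sevenfold cross-validation, with
scaling refitted inside each training fold by default so held-out samples
never leak into the preprocessing.  Per-variable statistics are the S-line
pair p(ctr) (covariance between a variable and the predictive score) and
p(corr) (the same, scaled as a correlation coefficient), and VIP with a
jack-knife standard error over the cross-validation submodels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import ScalingParams, apply_scaling, fit_scaling

__all__ = [
    "ClassVector",
    "OPLSDAModel",
    "CVMetrics",
    "fit_oplsda",
    "predict",
    "cross_validate",
    "sline",
    "vip",
    "vip_with_cvse",
]


@dataclass
class ClassVector:
    """±1 class coding (control +1, case −1 by this package's convention)."""

    y: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        vals = set(np.unique(self.y))
        if not vals <= {-1.0, +1.0}:
            raise ValueError(f"class vector must be coded ±1, got values {sorted(vals)}")
        if len(vals) < 2:
            raise ValueError("both classes must be present")

    @classmethod
    def from_labels(cls, labels, positive_label) -> "ClassVector":
        y = np.where(np.asarray(labels) == positive_label, 1.0, -1.0)
        return cls(y)

    @property
    def centered(self) -> np.ndarray:
        return self.y - self.y.mean()

    @property
    def mean(self) -> float:
        return float(self.y.mean())


@dataclass
class OPLSDAModel:
    w: np.ndarray            # K, unit-norm predictive weights
    t_pred: np.ndarray       # N predictive scores
    p_pred: np.ndarray       # K predictive loadings
    q: float                 # scalar y-loading
    w_ortho: np.ndarray      # K × A_o
    t_ortho: np.ndarray      # N × A_o
    p_ortho: np.ndarray      # K × A_o
    r2x_cum: float
    r2y_cum: float
    component_r2x: dict[str, float]
    y_mean: float

    @property
    def n_ortho(self) -> int:
        return self.w_ortho.shape[1]

    @property
    def n_variables(self) -> int:
        return self.w.size

    def summary(self) -> dict:
        return {
            "n_ortho": self.n_ortho,
            "r2x_cum": self.r2x_cum,
            "r2y_cum": self.r2y_cum,
            "component_r2x": self.component_r2x,
        }


@dataclass
class CVMetrics:
    q2_cum: float
    press: float
    ss_y: float
    fold_assignment: np.ndarray          # sample index → fold
    submodels: list[OPLSDAModel] = field(default_factory=list)

    @property
    def n_folds(self) -> int:
        return int(self.fold_assignment.max()) + 1


def fit_oplsda(Xs: np.ndarray, y: ClassVector | np.ndarray, n_ortho: int = 1) -> OPLSDAModel:
    """Fit a single-response OPLS model on an already scaled matrix."""
    Xs = np.asarray(Xs, dtype=float)
    if not isinstance(y, ClassVector):
        y = ClassVector(y)
    n, k = Xs.shape
    if n != y.y.size:
        raise ValueError("X and y sample counts differ")
    if n < 4:
        raise ValueError("need at least 4 samples")
    for cls_val in (-1.0, +1.0):
        if np.sum(y.y == cls_val) < 2:
            raise ValueError("each class needs at least 2 samples")
    if n_ortho < 0 or n_ortho > n - 2:
        raise ValueError(f"n_ortho must be in [0, N-2] = [0, {n - 2}]")

    y_c = y.centered
    ss_x = float(np.sum(Xs**2))
    ss_y = float(y_c @ y_c)

    w = Xs.T @ y_c
    norm_w = np.linalg.norm(w)
    if norm_w < 1e-12 * np.sqrt(ss_x * ss_y):
        raise ValueError("no predictive direction: y is orthogonal to X")
    w /= norm_w

    X = Xs.copy()
    w_o = np.empty((k, n_ortho))
    t_o = np.empty((n, n_ortho))
    p_o = np.empty((k, n_ortho))
    comp_r2x: dict[str, float] = {}
    for a in range(n_ortho):
        t = X @ w
        p = X.T @ t / (t @ t)
        wo = p - (w @ p) * w
        nw = np.linalg.norm(wo)
        if nw < 1e-12:
            raise ValueError(f"orthogonal component {a + 1}: no orthogonal variation left")
        wo /= nw
        to = X @ wo
        po = X.T @ to / (to @ to)
        X = X - np.outer(to, po)
        w_o[:, a], t_o[:, a], p_o[:, a] = wo, to, po
        comp_r2x[f"ortho_{a + 1}"] = float((to @ to) * (po @ po) / ss_x)

    t_pred = X @ w
    tt = t_pred @ t_pred
    if tt < 1e-24:
        raise ValueError("no predictive direction after orthogonal deflation")
    p_pred = X.T @ t_pred / tt
    q = float(y_c @ t_pred / tt)
    comp_r2x = {"predictive": float(tt * (p_pred @ p_pred) / ss_x), **comp_r2x}

    resid_y = y_c - t_pred * q
    r2y = 1.0 - float(resid_y @ resid_y) / ss_y
    r2x = float(sum(comp_r2x.values()))
    return OPLSDAModel(
        w=w, t_pred=t_pred, p_pred=p_pred, q=q,
        w_ortho=w_o, t_ortho=t_o, p_ortho=p_o,
        r2x_cum=r2x, r2y_cum=r2y, component_r2x=comp_r2x, y_mean=y.mean,
    )


def predict(
    model: OPLSDAModel,
    X_new: np.ndarray,
    scaling: ScalingParams | None = None,
) -> dict:
    """Project new samples: strip orthogonal variation, score, classify.

    If ``scaling`` is given, X_new is raw and the stored training transform is
    applied first.  Returns predictive/orthogonal scores, ŷ, and ±1 labels.
    """
    X = np.asarray(X_new, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if scaling is not None:
        X = apply_scaling(X, scaling)
    if X.shape[1] != model.n_variables:
        raise ValueError("dimension mismatch between X_new and model")
    X = X.copy()
    t_ortho = np.empty((X.shape[0], model.n_ortho))
    for a in range(model.n_ortho):
        to = X @ model.w_ortho[:, a]
        X = X - np.outer(to, model.p_ortho[:, a])
        t_ortho[:, a] = to
    t_pred = X @ model.w
    y_hat = t_pred * model.q + model.y_mean
    labels = np.where(y_hat >= 0, 1.0, -1.0)
    return {"t_pred": t_pred, "t_ortho": t_ortho, "y_hat": y_hat, "labels": labels}


def _stratified_folds(y: np.ndarray, n_folds: int, seed: int) -> np.ndarray:
    """Deterministic stratified round-robin fold assignment."""
    rng = np.random.default_rng(seed)
    folds = np.empty(y.size, dtype=int)
    pointer = 0
    for cls_val in (+1.0, -1.0):
        idx = np.flatnonzero(y == cls_val)
        idx = idx[rng.permutation(idx.size)]
        for i in idx:
            folds[i] = pointer % n_folds
            pointer += 1
    return folds


def cross_validate(
    X_raw: np.ndarray,
    y: ClassVector | np.ndarray,
    n_ortho: int = 1,
    n_folds: int = 7,
    seed: int = 0,
    scaling_mode: str = "pareto",
    rescale_per_fold: bool = True,
) -> CVMetrics:
    """Stratified k-fold cross-validation on the *unscaled* matrix.

    Each training fold is scaled with its own parameters (unless
    ``rescale_per_fold`` is False, in which case the full-data scaling is
    reused — the convention of some commercial tools).  Q²(cum) uses the
    centered total sum of squares of y computed once on all samples.
    """
    X_raw = np.asarray(X_raw, dtype=float)
    if not isinstance(y, ClassVector):
        y = ClassVector(y)
    n = X_raw.shape[0]
    if n_folds > n:
        raise ValueError(f"n_folds ({n_folds}) exceeds the number of samples ({n})")
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    folds = _stratified_folds(y.y, n_folds, seed)
    for g in range(n_folds):
        train = folds != g
        if len(np.unique(y.y[train])) < 2:
            raise ValueError(
                f"training fold {g} lost a class; use fewer folds than the smaller class size"
            )

    global_params = None
    if not rescale_per_fold:
        global_params = fit_scaling(X_raw, scaling_mode)

    y_all_c = y.centered
    ss_y = float(y_all_c @ y_all_c)
    press = 0.0
    submodels: list[OPLSDAModel] = []
    for g in range(n_folds):
        train = folds != g
        test = ~train
        params = global_params or fit_scaling(X_raw[train], scaling_mode)
        Xs_train = apply_scaling(X_raw[train], params)
        m = fit_oplsda(Xs_train, ClassVector(y.y[train]), n_ortho)
        pred = predict(m, X_raw[test], scaling=params)
        press += float(np.sum((y.y[test] - pred["y_hat"]) ** 2))
        submodels.append(m)
    q2 = 1.0 - press / ss_y
    return CVMetrics(q2_cum=q2, press=press, ss_y=ss_y, fold_assignment=folds, submodels=submodels)


def sline(model: OPLSDAModel, Xs: np.ndarray, var_ids=None) -> pd.DataFrame:
    """Per-variable S-line statistics against the predictive score.

    p(ctr) is the covariance (n−1 denominator) between the predictive score
    and the scaled variable; p(corr) is the corresponding correlation
    coefficient — scale-free, so it reads as reliability rather than signal
    intensity.
    """
    Xs = np.asarray(Xs, dtype=float)
    t = model.t_pred
    if Xs.shape[0] != t.size:
        raise ValueError("Xs rows do not match model samples")
    n = t.size
    t_c = t - t.mean()
    X_c = Xs - Xs.mean(axis=0)
    p_ctr = X_c.T @ t_c / (n - 1)
    sd_t = np.sqrt(t_c @ t_c / (n - 1))
    sd_x = X_c.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd_x <= 0)
    if zero.size:
        names = ", ".join(str(var_ids[j]) if var_ids is not None else str(j) for j in zero)
        raise ValueError(f"zero-variance column(s), p(corr) undefined: var_id {names}")
    p_corr = p_ctr / (sd_t * sd_x)
    out = pd.DataFrame({"p_ctr": p_ctr, "p_corr": p_corr})
    if var_ids is not None:
        out.insert(0, "var_id", list(var_ids))
    return out


def vip(model: OPLSDAModel, mode: str = "predictive") -> np.ndarray:
    """Variable importance for the projection.

    ``predictive`` (default): VIP_j = √K·|w_j| — only the class-predictive
    component carries importance, so mean(VIP²) = 1 exactly.  ``total``
    additionally weights the orthogonal weight vectors by their explained
    X-variation; the same normalization identity holds because every weight
    vector has unit norm.
    """
    k = model.n_variables
    if mode == "predictive":
        return np.sqrt(k) * np.abs(model.w)
    if mode == "total":
        weights = [model.component_r2x["predictive"]] + [
            model.component_r2x[f"ortho_{a + 1}"] for a in range(model.n_ortho)
        ]
        weights = np.asarray(weights)
        vecs = np.column_stack([model.w] + [model.w_ortho[:, a] for a in range(model.n_ortho)])
        contrib = (vecs**2) @ weights / weights.sum()
        return np.sqrt(k * contrib)
    raise ValueError(f"unknown VIP mode {mode!r}")


def vip_with_cvse(model: OPLSDAModel, cv: CVMetrics, mode: str = "predictive") -> tuple[np.ndarray, np.ndarray]:
    """VIP from the full model plus jack-knife SE over the CV submodels.

    cvSE_j = √(((G−1)/G)·Σ_g (VIP_j⁽ᵍ⁾ − mean_g VIP_j)²) over the G submodels.
    """
    if not cv.submodels:
        raise ValueError("cross-validation submodels unavailable; run cross_validate first")
    v = vip(model, mode)
    sub = np.vstack([vip(m, mode) for m in cv.submodels])
    g = sub.shape[0]
    cvse = np.sqrt((g - 1) / g * np.sum((sub - sub.mean(axis=0)) ** 2, axis=0))
    return v, cvse
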