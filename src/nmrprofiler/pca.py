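"""Unsupervised PCA for quality control: clustering, Hotelling's T², DModX.

PCA is computed by NIPALS (iterative power method with deflation), which is
the standard chemometrics formulation and matches truncated SVD up to column
sign.  Two diagnostics flag outlying samples:

* Hotelling's T² — the Mahalanobis-style distance of a sample's scores from
  the model center, with an F-based confidence limit
  ``A(N²−1)/(N(N−A)) · F_{1−α}(A, N−A)``.
* DModX — the normalized residual distance to the model plane, with the
  F-based limit ``√F_{1−α}(K−A, (N−A−1)(K−A))``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["PCAModel", "OutlierReport", "fit_pca", "hotelling_t2", "dmodx", "outlier_report"]

_NIPALS_TOL = 1e-12
_NIPALS_MAX_ITER = 10000


class ConvergenceError(RuntimeError):
    pass


@dataclass
class PCAModel:
    scores: np.ndarray          # N × A
    loadings: np.ndarray        # K × A, orthonormal columns
    r2x: np.ndarray             # per-component explained fraction of ||X||²_F
    residual: np.ndarray        # N × K
    ss_total: float

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]

    @property
    def n_samples(self) -> int:
        return self.scores.shape[0]

    @property
    def n_variables(self) -> int:
        return self.loadings.shape[0]

    @property
    def r2x_cum(self) -> float:
        return float(self.r2x.sum())


@dataclass
class OutlierReport:
    t2: np.ndarray
    t2_limit: float
    t2_flag: np.ndarray
    dmodx: np.ndarray
    dmodx_limit: float
    dmodx_flag: np.ndarray
    alpha: float

    def to_frame(self, sample_ids=None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "t2": self.t2,
                "t2_limit": self.t2_limit,
                "t2_flag": self.t2_flag,
                "dmodx": self.dmodx,
                "dmodx_limit": self.dmodx_limit,
                "dmodx_flag": self.dmodx_flag,
            }
        )
        if sample_ids is not None:
            df.insert(0, "sample_id", list(sample_ids))
        return df


def fit_pca(Xs: np.ndarray, n_components: int) -> PCAModel:
    """NIPALS PCA on an already scaled/centered matrix.

    Each loading vector's largest-magnitude element is made positive so the
    decomposition is reproducible across runs and platforms.
    """
    Xs = np.asarray(Xs, dtype=float)
    n, k = Xs.shape
    if not (1 <= n_components <= min(n - 1, k)):
        raise ValueError(
            f"n_components must be in [1, min(N-1, K)] = [1, {min(n - 1, k)}], got {n_components}"
        )
    ss_total = float(np.sum(Xs**2))
    if ss_total == 0:
        raise ValueError("zero matrix has no principal components")
    X = Xs.copy()
    scores = np.empty((n, n_components))
    loadings = np.empty((k, n_components))
    r2x = np.empty(n_components)
    for a in range(n_components):
        t = X[:, int(np.argmax(X.var(axis=0)))].copy()
        if not np.any(t):
            t = X[:, int(np.argmax((X**2).sum(axis=0)))].copy()
        for _ in range(_NIPALS_MAX_ITER):
            p = X.T @ t / (t @ t)
            p /= np.linalg.norm(p)
            t_new = X @ p
            if np.linalg.norm(t_new - t) <= _NIPALS_TOL * np.linalg.norm(t_new):
                t = t_new
                break
            t = t_new
        else:
            raise ConvergenceError(f"NIPALS did not converge for component {a + 1}")
        p = X.T @ t / (t @ t)
        p /= np.linalg.norm(p)
        t = X @ p
        j = int(np.argmax(np.abs(p)))
        if p[j] < 0:
            p, t = -p, -t
        scores[:, a] = t
        loadings[:, a] = p
        r2x[a] = (t @ t) / ss_total
        X = X - np.outer(t, p)
    return PCAModel(scores, loadings, r2x, X, ss_total)


def hotelling_t2(model: PCAModel, alpha: float = 0.05) -> tuple[np.ndarray, float]:
    """Per-sample Hotelling T² over the model's components and its 1−α limit."""
    n, a = model.n_samples, model.n_components
    if n <= a:
        raise ValueError("Hotelling T² needs N > A")
    var = model.scores.var(axis=0, ddof=1)
    t2 = np.sum(model.scores**2 / var, axis=1)
    fcrit = stats.f.ppf(1.0 - alpha, a, n - a)
    limit = a * (n**2 - 1) / (n * (n - a)) * fcrit
    return t2, float(limit)


def dmodx(model: PCAModel, alpha: float = 0.05) -> tuple[np.ndarray, float]:
    """Normalized distance-to-model per sample and its 1−α limit.

    dmodx_i = (s_i/s0)·√(N/(N−A−1)) where s_i is the sample residual SD over
    K−A degrees of freedom and s0 the pooled residual SD; the √(N/(N−A−1))
    factor corrects for the deflation of in-model residuals.
    """
    n, a, k = model.n_samples, model.n_components, model.n_variables
    if k <= a:
        raise ValueError("DModX needs K > A")
    e = model.residual
    s_i = np.sqrt(np.sum(e**2, axis=1) / (k - a))
    denom_df = (n - a - 1) * (k - a)
    s0 = np.sqrt(np.sum(e**2) / denom_df)
    limit = float(np.sqrt(stats.f.ppf(1.0 - alpha, k - a, denom_df)))
    # a residual that is zero to machine precision means a perfect fit
    if np.sum(e**2) <= 1e-16 * model.ss_total:
        return np.zeros(n), limit
    d = (s_i / s0) * np.sqrt(n / (n - a - 1))
    return d, limit


def outlier_report(model: PCAModel, alpha: float = 0.05) -> OutlierReport:
    t2, t2_lim = hotelling_t2(model, alpha)
    d, d_lim = dmodx(model, alpha)
    return OutlierReport(
        t2=t2,
        t2_limit=t2_lim,
        t2_flag=t2 > t2_lim,
        dmodx=d,
        dmodx_limit=d_lim,
        dmodx_flag=d > d_lim,
        alpha=alpha,
    )
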