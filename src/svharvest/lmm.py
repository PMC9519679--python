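"""Single-kernel linear mixed model machinery.

Model: ``y = X beta + u + eps`` with ``u ~ N(0, sg2 K)`` and
``eps ~ N(0, se2 I)``.  Variance components are estimated by exact REML on
the spectral decomposition of K, profiling everything down to a 1-D search
over ``delta = se2 / sg2`` (EMMA-style).  With n in the tens this costs a
single symmetric eigendecomposition plus a scalar optimisation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import optimize, stats

__all__ = ["KernelEigen", "MixedModelFit", "reml_fit"]

_LOG_DELTA_BOUNDS = (-12.0, 12.0)
_REML_XTOL = 1e-8


@dataclass
class KernelEigen:
    """Cached eigendecomposition of a (PSD) kernel matrix."""

    values: np.ndarray
    vectors: np.ndarray

    @classmethod
    def from_kernel(cls, K: np.ndarray, tol: float = 1e-6) -> "KernelEigen":
        K = np.asarray(K, dtype=float)
        if not np.allclose(K, K.T, atol=1e-8):
            raise ValueError("kernel matrix must be symmetric")
        vals, vecs = np.linalg.eigh(K)
        if vals.min() < -tol * max(1.0, vals.max()):
            raise ValueError(
                f"kernel not PSD beyond tolerance (min eigenvalue {vals.min():.3g})")
        return cls(values=np.clip(vals, 0.0, None), vectors=vecs)


@dataclass
class MixedModelFit:
    beta: np.ndarray
    beta_cov: np.ndarray
    sigma2_g: float
    sigma2_e: float
    delta: float
    reml_loglik: float
    df_resid: int
    eigvals: Optional[np.ndarray] = None   # kernel eigenvalues
    Xr: Optional[np.ndarray] = None        # rotated fixed-effects design

    def satterthwaite_df(self, index: int) -> float:
        """Satterthwaite denominator degrees of freedom for one fixed
        effect: ``df = 2 c^2 / (g' I^- g)`` with ``c = Var(beta_k)``, g its
        gradient over the variance components and I the REML information.

        Treating the REML variance components as known makes the Wald t
        anticonservative at small n; this is the standard correction.  With
        an identity kernel it reduces exactly to the OLS residual df.
        """
        if self.eigvals is None or self.Xr is None:
            return float(self.df_resid)
        d, Xr = self.eigvals, self.Xr
        n, p = Xr.shape
        v = self.sigma2_g * d + self.sigma2_e          # rotated Var(y) diag
        v = np.maximum(v, 1e-12)
        Xv = Xr / v[:, None]
        A = np.linalg.inv(Xr.T @ Xv)                   # Var(beta)
        c = A[index, index]
        # gradient of c over theta = (sigma2_g, sigma2_e); dV/dtheta = D, I
        grads = []
        for dv in (d, np.ones(n)):
            M = Xv.T @ (dv[:, None] * Xv)              # X' V^-1 dV V^-1 X
            grads.append(float((A @ M @ A)[index, index]))
        g = np.array(grads)
        # REML information: I_jk = 0.5 tr(P dV_j P dV_k) with
        # P = V^-1 - V^-1 X A X' V^-1; all diagonal + low-rank in
        # rotated space, so computed densely at this n
        Vinv = np.diag(1.0 / v)
        P = Vinv - Xv @ A @ Xv.T
        info = np.empty((2, 2))
        mats = (P * d[None, :], P)                     # P @ diag(d), P @ I
        for j in range(2):
            for k in range(2):
                info[j, k] = 0.5 * np.sum(mats[j] * mats[k].T)
        denom = float(g @ np.linalg.pinv(info) @ g)
        if denom <= 0:
            return float(self.df_resid)
        df = 2.0 * c * c / denom
        return float(np.clip(df, 1.0, self.df_resid))

    def wald_t(self, index: int,
               satterthwaite: bool = True) -> tuple[float, float, float]:
        """(estimate, SE, two-sided p) for one fixed effect, using a t
        reference with Satterthwaite degrees of freedom (or the residual
        df when disabled)."""
        est = float(self.beta[index])
        se = float(np.sqrt(self.beta_cov[index, index]))
        if se == 0:
            return est, se, 1.0
        t = est / se
        df = self.satterthwaite_df(index) if satterthwaite \
            else float(self.df_resid)
        p = 2.0 * stats.t.sf(abs(t), df)
        return est, se, float(max(p, np.finfo(float).tiny))


def _neg_reml(log_delta: float, d: np.ndarray, yr: np.ndarray,
              Xr: np.ndarray) -> float:
    delta = np.exp(log_delta)
    w = d + delta
    Xw = Xr / w[:, None]
    XtWX = Xr.T @ Xw
    XtWy = Xw.T @ yr
    try:
        beta = np.linalg.solve(XtWX, XtWy)
    except np.linalg.LinAlgError:
        return np.inf
    resid = yr - Xr @ beta
    n, p = Xr.shape
    rss = float(resid @ (resid / w))
    if rss <= 0:
        return np.inf
    sign, logdet_XtWX = np.linalg.slogdet(XtWX)
    if sign <= 0:
        return np.inf
    # restricted log-likelihood up to a constant
    ll = -0.5 * ((n - p) * np.log(rss / (n - p)) + np.sum(np.log(w))
                 + logdet_XtWX)
    return -ll


def reml_fit(
    y: np.ndarray,
    X: np.ndarray,
    eig: KernelEigen,
) -> MixedModelFit:
    """Exact REML fit of the single-kernel mixed model.

    Raises ``ValueError`` when the fixed-effects design is rank deficient
    (e.g. the tested covariate is collinear with the structure PCs).
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("fixed-effects design matrix is rank deficient")
    if n - p < 1:
        raise ValueError("no residual degrees of freedom")
    U, d = eig.vectors, eig.values
    yr = U.T @ y
    Xr = U.T @ X

    res = optimize.minimize_scalar(
        _neg_reml, bounds=_LOG_DELTA_BOUNDS, args=(d, yr, Xr),
        method="bounded", options={"xatol": _REML_XTOL})
    # also probe the boundaries (sg2 -> 0 corresponds to delta -> inf)
    cands = [res.x, _LOG_DELTA_BOUNDS[0], _LOG_DELTA_BOUNDS[1]]
    log_delta = min(cands, key=lambda v: _neg_reml(v, d, yr, Xr))
    delta = float(np.exp(log_delta))

    w = d + delta
    Xw = Xr / w[:, None]
    XtWX = Xr.T @ Xw
    beta = np.linalg.solve(XtWX, Xw.T @ yr)
    resid = yr - Xr @ beta
    sg2 = float(resid @ (resid / w)) / (n - p)
    se2 = sg2 * delta
    beta_cov = sg2 * np.linalg.inv(XtWX)
    return MixedModelFit(beta=beta, beta_cov=beta_cov, sigma2_g=sg2,
                         sigma2_e=se2, delta=delta,
                         reml_loglik=-_neg_reml(log_delta, d, yr, Xr),
                         df_resid=n - p, eigvals=d, Xr=Xr)
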