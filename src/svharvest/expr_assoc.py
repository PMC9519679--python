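"""Association of SV clusters with gene expression.

Two complementary analyses mirror the cohort-scale questions:

* genome-wide: PCA of the expression matrix, then a permutation test on the
  mean absolute Pearson correlation between cluster presence/absence
  (treated as a metric character) and the loadings of the samples on a
  principal component;
* gene-level: a mixed linear model with population-structure covariates and
  a kinship random effect (PK model), testing each qualifying cluster
  against the expression of its associated gene.

Clusters qualify when their MAF exceeds 0.15 — over 23 inbreds that means a
minor count of at least four.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .lmm import KernelEigen, reml_fit
from .types import log

__all__ = ["PCResult", "expression_pca", "pc_correlation_permutation",
           "PermutationResult", "compute_kinship", "pk_association",
           "PKModelFit", "MAF_FILTER"]

MAF_FILTER = 0.15


# ---------------------------------------------------------------------------
# expression PCA
# ---------------------------------------------------------------------------

@dataclass
class PCResult:
    loadings: np.ndarray          # samples x k
    variance_fraction: np.ndarray
    sample_ids: list[str]


def expression_pca(expr: pd.DataFrame, k: int = 3) -> PCResult:
    """PCA of a genes x samples expression matrix.

    Genes (features) are centred but not scaled; the returned loadings are
    the coordinates of the samples on the first ``k`` components, with
    variance fractions relative to the total variance.
    """
    n_samples = expr.shape[1]
    if n_samples < 2:
        raise ValueError("need at least two samples")
    if not 1 <= k < n_samples:
        raise ValueError("k must satisfy 1 <= k < number of samples")
    X = expr.to_numpy(dtype=float).T          # samples x genes
    Xc = X - X.mean(axis=0, keepdims=True)
    total = float((Xc ** 2).sum())
    if total == 0:
        raise ValueError("constant expression matrix: PCA is degenerate")
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    scores = U[:, :k] * s[:k]
    var_frac = (s[:k] ** 2) / (s ** 2).sum()
    # sign convention: largest-magnitude loading positive
    for j in range(scores.shape[1]):
        i = int(np.argmax(np.abs(scores[:, j])))
        if scores[i, j] < 0:
            scores[:, j] = -scores[:, j]
    return PCResult(loadings=scores, variance_fraction=var_frac,
                    sample_ids=list(expr.columns))


# ---------------------------------------------------------------------------
# permutation test against a PC
# ---------------------------------------------------------------------------

@dataclass
class PermutationResult:
    mean_abs_r: float
    q95: float
    p_value: float
    per_cluster_r: np.ndarray
    per_cluster_p: np.ndarray
    null_means: np.ndarray


def _row_correlations(P: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Pearson r of each row of P with v (rows must be non-constant)."""
    Pc = P - P.mean(axis=1, keepdims=True)
    vc = v - v.mean()
    denom = np.sqrt((Pc ** 2).sum(axis=1) * (vc ** 2).sum())
    return (Pc @ vc) / denom


def pc_correlation_permutation(
    presence: np.ndarray,
    pc_loading: np.ndarray,
    n_perm: int = 1_000,
    seed: int = 0,
    joint: bool = False,
) -> PermutationResult:
    """Permutation test of the mean |r| between cluster presence vectors
    and one PC's sample loadings.

    The null permutes each cluster's presence vector across samples
    independently per iteration (``joint=True`` applies one shared
    permutation per iteration instead).  ``p = (1 + #{null >= observed}) /
    (n_perm + 1)``, hence bounded below by ``1/(n_perm+1)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    P = np.atleast_2d(np.asarray(presence, dtype=float))
    v = np.asarray(pc_loading, dtype=float)
    keep = P.std(axis=1) > 0
    if not keep.all():
        log.warning("excluding %d constant presence vectors",
                    int((~keep).sum()))
    P = P[keep]
    if P.shape[0] == 0:
        raise ValueError("no polymorphic presence vectors to test")
    rng = np.random.default_rng(seed)
    n_clusters, n = P.shape

    obs_r = _row_correlations(P, v)
    obs = float(np.abs(obs_r).mean())

    null_means = np.empty(n_perm)
    null_abs = np.empty((n_perm, n_clusters))
    for it in range(n_perm):
        if joint:
            perm = rng.permutation(n)
            Pp = P[:, perm]
        else:
            keys = rng.random((n_clusters, n))
            Pp = np.take_along_axis(P, np.argsort(keys, axis=1), axis=1)
        r = np.abs(_row_correlations(Pp, v))
        null_abs[it] = r
        null_means[it] = r.mean()
    p = (1.0 + float((null_means >= obs).sum())) / (n_perm + 1.0)
    per_cluster_p = (1.0 + (null_abs >= np.abs(obs_r)).sum(axis=0)) / (n_perm + 1.0)
    return PermutationResult(mean_abs_r=obs,
                             q95=float(np.quantile(null_means, 0.95)),
                             p_value=p, per_cluster_r=obs_r,
                             per_cluster_p=per_cluster_p,
                             null_means=null_means)


# ---------------------------------------------------------------------------
# kinship and the PK model
# ---------------------------------------------------------------------------

def compute_kinship(markers: np.ndarray) -> np.ndarray:
    """Additive kinship from a samples x markers 0/1 matrix.

    ``K = Z Z^T / sum_k p_k (1 - p_k)`` with Z the column-centred marker
    matrix — the realised-relationship estimator adapted to haploid coding,
    normalised so the mean diagonal is comparable to 1.  Duplicated marker
    columns leave K unchanged (both numerator and normaliser double).
    """
    M = np.asarray(markers, dtype=float)
    if M.ndim != 2 or M.shape[0] < 2:
        raise ValueError("need a samples x markers matrix with >= 2 samples")
    p = M.mean(axis=0)
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("no polymorphic markers")
    Z = M[:, poly] - p[poly]
    norm = float((p[poly] * (1 - p[poly])).sum())
    return (Z @ Z.T) / norm


@dataclass
class PKModelFit:
    beta_sv: float
    se: float
    t_stat: float
    p_value: float
    sigma2_g: float
    sigma2_e: float
    n_structure_pcs: int


def pk_association(
    presence: np.ndarray,
    expression: np.ndarray,
    structure_pcs: Optional[np.ndarray],
    kinship: np.ndarray | KernelEigen,
) -> PKModelFit:
    """PK mixed-model test of one cluster against one gene's expression.

    ``y = mu + Q b + x beta_SV + u + e`` with ``u ~ N(0, sg2 K)``; variance
    components by exact REML on the spectral decomposition of K; Wald t test
    on ``beta_SV`` with the residual degrees of freedom.  Pass a
    pre-computed :class:`KernelEigen` to amortise the decomposition over
    many genes.
    """
    x = np.asarray(presence, dtype=float)
    y = np.asarray(expression, dtype=float)
    n = len(y)
    cols = [np.ones(n)]
    n_q = 0
    if structure_pcs is not None and np.size(structure_pcs):
        Q = np.atleast_2d(np.asarray(structure_pcs, dtype=float))
        if Q.shape[0] != n:
            Q = Q.T
        cols.append(Q)
        n_q = Q.shape[1]
    cols.append(x[:, None])
    X = np.column_stack(cols)
    eig = (kinship if isinstance(kinship, KernelEigen)
           else KernelEigen.from_kernel(np.asarray(kinship)))
    fit = reml_fit(y, X, eig)
    est, se, p = fit.wald_t(X.shape[1] - 1)
    t = est / se if se > 0 else 0.0
    return PKModelFit(beta_sv=est, se=se, t_stat=t, p_value=p,
                      sigma2_g=fit.sigma2_g, sigma2_e=fit.sigma2_e,
                      n_structure_pcs=n_q)


def maf_filter(presence: np.ndarray, threshold: float = MAF_FILTER) -> np.ndarray:
    """Boolean mask of rows whose minor-presence frequency exceeds the
    threshold (MAF > 0.15 by default)."""
    P = np.atleast_2d(np.asarray(presence, dtype=float))
    f = P.mean(axis=1)
    return np.minimum(f, 1 - f) > threshold
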