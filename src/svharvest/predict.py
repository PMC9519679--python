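"""Phenotype prediction: adjusted entry means, additive relationship
matrices, GBLUP, joined weighted kernels, and replicated k-fold
cross-validation.

The multi-environment model ``y_ijk = mu + E_j + G_i + (GxE)_ij + eps_ijk``
is solved as fixed-effects least squares on the genotype x environment cell
means, which matches the balanced-design answers exactly and avoids a
mixed-model dependency at this cohort size.  The relationship matrix is
``G = W* W*^T / m`` with W* the filtered, centred, unit-variance feature
matrix; GBLUP variance components come from exact REML (see
:mod:`svharvest.lmm`), and prediction ability is the Pearson correlation of
observed and predicted adjusted entry means in the validation folds,
summarised as the median over folds and then the median over replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .lmm import KernelEigen, reml_fit

__all__ = ["adjusted_entry_means", "build_G", "GMatrix", "gblup_predict",
           "enumerate_weight_grid", "build_weighted_G", "cross_validate",
           "CVResult", "grid_search_weights"]


# ---------------------------------------------------------------------------
# adjusted entry means
# ---------------------------------------------------------------------------

def adjusted_entry_means(
    table: pd.DataFrame,
    value: str = "value",
    genotype: str = "genotype",
    environment: str = "environment",
) -> pd.Series:
    """Genotype means adjusted for environment effects.

    Fits the additive two-way model ``cell_mean_ij = mu + G_i + E_j`` on the
    genotype x environment cell means by least squares and returns, per
    genotype, its predicted value averaged over all environments.  For a
    balanced complete design this equals the simple genotype mean; genotype
    contrasts are invariant to constant shifts of any environment.
    """
    cells = (table.groupby([genotype, environment])[value]
             .mean().reset_index())
    genos = sorted(cells[genotype].unique())
    envs = sorted(cells[environment].unique())
    if len(genos) < 2:
        raise ValueError("need at least two genotypes")
    g_idx = {g: i for i, g in enumerate(genos)}
    e_idx = {e: i for i, e in enumerate(envs)}
    n_g, n_e = len(genos), len(envs)

    # estimability: the genotype-environment incidence graph must be connected
    parent = list(range(n_g + n_e))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for row in cells.itertuples(index=False):
        a = find(g_idx[getattr(row, genotype)])
        b = find(n_g + e_idx[getattr(row, environment)])
        parent[a] = b
    if len({find(i) for i in range(n_g + n_e)}) > 1:
        raise ValueError("disconnected genotype x environment design: "
                         "adjusted means are not estimable")

    X = np.zeros((len(cells), n_g + n_e))
    y = cells[value].to_numpy(dtype=float)
    for r, row in enumerate(cells.itertuples(index=False)):
        X[r, g_idx[getattr(row, genotype)]] = 1.0
        X[r, n_g + e_idx[getattr(row, environment)]] = 1.0
    beta, *_rest = np.linalg.lstsq(X, y, rcond=None)
    g_eff = beta[:n_g]
    e_eff = beta[n_g:]
    adj = g_eff + e_eff.mean()
    return pd.Series(adj, index=genos, name="adjusted_mean")


# ---------------------------------------------------------------------------
# relationship matrices
# ---------------------------------------------------------------------------

@dataclass
class GMatrix:
    values: np.ndarray
    m: int
    label: str = ""
    sample_ids: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.values.shape[0]


def build_G(
    features: np.ndarray | pd.DataFrame,
    missing_max: float = 0.2,
    label: str = "",
) -> GMatrix:
    """Additive relationship matrix ``G = W* W*^T / m`` from a samples x
    features matrix.

    Columns that are monomorphic, have a missing fraction above
    ``missing_max``, or duplicate another column (after mean imputation) are
    discarded; the survivors are centred and scaled to unit variance.
    """
    sample_ids: list[str] = []
    if isinstance(features, pd.DataFrame):
        sample_ids = [str(s) for s in features.index]
        W = features.to_numpy(dtype=float)
    else:
        W = np.array(features, dtype=float)
    if W.ndim != 2 or W.shape[0] < 2:
        raise ValueError("need a samples x features matrix with >= 2 samples")
    n = W.shape[0]

    miss = np.isnan(W)
    keep = miss.mean(axis=0) <= missing_max
    W = W[:, keep]
    miss = miss[:, keep]
    if W.shape[1] and miss.any():
        col_means = np.nanmean(W, axis=0)
        W = np.where(miss, col_means, W)
    # monomorphic columns
    sd = W.std(axis=0)
    W = W[:, sd > 0]
    # exact duplicate columns
    if W.shape[1]:
        _, first_idx = np.unique(W.round(12), axis=1, return_index=True)
        W = W[:, np.sort(first_idx)]
    m = W.shape[1]
    if m == 0:
        raise ValueError("no informative features survive filtering")
    Wstar = (W - W.mean(axis=0)) / W.std(axis=0)
    G = (Wstar @ Wstar.T) / m
    return GMatrix(values=G, m=m, label=label, sample_ids=sample_ids)


def enumerate_weight_grid(step: float = 0.1) -> list[tuple[float, float, float]]:
    """All weight triples on the step grid with w1 + w2 + w3 = 1.

    Step 0.1 yields the 66 combinations of the joined weighted relationship
    matrix; step 1.0 degenerates to the three unit vectors.
    """
    if not 0.0 < step <= 1.0:
        raise ValueError("step must lie in (0, 1]")
    units = int(round(1.0 / step))
    if abs(units * step - 1.0) > 1e-9:
        raise ValueError("step must divide 1")
    out = []
    for i in range(units, -1, -1):
        for j in range(units - i, -1, -1):
            k = units - i - j
            out.append((i / units, j / units, k / units))
    return out


def build_weighted_G(Gs: Sequence[GMatrix],
                     w: Sequence[float]) -> GMatrix:
    """Joined weighted relationship matrix ``sum_i w_i G_i``."""
    if len(Gs) != len(w):
        raise ValueError("one weight per matrix required")
    if abs(sum(w) - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1")
    shapes = {g.values.shape for g in Gs}
    if len(shapes) != 1:
        raise ValueError("matrices must cover identical samples")
    vals = sum(wi * g.values for wi, g in zip(w, Gs))
    label = "+".join(f"{wi:.1f}*{g.label or 'G'}" for wi, g in zip(w, Gs))
    return GMatrix(values=vals, m=sum(g.m for g in Gs), label=label,
                   sample_ids=list(Gs[0].sample_ids))


# ---------------------------------------------------------------------------
# GBLUP
# ---------------------------------------------------------------------------

def gblup_predict(
    G: GMatrix | np.ndarray,
    y: np.ndarray,
    train_idx: Sequence[int],
    test_idx: Sequence[int],
) -> np.ndarray:
    """GBLUP predictions of the test genomic values.

    Variance components are estimated by REML on the training block of G;
    predictions are ``mu + G[test,train] (G[train,train] + delta I)^-1
    (y_train - mu)`` with ``delta = se2/sg2`` — algebraically identical to
    kernel ridge regression with shrinkage delta on the centred response.
    """
    Gm = G.values if isinstance(G, GMatrix) else np.asarray(G, dtype=float)
    y = np.asarray(y, dtype=float)
    train = np.asarray(train_idx, dtype=int)
    test = np.asarray(test_idx, dtype=int)
    if np.intersect1d(train, test).size:
        raise ValueError("train and test sets must be disjoint")
    y_tr = y[train]
    if y_tr.std() == 0:
        raise ValueError("zero training variance")
    G_tt = Gm[np.ix_(train, train)]
    eig = KernelEigen.from_kernel(G_tt)
    fit = reml_fit(y_tr, np.ones((len(train), 1)), eig)
    mu = float(fit.beta[0])
    delta = fit.delta
    A = G_tt + delta * np.eye(len(train))
    alpha = np.linalg.solve(A, y_tr - mu)
    return mu + Gm[np.ix_(test, train)] @ alpha


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    fold_abilities: np.ndarray      # n_rep x k
    rep_medians: np.ndarray         # n_rep

    @property
    def overall(self) -> float:
        """Median over replicates of the per-replicate median ability."""
        return float(np.median(self.rep_medians))


def _fold_indices(n: int, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    perm = rng.permutation(n)
    return [np.sort(f) for f in np.array_split(perm, k)]


def cross_validate(
    G: GMatrix | np.ndarray,
    y: np.ndarray,
    k: int = 5,
    n_rep: int = 200,
    seed: int = 0,
    predictor=gblup_predict,
) -> CVResult:
    """Replicated k-fold cross-validation of GBLUP prediction ability.

    Each replicate partitions the samples uniformly into k folds whose sizes
    differ by at most one (replicate r is seeded with ``seed + r``); ability
    is the Pearson correlation of observed and predicted values within the
    validation fold.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < k:
        raise ValueError("sample count must be >= k")
    if n // k < 3:
        raise ValueError(
            f"fold size {n // k} < 3: ability correlations are unstable")
    abilities = np.empty((n_rep, k))
    for r in range(n_rep):
        rng = np.random.default_rng(seed + r)
        folds = _fold_indices(n, k, rng)
        for fi, test in enumerate(folds):
            train = np.setdiff1d(np.arange(n), test)
            pred = predictor(G, y, train, test)
            obs = y[test]
            if np.std(obs) == 0 or np.std(pred) == 0:
                abilities[r, fi] = 0.0
            else:
                abilities[r, fi] = float(np.corrcoef(obs, pred)[0, 1])
    return CVResult(fold_abilities=abilities,
                    rep_medians=np.median(abilities, axis=1))


def grid_search_weights(
    Gs: Sequence[GMatrix],
    y: np.ndarray,
    step: float = 0.1,
    k: int = 5,
    n_rep: int = 200,
    seed: int = 0,
) -> tuple[tuple[float, float, float], float, pd.DataFrame]:
    """Search the weight grid for the joined matrix maximising CV ability.

    Returns the best triple, its median-of-medians ability and the full
    surface.  Ties resolve toward a larger weight on the first kernel.
    """
    if len(Gs) != 3:
        raise ValueError("the joined weighted matrix uses exactly 3 kernels")
    rows = []
    best: Optional[tuple] = None
    for w in enumerate_weight_grid(step):
        res = cross_validate(build_weighted_G(Gs, w), y, k=k, n_rep=n_rep,
                             seed=seed)
        rows.append((*w, res.overall))
        key = (res.overall, w[0], w[1])
        if best is None or key > best[0]:
            best = (key, w, res.overall)
    surface = pd.DataFrame(rows, columns=["w1", "w2", "w3", "ability"])
    assert best is not None
    return best[1], best[2], surface
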