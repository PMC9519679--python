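"""Adjusted entry means, relationship matrices, GBLUP and cross-validation."""

import numpy as np
import pandas as pd
import pytest

import svharvest as sv
from svharvest import predict as pr
from svharvest.lmm import KernelEigen, reml_fit


def _pheno(n_geno=10, envs=("e1", "e2", "e3"), reps=2, g_effects=None,
           env_effects=None, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    g_effects = g_effects if g_effects is not None else np.zeros(n_geno)
    env_effects = env_effects if env_effects is not None \
        else np.zeros(len(envs))
    rows = []
    for i in range(n_geno):
        for j, e in enumerate(envs):
            for k in range(reps):
                rows.append((f"g{i:02d}", e, k + 1,
                             10 + g_effects[i] + env_effects[j]
                             + rng.normal(0, noise)))
    return pd.DataFrame(rows, columns=["genotype", "environment",
                                       "replicate", "value"])


class TestAdjustedMeans:
    def test_balanced_design_equals_simple_means(self):
        tab = _pheno(g_effects=np.arange(10.0),
                     env_effects=np.array([0.0, 1.0, -2.0]), noise=0.3)
        adj = pr.adjusted_entry_means(tab)
        simple = tab.groupby("genotype")["value"].mean()
        assert np.allclose(adj.to_numpy(), simple.to_numpy(), atol=1e-9)

    def test_environment_shift_leaves_contrasts(self):
        tab = _pheno(g_effects=np.arange(10.0), noise=0.5)
        shifted = tab.copy()
        shifted.loc[shifted.environment == "e2", "value"] += 10.0
        a = pr.adjusted_entry_means(tab)
        b = pr.adjusted_entry_means(shifted)
        assert np.allclose(a.to_numpy() - a.mean(),
                           b.to_numpy() - b.mean(), atol=1e-9)

    def test_disconnected_design_rejected(self):
        rows = [("g1", "e1", 1, 1.0), ("g2", "e2", 1, 2.0)]
        tab = pd.DataFrame(rows, columns=["genotype", "environment",
                                          "replicate", "value"])
        with pytest.raises(ValueError):
            pr.adjusted_entry_means(tab)

    def test_recovery_improves_with_replication(self, ref, annotation):
        def recovery(n_env, n_rep, seed):
            spec = sv.CohortSpec(n_samples=23, seed=2)
            sim = sv.simulate_cohort_omics(ref, spec, annotation, h2=0.4,
                                           n_env=n_env, n_rep=n_rep,
                                           seed=seed, rates={"A": 2e-6})
            adj = pr.adjusted_entry_means(
                sim.phenotypes[sim.phenotypes.trait == "trait1"])
            truth = sim.genetic_values.loc["trait1", adj.index]
            return np.corrcoef(adj.to_numpy(), truth.to_numpy())[0, 1]

        light = np.mean([recovery(1, 1, s) for s in range(4)])
        heavy = np.mean([recovery(7, 4, s) for s in range(4)])
        assert heavy > light
        assert heavy > 0.9


class TestBuildG:
    def test_filters_and_scaling(self):
        rng = np.random.default_rng(0)
        base = (rng.random((30, 50)) < 0.5).astype(float)
        assert np.unique(base, axis=1).shape[1] == 50
        const = np.ones((30, 1))
        dup = base[:, :1]
        missing = base[:, :1].copy()
        missing[:12] = np.nan            # 40% missing
        W = np.hstack([base, const, dup, missing])
        G = pr.build_G(W)
        assert G.m == 50                 # constant, duplicate, missing gone
        assert np.diag(G.values).mean() == pytest.approx(1.0)
        assert np.allclose(G.values, G.values.T)

    def test_light_missingness_mean_imputed(self):
        rng = np.random.default_rng(1)
        W = rng.normal(size=(20, 30))
        W[0, 0] = np.nan                 # 5% missing in one column
        G = pr.build_G(W)
        assert G.m == 30
        assert np.isfinite(G.values).all()

    def test_no_surviving_features_rejected(self):
        with pytest.raises(ValueError):
            pr.build_G(np.ones((5, 4)))


class TestGBLUP:
    def _data(self, seed=0, n=23, m=200):
        rng = np.random.default_rng(seed)
        spec = sv.CohortSpec(n_samples=n, seed=seed)
        from svharvest.synthetic_data import _draw_presence
        P = _draw_presence(m, spec, rng).astype(float)
        G = pr.build_G(P.T)
        common = np.nonzero(P.sum(axis=1) >= 3)[0]
        w = np.zeros(m)
        w[rng.choice(common, 40, replace=False)] = rng.normal(size=40)
        g = w @ P
        g = (g - g.mean()) / g.std()
        return G, g, rng

    def test_equals_kernel_ridge(self):
        from sklearn.kernel_ridge import KernelRidge
        G, g, rng = self._data(seed=3)
        y = g + rng.normal(0, 0.5, len(g))
        train, test = np.arange(18), np.arange(18, 23)
        pred = pr.gblup_predict(G, y, train, test)
        eig = KernelEigen.from_kernel(G.values[np.ix_(train, train)])
        fit = reml_fit(y[train], np.ones((18, 1)), eig)
        kr = KernelRidge(alpha=fit.delta, kernel="precomputed")
        kr.fit(G.values[np.ix_(train, train)], y[train] - fit.beta[0])
        ridge = kr.predict(G.values[np.ix_(test, train)]) + fit.beta[0]
        assert np.allclose(pred, ridge, atol=1e-6)

    def test_overlapping_split_rejected(self):
        G, g, _ = self._data()
        with pytest.raises(ValueError):
            pr.gblup_predict(G, g, [0, 1, 2, 3], [3, 4])

    def test_zero_training_variance_rejected(self):
        G, _, _ = self._data()
        with pytest.raises(ValueError):
            pr.gblup_predict(G, np.zeros(23), np.arange(18),
                             np.arange(18, 23))


class TestWeights:
    @pytest.mark.parametrize("step,count", [(0.1, 66), (0.5, 6), (1.0, 3)])
    def test_grid_sizes(self, step, count):
        grid = pr.enumerate_weight_grid(step)
        assert len(grid) == count
        assert all(abs(sum(w) - 1) < 1e-9 for w in grid)

    def test_invalid_step(self):
        with pytest.raises(ValueError):
            pr.enumerate_weight_grid(0.0)
        with pytest.raises(ValueError):
            pr.enumerate_weight_grid(0.3)

    def test_unit_weight_reproduces_member(self):
        rng = np.random.default_rng(2)
        Gs = [pr.build_G((rng.random((10, 40)) < 0.5).astype(float))
              for _ in range(3)]
        joined = pr.build_weighted_G(Gs, (1.0, 0.0, 0.0))
        assert np.array_equal(joined.values, Gs[0].values)

    def test_weighted_sum(self):
        rng = np.random.default_rng(3)
        Gs = [pr.build_G((rng.random((8, 40)) < 0.5).astype(float))
              for _ in range(3)]
        w = (0.5, 0.3, 0.2)
        joined = pr.build_weighted_G(Gs, w)
        manual = sum(wi * g.values for wi, g in zip(w, Gs))
        assert np.allclose(joined.values, manual)


class TestCV:
    def test_fold_sizes_balanced(self):
        rng = np.random.default_rng(0)
        folds = pr._fold_indices(23, 5, rng)
        assert sorted(len(f) for f in folds) == [4, 4, 5, 5, 5]
        assert sorted(np.concatenate(folds).tolist()) == list(range(23))

    def test_oracle_predictor_scores_one(self):
        y = np.random.default_rng(1).normal(size=23)

        def oracle(G, yv, train, test):
            return yv[np.asarray(test)]

        res = pr.cross_validate(np.eye(23), y, n_rep=5, seed=0,
                                predictor=oracle)
        assert np.allclose(res.fold_abilities, 1.0)
        assert res.overall == 1.0

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(2)
        G = pr.build_G((rng.random((23, 100)) < 0.5).astype(float))
        y = rng.normal(size=23)
        a = pr.cross_validate(G, y, n_rep=5, seed=9)
        b = pr.cross_validate(G, y, n_rep=5, seed=9)
        assert np.array_equal(a.fold_abilities, b.fold_abilities)

    def test_small_folds_rejected(self):
        with pytest.raises(ValueError):
            pr.cross_validate(np.eye(10), np.arange(10.0), k=5, n_rep=1)


class TestRecoveryAndOrdering:
    def test_reml_variance_recovery_scaled_up(self):
        # n = 200, h2 = 0.5: REML components within 25% relative error
        rng = np.random.default_rng(4)
        n, m = 200, 500
        M = (rng.random((n, m)) < 0.5).astype(float)
        G = pr.build_G(M)
        eig = KernelEigen.from_kernel(G.values)
        L = eig.vectors * np.sqrt(eig.values)
        g = L @ rng.normal(size=n)
        y = g + rng.normal(0, 1.0, n)        # sg2 = se2 = 1
        fit = reml_fit(y, np.ones((n, 1)), eig)
        assert abs(fit.sigma2_g - 1.0) < 0.25
        assert abs(fit.sigma2_e - 1.0) < 0.25

    def test_sv_kernel_beats_random_kernel(self, ref, annotation):
        # phenotypes generated from SV presence: the SV kernel must beat a
        # kernel of independent random features (paired over cohorts)
        wins = 0
        n_cohorts = 6
        for seed in range(n_cohorts):
            spec = sv.CohortSpec(n_samples=23, seed=seed)
            sim = sv.simulate_cohort_omics(ref, spec, annotation, h2=0.8,
                                           n_env=3, n_rep=2, seed=seed + 50,
                                           rates={"A": 2e-6, "B": 1e-6})
            adj = pr.adjusted_entry_means(
                sim.phenotypes[sim.phenotypes.trait == "trait1"])
            y = adj.loc[sim.sample_ids].to_numpy()
            P = sim.presence.to_numpy(dtype=float).T
            G_sv = pr.build_G(P)
            rng = np.random.default_rng(seed + 999)
            G_rand = pr.build_G((rng.random(P.shape) < 0.3).astype(float))
            a_sv = pr.cross_validate(G_sv, y, n_rep=10, seed=seed).overall
            a_rand = pr.cross_validate(G_rand, y, n_rep=10,
                                       seed=seed).overall
            wins += a_sv >= a_rand
        assert wins >= 5
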