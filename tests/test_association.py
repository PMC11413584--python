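import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seaselect.association import (
    CHI2_1_MEDIAN,
    choose_k,
    consensus,
    fst_outlier_scan,
    lfmm_scan,
    prune_collinear,
    rda_scan,
)
from seaselect.simulate import SimParams, simulate_env, simulate_genotypes

from conftest import make_gm, random_gm


class TestPruneCollinear:
    def test_perfect_pair_keeps_first_listed(self, rng):
        a = rng.standard_normal(30)
        env = pd.DataFrame({"A": a, "B": a.copy(), "C": rng.standard_normal(30)})
        pruned, removed = prune_collinear(env)
        assert list(pruned.columns) == ["A", "C"]
        assert removed == ["B"]

    def test_identity_when_below_threshold(self, rng):
        env = pd.DataFrame(rng.standard_normal((100, 4)), columns=list("ABCD"))
        pruned, removed = prune_collinear(env)
        assert removed == []
        assert list(pruned.columns) == list("ABCD")

    def test_planted_near_duplicates_removed(self, rng):
        base = rng.standard_normal((40, 10))
        dup = base[:, :4] + 0.01 * rng.standard_normal((40, 4))
        env = pd.DataFrame(
            np.column_stack([base, dup]),
            columns=[f"P{i:02d}" for i in range(14)],
        )
        pruned, removed = prune_collinear(env)
        assert pruned.shape[1] == 10
        assert set(removed) == {"P10", "P11", "P12", "P13"}

    def test_constant_predictor_dropped(self, rng):
        env = pd.DataFrame({"A": np.ones(10), "B": rng.standard_normal(10)})
        pruned, removed = prune_collinear(env)
        assert "A" in removed and list(pruned.columns) == ["B"]


class TestRda:
    def _sim(self, seed=21, n_loci=400, n_adaptive=10, beta=2.0):
        params = SimParams(
            n_pops=8, n_per_pop=25, n_loci=n_loci, F=0.05,
            n_adaptive=n_adaptive, beta=beta, missing_rate=0.05, seed=seed,
        )
        env = simulate_env(8, predictor_names=["A", "B", "C"], seed=seed + 1)
        gm, meta, truth = simulate_genotypes(params, env)
        return gm, meta, env, truth

    def test_loading_threshold_semantics(self):
        """A SNP at 3.5 sigma is flagged, one at 2.9 sigma is not."""
        from seaselect import association

        rng = np.random.default_rng(0)
        load = rng.standard_normal(2000) * 0.01
        load = (load - load.mean()) / load.std() * load.std()  # centered
        sd = load.std()
        load[0] = load.mean() + 3.5 * sd
        load[1] = load.mean() + 2.9 * sd
        sd2 = load.std()
        mu = load.mean()
        flagged = np.abs(load - mu) > 3.0 * sd2
        assert flagged[0] and not flagged[1]

    def test_constrained_decomposition_matches_projection_oracle(self, rng):
        """RDA eigenvalues/loadings equal explicit hat-matrix projection
        followed by PCA."""
        from seaselect.association import _constrained_decomposition

        for _ in range(10):
            n, m, q = 20, 15, 3
            Y = rng.standard_normal((n, m))
            Y -= Y.mean(axis=0)
            X = rng.standard_normal((n, q))
            eig, _eres, _site, load, rank = _constrained_decomposition(Y, X)
            H = X @ np.linalg.pinv(X.T @ X) @ X.T
            Yhat = H @ Y
            evals, evecs = np.linalg.eigh(Yhat.T @ Yhat / (n - 1))
            evals = evals[::-1][:rank]
            np.testing.assert_allclose(eig, evals, atol=1e-8)
            for k in range(rank):
                v = evecs[:, ::-1][:, k]
                assert np.abs(np.abs(load[:, k] @ v) - 1) < 1e-8

    def test_recovers_planted_loci(self):
        gm, meta, env, truth = self._sim()
        _res, flags = rda_scan(
            gm, env, meta["locality"].to_numpy(), n_perm=99, seed=3
        )
        adaptive = set(truth.adaptive_locus_ids)
        recall = len(flags & adaptive) / len(adaptive)
        fpr = len(flags - adaptive) / (gm.n_loci - len(adaptive))
        assert recall >= 0.7
        assert fpr <= 0.02

    def test_null_full_model_not_significant(self):
        """Breaking the individual-to-environment link before fitting
        leaves the full model non-significant in most replicates."""
        n_ok = 0
        reps = 8
        for seed in range(reps):
            gm, meta, env, _ = self._sim(seed=50 + seed, n_loci=200, n_adaptive=0)
            rng = np.random.default_rng(seed)
            shuffled_locs = rng.permutation(meta["locality"].to_numpy())
            res, _ = rda_scan(gm, env, shuffled_locs, n_perm=99, seed=seed)
            if res.full_model_p > 0.05:
                n_ok += 1
        assert n_ok >= reps - 1


class TestLfmm:
    def test_gif_median_identity(self):
        """If every z^2 equals the chi2_1 median, lambda is 1."""
        z = np.full(100, np.sqrt(CHI2_1_MEDIAN))
        lam = np.median(z**2) / CHI2_1_MEDIAN
        assert lam == pytest.approx(1.0)

    def test_scale_equivariance_of_adjusted_statistic(self, rng):
        z = rng.standard_normal(500)
        lam = np.median(z**2) / CHI2_1_MEDIAN
        lam2 = np.median((2 * z) ** 2) / CHI2_1_MEDIAN
        assert lam2 == pytest.approx(4 * lam)
        np.testing.assert_allclose(z**2 / lam, (2 * z) ** 2 / lam2)

    def test_k0_matches_ols(self, rng):
        """With no latent factors the scan is per-SNP simple regression."""
        import statsmodels.api as sm

        gm = random_gm(rng, 40, 25)
        x = rng.standard_normal(40)
        res, _ = lfmm_scan(gm, x, K=0)
        xs = (x - x.mean()) / x.std()
        for j in range(5):
            y = gm.genotypes[:, j].astype(float)
            y = y - y.mean()
            fit = sm.OLS(y, sm.add_constant(xs)).fit()
            assert res.z[j] == pytest.approx(fit.tvalues[1], rel=1e-8)

    def test_null_calibration(self):
        params = SimParams(
            n_pops=8, n_per_pop=30, n_loci=2000, F=0.05, n_adaptive=0,
            missing_rate=0.05, seed=11,
        )
        env = simulate_env(8, predictor_names=["A"], seed=12)
        gm, meta, _ = simulate_genotypes(params, env)
        x = env.loc[meta["locality"], "A"].reset_index(drop=True)
        _res, flags = lfmm_scan(gm, x, K=7, alpha=0.01)
        fpr = len(flags) / gm.n_loci
        assert 0.002 <= fpr <= 0.03

    def test_k_bounds_rejected(self, rng):
        gm = random_gm(rng, 10, 20)
        with pytest.raises(ValueError, match="K must be smaller"):
            lfmm_scan(gm, rng.standard_normal(10), K=10)


class TestChooseK:
    def test_island_structure_recovered(self):
        params = SimParams(
            n_pops=4, n_per_pop=30, n_loci=500, F=0.15, n_adaptive=0,
            missing_rate=0.0, seed=9,
        )
        env = simulate_env(4, seed=9)
        gm, _meta, _ = simulate_genotypes(params, env)
        K = choose_k(gm, k_max=8, seed=2)
        assert K in {2, 3, 4}

    def test_panmictic_low_k(self):
        params = SimParams(
            n_pops=1, n_per_pop=100, n_loci=500, F=0.05, n_adaptive=0,
            missing_rate=0.0, seed=10,
        )
        env = simulate_env(1, seed=10)
        gm, _meta, _ = simulate_genotypes(params, env)
        assert choose_k(gm, k_max=5, seed=2) in {0, 1}

    def test_deterministic(self, rng):
        gm = random_gm(rng, 30, 80)
        assert choose_k(gm, 5, seed=7) == choose_k(gm, 5, seed=7)


class TestFstOutlierScan:
    def test_panmictic_calibration(self):
        """Essentially no discoveries on undifferentiated data."""
        total = 0
        for seed in range(5):
            params = SimParams(
                n_pops=4, n_per_pop=25, n_loci=200, F=0.002, n_adaptive=0,
                missing_rate=0.0, seed=60 + seed,
            )
            env = simulate_env(4, seed=60 + seed)
            gm, meta, _ = simulate_genotypes(params, env)
            _tbl, flags = fst_outlier_scan(
                gm, meta["locality"].to_numpy(), n_perm=2000, seed=seed
            )
            total += len(flags)
        assert total <= 1

    def test_planted_high_fst_recovered(self):
        """Strongly differentiated loci on a weak background are found."""
        rng = np.random.default_rng(5)
        n_pops, n_per = 4, 30
        # background: F=0.02; planted: fixed-ish differences
        params = SimParams(
            n_pops=n_pops, n_per_pop=n_per, n_loci=990, F=0.02, n_adaptive=0,
            missing_rate=0.0, seed=70,
        )
        env = simulate_env(n_pops, seed=70)
        gm, meta, _ = simulate_genotypes(params, env)
        planted = np.zeros((n_pops * n_per, 10), dtype=np.int16)
        freqs = np.tile([0.05, 0.35, 0.65, 0.95], 10// 2 + 1)
        for j in range(10):
            for p in range(n_pops):
                f = freqs[(j + p) % 4]
                planted[p * n_per : (p + 1) * n_per, j] = rng.binomial(2, f, n_per)
        geno = np.hstack([gm.genotypes, planted])
        gm_all = make_gm(geno)
        _tbl, flags = fst_outlier_scan(
            gm_all, meta["locality"].to_numpy(), n_perm=5000, seed=1
        )
        planted_ids = {f"l{j}" for j in range(990, 1000)}
        assert len(flags & planted_ids) >= 8

    def test_p_value_bounds(self, rng):
        gm = random_gm(rng, 20, 50)
        pops = np.repeat(["a", "b"], 10)
        tbl, _ = fst_outlier_scan(gm, pops, n_perm=500, seed=0)
        p = tbl["p"].dropna()
        assert (p > 0).all() and (p <= 1).all()


class TestConsensus:
    def test_set_algebra_example(self):
        part = consensus(
            {"rda": {"1", "2"}, "lfmm": {"2", "3"}, "fst": {"3", "4"}},
            universe={"1", "2", "3", "4", "5", "6"},
        )
        assert part.consensus == {"2", "3"}
        assert part.union == {"1", "2", "3", "4"}
        assert part.neutral == {"5", "6"}

    def test_empty_and_identical_sets(self):
        empty = consensus(
            {"a": set(), "b": set(), "c": set()}, universe={"x", "y"}
        )
        assert empty.consensus == set() and empty.neutral == {"x", "y"}
        same = consensus(
            {"a": {"x"}, "b": {"x"}, "c": {"x"}}, universe={"x", "y"}
        )
        assert same.consensus == same.union == {"x"}

    def test_flag_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="outside the universe"):
            consensus({"a": {"z"}}, universe={"x"})

    @settings(max_examples=50, deadline=None)
    @given(
        a=st.sets(st.integers(0, 20)),
        b=st.sets(st.integers(0, 20)),
        c=st.sets(st.integers(0, 20)),
        extra=st.sets(st.integers(0, 20)),
    )
    def test_monotone_and_partition_properties(self, a, b, c, extra):
        universe = set(range(21))
        ids = lambda s: {str(i) for i in s}
        part = consensus(
            {"a": ids(a), "b": ids(b), "c": ids(c)}, universe=ids(universe)
        )
        assert part.consensus <= part.union
        assert part.neutral == ids(universe) - part.union
        # enlarging one input never shrinks the union
        bigger = consensus(
            {"a": ids(a | extra), "b": ids(b), "c": ids(c)},
            universe=ids(universe),
        )
        assert part.union <= bigger.union
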