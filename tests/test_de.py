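"""Paired NB GLM: fitting, dispersions, LRT calibration, BH, power."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from dualseq import de, glm
from dualseq.de import (
    PairedNBModel,
    bh_adjust,
    build_design,
    estimate_dispersions,
    fit_gene_glm,
    likelihood_ratio_test,
    run_de,
)


def paired_design(n_pairs=4):
    conditions = ["a", "b"] * n_pairs
    pairs = np.repeat([f"P{i}" for i in range(n_pairs)], 2)
    return build_design(conditions, pairs)[0]


def group_design(n_per_group=4):
    return build_design(["a"] * n_per_group + ["b"] * n_per_group)[0]


def nb_sample(rng, mu, phi):
    if phi <= 0:
        return rng.poisson(mu)
    return rng.poisson(rng.gamma(1.0 / phi, phi * mu))


class TestDesign:
    def test_two_levels_required(self):
        with pytest.raises(ValueError, match="two condition"):
            build_design(["a", "b", "c"])

    def test_incomplete_pair_rejected(self):
        with pytest.raises(ValueError, match="pair"):
            build_design(["a", "a", "b", "b"], pairs=["P1", "P1", "P2", "P2"])


class TestGeneGLM:
    def test_null_gene_zero_logfc(self):
        X = paired_design(2)
        y = np.array([30, 30, 12, 12], float)
        fit = fit_gene_glm(y, X, 0.1)
        assert abs(fit["log2_fold_change"]) < 1e-6

    def test_exact_doubling_gives_unit_logfc(self):
        """Poisson MLE for a doubled condition is the exact count ratio."""
        X = paired_design(4)
        y = np.array([10, 20, 30, 60, 5, 10, 40, 80], float)
        fit = fit_gene_glm(y, X, 0.0)
        assert fit["log2_fold_change"] == pytest.approx(1.0, abs=1e-6)

    def test_all_zero_gene(self):
        X = group_design(3)
        fit = fit_gene_glm(np.zeros(6), X, 0.1)
        assert fit["log2_fold_change"] == 0.0
        assert fit["all_zero"]

    def test_likelihood_grid_oracle(self):
        """The IRLS optimum beats 100 perturbed condition coefficients."""
        rng = np.random.default_rng(1)
        X = group_design(4)
        y = nb_sample(rng, np.array([40, 40, 40, 40, 90, 90, 90, 90.0]), 0.1)
        fit = fit_gene_glm(y, X, 0.1)
        beta = fit["coefficients"]
        ll_opt = fit["loglik"]

        def loglik_at(b_cond):
            # profile the intercept at each perturbed condition coefficient
            def neg(b0):
                mu = np.exp(X @ np.array([b0, b_cond]))
                return -glm.nb_loglik(y, mu, 0.1)[0]

            res = optimize.minimize_scalar(neg, bounds=(-5, 15), method="bounded")
            return -res.fun

        for delta in np.linspace(-2, 2, 100):
            if abs(delta) < 1e-9:
                continue
            assert ll_opt + 1e-6 >= loglik_at(beta[1] + delta)

    def test_matches_statsmodels_nb_glm(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(2)
        X = group_design(4)
        y = nb_sample(rng, np.full(8, 60.0), 0.2).astype(float)
        off = np.log(rng.uniform(0.8, 1.2, 8))
        ours = fit_gene_glm(y, X, 0.2, offset=off)
        ref = sm.GLM(
            y, X, family=sm.families.NegativeBinomial(alpha=0.2), offset=off
        ).fit()
        assert np.allclose(ours["coefficients"], ref.params, atol=1e-6)


class TestDispersions:
    def test_poisson_data_boundary(self):
        rng = np.random.default_rng(3)
        mu = rng.lognormal(4, 1, 1000)[:, None] * np.ones(8)
        Y = rng.poisson(mu)
        est = estimate_dispersions(Y, group_design(4))
        assert est.common < 0.01

    def test_recovery_of_true_dispersion(self):
        X = group_design(4)
        for seed in range(3):
            rng = np.random.default_rng(100 + seed)
            mu = rng.lognormal(4, 1, 2000)[:, None] * np.ones(8)
            Y = nb_sample(rng, mu, 0.2)
            est = estimate_dispersions(Y, X)
            assert 0.15 <= est.common <= 0.25

    def test_infinite_prior_shrinks_to_common(self):
        rng = np.random.default_rng(4)
        mu = rng.lognormal(4, 1, 300)[:, None] * np.ones(8)
        Y = nb_sample(rng, mu, 0.15)
        est = estimate_dispersions(Y, group_design(4), prior_df=1e9)
        assert np.allclose(est.tagwise, est.common, rtol=0.06)

    def test_no_residual_df_raises(self):
        with pytest.raises(ValueError):
            estimate_dispersions(np.ones((10, 2)), np.eye(2))


class TestLRT:
    def test_identical_fits(self):
        stat, p = likelihood_ratio_test(-10.0, -10.0)
        assert stat == 0.0 and p == pytest.approx(1.0)

    def test_negative_statistic_raises(self):
        with pytest.raises(ValueError):
            likelihood_ratio_test(-11.0, -10.0)

    def test_statistic_equals_deviance_difference(self):
        """3v3 toy gene: 2*Δloglik equals the deviance drop computed with
        independent direct optimization of both models."""
        rng = np.random.default_rng(5)
        X = group_design(3)
        y = nb_sample(rng, np.array([20, 20, 20, 55, 55, 55.0]), 0.1).astype(float)
        phi = 0.1
        full = fit_gene_glm(y, X, phi)
        red = fit_gene_glm(y, X[:, :1], phi)
        stat, p = likelihood_ratio_test(full["loglik"], red["loglik"])

        def best_loglik(design):
            def neg(beta):
                mu = np.exp(design @ beta)
                return -glm.nb_loglik(y, mu, phi)[0]

            res = optimize.minimize(neg, np.zeros(design.shape[1]), method="Nelder-Mead",
                                    options={"xatol": 1e-10, "fatol": 1e-12})
            return -res.fun

        stat_oracle = 2.0 * (best_loglik(X) - best_loglik(X[:, :1]))
        assert stat == pytest.approx(stat_oracle, abs=1e-4)

    def test_null_pvalues_uniform(self):
        """Under a correctly specified NB null the LRT p-values are
        uniform (KS not rejected at alpha=0.01 in most seeds)."""
        X = group_design(4)
        ok = 0
        n_seeds = 6
        for seed in range(n_seeds):
            rng = np.random.default_rng(600 + seed)
            mu = rng.lognormal(4, 1, 1500)[:, None] * np.ones(8)
            Y = nb_sample(rng, mu, 0.1)
            model = PairedNBModel(Y, ["a"] * 4 + ["b"] * 4)
            res = model.fit(dispersion=0.1)
            ks = stats.kstest(res.table["p_value"], "uniform")
            ok += ks.pvalue > 0.01
        assert ok >= n_seeds - 1


class TestBH:
    def test_hand_computed_step_up(self):
        assert np.allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_all_ones(self):
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_single_p(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_matches_independent_step_up(self):
        rng = np.random.default_rng(6)
        p = rng.random(200)
        got = bh_adjust(p)
        # literal step-up: sort, scale by m/rank, cummin from the top
        order = np.argsort(p)
        m = len(p)
        scaled = p[order] * m / np.arange(1, m + 1)
        adj = np.minimum.accumulate(scaled[::-1])[::-1]
        expect = np.empty(m)
        expect[order] = np.minimum(adj, 1.0)
        assert np.allclose(got, expect)


class TestRunDE:
    def _simulate(self, seed, n_pairs=4, frac_de=0.0, log2fc=2.0, phi=0.1,
                  pair_sd=0.0, G=2000):
        rng = np.random.default_rng(seed)
        base = rng.lognormal(4, 1, G)
        de_mask = np.zeros(G, bool)
        n_de = int(frac_de * G)
        de_mask[:n_de] = True
        sign = rng.choice([-1.0, 1.0], G)
        fc = np.where(de_mask, 2.0 ** (sign * log2fc), 1.0)
        cols, conditions, pairs = {}, [], []
        for i in range(n_pairs):
            shift = np.exp(rng.normal(0, pair_sd, G))
            cols[f"a{i}"] = nb_sample(rng, base * shift, phi)
            cols[f"b{i}"] = nb_sample(rng, base * shift * fc, phi)
            conditions += ["a", "b"]
            pairs += [f"P{i}", f"P{i}"]
        return pd.DataFrame(cols)[[f"{c}{i}" for i in range(n_pairs) for c in "ab"]], \
            ["a", "b"] * n_pairs, pairs, de_mask

    def test_null_false_discovery_proportion(self):
        fdps = []
        for seed in range(8):
            counts, conditions, pairs, _ = self._simulate(700 + seed, G=1000)
            res = run_de(counts, conditions, pairs=pairs)
            sig = res.significant()
            fdps.append(1.0 if len(sig) else 0.0)
        se = np.std(fdps) / np.sqrt(len(fdps))
        assert np.mean(fdps) <= 0.05 + 2 * se + 1e-12

    def test_planted_de_sensitivity(self):
        counts, conditions, pairs, de_mask = self._simulate(
            42, frac_de=0.1, log2fc=2.0, phi=0.1
        )
        res = run_de(counts, conditions, pairs=pairs)
        sig = set(res.significant().index)
        true = set(np.flatnonzero(de_mask))
        assert len(sig & true) / len(true) >= 0.7

    def test_direction_bookkeeping(self):
        counts, conditions, pairs, _ = self._simulate(43, frac_de=0.1)
        res = run_de(counts, conditions, pairs=pairs)
        sig = res.significant()
        assert res.n_up == (sig["log2_fold_change"] > 0).sum()
        assert res.n_up + res.n_down == len(sig)
        assert (sig["direction"] == np.where(sig["log2_fold_change"] > 0, "up", "down")).all()

    def test_pairing_increases_power(self):
        """With strong pair effects the paired analysis finds more of the
        planted genes than the unpaired one, averaged over seeds."""
        gains = []
        for seed in range(6):
            counts, conditions, pairs, de_mask = self._simulate(
                800 + seed, frac_de=0.1, log2fc=1.5, phi=0.05, pair_sd=0.7, G=600
            )
            true = set(np.flatnonzero(de_mask))
            paired = run_de(counts, conditions, pairs=pairs)
            unpaired = run_de(counts, conditions)
            hit_p = len(set(paired.significant().index) & true)
            hit_u = len(set(unpaired.significant().index) & true)
            gains.append(hit_p - hit_u)
        assert np.mean(gains) > 0

    def test_gene_permutation_invariance(self):
        counts, conditions, pairs, _ = self._simulate(44, frac_de=0.05, G=500)
        res1 = run_de(counts, conditions, pairs=pairs)
        perm = np.random.default_rng(0).permutation(len(counts))
        res2 = run_de(counts.iloc[perm], conditions, pairs=pairs)
        assert set(res2.significant().index) == set(res1.significant().index)

    def test_fdr_monotone_vs_pvalue(self):
        counts, conditions, pairs, _ = self._simulate(45, frac_de=0.05, G=400)
        res = run_de(counts, conditions, pairs=pairs)
        assert (res.table["fdr"] >= res.table["p_value"] - 1e-12).all()

    def test_summary_mentions_counts(self):
        counts, conditions, pairs, _ = self._simulate(46, G=300)
        res = run_de(counts, conditions, pairs=pairs)
        text = res.summary()
        assert "genes tested" in text and "300" in text
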