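"""Randomisation/correlation inference, GLM and back-calculation oracles."""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
import pytest
from scipy import optimize, stats
from scipy.special import expit, logit

from fallout import stats_inference as si
from fallout.exposure_geo import ColonyRecord


def colony(i, banded, recovered, **cov):
    return ColonyRecord(
        colony_id=f"c{i}",
        centre_lon=-16.5,
        centre_lat=28.3,
        n_banded=banded,
        n_recovered=recovered,
        **cov,
    )


def random_colonies(rng, n, beta0=-2.0, slope=0.0, covariate="distance_to_sea_m", scale=5000.0):
    out = []
    for i in range(n):
        x = float(rng.uniform(0, scale))
        p = float(expit(beta0 + slope * x))
        nb = int(rng.integers(10, 60))
        out.append(
            colony(
                i,
                nb,
                int(rng.binomial(nb, p)),
                elevation_m=float(rng.uniform(0, 1000)),
                distance_to_sea_m=x if covariate == "distance_to_sea_m" else float(rng.uniform(0, 5000)),
                radiance_at_colony=float(rng.uniform(0, 30)),
                radiance_mean_3km=float(rng.uniform(0, 30)),
                radiance_max_3km=float(rng.uniform(30, 100)),
            )
        )
    return out


def binom_loglik(params, x, succ, fail):
    eta = params[0] + (params[1] * x if len(params) > 1 else 0.0)
    p = expit(eta)
    ll = succ * np.log(p) + fail * np.log1p(-p)
    # binomial coefficient terms to match the full likelihood
    ll += [math.lgamma(s + f + 1) - math.lgamma(s + 1) - math.lgamma(f + 1) for s, f in zip(succ, fail)]
    return float(np.sum(ll))


class TestCountArrangements:
    def test_study_sample_sizes(self):
        assert si.count_arrangements(18, 13) == 8568
        assert si.count_arrangements(32, 20) == 225_792_840

    def test_degenerate_group(self):
        assert si.count_arrangements(7, 0) == 1

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            si.count_arrangements(5, 6)


class TestRandomisationTest:
    def test_separated_groups_exhaustive(self):
        r = si.randomisation_test([1, 2, 3], [10, 11, 12])
        assert r.method == "exhaustive"
        assert r.n_arrangements == 20
        assert r.statistic == pytest.approx(-9.0)
        assert r.p_value == pytest.approx(0.1)

    def test_identical_multisets_p_one(self):
        r = si.randomisation_test([1.0, 2.0], [2.0, 1.0])
        assert r.p_value == 1.0

    def test_constant_pooled_data_warns(self):
        with pytest.warns(UserWarning, match="constant"):
            r = si.randomisation_test([3.0, 3.0], [3.0, 3.0, 3.0])
        assert r.p_value == 1.0

    @pytest.mark.parametrize("n,n1", [(4, 2), (6, 3), (7, 2), (8, 4), (9, 5), (10, 4)])
    def test_exhaustive_matches_mask_enumeration_oracle(self, n, n1):
        rng = np.random.default_rng(n * 100 + n1)
        pooled = rng.normal(0, 1, n)
        x, y = pooled[:n1], pooled[n1:]
        r = si.randomisation_test(x, y)
        # independent oracle: enumerate binary masks rather than index combos
        obs = abs(x.mean() - y.mean())
        count = total = 0
        for mask in range(2**n):
            if bin(mask).count("1") != n1:
                continue
            g1 = [pooled[i] for i in range(n) if mask >> i & 1]
            g2 = [pooled[i] for i in range(n) if not mask >> i & 1]
            total += 1
            if abs(np.mean(g1) - np.mean(g2)) >= obs - 1e-12:
                count += 1
        assert r.n_arrangements == total
        assert r.p_value == pytest.approx(count / total)

    def test_monte_carlo_within_3se_of_exhaustive(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, 6)
        y = rng.normal(0.8, 1, 6)
        exact = si.randomisation_test(x, y).p_value
        m = 100_000
        mc = si.randomisation_test(x, y, exhaustive_limit=10, n_iterations=m, seed=5)
        se = math.sqrt(exact * (1 - exact) / m)
        assert mc.method == "monte_carlo"
        assert abs(mc.p_value - exact) < 3 * se + 1 / m

    def test_one_sided_tails_complement(self):
        rng = np.random.default_rng(8)
        x = rng.normal(0, 1, 5)
        y = rng.normal(1, 1, 5)
        pg = si.randomisation_test(x, y, tail="greater").p_value
        pl = si.randomisation_test(x, y, tail="less").p_value
        # greater + less counts cover all arrangements, overlapping only at ties
        assert pg + pl >= 1.0


class TestSpearmanMcTest:
    def test_perfect_monotone_floor_p(self):
        u = np.arange(10.0)
        r = si.spearman_mc_test(u, 2 * u + 1, tail="greater", seed=0)
        assert r.rho == pytest.approx(1.0)
        assert r.p_value == pytest.approx(1 / 10_000)

    def test_reversed_is_negative_with_p_near_one(self):
        u = np.arange(10.0)
        r = si.spearman_mc_test(u, -u, tail="greater", seed=0)
        assert r.rho == pytest.approx(-1.0)
        assert r.p_value > 0.99

    def test_rho_matches_scipy_with_ties(self):
        rng = np.random.default_rng(3)
        u = rng.integers(0, 5, 20).astype(float)
        v = rng.integers(0, 5, 20).astype(float)
        r = si.spearman_mc_test(u, v, seed=1)
        assert r.rho == pytest.approx(stats.spearmanr(u, v).statistic, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            si.spearman_mc_test([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_power_at_moderate_association(self):
        # population Spearman ~0.47 at n=32 should reject (one-tailed, 5%)
        # in most replicates; deterministic under the fixed master seed
        rng = np.random.default_rng(12345)
        reject = 0
        n_rep = 60
        for _ in range(n_rep):
            u = rng.normal(0, 1, 32)
            v = 0.49 * u + math.sqrt(1 - 0.49**2) * rng.normal(0, 1, 32)
            r = si.spearman_mc_test(u, v, tail="greater", n_iterations=999, seed=int(rng.integers(2**31)))
            reject += r.p_value <= 0.05
        assert reject / n_rep >= 0.8


class TestYatesChi2:
    def test_printed_recovery_table(self):
        # 14 recoveries of 94 tagged vs 9 of 69 untagged birds
        chi2, p = si.yates_chi2(14, 80, 9, 60)
        assert round(p, 3) == 0.914

    def test_proportional_table_zero_statistic(self):
        chi2, p = si.yates_chi2(10, 10, 10, 10)
        assert chi2 == 0.0
        assert p == 1.0

    def test_matches_formula_oracle_on_random_tables(self):
        rng = np.random.default_rng(17)
        for _ in range(1000):
            a, b, c, d = (int(v) for v in rng.integers(1, 60, 4))
            chi2, p = si.yates_chi2(a, b, c, d)
            obs = np.array([[a, b], [c, d]], float)
            exp = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
            oracle = float(np.sum(np.maximum(np.abs(obs - exp) - 0.5, 0) ** 2 / exp))
            assert chi2 == pytest.approx(oracle, rel=1e-12)
            assert p == pytest.approx(stats.chi2.sf(oracle, 1), rel=1e-12)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            si.yates_chi2(0, 0, 5, 6)


class TestBinomialLogitGlm:
    def test_intercept_only_equals_pooled_proportion(self):
        rng = np.random.default_rng(2)
        colonies = random_colonies(rng, 15)
        fit = si.fit_binomial_logit(colonies, "none")
        pooled = sum(c.n_recovered for c in colonies) / sum(c.n_banded for c in colonies)
        assert expit(fit.params["intercept"]) == pytest.approx(pooled, rel=1e-8)
        assert fit.deviance_explained_pct == pytest.approx(0.0, abs=1e-9)

    def test_aicc_formula_arithmetic(self):
        # ll=-18, k=2, n=17: aic=40, aicc=40+12/14
        aicc = 40 + 2 * 2 * 3 / (17 - 2 - 1)
        assert aicc == pytest.approx(40.857142857142854)

    def test_aicc_exceeds_aic_and_converges(self):
        rng = np.random.default_rng(5)
        for n in (10, 40, 200):
            colonies = random_colonies(rng, n, slope=2e-4)
            fit = si.fit_binomial_logit(colonies, "distance_to_sea_m")
            assert fit.aicc > fit.aic
        assert fit.aicc - fit.aic < 0.15  # n=200: correction nearly gone

    def test_irls_matches_direct_likelihood_maximisation(self):
        rng = np.random.default_rng(31)
        for _ in range(50):
            n = int(rng.integers(8, 25))
            slope = float(rng.uniform(-4e-4, 4e-4))
            colonies = random_colonies(rng, n, beta0=float(rng.uniform(-3, -1)), slope=slope)
            try:
                fit = si.fit_binomial_logit(colonies, "distance_to_sea_m")
            except ValueError:
                continue  # separation is legitimately rejected
            x = np.array([c.distance_to_sea_m for c in colonies])
            succ = np.array([c.n_recovered for c in colonies], float)
            fail = np.array([c.n_banded - c.n_recovered for c in colonies], float)

            def nll(b):
                return -binom_loglik(b, x, succ, fail)

            best = optimize.minimize(
                nll,
                [fit.params["intercept"], fit.params["distance_to_sea_m"]],
                method="Nelder-Mead",
                options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000},
            )
            assert fit.log_likelihood == pytest.approx(-best.fun, abs=1e-6)

    def test_nested_deviance_monotone(self):
        rng = np.random.default_rng(23)
        for _ in range(10):
            colonies = random_colonies(rng, 20, slope=float(rng.uniform(-3e-4, 3e-4)))
            null = si.fit_binomial_logit(colonies, "none")
            uni = si.fit_binomial_logit(colonies, "distance_to_sea_m")
            assert uni.residual_deviance <= null.residual_deviance + 1e-9
            assert uni.null_deviance == pytest.approx(null.residual_deviance)

    def test_complete_separation_names_covariate(self):
        cols = [
            colony(0, 20, 0, distance_to_sea_m=100.0),
            colony(1, 20, 0, distance_to_sea_m=200.0),
            colony(2, 20, 20, distance_to_sea_m=5000.0),
            colony(3, 20, 20, distance_to_sea_m=6000.0),
        ]
        with pytest.raises(ValueError, match="distance_to_sea_m"):
            si.fit_binomial_logit(cols, "distance_to_sea_m")

    def test_too_few_colonies_for_aicc(self):
        cols = [colony(i, 10, 2, distance_to_sea_m=float(i * 500)) for i in range(3)]
        with pytest.raises(ValueError, match="AICc undefined"):
            si.fit_binomial_logit(cols, "distance_to_sea_m")


class TestRankModels:
    def test_single_fit_delta_zero(self):
        rng = np.random.default_rng(2)
        colonies = random_colonies(rng, 12)
        table = si.rank_models([si.fit_binomial_logit(colonies, "none")])
        assert table.delta_aicc.tolist() == [0.0]
        assert table.deviance_explained_pct.tolist() == [0.0]

    def test_mixed_colony_sets_rejected(self):
        rng = np.random.default_rng(2)
        f1 = si.fit_binomial_logit(random_colonies(rng, 12), "none")
        f2 = si.fit_binomial_logit(random_colonies(rng, 13), "none")
        with pytest.raises(ValueError, match="identical colony set"):
            si.rank_models([f1, f2])

    def test_generating_covariate_usually_ranks_first(self):
        # distance-generated data at the study's colony count: the distance
        # model should win the AICc ranking in most replicates
        rng = np.random.default_rng(99)
        wins = 0
        n_rep = 100
        for _ in range(n_rep):
            colonies = random_colonies(rng, 17, beta0=-3.0, slope=4e-4)
            fits = []
            for cov in ("none",) + si.GLM_COVARIATES:
                try:
                    fits.append(si.fit_binomial_logit(colonies, cov))
                except ValueError:
                    pass
            table = si.rank_models(fits)
            wins += table.covariate.iloc[0] == "distance_to_sea_m"
        assert wins / n_rep >= 0.7


class TestVif:
    def test_orthogonal_covariates_unity(self):
        rng = np.random.default_rng(7)
        n = 40
        cols = []
        for i in range(n):
            cols.append(
                colony(
                    i, 10, 2,
                    elevation_m=float(rng.normal()),
                    distance_to_sea_m=float(rng.normal()),
                    radiance_at_colony=float(rng.normal()),
                )
            )
        out = si.vif(cols, ["elevation_m", "distance_to_sea_m", "radiance_at_colony"])
        assert all(1.0 <= v < 1.3 for v in out.values())

    def test_duplicated_covariate_infinite(self):
        rng = np.random.default_rng(7)
        cols = []
        for i in range(20):
            x = float(rng.normal())
            cols.append(colony(i, 10, 2, elevation_m=x, distance_to_sea_m=x, radiance_at_colony=float(rng.normal())))
        out = si.vif(cols, ["elevation_m", "distance_to_sea_m", "radiance_at_colony"])
        assert math.isinf(out["elevation_m"])
        assert math.isinf(out["distance_to_sea_m"])

    def test_matches_ols_r2_oracle(self):
        rng = np.random.default_rng(11)
        n = 60
        z = rng.normal(0, 1, n)
        x1 = z + 0.5 * rng.normal(0, 1, n)
        x2 = z + 0.5 * rng.normal(0, 1, n)
        x3 = rng.normal(0, 1, n)
        cols = [
            colony(i, 10, 2, elevation_m=float(x1[i]), distance_to_sea_m=float(x2[i]), radiance_at_colony=float(x3[i]))
            for i in range(n)
        ]
        out = si.vif(cols, ["elevation_m", "distance_to_sea_m", "radiance_at_colony"])
        import statsmodels.api as sm

        for name, xj, others in (
            ("elevation_m", x1, np.column_stack([x2, x3])),
            ("distance_to_sea_m", x2, np.column_stack([x1, x3])),
            ("radiance_at_colony", x3, np.column_stack([x1, x2])),
        ):
            r2 = sm.OLS(xj, sm.add_constant(others)).fit().rsquared
            assert out[name] == pytest.approx(1.0 / (1.0 - r2), rel=1e-8)


class TestRecoveryAndPopulation:
    def test_printed_recovery_rates_round_to_14_pct(self):
        assert round(100 * si.pooled_recovery_rate(15, 110)) == 14
        assert round(100 * si.pooled_recovery_rate(23, 169)) == 14

    def test_printed_population_range(self):
        assert si.estimate_population(863, 0.14, 0.75).pairs == 8200
        assert si.estimate_population(1751, 0.14, 0.75).pairs == 16600

    def test_identity_rates(self):
        assert si.estimate_population(100, 1.0, 1.0).pairs == 100

    def test_monotonicity(self):
        base = si.estimate_population(1000, 0.14, 0.75).pairs_raw
        assert si.estimate_population(1100, 0.14, 0.75).pairs_raw > base
        assert si.estimate_population(1000, 0.2, 0.75).pairs_raw < base
        assert si.estimate_population(1000, 0.14, 0.9).pairs_raw < base

    def test_zero_rate_rejected(self):
        with pytest.raises(ValueError):
            si.estimate_population(100, 0.0, 0.75)

    def test_inverts_simulated_outcomes(self):
        # rate estimated from simulated colony recoveries reproduces the
        # generating cohort size within binomial error
        rng = np.random.default_rng(6)
        from fallout.synthetic_nightscape import GroundingModelConfig, simulate_colony_outcomes

        colonies = [
            colony(i, 0, 0, elevation_m=float(rng.uniform(0, 800)), distance_to_sea_m=float(rng.uniform(0, 4000)))
            for i in range(100)
        ]
        model = GroundingModelConfig(beta0=float(logit(0.14)), beta_distance_per_m=0.0, beta_elevation_per_m=0.0)
        recs = simulate_colony_outcomes(colonies, model, 40, rng)
        rate = si.pooled_recovery_rate(sum(r.n_recovered for r in recs), sum(r.n_banded for r in recs))
        success = 0.75
        fledged = 4000 * success  # 4,000 generating pairs
        rescued = int(round(fledged * 0.14))
        est = si.estimate_population(rescued, rate, success)
        assert est.pairs_raw == pytest.approx(4000, rel=0.1)
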