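"""Tests of the likelihood, the hierarchical sampler, and the summaries."""

import math

import numpy as np
import pytest
from scipy import stats

from dberm import (
    ConstraintViolation,
    DBERMParams,
    GroupDistribution,
    MCMCConfig,
    RecoveryCoefficients,
    SessionRecord,
    WKY_REFERENCE,
    cap_half_life,
    fit_shifted_exponential_mcmc,
    log_posterior,
    rat_log_likelihood,
    run_mcmc,
    simulate_cohort,
    strain_effect,
    summarize_posterior,
)
from dberm.cohort import PARAM_NAMES
from dberm.core import HALF_LIFE_CAP, LN2


def record(times, duration=65.0, rat="r1", strain="WKY", session=1):
    return SessionRecord(rat_id=rat, strain=strain, session_index=session,
                         response_times=np.asarray(times, dtype=float),
                         session_duration=duration)


STATIC = DBERMParams(L0=0.0, w0=120.0, b0=12.0, gamma=0.0, alpha=0.0, beta=0.0,
                     delta=1e-3, omega=0.0)


class TestRatLogLikelihood:
    def test_empty_session_without_censoring_is_zero(self):
        ll = rat_log_likelihood(record([]), None, STATIC,
                                include_first_latency=False, censor_tail=False)
        assert ll == 0.0

    def test_irt_shorter_than_delta_is_impossible(self):
        p = DBERMParams(**{**STATIC.__dict__, "delta": 0.5})
        ll = rat_log_likelihood(record([1.0, 1.2]), None, p, censor_tail=False,
                                include_first_latency=False)
        assert ll == -math.inf

    def test_single_process_matches_shifted_exponential_oracle(self):
        # with the bout probability at zero the likelihood collapses to a
        # shifted-exponential law computed independently here
        rng = np.random.default_rng(13)
        irts = rng.exponential(1 / 12.0, size=100) + STATIC.delta
        times = np.cumsum(irts)
        ll = rat_log_likelihood(record(times, duration=float(times[-1])), None,
                                STATIC, include_first_latency=True,
                                censor_tail=False)
        oracle = np.sum(np.log(12.0) - 12.0 * (irts - STATIC.delta))
        assert ll == pytest.approx(oracle, rel=1e-10)

    def test_censored_tail_term_lowers_likelihood(self):
        times = [1.0, 2.0, 3.0]
        base = rat_log_likelihood(record(times), None, STATIC, censor_tail=False)
        with_tail = rat_log_likelihood(record(times), None, STATIC, censor_tail=True)
        assert with_tail < base  # log-survival of a 62-min gap is negative

    def test_second_session_requires_coefficients(self):
        with pytest.raises(ConstraintViolation):
            rat_log_likelihood(record([1.0]), record([1.0], session=2), STATIC, None)

    def test_two_sessions_sum_with_recovery(self):
        c = RecoveryCoefficients(c_b0=0.5)
        r1, r2 = record([1.0, 2.0]), record([1.0, 4.0], session=2)
        total = rat_log_likelihood(r1, r2, STATIC, c, censor_tail=False,
                                   include_first_latency=False)
        from dberm import apply_recovery

        part1 = rat_log_likelihood(r1, None, STATIC, censor_tail=False,
                                   include_first_latency=False)
        part2 = rat_log_likelihood(r2, None, apply_recovery(STATIC, c),
                                   censor_tail=False, include_first_latency=False)
        assert total == pytest.approx(part1 + part2, rel=1e-12)

    def test_malformed_record_rejected(self):
        with pytest.raises(ValueError):
            record([2.0, 1.0])


class TestLogPosterior:
    def _setup(self):
        groups = [GroupDistribution("WKY", WKY_REFERENCE, 0.2)]
        ds = simulate_cohort(groups, 2, 1, 10.0, seed=2)
        ip = {r: (d["params"], None) for r, d in ds.metadata["true_params"].items()}
        mu = np.log([getattr(WKY_REFERENCE, n) for n in PARAM_NAMES])
        hp = {"WKY": {"mu": mu, "sigma": np.full(8, 0.5)}}
        return ds, ip, hp

    def test_finite_at_generative_point(self):
        ds, ip, hp = self._setup()
        assert math.isfinite(log_posterior(ds, ip, hp))

    def test_hyper_outside_support_is_minus_inf(self):
        ds, ip, hp = self._setup()
        hp["WKY"]["sigma"] = np.full(8, 6.0)  # above the flat-prior bound
        assert log_posterior(ds, ip, hp) == -math.inf

    def test_vague_population_approaches_likelihood_plus_constant(self):
        # as sigma grows the population term flattens: differences between
        # two parameter points converge to their likelihood differences
        ds, ip, hp = self._setup()
        rat = next(iter(ip))
        ip2 = dict(ip)
        p = ip[rat][0]
        ip2[rat] = (DBERMParams(**{**p.__dict__, "b0": p.b0 * 1.3}), None)
        hp["WKY"]["sigma"] = np.full(8, 4.9)
        dpost = log_posterior(ds, ip2, hp) - log_posterior(ds, ip, hp)
        recs = ds.sessions_for(rat)
        dlik = rat_log_likelihood(recs[0], None, ip2[rat][0]) - rat_log_likelihood(
            recs[0], None, ip[rat][0]
        )
        assert dpost == pytest.approx(dlik, abs=0.05)

    def test_identical_rats_contribute_identically(self):
        ds, ip, hp = self._setup()
        r1, r2 = list(ip)
        ip[r2] = ip[r1]
        recs1 = ds.sessions_for(r1)
        ll = rat_log_likelihood(recs1[0], None, ip[r1][0])
        # swapping which rat owns the shared parameters changes nothing
        assert rat_log_likelihood(recs1[0], None, ip[r2][0]) == ll


class TestConjugateToy:
    def test_kernel_matches_analytic_gamma_posterior(self):
        rng = np.random.default_rng(3)
        delta = 2e-3
        irts = rng.exponential(1 / 20.0, size=400) + delta
        samples = fit_shifted_exponential_mcmc(irts, delta, n_samples=20_000,
                                               burn_in=2000, seed=1)
        n, s = irts.size, float(np.sum(irts - delta))
        post = stats.gamma(a=n, scale=1 / s)
        assert samples.mean() == pytest.approx(post.mean(), rel=0.02)
        assert samples.std() == pytest.approx(post.std(), rel=0.10)
        lo, hi = np.quantile(samples, [0.025, 0.975])
        assert lo == pytest.approx(post.ppf(0.025), rel=0.03)
        assert hi == pytest.approx(post.ppf(0.975), rel=0.03)


class TestRunMcmc:
    def test_default_retained_sample_count(self):
        assert MCMCConfig().n_samples == 20_100

    def test_chains_honor_config_and_seed(self, small_wky_cohort):
        cfg = MCMCConfig(n_samples=120, burn_in=60, init_maxiter=100)
        a = run_mcmc(small_wky_cohort, cfg, seed=5)
        b = run_mcmc(small_wky_cohort, cfg, seed=5)
        assert a.n_samples == 120
        for rat in a.rat_ids:
            np.testing.assert_array_equal(a.individual[rat], b.individual[rat])
        np.testing.assert_array_equal(a.group_mu["WKY"], b.group_mu["WKY"])

    def test_retained_samples_satisfy_constraints(self, small_wky_cohort):
        cfg = MCMCConfig(n_samples=200, burn_in=100, init_maxiter=100)
        ch = run_mcmc(small_wky_cohort, cfg, seed=8)
        for rat in ch.rat_ids:
            th = np.exp(ch.individual[rat])
            L0, w0, b0 = th[:, 0], th[:, 1], th[:, 2]
            alpha, beta, omega = th[:, 4], th[:, 5], th[:, 7]
            assert np.all(w0 > b0)
            assert np.all(b0 >= omega)
            assert np.all(beta >= alpha)
            assert np.all(th > 0)

    def test_empty_dataset_fails_cleanly(self):
        from dberm.inference import InitializationError
        from dberm.cohort import CohortDataset

        with pytest.raises(InitializationError):
            run_mcmc(CohortDataset(records=[]), MCMCConfig(n_samples=10, burn_in=5))

    def test_two_session_fit_produces_coefficient_chains(self, wky_params):
        groups = [GroupDistribution("WKY", wky_params, 0.1,
                                    RecoveryCoefficients(), 0.1)]
        ds = simulate_cohort(groups, 2, 2, 10.0, seed=3)
        ch = run_mcmc(ds, MCMCConfig(n_samples=100, burn_in=80, init_maxiter=100),
                      seed=2)
        assert ch.coeff_mu is not None
        assert ch.individual_coeffs[ch.rat_ids[0]].shape == (100, 8)


@pytest.fixture(scope="module")
def fitted():
    groups = [GroupDistribution("WKY", WKY_REFERENCE, 0.2)]
    ds = simulate_cohort(groups, 3, 1, 15.0, seed=11)
    ch = run_mcmc(ds, MCMCConfig(n_samples=400, burn_in=300), seed=4)
    return ds, ch


@pytest.fixture(scope="module")
def two_strain_chains():
    from dberm import SHR_REFERENCE

    groups = [
        GroupDistribution("SHR", SHR_REFERENCE, 0.1),
        GroupDistribution("WKY", WKY_REFERENCE, 0.1),
    ]
    ds = simulate_cohort(groups, 3, 1, 20.0, seed=6)
    return run_mcmc(ds, MCMCConfig(n_samples=600, burn_in=500), seed=6)


class TestSummaries:
    def test_summary_tables_are_ordered_and_positive(self, fitted):
        _, ch = fitted
        summ = summarize_posterior(ch)
        g = summ.group
        assert set(g["parameter"]) == {
            "L0", "w0", "b0", "H_L", "H_w", "H_b", "delta_seconds", "omega"
        }
        assert (g["ci_low"] <= g["median"]).all()
        assert (g["median"] <= g["ci_high"]).all()
        assert (g["median"] > 0).all()
        assert len(summ.individual) == 3 * 8

    def test_constant_chain_summarizes_to_point(self):
        from dberm.inference import PosteriorChains

        mu = {"WKY": np.tile(np.log([2.0, 100.0, 10.0, 0.03, 0.03, 0.1,
                                     0.002, 1.0]), (50, 1))}
        ch = PosteriorChains(
            param_names=PARAM_NAMES, coeff_names=None, rat_ids=["r"],
            rat_strains={"r": "WKY"},
            individual={"r": mu["WKY"].copy()}, individual_coeffs=None,
            group_mu=mu, group_sigma={"WKY": np.full((50, 8), 0.1)},
            coeff_mu=None, coeff_sigma=None,
        )
        g = summarize_posterior(ch).group
        row = g[g.parameter == "L0"].iloc[0]
        assert row["median"] == row["ci_low"] == row["ci_high"] == pytest.approx(2.0)

    def test_linear_median_is_exp_of_log_location(self, fitted):
        _, ch = fitted
        j = PARAM_NAMES.index("b0")
        med = np.median(np.exp(ch.group_mu["WKY"][:, j]))
        g = summarize_posterior(ch).group
        assert g[g.parameter == "b0"].iloc[0]["median"] == pytest.approx(med, rel=1e-9)


class TestStrainEffect:
    def test_ratio_is_exp_of_log_effect(self, two_strain_chains):
        e = strain_effect(two_strain_chains, "b0")
        lo, med, hi = np.quantile(e.log_samples, [0.025, 0.5, 0.975])
        assert e.ratio_median == pytest.approx(math.exp(med), rel=1e-9)
        assert e.ratio_ci == (pytest.approx(math.exp(lo)), pytest.approx(math.exp(hi)))

    def test_significance_flag_matches_interval_rule(self, two_strain_chains):
        e = strain_effect(two_strain_chains, "b0")
        lo, hi = np.quantile(e.log_samples, [0.025, 0.975])
        assert e.significant == (lo > 0 or hi < 0)
        # the exp transform makes the equivalent rule: ratio CI excludes 1
        assert e.significant == (e.ratio_ci[0] > 1 or e.ratio_ci[1] < 1)

    def test_unknown_parameter_rejected(self, two_strain_chains):
        with pytest.raises(KeyError):
            strain_effect(two_strain_chains, "nonesuch")

    def test_half_life_effect_inverts_rate_effect(self, two_strain_chains):
        eh = strain_effect(two_strain_chains, "H_b")
        er = strain_effect(two_strain_chains, "beta")
        assert eh.ratio_median == pytest.approx(1 / er.ratio_median, rel=1e-9)


class TestCapHalfLife:
    @pytest.mark.parametrize(
        "value, expected, flag",
        [(19.37, 19.37, False), (1e9, HALF_LIFE_CAP, True), (0.0, 0.0, False)],
    )
    def test_cap(self, value, expected, flag):
        h = cap_half_life(value)
        assert h.minutes == expected and h.capped is flag

    def test_negative_rejected(self):
        with pytest.raises(ConstraintViolation):
            cap_half_life(-1.0)
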