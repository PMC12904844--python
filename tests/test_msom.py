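"""MSOM likelihood, sampler, diagnostics, and posterior bookkeeping."""

import numpy as np
import pandas as pd
import pytest

from topoccu.covariates import SiteCovariates
from topoccu.detections import DetectionHistory
from topoccu.msom import (
    MCMCConfig,
    MSOMSpec,
    PosteriorDraws,
    _expit,
    build_design,
    conditional_z_probability,
    gelman_rubin,
    psi_by_category,
    run_mcmc,
    site_marginal_loglik,
    summarize_posterior,
)


def brute_force_loglik(psi, p, y):
    """Oracle: enumerate z in {0, 1} and sum the joint probabilities."""
    p, y = np.asarray(p), np.asarray(y)
    lik_z1 = psi * np.prod(np.where(y == 1, p, 1 - p))
    lik_z0 = (1 - psi) * (0.0 if y.any() else 1.0)
    return np.log(lik_z1 + lik_z0)


def intercept_only_history(y_row, n_sites=1):
    y = np.asarray(y_row, dtype=np.uint8).reshape(1, n_sites, -1)
    J = y.shape[2]
    return DetectionHistory(
        y=y,
        effort=np.full((n_sites, J), 5.0),
        mask=np.ones((n_sites, J), dtype=bool),
        species=["sp"],
        site_ids=[f"s{i}" for i in range(n_sites)],
    )


def intercept_only_spec(history):
    N, J = history.n_sites, history.n_occasions
    return MSOMSpec(
        X=np.ones((N, 1)),
        W=np.ones((N, J, 1)),
        occ_names=["intercept"],
        det_names=["intercept"],
        species=list(history.species),
    )


class TestMarginalLikelihood:
    @pytest.mark.parametrize(
        "psi,p,y,expected",
        [
            (0.5, [0.5, 0.5], [0, 0], np.log(0.625)),
            (1.0, [1.0, 1.0], [1, 1], 0.0),
            (0.5, [0.5, 0.5], [1, 0], np.log(0.125)),
        ],
    )
    def test_closed_form_examples(self, psi, p, y, expected):
        assert site_marginal_loglik(psi, p, y) == pytest.approx(expected)

    def test_matches_brute_force_enumeration_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            J = rng.integers(1, 8)
            psi = rng.uniform(0.01, 0.99)
            p = rng.uniform(0.01, 0.99, J)
            y = (rng.random(J) < 0.4).astype(int)
            assert site_marginal_loglik(psi, p, y) == pytest.approx(
                brute_force_loglik(psi, p, y), rel=1e-12
            )

    def test_mask_excludes_occasions(self):
        full = site_marginal_loglik(0.3, [0.2, 0.9], [0, 1], mask=[True, True])
        masked = site_marginal_loglik(0.3, [0.2, 0.9], [0, 1], mask=[False, True])
        assert masked == pytest.approx(np.log(0.3 * 0.9))
        assert masked != pytest.approx(full)

    def test_probability_bounds_enforced(self):
        with pytest.raises(ValueError):
            site_marginal_loglik(1.2, [0.5], [0])
        with pytest.raises(ValueError):
            site_marginal_loglik(0.5, [-0.1], [0])


class TestConditionalZ:
    def test_bayes_rule_example(self):
        assert conditional_z_probability(0.5, [0.5, 0.5]) == pytest.approx(0.2)

    def test_uninformative_detection_returns_psi(self):
        assert conditional_z_probability(0.37, [0.0, 0.0]) == pytest.approx(0.37)

    def test_certain_occupancy(self):
        assert conditional_z_probability(1.0, [0.5]) == pytest.approx(1.0)


class TestChainAccounting:
    def test_full_survey_scale_configuration_retains_15000_draws(self):
        cfg = MCMCConfig(n_chains=3, n_iter=100_000, n_burnin=50_000, thin=10)
        assert cfg.n_retained == 15_000

    def test_small_run_draw_count_and_determinism(self):
        hist = intercept_only_history([1, 1, 0, 1])
        spec = intercept_only_spec(hist)
        cfg = MCMCConfig(n_chains=1, n_iter=100, n_burnin=0, thin=1, seed=9)
        d1 = run_mcmc(spec, hist, cfg)
        d2 = run_mcmc(spec, hist, cfg)
        assert d1.beta.shape == (1, 100, 1, 1)
        assert np.array_equal(d1.beta, d2.beta)  # fixed seed, bit-identical
        assert np.array_equal(d1.alpha, d2.alpha)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            MCMCConfig(n_iter=100, n_burnin=100)
        with pytest.raises(ValueError):
            MCMCConfig(thin=0)


class TestSamplerCorrectness:
    def test_detection_posterior_matches_quadrature_oracle(self):
        # single detected site, intercept-only: p's posterior is 1-D and can
        # be integrated numerically; with a logistic-width prior it is also
        # close to the flat-prior conjugate Beta(1+3, 1+1) answer
        prior_var = np.pi**2 / 3  # Normal approximation of Logistic(0,1) => ~flat on p
        hist = intercept_only_history([1, 1, 0, 1])
        spec = intercept_only_spec(hist)
        spec.prior_variance = prior_var

        a = np.linspace(-40, 40, 200_001)
        w = np.exp(
            -(a**2) / (2 * prior_var)
            + 3 * np.log(_expit(a))
            + np.log(_expit(-a))
        )
        oracle = np.trapezoid(_expit(a) * w, a) / np.trapezoid(w, a)

        cfg = MCMCConfig(n_chains=2, n_iter=30_000, n_burnin=5_000, thin=5, seed=4)
        d = run_mcmc(spec, hist, cfg)
        p_draws = _expit(d.alpha[:, :, 0, 0])
        mcse = p_draws.std() / np.sqrt(200)  # generous ESS guess
        assert p_draws.mean() == pytest.approx(oracle, abs=max(4 * mcse, 0.01))
        assert p_draws.mean() == pytest.approx(4 / 6, abs=0.03)

    def test_near_perfect_detection_recovers_naive_occupancy(self):
        # with p ~ 1 every occupied site is seen, so psi should match the
        # raw proportion of sites with a detection
        rng = np.random.default_rng(0)
        N, J = 60, 6
        z = rng.random(N) < 0.6
        y = np.zeros((1, N, J), dtype=np.uint8)
        y[0, z, :] = 1
        hist = DetectionHistory(
            y=y, effort=np.full((N, J), 5.0), mask=np.ones((N, J), bool),
            species=["sp"], site_ids=[f"s{i}" for i in range(N)],
        )
        spec = intercept_only_spec(hist)
        cfg = MCMCConfig(n_chains=2, n_iter=4000, n_burnin=2000, thin=2, seed=2)
        d = run_mcmc(spec, hist, cfg)
        psi_mean = _expit(d.beta[:, :, 0, 0]).mean()
        assert psi_mean == pytest.approx(z.mean(), abs=0.06)

    def test_doubling_thin_with_doubled_iterations_is_stable(self):
        hist = intercept_only_history([1, 0, 1, 0, 1, 1])
        spec = intercept_only_spec(hist)
        base = MCMCConfig(n_chains=1, n_iter=12_000, n_burnin=2_000, thin=2, seed=11)
        double = MCMCConfig(n_chains=1, n_iter=22_000, n_burnin=2_000, thin=4, seed=12)
        m1 = run_mcmc(spec, hist, base).alpha.mean()
        m2 = run_mcmc(spec, hist, double).alpha.mean()
        assert m1 == pytest.approx(m2, abs=0.08)

    def test_species_order_does_not_bias_estimates(self):
        rng = np.random.default_rng(5)
        N, J, S = 40, 8, 3
        psi_true = np.array([0.7, 0.4, 0.55])
        p_true = 0.45
        z = rng.random((S, N)) < psi_true[:, None]
        y = ((rng.random((S, N, J)) < p_true) & z[:, :, None]).astype(np.uint8)
        hist = DetectionHistory(
            y=y, effort=np.full((N, J), 5.0), mask=np.ones((N, J), bool),
            species=["a", "b", "c"], site_ids=[f"s{i}" for i in range(N)],
        )
        spec = MSOMSpec(
            X=np.ones((N, 1)), W=np.ones((N, J, 1)),
            occ_names=["intercept"], det_names=["intercept"], species=["a", "b", "c"],
        )
        rev = DetectionHistory(
            y=y[::-1].copy(), effort=hist.effort, mask=hist.mask,
            species=["c", "b", "a"], site_ids=hist.site_ids,
        )
        spec_rev = MSOMSpec(
            X=spec.X, W=spec.W, occ_names=["intercept"], det_names=["intercept"],
            species=["c", "b", "a"],
        )
        cfg = MCMCConfig(n_chains=2, n_iter=6000, n_burnin=2000, thin=2, seed=3)
        d_fwd = run_mcmc(spec, hist, cfg)
        d_rev = run_mcmc(spec_rev, rev, cfg)
        psi_fwd = _expit(d_fwd.beta[:, :, :, 0]).mean(axis=(0, 1))
        psi_rev = _expit(d_rev.beta[:, :, :, 0]).mean(axis=(0, 1))[::-1]
        assert np.allclose(psi_fwd, psi_rev, atol=0.04)  # within Monte-Carlo error


class TestGelmanRubin:
    def test_identical_chains_give_sub_unity_rhat(self):
        chain = np.random.default_rng(0).normal(size=500)
        r = gelman_rubin(np.stack([chain, chain]))
        assert r == pytest.approx(np.sqrt(499 / 500))

    def test_same_distribution_chains_near_one(self):
        rng = np.random.default_rng(1)
        chains = rng.normal(size=(3, 10_000))
        assert 0.99 <= gelman_rubin(chains) <= 1.01

    def test_shifted_chains_flagged(self):
        rng = np.random.default_rng(2)
        chains = np.stack([rng.normal(0, 1, 1000), rng.normal(10, 1, 1000)])
        assert gelman_rubin(chains) > 1.1

    def test_matches_arviz_on_random_chains(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(3)
        chains = rng.normal(size=(4, 500)) + rng.normal(size=(4, 1))
        ours = gelman_rubin(chains)
        theirs = float(az.rhat(chains[None].transpose(1, 2, 0)[..., 0]))
        # arviz uses the rank-normalized split variant; agreement is approximate
        assert ours == pytest.approx(theirs, abs=0.05)

    def test_degenerate_chains_flagged(self):
        with pytest.warns(RuntimeWarning, match="degenerate"):
            r = gelman_rubin(np.zeros((2, 100)))
        assert np.isnan(r)


class TestPosteriorSummaries:
    def test_degenerate_draws_are_strong(self):
        s = summarize_posterior(np.full(500, 0.7))
        assert s["mean"] == pytest.approx(0.7)
        assert s["q2.5"] == s["q97.5"] == 0.7
        assert s["support"] == "strong"

    def test_zero_centered_draws_have_no_support(self):
        rng = np.random.default_rng(0)
        s = summarize_posterior(rng.normal(0, 1, 4000))
        assert s["support"] == "none"

    def test_twelve_percent_below_zero_is_moderate(self):
        draws = np.concatenate(
            [np.linspace(-1, -0.01, 120), np.linspace(0.01, 1, 880)]
        )
        s = summarize_posterior(draws)
        assert s["q2.5"] < 0 < s["q97.5"]
        assert s["q12.5"] > 0
        assert s["support"] == "moderate"

    def test_interval_nesting(self):
        rng = np.random.default_rng(1)
        s = summarize_posterior(rng.normal(2, 3, 2000))
        assert s["q2.5"] <= s["q12.5"] <= s["q87.5"] <= s["q97.5"]

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError):
            summarize_posterior(np.ones(50))


class TestPsiByCategory:
    def make_draws(self, beta, classes, occ_names, variable="aspect"):
        S = beta.shape[2]
        spec = MSOMSpec(
            X=np.column_stack([np.ones(4)] + [np.eye(4)[:, :1]] * (len(occ_names) - 1)),
            W=np.ones((4, 2, 1)),
            occ_names=occ_names,
            det_names=["intercept"],
            species=[f"sp{i}" for i in range(S)],
            variable=variable,
            classes=classes,
        )
        cfg = MCMCConfig(n_chains=1, n_iter=2, n_burnin=1, thin=1)
        return PosteriorDraws(
            beta=beta, alpha=np.zeros((1, beta.shape[1], S, 1)), spec=spec, config=cfg
        )

    def test_inverse_logit_table(self):
        vals = np.array([-1.0, 0.0, 1.0])
        beta = np.tile(vals.reshape(1, 3, 1, 1), (1, 1, 1, 2))
        beta[:, :, :, 1] = 0.0  # class effect zero
        beta = np.repeat(beta, 40, axis=1)  # >= 100 draws for a summary
        d = self.make_draws(beta, ["E", "N"], ["intercept", "aspect[N]"])
        s = psi_by_category(d, "sp0", "N")
        assert s["mean"] == pytest.approx(np.mean([0.26894, 0.5, 0.73106]), abs=1e-4)

    def test_reference_category_uses_intercept_only(self):
        beta = np.zeros((1, 120, 1, 2))
        beta[:, :, :, 0] = 1.0
        beta[:, :, :, 1] = 5.0
        d = self.make_draws(beta, ["E", "N"], ["intercept", "aspect[N]"])
        assert psi_by_category(d, "sp0", "E")["mean"] == pytest.approx(_expit(np.array(1.0)))
        assert psi_by_category(d, "sp0", "N")["mean"] == pytest.approx(_expit(np.array(6.0)))

    def test_unknown_category_rejected(self):
        beta = np.zeros((1, 120, 1, 2))
        d = self.make_draws(beta, ["E", "N"], ["intercept", "aspect[N]"])
        with pytest.raises(ValueError, match="unknown"):
            psi_by_category(d, "sp0", "SSW")


class TestBuildDesign:
    def test_per_variable_design_shapes(self, small_landscape, small_survey):
        from topoccu.detections import build_detection_history, filter_independent_events

        _, covs = small_landscape
        truth, records, deployments = small_survey
        ev = filter_independent_events(records)
        hist = build_detection_history(ev, deployments, species=truth.species)
        spec = build_design(covs, hist, "ruggedness")
        k = len(spec.classes)
        assert spec.X.shape == (hist.n_sites, k)  # intercept + k-1 indicators
        assert spec.W.shape[2] == k + 1  # + log-effort
        assert spec.det_names[-1] == "log_effort_z"
        assert spec.reference == spec.classes[0]

    def test_single_class_variable_rejected(self):
        covs = SiteCovariates(
            table=pd.DataFrame(
                {"site_id": ["a", "b"], "ruggedness_class": ["low", "low"]}
            )
        )
        hist = intercept_only_history([0, 1], n_sites=1)
        hist.site_ids = ["a"]
        with pytest.raises(ValueError, match="single observed class"):
            build_design(covs, hist, "ruggedness")
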