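"""Priors, likelihood, MCMC sampling, diagnostics and sensitivity."""

import math

import numpy as np
import pandas as pd
import pytest

from fcrnpk import (
    AffinityTable,
    HalfLifeObservation,
    TraffickingParameters,
    build_priors,
    diagnostics,
    log_likelihood,
    make_affinity_fixture,
    make_half_life_fixtures,
    model_half_life,
    run_mcmc,
    sensitivity_analysis,
)
from fcrnpk.bayes import (
    PosteriorFit,
    _unpack,
    geweke_z,
    integrated_autocorr_time,
    sample_prior_unconstrained,
)

VARIANTS = ["wt", "DHS", "YTE", "LS"]


@pytest.fixture(scope="module")
def priors():
    return build_priors(make_affinity_fixture(), variants=VARIANTS)


class TestBuildPriors:
    def test_sorting_order_follows_endosomal_affinity(self, priors):
        assert priors.f_sort_order == ("YTE", "LS", "DHS", "wt")

    def test_release_fixed_for_non_binders(self, priors):
        assert priors.f_release_fixed == {"wt": 1.0, "DHS": 1.0}

    def test_release_order_follows_physiological_affinity(self, priors):
        # LS binds more strongly at pH 7.4 (smaller K_D) -> smaller release
        assert priors.f_release_order == ("YTE", "LS")

    def test_missing_variant_rejected(self):
        aff = make_affinity_fixture()
        with pytest.raises(KeyError):
            build_priors(aff, variants=["wt", "XYZ"])

    def test_prior_predictive_half_lives_finite(self, priors, rng):
        """Prior draws put f_sort strictly below 1, so the implied
        half-lives are finite for every variant."""
        from fcrnpk.bayes import _batch_half_lives

        u = sample_prior_unconstrained(priors, rng, 2000)
        logpos, f_sort, f_rel = _unpack(u, priors)
        fr_full = np.column_stack([
            f_rel[:, priors.f_release_order.index(v)]
            if v in priors.f_release_order else np.ones(len(u))
            for v in priors.f_sort_order
        ])
        t12 = _batch_half_lives(logpos, f_sort, fr_full)
        assert np.isfinite(t12).all()

    def test_prior_draws_satisfy_order_constraints(self, priors, rng):
        u = sample_prior_unconstrained(priors, rng, 100_000)
        _, f_sort, f_rel = _unpack(u, priors)
        assert np.all(np.diff(f_sort, axis=1) <= 0.0)
        assert np.all((f_sort > 0.0) & (f_sort < 1.0))
        assert np.all(np.diff(f_rel, axis=1) <= 0.0)
        assert np.all((f_rel > 0.0) & (f_rel < 1.0))


class TestLogLikelihood:
    def params(self, fs=0.9, fr=0.8):
        return TraffickingParameters(V_p=0.5, V_e=0.3, Q=1.0, Q_u=0.5,
                                     f_sort={"v": fs}, f_release={"v": fr})

    def test_hand_evaluated_normal_density(self):
        p = self.params()
        t12 = model_half_life(p, "v")
        se = 10.0
        obs = [HalfLifeObservation("v", mean=t12 + 10.0, sd=se * math.sqrt(7), n=7)]
        expected = -0.5 - math.log(10.0 * math.sqrt(2.0 * math.pi))
        assert log_likelihood(p, obs) == pytest.approx(expected, rel=1e-12)

    def test_maximized_when_model_matches_mean(self):
        p = self.params()
        t12 = model_half_life(p, "v")
        at_mean = log_likelihood(p, [HalfLifeObservation("v", t12, 5.0, 4)])
        off = log_likelihood(p, [HalfLifeObservation("v", t12 * 1.1, 5.0, 4)])
        assert at_mean > off

    def test_closed_system_is_minus_infinity(self):
        p = self.params(fs=1.0, fr=1.0)
        assert log_likelihood(p, [HalfLifeObservation("v", 100.0, 5.0, 4)]) == -math.inf

    def test_sd_option_changes_scale(self):
        p = self.params()
        obs = [HalfLifeObservation("v", 120.0, 12.0, 9)]
        assert log_likelihood(p, obs) != log_likelihood(p, obs, use_sd=True)


class TestBatchHalfLives:
    def test_vectorized_newton_matches_scalar_root_finder(self, rng):
        """The eigen-expansion bisection used inside the likelihood
        agrees with the scalar matrix-exponential Newton routine."""
        from fcrnpk import CompartmentState, time_to_half
        from fcrnpk.bayes import _batch_half_lives

        for _ in range(50):
            logpos = rng.normal(0.0, 1.0, size=(1, 4))
            fs = rng.uniform(0.05, 0.99, size=(1, 1))
            fr = rng.uniform(0.05, 0.99, size=(1, 1))
            p = TraffickingParameters(
                V_p=float(np.exp(logpos[0, 0])), V_e=float(np.exp(logpos[0, 1])),
                Q=float(np.exp(logpos[0, 2])), Q_u=float(np.exp(logpos[0, 3])),
                f_sort={"x": float(fs[0, 0])}, f_release={"x": float(fr[0, 0])},
            )
            batch = _batch_half_lives(logpos, fs, fr, "newton")[0, 0]
            scalar = time_to_half(CompartmentState.bolus(1.0), p, "x")
            assert batch == pytest.approx(scalar, rel=1e-7)

    def test_closed_system_infinite_in_both_definitions(self):
        from fcrnpk.bayes import _batch_half_lives

        ones = np.ones((1, 1))
        for mode in ("newton", "terminal"):
            assert _batch_half_lives(np.zeros((1, 4)), ones, ones, mode)[0, 0] == math.inf


class TestRunMCMC:
    def test_prior_only_recovers_lognormal_mean(self, priors):
        """With no observations the posterior is the prior; the sampled
        mean of Q_u matches exp(0.1 + 0.5^2/2) within 3 MC standard
        errors (chain-to-chain spread)."""
        fit = run_mcmc([], priors, seed=11, n_chains=4, n_warmup=100,
                       n_samples=12800, n_walkers=32, init="prior")
        j = fit.param_names.index("Q_u")
        chain_means = fit.draws[:, :, j].mean(axis=1)
        mcse = chain_means.std(ddof=1) / math.sqrt(fit.n_chains)
        expected = math.exp(0.1 + 0.125)
        assert abs(chain_means.mean() - expected) <= 3.0 * mcse

    def test_seed_determinism(self, priors):
        obs = make_half_life_fixtures("Tg276")
        kw = dict(n_chains=2, n_warmup=150, n_samples=480, n_walkers=24)
        a = run_mcmc(obs, priors, seed=7, **kw)
        b = run_mcmc(obs, priors, seed=7, **kw)
        np.testing.assert_array_equal(a.chains, b.chains)

    def test_draws_respect_constraints(self, priors):
        obs = make_half_life_fixtures("Tg276")
        fit = run_mcmc(obs, priors, seed=3, n_chains=2, n_warmup=300,
                       n_samples=960, n_walkers=24)
        flat = fit.draws.reshape(-1, len(fit.param_names))
        cols = {n: i for i, n in enumerate(fit.param_names)}
        for name in ("V_p", "V_e", "Q", "Q_u"):
            assert np.all(flat[:, cols[name]] > 0.0)
        f_sort = flat[:, [cols[f"f_sort[{v}]"] for v in priors.f_sort_order]]
        assert np.all((f_sort > 0.0) & (f_sort < 1.0))
        assert np.all(np.diff(f_sort, axis=1) <= 0.0)
        f_rel = flat[:, [cols[f"f_release[{v}]"] for v in priors.f_release_order]]
        assert np.all((f_rel > 0.0) & (f_rel < 1.0))
        assert np.all(np.diff(f_rel, axis=1) <= 0.0)

    def test_recovery_of_known_release_fractions(self):
        """Half-lives generated at known f_release (1.0 / 0.8 / 0.5) and
        fitted back rank the surface recaptures correctly, and the 95%
        credible intervals cover the generating values."""
        aff = AffinityTable(
            kd_ph58={"A": 20.0, "B": 50.0, "C": 100.0},
            ph74_detectable={
                "A": {"high": False}, "B": {"high": True}, "C": {"high": True},
            },
            kd_ph74_high={"B": 4000.0, "C": 500.0},
        )
        priors = build_priors(aff, variants=["A", "B", "C"])
        truth = TraffickingParameters(
            V_p=0.4, V_e=0.25, Q=1.2, Q_u=0.6,
            f_sort={"A": 0.95, "B": 0.93, "C": 0.91},
            f_release={"A": 1.0, "B": 0.8, "C": 0.5},
        )
        obs = [
            HalfLifeObservation(v, mean=model_half_life(truth, v),
                                sd=0.05 * model_half_life(truth, v) * math.sqrt(6), n=6)
            for v in ("A", "B", "C")
        ]
        ranks_ok = 0
        for seed in (1, 2, 3):
            fit = run_mcmc(obs, priors, seed=seed, n_chains=2, n_warmup=2500,
                           n_samples=2000, n_walkers=32)
            rec = fit.recapture_summary().set_index("variant")["recapture_mean"]
            if rec["C"] > rec["B"] > 0.0:
                ranks_ok += 1
            if seed == 1:
                flat = fit.draws.reshape(-1, len(fit.param_names))
                for v, fr_true in (("B", 0.8), ("C", 0.5)):
                    col = fit.param_names.index(f"f_release[{v}]")
                    lo, hi = np.percentile(flat[:, col], [2.5, 97.5])
                    assert lo <= fr_true <= hi
        assert ranks_ok >= 2

    def test_all_infinite_start_raises(self, priors):
        obs = [HalfLifeObservation("YTE", 1e-9, 1e-12, 1)]  # unreachable target
        with pytest.raises(RuntimeError):
            run_mcmc(obs, priors, seed=1, n_chains=1, n_warmup=10,
                     n_samples=32, n_walkers=8)


def synthetic_fit(chains, priors, n_warmup=0):
    """Wrap raw (n_chains, n_steps, n_walkers, P) draws as a PosteriorFit."""
    c, s, w, p = chains.shape
    return PosteriorFit(
        chains=chains, log_prob=np.zeros((c, s, w)),
        param_names=[f"p{i}" for i in range(p)], priors=priors, seed=0,
        n_warmup=n_warmup,
    )


class TestDiagnostics:
    def test_iid_chains_pass(self, priors, rng):
        """Independent-normal chains: autocorrelation time ~ 1 and the
        Geweke score is calibrated — standard-normal spread, and |z| < 2
        at (binomially consistent with) the nominal ~95% rate."""
        taus, zs = [], []
        for _ in range(500):
            x = rng.normal(size=2000)
            taus.append(integrated_autocorr_time(x))
            zs.append(geweke_z(x))
        zs = np.asarray(zs)
        pass_rate = (np.abs(zs) < 2.0).mean()
        # nominal P(|z|<2) = 0.9545; 0.925 is its lower 99.9% binomial
        # envelope at 500 trials — a miscalibrated z fails this
        assert pass_rate >= 0.925
        assert 0.85 <= zs.std() <= 1.15
        assert np.median(taus) == pytest.approx(1.0, abs=0.3)

    def test_trending_chain_flagged(self, priors, rng):
        drift = np.linspace(0.0, 5.0, 2000) + rng.normal(size=2000)
        assert abs(geweke_z(drift)) > 2.0

    def test_duplicate_chains_identical_stats(self, priors, rng):
        one = rng.normal(size=(1, 200, 8, 3))
        fit = synthetic_fit(np.concatenate([one, one]), priors)
        rep = diagnostics(fit)
        a = rep[rep.chain == 0].drop(columns="chain").reset_index(drop=True)
        b = rep[rep.chain == 1].drop(columns="chain").reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_short_chains_rejected(self, priors, rng):
        fit = synthetic_fit(rng.normal(size=(2, 5, 4, 3)), priors)
        with pytest.raises(ValueError):
            diagnostics(fit)

    def test_single_chain_rejected(self, priors, rng):
        fit = synthetic_fit(rng.normal(size=(1, 200, 8, 3)), priors)
        with pytest.raises(ValueError):
            diagnostics(fit)


class TestSensitivity:
    def params(self, fs=0.9, fr=0.6):
        return TraffickingParameters(V_p=0.4, V_e=0.25, Q=1.2, Q_u=0.6,
                                     f_sort={"v": fs}, f_release={"v": fr})

    def test_rate_rescaling_elasticities_sum_to_minus_one(self):
        """T1/2 scales as 1/c when Q and Q_u are both scaled by c, so
        the Q and Q_u elasticities sum to exactly -1."""
        tab = sensitivity_analysis(self.params(), "v").set_index("parameter")
        total = tab.loc["Q", "elasticity"] + tab.loc["Q_u", "elasticity"]
        assert total == pytest.approx(-1.0, abs=1e-5)

    def test_fixed_release_excluded(self):
        tab = sensitivity_analysis(self.params(fr=1.0), "v", fixed=("f_release",))
        assert "f_release" not in set(tab.parameter)
        assert "f_sort" in set(tab.parameter)

    def test_boundary_uses_one_sided_difference(self):
        tab = sensitivity_analysis(self.params(fr=1.0), "v").set_index("parameter")
        assert bool(tab.loc["f_release", "one_sided"])

    def test_positive_effect_of_fractions(self):
        tab = sensitivity_analysis(self.params(), "v").set_index("parameter")
        assert tab.loc["f_sort", "elasticity"] > 0.0
        assert tab.loc["f_release", "elasticity"] > 0.0

    def test_infinite_half_life_rejected(self):
        with pytest.raises(ValueError):
            sensitivity_analysis(self.params(fs=1.0, fr=1.0), "v")
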