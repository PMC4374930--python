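"""Bayesian mixing model: sampler correctness and convergence diagnostics."""

import numpy as np
import pytest
from scipy import stats

from n2oiso import (
    McmcSettings,
    MixingProblem,
    fit_mixing_model,
    gelman_rubin,
    geweke,
    summarize_posterior,
)
from n2oiso.synthetic_data import generate_mixture_observation

QUICK = dict(chain_length=12_000, burn_in=4_000, thinning=8, n_chains=3)

THREE_SOURCES = dict(
    source_names=["soil", "freshwater", "marine"],
    source_means=[[-16.7, 30.0], [-7.8, 40.8], [5.1, 44.8]],
    source_sds=[[11.2, 9.6], [9.7, 9.6], [1.9, 3.6]],
)


def quick_settings(seed=0, **overrides):
    kwargs = {**QUICK, **overrides, "seed": seed}
    return McmcSettings(**kwargs)


class TestProblemValidation:
    def test_needs_two_sources(self):
        with pytest.raises(ValueError, match="2 sources"):
            MixingProblem(["a"], [[0.0, 1.0]], [[1.0, 1.0]], [0.0, 0.0], [1.0, 1.0])

    def test_tracer_dimension_mismatch(self):
        with pytest.raises(ValueError):
            MixingProblem(
                ["a", "b"], [[0.0, 1.0], [1.0, 0.0]], [[1.0, 1.0], [1.0, 1.0]],
                [0.0], [1.0],
            )

    def test_zero_variance_tracer_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            MixingProblem(
                ["a", "b"], [[0.0], [1.0]], [[0.0], [0.0]], [0.5], [0.0],
            )


class TestSampler:
    def test_degenerate_identification(self):
        """Mixture at one source's mean with tiny SDs pins that source."""
        problem = MixingProblem(
            source_names=["a", "b", "c"],
            source_means=[[0.0, 0.0], [20.0, 0.0], [0.0, 20.0]],
            source_sds=np.full((3, 2), 0.01),
            mixture_mean=[0.0, 0.0],
            mixture_sd=[0.01, 0.01],
        )
        post = fit_mixing_model(problem, quick_settings(seed=1))
        assert post.mean()[0] > 0.95

    def test_two_source_one_tracer_matches_endmember_mixing(self):
        """With small SDs the posterior concentrates on the algebraic solution."""
        d1, d2, d_mix = 10.0, -10.0, 4.0
        problem = MixingProblem(
            source_names=["one", "two"],
            source_means=[[d1], [d2]],
            source_sds=[[0.3], [0.3]],
            mixture_mean=[d_mix],
            mixture_sd=[0.3],
        )
        post = fit_mixing_model(problem, quick_settings(seed=2))
        expected = (d_mix - d2) / (d1 - d2)
        assert post.mean()[0] == pytest.approx(expected, abs=0.03)

    def test_simplex_closure(self):
        problem = MixingProblem(mixture_mean=[-8.4, 31.7], mixture_sd=[1.0, 1.0], **THREE_SOURCES)
        post = fit_mixing_model(problem, quick_settings(seed=3))
        draws = post.draws
        np.testing.assert_allclose(draws.sum(axis=1), 1.0, atol=1e-12)
        assert (draws >= 0).all() and (draws <= 1).all()

    def test_seed_determinism(self):
        problem = MixingProblem(mixture_mean=[-8.4, 31.7], mixture_sd=[1.0, 1.0], **THREE_SOURCES)
        a = fit_mixing_model(problem, quick_settings(seed=4))
        b = fit_mixing_model(problem, quick_settings(seed=4))
        np.testing.assert_array_equal(a.chains, b.chains)

    def test_retained_draw_count(self):
        problem = MixingProblem(mixture_mean=[-8.4, 31.7], mixture_sd=[1.0, 1.0], **THREE_SOURCES)
        settings = quick_settings(seed=5)
        post = fit_mixing_model(problem, settings)
        assert post.chains.shape == (settings.n_chains, settings.draws_per_chain, 3)

    def test_label_permutation_equivariance(self):
        """Permuting source labels permutes the posterior (within MC error)."""
        problem = MixingProblem(mixture_mean=[-8.4, 31.7], mixture_sd=[1.0, 1.0], **THREE_SOURCES)
        perm = [2, 0, 1]
        permuted = MixingProblem(
            source_names=[THREE_SOURCES["source_names"][i] for i in perm],
            source_means=np.asarray(THREE_SOURCES["source_means"])[perm],
            source_sds=np.asarray(THREE_SOURCES["source_sds"])[perm],
            mixture_mean=[-8.4, 31.7],
            mixture_sd=[1.0, 1.0],
        )
        base = fit_mixing_model(problem, quick_settings(seed=6))
        other = fit_mixing_model(permuted, quick_settings(seed=6))
        np.testing.assert_allclose(other.mean(), base.mean()[perm], atol=0.04)

    def test_prior_only_matches_dirichlet_moments(self):
        """Likelihood-off sampling reproduces Dirichlet(1,1,1) closed forms."""
        problem = MixingProblem(mixture_mean=[0.0, 0.0], mixture_sd=[1.0, 1.0], **THREE_SOURCES)
        settings = McmcSettings(chain_length=34_000, burn_in=4_000, thinning=6,
                                n_chains=3, seed=7)
        post = fit_mixing_model(problem, settings, prior_only=True)
        draws = post.draws
        assert draws.shape[0] == 15_000
        # marginal of Dirichlet(1,1,1) is Beta(1,2): mean 1/3, var 1/18
        np.testing.assert_allclose(draws.mean(axis=0), 1 / 3, atol=0.02)
        np.testing.assert_allclose(draws.var(axis=0), 1 / 18, atol=0.01)
        q025 = np.percentile(draws[:, 0], 2.5)
        assert q025 == pytest.approx(stats.beta(1, 2).ppf(0.025), abs=0.01)

    def test_rhat_warning_surfaces_in_diagnostics(self):
        problem = MixingProblem(mixture_mean=[-8.4, 31.7], mixture_sd=[1.0, 1.0], **THREE_SOURCES)
        post = fit_mixing_model(problem, quick_settings(seed=8))
        assert set(post.diagnostics["r_hat"]) == set(THREE_SOURCES["source_names"])
        assert all(np.isfinite(list(post.diagnostics["r_hat"].values())))
        assert "warnings" in post.diagnostics


class TestGelmanRubin:
    def test_identical_chains(self):
        chain = np.linspace(0.0, 1.0, 50)
        assert gelman_rubin(np.stack([chain, chain])) == 1.0

    def test_offset_chains_match_hand_formula(self):
        a = np.arange(10.0)
        b = a + 100.0
        n = 10
        within = (np.var(a, ddof=1) + np.var(b, ddof=1)) / 2
        b_over_n = np.var([a.mean(), b.mean()], ddof=1)
        expected = np.sqrt(((n - 1) / n * within + b_over_n) / within)
        got = gelman_rubin(np.stack([a, b]))
        assert got == pytest.approx(expected, rel=1e-12)
        assert got > 10

    def test_split_well_mixed_chain(self, rng):
        x = rng.normal(0, 1, 20_000)
        assert gelman_rubin(x.reshape(2, -1)) < 1.05

    def test_input_validation(self):
        with pytest.raises(ValueError):
            gelman_rubin(np.zeros((1, 100)))


class TestGeweke:
    def test_constant_chain(self):
        assert geweke(np.ones(500)) == 0.0

    def test_iid_chain_small_z(self, rng):
        z = geweke(rng.standard_normal(20_000))
        assert abs(z) < 3

    def test_drifting_chain_large_z(self):
        assert abs(geweke(np.linspace(0.0, 10.0, 2000))) > 5

    def test_short_chain_rejected(self):
        with pytest.raises(ValueError):
            geweke(np.ones(50))


class TestSummaries:
    def test_point_mass_posterior(self):
        from n2oiso.bayes_mixing import MixingPosterior

        point = np.array([0.5, 0.3, 0.2])
        chains = np.tile(point, (2, 100, 1))
        post = MixingPosterior(["a", "b", "c"], chains)
        table = summarize_posterior(post)
        np.testing.assert_allclose(table["sd"].to_numpy(), 0.0, atol=1e-12)
        for col in table.columns:
            if col.startswith("q"):
                np.testing.assert_allclose(table[col].to_numpy(), point)

    def test_quantile_monotonicity_and_layout(self):
        problem = MixingProblem(mixture_mean=[-8.4, 31.7], mixture_sd=[1.0, 1.0], **THREE_SOURCES)
        post = fit_mixing_model(problem, quick_settings(seed=9))
        table = summarize_posterior(post)
        qcols = [c for c in table.columns if c.startswith("q")]
        assert qcols == ["q2.5%", "q5%", "q25%", "q50%", "q75%", "q95%", "q97.5%"]
        values = table[qcols].to_numpy()
        assert (np.diff(values, axis=1) >= 0).all()
        assert list(table.index) == THREE_SOURCES["source_names"]

    def test_too_few_draws_rejected(self):
        from n2oiso.bayes_mixing import MixingPosterior

        post = MixingPosterior(["a", "b"], np.full((2, 10, 2), 0.5))
        with pytest.raises(ValueError):
            summarize_posterior(post)


class TestRecovery:
    def test_posterior_covers_known_proportions(self):
        """Mixture simulated from the model: truth inside the 95% interval."""
        true_p = np.array([0.6, 0.3, 0.1])
        means = np.asarray(THREE_SOURCES["source_means"])
        sds = np.asarray(THREE_SOURCES["source_sds"])
        mixture = generate_mixture_observation(true_p, means, sds, noise_sd=1.0, seed=42)
        problem = MixingProblem(
            mixture_mean=mixture, mixture_sd=[1.0, 1.0], **THREE_SOURCES
        )
        post = fit_mixing_model(problem, quick_settings(seed=42))
        lo, hi = np.percentile(post.draws, [2.5, 97.5], axis=0)
        assert ((lo <= true_p) & (true_p <= hi)).all()
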