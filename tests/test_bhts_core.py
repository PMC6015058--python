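import numpy as np
import pytest
from scipy import integrate
from scipy.stats import invgamma, norm

from bhts.bhts_core import (
    BhtsHyperparameters,
    auto_hyperparameters,
    gibbs_step,
    init_state,
    mixture_density,
    nig_posterior,
    run_sampler,
    stick_weights,
)
from bhts.errors import DegenerateDataError, DomainError, ValidationError

from _model_data import model_generated_dataset, template_dataset, two_atom_state
from conftest import all_compound_dataset


def small_hyper(**kw):
    defaults = dict(mu10=0.30, mu00=0.10, a=6.0, b=0.002, H=2, K=2)
    defaults.update(kw)
    return BhtsHyperparameters(**defaults)


class TestAutoHyperparameters:
    def test_variance_rule(self):
        # v = 0.01 must give a = 3, b = 0.02 exactly
        rng = np.random.default_rng(0)
        x = rng.normal(size=200)
        x = (x - x.mean()) / x.std(ddof=1)  # mean 0, var 1
        z = 0.12 + 0.1 * x  # mean 0.12, sample variance 0.01
        ds = all_compound_dataset([z.reshape(10, 20)])
        hyper = auto_hyperparameters(ds)
        assert hyper.a == pytest.approx(3.0, abs=1e-12)
        assert hyper.b == pytest.approx(0.02, abs=1e-12)

    def test_mean_rule(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=100)
        x = (x - x.mean()) / x.std(ddof=1)
        z = 0.12 + 0.05 * x
        ds = all_compound_dataset([z.reshape(10, 10)])
        hyper = auto_hyperparameters(ds)
        assert hyper.mu00 == pytest.approx(0.06, abs=1e-12)
        assert hyper.mu10 == pytest.approx(0.18, abs=1e-12)

    def test_inverse_gamma_mean_matches_variance(self, rng):
        z = rng.lognormal(-2.0, 0.5, size=400)
        ds = all_compound_dataset([z.reshape(20, 20)])
        hyper = auto_hyperparameters(ds)
        v = z.var(ddof=1)
        assert hyper.b / (hyper.a - 1.0) == pytest.approx(v, abs=1e-12)

    def test_zero_variance_rejected(self):
        ds = all_compound_dataset([np.full((2, 3), 1.0)])
        with pytest.raises(DegenerateDataError):
            auto_hyperparameters(ds)

    def test_nonpositive_mean_rejected(self, rng):
        ds = all_compound_dataset([rng.normal(-1.0, 0.1, size=(4, 5))])
        with pytest.raises(DegenerateDataError):
            auto_hyperparameters(ds)

    def test_invariant_violation_rejected(self):
        with pytest.raises(ValidationError):
            BhtsHyperparameters(mu10=0.1, mu00=0.2, a=3.0, b=0.02).validate()


class TestStickWeights:
    def test_first_stick_absorbs_all(self):
        np.testing.assert_allclose(stick_weights(np.array([1.0, 0.3, 1.0])),
                                   [1.0, 0.0, 0.0])

    def test_hand_case(self):
        np.testing.assert_allclose(
            stick_weights(np.array([0.5, 0.5, 1.0])), [0.5, 0.25, 0.25]
        )

    def test_sums_to_one(self, rng):
        for _ in range(50):
            v = rng.random(8)
            v[-1] = 1.0
            assert abs(stick_weights(v).sum() - 1.0) < 1e-15

    def test_domain_error(self):
        with pytest.raises(DomainError):
            stick_weights(np.array([0.5, 1.5, 1.0]))

    def test_batched_axis(self, rng):
        v = rng.random((4, 2, 5))
        v[..., -1] = 1.0
        w = stick_weights(v, axis=-1)
        np.testing.assert_allclose(w.sum(axis=-1), 1.0, atol=1e-14)


class TestMixtureDensity:
    def test_degenerate_single_atom(self):
        state = two_atom_state(1, pi=1.0)
        state.local_sticks = np.tile(np.array([1.0, 1.0]), (1, 2, 1))
        z = 0.31
        got = mixture_density(z, state, 0)
        expected = norm.pdf(z, 0.30, np.sqrt(4e-4))
        assert got == pytest.approx(expected, rel=1e-12)

    def test_integrates_to_one(self):
        state = two_atom_state(3, pi=0.4)
        grid = np.linspace(-0.5, 1.0, 20001)
        dens = mixture_density(grid, state, 1)
        total = integrate.trapezoid(dens, grid)
        assert abs(total - 1.0) < 1e-6

    def test_symmetry(self):
        state = two_atom_state(1, pi=0.5, active_means=(0.3, 0.3),
                               inactive_means=(-0.3, -0.3))
        d_pos = mixture_density(0.17, state, 0)
        d_neg = mixture_density(-0.17, state, 0)
        assert d_pos == pytest.approx(d_neg, rel=1e-12)


class TestInitState:
    def test_deterministic(self, rng):
        ds = all_compound_dataset([rng.normal(0.2, 0.05, size=(8, 10))])
        h = small_hyper()
        s1 = init_state(ds, h, seed=42)
        s2 = init_state(ds, h, seed=42)
        np.testing.assert_array_equal(s1.b, s2.b)
        np.testing.assert_array_equal(s1.atom_means, s2.atom_means)
        np.testing.assert_array_equal(s1.local_sticks, s2.local_sticks)

    def test_both_channels_populated(self, rng):
        ds = all_compound_dataset([rng.normal(0.2, 0.05, size=(8, 10))])
        s = init_state(ds, small_hyper(), seed=0)
        assert 0 < s.b.sum() < s.b.size

    def test_atom_variances_positive(self, rng):
        ds = all_compound_dataset([rng.normal(0.2, 0.05, size=(8, 10))])
        s = init_state(ds, small_hyper(), seed=3)
        assert (s.atom_vars > 0).all()


class TestGibbsStep:
    def test_pi_concentrates_on_inactive_data(self):
        # data from a single inactive-range component: pi posterior ~ 0
        rng = np.random.default_rng(5)
        z = rng.normal(0.10, 0.02, size=(8, 10))
        ds = all_compound_dataset([z])
        h = small_hyper(a=8.0, b=0.003)
        state = init_state(ds, h, seed=1)
        step_rng = np.random.default_rng(2)
        pis = []
        for _ in range(500):
            state = gibbs_step(state, ds, h, step_rng)
            pis.append(state.pi)
        assert np.mean(pis[100:]) < 0.15

    def test_weights_sum_to_one_after_sweep(self, rng):
        ds = all_compound_dataset([rng.normal(0.2, 0.05, size=(8, 10))])
        h = small_hyper(H=4, K=6)
        state = init_state(ds, h, seed=1)
        state = gibbs_step(state, ds, h, np.random.default_rng(0))
        np.testing.assert_allclose(state.local_weights().sum(axis=-1), 1.0, atol=1e-12)
        np.testing.assert_allclose(state.global_weights().sum(axis=-1), 1.0, atol=1e-12)
        assert (state.atom_vars > 0).all()
        assert 0.0 < state.pi < 1.0

    def test_atom_update_matches_closed_form(self):
        # algebraic identity against independently coded conjugate formulas
        n, s1, s2 = 7.0, 1.4, 0.31
        mu0, a, b = 0.2, 4.0, 0.01
        mu_n, kappa_n, a_n, b_n = nig_posterior(n, s1, s2, mu0, a, b)
        zbar = s1 / n
        assert kappa_n == pytest.approx(1.0 + n, abs=1e-12)
        assert mu_n == pytest.approx((mu0 + n * zbar) / (1.0 + n), abs=1e-10)
        assert a_n == pytest.approx(a + n / 2.0, abs=1e-12)
        expected_b = b + 0.5 * (s2 - n * zbar**2) + n * (zbar - mu0) ** 2 / (
            2.0 * (1.0 + n)
        )
        assert b_n == pytest.approx(expected_b, abs=1e-10)

    def test_atom_posterior_matches_quadrature_oracle(self):
        # numerically integrate prior x likelihood for a tiny sample and
        # compare the posterior mean of mu with the conjugate parameter
        obs = np.array([0.25, 0.31, 0.28])
        mu0, a, b = 0.2, 5.0, 0.004
        mu_n, kappa_n, a_n, b_n = nig_posterior(
            obs.size, obs.sum(), (obs**2).sum(), mu0, a, b
        )

        mus = np.linspace(-0.2, 0.7, 301)
        vars_ = np.linspace(1e-4, 0.02, 301)
        mu_g = mus[:, None]
        var_g = vars_[None, :]
        prior = norm.pdf(mu_g, mu0, np.sqrt(var_g)) * invgamma.pdf(var_g, a, scale=b)
        lik = np.prod(norm.pdf(obs[:, None, None], mu_g[None], np.sqrt(var_g)[None]), axis=0)
        grid = prior * lik
        z0 = integrate.trapezoid(integrate.trapezoid(grid, vars_), mus)
        mean_mu = integrate.trapezoid(
            integrate.trapezoid(grid, vars_) * mus, mus
        ) / z0
        assert mean_mu == pytest.approx(float(mu_n), abs=1e-5)


class TestRunSampler:
    def test_separated_components_ranked(self):
        ds = model_generated_dataset(pi=0.10, seed=7)
        summary = run_sampler(ds, small_hyper(), n_iter=400, burn_in=150,
                              thin=2, seed=9)
        hits = summary.hit_prob[ds.truth]
        nonhits = summary.hit_prob[~ds.truth]
        assert hits.mean() > nonhits.mean()

    def test_deterministic(self):
        ds = model_generated_dataset(pi=0.10, seed=7)
        a = run_sampler(ds, small_hyper(), n_iter=120, burn_in=40, thin=2, seed=5)
        b = run_sampler(ds, small_hyper(), n_iter=120, burn_in=40, thin=2, seed=5)
        np.testing.assert_array_equal(a.hit_prob, b.hit_prob)
        np.testing.assert_array_equal(a.traces["pi"], b.traces["pi"])

    def test_mean_hit_prob_near_hit_fraction(self):
        ds = model_generated_dataset(pi=0.10, seed=11)
        summary = run_sampler(ds, small_hyper(), n_iter=600, burn_in=200,
                              thin=2, seed=13)
        assert abs(summary.hit_prob.mean() - 0.10) < 0.05

    def test_invalid_budget_rejected(self):
        ds = model_generated_dataset(pi=0.10, seed=7)
        with pytest.raises(ValidationError):
            run_sampler(ds, small_hyper(), n_iter=10, burn_in=20, seed=0)

    def test_bad_hyper_rejected_before_sampling(self):
        ds = model_generated_dataset(pi=0.10, seed=7)
        bad = BhtsHyperparameters(mu10=0.1, mu00=0.3, a=3.0, b=0.02, H=2, K=2)
        with pytest.raises(ValidationError):
            run_sampler(ds, bad, n_iter=10, burn_in=2, seed=0)

    def test_kept_iteration_invariants(self):
        ds = model_generated_dataset(pi=0.10, seed=3)
        summary = run_sampler(ds, small_hyper(), n_iter=200, burn_in=50,
                              thin=3, seed=17)
        assert summary.n_kept == 50
        assert ((summary.hit_prob >= 0) & (summary.hit_prob <= 1)).all()
        assert ((summary.traces["pi"] > 0) & (summary.traces["pi"] < 1)).all()

    def test_label_switching_guard(self):
        # active-channel mean must exceed inactive-channel mean in >= 95%
        # of kept iterations when the prior anchors are ordered
        ds = model_generated_dataset(pi=0.10, seed=19)
        summary = run_sampler(ds, small_hyper(), n_iter=500, burn_in=200,
                              thin=2, seed=23)
        frac = float(
            np.mean(summary.traces["mu_active"] > summary.traces["mu_inactive"])
        )
        assert frac >= 0.95


class TestParameterRecovery:
    @pytest.mark.parametrize("pi_true", [0.01, 0.05, 0.10])
    def test_pi_recovered(self, pi_true):
        errs = []
        for seed in (1, 2, 3):
            ds = model_generated_dataset(pi=pi_true, seed=seed)
            summary = run_sampler(ds, small_hyper(), n_iter=700, burn_in=300,
                                  thin=2, seed=seed + 40)
            errs.append(abs(summary.traces["pi"].mean() - pi_true))
        assert max(errs) < 0.03


class TestJointConsistency:
    def test_geweke_moments(self):
        # prior draws vs successive-conditional simulation on a tiny
        # instance must agree in the moments of pi and the atom means
        from bhts.bhts_core import sample_readouts_from_state
        from bhts.plate_io import Plate, ScreenDataset

        h = BhtsHyperparameters(mu10=0.30, mu00=0.10, a=6.0, b=0.002, H=2, K=2)
        ds = template_dataset(1, 4, 5)

        prior_rng = np.random.default_rng(101)
        prior_pis, prior_mu1 = [], []
        for _ in range(4000):
            prior_pis.append(prior_rng.beta(h.a_pi, h.b_pi))
            var = 1.0 / prior_rng.gamma(h.a, 1.0 / h.b)
            prior_mu1.append(prior_rng.normal(h.mu10, np.sqrt(var)))

        sc_rng = np.random.default_rng(202)
        state = init_state(ds, h, seed=7)
        sc_pis, sc_mu1 = [], []
        for _ in range(4000):
            z, _ = sample_readouts_from_state(state, ds, sc_rng)
            plates = [Plate("P1", z.reshape(4, 5), ds.plates[0].roles)]
            data = ScreenDataset(plates=plates)
            state = gibbs_step(state, data, h, sc_rng)
            sc_pis.append(state.pi)
            sc_mu1.append(float(state.atom_means[1].mean()))

        assert abs(np.mean(prior_pis) - np.mean(sc_pis)) < 0.05
        assert abs(np.std(prior_pis) - np.std(sc_pis)) < 0.05
        assert abs(np.mean(prior_mu1) - np.mean(sc_mu1)) < 0.05
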