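"""Closed-form objective components, the penalized bound, and training."""

import numpy as np
import pytest
from scipy import stats
from scipy.special import gammaln

from invvae import (
    InvVAE,
    ModelConfig,
    PosteriorState,
    RegressionParams,
    SimulationConfig,
    TrainingConfig,
    elbo_batch,
    kl_gaussian_pair,
    kl_to_prior,
    mi_penalty,
    poisson_loglik,
    simulate_cohort,
    train,
    trait_loglik,
)


class TestPoissonLoglik:
    def test_single_pair_zero_count_unit_rate(self):
        A = np.zeros((2, 2))
        lam = np.ones((2, 2))
        assert poisson_loglik(A, lam) == pytest.approx(-1.0)

    def test_single_pair_matches_pmf_oracle(self):
        A = np.zeros((2, 2))
        A[0, 1] = A[1, 0] = 3
        lam = np.full((2, 2), 2.0)
        expected = 3 * np.log(2.0) - 2.0 - np.log(6.0)
        assert poisson_loglik(A, lam) == pytest.approx(expected, abs=1e-12)
        assert poisson_loglik(A, lam) == pytest.approx(
            stats.poisson.logpmf(3, 2.0), abs=1e-10
        )

    def test_sum_over_pairs_matches_scipy(self, rng):
        V = 5
        M = rng.integers(0, 8, (V, V)).astype(float)
        A = np.triu(M, 1)
        A = A + A.T
        lam = np.abs(rng.normal(2, 0.5, (V, V))) + 0.1
        lam = (lam + lam.T) / 2
        iu, ju = np.triu_indices(V, k=1)
        oracle = stats.poisson.logpmf(A[iu, ju].astype(int), lam[iu, ju]).sum()
        assert poisson_loglik(A, lam) == pytest.approx(oracle, abs=1e-9)

    def test_maximized_at_observed_counts(self, rng):
        """Grid search over a rate multiplier peaks at lam = A."""
        V = 4
        M = rng.integers(1, 6, (V, V)).astype(float)
        A = np.triu(M, 1)
        A = A + A.T
        scales = np.linspace(0.2, 2.0, 181)
        lls = [poisson_loglik(A, s * A + 1e-12) for s in scales]
        assert scales[int(np.argmax(lls))] == pytest.approx(1.0, abs=0.011)

    def test_non_integer_counts_rejected(self):
        A = np.zeros((2, 2))
        A[0, 1] = A[1, 0] = 1.5
        with pytest.raises(ValueError):
            poisson_loglik(A, np.ones((2, 2)))


class TestGaussianKL:
    def test_prior_kl_closed_forms(self):
        assert kl_to_prior(np.zeros(3), np.ones(3)) == pytest.approx(0.0)
        mu = np.array([1.0, -2.0])
        assert kl_to_prior(mu, np.ones(2)) == pytest.approx(np.sum(mu**2) / 2)

    def test_prior_kl_matches_monte_carlo(self, rng):
        """Closed form within 3 standard errors of a 1e5-draw MC estimate."""
        mu = rng.normal(0, 1, 4)
        sd = np.abs(rng.normal(1, 0.3, 4)) + 0.2
        z = rng.normal(size=(100_000, 4)) * sd + mu
        logq = stats.norm.logpdf(z, mu, sd).sum(axis=1)
        logp = stats.norm.logpdf(z, 0, 1).sum(axis=1)
        diffs = logq - logp
        mc, se = diffs.mean(), diffs.std(ddof=1) / np.sqrt(len(diffs))
        assert abs(kl_to_prior(mu, sd) - mc) < 3 * se

    def test_pair_kl_closed_forms(self):
        assert kl_gaussian_pair([1.0], [2.0], [1.0], [2.0]) == pytest.approx(0.0)
        a, b = np.array([0.0, 1.0]), np.array([2.0, -1.0])
        assert kl_gaussian_pair(a, np.ones(2), b, np.ones(2)) == pytest.approx(
            np.sum((a - b) ** 2) / 2
        )

    def test_pair_kl_matches_monte_carlo(self, rng):
        ma, sa = rng.normal(0, 1, 3), np.abs(rng.normal(1, 0.2, 3)) + 0.2
        mb, sb = rng.normal(0, 1, 3), np.abs(rng.normal(1, 0.2, 3)) + 0.2
        z = rng.normal(size=(100_000, 3)) * sa + ma
        diffs = (stats.norm.logpdf(z, ma, sa) - stats.norm.logpdf(z, mb, sb)).sum(axis=1)
        mc, se = diffs.mean(), diffs.std(ddof=1) / np.sqrt(len(diffs))
        assert abs(kl_gaussian_pair(ma, sa, mb, sb) - mc) < 3 * se

    def test_pair_kl_asymmetry_and_nonnegativity(self):
        kl_ab = kl_gaussian_pair([0.0], [1.0], [1.0], [3.0])
        kl_ba = kl_gaussian_pair([1.0], [3.0], [0.0], [1.0])
        assert kl_ab >= 0 and kl_ba >= 0
        assert kl_ab != pytest.approx(kl_ba)


class TestMIPenalty:
    def test_identical_posteriors_give_zero(self):
        post = PosteriorState(mean=np.ones((4, 2)), scale=np.full((4, 2), 0.5))
        assert mi_penalty(post) == pytest.approx(0.0)

    def test_two_posteriors_hand_summation(self):
        mu = np.array([[0.0, 0.0], [1.0, 2.0]])
        sd = np.array([[1.0, 1.0], [0.5, 2.0]])
        post = PosteriorState(mean=mu, scale=sd)
        k01 = kl_gaussian_pair(mu[0], sd[0], mu[1], sd[1])
        k10 = kl_gaussian_pair(mu[1], sd[1], mu[0], sd[0])
        assert mi_penalty(post) == pytest.approx((k01 + k10) / 4.0, rel=1e-12)

    def test_monotone_in_displacement(self):
        base = np.zeros((3, 2))
        sd = np.ones((3, 2))
        small = base.copy()
        small[0, 0] = 0.5
        large = base.copy()
        large[0, 0] = 2.0
        p_small = mi_penalty(PosteriorState(mean=small, scale=sd))
        p_large = mi_penalty(PosteriorState(mean=large, scale=sd))
        assert 0 < p_small < p_large

    def test_requires_at_least_two(self):
        with pytest.raises(ValueError):
            mi_penalty(PosteriorState(mean=np.zeros((1, 2)), scale=np.ones((1, 2))))


class TestTraitLoglik:
    def test_density_at_its_mean(self):
        reg = RegressionParams(beta=[1.0, 2.0], intercept=0.5, noise_var=1.0)
        z = np.array([1.0, -1.0])
        y = float(z @ reg.beta + reg.intercept)
        assert trait_loglik(y, z, reg) == pytest.approx(-0.5 * np.log(2 * np.pi))

    def test_quadratic_shift(self):
        reg = RegressionParams(beta=[0.0], intercept=0.0, noise_var=2.0)
        base = trait_loglik(0.0, [0.0], reg)
        shifted = trait_loglik(1.5, [0.0], reg)
        assert shifted - base == pytest.approx(-(1.5**2) / (2 * 2.0))

    def test_matches_normal_pdf_oracle(self, rng):
        reg = RegressionParams(beta=rng.normal(size=3), intercept=0.3, noise_var=0.7)
        z = rng.normal(size=3)
        y = rng.normal()
        mu = z @ reg.beta + reg.intercept
        assert trait_loglik(y, z, reg) == pytest.approx(
            stats.norm.logpdf(y, mu, np.sqrt(0.7)), abs=1e-12
        )

    def test_missing_trait_contributes_zero(self):
        reg = RegressionParams(beta=[1.0], intercept=0.0, noise_var=1.0)
        assert trait_loglik(np.nan, [3.0], reg) == 0.0


def _toy_batch(n=4, V=6, seed=0, with_traits=True):
    syn = simulate_cohort(SimulationConfig(n=n, V=V, seed=seed))
    trait = np.arange(float(n)) if with_traits else None
    return syn.to_cohort(trait=trait)


class TestElboBatch:
    def test_breakdown_consistent_with_closed_form_components(self, rng):
        """The differentiable batch objective must agree term-by-term with
        the standalone numpy components evaluated on the same draws."""
        batch = _toy_batch(n=4, V=6, seed=1)
        cfg = ModelConfig(V=6, K=3, C=1, R=2, encoder_hidden=(8, 5),
                          mapper_hidden=(7,), seed=0)
        model = InvVAE.initialize(cfg, batch, np.random.default_rng(0))
        tc = TrainingConfig(lambda_mi=1.7, seed=0)
        eps = rng.standard_normal((4, 3))
        bd = elbo_batch(batch, model, tc, eps)

        A = np.rint(batch.adjacency)
        mean, scale = model.encode(A)
        z = mean + eps * scale
        c_pre = model.preprocess_c(batch.nuisance)
        recon = np.mean([
            poisson_loglik(A[i], model.decode_rates(z[i], c_pre[i]))
            for i in range(4)
        ])
        klp = np.mean([kl_to_prior(mean[i], scale[i]) for i in range(4)])
        reg = model.regression_params
        trait = np.mean([trait_loglik(batch.trait[i], z[i], reg) for i in range(4)])
        mi = mi_penalty(PosteriorState(mean=mean, scale=scale))

        assert bd.recon == pytest.approx(recon, rel=1e-9)
        assert bd.kl_prior == pytest.approx(klp, rel=1e-9)
        assert bd.trait == pytest.approx(trait, rel=1e-9)
        assert bd.mi_penalty == pytest.approx(mi, rel=1e-9)
        lam = tc.lambda_mi
        assert bd.total == pytest.approx(
            (1 + lam) * recon + trait - klp - lam * mi, rel=1e-9
        )

    def test_linearity_in_lambda(self, rng):
        batch = _toy_batch(n=4, V=6, seed=2)
        cfg = ModelConfig(V=6, K=3, C=1, R=2, encoder_hidden=(8, 5),
                          mapper_hidden=(7,), seed=0)
        model = InvVAE.initialize(cfg, batch, np.random.default_rng(0))
        eps = rng.standard_normal((4, 3))
        bd0 = elbo_batch(batch, model, TrainingConfig(lambda_mi=0.0), eps)
        bd2 = elbo_batch(batch, model, TrainingConfig(lambda_mi=2.0), eps)
        assert bd2.total - bd0.total == pytest.approx(
            2.0 * (bd0.recon - bd0.mi_penalty), rel=1e-9
        )

    def test_gate_equivalence_independent_coding(self, rng):
        """lambda=0, C=0 equals an independently coded non-invariant
        objective (reconstruction + trait - prior KL) on fixed draws."""
        batch = _toy_batch(n=4, V=6, seed=3)
        cfg = ModelConfig(V=6, K=3, C=0, R=2, encoder_hidden=(8, 5),
                          mapper_hidden=(7,), seed=0)
        model = InvVAE.initialize(cfg, batch, np.random.default_rng(0))
        eps = rng.standard_normal((4, 3))
        bd = elbo_batch(batch, model, TrainingConfig(lambda_mi=0.0), eps)

        # independent route: scipy densities, explicit loops, no shared code
        A = np.rint(batch.adjacency)
        iu, ju = np.triu_indices(6, k=1)
        mean, scale = model.encode(A)
        reg = model.regression_params
        totals = []
        for i in range(4):
            z = mean[i] + eps[i] * scale[i]
            lam = model.decode_rates(z, None)
            rec = float(stats.poisson.logpmf(A[i][iu, ju].astype(int), lam[iu, ju]).sum())
            tr = float(stats.norm.logpdf(batch.trait[i], z @ reg.beta + reg.intercept,
                                         np.sqrt(reg.noise_var)))
            kl = float(0.5 * np.sum(scale[i]**2 + mean[i]**2 - 1 - 2 * np.log(scale[i])))
            totals.append(rec + tr - kl)
        assert bd.total == pytest.approx(np.mean(totals), abs=1e-10 * max(1, abs(bd.total)))

    def test_finite_on_random_batch(self, rng):
        batch = _toy_batch(n=4, V=6, seed=4, with_traits=False)
        cfg = ModelConfig(V=6, K=3, C=1, R=2, encoder_hidden=(8, 5),
                          mapper_hidden=(7,), seed=1)
        model = InvVAE.initialize(cfg, batch, np.random.default_rng(1))
        bd = elbo_batch(batch, model, TrainingConfig(), rng.standard_normal((4, 3)))
        for v in (bd.recon, bd.trait, bd.kl_prior, bd.mi_penalty, bd.total):
            assert np.isfinite(v)

    def test_singleton_batch_rejected_with_penalty(self):
        batch = _toy_batch(n=1, V=6, seed=5)
        cfg = ModelConfig(V=6, K=3, C=1, R=2, encoder_hidden=(8, 5),
                          mapper_hidden=(7,), seed=0)
        model = InvVAE.initialize(cfg, batch, np.random.default_rng(0))
        with pytest.raises(ValueError):
            elbo_batch(batch, model, TrainingConfig(lambda_mi=1.0),
                       np.zeros((1, 3)))


class TestGradientConsistency:
    def test_objective_gradients_match_finite_differences(self, rng):
        """Autodiff gradients of the full objective vs central differences,
        spot-checked across every parameter array (rel err < 1e-4)."""
        from invvae.objective import _batch_objective_t

        batch = _toy_batch(n=5, V=6, seed=6)
        cfg = ModelConfig(V=6, K=3, C=1, R=2, encoder_hidden=(8, 5),
                          mapper_hidden=(7,), seed=0)
        model = InvVAE.initialize(cfg, batch, np.random.default_rng(0))
        tc = TrainingConfig(lambda_mi=1.3)
        A = np.rint(batch.adjacency)
        feats = model.featurize(A)
        A_ut = A[:, model._iu, model._ju]
        c_pre = model.preprocess_c(batch.nuisance)
        eps = rng.standard_normal((5, 3))

        def loss():
            _, l = _batch_objective_t(model, feats, A_ut, c_pre,
                                      batch.trait, eps, tc)
            return l

        l = loss()
        l.backward()
        check = np.random.default_rng(11)
        for name, p in model.params.items():
            flat = p.data.reshape(-1)
            gflat = p.grad.reshape(-1)
            for i in check.choice(flat.size, size=min(3, flat.size), replace=False):
                orig = flat[i]
                h = 1e-6 * max(1.0, abs(orig))
                flat[i] = orig + h
                lp = loss().item()
                flat[i] = orig - h
                lm = loss().item()
                flat[i] = orig
                fd = (lp - lm) / (2 * h)
                assert abs(fd - gflat[i]) <= 1e-4 * max(1.0, abs(fd), abs(gflat[i])), name


class TestTraining:
    def test_objective_improves_on_small_cohort(self):
        """Epoch-mean total is higher over the last 10 epochs than the
        first 10 on a 50-subject, 10-node cohort."""
        syn = simulate_cohort(SimulationConfig(n=50, V=10, seed=7))
        cohort = syn.to_cohort()
        mc = ModelConfig(V=10, K=4, C=1, R=3, encoder_hidden=(32, 16),
                         mapper_hidden=(16,), seed=0)
        tc = TrainingConfig(lambda_mi=1.0, batch_size=16, epochs=200, seed=1)
        model, history = train(cohort, mc, tc)
        assert history["total"].iloc[-10:].mean() > history["total"].iloc[:10].mean()

    def test_training_is_deterministic(self):
        syn = simulate_cohort(SimulationConfig(n=20, V=8, seed=8))
        cohort = syn.to_cohort()
        mc = ModelConfig(V=8, K=3, C=1, R=2, encoder_hidden=(16, 8),
                         mapper_hidden=(8,), seed=0)
        tc = TrainingConfig(lambda_mi=1.0, batch_size=10, epochs=10, seed=5)
        m1, h1 = train(cohort, mc, tc)
        m2, h2 = train(cohort, mc, tc)
        for k in m1.params:
            np.testing.assert_array_equal(m1.params[k].data, m2.params[k].data)
        assert h1["total"].tolist() == h2["total"].tolist()

    def test_checkpoint_written_each_epoch(self, tmp_path):
        syn = simulate_cohort(SimulationConfig(n=10, V=6, seed=9))
        cohort = syn.to_cohort()
        mc = ModelConfig(V=6, K=2, C=1, R=2, encoder_hidden=(8,),
                         mapper_hidden=(6,), seed=0)
        tc = TrainingConfig(lambda_mi=1.0, batch_size=5, epochs=3, seed=0)
        model, _ = train(cohort, mc, tc, checkpoint_dir=tmp_path)
        reloaded = InvVAE.load(tmp_path / "checkpoint.npz")
        for k in model.params:
            np.testing.assert_array_equal(model.params[k].data,
                                          reloaded.params[k].data)

    def test_strict_mode_rejects_fractional_counts(self):
        from invvae import ConnectomeCohort

        A = np.zeros((4, 5, 5))
        A[:, 0, 1] = A[:, 1, 0] = 1.5
        cohort = ConnectomeCohort(adjacency=A, nuisance=np.ones((4, 1)),
                                  trait=np.full(4, np.nan))
        mc = ModelConfig(V=5, K=2, C=1, R=2, encoder_hidden=(8,),
                         mapper_hidden=(6,), seed=0)
        tc = TrainingConfig(lambda_mi=1.0, batch_size=4, epochs=1, seed=0,
                            strict_counts=True)
        with pytest.raises(ValueError, match="non-integer"):
            train(cohort, mc, tc)

    def test_mismatched_nuisance_dimension_rejected(self):
        syn = simulate_cohort(SimulationConfig(n=6, V=6, seed=10))
        cohort = syn.to_cohort()
        mc = ModelConfig(V=6, K=2, C=3, R=2, encoder_hidden=(8,),
                         mapper_hidden=(6,), seed=0)
        with pytest.raises(ValueError, match="nuisance"):
            train(cohort, mc, TrainingConfig(epochs=1))
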