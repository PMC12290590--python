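"""Penalized variational objective and minibatch training loop.

Per subject the maximized quantity is the invariance-penalized evidence
lower bound

    total = (1 + lambda) * E_q[log p(A | z, c)] + log p(y | z)
            - KL[q(z|A) || N(0, I)] - lambda * MI_penalty,

where the mutual-information term I(z, c) is controlled through its upper
bound: the KL between each subject's posterior and the aggregate posterior
q(z), approximated inside a minibatch by the pairwise-KL average

    MI_penalty = (1/m^2) sum_{i,j} KL[q(z|A_i) || q(z|A_j)],

an upper bound on the batch KL-to-marginal by convexity of KL in its second
argument.  (The reconstruction part of the bound is carried by the
``1 + lambda`` coefficient, not duplicated.)  With lambda = 0 and C = 0 the
total reduces exactly to the GATE objective: reconstruction + trait
log-likelihood - prior KL.

Expectations are approximated with a single reparameterized draw per subject
per step; gradients flow through the whole objective via
:mod:`invvae.autodiff` and are averaged over the batch (Adam, gradient-norm
clipping at 10).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .autodiff import Adam, Tensor, clip_grad_norm, concat
from .connectome_io import ConnectomeCohort
from .model import InvVAE, ModelConfig, PosteriorState

__all__ = [
    "TrainingConfig",
    "ObjectiveBreakdown",
    "poisson_loglik",
    "kl_to_prior",
    "kl_gaussian_pair",
    "mi_penalty",
    "trait_loglik",
    "elbo_batch",
    "train",
]

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class TrainingConfig:
    lambda_mi: float = 1.0
    batch_size: int = 64
    epochs: int = 100
    learning_rate: float = 1e-3
    mc_samples: int = 1
    trait_weight: float = 1.0
    grad_clip: float = 10.0
    strict_counts: bool = False  # error on non-integer counts instead of rounding
    seed: int = 0

    def __post_init__(self):
        if self.lambda_mi < 0:
            raise ValueError("lambda_mi must be nonnegative")
        if self.lambda_mi > 0 and self.batch_size < 2:
            raise ValueError("the marginal surrogate needs batches of size >= 2")


@dataclass
class ObjectiveBreakdown:
    """Per-batch (or per-epoch) values of the objective's four terms."""

    recon: float
    trait: float
    kl_prior: float
    mi_penalty: float
    total: float


# ---------------------------------------------------------------------------
# closed-form components (numpy; the training loop re-expresses them in
# autodiff primitives, and the test suite checks the two paths agree)


def poisson_loglik(A: np.ndarray, rates: np.ndarray) -> float:
    """log p(A | rates) summed over unordered pairs u < v.

    A must hold (near-)integer counts; rates strictly positive.
    """
    A = np.asarray(A, dtype=float)
    rates = np.asarray(rates, dtype=float)
    V = A.shape[0]
    iu, ju = np.triu_indices(V, k=1)
    a = A[iu, ju]
    lam = rates[iu, ju]
    if np.max(np.abs(a - np.rint(a))) > 1e-6:
        raise ValueError("counts must be integers for the Poisson likelihood")
    a = np.rint(a)
    if np.any(lam <= 0):
        raise ValueError("rates must be strictly positive")
    return float(np.sum(a * np.log(lam) - lam - gammaln(a + 1.0)))


def kl_to_prior(mean: np.ndarray, scale: np.ndarray) -> float:
    """KL[N(mean, diag(scale^2)) || N(0, I)], closed form, >= 0."""
    mean = np.asarray(mean, float).reshape(-1)
    scale = np.asarray(scale, float).reshape(-1)
    if np.any(scale <= 0):
        raise ValueError("scale must be strictly positive")
    return float(0.5 * np.sum(scale**2 + mean**2 - 1.0 - 2.0 * np.log(scale)))


def kl_gaussian_pair(mean_a, scale_a, mean_b, scale_b) -> float:
    """KL between two diagonal Gaussians, KL[N_a || N_b]; >= 0."""
    ma = np.asarray(mean_a, float).reshape(-1)
    sa = np.asarray(scale_a, float).reshape(-1)
    mb = np.asarray(mean_b, float).reshape(-1)
    sb = np.asarray(scale_b, float).reshape(-1)
    if np.any(sa <= 0) or np.any(sb <= 0):
        raise ValueError("scales must be strictly positive")
    return float(np.sum(
        np.log(sb) - np.log(sa) + (sa**2 + (ma - mb) ** 2) / (2.0 * sb**2) - 0.5
    ))


def mi_penalty(posteriors: PosteriorState) -> float:
    """Batch surrogate for E[KL[q(z|A) || q(z)]]: mean pairwise Gaussian KL.

    Averaging KL[q_i || q_j] over all ordered pairs (including i = j, which
    contributes zero) upper-bounds the KL to the batch marginal by convexity
    of KL in its second argument.
    """
    m = posteriors.mean.shape[0]
    if m < 2:
        raise ValueError("the marginal surrogate needs at least 2 posteriors")
    mu = posteriors.mean
    s = posteriors.scale
    mu_i, mu_j = mu[:, None, :], mu[None, :, :]
    s_i, s_j = s[:, None, :], s[None, :, :]
    kl = np.sum(
        np.log(s_j) - np.log(s_i) + (s_i**2 + (mu_i - mu_j) ** 2) / (2.0 * s_j**2) - 0.5,
        axis=2,
    )
    return float(kl.sum() / (m * m))


def trait_loglik(y: float, z: np.ndarray, reg) -> float:
    """Gaussian log-density of y at mean z.beta + b; NaN (missing) gives 0."""
    if y is None or (isinstance(y, float) and np.isnan(y)) or np.isnan(y):
        return 0.0
    mu = float(np.asarray(z, float).reshape(-1) @ reg.beta + reg.intercept)
    v = reg.noise_var
    return float(-0.5 * (_LOG2PI + np.log(v) + (y - mu) ** 2 / v))


# ---------------------------------------------------------------------------
# the differentiable batch objective


def _batch_objective_t(
    model: InvVAE,
    feats: np.ndarray,      # (m, P) encoder features
    A_ut: np.ndarray,       # (m, P) counts over pairs
    c_pre: np.ndarray,      # (m, C) preprocessed nuisance
    y: np.ndarray,          # (m,) traits, NaN = missing
    eps: np.ndarray,        # (m, K) standard-normal draws
    tc: TrainingConfig,
) -> tuple[ObjectiveBreakdown, Tensor]:
    m = feats.shape[0]
    lam_coef = tc.lambda_mi

    mean, scale = model.encode_t(Tensor(feats))
    z = mean + Tensor(eps) * scale
    z_tilde = concat([z, Tensor(c_pre)], axis=1) if model.config.C > 0 else z

    # reconstruction: Poisson log-likelihood over pairs, subject-averaged
    eta = model.pair_log_rates_t(z_tilde)
    const = float(np.mean(np.sum(gammaln(np.rint(A_ut) + 1.0), axis=1)))
    recon = (Tensor(A_ut) * eta - eta.exp()).sum(axis=1).mean() + (-const)

    # prior KL, closed form
    scale2 = scale * scale
    klp = ((scale2 + mean * mean - 1.0 - scale2.log()).sum(axis=1) * 0.5).mean()

    # trait term (missing y drops out)
    mask = np.isfinite(y).astype(float)
    y_fill = np.where(np.isfinite(y), y, 0.0)
    mu_y = z @ model.params["reg_beta"] + model.params["reg_b"]
    logvar = model.params["reg_logvar"]
    resid2 = (Tensor(y_fill) - mu_y) ** 2.0
    ll_y = (resid2 * (-logvar).exp() + logvar + _LOG2PI) * (-0.5)
    trait = (Tensor(mask) * ll_y).sum() * (tc.trait_weight / m)

    # minibatch pairwise-KL surrogate for the mutual-information bound
    if m >= 2:
        K = model.config.K
        mu_i = mean.reshape(m, 1, K)
        mu_j = mean.reshape(1, m, K)
        s_i = scale.reshape(m, 1, K)
        s_j = scale.reshape(1, m, K)
        term = (s_j.log() - s_i.log()
                + (s_i * s_i + (mu_i - mu_j) ** 2.0) / (s_j * s_j * 2.0) - 0.5)
        mi = term.sum() * (1.0 / (m * m))
    else:
        mi = Tensor(0.0)

    total = recon * (1.0 + lam_coef) + trait - klp - mi * lam_coef
    bd = ObjectiveBreakdown(
        recon=recon.item(), trait=trait.item(), kl_prior=klp.item(),
        mi_penalty=mi.item(), total=total.item(),
    )
    return bd, -total


def _prepare_counts(A: np.ndarray, strict: bool) -> np.ndarray:
    dev = np.max(np.abs(A - np.rint(A))) if A.size else 0.0
    if strict and dev > 1e-8:
        raise ValueError(f"non-integer counts (max deviation {dev:.3g}) in strict mode")
    return np.rint(A)


def elbo_batch(
    batch: ConnectomeCohort,
    model: InvVAE,
    config: TrainingConfig,
    eps: np.ndarray,
) -> ObjectiveBreakdown:
    """Single-draw Monte-Carlo estimate of the penalized bound on one batch."""
    if config.lambda_mi > 0 and batch.n_subjects < 2:
        raise ValueError("the marginal surrogate needs batches of size >= 2")
    A = _prepare_counts(batch.adjacency, config.strict_counts)
    feats = model.featurize(A)
    A_ut = A[:, model._iu, model._ju]
    c_pre = model.preprocess_c(batch.nuisance) if model.config.C > 0 else np.zeros((A.shape[0], 0))
    bd, _ = _batch_objective_t(model, feats, A_ut, c_pre, batch.trait, np.asarray(eps, float), config)
    return bd


def train(
    cohort: ConnectomeCohort,
    model_config: ModelConfig,
    training_config: TrainingConfig,
    checkpoint_dir=None,
) -> tuple[InvVAE, pd.DataFrame]:
    """Minibatch stochastic gradient ascent on the penalized bound.

    The seed controls initialization, epoch shuffling and the per-batch
    reparameterization draws; identical seeds give identical fits.  Returns
    the fitted model and a per-epoch log of the objective terms.  A non-finite
    objective aborts with a diagnostic naming the offending term.
    """
    tc = training_config
    if model_config.C not in (0, cohort.n_nuisance):
        raise ValueError(
            f"model expects C={model_config.C} nuisance columns, cohort has {cohort.n_nuisance}"
        )
    A = _prepare_counts(cohort.adjacency, tc.strict_counts)
    n = A.shape[0]
    rng = np.random.default_rng(tc.seed)
    model = InvVAE.initialize(model_config, cohort, rng)
    opt = Adam(model.parameters(), lr=tc.learning_rate)

    feats_all = model.featurize(A)
    A_ut_all = A[:, model._iu, model._ju]
    c_all = (model.preprocess_c(cohort.nuisance)
             if model_config.C > 0 else np.zeros((n, 0)))
    y_all = cohort.trait

    rows = []
    for epoch in range(tc.epochs):
        perm = rng.permutation(n)
        batch_bds = []
        for start in range(0, n, tc.batch_size):
            idx = perm[start:start + tc.batch_size]
            if idx.size < 2 and tc.lambda_mi > 0:
                continue  # the marginal surrogate is undefined on a singleton
            for _ in range(tc.mc_samples):
                eps = rng.standard_normal((idx.size, model_config.K))
                bd, loss = _batch_objective_t(
                    model, feats_all[idx], A_ut_all[idx], c_all[idx],
                    y_all[idx], eps, tc,
                )
                for name in ("recon", "trait", "kl_prior", "mi_penalty"):
                    if not np.isfinite(getattr(bd, name)):
                        raise FloatingPointError(
                            f"non-finite objective term '{name}' at epoch {epoch}"
                        )
                opt.zero_grad()
                loss.backward()
                clip_grad_norm(model.parameters(), tc.grad_clip)
                opt.step()
                batch_bds.append(bd)
        rows.append({
            "epoch": epoch,
            "recon": np.mean([b.recon for b in batch_bds]),
            "trait": np.mean([b.trait for b in batch_bds]),
            "kl_prior": np.mean([b.kl_prior for b in batch_bds]),
            "mi_penalty": np.mean([b.mi_penalty for b in batch_bds]),
            "total": np.mean([b.total for b in batch_bds]),
        })
        if checkpoint_dir is not None:
            from pathlib import Path

            ckpt = Path(checkpoint_dir)
            ckpt.mkdir(parents=True, exist_ok=True)
            model.save(ckpt / "checkpoint.npz")
    return model, pd.DataFrame(rows)
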