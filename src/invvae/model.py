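"""The invariant graph VAE: encoder, latent-space Poisson decoder, trait head.

Generative model per subject i with latent z_i in R^K and nuisance c_i in R^C:

    z_i ~ N(0, I_K)
    z~_i = z_i (+) c_i                      (concatenation)
    X(z~_i) in R^{V x R}                    (node positions in network space)
    psi_uv  = sum_r alpha_r X_ur X_vr       (weighted inner product, alpha_r > 0)
    lam_uv  = exp(xi_uv + psi_uv)           (xi = population baseline)
    A_uv | z_i, c_i ~ Poisson(lam_uv)       (unordered pairs u < v)
    y_i | z_i ~ N(z_i . beta + b, sigma^2)  (Gaussian trait regression)

With C = 0 the decoder receives z alone and the model reduces to the
non-invariant GATE baseline: byte-for-byte the same code path.

The encoder is an MLP on the log1p-transformed upper-triangle count vector;
the z~ -> X map is an MLP (optionally followed by one graph-convolution
smoothing step against a template adjacency, which couples node positions
through the population graph).  All forward maps are built from
:mod:`invvae.autodiff` primitives so the training loop can differentiate the
full objective; public operations below return plain numpy arrays.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field

import numpy as np

from .autodiff import Tensor, concat, softplus

__all__ = [
    "ModelConfig",
    "PosteriorState",
    "DecoderParams",
    "RegressionParams",
    "InvVAE",
    "reparameterize",
    "concat_nuisance",
    "edge_scores",
    "edge_rates",
    "sample_network",
    "predict_trait",
]


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    K : connectome latent dimension (68 recommended at full scale)
    C : nuisance dimension; 0 switches to the GATE (non-invariant) baseline
    R : network latent-space dimension (node-position space)
    """

    V: int = 68
    K: int = 68
    C: int = 1
    R: int = 8
    encoder_hidden: tuple[int, ...] = (256, 128)
    mapper_hidden: tuple[int, ...] = (128,)
    mapper_type: str = "mlp"  # "mlp" | "gcn_smooth"
    exponent_clamp: float = 30.0
    seed: int = 0

    def __post_init__(self):
        if min(self.K, self.R, self.V) < 1 or self.C < 0:
            raise ValueError("require K, R, V >= 1 and C >= 0")
        if self.mapper_type not in ("mlp", "gcn_smooth"):
            raise ValueError("mapper_type must be 'mlp' or 'gcn_smooth'")
        self.encoder_hidden = tuple(int(h) for h in self.encoder_hidden)
        self.mapper_hidden = tuple(int(h) for h in self.mapper_hidden)


@dataclass
class PosteriorState:
    """Diagonal-Gaussian posterior q(z|A): per-subject mean and scale (sd)."""

    mean: np.ndarray  # (n, K)
    scale: np.ndarray  # (n, K), strictly positive

    def __post_init__(self):
        self.mean = np.atleast_2d(np.asarray(self.mean, dtype=float))
        self.scale = np.atleast_2d(np.asarray(self.scale, dtype=float))
        if self.mean.shape != self.scale.shape:
            raise ValueError("mean and scale shapes disagree")
        if np.any(self.scale <= 0):
            raise ValueError("posterior scales must be strictly positive")


@dataclass
class DecoderParams:
    """Decoder view: symmetric baseline xi, positive alpha, mapper weights."""

    xi: np.ndarray           # (V, V) symmetric, diagonal irrelevant
    log_alpha: np.ndarray    # (R,); alpha = exp(log_alpha) > 0
    mapper_weights: dict = field(default_factory=dict)

    @property
    def alpha(self) -> np.ndarray:
        return np.exp(self.log_alpha)


@dataclass
class RegressionParams:
    """Gaussian trait head y ~ N(z.beta + b, sigma^2)."""

    beta: np.ndarray
    intercept: float
    noise_var: float

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float).reshape(-1)
        if self.noise_var <= 0:
            raise ValueError("noise_var must be positive")


# ---------------------------------------------------------------------------
# stateless operations


def reparameterize(mean: np.ndarray, scale: np.ndarray, eps: np.ndarray) -> np.ndarray:
    """z = mean + eps * scale (elementwise location-scale draw)."""
    return np.asarray(mean, float) + np.asarray(eps, float) * np.asarray(scale, float)


def concat_nuisance(z: np.ndarray, c: np.ndarray | None) -> np.ndarray:
    """z~ = z (+) c; with C = 0 (empty c) returns z unchanged."""
    z = np.asarray(z, dtype=float)
    if c is None:
        return z
    c = np.asarray(c, dtype=float).reshape(-1)
    if c.size == 0:
        return z
    return np.concatenate([z, c])


def edge_scores(X: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """psi = X diag(alpha) X^T; symmetric, diagonal computed but unused."""
    X = np.asarray(X, dtype=float)
    alpha = np.asarray(alpha, dtype=float).reshape(-1)
    if np.any(alpha <= 0):
        raise ValueError("alpha must be strictly positive")
    return (X * alpha) @ X.T


def edge_rates(psi: np.ndarray, xi: np.ndarray, clamp: float = 30.0) -> np.ndarray:
    """lam = exp(xi + psi) with the exponent clamped to +-clamp for stability."""
    return np.exp(np.clip(np.asarray(xi, float) + np.asarray(psi, float), -clamp, clamp))


def sample_network(rates: np.ndarray, seed=None) -> np.ndarray:
    """Draw a symmetric zero-diagonal count matrix with Poisson(lam_uv) edges."""
    rates = np.asarray(rates, dtype=float)
    if np.any(rates <= 0):
        raise ValueError("rates must be strictly positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    V = rates.shape[0]
    iu, ju = np.triu_indices(V, k=1)
    draws = rng.poisson(rates[iu, ju])
    A = np.zeros((V, V))
    A[iu, ju] = draws
    A[ju, iu] = draws
    return A


def predict_trait(z: np.ndarray, reg: RegressionParams) -> float:
    """Point prediction y_hat = z . beta + b at the posterior mean."""
    return float(np.asarray(z, float).reshape(-1) @ reg.beta + reg.intercept)


# ---------------------------------------------------------------------------
# the parameterized model


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class InvVAE:
    """Parameter container + differentiable forward maps of the invariant VAE."""

    def __init__(self, config: ModelConfig, params: dict[str, Tensor],
                 c_shift: np.ndarray, template: np.ndarray | None = None):
        self.config = config
        self.params = params
        self.c_shift = np.asarray(c_shift, dtype=float).reshape(-1)
        self.template = template
        V = config.V
        self._iu, self._ju = np.triu_indices(V, k=1)
        self._smoother = None
        if config.mapper_type == "gcn_smooth":
            if template is None:
                raise ValueError("gcn_smooth mapper requires a template adjacency")
            T = (np.asarray(template, float) > 0).astype(float) + np.eye(V)
            d = T.sum(axis=1)
            self._smoother = T / np.sqrt(np.outer(d, d))

    # -- construction ------------------------------------------------------

    @classmethod
    def initialize(cls, config: ModelConfig, cohort=None,
                   rng: np.random.Generator | None = None) -> "InvVAE":
        """Fresh parameters; xi warm-started from the training mean counts."""
        rng = rng or np.random.default_rng(config.seed)
        V, K, C, R = config.V, config.K, config.C, config.R
        P = V * (V - 1) // 2
        iu, ju = np.triu_indices(V, k=1)

        p: dict[str, Tensor] = {}
        widths = [P, *config.encoder_hidden]
        for li in range(len(widths) - 1):
            p[f"enc_W{li}"] = Tensor(_glorot(rng, widths[li], widths[li + 1]), requires_grad=True)
            p[f"enc_b{li}"] = Tensor(np.zeros(widths[li + 1]), requires_grad=True)
        h_last = widths[-1]
        p["enc_Wmu"] = Tensor(_glorot(rng, h_last, K), requires_grad=True)
        p["enc_bmu"] = Tensor(np.zeros(K), requires_grad=True)
        p["enc_Wls"] = Tensor(_glorot(rng, h_last, K), requires_grad=True)
        p["enc_bls"] = Tensor(np.zeros(K), requires_grad=True)

        mwidths = [K + C, *config.mapper_hidden, V * R]
        for li in range(len(mwidths) - 1):
            p[f"map_W{li}"] = Tensor(_glorot(rng, mwidths[li], mwidths[li + 1]), requires_grad=True)
            p[f"map_b{li}"] = Tensor(np.zeros(mwidths[li + 1]), requires_grad=True)

        if cohort is not None:
            mean_counts = cohort.adjacency.mean(axis=0)[iu, ju]
            xi0 = np.log(mean_counts + 1e-3)
        else:
            xi0 = np.zeros(P)
        p["xi"] = Tensor(xi0, requires_grad=True)
        p["log_alpha"] = Tensor(np.zeros(R), requires_grad=True)

        p["reg_beta"] = Tensor(np.zeros(K), requires_grad=True)
        obs = cohort.trait[cohort.trait_observed] if cohort is not None else np.array([])
        p["reg_b"] = Tensor(np.array(float(obs.mean()) if obs.size else 0.0), requires_grad=True)
        p["reg_logvar"] = Tensor(np.array(0.0), requires_grad=True)

        if C > 0 and cohort is not None and cohort.n_nuisance == C:
            c_shift = cohort.nuisance.min(axis=0)
        else:
            c_shift = np.zeros(C)
        template = cohort.adjacency.mean(axis=0) if (
            cohort is not None and config.mapper_type == "gcn_smooth") else None
        return cls(config, p, c_shift, template)

    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    # -- featurization and preprocessing ------------------------------------

    def featurize(self, A: np.ndarray) -> np.ndarray:
        """Encoder input: log1p of the upper-triangle count vector(s)."""
        A = np.asarray(A, dtype=float)
        if not np.all(np.isfinite(A)):
            raise ValueError("adjacency contains non-finite entries")
        if A.ndim == 2:
            A = A[None]
        return np.log1p(A[:, self._iu, self._ju])

    def preprocess_c(self, c_raw: np.ndarray) -> np.ndarray:
        """Shift the nuisance so the training minimum maps to 0."""
        c = np.asarray(c_raw, dtype=float).reshape(-1, self.config.C)
        return c - self.c_shift

    # -- differentiable forward pieces (Tensor in, Tensor out) --------------

    def encode_t(self, feats) -> tuple[Tensor, Tensor]:
        h = Tensor._lift(feats)
        for li in range(len(self.config.encoder_hidden)):
            h = (h @ self.params[f"enc_W{li}"] + self.params[f"enc_b{li}"]).tanh()
        mean = h @ self.params["enc_Wmu"] + self.params["enc_bmu"]
        scale = softplus(h @ self.params["enc_Wls"] + self.params["enc_bls"])
        return mean, scale

    def positions_t(self, z_tilde) -> Tensor:
        h = Tensor._lift(z_tilde)
        n_hidden = len(self.config.mapper_hidden)
        for li in range(n_hidden):
            h = (h @ self.params[f"map_W{li}"] + self.params[f"map_b{li}"]).tanh()
        h = h @ self.params[f"map_W{n_hidden}"] + self.params[f"map_b{n_hidden}"]
        m = h.shape[0]
        X = h.reshape(m, self.config.V, self.config.R)
        if self._smoother is not None:
            X = Tensor(self._smoother) @ X
        return X

    def pair_scores_t(self, X: Tensor) -> Tensor:
        """psi over unordered pairs u < v: sum_r alpha_r X_ur X_vr, shape (m, P)."""
        alpha = self.params["log_alpha"].exp()
        Xu = X.take(self._iu, axis=1)
        Xv = X.take(self._ju, axis=1)
        return (Xu * Xv * alpha).sum(axis=2)

    def pair_log_rates_t(self, z_tilde) -> Tensor:
        """Clamped log Poisson rates eta_uv = xi_uv + psi_uv over pairs."""
        psi = self.pair_scores_t(self.positions_t(z_tilde))
        eta = self.params["xi"] + psi
        b = self.config.exponent_clamp
        return eta.clip(-b, b)

    # -- public numpy API ----------------------------------------------------

    def encode(self, A: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Posterior (mean, scale) for one V x V network (or a stack)."""
        single = np.asarray(A).ndim == 2
        mean, scale = self.encode_t(Tensor(self.featurize(A)))
        m, s = mean.data, scale.data
        return (m[0], s[0]) if single else (m, s)

    def posterior(self, A_stack: np.ndarray) -> PosteriorState:
        mean, scale = self.encode_t(Tensor(self.featurize(A_stack)))
        return PosteriorState(mean=mean.data, scale=scale.data)

    def latent_positions(self, z_tilde: np.ndarray) -> np.ndarray:
        """Node positions X in R^{V x R} for one concatenated latent z~."""
        z_tilde = np.asarray(z_tilde, dtype=float).reshape(1, -1)
        if z_tilde.shape[1] != self.config.K + self.config.C:
            raise ValueError("z_tilde must have length K + C")
        X = self.positions_t(Tensor(z_tilde)).data[0]
        if not np.all(np.isfinite(X)):
            raise FloatingPointError("non-finite node positions")
        return X

    def decode_rates(self, z: np.ndarray, c: np.ndarray | None = None) -> np.ndarray:
        """Symmetric positive V x V Poisson rate matrix for one subject.

        ``c`` is the preprocessed (min-shifted) nuisance vector; with C = 0
        this is exactly the GATE decoder.
        """
        z_tilde = concat_nuisance(z, c)
        X = self.latent_positions(z_tilde)
        psi = edge_scores(X, np.exp(self.params["log_alpha"].data))
        xi = self.xi_matrix
        return edge_rates(psi, xi, clamp=self.config.exponent_clamp)

    @property
    def xi_matrix(self) -> np.ndarray:
        V = self.config.V
        xi = np.zeros((V, V))
        xi[self._iu, self._ju] = self.params["xi"].data
        xi[self._ju, self._iu] = self.params["xi"].data
        return xi

    @property
    def decoder_params(self) -> DecoderParams:
        return DecoderParams(
            xi=self.xi_matrix,
            log_alpha=self.params["log_alpha"].data.copy(),
            mapper_weights={k: v.data.copy() for k, v in self.params.items()
                            if k.startswith("map_")},
        )

    @property
    def regression_params(self) -> RegressionParams:
        return RegressionParams(
            beta=self.params["reg_beta"].data.copy(),
            intercept=float(self.params["reg_b"].data),
            noise_var=float(np.exp(self.params["reg_logvar"].data)),
        )

    # -- persistence ---------------------------------------------------------

    def save(self, path) -> None:
        """Single-archive checkpoint with the config embedded."""
        arrays = {f"param_{k}": v.data for k, v in self.params.items()}
        arrays["c_shift"] = self.c_shift
        if self.template is not None:
            arrays["template"] = self.template
        cfg = json.dumps(asdict(self.config))
        np.savez(path, __config__=np.frombuffer(cfg.encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "InvVAE":
        with np.load(path) as z:
            cfg_dict = json.loads(bytes(z["__config__"]).decode())
            cfg_dict["encoder_hidden"] = tuple(cfg_dict["encoder_hidden"])
            cfg_dict["mapper_hidden"] = tuple(cfg_dict["mapper_hidden"])
            config = ModelConfig(**cfg_dict)
            params = {k[len("param_"):]: Tensor(z[k], requires_grad=True)
                      for k in z.files if k.startswith("param_")}
            template = z["template"] if "template" in z.files else None
            return cls(config, params, z["c_shift"], template)
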