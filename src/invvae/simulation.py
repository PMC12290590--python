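"""Synthetic study generator: community graphs, nuisance mixture, propagation.

The validation study that this module reproduces works on random two-community
graphs (stochastic block model, within-community edge probability 0.25,
between 0.01, 68 nodes).  Each subject's clean binary graph ``A`` is corrupted
by a per-subject positive scalar ``s`` drawn from a two-component Gaussian
mixture — 20% of subjects from N(0.6, 0.05) (large artifact, edge shrinkage)
and the rest from N(1, 0.01) (small artifact) — propagated through the graph
as the matrix product

    A_tilde = (s A)^T (s A) = s^2 A^T A.

The second mixture parameter is read as a standard deviation by default
(``spread_is="sd"``); variance mode is available.  A trait simulator draws
scores linearly from latent embeddings for parameter-recovery experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .connectome_io import ConnectomeCohort

__all__ = [
    "SimulationConfig",
    "SyntheticCohort",
    "simulate_community_graphs",
    "simulate_nuisance",
    "propagate_nuisance",
    "simulate_cohort",
    "simulate_traits",
]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort generator (defaults = study values)."""

    n: int = 1000
    V: int = 68
    n_communities: int = 2
    p_in: float = 0.25
    p_out: float = 0.01
    large_fraction: float = 0.20
    comp_large: tuple[float, float] = (0.6, 0.05)
    comp_small: tuple[float, float] = (1.0, 0.01)
    spread_is: str = "sd"  # "sd" | "variance"
    seed: int = 0
    round_counts: bool = True
    zero_diagonal: bool = True
    elementwise: bool = False  # A_tilde = s^2 A instead of s^2 A^T A
    nuisance_floor: float = 1e-3

    def __post_init__(self):
        if not (0.0 <= self.p_in <= 1.0 and 0.0 <= self.p_out <= 1.0):
            raise ValueError("edge probabilities must lie in [0, 1]")
        if not (0.0 <= self.large_fraction <= 1.0):
            raise ValueError("large_fraction must lie in [0, 1]")
        if self.V < 2 or self.n < 1 or self.n_communities < 1:
            raise ValueError("need V >= 2, n >= 1, n_communities >= 1")
        if self.comp_large[1] <= 0 or self.comp_small[1] <= 0:
            raise ValueError("mixture spreads must be positive")
        if self.spread_is not in ("sd", "variance"):
            raise ValueError("spread_is must be 'sd' or 'variance'")

    def community_sizes(self) -> list[int]:
        """Equal split; an odd remainder goes to the first communities."""
        base = self.V // self.n_communities
        rem = self.V % self.n_communities
        return [base + (1 if k < rem else 0) for k in range(self.n_communities)]


@dataclass
class SyntheticCohort:
    """Clean graphs, nuisance values and corrupted counts, with bookkeeping."""

    clean: np.ndarray            # (n, V, V) binary
    nuisance_values: np.ndarray  # (n,) the s_i
    corrupted: np.ndarray        # (n, V, V) counts
    community_labels: np.ndarray  # (V,) ints
    large_mask: np.ndarray       # (n,) True for subjects from the large-artifact component
    config: SimulationConfig = field(default=None, repr=False)

    def to_cohort(self, trait: np.ndarray | None = None) -> ConnectomeCohort:
        """Package corrupted networks + s as a standard cohort."""
        n = self.corrupted.shape[0]
        return ConnectomeCohort(
            adjacency=self.corrupted,
            nuisance=self.nuisance_values.reshape(n, 1),
            trait=np.full(n, np.nan) if trait is None else np.asarray(trait, dtype=float),
            nuisance_units="a.u.",
        )


def simulate_community_graphs(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """Sample n independent stochastic-block-model graphs.

    Each unordered node pair is an edge with probability ``p_in`` within a
    community and ``p_out`` across; graphs are resampled independently per
    subject.  Returns the (n, V, V) binary stack and the length-V community
    labels (shared across subjects; node order is fixed).
    """
    rng = np.random.default_rng(config.seed)
    sizes = config.community_sizes()
    labels = np.repeat(np.arange(config.n_communities), sizes)
    p = np.full((config.n_communities, config.n_communities), config.p_out)
    np.fill_diagonal(p, config.p_in)
    A = np.zeros((config.n, config.V, config.V))
    nodes = list(range(config.V))
    for i in range(config.n):
        g = nx.stochastic_block_model(sizes, p, seed=rng)
        A[i] = nx.to_numpy_array(g, nodelist=nodes)
    return A, labels


def simulate_nuisance(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """Draw the per-subject nuisance scalars s_i from the two-part mixture.

    Exactly ``round(large_fraction * n)`` subjects (chosen at random) receive
    large-artifact draws; the split is deterministic in count.  Values are
    floored at ``nuisance_floor`` to stay positive.  Returns (s, large_mask).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n = config.n
    n_large = int(round(config.large_fraction * n))
    idx = rng.permutation(n)
    large_mask = np.zeros(n, dtype=bool)
    large_mask[idx[:n_large]] = True

    def scale(spread: float) -> float:
        return spread if config.spread_is == "sd" else float(np.sqrt(spread))

    s = np.empty(n)
    s[large_mask] = rng.normal(config.comp_large[0], scale(config.comp_large[1]), n_large)
    s[~large_mask] = rng.normal(config.comp_small[0], scale(config.comp_small[1]), n - n_large)
    return np.maximum(s, config.nuisance_floor), large_mask


def propagate_nuisance(
    A: np.ndarray,
    s: float,
    round_counts: bool = True,
    zero_diagonal: bool = True,
    elementwise: bool = False,
) -> np.ndarray:
    """Corrupt one clean graph: A_tilde = (sA)^T (sA) = s^2 A^T A.

    The matrix-product form turns a binary graph into weighted counts (the
    off-diagonal entries of A^T A count common neighbours) scaled by s^2, so
    a small s shrinks all edge values.  ``elementwise=True`` applies the
    scaling directly, A_tilde = s^2 A.  The diagonal is zeroed by default to
    preserve the no-self-connection invariant, and entries are rounded to the
    nearest integer so the result is a valid count matrix.
    """
    A = np.asarray(A, dtype=float)
    if s <= 0:
        raise ValueError("nuisance scalar s must be positive")
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("A must be a square matrix")
    if np.max(np.abs(A - A.T)) > 1e-8:
        raise ValueError("A must be symmetric")
    out = (s * s) * A if elementwise else (s * A).T @ (s * A)
    if zero_diagonal:
        out = out.copy()
        np.fill_diagonal(out, 0.0)
    if round_counts:
        out = np.rint(out)
    return out


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Compose graph, nuisance and propagation generators into a cohort."""
    clean, labels = simulate_community_graphs(config)
    s, large_mask = simulate_nuisance(config)
    corrupted = np.stack([
        propagate_nuisance(
            clean[i], s[i],
            round_counts=config.round_counts,
            zero_diagonal=config.zero_diagonal,
            elementwise=config.elementwise,
        )
        for i in range(config.n)
    ])
    return SyntheticCohort(
        clean=clean,
        nuisance_values=s,
        corrupted=corrupted,
        community_labels=labels,
        large_mask=large_mask,
        config=config,
    )


def simulate_traits(
    latents: np.ndarray,
    beta: np.ndarray,
    intercept: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Draw traits y_i = z_i . beta + b + N(0, noise_sd^2) from embeddings."""
    latents = np.atleast_2d(np.asarray(latents, dtype=float))
    beta = np.asarray(beta, dtype=float).reshape(-1)
    if latents.shape[1] != beta.shape[0]:
        raise ValueError("latents and beta dimensions disagree")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    y = latents @ beta + intercept
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, latents.shape[0])
    return y
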