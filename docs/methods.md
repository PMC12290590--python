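# Methods

## Model

Each subject's connectome is a symmetric, zero-diagonal matrix of
nonnegative integer edge counts on a fixed, pre-aligned parcellation (nodes
correspond across subjects). Edges are modeled as conditionally independent
Poisson variables over unordered pairs u < v; the diagonal is excluded
(no self-connections) and each pair is counted once. The Poisson rate is

    λ_uv = exp(ξ_uv + Σ_r α_r X_ur(z̃) X_vr(z̃)),

a latent-space network model: ξ_uv is a population baseline shared across
subjects, and the V node positions X(z̃) ∈ R^{V×R} are produced from the
subject's concatenated latent z̃ = z ⊕ c by a learned smooth map. Large
positive inner products between two nodes' positions mean strong expected
connectivity. Because the nuisance c enters the decoder directly, variation
attributable to c can be explained without being stored in z.

The trait head is a univariate Gaussian regression y ~ N(zᵀβ + b, σ²) on
the connectome latent only — the nuisance is deliberately excluded from
trait prediction.

## Objective

The maximized quantity per subject is

    (1+λ)·E_q[log p(A|z,c)] + log p(y|z) − KL[q(z|A) ‖ N(0,I)] − λ·MI_penalty.

The mutual information I(z, c) is intractable; it is bounded above by
E_A[KL[q(z|A) ‖ q(z)]] minus a reconstruction term. The reconstruction part
is absorbed into the (1+λ) coefficient on the likelihood term. The KL to the
aggregate posterior q(z) is itself intractable, and is approximated within
each minibatch by the average pairwise KL between subjects' diagonal-Gaussian
posteriors,

    MI_penalty = (1/m²) Σ_{i,j} KL[q(z|A_i) ‖ q(z|A_j)],

which upper-bounds the batch KL-to-marginal by convexity of KL in its second
argument, is closed-form, and is differentiable. This is one defensible
surrogate among several in the bound family; it requires batches of at least
two subjects when λ > 0.

One sign choice deserves note: the trait log-likelihood is *rewarded* (enters
with +1), as follows from the evidence-lower-bound derivation; readings that
bracket it with the penalized terms contradict the bound and were not used.

With λ = 0 and C = 0 the objective reduces exactly — same code path — to the
non-invariant graph autoencoder (GATE) objective: reconstruction + trait
log-likelihood − prior KL. The test suite checks this equivalence against an
independently coded implementation at 1e−10.

## Architectures and numerical choices

* **Encoder**: MLP on the log1p-transformed upper-triangle count vector
  (length V(V−1)/2), two tanh hidden layers (default 256, 128), linear mean
  head and softplus scale head. Chosen for determinism and simplicity; node
  order is fixed, so no permutation equivariance is attempted.
* **Position map**: MLP (default one hidden tanh layer of 128) from z̃ to
  V·R values reshaped to V×R. An optional variant (`mapper_type="gcn_smooth"`)
  applies one symmetric-normalized graph-convolution smoothing step
  X ← D^{−1/2}(T+I)D^{−1/2} X against a template adjacency T (binarized
  population mean of the training networks), which couples node positions
  through the population graph.
* **Constraints**: α_r = exp(free parameter) > 0; the posterior scale is a
  softplus output. α and the scale of X are jointly unidentifiable — only
  their product matters for λ — which is acceptable because all downstream
  quantities depend on λ only.
* **Initialization**: Glorot-uniform weights; ξ_uv warm-started at
  log(mean training count + 1e−3), which stabilizes early training by making
  the initial rates match the data marginally.
* **Overflow**: the exponent ξ + ψ is clamped at ±30 before exponentiation
  (gradient passes only where unclamped).
* **Nuisance preprocessing**: c is shifted so the training minimum is 0
  (0 = least motion observed); the scale is untouched. Adjusted-network
  generation decodes at c = 0 by default; for the synthetic study the
  "no-artifact" reference is s = 1 passed through the same shift.
* **Training**: single reparameterized draw per subject per step
  (configurable), Adam at 1e−3, gradient-norm clipping at 10, seeded
  shuffling; counts are rounded to integers (strict mode errors instead).
  A non-finite objective aborts with the offending term named. Identical
  seeds give bit-identical fits. Gradients come from the package's compact
  reverse-mode engine (`invvae.autodiff`) and are verified against central
  finite differences (relative error < 1e−4 asserted; ~1e−6 typical).
* **Percentile groups**: nearest-rank convention — the bottom `low`% of
  subjects by value form the small group (size ⌈low/100·n⌉), the top
  `(100−high)`% the large group; ties broken by subject order. The
  convention is a documented choice; degenerate all-equal inputs are an
  error.
* **PCA**: column-centered SVD with the sign of each component fixed by
  making its largest-magnitude loading positive, so scores are reproducible.

## Synthetic study

The generator emulates a two-community world: per-subject Bernoulli graphs
(stochastic block model, V = 68, equal communities, p_in = 0.25,
p_out = 0.01, resampled independently per subject), a positive nuisance
scalar s with exactly 20% of subjects drawn from N(0.6, 0.05) and the rest
from N(1, 0.01), and corruption by the matrix product Ã = (sA)ᵀ(sA). Choices
the generator fixes:

* The mixture's second parameter is read as a **standard deviation** by
  default (clean separation between the artifact groups); a variance mode
  exists. The source description is ambiguous on this point.
* The propagation is the **literal matrix product** — the off-diagonal of
  AᵀA counts common neighbours, so the corrupted "counts" are a
  neighbourhood-overlap matrix scaled by s², not a rescaling of A. An
  elementwise mode (Ã = s²A) is provided as an option. The diagonal is
  zeroed (no self-connections) and entries are rounded to integers so the
  Poisson likelihood applies.
* The large-artifact subset has an exact deterministic size round(0.2·n)
  rather than per-subject Bernoulli membership.
* Graphs are resampled per subject (not one fixed graph perturbed), and an
  odd V puts the extra node in the first community.

What the generator does **not** emulate: realistic fiber-count magnitudes or
their heavy-tailed distributions, spatial autocorrelation of edges, any
relationship between motion and traits, or longitudinal motion structure.
Passing the synthetic suite therefore demonstrates that the machinery
removes a known multiplicative nuisance at these noise levels, not that it
removes real scanner artifacts from real cohorts.

The trait simulator draws y = Zβ + b + ε from given embeddings, enabling
parameter-recovery experiments where the ground-truth coefficients are
known.

## Evaluation protocols

* **Adjusted networks**: decode each subject's posterior *mean* (not a
  sample) at the reference nuisance; deterministic at test time. Optional
  Poisson sampling on top.
* **Trait cross-validation**: traits are residualized on the nuisance by OLS
  before evaluation (raw mode behind a flag); subjects are shuffled once by
  seed into disjoint folds (no stratification); per fold the full objective
  is retrained and held-out traits are predicted from posterior means
  through the regression head; Pearson r per fold. After fold training the
  Gaussian head (β, b, σ²) is re-estimated in closed form — its exact
  maximum-likelihood solution given the training-fold posterior means —
  because stochastic joint updates leave residual error in the linear head
  long after the embedding has stabilized; only training-fold information is
  used.
* **Invariance report**: cross-validated R² of a linear probe predicting
  each nuisance column from posterior means, plus the distance between
  extreme-group centroids in the first-2-PC plane scaled by pooled
  within-group spread (rotation invariant).

## Problem sizes

The shipped studies run at reduced scale so the whole suite completes in a
few minutes on one CPU: the invariance study uses n = 300 subjects of V = 30
nodes with K = 8, R = 3 and 200 epochs; trait recovery uses n = 250, V = 20,
K = 16 and 300 epochs per fold; generator-fidelity checks use 200 graphs at
the full V = 68. The model defaults (K = 68, V = 68, wider MLPs) target
full-size cohorts.

## Known limitations

* The encoder is a plain MLP on the flattened upper triangle; it does not
  exploit graph structure beyond the optional template-smoothing step in the
  decoder.
* The minibatch pairwise-KL surrogate upper-bounds the aggregate-posterior
  KL but its tightness depends on batch size; very small batches make the
  penalty noisy.
* Only scalar-or-vector per-subject nuisances are supported; a single
  summary of motion ignores its temporal structure.
* The trait head is a single univariate Gaussian; multi-trait or
  non-Gaussian outcomes are out of scope.
* Invariance is penalized, not enforced: residual nuisance information in
  the embedding (nonzero probe R²) remains, shrinking with λ at some cost in
  reconstruction.
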