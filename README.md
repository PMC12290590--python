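# invvae — motion-invariant variational autoencoding of structural connectomes

Brain structural connectomes — symmetric matrices of streamline (fiber)
counts between parcellated brain regions, reconstructed from diffusion MRI —
are systematically distorted by in-scanner head motion: subjects who move
more show depressed fiber counts across most region pairs, even after
image-level motion correction. When connectome representations are then used
to predict cognition-related traits, this nuisance signal contaminates both
the embedding and the downstream inference.

`invvae` learns low-dimensional connectome representations that are
*statistically decoupled* from a per-subject nuisance covariate such as RMS
head motion. It is a graph variational autoencoder over a Poisson
latent-space network model, trained with a mutual-information penalty in the
spirit of the information bottleneck. The package is aimed at researchers
working with cohorts of weighted undirected networks (one per subject) plus
per-subject covariates and trait scores.

## Model

For subject *i* with adjacency matrix `A_i` (V×V counts), nuisance `c_i ∈ R^C`
and trait `y_i`:

    z_i ~ N(0, I_K)                          latent connectome representation
    z~_i = z_i ⊕ c_i                         concatenation
    X(z~_i) ∈ R^{V×R}                        node positions in a network latent space
    ψ_uv = Σ_r α_r X_ur X_vr                 weighted inner product, α_r > 0
    λ_uv = exp(ξ_uv + ψ_uv)                  ξ = population baseline connectivity
    A_i[uv] | z_i, c_i ~ Poisson(λ_uv)       for unordered pairs u < v
    y_i | z_i ~ N(z_iᵀβ + b, σ²)             Gaussian trait regression

Training maximizes a penalized evidence lower bound

    (1+λ)·E_q[log p(A|z,c)] + log p(y|z) − KL[q(z|A) ‖ N(0,I)] − λ·MI(z,c)

where the mutual information between representation and nuisance is
controlled through a minibatch surrogate: the average pairwise KL divergence
between subjects' posteriors, an upper bound on the KL to the aggregate
posterior. Setting λ = 0 and C = 0 recovers the non-invariant GATE baseline
(same generative model, no nuisance channel, no penalty).

Because the decoder receives the nuisance explicitly, a fitted model can
generate *nuisance-adjusted* networks: decode each subject's posterior mean
with the nuisance input pinned to a reference value (c = 0, i.e. the least
motion observed in training).

## Worked example

The package ships the synthetic validation study: two-community random
graphs (within-community edge probability 0.25, between 0.01) corrupted by a
per-subject scalar `s` drawn from a mixture — 20% of subjects from
N(0.6, 0.05) (large artifact) and the rest from N(1, 0.01) — propagated as
`Ã = (sA)ᵀ(sA)`.

```python
import numpy as np
from invvae import *
from invvae.analysis import *

syn = simulate_cohort(SimulationConfig(n=200, V=20, seed=7))
cohort = syn.to_cohort()
arch = dict(V=20, K=8, R=3, encoder_hidden=(64, 32), mapper_hidden=(32,), seed=0)

inv, hist = train(cohort, ModelConfig(C=1, **arch),
                  TrainingConfig(lambda_mi=1.0, batch_size=64, epochs=150, seed=1))
gate, _ = train(cohort, ModelConfig(C=0, **arch),
                TrainingConfig(lambda_mi=0.0, batch_size=64, epochs=150, seed=1))

s = syn.nuisance_values.reshape(-1, 1)
r2_inv = invariance_report(inv.posterior(cohort.adjacency).mean, s, seed=0)
r2_gate = invariance_report(gate.posterior(cohort.adjacency).mean, s, seed=0)

corrected = generate_adjusted(cohort, inv, reference_c=1.0 - inv.c_shift[0])
recon = generate_adjusted(cohort, gate)
```

Output (a minute or so on one CPU):

```
R^2(s | z)  inv-VAE: 0.134   GATE: 0.421
mean |large - small| edge difference
  observed (corrupted): 0.224
  inv-VAE corrected at s=1: 0.047
  GATE reconstruction: 0.069
```

Reading: a linear probe recovers far less of the nuisance `s` from the
invariant embedding than from the GATE embedding, and the systematic
large-vs-small-artifact edge difference visible in the corrupted data is
largely removed in the corrected networks, while the non-invariant baseline
reconstructs it.

The same workflows are available from the shell:

```sh
invvae simulate --n 200 --v 20 --seed 7 --out data/
invvae train    --data data/ --lambda 1.0 --seed 1 --out ckpt/
invvae adjust   --ckpt ckpt/checkpoint.npz --data data/ --reference 0 --out adjusted/
invvae groups   --data data/ --low 5 --high 95 --out groups.csv
invvae evaluate --data data/ --folds 5 --seed 1 --report report.csv
```

Every command writes a `manifest.json` with the effective configuration,
seed and input digests.

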