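# coralfish

Tools for asking two linked questions about reef-fish assemblages on
low-coral ("marginal") reefs: **which fish species depend on corals**, and
**how much functional diversity the assemblage would lose if those species
vanished with the corals**.

The package is aimed at community ecologists working with
detection/non-detection data from replicated surveys (e.g. stationary video
plots) plus benthic photoquadrat cover and species trait tables.  It
implements the full chain — hierarchical multi-species site-occupancy
modelling with imperfect detection, credible-interval identification of
coral-associated fish, and convex-hull trait-space loss scenarios — along
with a synthetic-data generator with known ground truth, so every stage can
be exercised and validated without field data.

## The model

True presence of fish species *k* at site *i* is separated from imperfect
observation across the J_i video-plot occasions at that site:

    z_ik ~ Bernoulli(ψ_ik)          logit(ψ_ik) = α_k + β₁ₖ·coral_i + β₂ₖ·turf_i
    y_ijk ~ Bernoulli(z_ik · p_ijk)  logit(p_ijk) = a_k + δ·deep_i + u_ij

Covers are standardized, so β₁ₖ and β₂ₖ are standardized effect sizes of
coral and turf cover on occupancy.  Species coefficients are partially
pooled through community hyperdistributions (α_k ~ N(μ_α, σ_α²), etc.);
u_ij is a per-plot random effect and δ a depth-category effect on
detection.  The latent z is marginalized out of the likelihood and the
posterior is sampled by an adaptive Metropolis-within-Gibbs scheme (3
chains × 1000 saved draws by default), with split-chain R̂ and a
Freeman–Tukey posterior-predictive Bayesian p-value (BPV ≈ 0.5 = good fit)
as diagnostics.

A species is **coral-associated** when the 90% credible interval of β₁ₖ
lies above zero and its turf effect is non-positive.  Species are embedded
in a functional trait space (Gower distances over mixed trait types →
PCoA with Cailliez correction), and the reduction in functional space from
removing a species set R is

    RFS = (1 − FS_reduced / FS_complete) × 100   [%]

where FS is the area of the 2-D convex hull of the remaining species.
Deterministic removals (all coral-associated fish; per-coral sets) are
compared against uniform random removals and a vertex-weighted
randomization that preferentially removes the most functionally distinct
(hull-vertex) species.

## Worked example

```python
import numpy as np
from coralfish.synthetic import (CommunityHyperparams, simulate_covariates,
                                 simulate_species_params, simulate_detection_history)
from coralfish.data_io import filter_species
from coralfish.occupancy import ModelConfig, fit
from coralfish.association import classify_fit

hyper = CommunityHyperparams()          # community-level truth
cov = simulate_covariates(50, seed=1, coral_taxa=("coralA",))
sp = simulate_species_params(12, hyper, seed=2)
dh, truth = simulate_detection_history(sp, cov, np.full(50, 4), hyper, seed=3)
dh, report = filter_species(dh)

ps, diag = fit(dh, cov, ModelConfig(n_chains=3, n_saved_per_chain=500,
                                    warmup=1000, seed=4))
print(f"max Rhat {diag.max_rhat:.3f}  BPV {diag.bpv:.2f}")
cls = classify_fit(ps, ci_level=0.90)
print(cls["response_coral"].value_counts().to_dict())
print("coral-associated:", sorted(cls.loc[cls.coral_associated, "species_id"]))
```

Output:

```
max Rhat 1.048  BPV 0.58
{'positive': 6, 'neutral': 5, 'negative': 1}
coral-associated: ['sp0002', 'sp0006', 'sp0010']
```

An R̂ below 1.1 indicates the three chains agree; a BPV near 0.5 means the
model reproduces the detection-frequency structure of its input.  Six of
the twelve simulated species respond credibly positively to coral cover at
the 90% level; three of them also have a non-positive turf response and
would be removed in the coral-loss scenarios.

The same analysis runs end-to-end from the shell:

```bash
coralfish run-all --outdir runs/demo --seed 1     # simulate … report
coralfish summary --outdir runs/demo
```

which writes per-stage artifacts (filtered detections, site covariates,
per-species classifications, trait-space coordinates, scenario RFS tables,
a JSON report) under `runs/demo/`, all reproducible byte-for-byte from the
configuration and seed.

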