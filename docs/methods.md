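# Methods

`coralfish` implements a complete inference chain for asking how much a
reef-fish assemblage depends on corals, and what its functional diversity
would lose if the coral-dependent fish disappeared.  It has three parts: a
hierarchical multi-species site-occupancy model fitted by MCMC, a
credible-interval rule that flags coral-associated species, and a
convex-hull trait-space analysis that contrasts the removal of those
species with random removals.  A synthetic-data generator with known ground
truth makes every stage testable without field data.

## The occupancy model

Detection/non-detection data come from replicated surveys: at site *i*,
each 10-minute video plot *j* is one sampling occasion (a time-for-space
substitution — spatial replicates stand in for repeat visits).  For fish
species *k*:

    z_ik ~ Bernoulli(psi_ik)                       (true presence)
    logit(psi_ik) = alpha_k + beta1_k x1_i + beta2_k x2_i
    y_ijk | z_ik ~ Bernoulli(z_ik * p_ijk)         (observation)
    logit(p_ijk) = a_k + delta * deep_i + u_ij

where `x1` is the site cover of one coral taxon and `x2` turf-algae cover,
both standardized to mean 0, SD 1 across sites (slopes are therefore
standardized effect sizes; because coral cover has a very small SD on
marginal reefs, per-unit coral effects are much steeper than turf effects).
`deep_i` indicates the 8–15 m depth category and `u_ij ~ N(0, sd_plot^2)`
is a per-video-plot random effect.  One model is fitted per (coral taxon,
life stage); with eight qualifying corals and two stages that is 16 runs.

Species coefficients are partially pooled: `alpha_k ~ N(mu_alpha,
sd_alpha^2)` and likewise for both slopes and the detection intercepts.
Pooling lets well-detected species stabilize estimates for sparsely
detected ones.  A `pooling="fixed"` mode replaces the estimated
hyperdistributions with fixed weakly-informative `N(0, 1.5^2)` priors per
species; it is used where unshrunken per-species estimates are wanted
(e.g. when checking the frequentist calibration of the classification rule,
where hierarchical shrinkage intentionally deflates the false-positive rate
below its nominal level — a property, not a bug, of the pooled model).

The latent `z` is marginalized out: a site's likelihood contribution is
`psi * prod_j p^y (1-p)^(1-y)` when the species was seen there and
`psi * prod_j (1-p) + (1-psi)` otherwise.  These 2^J history probabilities
sum to one, which the tests verify exhaustively for J <= 4.

### Priors

Supplementary detail of the original detection model was not available, so
priors are explicit package defaults, configurable in `PriorConfig`:
hyper-means `N(0, 1.5^2)` on the logit scale (weakly informative —
roughly uniform on the probability scale), hyper-SDs half-Normal(1), depth
effect `N(0, 1.5^2)`, plot effects `N(0, sd_plot^2)` with
`sd_plot ~ half-Normal(1)`.

### Sampling

The sampler is an adaptive Metropolis-within-Gibbs scheme written in numpy
against the marginalized likelihood:

- component-wise Gaussian random-walk updates for `alpha_k`, `beta1_k`,
  `beta2_k` and `a_k`, proposed and accepted independently across species
  (the likelihood factorizes over species given the hyperparameters), with
  per-species proposal scales;
- a scalar random-walk update for the depth effect `delta`;
- per-site block updates for the plot effects `u_ij` (occasions within a
  site are coupled through the all-zero marginal term);
- conjugate Gibbs draws for hyper-means; log-scale random walks for
  hyper-SDs;
- interweaving rescale moves — joint multiplicative proposals on
  `(theta_k - mu, sd)` for each pooled family and on `(u, sd_plot)` — which
  break the funnel coupling between scale parameters and their effects.
  Without these, `sd_plot` and (near `sd -> 0`) the slope hyper-SDs mix an
  order of magnitude more slowly.

Proposal scales adapt by Robbins–Monro toward 44% acceptance
(componentwise; 30% for blocks) during warmup only, so the retained chains
are valid MCMC.  Defaults mirror the original sampling design: 3 chains x
1000 saved draws = 3000 posterior samples, with 2000 warmup iterations per
chain.  All randomness flows from a single integer seed through
`numpy.random.SeedSequence`; identical settings reproduce draws exactly.

### Diagnostics

Convergence is summarized by the classic split-chain Gelman–Rubin
statistic per parameter (threshold 1.1; exceeding it warns but still
returns results).  Goodness of fit uses a posterior-predictive Bayesian
p-value: the latent `z` is drawn from its conditional posterior, expected
per-site detection counts `E_ik = z_ik * sum_j p_ijk` are compared with
observed and replicated counts through the Freeman–Tukey discrepancy
`sum (sqrt(n) - sqrt(E))^2` (a chi-square variant is available; the source
analysis does not name its statistic, so the choice is a package default).
BPV near 0.5 indicates the model generates data like those observed.

## Classification of responses

For each fitted model, a species' response to a covariate is `positive`
when the lower bound of the equal-tailed credible interval of its slope
exceeds 0, `negative` when the upper bound is below 0, `neutral`
otherwise.  The default level is 0.90 (the level shown in the source
coefficient plots; configurable).  A species is **coral-associated** when
its coral slope is credibly positive and its turf effect non-positive; the
turf condition is read as posterior mean <= 0 by default (an upper-CI-bound
reading is selectable).  The total coral-associated set per life stage is
the union over the per-coral models, deduplicated by species.

## Functional trait space

Six traits enter the space: total length (cm), trophic level, aspect
ratio, group size (ordered categorical, schooling above solitary), maximum
preferred temperature (degC) and maximum depth (m).  A 4-trait variant
(group size, maximum body size, trophic level, aspect ratio) is selectable
via `trait_set="four"`; the source figures are ambiguous about which set
produced the printed values, so both are exposed and neither is privileged.

Pairwise dissimilarity is Gower's coefficient: quantitative traits
contribute range-normalized absolute differences; the ordered trait is
converted to tie-averaged ranks first.  PCoA embeds the matrix in 2 axes
(configurable); because Gower distances are generally non-Euclidean, the
Cailliez correction is applied by default (Lingoes and drop-negative are
alternatives).  Zero-eigenvalue axes are legitimate (exact embeddings of
lower-dimensional configurations); axes that would require negative
eigenvalues are refused.

Functional richness of a species set is the area of the 2-D convex hull of
its coordinates (degenerate sets — fewer than three points, or collinear —
have area 0 and are flagged).  One complete space is built from all
species; stage-specific removal sets are applied to that common space.
The reduction in functional space after removing set R is
`RFS = (1 - FS_reduced / FS_complete) * 100`, in percent.

## Loss scenarios

Deterministic scenarios remove (i) all coral-associated fish of a stage
("total loss") and (ii) each coral's associated fish separately.  Because
per-coral sets are subsets of the union, per-coral RFS never exceeds the
total-loss RFS.  Random baselines remove the same number of species with
uniform probability (100 runs by default), and a vertex-weighted variant
gives species on the current convex hull a higher removal probability
(default weight 10 : 1 against interior species), removing sequentially and
refreshing hull membership after every removal.  The weighting magnitude
and refresh policy are package choices — the source describes the rule
only qualitatively — and both are configurable; weight 1 reduces exactly to
uniform sampling.  Comparison tables report whether each deterministic RFS
falls inside the corresponding random distribution's range and its
empirical quantile.

## The synthetic generator

`coralfish.synthetic` draws data from exactly the model above, so recovery
tests are well-posed.  Defaults emulate the Southwestern Atlantic field
design: 36 sites; 1–12 occasions per site (rounded normal, mean 4.84, SD
2.56, clipped); coral cover zero-inflated Beta (zero probability 0.25,
positive part 22 * Beta(1.3, 4.0625), giving mean exactly 4% with maxima
near 20%); turf cover 15 + 66 * Beta(3.5, 2) (mean 57%, range 15–81%);
depth category Bernoulli(0.5); 113 species (47 with a juvenile stage)
whose intercepts and slopes are community draws, with detection declining
in log body length and higher on deep reefs.  The generator returns the
full latent truth (psi, z, p, plot effects) alongside the data.

What the generator does **not** emulate: spatial autocorrelation among
sites, temporal dynamics (single-season by construction), abundance (the
model is presence-based), trait–occupancy correlations beyond body size,
and taxonomic detection biases.  Passing recovery tests therefore
demonstrate correctness of the inference machinery under the model's own
assumptions, not robustness to real-data violations of them.

## Numerical and design choices

- Covariates are standardized per fitted dataset with the n-1 sample SD;
  zero-variance covariates are rejected by name.
- Cover aggregation is pinned as nested means: point fraction per subunit
  (50 points each), mean over a quadrat's five subunits, mean over a
  site's quadrats — the source states only "site-level averages".
- A "site" is the unique (locality, place, depth category) combination;
  site identifiers are assumed to encode it.
- The published life-stage rules leave species with maximum total length
  in [5, 8) cm undefined; the package applies the 8–16 cm rule there by
  default, always emits a warning, and the policy is configurable
  (including hard failure).
- Ragged occasion designs are encoded by row absence in the tidy CSVs,
  never by sentinel zeros; internal tensors carry NaN padding.
- Classification requires at least 100 posterior draws; equal-tailed
  quantile intervals are used throughout.
- Scenario RNG streams are separated from model-fit seeds, and all stage
  seeds derive deterministically from one base seed.

## Problem sizes used in the checks

The test suite and the acceptance script exercise the chain at reduced but
statistically adequate sizes, chosen as package defaults for desk-scale
verification: parameter recovery and null calibration use 200 sites x 40
species x 5 occasions with 3 chains (the full 3000-draw budget for the
recovery check); the end-to-end synthetic pipeline run uses 36 sites and a
reduced species pool and chain length.  Hull-area oracles use 50-point
clouds against rejection sampling (2 x 10^5 points); random-loss
expectations are verified exhaustively on 6-species spaces.

## Known limitations

- The random-walk sampler, while adequate at the tested sizes, mixes more
  slowly than gradient-based samplers would at much larger K or with
  strongly separated detection/occupancy scales.
- BPV uses detection frequencies only; structural misfit orthogonal to
  that statistic (e.g. covariate nonlinearity) can go undetected.
- Hull-based richness ignores density within the hull; with 2 axes the
  trait space is a planar caricature of six traits (the PCoA eigenvalue
  spectrum quantifies what the two axes retain).
- No multiplicity correction is applied across the eight per-coral models,
  matching the source analysis.
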