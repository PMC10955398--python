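# Methods

`geophylocausal` implements a diachronic causal analysis of
environment→trait effects on a geo-annotated, time-calibrated phylogeny.
The motivating application is the question of whether ambient humidity
influences the number of lexical tones in a language family, but every
stage is generic: any continuous trait evolving on a tree whose nodes
carry ages and locations, paired with any gridded space–time environment
field, fits the same contracts.

## The scientific problem

Present-day (synchronic) cross-cultural data are generated by a branching
historical process. Two consequences follow:

1. **Genealogical autocorrelation.** Related lineages share most of their
   history, so leaf-level observations are not independent. A naive
   regression of a trait on an environmental variable across extant
   lineages can be "significant" far more often than its nominal type-I
   rate even under a null model with no environmental effect.
2. **Founder amplification.** A single early branch that moves into a
   different environment creates two long-lived clusters. Whether those
   clusters happen to align with trait clusters is essentially one random
   draw, yet it determines the sign and strength of the synchronic
   correlation. The node-importance analysis quantifies this: the
   regression slope is dominated by a handful of early, large-clade
   nodes.

The remedy is to model *changes* along edges rather than states at
leaves: for each ancestor→descendant pair, the trait change is regressed
on the environment experienced along that edge, with explicit controls
for what phylogenetically and geographically close lineages were doing.

## The causal models

The unit of analysis is the edge (ancestor *i* → descendant *i*) with
duration `dA_i` (ky). The core model is

```
T_desc,i − T_anc,i ~ Normal(μ_i, σ_i)
μ_i  = (α + η·H_i + γ·Gt_i + ρ·Pt_i) · dA_i
σ_i  = σ0 + β·dA_i
```

* `H_i` — mean of the humidity at the ancestor and descendant node: the
  change is assumed to happen at unknown times along the edge, averaging
  out across the sample.
* `Gt_i` — mean trait value of lineages alive at the descendant's age
  whose (linearly interpolated) location lies within 500 km: the contact/
  borrowing channel. Lineage values are interpolated along their edge at
  the proportional time point (`v_anc + p·(v_desc − v_anc)`).
* `Pt_i` — mean trait value of all nodes within a cophenetic radius
  (default 0.02 in native units, or a fraction of tree depth), excluding
  the node itself and its own ancestor, *not* filtered for
  contemporaneity: residual heritable effects (lineage-specific rates,
  drift).
* Multiplying the bracket by `dA_i` normalises all effects to per-ky
  rates; the `β` term lets residual variance grow with edge duration
  (unconstrained, so the data decide).

Two latent measurement layers propagate uncertainty:

* interior-node traits: `T_node ~ Normal(T_REC, T_SE)` with `T_REC`/`T_SE`
  the ancestral-reconstruction posterior mean/standard error, one shared
  latent per node across all edges it joins (per-row independent latents
  would be incoherent);
* neighbourhood summaries: `Gt_i ~ Normal(Gt_MEAN,i, Gt_SD,i)` and
  likewise `Pt`, carrying the spread of the neighbourhood rather than
  only its mean.

**Model LIN** uses the linear `γ·Gt + ρ·Pt` terms. **Model GP** replaces
them with latent per-edge effects `g + p` drawn from Gaussian processes
over pairwise distance: a squared-exponential kernel
`amp²·exp(−δ²/2ℓ²)` on great-circle distance (km) and an
Ornstein–Uhlenbeck kernel `amp²·exp(−δ/ℓ)` on cophenetic distance. The
GP effects are indexed by the row's descendant node and enter inside the
`dA`-scaled bracket, mirroring the LIN terms they replace. The GP route
is smoother in how it treats "closeness" but cannot respect
contemporaneity (a kernel needs one value per pair of nodes).

### Priors and scaling

Inputs (`H`, `Gt`, `Pt`) are z-scaled — divided by their sample SD,
**not centred** — so one model unit is one data SD and zero keeps its
meaning; divisors are stored so coefficients can be mapped back to raw
units (`η_raw = η / sd(H)`). Priors: coefficients and `β` ~ Normal(0, 1),
`σ0` ~ Exponential(1) (for ratio-type outcomes with tiny scales the
tighter Normal(0, 0.5) / Exponential(5) settings are provided); GP
amplitude ~ half-Normal(0, 1); GP lengthscale ~ Lognormal centred on the
median observed distance with unit log-sd, so prior mass spans the
observed distance range. `σ_i > 0` is enforced by soft rejection (−∞ log
density) rather than constraining `β`.

### Inference: marginalised likelihood + ensemble MCMC

All latent layers are Gaussian and enter linearly, so they are
marginalised analytically. Writing `y` for the vector of
reconstruction-mean trait changes, `U` for the signed incidence of rows
on latent interior nodes and `S` for their reconstruction variances, the
marginal is

```
y ~ MultiNormal(m(θ), D(θ) + U S Uᵀ [+ diag(dA)·(G+P)·diag(dA)])
```

with `D` collecting per-row variances (`σ_i²` plus, for LIN, the
`γ²dA²Gt_SD²`-type propagated measurement variances). The Woodbury
identity keeps evaluation cheap when only the interior-node low-rank part
is present. The handful of top-level parameters (6 for LIN, up to 8 for
GP) are sampled with an affine-invariant ensemble sampler
(differential-evolution moves, walkers initialised in a small ball around
the posterior mode found by Nelder–Mead). Walkers are treated as chains
for split-R̂ and ESS; a fit with any R̂ ≥ 1.01 is returned flagged as
unconverged, never silently. This is an exact reformulation of the
hierarchical model — not an approximation — and latent draws (interior
`T`, per-row `Gt`/`Pt`, GP effects) are recovered afterwards by exact
Gaussian conditioning on each retained parameter draw.

Pointwise log-likelihoods for PSIS-LOO use each row's marginal normal
density `log N(y_i; m_i, V_ii)`; when the marginal covariance is diagonal
(fully observed traits, LIN variant) these are the exact conditional
densities, which is the regime in which the exact-LOO oracle test runs.
PSIS-LOO results are only trusted when all Pareto-k diagnostics are below
0.7.

### Hypothesis testing and model comparison

Savage–Dickey density ratios give the Bayes factor for a point null at
zero: `BF₁₀ = p_prior(0) / p_posterior(0)` (BF₁₀ < 1 supports the null).
The posterior density at zero is a Gaussian KDE with Silverman bandwidth
when zero lies within 3 posterior SDs of the mean; beyond that a KDE
cannot see the tail (its extreme sample is many bandwidths away), so a
moment-matched normal tail density is used instead — exact for normal
posteriors. Widening the alternative's prior lowers its density at zero
and therefore lowers BF₁₀: the point null gains support (Lindley
behaviour). Model variants are compared by PSIS-LOO expected log
predictive density via arviz.

## Supporting stages

**Ancestral state reconstruction.** Continuous ASR under Brownian motion
by exact Gaussian conditioning: each edge contributes a 2×2 precision
block `1/(rate·B)`, interior nodes are conditioned on the observed leaves
and an optional fossilised root (e.g. the proto-language fixed at 2
tones); the diffusion rate is profiled by ML. This targets the same
distribution as random-walk-MCMC reconstruction but is deterministic,
which the oracle tests exploit. Optional bounds (e.g. 0–12 tones)
truncate each node's conditional distribution; zero-length edges are
given a precision-limit length of 1e−10. Trait-specific soft priors
(gamma for inventory counts, normal for ratios) are available as
truncation settings and default off for synthetic runs.

**Pagel's λ.** ML over the λ-transformed tip covariance (off-diagonal
shared path lengths × λ), root state and rate profiled analytically;
λ = 1 recovers Brownian motion and λ = 0 an iid-normal model (checked in
closed form). The optimiser is bounded scalar minimisation with explicit
boundary evaluation.

**Humidity field.** The gridded (year, lat, lon, humidity) table is
interpolated by tensor-product B-spline regression (knot per unique grid
value, capped so the basis stays comfortably smaller than the training
data; tiny ridge for conditioning), with in-sample and seeded 5-fold
held-out R² reported, and a trilinear baseline for comparison. Node ages
(ky BP from a tree reference year, default 2000 CE) are converted to the
grid's year axis (default calendar CE; a years-before-present grid uses
its own reference year, default 1850 CE). Evaluation outside the
training bounding box is an error.

**Bias diagnostics.** `type1_error_study` simulates trait histories under
the null rule `T_desc = T_anc + ε·B`, `ε ~ Normal(0,1)` — the increment
SD scales linearly with branch length *by design*; standard Brownian
√B-scaling is available as an option — and applies leaf-level OLS of
trait on humidity with a two-sided slope test. `node_importance` adds a
fixed δ (default 1) to the trait of every leaf in a node's subtree and
records the absolute slope change; only leaves enter the regression, so
interior values are never perturbed, and a whole-tree shift provably
leaves the slope unchanged (importance exactly 0 at the root). No
canonical cutoff for "highly important" is asserted; the report exposes
the distribution and a configurable threshold.

**Comparative tests.** The discrete co-evolution test fits 4-rate
(independent) and 8-rate (state-dependent) CTMCs on the joint state space
of two binarised traits by multi-start L-BFGS over log-rates, with the
dependent fit additionally seeded from the independent optimum so the
nesting inequality holds by construction. Likelihoods use Felsenstein
pruning with per-node rescaling; transition matrices come from one
eigendecomposition of the generator batched over edges (expm fallback).
The root uses the fitted generator's stationary distribution unless
fossilised. The continuous test estimates the evolutionary correlation
from phylogenetically independent contrasts (with an optional extra
root-fossil contrast). Both have Bayesian modes whose marginal
likelihoods come from stepping-stone sampling (β ladder from the
Beta(0.3, 1) quantiles, random-walk Metropolis per stone) under
Uniform(0, r_max) rate priors.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes,
at study-scale defaults: a pure-birth (Yule) crown tree conditioned on
the tip count (100–500 tips in study configurations; topology realism
matters less than age structure because the empirical tree is fixed in
the motivating analysis), rescaled to a 5 ky crown age with extant tips;
Brownian dispersal on raw lat/lon degrees (2°/√ky default, clamped at the
poles — no spherical correction, adequate at continental extents); an
optional founder jump of 20–25° applied to one early internal edge whose
subtree is closest to half the tips, reproducing the two-cluster
phenomenon; a humidity surface linear in latitude (0.05 units/degree)
plus small iid noise (0.02), sampled at node locations so humidity
inherits phylogenetic signal λ ≈ 1 from the dispersal process; and trait
histories under the null rule above (root fossil 2, mirroring a two-tone
proto-language) or the causal rule with configurable (α, η, γ, ρ, σ0, β).
The causal generator processes edges root-to-tip in ancestor-age order;
neighbour lineages not yet fully simulated contribute their most recent
simulated value, and empty neighbourhoods contribute zero — choices
needed to make the generative model well-defined where the inferential
model is agnostic.

What the generator does **not** emulate: discrete tonogenesis mechanics,
borrowing from lineages outside the tree, realistic spherical dispersal,
non-ultrametric sampling, or climate dynamics beyond a smooth trend.
Passing tests therefore demonstrate correctness of the machinery and
calibration under the stated generative assumptions, not validity of any
real-data conclusion.

## Numerical choices and problem sizes

* Tolerances: exact-oracle equivalences at 1e−8 (ASR) and 1e−10 (CTMC
  pruning, rank-one OLS identity); transition-matrix rows sum to 1 within
  1e−10; age consistency within 1e−9 ky.
* Sampler defaults: 32 walkers, 6000 steps, 3000 burn-in, thin 6
  (16,000 retained draws); smoke/pipeline runs use shorter chains and are
  flagged if unconverged.
* Monte-Carlo study sizes in the test suite and acceptance script are
  chosen to make each check statistically decisive at its assertion band:
  100-replicate type-I studies on 200-tip trees (1000 replicates on the
  star-tree control), 20-replicate recovery/calibration loops at 150 tips
  (~300 edges), 30–40-replicate CTMC calibrations at 80–100 tips with
  binomial assertion bands, 30-row exact-LOO comparisons.
* Degenerate inputs: zero-length edges are dropped from the pair table
  (logged); empty neighbourhoods are flagged and pinned to zero on the
  scaled scale; constant traits raise explicit errors in λ, correlation
  and discrete-test fitting; a threshold outside the data range in
  `binarize` warns rather than fails.

## Known limitations

* The ensemble sampler's walkers are initialised near the mode; for
  strongly multimodal posteriors (not observed in these models) R̂ across
  walkers could miss modes. R̂/ESS are computed walker-as-chain, which is
  slightly optimistic relative to fully independent chains.
* The uncentred z-scaling (kept for interpretability of the zero point)
  makes the intercept and the humidity coefficient strongly collinear;
  the affine-invariant moves handle this, but chains need to be long.
* Pt/Gt neighbourhood summaries use reconstruction means, so
  neighbourhood uncertainty beyond the Normal(mean, SD) layer is ignored.
* PSIS-LOO pointwise densities are row-marginals; with many shared latent
  interior nodes they understate row dependence, and the exact-LOO oracle
  is only claimed in the diagonal regime.
* The GP variant scales cubically in the number of edges per likelihood
  evaluation; a few hundred edges is comfortable, thousands are not.
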