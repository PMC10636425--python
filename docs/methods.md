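# Methods

## Model

The package fits the closed-population spatial capture–recapture model
M0 with Bayesian data augmentation.

**Data.** A binary tensor y[i, j, k] over n identified individuals, J
camera-trapping sites and K one-day occasions, with at most one
detection per cell, plus a J × K usage mask recording when each site
was operational. Paired cameras at one location are a single site; a
stolen or destroyed camera is usage = 0 from the loss date onward.
Capping detections at one per individual–site–day reduces temporal
autocorrelation and makes every cell a Bernoulli outcome.

**Augmentation.** The unknown population size is embedded in a fixed
super-population of M rows (M must comfortably exceed any plausible N;
the presets use 100, or 300 for the largest survey). Row i is real when
the latent indicator z_i = 1, with z_i ~ Bernoulli(ψ) and ψ ~ U(0, 1),
which induces N = Σ z_i ~ Uniform-Binomial(M) a priori. Detected rows
have z_i ≡ 1.

**Detection.** Each row has a latent activity centre s_i, uniform over
the state space S — the trap bounding box expanded by a buffer b on all
sides. Detection probability at trap j is half-normal,
p_ij = g0 · exp(−d_ij² / (2σ²)), maximal (g0) at the activity centre
and decaying with the centre-to-trap distance d_ij; σ is the
detection-function scale in km. The half-normal is the standard form
associated with a "detection scale" parameter and is what the buffer
heuristic below assumes. Detection is constant across individuals and
occasions (M0): with sexes unknown for most photographed animals,
individual covariates cannot be fitted without overfitting.

**Likelihood.** Because occasions are exchangeable under M0, the
Bernoulli product over occasions collapses per site to
p_ij^c_ij (1 − p_ij)^(e_j − c_ij), with c_ij the individual-by-site
detection count and e_j = Σ_k usage[j, k] the site's trap-nights. This
is an exact rewrite, not an approximation; partial effort enters
through the usage-weighted exponent. Augmented all-zero rows contribute
(1 − p_ij)^{e_j} when z_i = 1 and nothing when z_i = 0. Sites with zero
usage contribute exactly zero. Zero-probability configurations return
−∞ rather than raising.

**Priors.** g0 ~ U(0, 1); σ ~ U(0, half the smaller side of S);
ψ ~ U(0, 1); s_i ~ U(S). These are the vague defaults of the Bayesian
SCR literature; with the sparse data this package targets, the σ upper
bound matters most and is deliberately tied to the state-space size so
the prior cannot place mass on movement scales larger than the region
being modelled.

## Sampler

Metropolis-within-Gibbs, per iteration:

1. **Activity centres.** Bivariate Gaussian random-walk proposal per
   row, reflected at the boundary of S (so proposals stay in S and the
   kernel remains symmetric). Rows with z = 0 have the uniform prior as
   their full conditional and are redrawn directly — a Gibbs move that
   costs nothing and mixes the augmented pool.
2. **g0** on the logit scale and **σ** on the log scale, random-walk
   Metropolis with the appropriate Jacobian terms; σ proposals beyond
   the prior bound are rejected.
3. **z** for undetected rows from its Bernoulli full conditional,
   P(z_i = 1 | ·) = ψ p0_i / (ψ p0_i + 1 − ψ), where p0_i is row i's
   all-zero-history probability.
4. **ψ** from its conjugate Beta(1 + Σz, 1 + M − Σz) conditional.

Proposal scales adapt during burn-in only (batched Robbins–Monro toward
0.44 acceptance for scalars, 0.25 for the bivariate moves) and are
frozen afterwards, so the retained draws come from a fixed, valid
transition kernel. Post-adaptation acceptance rates are reported and
land in (0.1, 0.6) on well-informed scenarios.

Defaults: 3 chains × 10,000 iterations, burn-in 2,000, so 8,000
retained draws per chain. Realised density D = N / |S| × 100 km² is an
exact per-draw transform of N. (z, s) are thinned by 10 for the map
products, post burn-in by default; `include_burnin_maps` switches to
thinning from iteration 1 for an all-iterations denominator. Chains run
sequentially on independent generator streams spawned from one seed:
identical configurations are byte-identical, and chains remain
statistically independent.

## Buffer choice

The buffer should be 2–3 times σ (beyond ~4σ the detection probability
is negligible). When not set explicitly, the package suggests
4 × RPSV, where RPSV is the root pooled spatial variance of capture
locations about individual centroids — a movement-scale estimator that
approximates σ under half-normal detection. This heuristic needs at
least one individual captured at two distinct sites; otherwise the
buffer must be given manually. It is validated by simulation (RPSV
within 20% of the true σ under heavy sampling), not against any
external algorithm; explicit `buffer_km` reproduces externally derived
state spaces.

## Diagnostics and summaries

- **Gelman–Rubin.** Classic multi-chain form: with W the mean
  within-chain variance and B/n the variance of chain means,
  point = sqrt(((n−1)/n · W + B/n) / W). The 95% upper bound replaces
  the between-chain term with its 97.5% sampling quantile (an F
  quantile with method-of-moments degrees of freedom for W, after
  Brooks and Gelman). Convergence is declared when every monitored
  parameter's upper bound is < 1.1. A split-half variant is available
  behind a flag for sensitivity to within-chain trends. All chains
  constant and equal return 1 by convention (warned); disjoint constant
  chains return a large finite value rather than infinity.
- **HPD.** Shortest contiguous window of the sorted draws containing
  ⌈0.95 n⌉ points, ties broken toward the lowest start; adequate for
  the unimodal posteriors produced here, and never wider than the
  equal-tailed interval.
- **CV.** Posterior SD (n−1 denominator) over posterior mean of the
  pooled post-burn-in D draws; ≤ 0.20 is labelled high precision,
  ≤ 0.35 moderate, above that low.

## Spatial products

The MCP is the convex hull of the trap coordinates (shoelace area;
degenerate arrays are an error). MCP density counts realised activity
centres inside the hull — boundary points count as inside — summed over
thinned draws, divided by the number of draws and the hull area. The
raster accumulates realised centres on a 1-km, integer-aligned lattice
with half-open pixel membership (pixels partition the plane), divided
by the number of draws; over the full state-space extent its mass
equals the posterior mean realised N, and with 1-km pixels values are
densities in individuals/km². Raster extent defaults to the MCP
bounding box and can cover the state space instead.

## Synthetic surveys

The generator emulates the systematic field design the pipeline
targets: a 2.5 × 2.5 km grid with every other cell (checkerboard
parity) holding a paired-camera site, 90–120 daily occasions over one
winter, optional mid-survey camera losses, activity centres uniform
over the buffered state space, N ~ Poisson(D·|S|/100) (or fixed), and
daily Bernoulli detections from the half-normal model. Detected
individuals' events are emitted in the same CSV dialect the readers
consume, so simulated surveys double as format fixtures.

Presets `sbnp`, `ucez`, `bpp` fix J = 35/65/50 sites, K = 90/112/120
occasions, M = 100/300/100 and buffers of 13/16/20 km, matching three
lynx surveys' layouts, with σ set to a quarter of each buffer. g0
values (0.012/0.0025/0.013) were chosen once so the simulated capture
patterns resemble those surveys' tallies — in particular, the
exclusion-zone-like preset yields roughly half of detected individuals
captured only once. Sparsity comes from g0 itself, never from post-hoc
subsampling. `demo_config()` is the exclusion-zone-like scenario
reduced to 30 sites, 60 occasions and M = 100 so that a full
simulate–fit cycle takes seconds; the test suite and the acceptance
script use it with 3 × 2,000-iteration chains (burn-in 500) for
replicated checks and full production settings for single fits.

What the generator does **not** emulate: individual heterogeneity and
sex differences in detection, behavioural responses to traps
(trap-happiness/shyness), territorial spacing of activity centres
(centres are independent uniforms), habitat structure, and
photo-identification error. Passing recovery tests therefore
demonstrate correctness of the estimator under its own assumptions, not
robustness to their violation in field data.

## Deterministic capture-pattern fixtures

`RECAPTURE_PATTERNS` encodes, per study area, the per-individual
(detections, distinct sites) breakdowns whose tallies the survey
summaries must reproduce exactly (e.g. 5 individuals with 22 recaptures
of which 10 spatial; 22 with 24/19; 14 with 65/13). `recapture_fixture`
realizes any such pattern as a concrete trap list plus dated records,
visiting each individual's distinct sites on consecutive days first —
so recaptures and spatial recaptures follow by construction, and the
tally code is tested against enumerable truth.

## Numerical choices

- "Recapture" = any detection beyond an individual's first; "spatial
  recapture" = per-individual distinct sites minus one. These are the
  only readings under which the fixtures' per-individual breakdowns sum
  to their survey totals and spatial ≤ total always holds.
- Occasions are 1-based days from the configured window start; window
  configuration (not hard-coded month rules) excludes mating-season
  data.
- Duplicate same-individual/site/day photographs collapse to one
  detection; events outside the window or at zero-usage site-days are
  dropped and logged, never silently.
- log(0) paths return −∞ under suppressed warnings; 0 · log(0) terms
  are masked to zero.
- HPD ties break to the lowest start; R-hat guards W = 0 cases as
  described above.
- MCP boundary membership is inclusive (`covers`, not `contains`), so
  centres on the hull edge count.

## Limitations

Single-season (demographically closed) surveys only; no individual or
sex-specific detection parameters; rectangular state spaces without
habitat masks (density is averaged over the buffered rectangle, which
can differ from habitat-weighted density); MCP densities carry no
uncertainty statement; the buffer heuristic is an approximation and
should be overridden when telemetry-based home-range information
exists. In very sparse surveys analysed with short chains, 95% HPD
coverage of the movement scale can fall modestly below nominal; the
acceptance script reports the observed coverage counts rather than
assuming nominal behaviour.
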