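# Methods

## The kinetic model

Carbon load in airway macrophages (AM BC) is treated as a one-compartment
clearance process: a subject's slide-level outcome (median or 90th
percentile BC area over the cells of one sputum sample, μm²) follows

    y_ij ~ LogNormal( log R0_i − k_i t_ij , σ_obs )

where `t_ij` is days since the subject's time origin, `R0_i` the carbon
load at that origin and `k_i` the net decay constant. `k` is in day⁻¹
throughout: ln(2)/k with k in day⁻¹ reproduces the half-lives the model is
meant to produce (e.g. k = 0.013 day⁻¹ → 53 days), whereas a literal
"μm²/day" reading would not make ln(2)/k a time. `k` is unconstrained in
sign: a negative value means net accumulation, expected for subjects moving
*into* a more polluted environment. The observed kinetics are a *net*
balance of macrophage clearance and continued (lower) deposition, so `k` is
not a pure biological clearance rate.

Subjects are partially pooled within exposure groups:

    log R0_i ~ Normal( log R0_g , σ_R )
    k_i      ~ Normal( k_g , σ_k )

A pooled variant (`group_effect=False`) replaces the per-group means with
common ones; comparing the two by DIC tests whether exposure history
matters.

### Time origins and the resident anchor

* **Newcomers** (recently arrived from elsewhere): origin at the *arrival*
  day. Their first measurement happens a latency of days-to-weeks later, so
  R0_i is a model-based extrapolation back to day 0.
* **Residents** (stable exposure): origin at their first valid measurement
  (T1). Under the default `resident_r0_rule="fixed_to_T1"`, the subject's
  R0_i is fixed to the observed T1 value. Two consequences are handled
  explicitly: (1) the T1 row is removed from the observation likelihood —
  keeping it would contribute an exactly-zero residual and bias σ_obs
  downward; (2) the anchored log R0_i enters the hierarchy as an *observed*
  draw from Normal(log R0_g, σ_R), so the group-level R0_g is still
  estimated. Because the anchor carries measurement noise, this rule is
  statistically fragile; `resident_r0_rule="estimated"` treats residents
  like newcomers (origin still at T1) and is provided as the robust
  alternative.

### Priors (weakly informative, defaults in `PriorSpec`)

| parameter | prior | default scale | rationale |
|---|---|---|---|
| log R0_g | Normal(0, 2) | log μm² | spans ~0.02–50 μm², far wider than plausible loads |
| k_g | Normal(0, 0.05) | day⁻¹ | half-lives down to ~2 weeks; sign-free |
| σ_R | Half-Normal(1) | log scale | subject heterogeneity up to ~e±2-fold |
| σ_k | Half-Normal(0.02) | day⁻¹ | subject slopes within ±0.04 of the group |
| σ_obs | Half-Normal(1) | log scale | observation CV up to ~100%+ |
| covariate β on log R0 / k | Normal(0, 1) / Normal(0, 0.01) | — | effects no larger than the group signal itself |

Scales are sampled as log σ with the Jacobian included. Covariates `sex`
and `age` (centred) act additively on log R0 and on k; `season` (4-level
meteorological coding from the visit's day of year, winter reference) acts
on the observation log-mean.

### Sampling

The model is linear-Gaussian in the non-centred subject effects given the
hyperparameters, so the subject effects are integrated out analytically
(Woodbury identity on a rank-2 covariance update per subject). The sampled
space is only the 2G + B + 3 hyperparameters, explored with emcee's
ensemble sampler (differential-evolution + snooker moves, 2·ndim + 32
walkers, 1800 burn-in + 1200 kept steps thinned by 6 by default). Subject
effects are then drawn *exactly* from their conditional 2×2 Gaussian
posteriors for every stored draw (Rao-Blackwellisation), which makes the
stored (hyper, subject) draws exact joint posterior samples.

Diagnostics: the walker ensemble provides the parallel chains; split-chain
R̂ and bulk ESS (arviz) are computed for every reported parameter, with
thresholds R̂ < 1.05 and ESS > 400. A fit failing them is returned with
`converged=False` rather than raised, so callers can inspect it, but it
must not be reported. Walkers in one ensemble are not fully independent
chains, so this R̂ is a slightly optimistic diagnostic; at the default
chain lengths it sits near 1.01–1.03 with ESS in the thousands.

### Derived quantities

Clearance half-life = ln(2)/k for k > 0, +∞ ("no net clearance") for
k ≤ 0. Credible bounds use the monotone transform of the k quantiles:
(ln2/k_97.5, ln2/k_2.5), with an infinite upper bound when the k interval
reaches 0; the posterior mass with k ≤ 0 is reported alongside.

### DIC

Deviance is the *conditional* −2 log p(y | subject parameters, σ_obs)
(log-normal density, including the Jacobian Σ log y). The resident anchor
terms belong to the random-effects layer, not the observation likelihood,
and are excluded. D(θ̂) evaluates the deviance at the posterior mean of
every parameter on its sampling scale (subject effects at their posterior
mean standardised values). pD = D̄ − D(θ̂), DIC = D̄ + pD; with a
continuous likelihood DIC is routinely negative. Comparisons require
identical observation sets — enforced via a data fingerprint — and report
ordering plus deltas only; no significance threshold is attached to a DIC
difference.

### Posterior predictive checks

Replicate datasets are simulated from stored posterior draws at the
observed design points and smoothed per group with a lowess local-linear
(tricube) smoother, span 0.75 by default, evaluated on a 40-point grid per
group. The check reports the fraction of grid points at which the observed
smooth lies inside the central 95% replicate envelope. Under
self-consistent data this fraction sits near 1; a structurally wrong model
(e.g. two-phase decay fitted by a single exponential) drops well below.

## The synthetic cohort generator

The generator emulates the study conditions of the panel design, not any
particular dataset: 3 groups × 15 subjects scheduled for 8 visits 42 days
apart (±3 days jitter), newcomer latency uniform over 1–19 days (LMIC) and
2–23 days (HIC), sputum induction succeeding with probability 0.85 per
visit, and a monotone dropout hazard of 0.03 per visit from visit 5 onward
(subjects always attend ≥4 visits, mirroring the reported completion
pattern). Group-level truths default to R0 = 1.122/0.387/0.275 μm² and
k = 0.013/0.002/−0.001 day⁻¹ (LMIC/HIC/BE), the reported median-outcome
kinetics.

Per-cell BC areas are log-normal around the subject's current curve value
(right-skewed, non-negative, median ≪ p90), with log-SD 1.3 chosen so the
slide p90 sits ~5× above the median, matching the reported ratio of
90th-percentile to median kinetics at t = 0. Each slide records the median
and p90 of 25 cells (linear-interpolation percentiles — the same rule used
everywhere in the package). Subject heterogeneity defaults to σ_R = 0.5
(log scale) and σ_k = 0.002 day⁻¹; an extra slide-level log-normal noise of
0.25 combines with the sampling noise of a 25-cell median
(≈1.25·1.3/√25 ≈ 0.33) to a total observation CV near 40%, the
intra-individual variation reported for stable residents. An optional
point mass at zero models cells without inclusions (default 0).

What the generator does *not* emulate: outcome-dependent kinetics (the
slower p90 decay arises in real data from size-dependent clearance; here
p90 and median share k_i), travel-related excursions, assay drift, or
informative missingness (induction failure is independent of carbon load).
Passing recovery tests therefore demonstrates correctness of the inference
under the stated design, not robustness to those real-data features.

## Image quantification

Colour micrographs are collapsed to intensity by Rec. 709 luminance
(scikit-image's convention). Within each provided binary cell mask an
automatic threshold — Otsu by default, IsoData (the classic ImageJ-style
"Default") as the alternative — separates dark carbon pixels from the
stained cytoplasm; pixels strictly below the threshold are counted and
converted to μm² via the calibration (brightfield ×100: 146 px = 10 μm;
confocal 2-D: 75 px = 10 μm; 3-D projections: 158 px = 41 μm). Manual
freehand refinement of real workflows is replaced by explicit mask inputs;
no segmentation of real slides is attempted. A mask with uniform intensity
has no meaningful threshold and yields zero foreground by convention; on a
noisy but carbon-free cell an automatic threshold will still split the
noise, so blank-cell behaviour is only guaranteed for noiseless input.
Whether boundary-touching pixels belong to the cell is decided entirely by
the mask supplied.

The synthetic micrograph generator renders dark disks on a lighter
background with exact per-blob pixel counts recorded *before* noise is
added, giving pixel-perfect oracles for the quantification path.

## Agreement statistics

Bland–Altman analysis runs on natural-log areas by default (areas are
strictly positive and span orders of magnitude; a constant multiplicative
bias becomes a constant mean difference), with limits of agreement at
mean ± 2·SD of the differences. Spearman's rank correlation (midranks for
ties) gets a 95% CI via the Fisher z-transform with variance 1/(n−3) — an
approximation for rank correlations, so a pair-resampling bootstrap CI is
available and both are labelled. The ICC is ICC(2,1) — two-way random
effects, absolute agreement, single measurement — computed from the
two-way mean squares; since the form convention varies across the
literature, the form identifier is printed in every report.

## Numerical choices and degenerate inputs

* Percentiles everywhere use linear interpolation between order statistics
  (numpy default).
* Outcomes equal to exactly 0 are offset to half the smallest nonzero
  outcome before log-transforming, with a warning (log-normal support
  excludes 0).
* Exactly noise-free data make the log-normal likelihood unbounded as
  σ_obs → 0; the sampler guards |log σ| ≤ 15 but such posteriors are
  degenerate by construction. Validation therefore uses a small-noise
  sequence and checks that credible intervals shrink as noise decreases.
* Resident subjects with fewer than two valid slides cannot contribute
  under the anchoring rule and are dropped with a recorded reason, as are
  subjects with no valid slides at all.
* MCMC chain lengths (1800 + 1200 steps, thin 6) and the 20-replicate
  simulation studies are the package defaults; they give R̂ < 1.05 and
  ESS > 400 on the emulated design while keeping a full replicate study in
  the minutes range on a single CPU.

## Known limitations

* The likelihood family (log-normal) and the hierarchy's distributional
  forms are package design choices among several defensible options for
  positive right-skewed outcomes; the `normal_on_log` switch only changes
  the deviance convention, not the fitted posterior.
* DIC with the conditional focus counts partially pooled subject effects in
  pD; other foci (marginal likelihood) give different absolute values.
  Only within-package comparisons on identical data are meaningful.
  WAIC/LOO alternatives are out of scope (future work).
* The fixed-to-T1 resident rule conditions on a noisy observation; group
  σ_R absorbs that noise, slightly inflating the apparent subject
  heterogeneity.
* The Fisher-z Spearman CI and the lowess span (0.75) are conventional
  defaults, both configurable and recorded in outputs.
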