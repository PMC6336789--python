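# Methods

This note documents the models, priors, numerical choices and limitations
behind `cosmotrace`, in the order of the analysis chain.

## Camera model and gain estimation

Raw counts are modelled as `counts = offset + g·Poisson(λ) + N(0, σ_r²)`
with gain `g` (counts/photon), offset, and Gaussian read noise. This
scaled-Poisson model reproduces the linear mean–variance relation
`Var = g·(mean − offset) + σ_r²` that the calibration exploits; the full
electron-multiplying register cascade (which adds an excess-noise factor)
is deliberately not modelled, because the pipeline consumes only the
linear relation. Gain is the least-squares slope of pooled per-pixel
temporal variances against means across ≥ 2 illumination levels plus a
dark stack, after discarding the top 1% variance pixels per level (hot
pixels; the robustness recipe is this package's choice). Offset is the
dark mean. Photon conversion clips at zero.

*Consequence:* photon-unit thresholds downstream (150-photon event
criterion) are correct up to gain error, which the tests hold under 5%
with 3 × 200 calibration frames.

## Geometry

**Channel map.** `y = A x + b` fitted by least squares to bead pairs;
correspondence by mutual nearest neighbour within 5 px after removing the
median translation. ≥ 3 non-collinear beads required; the canonical
calibration input is ten bead images. No nonlinear (spline) mapping.

**Drift.** Consecutive-frame shifts from the FFT cross-correlation peak,
sub-pixel via 3×3 parabolic interpolation, cumulatively summed and
anchored at frame 0. The `DriftTrack` stores the apparent motion of the
sample; corrections subtract it so all coordinates live in the frame-0
reference. Pairs whose correlation peak falls below 5 SD of the
correlation surface hold the previous shift and are flagged with infinite
uncertainty. Drift is estimated on the target channel only (the targets
are the densest static structure). Accuracy on simulated fields is
< 0.1 px per step; images are never interpolated.

**Coordinates.** 0-based pixel indices; a spot at integer (x, y) is
centred in that pixel; nm enter only through `pixel_size_nm`
(default 160).

## Detection (GLRT)

Per pixel, H1 = pixel-integrated Gaussian of fixed width σ_psf centred
there with free amplitude ≥ 0 and free flat background, H0 = background
only, both Poisson. The statistic 2·log LR has the boundary null mixture
`0.5·χ²₀ + 0.5·χ²₁`, so the threshold for per-pixel false-alarm
probability `p_fa` is the upper 2·p_fa quantile of χ²₁. A Monte-Carlo
calibration utility exists for low-background regimes where the
asymptotic null degrades; with default settings the empirical false-alarm
rate stays within a factor 2 of `p_fa` for backgrounds of 2–50
photons/px. Positive pixels are grouped by 8-connectivity, one candidate
per group at the score maximum; groups larger than `max_cluster_px`
(default 64) are rejected as aggregates. Detection runs on the first
frame by default.

Site quality: any pair closer than 50 nm loses **both** members
(`proximity`); fitted width > 2 σ_psf rejects (`width`); circularity —
the minor/major eigenvalue ratio of the background-subtracted
second-moment matrix, a formula this package fixes since only the
criterion name is standard — below 0.7 rejects (`circularity`). Every
rejection carries its reason; there is no manual-vetting stage.

## Localization (MLE + CRLB)

Model: `μ_i = bg + I·Ex_i·Ey_i`, with `E` the Gaussian integrated over
the unit pixel (erf differences). Fitting maximizes the Poisson
log-likelihood by damped Fisher scoring (analytic first derivatives,
Fisher information as the curvature — positive-definite by construction)
with per-window backtracking so the likelihood never decreases below its
initialization. Initialization is the background-subtracted centroid.
Convergence: max parameter step < 1e-6 or 100 iterations. Window size
2⌈3σ⌉+1 captures > 99% of spot flux. The inverse Fisher information at
the optimum is the CRLB, reported per parameter; on simulated spots at
1000 photons the empirical RMSE matches it within 10% and the bias is
below CRLB/5. Degenerate inputs (all-zero windows, centres drifting out
of the window) return flagged non-converged records, never exceptions;
non-converged frames stay in the trace as gaps.

σ_gf is fitted per frame in the binder channel (needed for the ≤ 4.6
width criterion, interpreted in pixels); target-site fitting can hold it
fixed at the calibrated PSF width. No astigmatic/3-D PSF; the likelihood
is photon-Poisson (no EMCCD excess-noise term).

## Events and kinetics

A frame is bound iff all four criteria hold: `I_gf > 150` photons,
`I_gf / (2π σ_gf² · bg_est) > 1` (the denominator integrates the local
background over the fitted spot footprint — the SBR formula is this
package's choice), distance to the drift-corrected site < 1 px, and
`σ_gf ≤ 4.6` px. Gap closing (≤ 2 frames) runs **before** the minimum-
duration filter (≥ 2 frames): blinking bridges first, then short flashes
drop. The defaults are the low end of the 2–5-frame range. Only the first
event per site enters arrival/dwell tables (later events may involve
photobleached molecules); event-free sites are right-censored at the
movie end, dwells reaching the last frame at the trace end.

Rates: censored-exponential MLE `k̂ = d/Σt` with profile-likelihood CI
(χ²_{2d} inversion); `k_on = k_obs/[binder]` with the concentration a
required metadata field. Non-specific binding: the dark-location arrival
rate is subtracted from the target rate (floored at zero with a warning),
propagated through paired bootstrap cycles; the subtraction formula is
this package's documented choice. Dissociation at or below a supplied
bleaching rate is flagged `photobleach_limited` and suppressed, with
optional subtraction.

**Bootstrap.** Molecules (sites) are the independent unit. Each of 1000
cycles resamples ⌈0.9·n⌉ sites *with replacement* and refits; the SD
across cycles is the SE. With replacement is chosen (over a 90% subsample
without replacement) because only then does the SD estimate the sampling
SE of the estimator — it matches the analytic exponential-MLE SE k/√n
within 25% at n = 500 — whereas a without-replacement 90% subsample SD is
smaller by the finite-population factor ≈ √((1−0.9)/0.9) ≈ 1/3.
`BootstrapConfig(replace=False)` retains the subsample protocol; the
MGHMM precision analysis (below) uses exactly that protocol, since there
the quantity of interest is reproducibility across 90% subsamples.

Replicate experiments merge by pooling arrival/dwell tables (sites
relabelled) and refitting jointly, so pooled SEs shrink like 1/√replicates.
No multi-exponential dwell mixtures; temperatures are independent datasets.

## VBEM-MGHMM

Observations per frame are (signal, background) ∈ R² — correlated,
non-zero-mean — emitted by a K-state hidden Markov chain with full-
covariance Gaussian emissions (the dimension is generic; 1-D reduces to
the classical case). Conjugate priors: symmetric Dirichlet(1) on the
initial distribution and each transition row; a shared Normal–Wishart
(m₀, κ₀, ν₀, W₀) on each state's mean and precision.

Updates are the standard conjugate VBEM equations: the E-step runs
scaled forward–backward under the *expected* log transition matrix
(digamma differences) and expected log emission densities (digamma/
log-det terms, −D/2κ correction, ν-weighted quadratic form); the M-step
applies the closed-form Dirichlet and Normal–Wishart updates from the
responsibilities and pairwise marginals. The ELBO is the forward
normalizer of the sub-probability parameterization minus the KL
divergences of all parameter posteriors from their priors; it is exact
for this factorization, asserted non-decreasing at every iteration, and
for K = 1 equals the closed-form conjugate log evidence to machine
precision (a tested identity). Convergence: relative ELBO change < 1e-8
or 500 iterations. Initialization: seeded k-means++ responsibilities,
plus jittered restarts; the best-ELBO restart wins. Traces are batched by
length so forward–backward vectorizes across hundreds of traces.

**Priors.** `m` defaults to the mean (signal, background) of an
identified single binding event; κ = ν = W^{1/2} = 10 are the packaged
model-order-selection defaults. The `W_sqrt` knob parameterizes the
Wishart scale as `W₀ = I/(ν₀·W_sqrt²)`, i.e. the prior expected emission
precision is `I/W_sqrt²` — the prior's typical emission SD is `W_sqrt`
photons. This is an interpretive choice (the knob is conventionally
described only as the scale of the prior on the signal variance) and is
deliberately informative-but-weak: ten pseudo-counts of a tight variance.

**Order selection.** Fit every K in the range, take the largest ELBO;
ties within 1e-6 relative break toward smaller K (parsimony on ELBO
plateaus). Failed fits (non-positive-definite scale updates across all
restarts) are excluded with a warning. Because the bound weighs data
against prior, very small datasets bias toward the prior (fewer states)
and very large datasets can over-select (Lindley's phenomenon) — the
per-K ELBO table is returned for that diagnostic. Under the packaged
simulation conditions the true K = 3 is recovered from 750 points up;
the under-selection window therefore lies below the smallest ladder size
and is not exhibited by these conditions.

**Decoding and occupancy kinetics.** Viterbi under the posterior-expected
parameters; states relabelled by ascending signal mean so label k = k
bound complexes. Level-resolved rates use the discrete-time transition-
count estimator — (k→k+1 counts)/(time at level k) — with bootstrap-over-
traces SDs; continuous-time EM is out of scope. For a target with two
identical independent sites the aggregate ratios are
`k_on(1→2)/k_on(0→1) = (1−p_off)/(2(1−p_on)) ≈ 0.5` and
`k_off(2→1)/k_off(1→0) ≈ 2`, the yardstick the multi-site analysis
reports against.

## Synthetic data: what it does and does not emulate

The generator produces calibration stacks, bead fields (affine-mapped,
jittered), drifting two-channel binding movies (spots as pixel-integrated
Gaussians — identical to the fitting model, enabling exact-recovery
tests; drift applied to spot centres in scene space, avoiding
interpolation artifacts), and MGHMM observation traces.

The packaged trace conditions (`two_site_truth`) are: two independent
identical sites, per-frame p_on = 0.01 and p_off = 0.005 per site
(K = 3 occupancy levels), signal mean 60 + 330·(bound complexes)
photons, background mean 200 photons, SDs 80 and 40 with correlation
0.2, frame interval 0.1 s; the canonical dataset is 400 traces × 1500
frames = 600,000 points, with bootstrap sub-datasets of 750 to 480,000
points. These values were fixed once as representative single-molecule
imaging conditions (spot intensities of a few hundred photons over
hundreds of photons of integrated background, dwells of tens of frames).

Not emulated: EMCCD excess noise beyond the linear mean–variance
relation, pixel-response non-uniformity, axial (z) structure, FRET
between channels, and non-Markovian (multi-exponential) kinetics.
Passing tests therefore demonstrate correctness of the estimators under
the stated forward models, not robustness to camera excess noise or
model misspecification on real data.

## Problem sizes used in the checks

The quantitative suite runs at the canonical 600,000-point scale for the
dataset-size, precision and ratio checks; order selection walks the
ladder from 750 points; localization precision uses 500 Poisson
realizations at 1000 photons; censored-MLE bias uses 100 replicates of
n = 1000 per rate. The MGHMM precision analysis uses 8–10 replicate
fits on 90% subsamples, warm-started from the full fit (warm starts
change only runtime, not the converged bound).

## Known limitations

- GLRT p-value control is asymptotic; at backgrounds ≲ 1 photon/px use
  the Monte-Carlo threshold.
- The localization likelihood ignores EMCCD excess noise; on real EMCCD
  data precisions are optimistic by up to √2.
- Occupancy rates assume at most one level change per frame; at frame
  intervals long relative to the kinetics, double transitions within a
  frame bias the level rates (the independent-sites ratios are affected
  only at second order).
- `select_order` cost grows linearly in |K range| × dataset size; for
  millions of points fit a subsample first and warm-start.
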