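# cosmotrace

Automated Bayesian analysis of **co-localization single-molecule
spectroscopy (CoSMoS)** binding assays: experiments in which surface-
tethered target molecules are imaged in one color channel while a
fluorescently labelled binding partner arrives and departs in a second
channel. From raw two-channel camera stacks the pipeline produces
calibrated photon counts, detected and fitted molecule positions, scored
binding events, association/dissociation rate constants with bootstrap
errors, and — its distinctive capability — the number of *simultaneously*
bound complexes per target, inferred without extra dye colors.

It is written for single-molecule biophysicists who want a scriptable,
reproducible alternative to interactive trace-picking: every stage is a
library function with explicit parameters, every threshold is in physical
units (photons, pixels, seconds), and a frozen YAML config reruns an
analysis to byte-identical outputs.

## The analysis chain

1. **Gain calibration.** An EMCCD in its linear regime satisfies
   Var[counts] = g·(E[counts] − offset) for Poisson photon input; the gain
   *g* is the slope of the per-pixel temporal variance against the mean
   over uniform-illumination stacks, the offset is the dark-frame mean.
   All downstream intensities are in photons.
2. **Channel registration and drift.** An affine map (rotation, scaling,
   shear, translation) is least-squares fitted to matched bead positions;
   lateral drift is tracked per frame from the cross-correlation of
   consecutive images, using the immobilized targets themselves as
   markers. Coordinates are corrected; images are never resampled.
3. **Detection.** Each pixel is tested with a generalized likelihood
   ratio test (GLRT) — Gaussian spot vs. flat background under the
   Poisson likelihood — at a user-controlled per-pixel false-alarm
   probability, so sensitivity is traded against a *known* false-positive
   rate rather than an ad-hoc intensity cutoff. Sites closer than 50 nm,
   too wide, or insufficiently circular are discarded with recorded
   reasons.
4. **Localization.** Every site, every frame: maximum-likelihood fit of
   the pixel-integrated Gaussian model, returning position (x_est, y_est),
   background bg_est, intensity I_gf and width σ_gf together with their
   Cramér–Rao lower bounds — the estimator attains the theoretical
   maximum precision, and says so quantitatively.
5. **Co-localization events.** A frame is *bound* when I_gf > 150
   photons, signal/background > 1, the fitted position is within 1 pixel
   of the target, and σ_gf ≤ 4.6; gaps of ≤ 2 frames (blinking) are
   closed before runs shorter than 2 frames are dropped.
6. **Kinetics.** First-arrival and dwell times are fitted by the
   right-censored exponential MLE, k̂ = (#uncensored)/(Σ times);
   k_on = k_obs/[binder]. Non-specific surface binding measured at
   target-free "dark" locations is subtracted; errors are SDs over
   1000-cycle bootstraps of 90% of the molecules; dissociation slower
   than photobleaching is flagged, not reported.
7. **Occupancy (VBEM-MGHMM).** Per-frame (signal, background) vectors —
   correlated, non-zero-mean — are modelled by a hidden Markov model with
   full multivariate-Gaussian emissions under conjugate Dirichlet /
   Normal–Wishart priors. Variational Bayesian evidence maximization
   yields the evidence lower bound (ELBO), which selects the number of
   occupancy states automatically; Viterbi decoding and level-resolved
   transition rates then test, e.g., whether two adjacent binding sites
   are independent (expected rate ratios: k_on 0.5×, k_off 2×).

A synthetic-data module generates every input — calibration stacks, bead
fields, drifting two-channel movies, MGHMM traces — with recorded ground
truth, so the whole chain is testable end to end.

## A worked example

`examples/04_occupancy_hmm.py` simulates 60 traces from a target with two
independent, identical binding sites (per-frame binding probability 0.01
per site, release 0.005) and runs the full occupancy analysis:

```
ELBO per model order: {1: -1079910, 2: -1020225, 3: -987078, 4: -987222}
selected K = 3 (truth: 3 occupancy levels)
frame-label accuracy vs ground truth: 1.000
k_on ratio  (level 1->2 / 0->1): 0.492 +- 0.046  (independent sites: 0.5)
k_off ratio (level 2->1 / 1->0): 1.701 +- 0.160  (independent sites: 2)
```

The ELBO rises to K = 3 and falls at K = 4 — the bound's built-in
complexity penalty selects the true order. Decoded occupancy levels then
give aggregate rates per level: binding into the doubly-bound level is
half as fast as into the singly-bound level (one free site instead of
two), and release is twice as fast (two bound complexes instead of one) —
the signature of independent sites, recovered within bootstrap error.

The other examples cover gain calibration, detection + CRLB-bounded
localization, bulk kinetics, and the full pipeline from a YAML config
(also available from the shell: `cosmotrace simulate`, `cosmotrace run`,
`cosmotrace merge`, …).

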