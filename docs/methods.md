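# Methods

This note documents the models implemented in `cvrflow`, the synthetic-data
generator that stands in for acquired gas-challenge data, the numerical
choices behind each estimator, and the limits of what the test suite shows.

## The experiment being modelled

A subject breathes through a computer-controlled gas delivery system while
BOLD fMRI is acquired (TR = 1.05 s, 1000 volumes). The respiratory paradigm
is a 90-s hypercapnic block (+10 mmHg PetCO2), a 120-s ramp rising to
+12 mmHg, and a 180-s hyperoxic block targeting 680 mmHg PetO2, each
followed by a 120-s baseline. Hypercapnia dilates cerebral vessels and
raises the BOLD signal; when CO2 returns to baseline the vasoconstrictive
rebound shrinks cerebral blood volume (CBV), and the displaced volume is
replaced by CSF flowing into the imaging slab. Fresh, unsaturated spins
entering the bottom slices produce a transient time-of-flight signal spike —
an inflow-only effect; outflow is invisible. Brief hyperoxia raises the BOLD
signal through venous saturation without changing CBV, so it must produce no
inflow; it acts as the experiment's negative control.

## Synthetic data generator

No public dataset exists for this paradigm, so every analysis stage is
exercised against a forward model with known truth.

**Gas traces.** End-tidal targeting is idealized: block epochs are plateaus
reached by linear transitions of length `transition_time`, the ramp rises
linearly to its maximum over the epoch. The return transition is placed in
the `transition_time` window immediately *after* each epoch, so the stimulus
starts decaying exactly at the epoch end — which is where the inflow fit
window begins and where inflow is expected to start. Defaults:
`transition_time` = 10 s (prospective targeting settles over a few breaths),
baselines 40 mmHg CO2 / 110 mmHg O2 (typical adult values; individual
baselines vary in practice). The leading baseline defaults to 172.5 s, which
places the end of the hypercapnic block exactly at volume 250 (262.5 s).
Breath-to-breath variability is not modelled.

**BOLD.** `s(t) = s0 + cvr_amplitude · (ΔCO2 ⊛ h_τ)(t) + ε` sampled at the
volume times, with `h_τ(t) = (1/τ)e^{−t/τ}` normalized to unit discrete sum
and `ε` i.i.d. Gaussian. Defaults: s0 = 1000 a.u., cvr_amplitude = 2 a.u./mmHg
(a 2% signal change for the +10 mmHg block), τ = 10 s, noise SD = 2 a.u. —
a contrast-to-noise ratio of 10 for the block response, representative of a
de-noised regional average rather than a single voxel. O2 is given zero
vasoactivity by default (`o2_amplitude = 0`): short hyperoxic blocks change
venous saturation, not CBV, and the saturation pathway is deliberately
excluded from the inflow drive.

**CSF inflow.** The inflow trace is the rectified negative temporal
derivative of the noise-free BOLD signal — only CBV *decreases* drive
inflow — scaled by `inflow_gain` (30 s by default, which makes the inflow
excursion an order of magnitude larger than the regional BOLD change, as
observed for time-of-flight spikes), shifted by a transit delay
(`inflow_delay_s` = 1.26 s), offset by a 100-a.u. baseline, plus noise.
Right-sided asymmetry is imposed by stretching the right side of each
rectified peak by a factor `1 + inflow_skew` (default 1.0), each connected
peak warped about its own maximum. The generator records the true right
HWHM of the block-offset peak measured numerically on the noiseless trace.

**Volumes and masks.** The brain is an ellipsoid with CSF/WM/GM shells; the
edema mask is grown by seeded breadth-first search over 6-connected brain
voxels to `round(target · n_brain)` voxels, so the achieved fraction is
within one voxel of the target. In the 4D stack, GM voxels carry the full
CO2 response, WM half of it, and a small cluster of voxels at the centre of
each of the two bottom slices carries the inflow trace. The default
16×16×8 grid keeps a full synthetic subject under a second of compute; the
grid size only dilutes averages, it does not change any estimator.

## Estimators

**Tau fit.** For each candidate τ on a grid (0.5–120 s, step 0.5 s) the CO2
trace is convolved with the unit-sum exponential kernel (kernel support
25 τ; the pre-scan signal is assumed at its initial value, so a constant
trace maps to itself) and the GM BOLD signal is regressed on it by OLS over
the analysis window; the τ with minimal RSS wins, exact ties going to the
smaller τ. An exhaustive grid is robust and exactly reproducible for a
one-parameter problem; an intercept is always included and a linear drift
term is optional (off by default). The default window is volumes 250–450
(262.5–472.5 s), the return-to-baseline phase after the hypercapnic block;
the ramp is deliberately not given its own fit because gradual CO2 changes
do not probe the response dynamics.

A window design note: the 250–450 window sees only the offset decay, and a
slow response (τ = 60 s) is then weakly identified — at CNR 10 the grid
estimator is unbiased but SD(τ̂) ≈ 4.7 s, and only ~80% of replicates land
within 10% of truth. Widening the window to 200–450, which adds part of the
block plateau, brings recovery to ≥94% for τ ∈ {5, 20, 60} s. The recovery
experiments therefore use the 200–450 variant; both windows are accepted via
configuration and the analysis default remains 250–450.

**Wavelet de-noising.** `sym4` decomposition to level 2 with symmetric
boundary extension; detail coefficients are hard-thresholded with the
level-independent universal threshold `λ = σ̂ √(2 ln N)`, where
`σ̂ = median(|d₁|)/0.6745` from the finest detail level (the standard
Donoho–Johnstone scale estimate); approximation coefficients pass through.

**Inflow voxel selection.** Within each of the two bottom slices, voxels
are ranked by max−min contrast of their de-noised traces over the fit
window; the top 5 per slice are kept (ties resolve by voxel index), the
per-slice means are averaged. High contrast is what manual selection of
inflow voxels keys on; 5 voxels per slice is a choice, not a measured value.

**Inflow peak fit.** Nonlinear least squares of the skew-normal-plus-line
model over the fit window, with ξ initialized at the detrended maximum,
ω at a sixth of the window span, the line through the window endpoints, and
amplitude from the detrended peak height; restarts from α₀ ∈ {−2, 2} on
failure. Bounds: amplitude ≥ 0 (inflow cannot be negative), ω ∈ (TR, span),
|α| ≤ 20, ξ within half a span of the window. The fit window runs from the
end of the hypercapnic block to the midpoint between the block end and the
ramp peak — far enough to include the whole tail of the block-offset peak,
short enough to exclude the ramp-offset peak. For file-based runs without a
protocol description the static default (volumes 250–525) is used.

**Right HWHM.** The skew-normal mode has no closed form; it is located by a
dense grid plus bounded refinement, and the right half-height point by
bisection to 10⁻⁶ ω. For α = 0 this reduces to ω√(2 ln 2). Note that at
fixed ω the right HWHM is *maximal* at α = 0 and shrinks for any |α| > 0:
skewness lengthens the far tail but narrows the half-height region around
the mode. A broader fitted peak therefore shows up mainly through ω.

**Lags.** Pearson correlation over integer-volume shifts within ±max_lag,
overlap samples only (no padding, to avoid edge bias in r), signed maximum
(anticorrelation is not chased), ties toward the smallest |lag|. Positive
lag means the second signal is delayed with respect to the first; the
pipeline passes the reference (negated BOLD or CO2 derivative) first, so
inflow delays come out positive. Lag resolution is one TR (1.05 s).

**Inflow presence.** A dataset counts as showing inflow when the de-noised
selected-voxel trace exceeds the baseline level by more than 3× the
measurement noise within the post-block window. The baseline level is the
median over the baseline window (a constant — extrapolating a fitted trend
hundreds of volumes forward would inject spurious excursions); the noise SD
comes from the *raw* selected-voxel trace, because smoothing understates
the measurement noise against which a peak must be judged. The threshold is
configurable; screening is qualitative in practice and this rule is its
reproducible stand-in.

**Group statistics.** OLS regressions of τ on edema fraction (all datasets)
and on inflow HWHM (inflow datasets only; datasets without inflow stay in
the τ analyses), with the two-sided slope p-value from the t distribution
(n−2 df), and a paired two-sided t test on pre/post τ for subjects measured
twice. Identical pre/post values return (t = 0, p = 1) by convention.

## Pipeline ordering and its consequences

The subject pipeline mirrors the acquisition-processing order: regional
extraction with edema exclusion (edema dilated by one voxel,
6-connectivity), de-noising, CO2 resampling to the volume grid, bulk
alignment of the CO2 trace to the whole-brain BOLD mean, then the τ and
inflow fits. Bulk alignment exists to absorb the unknown offset between the
gas-recording and scanner clocks; because it maximizes correlation it also
absorbs part of the bulk hemodynamic delay, so the pipeline τ describes the
response *shape after the bulk shift is removed* and sits below the
generator's τ on synthetic data (which has no clock offset). Parameter
recovery is assessed at the estimator level with the unshifted regressor,
where the forward and inverse models match exactly.

## What the synthetic tests do and do not show

Passing tests establish that the estimators recover the parameters of their
own generating model under Gaussian noise, that the inflow machinery
responds to CBV decreases and not to hyperoxia, and that the group
statistics recover a built-in edema–τ dependence. They do not establish
robustness to real-data features the generator omits: motion, partial
volume with veins, breath-to-breath end-tidal variability, scanner drift
(beyond the optional linear term), Rician magnitude noise at low SNR,
through-slab flow geometry, or anatomical variability in where inflow
appears. The 1.05-s TR also limits lag resolution well below the precision
at which transit delays differ across people.

## Degenerate inputs and tie-breaks

Constant signals raise explicit undefined-correlation/fit errors rather
than returning NaN; empty mask selections raise an empty-region error;
τ ≤ 0, ω ≤ 0 and malformed windows are rejected up front; equal-contrast
voxels, equal-RSS τ candidates and equal-correlation lags all resolve
deterministically (index order, smaller τ, smaller |lag|). Reports are
written with sorted keys so repeated runs are byte-identical.
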