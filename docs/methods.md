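# Methods

This note documents the models, algorithms, defaults and design choices
behind `wormscreen`, and what its synthetic generators do and do not
emulate.

## Conventions

Image stacks are arrays indexed `(t, z, y, x, c)`, 0-based, with voxel
centers at integer coordinates and physical voxel sizes `(dz, dy, dx)` in
µm. Channel 0 is the calcium indicator ("G"), channel 1 the
activity-independent reference fluorophore ("R"); all physiology is read
from the G/R ratio, which cancels motion and expression artifacts common to
both channels. Behavior labels are `forward`, `reversal`, `turn`, `pause`,
plus `unknown` for unscored frames; `unknown` frames are excluded from
every statistic (fraction denominators, bout boundaries).

## Stimulus protocol and phases

A protocol is `pre_duration`, then `repeats` cycles of
`stim_duration` + `isi`, with base/stimulus temperatures and the
cultivation temperature T_C carried as metadata. The default is the
canonical noxious-heat protocol: 50 s baseline, then 5 × (20 s at 33 °C +
30 s ISI at 23 °C), 300 s total. Phase windows are P = [0, pre), then
alternating H_i / L_i; the plate's ~10 s heating ramp is counted inside the
H window (heating phases are treated as full-temperature blocks). An empty
pre-phase is omitted.

## Registration

Rigid per-volume translation is estimated by upsampled cross-correlation
(the single-step DFT algorithm, via scikit-image), refined to 1/upsample
voxel around the coarse correlation peak; the default upsample of 20 gives
0.05-voxel resolution. Shifts are estimated on the reference channel —
which carries no activity transients by construction — and the same shift
is applied to both channels by Fourier interpolation (circular boundaries;
an optional edge crop discards wrap-around). Rotation and deformation are
not modeled: the imaged preparation is paralyzed, so residual motion is
translational wobble. Registration is per-volume (one 3D shift per time
point) rather than per-slice: a rigid preparation gives no reason for
slices of one volume to move independently.

## Deconvolution

Richardson–Lucy with the standard multiplicative update
`u ← u · (K̃ ∗ (v / (K ∗ u)))`, using mirrored-boundary convolution so that
flux is conserved (within 1% for blobs away from edges) and iterates remain
non-negative; `iterations=0` returns the input. The PSF is either an
explicit unit-sum kernel with odd extents or a parametric 3D Gaussian
(default σ = (1.0, 0.8, 0.8) voxels). Richardson–Lucy was chosen because it
is well-defined, testable, and the standard iterative deconvolution for
wide-field stacks; the stage is optional (`deconvolve: false` by default).

## GVF detection and tracking

The gradient vector field is the diffusion of the smoothed intensity
gradient: `f` = Gaussian-smoothed volume (σ = 1 voxel) rescaled to [0, 1]
(making the field invariant to global intensity scaling), and

    v ← v + dt · [ μ ∇²v − (v − ∇f) |∇f|² ]

iterated `n_iter` times. Defaults: μ = 0.2, dt = 0.5, n_iter = 80; 3D
stability requires dt·μ ≤ 1/6. Nuclei are bright blobs, so intensity ascent
finds centers directly (no edge map is needed). Anisotropic voxels scale
each gradient component by 1/voxel_size.

**Detection.** Every voxel is advected along the field in fixed 0.5-voxel
steps (≤ 200 steps, stopping where the local field magnitude < 1e-3);
convergence points are binned at half-voxel resolution and greedily
clustered (largest basin first) within `merge_radius` (default 2 voxels).
A cluster becomes a nucleus center (mean of its convergence points,
subvoxel) if (a) its basin holds ≥ `min_basin` source voxels (default 30)
and (b) the smoothed intensity at the center reaches ≥ 10% of the volume's
99.9th-percentile intensity. The intensity floor matters: flow stalls on
the dark saddle lines between neighboring nuclei, producing well-populated
but dark spurious clusters. The basin sizes of accepted plus rejected
clusters always partition the advected voxels.

**Tracking.** For each neuron and each next frame, the GVF is recomputed
inside a crop of half-size (3, 7, 7) voxels (z, y, x) around the previous
center and the center is advected to its local sink. A track is marked
`lost` when the sink moves more than `max_step` (default 4 voxels/frame) or
its local intensity falls below a robust background ceiling
(median + 5 × 1.4826 × MAD of the frame). When two tracks approach within
`merge_radius`, the one with lower mean intensity over the previous 5
frames is flagged `merged`. Lost and merged tracks are frozen, not
re-seeded. The whole detect-and-track stage is deterministic.

## Trace extraction and screening

The per-frame ratio is mean(G)/mean(R) over a spherical mask (physical
radius = `mask_radius` × the x-voxel pitch, default 2 voxels) centered on
the tracked position; frames that are not `tracked`, or whose reference
mean falls below a floor, are missing. Traces are normalized to their
time-series minimum (the transient baseline; idempotent), linearly
interpolated onto a common time base, and averaged pointwise with
SE = sd/√n (SE = 0 by convention where only one trace contributes, with the
coverage count recorded). Averages are computed on min-normalized ratios —
normalizing first keeps every worm's baseline at 1 so the average reflects
transient shape, not expression level — and the choice is recorded in the
output metadata.

Screening correlates each trace (Pearson; missing values pairwise-excluded;
≥ 50% of points must be defined) with the stimulus boxcar (1 during heat).
`r ≥ +0.5` → positive, `r ≤ −0.5` → negative, otherwise uncorrelated; a
fixed, configurable threshold makes the screen reproducible where visual
classification would not be. Per-cycle amplitude
A_i = max(trace in H_i) − median(trace in the 10 s before H_i), and the
adaptation index is (A₁ − A_last)/A₁ for A₁ > 0. Correlation-sorted
orderings (for heat-map display) sort descending by r, undefined
correlations last, ties by neuron id.

## Ethogram statistics

**Transitions.** Runs of identical labels shorter than `min_bout` frames
(default 2) are absorbed into the preceding bout — manual frame labeling
implies smoothing that is made explicit here. Each boundary between
surviving bouts emits an event carrying the full duration of the preceding
bout; durations are *not* truncated at phase boundaries, and the event
belongs to the phase containing the transition instant. Consequently the
harmonic-mean rate in a phase right after a quiet phase is pulled down by
long bouts that began earlier — visible in the README example, where the
measured heat-phase rate sits below the generator's instantaneous rate.
Bouts adjacent to `unknown` frames emit no event at that boundary.

**Rates.** The per-event rate is 1/d; the phase rate is the harmonic mean
of event rates, identically n/Σd. Its SD is the leave-one-out jackknife
√[(n−1)/n · Σ(θ₍ᵢ₎ − θ̄)²]; undefined for n = 1. An empty event set yields a
*missing* rate, distinct from zero: no opportunity to transition is not
evidence of a zero rate. Behavior-network graphs omit zero-rate edges and
draw edge widths proportional to rates.

**Uncertainty.** Confidence intervals are bias-corrected (BC, not BCa — no
acceleration term) percentile bootstrap intervals with B = 1000 resamples:
z₀ = Φ⁻¹(#{θ* < θ̂}/B), endpoints at the Φ(2z₀ ± z₍₁₊ℓ₎/₂) quantiles of the
bootstrap distribution. The resampling unit is the worm for fractions and
the transition event for rates (both defaults are explicit arguments). The
default level is 0.834 because two equal-SE 83.4% intervals that just touch
correspond to a two-sided z-test p ≈ 0.05 — exactly,
p = 2Φ(−√2·z₀.₉₁₇) = 0.0501 (83.4% is the conventional rounding of the
83.41% level that gives p = 0.05 exactly). Every bootstrap takes an
explicit seed; there is no hidden random state. The measured coverage of
this BC interval for a normal mean at n = 50 is about 82% — the mild
undercoverage of percentile-type intervals at moderate n.

**Comparisons.** Group-versus-control uses the two-sided Mann–Whitney test
(exact null distribution for tie-free samples with min(n, m) ≤ 8,
tie-corrected normal approximation otherwise), star-coded at 0.05 / 0.01 /
0.001, alongside per-group bootstrap CIs and a CI-non-overlap flag. No
multiple-testing correction is applied across the comparison family, by
design. Post-stimulus reversal responses are quantified as the duration of
the first reversal bout *starting* within 3 s of the stimulus (an ongoing
reversal does not count), measured to its natural end.

## Synthetic generators

**Imaging.** Nuclei are isotropic 3D Gaussian blobs (σ = radius/2,
truncated at 3σ; default radius 2.5 voxels) with peak baselines of 1000
counts per channel — realistic EMCCD photon counts for a bright nucleus.
The G channel is modulated by the neuron's true ratio trace; R is constant
at the identical position. Traces follow
`1 + sign·gain·γ^cycle·k(t)`, where k(t) rises as a saturating exponential
(τ_on = 2 s) during heat and decays exponentially (τ_off = 5 s) after;
γ ∈ (0, 1] is the per-cycle adaptation factor. The four response classes
are positively correlated adapting responders, negatively correlated
non-adapting responders, neurons with smooth stimulus-independent
fluctuations (low-pass-filtered noise, 5 s timescale), and silent neurons;
the default screen holds 5 of each on a grid with 10-voxel margins in an
8×64×64 volume. These kinetic constants are plausible for nuclear calcium
indicators but are placeholders, not measured values. Rigid drift is a
smoothed, mean-reverting random walk (per-axis step σ = (0.1, 0.5, 0.5)
voxels, single-frame steps capped at 2 voxels, excursions capped at 6): a
paralyzed, stage-tracked preparation wobbles about a fixed position rather
than wandering, and a free random walk would exit any finite volume over a
600-frame protocol. Both channels are blurred by a Gaussian PSF
(σ = (1.0, 0.8, 0.8)), then mean-preserving Gaussian shot noise
(variance = mean above a 10-count floor; a Gaussian stand-in for Poisson,
accurate at these counts and much faster) and 2-count read noise are added.
The generator returns exact ground truth (per-frame centers, true traces,
drift, class labels); with noise and drift disabled, extracting the ratio
at the true centers reproduces the true traces to numerical precision.

Not emulated: worm-body deformation, optical aberrations, bleaching,
indicator kinetics beyond the single-exponential kernel, and nucleus
crowding beyond partial blob overlap. Passing tests therefore demonstrate
correctness of the algorithms under rigid motion and realistic counting
noise, not robustness to non-rigid tissue motion.

**Behavior.** Ethograms are sampled from a 4-state continuous-time Markov
chain whose off-diagonal rate matrix switches with the stimulation phase
(pre/heat/interval). Event times are drawn Gillespie-style; at a phase
boundary the waiting time is simply re-drawn under the new rates, which is
exact by memorylessness. Each frame takes the state occupied at its
midpoint — the simplest deterministic discretization. The default chain is
mostly-forward at baseline with the forward→reversal rate boosted 10-fold
during heat (the avoidance response); true rate matrices are returned
alongside the ethograms. Real worm behavior has non-exponential bout
distributions and history dependence (e.g. habituation within a phase);
the CTMC is a stand-in with known ground truth, not a behavioral model.

## Problem sizes in the test suite

The suite exercises the default study conditions at desk scale: the
tracking benchmark uses the 20-nucleus default volume over 100 frames; the
screening benchmark uses the full 600-frame default protocol; bootstrap
coverage uses 6000 Monte-Carlo replicates of n = 50 with B = 1000 (the
acceptance script uses the canonical 2000 replicates); CTMC rate recovery
uses 100 replicate runs of ~250 events each. Seeds are fixed throughout;
every stochastic routine takes its generator explicitly.

## Known limitations

- Rigid-translation registration only; freely behaving recordings are out
  of scope.
- Neurons appearing after the first frame are never seeded; lost tracks are
  not recovered.
- Anatomical identity assignment (which neuron is AFD, AWC, …) requires
  marker lines and manual inspection and is not attempted here.
- The screen's boxcar correlation is blind to response latency and shape;
  strongly adapting responders correlate only moderately (r ≈ 0.55 under
  default conditions) and sit closer to the 0.5 threshold than
  non-adapting ones.
- BC intervals mildly undercover at small n (see above); BCa with an
  acceleration estimate was deliberately not used because the upstream
  procedure specifies bias correction only.
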