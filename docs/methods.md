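# Methods

This note documents the model equations, the parameter choices and their
rationale, the numerical conventions, and the design decisions taken where
the underlying physiology leaves the implementation open.  It also states
precisely what the synthetic populations emulate and therefore what the
passing tests do — and do not — demonstrate about real recordings.

## Stimulus

The joint-angle variable is the Sc-Pd joint angle in degrees, dorsal
positive.  `build_staircase` produces, per trial, five holds at the plateau
sequence −E, 0, +E, 0, −E (default E = 50°) joined by four constant-velocity
ramps (two up, two down), so each trial is symmetric in space and time.
Traces are sampled at the mid-points of uniform Δt bins (Δt = 1 ms, shared by
every downstream filter and by the spike generator), which makes a trial an
exact palindrome and keeps each ramp's sampled slope exactly ±v.

*Hold duration* is not constrained by physiology here; the generic default is
1 s.  The selectivity/coding-space analysis protocol (`run_population`) uses
2-s holds: tonic hold rates are then well estimated at every velocity, and
the band-pass carry-over at hold onsets (below) is diluted enough that the
motion scores of movement-type neurons retain their contrast.  Trials per
velocity default to 4 (configurable 2–8, the plausible experimental range);
the analysis of the synthetic reference sample uses 8 to stabilise the very
low-rate position-sensitive models' scores, while modelled parameter sweeps
keep n = 4.

`segment_intervals` labels each sample as ramp (up/down, lower/upper
half-range) or hold (ventral/rest/dorsal) from finite differences: a sample
is a ramp sample when both its forward and backward difference exceed the
slope tolerance (0.5 °/s, below the slowest protocol velocity of 1 °/s) with
a common sign.  This assigns breakpoint-straddling samples to the hold side,
so the labelled ramp length is exact on generated traces.  Non-constant
slopes within a ramp run raise `SegmentationError` — the segmentation is
defined only for piecewise-linear protocols.

## Hair-field afferents

Two rows of 20 hairs flank the joint; hair i starts deflecting at onset
angle 2.5°·i on its side and follows the joint with slope 1 up to a
saturation of 50° (the full half-range).  Only the onset spacing and slope
are physiologically anchored; the saturation angle is unknown.  50° keeps
only the most proximal hair saturable, which preserves a strong tonic
population signal (required by the simple position-sensitive DINs) at the
cost of a synchronised deflection stop at ramp ends; smaller saturation
values were examined and rejected because they weaken the tonic signal
without removing the stop transient at fast ramps.

Afferent activation is the lead-lag form

    act = (w_l · LPF_τl[x] + w_h · HPF_τh[x] − offset) / norm

with τl = 10 ms, w_l = 2, τh = 30 ms, w_h = 20, offset = 35, norm = 100.  The
offset is subtracted *before* the normalisation; the alternative order
(normalise, then subtract 35) makes the activation permanently negative and
the model silent, so it is not viable with these constants.  At full tonic
deflection act = (2·50 − 35)/100 = 0.65; a 100 °/s ramp adds ≈ 20·0.03·100 /
100 = 0.60 of phasic drive.

Filters are discrete first-order exponential integrators, y[k] = y[k−1] +
(1 − e^(−Δt/τ))(x[k] − y[k−1]); the high-pass is the complement x − LPF[x].
All filters (and the spike-count integrator below) start at the steady state
for their first input sample, so a protocol that begins mid-hold starts
transient-free.

The spike generator emits a spike in a step when act·Δt·Rmax ≥ rand
(uniform on [0, 1]); probabilities are capped at 1, negative activation
yields none, and an absolute refractory period of 3 ms blocks spikes until
more than 3 ms have elapsed since the last one.  For constant activation a
the stationary rate is 1 / (refractory + Δt / min(1, a·Δt·Rmax)); at a = 1,
Rmax = 300 s⁻¹ this gives 300 Hz without and ≈ 158 Hz with the refractory
period.  Per-afferent random streams are spawned from one master seed in row
order then hair order, which makes mirrored stimuli with swapped rows
reproduce bit-identical, side-swapped output.

## DIN models

All variants share: per-row spike integration (each afferent spike adds a
unit impulse to a 5-ms leaky integrator — mean input ≈ k·r·τ for k afferents
at rate r), per-row gains W_d/W_v, summation.  The direct branch (SP types)
divides the input by its normalisation (4) and spikes at Rmax = 10 s⁻¹.  The
band-pass branch computes b = 20·HPF₄₀ₘₛ[2·LPF₅₀ₘₛ[input]] — a *series*
cascade with multiplied weights.  A parallel lead-lag (as in the afferents)
has DC gain 2 and would make movement-type DINs fire tonically during the
extreme holds, which contradicts their defining hold-phase silence given the
printed offsets; the series cascade has zero DC gain and extracts transients
only.  After rectification (none for ExDP, |·| for ON/DP, −|·| for OFF) the
output is divided by the normalisation and shifted by the offset.  The OFF
relation act = 1 − |b|/40 is exactly the ON drive inverted, halved (norm 40
vs 20) and riding on a baseline of 1, hence a 30-Hz resting rate at
Rmax = 30.  DIN spike generation has no refractory period — none is
described for these neurons, and Rmax already caps their rates.

**Mean-field afferent drive.**  By default `simulate_din` (and everything
downstream) drives the DIN with each afferent's *expected* spike count per
step — the stationary renewal rate of the generator evaluated on the
afferent's activation — rather than a single stochastic spike realisation.
The band-pass weights amplify the shot noise of 40 independent afferents so
strongly (σ_b ≈ 14 during tonic extreme holds, versus a ramp signal of ≈ 9
at 40 °/s) that with sampled spikes every movement-type DIN fires during
holds at a large fraction of its ramp rate, at any hair-saturation value;
the printed offsets and normalisations are only consistent with a low-noise
input regime.  The mean-field drive represents the massed convergence this
two-row model abstracts (the real joint carries four hair fields, and each
model "hair" stands for several afferents); the stochastic path remains
available via `drive="spikes"` and `integrate_afferent_input`.

One mechanistic point carried over from the spiking picture: velocity
sensitivity arises because faster ramps recruit hairs at shorter intervals,
so the summed input rises faster and the band-pass output grows ∝ velocity —
recruitment dynamics, not any velocity-tuned element.

A genuine consequence of the architecture is the *hold-onset transient*: at
the end of each ramp the afferents' phasic component decays (τ ≈ 30 ms),
the band-pass differentiates that decay, and full-wave rectification turns
it into excitation lasting ~0.2–0.3 s into the hold.  Steady-state hold
activation is exactly the offset (≤ 0 for ON/DP/ExDP), so hold-phase rate
tests measure the steady part of holds (first 0.5 s after a ramp excluded).

`velocity_tuning` reports mean rates over the ramp windows for every type.
For the OFF type a whole-trial window is also available, but it is not
monotone in velocity by construction: once suppression saturates
(|b|/40 > 1 throughout the ramp) the suppressed spike deficit stops growing
while the trial shortens, so the whole-trial rate flattens and recovers
slightly beyond ≈150 °/s.  The ramp-window OFF rate falls from near the
30-Hz baseline at 12 °/s towards zero at 400 °/s.

## Selectivity scores

s = (A − B)/(A + B) of mean spike rates (averaged across trials before
scoring); zero with a cleared validity flag when both rates are zero.
Interval sets: direction — up ramps vs down ramps; position — upper-half
ramps + dorsal hold vs lower-half ramps + post-ramp ventral hold; motion —
all ramps vs holds.  The *settling hold* at the start of each trial (the
ventral hold no ramp precedes) is excluded from every set.  This exclusion
matters twice over: (i) with it included, the lower/position set spans twice
the hold time of the upper set, and a perfectly symmetric movement-sensitive
neuron scores position h/(4+3h) → +1/3 with hold duration h — a pure
protocol artifact; (ii) ventral-preferring neurons would fire during one
more hold than their dorsal mirror images, systematically coupling the sign
of the position scores to the motion scores.  With the exclusion the
analysis is exactly dorsoventrally symmetric and duration-matched.

Sign conventions: levation (upward) positive for direction, dorsal positive
for position, movement positive for motion.  The four analysis velocities
default to 12, 50, 150, 400 °/s — the working range of the protocol; the
characterisation refuses velocities outside [12, 400].

## Coding-space

Covariance PCA (centred, unscaled columns — all twelve share the [−1, 1]
selectivity scale) of the neurons × 12 matrix; Kaiser-Guttman retention
keeps PCs whose variance fraction exceeds 1/12.  Orientation is
canonicalised: PC1 is flipped so movement-selective neurons project to the
negative side (a movement-indifferent neuron lands in the right half-plane),
PC2 so dorsal position selectivity is positive, and the remaining PCs so
their largest-magnitude loading is positive — making the fit deterministic.
Both the signed PC2 and |PC2| are reported; the fold-over treats dorsal- and
ventral-preferring neurons as equally *posture-sensitive*.

Classification uses two axis-aligned thresholds fitted by the max-gap
midpoint (max-accuracy split with a warning when groups overlap): the
posture threshold on |PC2| splits SP/DP from ON/OFF, the movement threshold
on PC1 splits ON/DP from OFF/SP.  `resample_variance` repeats the fit on
bootstrap draws of 50 or on balanced 6-per-group subsamples, skipping and
counting degenerate draws.

## Synthetic populations

`build_sweep_population` encodes the single-parameter model sweeps: ON
offsets (−0.2, −0.1, 0, 0.05, 0.01), OFF normalisations 40/d for divisors
(0.1, 0.4, 0.7, 1.3) — the most sensitive OFF norm, 40/1.3 ≈ 30.8, stays
≈1.5× the ON norm — and dorsal-major weight proportions 1:0 … 1:0.8 for SP
and DP, plus one input-less DIN firing at a constant ≈20 Hz.  The ExDP
variant is excluded from coding-space sweeps because the three scores cannot
distinguish it from other DP types.

`build_reference_population` is a synthetic stand-in for a recorded DIN
sample (five groups × 15).  Its members scatter along the same parameter
axes as the sweeps, with three deliberate structural properties:

* **stratified draws** — member i occupies stratum i of its group's span,
  so every realisation covers the group's full spread and the variance
  structure of the matrix (hence the PC identities) is stable across seeds;
* **mirrored dorsal/ventral twins** in SP/DP (shared ratio and jitter), so
  the signed position scores are symmetric by construction and contribute no
  sample covariance with the motion scores.  PC1 (~0.54 of variance) and
  PC2 (~0.36) are close enough that such covariance would rotate them into
  each other, which is also why near-boundary subsamples can swap PC order —
  an instability intrinsic to this analysis;
* **weight ratios in [0.15, 0.8]**: the empirically grouped
  position-sensitive types are selected for clear position selectivity, and
  single-field (1:0) models sit at the top edge of their clusters; extending
  the reference to ratio 0 would let the signed position+direction variance
  block overtake the motion block and destabilise the axes.  (Low-ratio SP
  models are also strongly direction-selective — phasic afferents fire far
  more during hair loading than release — so position and direction flip
  sign together and pool into one "side" variance block.)

The UNSP group (high background, few extra spikes during fast movement) is a
weak-gain, high-offset band-pass neuron.  All neurons of a run listen to one
shared simulated periphery per velocity, as the biological DINs do.

**What this shows and does not show.**  With this construction the pipeline
reproduces, on synthetic data, the qualitative structure reported for real
DIN samples: two retained PCs with motion-dominated PC1 and
position-dominated PC2, ≥95 % linear-threshold classification of the four
major groups, graded sweep trajectories (monotone PC1 along the OFF 1/norm
sweep and along the non-negative ON offsets — the full ON trajectory is
curved, since negative offsets change *which* responses survive rather than
the hold/ramp balance), and co-localisation of swept models with their
reference clusters.  None of this validates the model against actual
recordings: the reference population is built from the model itself, so
these are consistency and construct-validity checks of the analysis chain,
not an empirical test.

## Problem sizes and numerics

The default analysis uses 4 velocities × (4 or 8) trials per neuron; one
hair-field simulation per velocity is shared population-wide, so a full
reference-plus-sweeps run (95 neurons) completes in a few seconds.  Spike
times live at bin mid-points (k + ½)Δt.  The hull-containment comparison of
sweeps versus reference clusters dilates each group's convex hull by 20 % of
its diameter plus 0.15 PC units (≈2 σ of a single 4-trial projection for the
low-rate types); the SP 1:0 endpoint is checked against the cluster's
movement span and posture edge, which it probes by construction.

## Known limitations

* All sensilla share one parameter set; real hair fields contain afferents
  with heterogeneous dynamics.
* The mean-field afferent drive removes afferent-population noise from the
  DIN input; correlated afferent fluctuations and their possible role in DIN
  variability are not modelled.
* Campaniform sensilla, chordotonal organs, the head-scape joint, and active
  (self-generated) antennal movement are out of scope; so are the few-fast
  and unspecific DIN types as explicit models (the latter only appears as a
  reference-population stand-in).
* The spike generator reproduces mean rates, not fine temporal statistics;
  real SP-type DINs fire more regularly than a Bernoulli generator.
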