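# Methods

## Scope and model of the data

`spikemap` sorts dense extracellular recordings from square multielectrode
grids (the reference geometry is 64×64 electrodes at 42 µm pitch sampled at
18 kHz; all sizes are parameters). The signal model is the standard one for
in-vitro cortical preparations: each neuron contributes a stereotyped
biphasic waveform — a dominant negative trough, largest near the soma / axon
initial segment, followed by a positive rebound — whose amplitude decays
with distance from the soma; many neurons superimpose linearly on a Gaussian
background. The pipeline is fully unsupervised: no template libraries and no
manual curation.

## Preprocessing

* **Bandpass.** Second-order Butterworth, 300–5000 Hz, applied
  forward–backward (`sosfiltfilt`). Zero-phase filtering is a deliberate
  choice: it leaves trough times unshifted so that snippets cut from the raw
  trace align with detections on the filtered trace. The effective magnitude
  response is the squared order-2 response.
* **Artifacts.** Samples with |v| strictly above 500 µV are replaced by the
  mean of the channel's *non-flagged* samples (the mean over everything
  would be biased by the artifacts being removed). Channels flagged
  everywhere are carried as dead, never dropped, so geometry indexing stays
  stable.
* **Detection threshold.** Per channel, −x·σ̂ with x = 4.5 by default.
  σ̂ comes from a least-squares Gaussian fit to the voltage histogram
  (Freedman–Diaconis bins) restricted to |v| ≤ 3·σ_MAD; the restriction
  stops spike tails from inflating the noise estimate, and the fit falls
  back to the MAD estimate if it fails to converge. Traces longer than
  2×10⁵ samples are strided down before the fit — the SD estimate is
  unaffected and the cost becomes independent of recording length.

## Detection and waveforms

Events are local minima of the filtered trace below threshold. An absolute
refractory rule discards successive events closer than 2 ms, keeping the
earliest by default (`keep="deepest"` is available; which member the
original procedure kept is not determinable, so both are exposed). When a
photostimulation protocol is present, detections within 5 ms after a pulse
onset are dropped — light pulses saturate the amplifiers for roughly that
long. Snippets of −5…+5 ms (181 samples at 18 kHz, inclusive endpoints) are
cut from the **unfiltered** trace, trough-aligned, so spike shape is not
distorted by the bandpass.

Cluster SNR is |trough of the mean waveform| divided by the SD of the
residuals (waveforms − mean) pooled over samples; identical waveforms give
an `inf` sentinel.

## Unit isolation

Per channel: PCA (2 components by default) → k-means (k = 2 by default, 10
restarts, seeded; `k="auto"` maximizes the Calinski–Harabasz index over
k ∈ [2, 6]) → tenfold stratified cross-validated LDA error for every cluster
pair, equal-covariance assumption. Chance is 0.5. Pairs with CV error ≥ 0.4
are statistically inseparable and merged (`inseparable_merged`); separable
pairs stay distinct units. The merge direction deserves a note: LDA is used
here as a *separability score*, so near-chance error means "one neuron" and
low error means "two" — this is the only reading consistent with the
purpose of the step.

Channels with fewer than 20 spikes are not clustered; they contribute a
single unvalidated unit carrying a `low_count` flag (with fewer spikes than
that, neither the SNR nor the LDA statistic is meaningful, so such units are
recorded but not accepted). Accepted units must also clear a minimum firing
rate (0.02 Hz) and minimum SNR (4 — the SNR distribution of sorted clusters
is broad and the cutoff is exposed as a parameter).

**Known limitation.** k-means with fixed k = 2 always produces a split, and
LDA evaluated on k-means labels is biased toward separability (the labels
are linearly separable by construction), so a channel carrying one strong
unit is often reported as two accepted units with nearly identical
waveforms. The merge rule catches truly overlapping clouds but not this
oversplit. Ground-truth matching (below) is therefore done by soma
position, not by unit count, and recovery statistics count matched
ground-truth cells.

## Localization

For each accepted unit the spatial footprint — the spike-triggered average
of the raw trace on every channel within 250 µm — is computed, and the soma
channel is the one with the deepest mean-waveform trough (the largest
negative deflection arises nearest the soma/AIS). Sub-pitch position comes
from the center of mass of the 3×3 patch of |trough| amplitudes around the
soma channel,

    r = Σᵢⱼ i·aᵢⱼ / Σᵢⱼ aᵢⱼ,   c = Σᵢⱼ j·aᵢⱼ / Σᵢⱼ aᵢⱼ,

with off-array neighbors weighted 0 and positive-only waveforms weighted 0
(weights must be non-negative). Per-spike centers of mass (single-spike
trough amplitudes on the same patch, up to 500 spikes) quantify
localization scatter.

Two screening rules follow:

* **Amplitude decay.** OLS of |trough| vs distance over the footprint; a
  positive slope means the signal grows away from its supposed soma —
  physically implausible for a somatic unit — and flags `increasing_decay`.
* **Duplicates.** (i) *Far-field consolidation*: a unit whose soma channel
  differs from its detection channel is a far-field image; if the soma
  channel hosts its own somatic unit the image is flagged `duplicate`
  (images that are a cell's only representation are kept). (ii)
  *Correlation*: for pairs of units whose homes lie within 250 µm, Pearson
  correlation of 100 ms non-overlapping spike counts above 0.5 flags the
  smaller-|trough| member (the larger-amplitude unit is nearest the soma).
  The 0.5 threshold is a package choice — the correlation cutoff is
  user-defined in this method family. At most one member of a pair is ever
  flagged.

## Cell typing

The accepted unit's mean raw waveform is resampled by a natural cubic
spline at 90 kHz (5× the native rate; exact at the knots). Two time
constants are measured:

* **FW** — full width of the trough at half-maximum. The reference level is
  the mean of the first 2 ms of the window (the method family does not
  define a baseline; the pre-trough window is flat for any plausible spike),
  the half level is (baseline + trough)/2, and the crossing times flanking
  the trough are linearly interpolated on the fine grid.
* **PP** — time from the trough to the largest subsequent positive peak.
  A unit with no rebound distinguishable from interpolation ringing
  (relative tolerance 10⁻⁹ of the trough depth) has PP undefined and is
  excluded from typing.

Both are invariant to amplitude scaling and constant offsets by
construction. Units are clustered by k-means on z-scored (FW, PP) — the
standardization keeps either duration from dominating — with k chosen by
the Calinski–Harabasz criterion by default (a fixed k can be supplied; with
a rare fast-spiking class and fixed k = 2, k-means may prefer splitting the
broad majority over isolating the few narrow outliers, which inverts the
labels — CH selection avoids this by allowing enough clusters for the
narrow group to separate) — and the single
cluster whose centroid has the smallest standardized FW + PP sum is labeled
I; all other clusters pool to E (for k > 2 exactly one cluster stays I,
matching the expectation of a single fast-spiking class). Note the scheme
always names a fastest cluster I: on a population with no genuinely
fast-spiking cells it will still split off the relatively fastest units, so
labels are only meaningful when both classes are plausibly present.

Supporting statistics: Fano factor of non-overlapping bin counts (unbiased
variance / mean; bins 10–1000 ms), mean pairwise spike-count correlation
versus electrode distance (100 ms bins, 42 µm distance bins), and
Hartigan's dip test on the inter-spike-interval distribution. The dip
statistic is implemented in-package (the classical greatest-convex-minorant
/ least-concave-majorant algorithm, verified against its exact values: 0.25
for two equal point masses, 1/(2n) for evenly spaced data) and calibrated by
bootstrap against the U(0,1) null, the asymptotically least favorable
unimodal distribution; p < 0.05 flags bursting. A log-ISI variant is
available.

## Optogenetic validation

A protocol is an ordered list of labeled epochs (baseline / opto-on /
opto-off / …) plus 100 ms light-pulse onsets. Each unit's response is the
z-score of its firing rate in the response epoch (default: whole opto-on
epoch; a post-pulse window mode exists) relative to the mean and SD of its
baseline rate measured in non-overlapping 1 s bins — the baseline bin size
is a package choice, exposed as a parameter. z > 3 labels a responder; a
zero baseline SD gives a NaN sentinel and "non-responder". PSTHs (counts
aligned to pulse onsets, averaged over pulses, scaled to Hz) and two-sided
Wilcoxon rank-sum comparisons between condition samples complete the stage.
Responder fractions per waveform-derived label summarize the validation.

## Synthetic ground truth

The simulator emulates the statistical structure of slice recordings, not
their biophysics: homogeneous Poisson firing with a 2 ms dead time
(piecewise-constant rates across protocol epochs; opsin-carrying narrow
units multiply their rate by `opto_gain`, default 5, during opto-on),
biphasic Gaussian-component templates with class-specific draws (narrow
trough width 0.1–0.2 ms and peak delay 0.3–0.6 ms; broad 0.3–0.6 ms and
0.8–1.5 ms — simulator conventions chosen so kinetics separate the
classes), exponential spatial decay exp(−d/λ) with λ = 30 µm (a linear mode
exists for decay-fit tests), i.i.d. Gaussian noise, and full-array
saturation for 5 ms after each light pulse.

Default study conditions: 16×16 grid at 42 µm pitch (desk-scale; 64×64 is
supported), 18 kHz, 120 s, 20 units of which 10% are narrow, trough
amplitudes U(150, 250) µV over 10 µV noise (SNR 15–25), rates
U(0.5, 5) Hz. The amplitude floor is set so a soma anywhere within a pitch
cell stays above the 4.5σ threshold on its nearest channel
(150·e^(−29.7/30) ≈ 55 µV > 45 µV); somata keep ≥ 20 µm separation (a soma
diameter) and one pitch of border margin. Everything derives from one
`numpy` generator, so simulations are bit-reproducible from the seed.

What the simulator does **not** model — and hence what passing tests do not
show about real tissue: bursting and rate nonstationarity, electrode
impedance variation and ADC quantization, axonal propagation signatures,
overlapping-spike interactions beyond linear summation, drift, and
correlated network activity (a shared-drive construction is used only in
the correlation-vs-distance test).

## Validation studies and problem sizes

`spikemap.validation` packages three seeded studies, used by the test suite
and by `scripts/acceptance.py`:

* **LDA chance level** — two n = 500 classes from one 2-D standard
  Gaussian, tenfold CV, 20 repetitions; the mean error estimates the 0.5
  chance level.
* **End-to-end recovery** — 10 seeds of the default 120 s simulation;
  accepted units are matched to ground truth greedily by soma position
  within one pitch. Reported: recovery fraction, fraction of matched units
  whose soma channel center is within one pitch of the true soma, and E/I
  label accuracy on matched units.
* **Opto responders** — 20 seeds of ground-truth trains under a 2 min
  baseline / 2 min opto-on protocol; responder rates for gained vs
  unmodulated units.

Fano calibration uses the mean FF across 20 seeds per bin duration: a
single 600 s train has only 600 one-second bins, so the per-seed FF
fluctuates by ≈ 0.06 SD and only the across-seed mean is a stable
calibration target.

## Numerical choices and degenerate inputs

Tie-breaks and sentinels are explicit throughout: refractory ties keep the
earliest event; zero residual SD → SNR `inf`; zero baseline SD → z NaN;
zero-variance count vectors skip correlation pairs; an all-zero COM matrix
is an error rather than a silent (0,0); degenerate (zero-variance) traces
raise at threshold estimation and the channel is skipped; classes smaller
than the fold count reduce the fold count with a warning. Units are µV and
seconds internally, with ms at API boundaries where the field convention is
ms.
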