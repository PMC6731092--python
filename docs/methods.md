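# Methods

This note documents the models and procedures implemented in `loopmapper`,
the assumptions behind them, and the choices made where the underlying
experimental workflow leaves the design open.

## In vivo response classification

### PSTH construction

Peri-stimulus time histograms use 1 ms half-open bins `[l, l+1 ms)` aligned
to laser onset at 0, so a spike exactly at onset falls in bin 0.  Per-bin
rate is the spike count summed over trials divided by `n_trials × bin_width`
(spikes/s).  The smoothed track is a discrete convolution with a unit-area
Gaussian kernel truncated at ±3σ with reflection (edge-including) padding;
this conserves total area to machine precision, so
`Σ raw_rate × bin_width × n_trials` always equals the in-window spike count.

The kernel width is configurable with default **σ = 2 ms**: wide enough to
suppress single-bin counting noise, narrow enough to preserve millisecond
latency resolution.  The baseline window is configurable with default
**[−1 s, 0)** per trial — the 4 s inter-stimulation interval leaves ample
unstimulated time before each onset.

### Baseline SD: raw bins, not smoothed bins

The classifier thresholds are `mean + k_up·SD` for excitation (default
`k_up = 3`) and `max(mean − k_down·SD, 0)` for inhibition (default
`k_down = 1`), scanned on the smoothed track from onset.  The **SD is
measured on the raw 1 ms baseline bins** (population SD); the mean on the
smoothed track.  This is a deliberate and load-bearing choice:

* The smoothed track's SD shrinks with kernel width (≈ 0.37× the raw SD at
  σ = 2 ms).  A `mean − 1·SD_smoothed` inhibition threshold then sits only
  one noise-SD below the track it is scanned on, and a perfectly stationary
  Poisson unit dips below it roughly every 5–10 kernel widths.  Measured on
  simulated stationary units (10 spikes/s, 30 trials), that design labels
  ~50% of null units "responsive" and, worse, destroys genuine excited units
  by finding spurious early inhibition first.  With raw-bin SD the same null
  cohort yields 0% false positives.
* Raw-bin SD equals `sqrt(rate / (n_trials × bin_width))` in expectation,
  which exceeds the mean rate whenever the rate is below
  `1/(n_trials × bin_width)` ≈ 33 spikes/s at 30 trials × 1 ms.  The
  inhibition threshold is then floored at 0 and inhibition is structurally
  undetectable for typical cortical spontaneous rates — consistent with the
  overwhelming predominance of excited over inhibited units this class of
  experiment reports.  Units with zero baseline SD are flagged
  unclassifiable and counted as unresponsive.

A `sd_track="smoothed"` switch retains the alternative for comparison.

### Latency and categorization

Latency is the left edge of the first smoothed bin beyond either threshold
within the stimulation period.  A unit is positive/negative only if that
latency falls in the acceptance window (default **5–35 ms**, half-open);
crossings *before* 5 ms mark potential antidromic activation and render the
unit unresponsive — they are not skipped over.  When crossings tie,
excitation wins (disinhibition of the thalamo-cortical pathway predicts
excitation).  A single smoothed-bin crossing suffices; the kernel already
integrates adjacent bins.  `window_sensitivity` re-runs the identical scan
under nested windows (5–15, 5–25, 5–35, 5–45 ms); responsive counts are
non-decreasing by construction.  Latency histograms use the raw first
crossing with the window restriction disabled.

Known limitation: with the excitation threshold ≈ `rate + 3·SD_raw`, the
crossing sits high on the rising edge of the evoked response.  For an
80 spikes/s step on a 10 spikes/s baseline this places the threshold ~1.2
evoked-noise SDs below the evoked plateau, so the crossing time carries a
positive skew: the median detected latency is ~1–1.5 ms after the true
onset, and roughly 5–10% of units cross more than 4 ms late at 30 trials.
This is intrinsic to first-crossing detection with a stringent threshold,
not a tunable defect; more trials or a larger evoked rate sharpen it.

## Synthetic spike trains

Units are simulated as inhomogeneous Poisson processes by thinning
(Lewis–Shedler acceptance sampling), exact for the piecewise-constant rate
functions used here: baseline everywhere except
`[onset + latency, onset + latency + duration]` within each trial's
stimulation period, where the rate is `baseline ± delta` floored at zero
(rates cannot be negative).  The default protocol is the standard one:
1 s stimulation (constant, or 5/20 Hz 10 ms pulses), 30 trials, 4 s
inter-stimulation interval.  The default spontaneous rate is 5 spikes/s, a
typical cortical value.  One master seed fans out to per-unit child seeds
via `SeedSequence` spawn keys, so adding units to a cohort never perturbs
earlier ones and every generator is bit-reproducible for a fixed seed.

The generator emulates stationarity, Poisson count statistics, and a
step-shaped evoked rate.  It does **not** emulate refractoriness, bursting,
slow rate drift, pulse-locked responses within pulsed trains, or
unit-to-unit correlation; passing tests therefore validate the analysis
pipeline's arithmetic and decision rules, not its robustness to every
departure from Poisson firing found in vivo.

## Slice IPSC measurement

Sweeps are synthesized as peak-normalized difference-of-exponentials IPSCs
(defaults τ_rise 1.5 ms, τ_decay 12 ms, 10 kHz sampling as in the recording
protocol, inward polarity), with the second response (amplitude
`a1 × PPR`) superposed linearly on the decay of the first at a 50 ms
inter-pulse interval, plus white noise (default SD 2 pA).

Measurement: baseline and noise SD come from the pre-pulse-1 window.  The
first amplitude is the extremum of the baseline-subtracted current within
20 ms of pulse 1; polarity is auto-detected from the larger deflection, and
amplitudes are reported as positive magnitudes.  To avoid the upward bias a
raw single-sample extremum acquires from noise, the peak sample is located
on a lightly smoothed (~0.5 ms boxcar) copy and the amplitude is the mean of
raw samples within ±0.3 ms of it.  Because at 50 ms the first IPSC has not
fully decayed for slow τ, the second amplitude is measured against the
*projected decay*: a single exponential fitted to the 10 ms preceding pulse
2 and extrapolated through the second response window (a
`local_baseline` switch substitutes constant subtraction).  Sweeps whose
first amplitude does not exceed 3× the baseline noise SD are reported as
non-responding, with no PPR.  PPR = a2/a1 exactly; it is invariant to gain
and to constant holding-current offsets.

## Anatomical quantification

Coordinates are mm from bregma (AP positive anterior, DV positive ventral
from dura); ML is stored hemisphere-collapsed (absolute), so bilateral data
must be pre-mirrored.  The atlas-drawn striatal outline is replaced by a
configurable partition of axis-aligned boxes; defaults implement the three
explicit border rules — TS begins at AP −0.8 mm (everything posterior is
TS), the ventral tier (VMS/VLS) extends anterior of AP +0.7 mm, and the
medial/lateral splits sit midway across the ventral and dorsal tiers.  The
dorsoventral boundary is never given numerically in the source workflow and
is a pure configuration parameter (default 3.2 mm).  Ties on shared
boundary planes resolve by region order: TS first, then medial before
lateral — a cell exactly on the midline is medial.  Points falling in no
region (e.g. deep posterior to the ventral tier's AP extent) are "outside".

ROI counting uses 600 µm-diameter circles in the coronal plane over three
adjacent 160 µm sections centered on the section nearest the ROI's AP
coordinate (rim-inclusive); the rat ROI centers from the source workflow
ship as defaults.  Normalized distributions are percentages of the
five-region total, by ROI counts (rat workflow) or whole-region assignment
(mouse workflow) — both are provided because the source counting procedure
is ambiguous between them.  Density maps split the cloud's AP extent into
eight equal rostro-caudal slabs and bin each slab's (ML, DV) projection into
160 µm square bins ("160 µm²" is read as 160 µm-side squares, matching the
section interval); bins are normalized to the densest bin on a log scale as
`log(1+count)/log(1+max)`, which handles empty bins and maps the densest
bin to 1.  SNr medial/lateral fractions normalize each cell's ML position by
its section's measured medial and lateral edges, assign divisions by
`floor(u·n)` (boundary → lateral), and average fractions over sections with
equal weight; out-of-range cells are clipped with a warning.  Luminance
profiles subtract background, clip at zero, and normalize to percentages.

## Statistics

* **Two-proportion z-test**, pooled, no continuity correction:
  `z = (p̂1 − p̂2)/√(p̂(1−p̂)(1/n1 + 1/n2))`.  The uncorrected pooled form is
  the one that reproduces all three published z statistics from their
  printed counts.
* **Unpaired Student's t-test** with pooled variance, from raw values or
  from printed `mean ± SEM, n` (SD recovered as `SEM·√n`), df = n1+n2−2.
  The pooled (not Welch) form is forced by the published df = 11 for
  n = 8 vs 5.  Both t and z are reported as absolute values with two-sided
  p-values, matching how the source reports them regardless of direction.
* **Two-way fixed-effects ANOVA** with interaction, Type III sums of squares
  on sum-coded contrasts by default (the GraphPad-style convention for the
  unbalanced 3-site × 5-region design with 3/4/4 animals, giving interaction
  df 8 and residual df 40); Types I and II are available.  Implemented over
  a statsmodels OLS fit; a hand-computed sums-of-squares decomposition
  serves as the independent oracle in the tests.  Note the design treats the
  per-animal region percentages as independent observations although they
  sum to 100 within an animal; this replicates the published analysis as
  printed.

## Problem sizes and tolerances

Validation cohorts use 200 positive units and 500 null units for classifier
calibration, 1000-point clouds for geometric oracle equivalence, 2000
replicates for type-I-error calibration, and 20 sweeps for noisy amplitude
recovery; the full suite runs in a few seconds.  Numerical tolerances:
smoothing area conservation 1e−9 relative; raw/summary t-test agreement
1e−12; PPR recovery ±0.01 on noise-free sweeps; statistical recoveries use
3×SEM or 3σ binomial/Poisson bands.
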