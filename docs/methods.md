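# Methods

## The measurement problem

Optogenetic motor mapping stimulates many points of the dorsal cortex of an
awake head-restrained mouse (here a 6 x 8 grid covering 3.9 x 5.0 mm of the
left hemisphere, aligned to Bregma) while filming both C2 whiskers at 500 Hz.
Each 1-s trial has a 500-ms prestimulus baseline followed by 500 ms of
stimulation. The analysis turns the per-trial bilateral angle traces into
per-mouse and cross-mouse motor maps, localizes the hotspots of the three
canonical response regions (wS1: contralateral retraction; wM1/wM2 and PtA:
bilateral rhythmic protraction), compares high and low laser power, and
overlays the motor map with intrinsic-imaging sensory maps.

Because the stimulated hemisphere is the left one, the *right* whisker is
contralateral and the *left* whisker ipsilateral throughout.

## Trial inclusion (QC)

A trial is analyzed only if the mouse was not whisking before the stimulus:
the sample standard deviation (n-1 denominator) of the whisker angle over the
100 frames (200 ms) immediately preceding onset must be strictly below
1 degree. The rule is applied to both whiskers by default (`apply_to`
configurable, since a single-whisker reading is also defensible). Untracked
trials (non-finite angles) are partitioned out first and reported separately.
The exclusion report carries the moving fraction both pooled over trials and
as the unweighted mean of per-mouse fractions, because either convention
could be meant by a single printed percentage.

## Per-trial metrics

All metrics reference the *baseline*, the mean angle over the two frames
(4 ms) before onset, making every metric invariant to a constant offset.

* **mean change** — mean over the 250 stimulation frames minus baseline.
* **binned change** — the same in six 20-ms bins tiling 0-120 ms.
* **latency** — first stimulation frame whose absolute deviation from
  baseline strictly exceeds 4 degrees; frame `i` is stamped
  `(i - onset + 1) * 2 ms` (end-of-frame), so the smallest observable latency
  is 2 ms. Trials never crossing the threshold are censored and excluded
  from latency maps (the censored fraction is reported).
* **early peak** — the signed deviation of largest magnitude within the
  first 100 ms; exact ties go to the earliest frame (deterministic and
  order-independent).
* **5-15 Hz band amplitude** — over the last 400 ms of stimulation
  (200 frames, 2.5-Hz frequency resolution), mean-subtract, FFT, form the
  one-sided amplitude spectrum `2|X_k|/N` (degrees), and sum the bins at 5,
  7.5, 10, 12.5 and 15 Hz (`bin_sum`, default; an on-grid sinusoid of
  amplitude A returns exactly A). A `trapezoid` mode integrating the same
  amplitudes in Hz (degree-Hz units) is offered because the FFT scaling
  convention of the original analysis code is not fixed by the published
  description; the two modes are monotonically related, so maps and hotspot
  locations are unaffected by the choice. No windowing/taper is applied.
* **bilateral difference** — left-minus-right mean change.
* **zero-lag correlation** — the two stimulation-window traces are z-scored
  (1/N normalization for both the SD and the average of the product, so
  identical traces give exactly 1.0) and multiplied at zero lag. Zero-variance
  windows are flagged NaN and excluded from maps.

## Map aggregation and hotspots

Per mouse, the site value is the *median* over that mouse's included trials
(midpoint of the two central order statistics for even counts); sites with no
usable trials are missing. The cross-mouse map is the arithmetic mean over
mice with a value at the site; a site is missing only if missing in every
mouse. Cross-mouse SDs use n-1.

Hotspots are masked extrema of the contralateral mean-change maps: wS1 is the
minimum over the whole grid, wM1/wM2 the maximum over sites strictly anterior
to Bregma, PtA the maximum over sites at or posterior to Bregma (cells at
AP = 0 are assigned posterior; configurable). Extremum ties break to the
smallest row, then column index. Two readouts are provided, since "the peak
of the average map" admits both: per-mouse peaks summarized as mean +/- SD of
coordinates and values, and the grand-average-map peak with each mouse's
median read at that fixed site. Retraction magnitudes are reported positive
with a direction label.

Grid geometry: 6 columns span ML 0-3.9 mm (0.78-mm pitch), 8 rows span AP
+2.5 to -2.5 mm (0.71-mm pitch). The exact origin is not fixed by the
published grid dimensions alone; this assignment places all reported
hotspots (up to 3.1 mm lateral, +2.1 to -1.4 mm AP) inside the grid and is
configurable; recorded stimulation coordinates override it when loaded.

Power comparison at a hotspot site: amplitude reduction
`(1 - low/high) * 100` (signs divide out, so a shrinking retraction is a
positive reduction) and latency increase `(low/high - 1) * 100`; a zero
high-power value leaves the ratio undefined (NaN).

## Synthetic data generator

The generator defines the study conditions for all pipeline-level tests:
4 mice, 48 sites, 12 high- + 6 low-power repetitions per site (3456 trials),
500-Hz 500-frame trials with onset at frame 250.

Per trial, each whisker's trace is

```
angle(t) = rest + AR1(t) + s * A_sust * (1 - exp(-(t - L)/tau))
               + s * A_rhy * ramp(t) * sin(2*pi*f*(t - L) + phi)   for t > L
```

with `AR1` stationary Gaussian noise (SD 0.3 deg, lag-1 coefficient 0.9),
`L` the per-trial latency (Gaussian, truncated at 0), `f` drawn once per
trial from 8-12 Hz and shared between the whiskers, `ramp` a linear ramp to
full amplitude over 100 ms, and `s = 0.4` plus a +30-ms latency increment
for low-power trials ("less reliable, delayed and smaller"). Frame times use
the same end-of-frame clock as the latency metric, so in the step limit
(tau -> 0) an injected latency is recovered within one frame. This is the
minimal model producing every feature the metrics measure; it makes no claim
about muscle biomechanics or the within-burst dynamics of the 50-Hz light
waveform.

Region archetypes sit near the empirically reported response scales (wS1:
-15 deg contra / +15 deg ipsi sustained, anti-phase, 34-ms latency; wM1/wM2:
+17/+18 deg, in-phase, 47 ms; PtA: +12/+14 deg with the strongest 8-12-Hz
rhythm, 46 ms). Their centers snap to the grid site nearest the nominal
stereotaxic coordinates so hotspot recovery has an exact ground truth. Every
site receives a kernel-weighted blend of the three archetypes (Gaussian
kernel, sigma 0.6 mm); a site is labeled by its dominant region when that
weight reaches 0.1, else "silent". Outside the wS1 block, a weak 1-deg
in-phase rhythmic floor is added to both whiskers: empirically, bilateral
whisker movements are positively correlated almost everywhere except wS1,
and without a weak common drive the correlation sign at quiet sites would be
noise. Trial-to-trial variability (latency SD, amplitude noise, 2-deg
rest-angle spread) is configuration with no claim of realism — the published
analysis does not constrain it.

QC contamination is a discrete mixture: with probability 0.32 a trial gets
an 8-12-Hz prestimulus sinusoid of amplitude 2-4 deg on both whiskers, which
violates the quiescence criterion by construction (worst-case sample SD
~1.34 deg > 1 deg); 3.6% of trials are untracked (all-NaN). This exercises
the QC branch at a controllable rate rather than modeling a continuous
behavioral state.

Determinism: each trial's random stream derives from
`(seed, mouse, site, rep, power)`, so any subset regenerates identically
regardless of generation order.

What the generator does *not* emulate: real whisking kinematics (setpoint
drift, amplitude envelopes, harmonics), cross-trial adaptation, session
effects, tracking noise correlated with movement, and any spatial structure
beyond three Gaussian hotspots. Passing pipeline tests therefore demonstrate
correctness of the *analysis* under the stated generative assumptions, not
fidelity of the model to recorded behavior.

The intrinsic-imaging generator produces 100-frame stacks at 10 Hz (40
baseline, 40 stimulation, 20 post) with a Gaussian reflectance *decrease*
(default peak -1%, sigma 0.5 mm) during stimulation plus pixel noise, on a
96 x 96 grid at 0.06 mm/px with Bregma at pixel (48, 12).

## Sensory maps and overlay

dR/R = (mean stimulation image - mean baseline image) / mean baseline image,
averaged over trials; all 40 stimulation frames enter the response mean (no
hemodynamic-lag offset — none is fixed by the published description;
configurable). The image is Gaussian-smoothed (default sigma 5 px,
configurable; the original smoothing width is unpublished) and the body-part
contour is drawn at `min * (1 - level_fraction)` with `level_fraction = 0.2`,
i.e. at 80% of the peak signal depth — a tight outline of the activity
focus. Among closed contours at that level, the smallest one enclosing the
global minimum is returned; a flat image or a contour cut by the border is
an explicit failure, never a guess. The overlay reports whether the motor
map's minimum cell center falls inside the whisker contour. For a Gaussian
blob of width sigma_b smoothed with sigma_s, the contour is analytically a
circle of radius `sqrt(sigma_b^2 + sigma_s^2) * sqrt(2 ln(1/(1 - f)))`,
which the tests verify to sub-pixel accuracy.

## Numerical conventions (summary)

* Strict inequalities at both printed thresholds: QC excludes at SD >= 1 deg
  ("< 1 deg"), latency requires deviation > 4 deg ("more than +/- 4 deg").
* Sample SD n-1 for QC and cross-mouse statistics; 1/N inside the
  correlation z-scores.
* End-of-frame timestamps; 0-based frame indices; onset is the first
  stimulation frame.
* Median of even counts = midpoint; extremum ties = smallest row, then
  column.
* CSV dialect fixed: UTF-8, comma separator, '.' decimal, header row;
  map CSVs use `%.17g` so doubles round-trip exactly.

## Problem sizes

The default study (3456 trials of 500 frames x 2 whiskers) generates in
about a second and the full pipeline — QC, metrics, maps, hotspots, power
comparison, 20-trial imaging average — completes in a few seconds; the test
suite uses the same sizes plus smaller single-mouse datasets for I/O and CLI
checks.

## Known limitations

* The deposited-dataset loader is written against a documented adapter
  layout and validated on synthetic fixtures; the original deposit's internal
  file naming is not published, so unknown layouts raise with a file listing
  rather than guessing. Whether deposited angles are absolute or already
  baseline-referenced must be resolved by the adapter when such data is
  mounted.
* Absolute band-amplitude values depend on the FFT scaling convention
  (`bin_sum` default); comparisons within and between maps are
  scale-consistent either way.
* No statistical testing between regions and no spatial interpolation of
  maps — the maps are raw site grids by design.
* The latency-censored fraction of the synthetic study (~48%) is much larger
  than in recorded data, because half the synthetic grid is genuinely silent
  with sub-threshold responses; it is a property of the generator layout,
  not of the detector.
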