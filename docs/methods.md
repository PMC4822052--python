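# Methods

`motorquant` quantifies kinesin motor activity from fluorescence microscopy
in five complementary readouts, and ships a synthetic-data generator that
produces each input with known ground truth.  This note records the models
behind each readout, the tunable parameters that matter, what the generator
does and does not emulate, and the numerical choices made where the design
was genuinely open.

## Golgi dispersion integrity

Active kinesins targeted to the Golgi scatter it from its tight perinuclear
cluster into vesicles throughout the cytoplasm; inhibited motors leave it
compact.  Per cell, the readout is

    integrity = SD_i / sqrt(mean)

over a measurement region built by segmenting the nucleus (Otsu threshold
inside a user-drawn coarse ROI, largest connected component, holes filled)
and dilating it outward by 10 px with a Euclidean disc.  The sqrt(mean)
normalizer is what makes the statistic comparable across staining
efficiencies and exposure times: for pure Poisson shot noise the variance
equals the mean, so SD/sqrt(mean) = 1 at *any* illumination, and a compact
perinuclear Golgi — bright structure on dark surround inside the region —
pushes the statistic far above that floor, while dispersal drives it down
toward it.

Choices that were open and how they were resolved:

* **Population vs sample SD** — population (divide-by-N). The statistic
  describes one region; it is not an estimator of a sampling distribution.
  `ddof=1` switches conventions; on regions of thousands of pixels the
  difference is negligible.
* **Region** — the full dilated nuclear area by default; `region="ring"`
  excludes the nucleus proper for users who prefer the annulus only.
* **Structuring element** — a Euclidean disc (isotropy), realized exactly
  through the distance transform.
* The coarse nucleus ROI is an input (drawn by the user or supplied per
  batch); automatic whole-cell segmentation is out of scope.

The tip-accumulation readout for neurite-bearing cells is the plain ratio
of distal (tip) to proximal (shaft) mean fluorescence; background
subtraction is off by default and available as a constant.

## Peroxisome redistribution

Motors recruited to peroxisomes at a treatment time drag them outward.  Per
frame of the 561-nm channel, objects are segmented by a local adaptive
threshold — keep a pixel iff it exceeds the local mean over a
`window_px × window_px` neighbourhood (default 15 px) by more than `offset`
(default 2× the robust background SD, 1.4826·MAD) — with components under
4 px removed.  The readout is the mean Euclidean distance of **all object
pixels** (not centroids) from a user-supplied cell centre, in µm, plus the
mean 488-nm intensity over those pixels (motor recruitment).  Frames with
no objects propagate NaN, never zero: a zero would fake inward motion.
The outward speed is the OLS slope of distance vs time over a
post-treatment window that excludes the boundary-clamped tail.

## Microtubule sliding

A zone of photoconverted microtubules is imaged at 60-s intervals.  The
pipeline is: ratio-method bleach correction (every frame rescaled to frame
0's whole-frame mean); a single Otsu threshold computed on frame 0 and
reused for all frames (recomputing per frame would conflate threshold drift
with motility); removal of thresholded components under 4 px (shot-noise
specks, not microtubules); the initial zone as the morphological closing of
the filled convex hull of the frame-0 mask (so the motile fraction is 0 at
frame 0 by construction; a user-supplied zone mask overrides this); and per
frame

    %MF = 100 · (microtubule pixels outside the zone) / (all microtubule pixels).

The sliding rate is the slope of the *initial linear section* of %MF vs
time: among all windows anchored at frame 0 with ≥ 4 points, the one with
the highest linear-fit R² (ties, within 1e-12, to the longer window; a flat
series has undefined R², reported as 0 with slope 0).  The implementation
enumerates every anchored window, so it is its own exhaustive search; tests
verify it against an independently coded enumeration.  Total microtubule
pixels are counted over the whole frame, not a cell footprint.

## Single-molecule motility

Trajectories come from external tracking software as tables in nm and
seconds.  Tracks are kept when their lifetime is ≥ 0.5 s and every sample
falls on the microtubule mask dilated by 1 px.  Each surviving track is one
landing event:

* **motile** — net start-to-end displacement > 250 nm.  The start-to-end
  vector (not the path sum) makes run lengths insensitive to localization
  noise, which matters for slow or inhibited motors.
* **immotile** — displacement < 250 nm with a dwell of 2.5–10 s.  Shorter
  or longer dwellers are discarded (long dwellers are likely nonspecific
  adsorption); a displacement exactly at the cutoff is discarded
  (measure-zero).

Frequencies are events per µm of microtubule per minute; the microtubule
length is the 8-connected path length of the skeletonized mask (orthogonal
steps 1 px, diagonal √2).

Run lengths above the 250-nm cutoff follow a shifted exponential when the
underlying run-length law is exponential.  By memorylessness the MLE of the
underlying exponential mean is `mean(run) − 250 nm`, and that is the default
reported `mean_run_nm`: it is the quantity that converges to the generating
mean in simulation.  `cutoff_correction=False` reports the plain fitted
mean of the observed runs instead (the uncorrected convention, larger by
exactly the cutoff); users comparing against pipelines that ignore the
cutoff should use it knowingly.  Velocity per event is displacement over
duration (a normal-fit mean across events), not frame-to-frame speed.
95% CIs are percentile bootstrap over events, 2,000 resamples, seeded.

Condition comparisons report the ratio of mean per-movie frequencies
(+drug / −drug), a heteroscedastic (Welch) two-tailed t-test on per-movie
frequencies, and a two-sample Kolmogorov–Smirnov test when per-cell rate
distributions are supplied.

## Synthetic data generator

Every generator draws all randomness from one `numpy.random.default_rng(seed)`
and writes a `SyntheticTruth` sidecar with every generative parameter, so
identical (seed, params) reproduce bit-identical data.

What is emulated, and the defaults:

* **Optics** — point sources are 2-D Gaussians of sd 1.3 px (a PSF
  stand-in; no aberrations or gain model) over a flat background, with
  per-pixel Poisson noise applied last.
* **Golgi scenes** — compact: ~15 spots in a crescent within 2–8 px of the
  nucleus border; dispersed: 40 spots uniform over the cytoplasmic annulus.
  Total expected signal is equal across states so only geometry differs.
* **Peroxisome movies** — 30 puncta at 2–7 µm initial radius, Brownian
  jitter (30 nm/frame) before treatment, 20 nm/s radial motion after,
  clamped at an 11-µm cell radius; 15-s frame interval; the 488 recruitment
  channel ramps to plateau over 60 s.
* **Sliding movies** — 40 short filaments seeded with a minimum spacing
  inside a central zone (spacing keeps filament pixel counts proportional
  to filament counts); a scheduled subset is translated outside the zone so
  the true motile fraction follows `min(rate · t, plateau)` with an 85%
  plateau; 60-s interval; photobleaching of 2% per frame (a typical
  spinning-disk scale — the analysis removes it, and stronger bleaching
  mainly stresses how far above background the frame-0 threshold sits).
* **Trajectories** — filaments are near-straight bounded-curvature
  polylines (taxol-stabilized microtubules are stiff at field scale), aimed
  across the field so they never fold at the frame border.  Landings are a
  Poisson process (`rate · length · duration` expected); motile runs are
  Exponential(1200 nm) with Normal velocities truncated positive; immotile
  dwells are Uniform(2.5, 10) s so generated immotile events fall inside
  the counting window (configurable to generate out-of-window dwellers for
  filter tests); localization noise is isotropic Gaussian (15 nm).  Start
  times are drawn so each engagement completes within the movie — the
  generator models complete events, trading a slight thinning of late
  landings for unbiased run-length statistics.  The recorded true run is
  the realized endpoint-to-endpoint displacement, which equals the
  exponential draw except where curvature or a filament end intervenes.
* The default single-molecule velocity is 300 ± 60 nm/s.  This is slower
  than typical kinesin-1 gliding speeds and is a deliberate testability
  choice: with the 0.5-s minimum-lifetime filter, motors faster than
  500 nm/s lose runs shorter than `0.5 · v` > 250 nm, which left-truncates
  the run-length distribution beyond the detection cutoff and biases any
  estimator that only corrects for the 250-nm threshold.  At 300 nm/s the
  lifetime filter is inactive on motile events and run-length recovery is
  clean.  Landing rates (and this velocity) are not calibrated to any real
  motor.

What passing tests on these data do **not** show: robustness to real PSFs,
camera gain and read noise, uneven illumination, drift (input movies are
assumed registered), organelle shape, motor pausing within runs, or
tracking-software failure modes — trajectories are consumed downstream of
tracking by design.

## Numerical conventions and degenerate inputs

* Images are `(frame, channel, row, col)`; 0-based pixel indices; physical
  `x = col · pixel_size_nm`, `y = row · pixel_size_nm`.  Calibration always
  comes from the caller, never from TIFF tags.
* Constant ROI intensities make the nucleus threshold degenerate → error.
  Empty segmentation masks → error (Golgi, sliding frame 0) or NaN gaps
  (peroxisome frames).  Zero-mean frames make bleach correction fail.
* Welch p on two identical constant groups is defined as 1 (no evidence of
  difference) rather than NaN.
* Zero motile events: frequencies are still reported; fits are NaN.
* CSV round trips use 17-significant-digit formatting and round-trip float
  parsing, so write → read → write is byte-identical.

## Problem sizes

The test suite and the acceptance script run entirely on generated data:
160–256 px scenes, 11-frame sliding movies, 40-frame peroxisome movies, and
single-molecule fields of ~40 µm microtubule observed for 2–2.5 min at
landing rates giving ~300–550 motile events per field (9 movies per
condition for the inhibitor-ratio experiment, mirroring a three-experiment
design).  These sizes give each estimator enough events for its stated
tolerance while keeping a full run under a minute on one core.
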