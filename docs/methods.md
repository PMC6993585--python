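# Methods

## Signal model and preprocessing

Continuous-wave fNIRS measures optical-density changes at three
wavelengths (780/805/830 nm). The modified Beer–Lambert law relates them
to chromophore concentration changes; we solve the 3×2 least-squares
system per channel and sample with literature extinction coefficients and
the differential pathlength factor fixed at 1, so ΔHbO is in arbitrary
consistent units — only correlations are consumed downstream. HbR is
computed and returned but not analyzed (its SNR is conventionally lower).

All filters are 4th-order Butterworth applied forward–backward
(`sosfiltfilt`), i.e. zero-phase, which matters because instantaneous
phases are extracted later. The chain is band-pass 0.01–1.5 Hz, then
ordinary least squares of every standard channel on `[1, mean of
short-separation channels]`, then low-pass 0.15 Hz. The short-channel
regressor is taken from the band-passed data so both sides of the
regression saw identical filtering. The chain is linear in the standard
channels (for a fixed regressor span) and length-preserving.

A caveat verified empirically: after the final 0.15 Hz low-pass, the
sample correlation between *any* two independent 0.01–0.15 Hz signals of
480 s has a chance floor of |r| ≈ 0.07–0.09 (≈2·bandwidth·duration
effective degrees of freedom). Claims that the regression residual is
"uncorrelated" with the scalp signal can therefore only be tested at the
chance floor; the test suite uses 1920-s recordings for that check, where
the floor is below 0.05.

## Dynamic connectivity and variability

dRSFC is the windowed Pearson correlation of each channel pair (window
20 s = 351 samples at 57 ms; step one sample by default, coarser steps
for batch experiments — the window's information content, about 5.6
degrees of freedom for 0.01–0.15 Hz signals, is unchanged by the step).
Windowed sums are computed by cumulative sums and verified against naive
per-window recomputation to 1e-12. Zero-variance windows yield NaN and
are excluded from variances and averages. Variance of dRSFC is the
sample variance (ddof=1) of an edge's windowed r over windows, on raw r
(not Fisher z). Edges are categorized by the unordered ROI pair of their
endpoints; the group comparison uses per-subject means (within-ROI,
between-ROI, short-channel pairs) and two-sample t-tests, Bonferroni-
corrected over the three reported comparisons.

At 480 s, 57 ms sampling and a 20-s window there are 8,071 windows at
step 1.

## Edge clustering and cluster-count selection

k-means (Euclidean) runs on the [edges × windows] matrix per subject with
random centroid initialization and many restarts (the lowest-inertia run
wins); centroids are exact member means. The ratio A = (mean pairwise
centroid distance) / (mean member-to-own-centroid distance); there is no
canonical formula for A, so this is our definition. The validity index
at each k is sd(A)/mean(A) across subjects, and the elbow is the maximum
discrete second difference of validity(k), ties to the smaller k.

Empirically, on the synthetic cohorts the validity curve rises smoothly
from k=2 to a peak at the planted community count and then declines to a
plateau; it lacks a stable-then-rising elbow, so the chosen k is noisy
(see Limitations). Restarts do not change this: the cross-subject
dispersion of A is data-driven, not solution-driven.

Cross-subject label unification ("two loops"): the spatial signature of a
cluster is its binary edge-membership vector; subjects are matched to a
template by optimal one-to-one assignment (Hungarian) maximizing total
Pearson correlation of those vectors — greedy matching can deadlock on
near-ties. Loop 1 uses one subject's maps as template; loop 2 replaces
the template with the group-mean map per label and iterates to a fixed
point (cap 100 iterations). Relabeling permutes label names only; no
partition changes. The reproducibility split halves the cohort at random
(extra subject to the first half), repeats clustering + relabeling per
half, and reports matched-cluster correlations of the occurrence maps.

## Phase dynamics

The instantaneous phase of a centroid time course is the argument of its
convolution with a Gaussian-windowed complex exponential (center
frequency 0.08 Hz, envelope width 10 s), truncated at ±4σ and normalized
to unit energy (phase is normalization-invariant). The kernel uses the
analytic-signal convention, so the phase of cos(2πft) advances at
+360f °/s. Samples within one truncation radius of either end are flagged
boundary-unreliable and excluded from fingerprints and synchronization
fractions. Phase differences are wrapped to (−180°, 180°]; positive
synchronization is (−45°, 45°], reverse is beyond ±135°.

## EEG microstates

Preprocessing: 1–100 Hz band-pass (order 4), 50 Hz notch (Q=30), mask
channels whose peak |amplitude| exceeds 5× the pooled SD of all channels,
average re-reference over good channels, polyphase downsample to 125 Hz.
The anti-alias FIR is deliberately short (4·decimation+1 taps): with
~100 ms microstate segments, a long filter smears state boundaries.

GFP is the population SD across good electrodes per sample; peaks are
strict local maxima (plateaus take the left-most sample). AAHC starts
from singleton clusters of the GFP-peak maps (a random subset of at most
1000 maps bounds the quadratic cost), repeatedly dissolves the cluster
with the smallest GEV contribution and reassigns its members by largest
squared (polarity-invariant) spatial correlation; the cluster template is
the first principal axis of its member maps. CV(k) penalizes residual
variance by ((n_e−1)/(n_e−1−k))² and is minimized over k=1..8.
Backfitting labels every sample with the template of largest
|spatial correlation| (computed on average-referenced maps); flat samples
inherit the previous label. No temporal smoothing is applied.

## Cross-modal coupling

Binary microstate series are causally convolved with the canonical
double-gamma HRF (peak 6 s, undershoot 16 s, dispersions 1 s, ratio 1:6,
32 s support), resampled to the fNIRS rate 17.5439 Hz (rational polyphase
8/57 from 125 Hz), aligned with centroid window series by truncation to
the common length, correlated (Pearson), Fisher-z transformed, and tested
per cell against zero across subjects (uncorrected by default, optional
BH-FDR).

## The synthetic generator

The generator is the package's test bed; its defaults are the study
conditions for all recovery experiments.

* **Geometry/timing:** 36 standard + 4 short channels over five ROIs
  (F, C, P, T, O), 57 ms sampling, 480 s; 30-electrode EEG at 1000 Hz.
* **Hemodynamics:** channels are drawn from a time-varying target
  covariance (unit channel variance) via per-sample Cholesky mixing of
  per-channel flat-spectrum 0.01–0.15 Hz latents. Channels within one ROI
  share covariance 0.75 (stable local connectivity). The ten inter-ROI
  couplings are partitioned into three networks (a fronto-central-
  parietal triangle plus the temporo-occipital pair, and two chains
  through T and O); each network's coupling follows a train of smooth
  flat-topped activation bumps on a slow cycle (0.004 Hz), staggered so
  activations never overlap, with a mild anti-correlated baseline between
  activations (amplitude per network auto-shrunk to keep the covariance
  positive definite; 0.65 for the triangle, ≈0.48 for the chains).
  Within-ROI edges form a fourth, stable planted community.
  Per-channel latents (rather than one latent per ROI or network) matter:
  shared latents would give whole edge groups coherent windowed-sampling
  noise that k-means mistakes for structure.
* **Superficial physiology:** one shared scalp signal (cardiac ~1 Hz,
  respiratory ~0.3 Hz, Mayer ~0.1 Hz, slow drift) added to every channel;
  short channels contain only this plus white noise.
* **EEG:** microstate templates are low-order spatial harmonics over the
  electrode ring (exactly orthogonal, zero-mean, bounded entries); the
  momentary map is the active template carried by a saturated (tanh)
  alpha-band oscillation plus white sensor noise (SD 0.05 per electrode
  against unit-norm templates). Dwell times are uniform on 80–120 ms and
  the successor state is never the current one. When cross-modal coupling
  is enabled, the probability of entering microstate 0 scales with
  network 0's momentary coupling.

### What the generator does and does not emulate

It reproduces the band structure, window statistics, channel geometry and
the qualitative phenomena the pipeline targets (stable local vs variable
long-range connectivity, network alternation including anti-phase
episodes, quasi-stable EEG topographies, HRF-mediated cross-modal
correlation). It does **not** emulate motion artifacts, heterogeneous
channel SNR, spatially correlated sensor noise, realistic EEG background
(the per-sample map SNR is set high enough that plain argmax backfitting
— no temporal smoothing — recovers dwell times; on real EEG, backfit
labels fragment at oscillation zero-crossings and smoothing would be
required), or overlap between network activations. Passing recovery
tests therefore demonstrates correctness of the implementation under
favorable, identifiable conditions, not expected performance on real
recordings.

### Numerical choices

Flat (FFT-masked) spectra for all band-limited latents maximize the
effective degrees of freedom per analysis window; Butterworth-shaped
noise would inflate windowed-correlation sampling noise by ~40%. The
covariance is guarded by a Cholesky attempt with progressive shrinkage of
the modulated blocks (factor 0.9, at most 20 steps). Activation phase,
physiological frequencies and all noise are drawn from one seeded
generator; a fixed seed reproduces every array bit for bit.

## Experiment sizes (acceptance script and acceptance tests)

Chosen for a single-CPU run: community recovery on 20 subjects
(restarts 20, window step 10); validity scan on 10 replicate cohorts of
10 subjects (restarts 10, k = 2..8); variability ordering on 20 subjects;
microstate recovery on 10 subjects; coupling detection on 5 replicate
cohorts of 10 subjects plus 5 matched null cohorts (coupling disabled);
type-I calibration with 2000 resamples (variability test) and 300
simulated cohorts (cross-modal test).

## Design choices where the method description was open

* Windowed variance on raw r (not Fisher z); z offered as an option.
* The "spatial distribution matrix" of a cluster is its binary
  edge-membership vector.
* Cluster-count selection is applied once group-wide.
* Polarity-invariant spatial correlation throughout the microstate
  analysis; the bad-channel rule reads "5× SD" as peak amplitude against
  the pooled across-channel SD.
* Cross-modal alignment truncates both series to the common length after
  resampling to the fNIRS clock (and to the window clock when a coarser
  window step was used).
* Cross-modal specificity is assessed on matched null cohorts with the
  coupling disabled. With a compositional occupancy (states sum to one)
  and time-sharing networks, a planted coupling mechanically induces
  genuine associations in the same row/column of the cluster-by-state
  matrix, so "false positives" are only well-defined where nothing was
  planted.

## Known limitations

* The validity-index elbow does not reliably recover the planted network
  count on this generator (see the clustering section); the quantity is
  reported as measured.
* Recovered mean dwell times run ~20% below the planted mean because
  label flips at carrier zero-crossings split segments; this is inherent
  to unsmoothed per-sample backfitting.
* The group atlas's occurrence probabilities assume the same k across
  subjects.
* Statistical calibration of the cross-modal test relies on
  subject-level independence; autocorrelation within a subject inflates
  per-subject |r| but not the group-level type-I error.
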