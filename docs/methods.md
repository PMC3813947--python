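# Methods

This note documents the models, conventions and numerical choices behind
`oligosort`, in the order the pipeline applies them, together with what the
synthetic benchmark does and does not establish.

## Signal model and conventions

A recording is a single extracellular voltage channel, gain-corrected to
μV.  The canonical processing rate is 10 kHz; acquisition at higher rates
(e.g. 40 kHz oversampling against aliasing and peak-alignment jitter) is
reduced by polyphase FIR resampling (`resample_recording`), which is linear
and band-limited; any rational ratio is supported.  Timestamps are seconds
from recording start (float); sample indices are 0-based; all analysis
windows are half-open in samples, `[lo, hi)`.  Event tables serialize
timestamps at 0.1-ms resolution, which bounds round-trip error at the
sample grid of the canonical rate.

The background noise is assumed stationary with a symmetric, light-tailed
amplitude distribution, and spiking sparse: at 5 Hz firing with 5-ms
spikes, spikes occupy a duty cycle of only 0.025.  Under these assumptions
the median-based estimator

    sigma_n = median(|x|) / 0.6745

recovers the noise SD essentially unbiased (the 0.6745 is the median of
|N(0,1)|) and moves by only a few percent when spikes are superimposed,
because the median ignores the sparse large-amplitude excursions.  The
detection threshold is 5·sigma_n — referred to throughout as the
recording's *noise level*.  An all-zero trace yields sigma_n = 0 and
detection refuses to run rather than detect everything.

## Detection and snippets

Detection takes positive-going peaks (the spikes of interest are biphasic
with an initial overshoot; a config flag switches to absolute-value
detection).  Within each contiguous supra-threshold run the peak is the
argmax, ties broken by the earliest sample; within any `min_separation`
window (default 1 ms, well under the 3-ms refractory bound) only the
largest peak survives.  Snippets span 12 ms before to 13 ms after the peak
— 250 samples with the peak at index 120 at 10 kHz.  Events whose window
would cross a recording edge are dropped with a warning.

## Waveform features

Six features are computed on the 5-ms early phase (2 ms before to 3 ms
after the peak), chosen because the later afterpotential is the part most
often contaminated by other fibers:

| feature | definition | units |
|---|---|---|
| peak amplitude | value at the aligned peak | μV |
| peak roundness | central second difference at the peak | μV/ms² |
| prespike RMS | RMS of the 1-ms segment starting 2 ms before the peak | μV |
| repolarization rate | max of −dV/dt between peak and post-peak minimum | μV/ms |
| afterhyperpolarization | minimum after the peak within the segment | μV |
| reference correlation | Pearson r against the cluster reference, same segment | — |

Roundness is expressed per ms² (only relative scale matters once
z-scored).  A flat segment leaves the correlation undefined; it is recorded
as 0 and flagged.  Z-scores use the sample SD (n−1); zero-variance features
are excluded with a warning.  The full-waveform alternative takes the 32
consecutive samples `[peak − 1.2 ms, peak + 2 ms)` — half-open so that
12 + 20 samples give exactly ℝ³² — each column z-scored.

## Clustering

k-means is implemented directly (not delegated) because the cityblock
variant — L1 assignment with per-dimension *median* centroids — is part of
the method, alongside the conventional squared-Euclidean/mean variant.
Lloyd iterations run until the assignment is a fixed point or 300
iterations; the best of 10 restarts by total within-cluster distance wins.
Because inputs are z-scored, initial centroids are drawn from N(0,1)^d
with a data-independent RNG; this makes results deterministic given the
seed and exactly equivariant under row permutation.  An empty cluster is
reseeded at the currently worst-fit point, which behaves like a furthest
-point heuristic under repetition.  k is never chosen automatically: the
cluster count of a recording is an analyst's judgement; the CLI offers a
silhouette sweep to inform it.  Silhouette values use the clustering
metric; singleton clusters score 0 by convention.

## Homogeneity selection (Hotelling T²)

Within one cluster the z-scored features are modelled as multivariate
normal.  A centered PCA retains components with eigenvalues above
1e−10·λ₁ (rank guard); each spike's T² = Σ score²ⱼ/λⱼ.  With estimated
mean and covariance, null T² follows p(n−1)/(n−p)·F(p, n−p); the cutoff is
its quantile at the configured scope (default 0.9999, i.e. one flagged
spike per 10,000 under the null; χ²_p is the large-n limit).  On 10⁶ null
6-D Gaussian draws the retained fraction measures 99.99% within binomial
error (`scripts/acceptance.py`).

Selection is a single fit-and-flag pass by default.  When outliers are
*correlated* — many overlaps distorting the cluster in similar directions —
they inflate the fitted covariance along their own direction and mask one
another; the `t2_iterate` flag refits on the selected set until stable,
which restores sensitivity (the contamination property test documents the
difference: 20/20 flagged iterated vs 13/20 single-pass on a 5%
contaminated cluster).  The iterate mode is recommended, and used in the
acceptance suite, for recordings with substantial synchrony.

## Subtraction algorithm (SA)

The SA treats a T²-unselected waveform as the cluster's ideal waveform plus
an additive interference, and asks whether that interference is real:

1. residual = outlier − reference (the reference averages the T²-selected
   members, so it is nearly noise-free for clusters of ≥ 20 spikes);
2. the residual maximum is searched 2–15 ms into the 25-ms window — i.e.
   interference peaking from 10 ms before to 3 ms after the spike peak —
   and a 5-ms segment (2 ms before to 3 ms after the maximum) excerpted;
3. the outlier is retrieved if **either** the residual peak is below
   4σₙ (80% of the noise level: indistinguishable from noise), **or** the
   segment occurs elsewhere in the recording: sliding-window normalized
   cross-correlation (FFT-based; an exhaustive per-sample scan is the test
   oracle) over a 10-min epoch, accepting local correlation maxima with
   r > 0.95 whose window peak magnitude is within 30% of the residual peak
   (|1 − candidate/residual| < 0.3).  Windows within ±25 ms of the
   outlier's own position are excluded so the outlier cannot match itself.

The two criteria are a disjunction by default: retrieved residuals are
routinely full-amplitude spikes of *other* fibers, which can never satisfy
a sub-threshold condition.  A config switch (`sa_criteria="and"`) restores
the conjunctive reading.

**Pitfall guard.**  An outlier at about twice the reference amplitude
leaves a residual that *is* the reference; since the recording trivially
contains reference-shaped signals, the match route would retrieve it
falsely.  Such cases are flagged (`flagged-pitfall`) for manual review,
never silently retrieved.  The guard requires both shape (r > 0.95 against
the reference core) and magnitude (residual peak within 30% of the
reference peak): correlation alone is insufficient as a trigger because
*all* spike cores are generically biphasic and correlate highly — with a
shape-only guard the SA would flag essentially every genuine overlap
residual and retrieve nothing.

**Operating range.**  With noise present on both the residual and the
candidate segments, r between two copies of the same spike is roughly
s²/(s² + σₙ²) with s the segment's signal RMS; r > 0.95 therefore requires
s ≳ 4.4σₙ, i.e. interference peaks of roughly ≥ 2× the noise level.  The
match route is thus a high-SNR instrument; smaller interference is covered
by the sub-threshold route (< 0.8× the noise level), leaving a gap between
~0.8× and ~2× the noise level where SA cannot certify a residual either
way.  The acceptance suite exercises both sides of this dichotomy.

## Unit validation

ISIs below 3 ms violate the refractory period; a unit is `clean` below a
0.1% violation fraction, `marginal` below 1%, `violating` above (the
clean/non-clean boundary is the operative one; the marginal band is our
reporting convention).  The ln-ISI histogram uses Scott's width
h = 3.49·s·n^(−1/3) computed on the ln-ISIs (the histogram lives on the ln
scale), runs from ln 0.003 = −5.809 to the 99.9th percentile, and is
normalized so Σ pd·h = 1 over the in-range ISIs.

Gaussian-sum fits (k = 1–3 modes) use nonlinear least squares with modes
initialized at the k largest histogram peaks (greedy, minimum separation
2h), amplitudes at the peak densities, widths at h, plus 5 jittered
restarts.  Three numerical choices matter for honest model selection:

* the fit covers the *occupied support* only — leading/trailing empty bins
  say nothing about mode count but would inflate n_b in AICc;
* residuals are Poisson-weighted (1/√pd, floored at 5% of the peak):
  bin-count variance grows with density, and an unweighted fit lets extra
  modes chase the noise concentrated near density peaks — at n = 5000 ISIs
  this overfits badly (unimodal data selected as trimodal in nearly every
  replicate).  AICc uses the weighted SSR; the AICc formula itself,
  n_b·ln(SSR/n_b) + 2K + 2K(K+1)/(n_b−K−1) with K = 3k, is evaluated
  exactly as written, and `aicc` refuses n_b ≤ K + 1;
* identifiability: widths are bounded below by h (a feature narrower than
  one bin is unresolvable), and a converged fit only counts as a k-mode
  solution if its curve actually exhibits k local maxima with every
  component amplitude ≥ 5% of the peak density — a sum of k Gaussians can
  be unimodal, and such degenerate fits must not compete as k-mode models.

With these choices AICc recovers the generating mode count in 50/50
replicates for each of k = 1, 2, 3 at n = 5000 (three well-separated
designs; see the acceptance suite).  The best model's fitted density must
also *decline* toward the refractory bound: the fitted value at ln 0.003
below 10% of the smallest mode's peak (configurable; this operationalizes
a visual criterion, and the raw ratio is always reported).  An abrupt
absence of short ISIs with no decline suggests overlap shadowing rather
than a true refractory period.

Feature-vs-preceding-ISI dependence is fitted on Scott-binned means (bins
with ≥ 2 spikes) against ln-ISI bin centers: exponential relaxation
y = y₀ + a·e^(−(x−x₀)/t) with x₀ *fixed* at ln 0.003 — a·e^(x₀/t) is
otherwise redundant with a — so K = 3, versus linear y = mx + b with
K = 2.  The lower-AICc model wins unless its goodness test fails while the
other's passes.  Goodness uses Spearman's r between observed and predicted
bin means and the standard t-for-correlation with the square root over the
degree-of-freedom ratio, t = r·√((n_b−K−1)/(1−r²)); a printed variant of
this statistic without the root exists in the literature this follows, but
the rooted form is the one with the documented null distribution, so it is
the one implemented.  p ≥ 0.05 marks the fit `failed`.  A unit's verdict is
`single-fiber` iff it is refractory-clean *and* its ISI density declines;
feature-ISI dependence supports but neither makes nor vetoes the verdict.
Units under 30 spikes get a `partial` report and no verdict.

## Synthetic benchmark

`make_template` builds biphasic templates: a Gaussian rise (σ = `rise_ms`)
to the peak, Gaussian fall (`fall_ms`), an alpha-function
afterhyperpolarization of relative depth `ahp_frac` peaking at
`ahp_tau_ms`, and an optional rebound; the trace is normalized to peak 1 at
the alignment sample and scaled by `peak_snr · σ` at insertion.
`peak_snr` is denominated in σₙ; conditions quoted in multiples of the
*noise level* (the 5σₙ detection threshold) are converted explicitly
(×5) where used.  The default bank of seven shapes uses sub-ms rises
(0.25–0.45 ms) as in real fiber spikes — broad-peaked templates would make
the peak sample ambiguous under noise and blur ground-truth timing through
no fault of the sorter.

Noise is white Gaussian by default (AR(1) with matched marginal SD as an
option); spike times are uniform with a same-group spacing floor (default
10 ms) and snapped to the sample grid so ground truth is exact.  The
synchrony option re-places a fraction of group B's spikes within
±`jitter_ms` of random group-A spikes.  Jitter at the default 1 ms forces
true waveform collisions (merged detections); jitter of several ms models
burst-scale synchrony, where the partner spike rides *inside* the 25-ms
window, dispersing the cluster and producing exactly the T²-outliers the
SA is designed to retrieve.  The acceptance ablation uses 5 ms for this
reason.

Scoring matches unit spikes to ground truth greedily, one-to-one, nearest
first, within 0.5 ms; units map to groups by majority vote unless a
mapping is given, several units voting for one group being pooled with a
warning.  Greedy matching can in principle differ from an optimal
assignment, but with a 0.5-ms tolerance against ≥ 10-ms same-group spacing
the difference is immaterial.

**What the benchmark does not emulate:** waveform nonstationarity (the
generator's templates are exact repeats, so preceding-ISI dependence of
features is absent by construction), correlated or bursty firing beyond
the pairwise synchrony option, electrode drift, and non-Gaussian or
nonstationary noise.  Passing the end-to-end suite therefore demonstrates
the algorithmic machinery — detection calibration, overlap decomposition,
selection coverage — not robustness to every property of real recordings.

## Problem sizes and determinism

The test and acceptance suites run at desk scale by choice: 2–3-min
epochs, ~100–150 spikes per group, 10⁶-sample calibration draws, 50-fold
replication for model selection.  Epoch presets up to 30 min are available
in the generator and CLI.  Every stochastic step (generator, k-means
restarts, fit jitter) is seeded; identical seeds give byte-identical
datasets and bit-identical pipeline outputs, which the CLI test verifies
by re-running a stage from its written inputs.

## Known limitations

* SA subtracts exactly one reference; simultaneous multi-template
  deconvolution (three-way overlaps) is out of scope.
* The SA match route needs the interference to recur (≥ 1 match in the
  scan epoch) and to be large (≥ ~2× the noise level, see above); rare or
  mid-amplitude interference is rejected conservatively.
* T² selection assumes an elliptical cluster core; the single-pass default
  under-flags correlated contamination (use `t2_iterate`).
* k is analyst-chosen; a poor k silently merges or splits fibers, which
  the validation battery (refractory violations, bimodal short-ISI modes)
  is designed to catch downstream.
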