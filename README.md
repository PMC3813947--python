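# oligosort

Spike sorting for **oligofiber nerve recordings** — single-electrode
(suction-pipette) recordings of a *few* dissociated nerve fibers at once, as
used to study sympathetic nerve discharge (SND) in vitro.  Sympathetic
fibers often fire in synchronous bursts, so a recording of several fibers
contains *overlapped* spikes: complex waveforms that ordinary waveform
clustering discards as outliers, silently deleting exactly the spikes that
carry the synchrony.  `oligosort` implements a complete sorting chain whose
distinguishing step is a **data-based subtraction algorithm (SA)** that
decomposes such outliers and retrieves them, restoring the fidelity of the
spike trains during synchronous discharge.

Intended users: electrophysiologists sorting single-channel peripheral-nerve
or similar sparse-unit recordings, and methodologists who need a
ground-truth benchmark for overlap-resolving sorters.

## The method

Given one gain-corrected voltage channel (μV, nominally 10 kHz):

1. **Detection.**  The noise SD is estimated robustly as
   σₙ = median(|x|)/0.6745; spikes are peaks above the 5σₙ threshold
   (the recording's *noise level*).  Each spike is cut into a peak-aligned
   25-ms snippet (12 ms before to 13 ms after the peak).
2. **Features.**  Six parameters describe the 5-ms early phase of each
   waveform (2 ms before to 3 ms after the peak): peak amplitude *a*, peak
   roundness *b* (second derivative at the peak, μV/ms²), prespike RMS *c*,
   repolarization rate *d*, afterhyperpolarization *e*, and the correlation
   *f* with a reference waveform.  Each spike becomes a z-scored point in
   ℝ⁶ (a 32-sample raw-waveform alternative, ℝ³², is also provided).
3. **Clustering.**  k-means with the *cityblock* distance (centroids are
   per-dimension medians; squared-Euclidean/mean is available), k chosen by
   the analyst, cluster separation reported as silhouette values
   s(i) = (b−a)/max(a,b).
4. **Homogeneity (Hotelling T²).**  Per cluster, a PCA model scores each
   spike's T² = Σⱼ score²ⱼ/λⱼ; spikes beyond the 99.99% scope
   (cutoff p(n−1)/(n−p)·F₍p,n−p₎) are *T²-unselected* outliers.
5. **Subtraction algorithm.**  Each outlier minus the cluster reference
   leaves a residual; its maximum is located 2–15 ms into the window and a
   5-ms segment around it is excerpted.  The outlier is *retrieved* if the
   residual is sub-threshold (< 4σₙ, i.e. 80% of the noise level) **or**
   demonstrably occurs elsewhere in the recording (normalized
   cross-correlation r > 0.95 and peak magnitude within 30%, scanned over a
   10-min epoch).  A residual that reproduces the cluster's own reference
   (shape *and* magnitude) is the double-amplitude pitfall and is flagged
   for review, never silently retrieved.
6. **Unit validation.**  T²-selected plus SA-retrieved spikes form a *unit
   activity*; it is credited to a single fiber only if (i) fewer than 0.1%
   of interspike intervals violate a 3-ms refractory period, and (ii) the
   ln-ISI density (Scott-binned, h = 3.49·s·n^(−1/3)) is well fitted by a
   1–3-mode Gaussian sum — selected by
   AICc = n_b·ln(SSR/n_b) + 2K + 2K(K+1)/(n_b−K−1) — that declines promptly
   toward ln(3 ms) = −5.809.  Preceding-ISI dependence of waveform features
   (exponential relaxation y = y₀ + a·e^(−(x−x₀)/t) vs linear, AICc plus a
   Spearman goodness test) is reported as supporting evidence.

A **synthetic-recording generator** inserts parametric biphasic templates
(amplitudes in σₙ units) into white or AR(1) noise, optionally forcing
near-coincident firing between two groups, and scores any sorting result
against the known ground truth.

## Worked example

Two fibers (peaks at 3× and 6× the 5σₙ noise level) in σ = 10 μV noise,
with half of fiber 1's spikes forced to fire within ±5 ms of fiber 2:

```python
import dataclasses
from oligosort import (RunConfig, SyncConfig, default_template_specs,
                       generate_dataset, score_sorting, sort_recording,
                       validate_unit)

specs = [dataclasses.replace(s, peak_snr=s.peak_snr * 5.0)
         for s in default_template_specs((3.0, 6.0), n_spikes=150)]
sync = SyncConfig(group_a=2, group_b=1, fraction=0.5, jitter_ms=5.0)
ds = generate_dataset(specs, noise_sigma=10.0, epoch_s=180.0, sync=sync, seed=42)

cfg = RunConfig(k=2, sa_epoch_s=180.0, seed=0, t2_iterate=True)
result = sort_recording(ds.recording, cfg)
print(f"sigma_n = {result.noise.sigma_n:.2f} uV, "
      f"threshold = {result.noise.threshold:.2f} uV")
for unit in result.units:
    print(f"unit {unit.cluster_id}: {unit.n_t2} T2-selected + "
          f"{unit.n_sa} SA-retrieved of {unit.cluster_size}")
print(score_sorting(ds.ground_truth, result.units).per_group)
```

prints

```
sigma_n = 10.17 uV, threshold = 50.86 uV
unit 0: 144 T2-selected + 6 SA-retrieved of 151
unit 1: 108 T2-selected + 2 SA-retrieved of 110
 group_id  n_true  n_sorted  n_matched  accuracy  false_positives
        1     150       110        110  0.733333                0
        2     150       150        150  1.000000                0
```

The noise estimate recovers the generator's σ within 2%; the big fiber is
sorted perfectly (SA retrieved the overlap-distorted outliers that the T²
filter had removed), while the synchronized small fiber loses the spikes
that merged into compounds.  Validation then judges each unit:

```python
for unit in result.units:
    val = validate_unit(unit.timestamps)
    print(unit.cluster_id, val.single_fiber_verdict, val.refractory_class)
```

```
0 single-fiber clean
1 not-single-fiber violating
```

— the clean fiber passes the refractory and ISI-distribution battery, the
synchrony-corrupted unit is correctly rejected.

## Command line

The same chain is scriptable: `oligosort simulate | detect | features |
cluster | pipeline | validate | score`, exchanging TSV/npz/JSON files with
the run configuration (YAML) embedded in every summary.  See
`oligosort --help`.

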