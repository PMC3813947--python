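"""Waveform feature extraction and standardization.

Six features summarize each spike, all computed on the 5-ms segment from
2 ms before to 3 ms after the peak (the early phase least contaminated by
other fibers' activity):

a. peak amplitude (μV)
b. peak roundness -- the central second difference at the peak, μV/ms²
c. prespike RMS -- RMS of the 1-ms segment starting 2 ms before the peak, μV
d. repolarization rate -- steepest fall between the peak and the post-peak
   minimum, μV/ms
e. afterhyperpolarization -- the post-peak minimum, μV
f. correlation coefficient with the cluster's reference waveform

After z-scoring, every spike is one point in R^6.  The alternative
"full-waveform" representation takes the 32 raw amplitude samples from
1.2 ms before to 2 ms after the peak (R^32), each dimension then z-scored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .detection import ReferenceWaveform, WaveformSet

__all__ = [
    "FEATURE_NAMES",
    "FeatureTable",
    "extract_features",
    "zscore_features",
    "full_waveform_vectors",
]

FEATURE_NAMES = (
    "peak_amplitude",
    "peak_roundness",
    "prespike_rms",
    "repolarization_rate",
    "afterhyperpolarization",
    "ref_correlation",
)

#: feature segment geometry in ms around the peak
SEGMENT_PRE_MS = 2.0
SEGMENT_POST_MS = 3.0
#: full-waveform vector geometry: [peak - 1.2 ms, peak + 2 ms) -> 32 samples at 10 kHz
FULLWAVE_PRE_MS = 1.2
FULLWAVE_POST_MS = 2.0


@dataclass
class FeatureTable:
    """Per-spike waveform features, plus the z-scored view used for clustering."""

    values: pd.DataFrame
    active_features: tuple = FEATURE_NAMES
    zscores: pd.DataFrame | None = None
    flags: pd.DataFrame | None = None

    @property
    def n_spikes(self) -> int:
        return len(self.values)


def _segment_bounds(align_index: int, rate: float) -> tuple[int, int]:
    pre = int(round(SEGMENT_PRE_MS * rate / 1000.0))
    post = int(round(SEGMENT_POST_MS * rate / 1000.0))
    return align_index - pre, align_index + post


def extract_features(ws: WaveformSet, ref: ReferenceWaveform) -> FeatureTable:
    """Compute the six features for every snippet row.

    The reference must share the set's alignment convention.  A flat
    (zero-variance) segment leaves the reference correlation undefined; it
    is recorded as 0 and flagged.
    """
    if ref.align_index != ws.align_index:
        raise ValueError("reference and waveform set must share alignment")
    ai = ws.align_index
    lo, hi = _segment_bounds(ai, ws.rate)
    if lo < 1 or hi > ws.n_samples:
        raise ValueError("snippets too short for the 2/3-ms feature segment")
    per_ms = ws.rate / 1000.0  # samples per ms
    pre_n = int(round(SEGMENT_PRE_MS * per_ms))
    one_ms = int(round(per_ms))

    w = ws.waveforms
    ref_seg = ref.mean_waveform[lo:hi]
    ref_centered = ref_seg - ref_seg.mean()
    ref_norm = np.sqrt((ref_centered**2).sum())

    rows = []
    flat_flags = np.zeros(ws.n_spikes, dtype=bool)
    for i in range(ws.n_spikes):
        x = w[i]
        peak = x[ai]
        # b: central second difference at the peak, scaled to μV/ms²
        roundness = (x[ai - 1] - 2.0 * x[ai] + x[ai + 1]) * per_ms**2
        # c: RMS of the 1-ms window starting 2 ms before the peak
        pres = x[ai - pre_n : ai - pre_n + one_ms]
        prespike = float(np.sqrt(np.mean(pres**2)))
        # e: post-peak minimum within the feature segment (exclusive of peak)
        post = x[ai + 1 : hi]
        ahp_off = int(np.argmin(post))
        ahp = float(post[ahp_off])
        # d: steepest fall between the peak and the post-peak minimum
        fall = x[ai : ai + ahp_off + 2]
        if fall.size >= 2:
            repol = float(np.max(-np.diff(fall)) * per_ms)
        else:
            repol = 0.0
        # f: Pearson correlation with the reference over the same segment
        seg = x[lo:hi]
        seg_c = seg - seg.mean()
        seg_norm = np.sqrt((seg_c**2).sum())
        if seg_norm == 0 or ref_norm == 0:
            corr = 0.0
            flat_flags[i] = True
        else:
            corr = float(np.dot(seg_c, ref_centered) / (seg_norm * ref_norm))
        rows.append((peak, roundness, prespike, repol, ahp, corr))

    values = pd.DataFrame(rows, columns=list(FEATURE_NAMES))
    flags = pd.DataFrame({"flat_segment": flat_flags})
    return FeatureTable(values=values, flags=flags)


def zscore_features(ft: FeatureTable, active=None) -> FeatureTable:
    """Standardize the active features over the analyzed epoch.

    z = (value - mean) / SD with the sample SD (n-1 denominator).
    Zero-SD features are excluded with a warning.
    """
    if ft.n_spikes < 2:
        raise ValueError("need at least two spikes to z-score features")
    active = tuple(active) if active is not None else tuple(ft.values.columns)
    keep, dropped = [], []
    for name in active:
        sd = ft.values[name].std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            dropped.append(name)
        else:
            keep.append(name)
    if dropped:
        warnings.warn(f"excluded zero-variance feature(s): {dropped}")
    sub = ft.values[keep]
    z = (sub - sub.mean()) / sub.std(ddof=1)
    return FeatureTable(
        values=ft.values, active_features=tuple(keep), zscores=z, flags=ft.flags
    )


def zscore_matrix(x: np.ndarray) -> np.ndarray:
    """Column-wise z-scores (sample SD); zero-variance columns pass as zeros."""
    x = np.asarray(x, dtype=float)
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    sd = np.where(sd == 0, 1.0, sd)
    return (x - mu) / sd


def full_waveform_vectors(ws: WaveformSet) -> np.ndarray:
    """The R^32 representation: samples ``[peak - 1.2 ms, peak + 2 ms)``.

    At 10 kHz this is exactly 32 consecutive amplitude values (12 + 20,
    peak included).  Snippets at other rates must be resampled first.
    """
    pre = int(round(FULLWAVE_PRE_MS * ws.rate / 1000.0))
    post = int(round(FULLWAVE_POST_MS * ws.rate / 1000.0))
    lo, hi = ws.align_index - pre, ws.align_index + post
    if lo < 0 or hi > ws.n_samples:
        raise ValueError("snippets too short for the full-waveform window")
    return ws.waveforms[:, lo:hi].copy()
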