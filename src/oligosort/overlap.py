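"""Data-based subtraction algorithm (SA) for overlapped spikes.

A T²-unselected outlier waveform is assumed to be the cluster's ideal
waveform distorted by an added signal (another fiber's spike, or noise).
Subtracting the cluster reference leaves a residual; the residual's maximum
is located within 2-15 ms of the 25-ms window and a 5-ms segment (2 ms
before to 3 ms after that maximum) is excerpted.  The outlier is retrieved
as a true cluster member when the residual is explainable:

* sub-threshold -- its peak stays below 4σₙ, i.e. below 80% of the 5σₙ
  detection threshold, so it is within the noise; or
* matched -- signals similar to the residual (Pearson r > 0.95, peak
  magnitude within 30%) actually occur elsewhere in the original recording
  (a 10-min scan epoch by default).

A residual that itself resembles the cluster's own reference (r > 0.95)
signals the double-amplitude pitfall: the recording trivially contains the
reference shape, so such cases are flagged for manual review rather than
silently retrieved.  The two retrieval criteria are applied as a
disjunction by default; ``criteria="and"`` restores the conjunctive
reading.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import maximum_filter1d
from scipy.signal import fftconvolve

from .detection import NoiseEstimate, ReferenceWaveform, WaveformSet
from .io import ContinuousRecording

__all__ = [
    "ResidualWaveform",
    "SAMatch",
    "SADecision",
    "UnitActivity",
    "compute_residual",
    "scan_recording",
    "classify_outlier",
    "assemble_unit",
    "apply_sa",
    "SA_SIGMA_CEILING",
]

#: residual-peak ceiling for the sub-threshold route, in units of sigma_n
SA_SIGMA_CEILING = 4.0
#: residual-maximum search window within the 25-ms snippet, ms
SEARCH_LO_MS = 2.0
SEARCH_HI_MS = 15.0
#: residual segment geometry around the residual maximum, ms
RES_PRE_MS = 2.0
RES_POST_MS = 3.0


@dataclass
class ResidualWaveform:
    """Outlier minus reference, with the 5-ms excerpt around its maximum."""

    full_residual: np.ndarray
    residual_max_index: int
    residual_max_time: float  # seconds within the snippet window
    segment: np.ndarray
    residual_peak: float
    rate: float


@dataclass
class SAMatch:
    """Occurrences of the residual segment found in the original recording."""

    match_times: np.ndarray
    correlations: np.ndarray
    magnitude_ratios: np.ndarray
    n_matches: int
    scan_epoch: float


@dataclass
class SADecision:
    """Outcome of the SA evaluation for one T²-unselected waveform."""

    verdict: str  # retrieved-subthreshold | retrieved-matched | rejected-outlier | flagged-pitfall
    criteria_log: dict = field(default_factory=dict)

    @property
    def retrieved(self) -> bool:
        return self.verdict.startswith("retrieved")


@dataclass
class UnitActivity:
    """Merged T²-selected plus SA-retrieved spikes of one putative fiber."""

    timestamps: np.ndarray
    spike_ids: np.ndarray
    provenance: np.ndarray  # "T2" or "SA" per spike
    cluster_id: int | str
    cluster_size: int
    n_t2: int = 0
    n_sa: int = 0

    @property
    def n_spikes(self) -> int:
        return self.timestamps.size

    @property
    def fraction_retrieved(self) -> float:
        """SA-retrieved fraction of the T²-unselected pool."""
        unselected = self.cluster_size - self.n_t2
        return self.n_sa / unselected if unselected else 0.0

    @property
    def fraction_retained(self) -> float:
        """Unit spikes as a fraction of the original cluster."""
        return self.n_spikes / self.cluster_size if self.cluster_size else 0.0


def compute_residual(
    outlier: np.ndarray, reference: ReferenceWaveform, rate: float | None = None
) -> ResidualWaveform:
    """Point-wise outlier-minus-reference residual and its 5-ms excerpt."""
    outlier = np.asarray(outlier, dtype=float).ravel()
    rate = float(rate if rate is not None else reference.rate)
    if outlier.size != reference.mean_waveform.size:
        raise ValueError("outlier and reference must have identical length/alignment")
    residual = outlier - reference.mean_waveform
    lo = int(round(SEARCH_LO_MS * rate / 1000.0))
    hi = int(round(SEARCH_HI_MS * rate / 1000.0))
    m = lo + int(np.argmax(residual[lo:hi]))
    pre = int(round(RES_PRE_MS * rate / 1000.0))
    post = int(round(RES_POST_MS * rate / 1000.0))
    seg_lo = max(m - pre, 0)
    segment = residual[seg_lo : m + post]
    return ResidualWaveform(
        full_residual=residual,
        residual_max_index=m,
        residual_max_time=m / rate,
        segment=segment,
        residual_peak=float(residual[m]),
        rate=rate,
    )


class RecordingScanCache:
    """Windowed sums and maxima of one recording epoch, shared across scans."""

    def __init__(self, rec: ContinuousRecording, epoch_s: float, seg_len: int):
        n_scan = min(int(round(epoch_s * rec.rate)), rec.n_samples)
        self.x = rec.samples[:n_scan]
        self.rate = rec.rate
        self.t0 = rec.t0
        self.seg_len = seg_len
        self.n_windows = n_scan - seg_len + 1
        if self.n_windows <= 0:
            raise ValueError("scan epoch shorter than the residual segment")
        csum = np.concatenate(([0.0], np.cumsum(self.x)))
        csum2 = np.concatenate(([0.0], np.cumsum(self.x**2)))
        self.win_sum = csum[seg_len:] - csum[:-seg_len]
        win_sq = csum2[seg_len:] - csum2[:-seg_len]
        self.win_var = win_sq - self.win_sum**2 / seg_len  # L * variance
        np.clip(self.win_var, 0.0, None, out=self.win_var)
        wmax = maximum_filter1d(self.x, size=seg_len)
        self.win_max = wmax[seg_len // 2 : seg_len // 2 + self.n_windows]


def scan_recording(
    residual: ResidualWaveform,
    rec: ContinuousRecording,
    epoch_s: float = 600.0,
    r_min: float = 0.95,
    mag_tol: float = 0.30,
    exclude_time: float | None = None,
    exclude_halfwidth_s: float = 0.025,
    cache: RecordingScanCache | None = None,
) -> SAMatch:
    """Find occurrences of the 5-ms residual segment in the recording.

    A sliding-window normalized cross-correlation (FFT-based) of the
    segment against the first ``epoch_s`` seconds of the recording is
    thresholded at ``r_min``; one candidate per supra-threshold run is kept
    (its correlation maximum) and must also match the residual peak within
    ``mag_tol`` relative magnitude.  Windows within ±25 ms of
    ``exclude_time`` (the outlier's own position) are excluded.
    """
    seg = np.asarray(residual.segment, dtype=float)
    L = seg.size
    seg_c = seg - seg.mean()
    seg_ss = float((seg_c**2).sum())
    if seg_ss == 0 or residual.residual_peak <= 0:
        return SAMatch(np.array([]), np.array([]), np.array([]), 0, epoch_s)
    if cache is None or cache.seg_len != L:
        cache = RecordingScanCache(rec, epoch_s, L)

    cross = fftconvolve(cache.x, seg_c[::-1], mode="valid")
    denom = np.sqrt(cache.win_var * seg_ss)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, cross / denom, -np.inf)
    r = np.clip(r, -1.0, 1.0, out=r)

    if exclude_time is not None:
        pos = int(round((exclude_time - cache.t0) * cache.rate))
        ex = int(round(exclude_halfwidth_s * cache.rate))
        lo = max(pos - ex - L + 1, 0)
        hi = min(pos + ex + 1, cache.n_windows)
        if lo < hi:
            r[lo:hi] = -np.inf

    above = r > r_min
    times, corrs, ratios = [], [], []
    if above.any():
        edges = np.diff(above.astype(np.int8))
        starts = np.flatnonzero(edges == 1) + 1
        ends = np.flatnonzero(edges == -1) + 1
        if above[0]:
            starts = np.r_[0, starts]
        if above[-1]:
            ends = np.r_[ends, above.size]
        peak_offset = int(np.argmax(seg))
        for s, e in zip(starts, ends):
            t = s + int(np.argmax(r[s:e]))
            cand_peak = cache.win_max[t]
            ratio = cand_peak / residual.residual_peak
            if abs(1.0 - ratio) < mag_tol:
                times.append(cache.t0 + (t + peak_offset) / cache.rate)
                corrs.append(r[t])
                ratios.append(ratio)
    return SAMatch(
        match_times=np.asarray(times),
        correlations=np.asarray(corrs),
        magnitude_ratios=np.asarray(ratios),
        n_matches=len(times),
        scan_epoch=epoch_s,
    )


def _reference_core(reference: ReferenceWaveform) -> np.ndarray:
    pre = int(round(RES_PRE_MS * reference.rate / 1000.0))
    post = int(round(RES_POST_MS * reference.rate / 1000.0))
    ai = reference.align_index
    return reference.mean_waveform[ai - pre : ai + post]


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if a.size != b.size or a.size < 2:
        return 0.0
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a**2).sum() * (b**2).sum())
    return float(a @ b / denom) if denom > 0 else 0.0


def classify_outlier(
    residual: ResidualWaveform,
    matches: SAMatch,
    noise: NoiseEstimate,
    own_reference: ReferenceWaveform,
    sigma_ceiling: float = SA_SIGMA_CEILING,
    r_pitfall: float = 0.95,
    pitfall_mag_tol: float = 0.30,
    criteria: str = "or",
) -> SADecision:
    """Decide the fate of one T²-unselected waveform.

    Retrieval routes (default disjunction): residual peak below
    ``sigma_ceiling``·σₙ, or at least one match in the recording.  A
    residual that reproduces the cluster's own reference -- correlation
    > ``r_pitfall`` AND peak magnitude within ``pitfall_mag_tol`` of the
    reference peak -- signals the double-amplitude trap: the recording
    trivially contains reference-shaped signals of that size, so the match
    route cannot be trusted.  Such cases override any retrieval with
    ``flagged-pitfall`` and are left for manual review.  (The magnitude
    condition keeps ordinary overlap residuals, which share the generic
    biphasic shape of all spikes but not the reference's amplitude, out of
    the pitfall path.)
    """
    if noise.sigma_n <= 0:
        raise ValueError("classification requires a positive noise estimate")
    if criteria not in {"or", "and"}:
        raise ValueError("criteria must be 'or' or 'and'")
    subthreshold = residual.residual_peak < sigma_ceiling * noise.sigma_n
    matched = matches.n_matches >= 1
    ref_core = _reference_core(own_reference)
    own_r = _pearson(residual.segment, ref_core)
    ref_peak = float(ref_core.max())
    mag_like_ref = (
        ref_peak > 0
        and abs(1.0 - residual.residual_peak / ref_peak) < pitfall_mag_tol
    )
    log = {
        "residual_peak": residual.residual_peak,
        "subthreshold": subthreshold,
        "n_matches": matches.n_matches,
        "matched": matched,
        "own_reference_r": own_r,
        "own_reference_mag_like": mag_like_ref,
        "criteria": criteria,
    }
    if own_r > r_pitfall and mag_like_ref:
        return SADecision("flagged-pitfall", log)
    if criteria == "and":
        if subthreshold and matched:
            return SADecision("retrieved-subthreshold", log)
        return SADecision("rejected-outlier", log)
    if subthreshold:
        return SADecision("retrieved-subthreshold", log)
    if matched:
        return SADecision("retrieved-matched", log)
    return SADecision("rejected-outlier", log)


def assemble_unit(
    selected: np.ndarray,
    retrieved: np.ndarray,
    ws: WaveformSet,
    cluster_id: int | str = 0,
    cluster_size: int | None = None,
) -> UnitActivity:
    """Combine T²-selected and SA-retrieved spikes into one unit activity."""
    selected = np.asarray(selected, dtype=int)
    retrieved = np.asarray(retrieved, dtype=int)
    if np.intersect1d(selected, retrieved).size:
        raise ValueError("selected and retrieved spike ids must be disjoint")
    ids = np.concatenate([selected, retrieved])
    prov = np.array(["T2"] * selected.size + ["SA"] * retrieved.size)
    order = np.argsort(ws.timestamps[ids], kind="stable")
    if cluster_size is None:
        cluster_size = ids.size
    return UnitActivity(
        timestamps=ws.timestamps[ids][order],
        spike_ids=ids[order],
        provenance=prov[order],
        cluster_id=cluster_id,
        cluster_size=int(cluster_size),
        n_t2=int(selected.size),
        n_sa=int(retrieved.size),
    )


def apply_sa(
    ws: WaveformSet,
    selected: np.ndarray,
    unselected: np.ndarray,
    reference: ReferenceWaveform,
    rec: ContinuousRecording,
    noise: NoiseEstimate,
    epoch_s: float = 600.0,
    r_min: float = 0.95,
    mag_tol: float = 0.30,
    sigma_ceiling: float = SA_SIGMA_CEILING,
    criteria: str = "or",
    cluster_id: int | str = 0,
) -> tuple[UnitActivity, list[SADecision]]:
    """Run the SA over every T²-unselected waveform of one cluster.

    Returns the assembled unit (T²-selected + retrieved) and the per-outlier
    decisions, index-aligned with ``unselected``.
    """
    unselected = np.asarray(unselected, dtype=int)
    decisions: list[SADecision] = []
    retrieved: list[int] = []
    cache: RecordingScanCache | None = None
    for idx in unselected:
        residual = compute_residual(ws.waveforms[idx], reference, rate=ws.rate)
        if cache is None and residual.segment.size:
            try:
                cache = RecordingScanCache(rec, epoch_s, residual.segment.size)
            except ValueError:
                cache = None
        matches = scan_recording(
            residual,
            rec,
            epoch_s=epoch_s,
            r_min=r_min,
            mag_tol=mag_tol,
            exclude_time=ws.timestamps[idx],
            cache=cache,
        )
        decision = classify_outlier(
            residual, matches, noise, reference,
            sigma_ceiling=sigma_ceiling, r_pitfall=r_min, criteria=criteria,
        )
        decisions.append(decision)
        if decision.retrieved:
            retrieved.append(int(idx))
    unit = assemble_unit(
        np.asarray(selected, dtype=int),
        np.asarray(retrieved, dtype=int),
        ws,
        cluster_id=cluster_id,
        cluster_size=int(len(selected) + len(unselected)),
    )
    return unit, decisions
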