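import numpy as np
import pytest

from oligosort import (
    ContinuousRecording,
    NoiseEstimate,
    ReferenceWaveform,
    TemplateSpec,
    WaveformSet,
    assemble_unit,
    classify_outlier,
    compute_residual,
    make_template,
    scan_recording,
)
from oligosort.overlap import SAMatch

SIGMA = 10.0
A_SPEC = TemplateSpec(group_id=1, peak_snr=10.0)
B_SPEC = TemplateSpec(group_id=2, peak_snr=6.0, rise_ms=0.3, fall_ms=0.45,
                      ahp_frac=0.55, ahp_tau_ms=2.0)


def _reference(template, amplitude):
    return ReferenceWaveform(template * amplitude, n_averaged=20, align_index=120,
                             rate=10_000.0, source_cluster=1)


@pytest.fixture
def ref_a():
    return _reference(make_template(A_SPEC), 10 * SIGMA)


@pytest.fixture
def template_b():
    return make_template(B_SPEC) * 6 * SIGMA


@pytest.fixture
def b_recording(template_b):
    """60-s quiet recording with template B inserted at 10 known times."""
    rate = 10_000.0
    x = np.zeros(int(60 * rate))
    times = 2.0 + 5.0 * np.arange(10)
    for t in times:
        idx = int(t * rate)
        x[idx - 120 : idx + 130] += template_b
    return ContinuousRecording(x, rate=rate), times


def _empty_match():
    return SAMatch(np.array([]), np.array([]), np.array([]), 0, 60.0)


class TestComputeResidual:
    def test_identity_gives_zero(self, ref_a):
        res = compute_residual(ref_a.mean_waveform.copy(), ref_a)
        np.testing.assert_allclose(res.full_residual, 0.0)
        assert res.residual_peak == 0.0

    def test_overlap_recovers_added_template(self, ref_a, template_b):
        # B rides 4 ms ahead of the A peak (within the 2-15 ms search window)
        outlier = ref_a.mean_waveform + np.roll(template_b, -40)
        res = compute_residual(outlier, ref_a)
        assert res.residual_max_index == 80
        np.testing.assert_allclose(res.segment, np.roll(template_b, -40)[60:110])
        assert res.residual_peak == pytest.approx(6 * SIGMA)

    def test_double_amplitude_residual_is_reference(self, ref_a):
        res = compute_residual(2.0 * ref_a.mean_waveform, ref_a)
        np.testing.assert_allclose(res.full_residual, ref_a.mean_waveform)
        # pitfall precondition: residual correlates 1.0 with the own reference
        seg_ref = ref_a.mean_waveform[100:150]
        r = np.corrcoef(res.segment, seg_ref)[0, 1]
        assert r == pytest.approx(1.0)

    def test_misaligned_inputs_rejected(self, ref_a):
        with pytest.raises(ValueError):
            compute_residual(np.zeros(100), ref_a)


class TestScanRecording:
    def test_finds_inserted_occurrences(self, ref_a, template_b, b_recording):
        rec, times = b_recording
        outlier = ref_a.mean_waveform + np.roll(template_b, -40)
        res = compute_residual(outlier, ref_a)
        match = scan_recording(res, rec, epoch_s=60.0)
        assert match.n_matches >= 10
        assert np.all(match.correlations > 0.999)
        # every insertion is matched at its exact peak time
        for t in times:
            assert np.min(np.abs(match.match_times - t)) < 1e-3

    def test_all_zero_recording(self, ref_a, template_b):
        rec = ContinuousRecording(np.zeros(600_000), rate=10_000.0)
        outlier = ref_a.mean_waveform + np.roll(template_b, -40)
        res = compute_residual(outlier, ref_a)
        assert scan_recording(res, rec, epoch_s=60.0).n_matches == 0

    def test_magnitude_criterion_rejects_scaled_candidate(self, ref_a, template_b):
        # candidate at 1.4x the residual peak: r = 1 but 40% magnitude difference
        rate = 10_000.0
        x = np.zeros(int(30 * rate))
        idx = int(5 * rate)
        x[idx - 120 : idx + 130] += 1.4 * template_b
        rec = ContinuousRecording(x, rate=rate)
        outlier = ref_a.mean_waveform + np.roll(template_b, -40)
        res = compute_residual(outlier, ref_a)
        assert scan_recording(res, rec, epoch_s=30.0).n_matches == 0

    def test_own_position_excluded(self, ref_a, template_b):
        rate = 10_000.0
        x = np.zeros(int(30 * rate))
        t_own = 5.0
        idx = int(t_own * rate)
        x[idx - 120 : idx + 130] += template_b  # only occurrence: the outlier itself
        rec = ContinuousRecording(x, rate=rate)
        outlier = ref_a.mean_waveform + np.roll(template_b, -40)
        res = compute_residual(outlier, ref_a)
        # the residual B sits 4 ms before the snippet peak = outlier timestamp
        match = scan_recording(res, rec, epoch_s=30.0, exclude_time=t_own - 0.004)
        assert match.n_matches == 0

    def test_agrees_with_exhaustive_scan(self, rng, ref_a, template_b):
        # brute-force per-sample Pearson r is the oracle on a short epoch
        rate = 10_000.0
        x = rng.normal(0, 1.0, int(2 * rate))
        for t in (0.5, 1.2):
            idx = int(t * rate)
            x[idx - 120 : idx + 130] += template_b
        rec = ContinuousRecording(x, rate=rate)
        outlier = ref_a.mean_waveform + np.roll(template_b, -40)
        res = compute_residual(outlier, ref_a)
        match = scan_recording(res, rec, epoch_s=2.0, r_min=0.95)

        seg = res.segment
        L = seg.size
        r_brute = np.array(
            [np.corrcoef(x[i : i + L], seg)[0, 1] for i in range(x.size - L + 1)]
        )
        brute_hits = np.flatnonzero(r_brute > 0.95)
        # every reported match corresponds to a brute-force supra-threshold offset
        for t_m, r_m in zip(match.match_times, match.correlations):
            offset = int(round(t_m * rate)) - int(np.argmax(seg))
            assert offset in brute_hits
            assert r_m == pytest.approx(r_brute[offset], abs=1e-9)
        assert match.n_matches == 2


class TestClassify:
    def test_zero_residual_retrieved_subthreshold(self, ref_a):
        res = compute_residual(ref_a.mean_waveform.copy(), ref_a)
        d = classify_outlier(res, _empty_match(), NoiseEstimate(SIGMA, 5 * SIGMA), ref_a)
        assert d.verdict == "retrieved-subthreshold"

    def test_matched_residual_retrieved(self, ref_a, template_b, b_recording):
        rec, _ = b_recording
        outlier = ref_a.mean_waveform + np.roll(template_b, -40)
        res = compute_residual(outlier, ref_a)
        match = scan_recording(res, rec, epoch_s=60.0)
        d = classify_outlier(res, match, NoiseEstimate(SIGMA, 5 * SIGMA), ref_a)
        assert d.verdict == "retrieved-matched"

    def test_double_amplitude_flagged_pitfall(self, ref_a, b_recording):
        # even with matches present, a residual resembling the own reference
        # must be flagged, never silently retrieved
        rec, _ = b_recording
        res = compute_residual(2.0 * ref_a.mean_waveform, ref_a)
        fake_matches = SAMatch(np.array([1.0]), np.array([0.99]), np.array([1.0]), 1, 60.0)
        d = classify_outlier(res, fake_matches, NoiseEstimate(SIGMA, 5 * SIGMA), ref_a)
        assert d.verdict == "flagged-pitfall"

    def test_unmatched_suprathreshold_rejected(self, ref_a, rng):
        # a 6-sigma noise burst absent from the recording must be rejected
        burst = np.zeros(250)
        shape = rng.normal(0, 1, 50)
        shape[25] = 8.0  # clear positive peak
        burst[60:110] = shape / np.max(shape) * 6 * SIGMA
        outlier = ref_a.mean_waveform + burst
        res = compute_residual(outlier, ref_a)
        d = classify_outlier(res, _empty_match(), NoiseEstimate(SIGMA, 5 * SIGMA), ref_a)
        assert d.verdict == "rejected-outlier"

    def test_conjunctive_mode(self, ref_a, template_b, b_recording):
        rec, _ = b_recording
        outlier = ref_a.mean_waveform + np.roll(template_b, -40)
        res = compute_residual(outlier, ref_a)
        match = scan_recording(res, rec, epoch_s=60.0)
        noise = NoiseEstimate(SIGMA, 5 * SIGMA)
        # matched but above 4-sigma: the conjunctive reading rejects it
        d = classify_outlier(res, match, noise, ref_a, criteria="and")
        assert d.verdict == "rejected-outlier"


class TestAssembleUnit:
    def _ws(self, n):
        ts = np.arange(n, dtype=float) * 0.05
        return WaveformSet(np.zeros((n, 250)), 120, 10_000.0, ts)

    def test_empty_retrieved(self):
        ws = self._ws(10)
        unit = assemble_unit(np.arange(10), np.array([], int), ws, cluster_size=10)
        assert unit.n_spikes == 10
        assert (unit.provenance == "T2").all()

    def test_counts_and_fractions(self):
        ws = self._ws(100)
        unit = assemble_unit(np.arange(90), np.arange(90, 100), ws, cluster_size=110)
        assert unit.n_spikes == 100
        assert unit.n_sa == 10
        assert unit.fraction_retained == pytest.approx(100 / 110)
        assert unit.fraction_retrieved == pytest.approx(10 / 20)
        assert np.all(np.diff(unit.timestamps) > 0)

    def test_overlapping_ids_rejected(self):
        ws = self._ws(10)
        with pytest.raises(ValueError, match="disjoint"):
            assemble_unit(np.arange(5), np.arange(4, 8), ws)
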