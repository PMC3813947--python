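import numpy as np
import pytest

from oligosort import (
    ContinuousRecording,
    NoiseEstimate,
    TemplateSpec,
    WaveformSet,
    generate_dataset,
    make_template,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def noise_recording(rng):
    """100 s of white noise, SD 2 μV, at the canonical 10 kHz."""
    return ContinuousRecording(rng.normal(0, 2.0, 1_000_000), rate=10_000.0)


@pytest.fixture
def small_dataset():
    """Two well-separated groups in 30 s of σ=10 noise."""
    specs = [
        TemplateSpec(group_id=1, peak_snr=8.0, n_spikes=50, rise_ms=0.3, fall_ms=0.5,
                     ahp_frac=0.25, ahp_tau_ms=2.0),
        TemplateSpec(group_id=2, peak_snr=14.0, n_spikes=50, rise_ms=0.5, fall_ms=0.8,
                     ahp_frac=0.45, ahp_tau_ms=3.5),
    ]
    return generate_dataset(specs, noise_sigma=10.0, epoch_s=30.0, seed=7)


def template_waveform_set(spec=None, amplitude=80.0, n=20, noise_sd=0.0, seed=0,
                          rate=10_000.0):
    """WaveformSet of identical (optionally noisy) template snippets."""
    spec = spec or TemplateSpec(group_id=1, peak_snr=8.0)
    base = make_template(spec, rate) * amplitude
    rng = np.random.default_rng(seed)
    rows = np.tile(base, (n, 1))
    if noise_sd:
        rows = rows + rng.normal(0, noise_sd, rows.shape)
    ts = 0.5 + np.arange(n) * 0.1
    return WaveformSet(rows, align_index=120, rate=rate, timestamps=ts)


@pytest.fixture
def unit_noise_estimate():
    return NoiseEstimate(sigma_n=1.0, threshold=5.0)
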