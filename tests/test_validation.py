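import numpy as np
import pytest

from oligosort import (
    aicc,
    fit_feature_vs_isi,
    fit_gaussian_curve,
    isi_histogram,
    refractory_check,
    select_isi_model,
    validate_unit,
)
from oligosort.validation import (
    LN_REFRACTORY,
    ISIHistogram,
    exponential_relaxation,
    gaussian_sum,
)


def timestamps_from_isis(isis):
    return np.concatenate([[0.0], np.cumsum(isis)])


def lognormal_timestamps(mu, sd, n, seed=0):
    rng = np.random.default_rng(seed)
    return timestamps_from_isis(rng.lognormal(mu, sd, n))


class TestRefractory:
    def test_no_violations(self):
        n, frac, cls = refractory_check(timestamps_from_isis([0.005, 0.010]))
        assert (n, frac, cls) == (0, 0.0, "clean")

    def test_half_violating(self):
        n, frac, cls = refractory_check(timestamps_from_isis([0.002, 0.005]))
        assert n == 1
        assert frac == pytest.approx(0.5)
        assert cls == "violating"

    def test_threshold_partition(self):
        # 1 violation in 2000 ISIs (0.05%) is clean; 1 in 50 (2%) is violating
        clean = timestamps_from_isis([0.002] + [0.5] * 2000)
        bad = timestamps_from_isis([0.002] + [0.5] * 49)
        assert refractory_check(clean)[2] == "clean"
        assert refractory_check(bad)[2] == "violating"

    def test_left_edge_constant(self):
        assert LN_REFRACTORY == pytest.approx(-5.809, abs=1e-3)

    def test_too_few_spikes(self):
        with pytest.raises(ValueError):
            refractory_check(np.array([1.0]))


class TestHistogram:
    def test_scott_bin_width(self):
        ts = lognormal_timestamps(0.0, 1.0, 1000, seed=1)
        hist = isi_histogram(ts)
        ln = np.log(np.diff(ts))
        expected = 3.49 * np.std(ln, ddof=1) * ln.size ** (-1 / 3)
        assert hist.h == pytest.approx(expected, rel=1e-12)
        assert hist.bin_edges[0] == pytest.approx(LN_REFRACTORY)

    def test_normalization(self):
        for seed in (0, 1, 2):
            ts = lognormal_timestamps(-1.0, 0.8, 500, seed=seed)
            hist = isi_histogram(ts)
            assert np.sum(hist.pd * hist.h) == pytest.approx(1.0, abs=1e-9)

    def test_lognormal_density_recovery(self):
        # ln-ISIs ~ N(0,1): the histogram approximates the standard normal pdf
        ts = lognormal_timestamps(0.0, 1.0, 10_000, seed=42)
        hist = isi_histogram(ts)
        expected = np.exp(-0.5 * hist.centers**2) / np.sqrt(2 * np.pi)
        assert np.max(np.abs(hist.pd - expected)) < 0.05


class TestGaussianFit:
    def _hist_from_curve(self, a, b, c, span=4.0, n_bins=40):
        h = 2 * span / n_bins
        edges = b - span + h * np.arange(n_bins + 1)
        centers = 0.5 * (edges[:-1] + edges[1:])
        dens = gaussian_sum(centers, np.atleast_1d(a), np.atleast_1d(b), np.atleast_1d(c))
        return ISIHistogram(
            isis=np.array([]), ln_isis=np.array([]), bin_edges=edges,
            h=h, pd=dens, n_in_range=1000,
        )

    def test_peak_identity(self):
        assert gaussian_sum(0.0, [0.4], [0.0], [1.0]) == pytest.approx(0.4)

    def test_single_mode_parameter_recovery(self):
        hist = self._hist_from_curve(0.4, 0.0, 1.0)
        fit = fit_gaussian_curve(hist, 1)
        assert fit.amplitudes[0] == pytest.approx(0.4, abs=1e-4)
        assert fit.modes[0] == pytest.approx(0.0, abs=1e-4)
        assert fit.widths[0] == pytest.approx(1.0, abs=1e-4)
        assert fit.adjusted_r > 0.999

    def test_nested_models_reduce_ssr(self):
        h = 0.25
        edges = -4 + h * np.arange(41)
        centers = 0.5 * (edges[:-1] + edges[1:])
        dens = gaussian_sum(centers, [0.3, 0.2], [-2.0, 1.5], [0.5, 0.7])
        hist = ISIHistogram(np.array([]), np.array([]), edges, h, dens, 1000)
        f1 = fit_gaussian_curve(hist, 1)
        f2 = fit_gaussian_curve(hist, 2)
        assert f2.ssr <= f1.ssr + 1e-12
        assert f2.aicc < f1.aicc

    def test_mode_count_recovery_each_k(self):
        rng = np.random.default_rng(11)
        designs = {
            1: ([1.0], [0.5]),
            2: ([np.log(0.1), np.log(2.0)], [0.4, 0.4]),
            3: ([np.log(0.1), np.log(1.0), np.log(10.0)], [0.4, 0.4, 0.4]),
        }
        for true_k, (modes, widths) in designs.items():
            parts = [rng.lognormal(m, w, 5000 // len(modes)) for m, w in zip(modes, widths)]
            ts = timestamps_from_isis(rng.permutation(np.concatenate(parts)))
            hist = isi_histogram(ts)
            fits = {k: fit_gaussian_curve(hist, k, seed=0) for k in (1, 2, 3)}
            best_k, _ = select_isi_model(fits)
            assert best_k == true_k


class TestAICc:
    def test_hand_arithmetic(self):
        # 20·ln(1) + 2·3 + 2·3·4/16 = 7.5
        assert aicc(20.0, 20, 3) == pytest.approx(7.5)

    def test_monotone_in_ssr(self):
        vals = [aicc(s, 25, 6) for s in (1.0, 2.0, 5.0, 10.0)]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_guard(self):
        with pytest.raises(ValueError):
            aicc(1.0, 4, 3)

    def test_selection_arithmetic(self):
        class F:
            def __init__(self, a):
                self.aicc, self.converged = a, True

        best, deltas = select_isi_model({1: F(10.0), 2: F(5.0), 3: F(7.0)})
        assert best == 2
        assert deltas["2-1"] == pytest.approx(-5.0)
        assert deltas["3-1"] == pytest.approx(-3.0)
        assert deltas["3-2"] == pytest.approx(2.0)

    def test_only_converged_considered(self):
        class F:
            def __init__(self, a, ok=True):
                self.aicc, self.converged = a, ok

        best, _ = select_isi_model({1: F(10.0), 2: F(1.0, ok=False)})
        assert best == 1


class TestFeatureISI:
    def test_exponential_asymptote(self):
        y = exponential_relaxation(np.array([1e9]), 7.0, -3.0, 1.0)
        assert y[0] == pytest.approx(7.0)

    def test_exponential_recovery(self):
        # amplitudes relax with preceding ISI: y0=100, a=-30, t=1 (ln-s units)
        rng = np.random.default_rng(5)
        isis = rng.lognormal(-4.0, 0.8, 2000)
        x = np.log(isis)
        y = exponential_relaxation(x, 100.0, -30.0, 1.0) + rng.normal(0, 2.0, x.size)
        fit = fit_feature_vs_isi(y, isis, "peak_amplitude")
        assert fit.model == "exponential"
        assert fit.aicc_exponential < fit.aicc_linear
        assert fit.params["y0"] == pytest.approx(100.0, rel=0.10)
        assert fit.params["a"] == pytest.approx(-30.0, rel=0.10)
        assert fit.params["t"] == pytest.approx(1.0, rel=0.10)
        assert fit.p_value < 0.05

    def test_pure_noise_fails_goodness(self):
        rng = np.random.default_rng(8)
        isis = rng.lognormal(-2.0, 1.0, 1000)
        y = rng.normal(50.0, 5.0, isis.size)
        fit = fit_feature_vs_isi(y, isis, "peak_amplitude")
        assert fit.model == "failed"
        assert fit.p_value >= 0.05

    def test_linear_trend_selected(self):
        rng = np.random.default_rng(9)
        isis = rng.lognormal(-2.0, 1.0, 3000)
        x = np.log(isis)
        y = 2.0 * x + 10.0 + rng.normal(0, 0.5, x.size)
        fit = fit_feature_vs_isi(y, isis, "peak_amplitude")
        assert fit.model == "linear"
        assert fit.params["m"] == pytest.approx(2.0, rel=0.1)


class TestValidateUnit:
    def test_single_template_unit_verdict(self):
        ts = lognormal_timestamps(0.0, 0.7, 2000, seed=3)
        rep = validate_unit(ts)
        assert rep.refractory_class == "clean"
        assert rep.leftward_decline is True
        assert rep.single_fiber_verdict == "single-fiber"

    def test_merged_fibers_rejected(self):
        # two similar fibers: a 5-ms ISI mode plus refractory violations
        rng = np.random.default_rng(4)
        slow = rng.lognormal(0.5, 0.5, 1500)
        fast = rng.lognormal(np.log(0.005), 0.5, 500)  # overlap-induced short ISIs
        ts = timestamps_from_isis(rng.permutation(np.concatenate([slow, fast])))
        rep = validate_unit(ts)
        assert rep.single_fiber_verdict == "not-single-fiber"
        assert rep.refractory_class != "clean"

    def test_small_unit_partial(self):
        ts = np.linspace(0, 1, 10)
        rep = validate_unit(ts)
        assert rep.single_fiber_verdict == "partial"
        assert rep.best_isi_k is None
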