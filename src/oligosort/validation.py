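"""Single-fiber validation of unit activities.

Three lines of evidence decide whether a unit plausibly originates from one
fiber:

1. **Refractory analysis** -- interspike intervals (ISIs) below 3 ms violate
   the axonal refractory period; a unit is "clean" when fewer than 0.1% of
   its ISIs do.
2. **ISI probability distribution** -- sympathetic preganglionic firing
   yields near-Gaussian ISI densities on the natural-log scale.  ln-ISIs
   are binned with Scott's bin width h = 3.49·s·n^(-1/3) from ln(0.003)
   (= -5.809, the refractory bound) to the 99.9th percentile, and the
   density is fitted by sums of 1-3 Gaussians; the corrected Akaike
   information criterion AICc = n_b·ln(SSR/n_b) + 2K + 2K(K+1)/(n_b-K-1)
   selects the mode count.  A genuine single fiber shows the density
   declining promptly toward the refractory bound.
3. **Preceding-ISI dependence of waveform features** -- per-bin feature
   means are fitted against ln preceding-ISI by an exponential relaxation
   y = y0 + a·exp(-(x-x0)/t) or a line y = m·x + b, selected by AICc
   subject to a goodness-of-fit test (Spearman r of observed vs predicted,
   t = r·sqrt(df/(1-r²)), df = n_b - K - 1).

Note the goodness t-statistic uses the standard square-root form of the
t-for-correlation; see docs/methods.md for the convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "ISIHistogram",
    "GaussianCurveFit",
    "FeatureISIFit",
    "ValidationReport",
    "REFRACTORY_S",
    "LN_REFRACTORY",
    "refractory_check",
    "isi_histogram",
    "gaussian_sum",
    "fit_gaussian_curve",
    "aicc",
    "select_isi_model",
    "fit_feature_vs_isi",
    "validate_unit",
]

#: refractory period (s) and its natural log (the histogram's left edge)
REFRACTORY_S = 0.003
LN_REFRACTORY = float(np.log(REFRACTORY_S))  # -5.809
#: refractory-violation fraction below which a unit is "clean"
CLEAN_FRACTION = 0.001
#: boundary between "marginal" and "violating" (our operationalization)
VIOLATING_FRACTION = 0.01


@dataclass
class ISIHistogram:
    """ln-ISI probability density with Scott's-choice bins."""

    isis: np.ndarray
    ln_isis: np.ndarray
    bin_edges: np.ndarray
    h: float
    pd: np.ndarray
    n_in_range: int

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def n_bins(self) -> int:
        return self.pd.size


@dataclass
class GaussianCurveFit:
    """A k-mode Gaussian curve fitted to the ISI density."""

    k_modes: int
    amplitudes: np.ndarray
    modes: np.ndarray
    widths: np.ndarray
    ssr: float
    aicc: float
    adjusted_r: float
    converged: bool = True

    def predict(self, x: np.ndarray) -> np.ndarray:
        return gaussian_sum(x, self.amplitudes, self.modes, self.widths)


@dataclass
class FeatureISIFit:
    """Preceding-ISI dependence of one waveform feature."""

    feature_name: str
    model: str  # "exponential" | "linear" | "failed"
    params: dict
    aicc_exponential: float
    aicc_linear: float
    spearman_r: float
    t_stat: float
    p_value: float
    n_bins: int


@dataclass
class ValidationReport:
    """Combined single-fiber evidence for one unit activity."""

    n_spikes: int
    refractory_violations: int
    refractory_fraction: float
    refractory_class: str
    best_isi_k: int | None
    isi_fits: dict
    delta_aicc: dict
    leftward_decline: bool | None
    decline_ratio: float | None
    feature_fits: dict
    features_supporting: int
    single_fiber_verdict: str
    reasons: list = field(default_factory=list)


def refractory_check(
    timestamps: np.ndarray, refractory: float = REFRACTORY_S
) -> tuple[int, float, str]:
    """Count refractory violations (ISIs < 3 ms) and classify the unit.

    Returns ``(n_violations, fraction, class)`` with class ``clean``
    (< 0.1% of ISIs), ``marginal`` (< 1%) or ``violating``.
    """
    timestamps = np.asarray(timestamps, dtype=float)
    if timestamps.size < 2:
        raise ValueError("refractory analysis needs at least two spikes")
    isis = np.diff(np.sort(timestamps))
    n_viol = int((isis < refractory).sum())
    frac = n_viol / isis.size
    if frac < CLEAN_FRACTION:
        cls = "clean"
    elif frac < VIOLATING_FRACTION:
        cls = "marginal"
    else:
        cls = "violating"
    return n_viol, frac, cls


def isi_histogram(timestamps: np.ndarray) -> ISIHistogram:
    """ln-ISI density histogram with Scott's bin width.

    h = 3.49·s·n^(-1/3) on the ln-ISIs; the range runs from ln(0.003) to
    the 99.9th percentile of the ln-ISIs, and the density is normalized so
    that sum(pd)·h = 1 over the in-range ISIs.
    """
    timestamps = np.asarray(timestamps, dtype=float)
    isis = np.diff(np.sort(timestamps))
    isis = isis[isis > 0]
    if isis.size < 2:
        raise ValueError("need at least two positive ISIs")
    if isis.size < 30:
        warnings.warn(f"only {isis.size} ISIs; histogram will be unstable")
    ln = np.log(isis)
    s = float(np.std(ln, ddof=1))
    n = ln.size
    if s == 0:
        warnings.warn("all ISIs identical; degenerate single-bin histogram")
        h = 1e-6
        edges = np.array([ln[0] - h / 2, ln[0] + h / 2])
        return ISIHistogram(isis, ln, edges, h, np.array([1.0 / h]), n)
    h = 3.49 * s * n ** (-1.0 / 3.0)
    left = LN_REFRACTORY
    right = float(np.percentile(ln, 99.9))
    n_bins = max(int(np.ceil((right - left) / h)), 1)
    edges = left + h * np.arange(n_bins + 1)
    in_range = (ln >= left) & (ln <= edges[-1])
    counts, _ = np.histogram(ln[in_range], bins=edges)
    n_in = int(in_range.sum())
    dens = counts / (n_in * h) if n_in else counts.astype(float)
    return ISIHistogram(isis, ln, edges, h, dens, n_in)


def gaussian_sum(x, amplitudes, modes, widths) -> np.ndarray:
    """y = sum_i a_i · exp(-1/2·((x - b_i)/c_i)²)."""
    x = np.asarray(x, dtype=float)[..., None]
    a = np.asarray(amplitudes, dtype=float)
    b = np.asarray(modes, dtype=float)
    c = np.asarray(widths, dtype=float)
    return (a * np.exp(-0.5 * ((x - b) / c) ** 2)).sum(axis=-1)


def aicc(ssr: float, n_b: int, K: int) -> float:
    """Corrected Akaike information criterion for a least-squares fit."""
    if n_b <= K + 1:
        raise ValueError(f"AICc undefined: need n_b > K + 1 (n_b={n_b}, K={K})")
    if ssr <= 0:
        raise ValueError("AICc requires a positive SSR")
    return n_b * np.log(ssr / n_b) + 2 * K + 2 * K * (K + 1) / (n_b - K - 1)


def _adjusted_r(y: np.ndarray, yhat: np.ndarray, K: int) -> float:
    """Signed square root of adjusted R² (sign of the raw correlation)."""
    n = y.size
    sst = float(((y - y.mean()) ** 2).sum())
    ssr = float(((y - yhat) ** 2).sum())
    if sst == 0 or n - K - 1 <= 0:
        return 0.0
    r2 = 1.0 - ssr / sst
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - K - 1)
    sign = np.sign(np.corrcoef(y, yhat)[0, 1]) if np.std(yhat) > 0 else 1.0
    return float(sign * np.sqrt(max(adj, 0.0)))


def _greedy_peak_init(centers: np.ndarray, dens: np.ndarray, k: int, h: float):
    """Initial modes at the k largest density peaks, min separation 2h."""
    order = np.argsort(dens)[::-1]
    picked: list[int] = []
    for idx in order:
        if all(abs(centers[idx] - centers[j]) >= 2 * h for j in picked):
            picked.append(int(idx))
        if len(picked) == k:
            break
    while len(picked) < k:  # fall back to spreading over the range
        picked.append(int(np.argmax(np.abs(centers - centers[picked[-1]]))))
    return picked


def fit_gaussian_curve(hist: ISIHistogram, k_modes: int, n_restarts: int = 5, seed: int = 0) -> GaussianCurveFit:
    """Least-squares fit of a k-mode Gaussian sum to the binned ISI density.

    The fit runs over the occupied support (leading/trailing empty bins
    carry no information about the mode count) and is Poisson-weighted
    (bin-count variance grows with density, so an unweighted fit lets
    spurious modes chase noise near the peaks); AICc uses the weighted SSR.
    Modes initialize at the k largest histogram peaks (minimum separation
    2h), amplitudes at the peak densities, widths at h; jittered restarts
    guard against local minima.  Widths are bounded below by the bin width
    h -- a narrower feature cannot be resolved by the histogram.  A fit
    whose modes come closer than 2h, or whose smallest component is below
    5% of the peak density, is not a k-mode solution and is marked
    ``converged=False``; the same flag marks optimizer failure.
    """
    x_all, y_all = hist.centers, hist.pd
    occupied = np.flatnonzero(y_all > 0)
    if occupied.size == 0:
        raise ValueError("empty histogram")
    sl = slice(occupied[0], occupied[-1] + 1)
    x, y = x_all[sl], y_all[sl]
    n_b, K = x.size, 3 * k_modes
    if n_b <= K + 1:
        raise ValueError(f"too few occupied bins ({n_b}) for a {k_modes}-mode fit")
    w = 1.0 / np.sqrt(np.maximum(y, 0.05 * y.max()))
    peaks = _greedy_peak_init(x, y, k_modes, hist.h)
    base = np.concatenate(
        [np.maximum(y[peaks], 1e-6), x[peaks], np.full(k_modes, max(hist.h, 1e-3))]
    )
    lo = np.concatenate(
        [np.full(k_modes, 0.0), np.full(k_modes, x[0] - 5), np.full(k_modes, hist.h)]
    )
    hi_b = np.concatenate(
        [np.full(k_modes, 10 * max(y.max(), 1e-6)), np.full(k_modes, x[-1] + 5),
         np.full(k_modes, 10 * (x[-1] - x[0] + 1))]
    )

    def unpack(p):
        return p[:k_modes], p[k_modes : 2 * k_modes], p[2 * k_modes :]

    def residuals(p):
        return w * (gaussian_sum(x, *unpack(p)) - y)

    rng = np.random.default_rng(seed)
    best = None
    for trial in range(n_restarts):
        p0 = base.copy()
        if trial:
            p0 = p0 * (1 + 0.3 * rng.standard_normal(p0.size))
            p0[k_modes : 2 * k_modes] += hist.h * rng.standard_normal(k_modes)
        p0 = np.clip(p0, lo, hi_b)
        try:
            sol = optimize.least_squares(residuals, p0, bounds=(lo, hi_b), max_nfev=2000)
        except Exception:
            continue
        ssr = float(2 * sol.cost)
        if best is None or ssr < best[0]:
            best = (ssr, sol.x)
    if best is None:
        return GaussianCurveFit(
            k_modes, np.full(k_modes, np.nan), np.full(k_modes, np.nan),
            np.full(k_modes, np.nan), np.inf, np.inf, 0.0, converged=False,
        )
    ssr, p = best
    a, b, c = unpack(p)
    order = np.argsort(b)
    a, b, c = a[order], b[order], c[order]
    yhat = gaussian_sum(x, a, b, c)
    # identifiability: the fitted curve must genuinely show k distinct modes
    # (a sum of k Gaussians can be unimodal) with non-negligible components
    xg = np.linspace(b.min() - 3 * c.max(), b.max() + 3 * c.max(), 2000)
    yg = gaussian_sum(xg, a, b, c)
    dg = np.diff(yg)
    n_maxima = int(((dg[:-1] > 0) & (dg[1:] <= 0)).sum())
    identifiable = n_maxima >= k_modes and np.min(a) >= 0.05 * y.max()
    return GaussianCurveFit(
        k_modes=k_modes,
        amplitudes=a,
        modes=b,
        widths=c,
        ssr=ssr,
        aicc=aicc(max(ssr, 1e-300), n_b, K),
        adjusted_r=_adjusted_r(y, yhat, K),
        converged=identifiable,
    )


def select_isi_model(fits: dict) -> tuple[int | None, dict]:
    """Pick the mode count with minimal AICc; report pairwise ΔAICc.

    ``fits`` maps k -> GaussianCurveFit.  ΔAICc keys follow the
    higher-minus-lower convention, e.g. ``"2-1"`` = AICc(2) - AICc(1).
    """
    ok = {k: f for k, f in fits.items() if f.converged}
    if not ok:
        return None, {}
    best_k = min(ok, key=lambda k: ok[k].aicc)
    deltas = {}
    ks = sorted(ok)
    for i, k1 in enumerate(ks):
        for k2 in ks[i + 1 :]:
            deltas[f"{k2}-{k1}"] = ok[k2].aicc - ok[k1].aicc
    return best_k, deltas


def exponential_relaxation(x, y0, a, t, x0=LN_REFRACTORY):
    """y = y0 + a·exp(-(x - x0)/t); x0 fixed at ln(0.003) for identifiability."""
    return y0 + a * np.exp(-(np.asarray(x, dtype=float) - x0) / t)


def _goodness(y: np.ndarray, yhat: np.ndarray, K: int) -> tuple[float, float, float]:
    """Spearman r of observed vs predicted and the rooted t-test."""
    n_b = y.size
    df = n_b - K - 1
    if df <= 0 or np.std(yhat) == 0:
        return 0.0, 0.0, 1.0
    r = float(stats.spearmanr(y, yhat).statistic)
    if not np.isfinite(r):
        return 0.0, 0.0, 1.0
    if abs(r) >= 1.0:
        return r, np.inf, 0.0
    t = r * np.sqrt(df / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df)
    return r, float(t), float(p)


def fit_feature_vs_isi(
    feature_values: np.ndarray,
    preceding_isis: np.ndarray,
    feature_name: str = "feature",
    alpha: float = 0.05,
    seed: int = 0,
) -> FeatureISIFit:
    """Fit a feature's per-bin means against ln preceding-ISI.

    Both the exponential-relaxation model (free y0, a, t; K=3) and the
    linear model (K=2) are attempted; the lower-AICc model wins unless its
    goodness test fails while the other's passes.  ``model="failed"`` marks
    p >= alpha for the winner.
    """
    y_all = np.asarray(feature_values, dtype=float)
    isis = np.asarray(preceding_isis, dtype=float)
    keep = np.isfinite(y_all) & (isis > 0)
    y_all, isis = y_all[keep], isis[keep]
    if y_all.size < 10:
        raise ValueError("too few spikes for a feature-vs-ISI fit")
    ln = np.log(isis)
    s = float(np.std(ln, ddof=1))
    h = 3.49 * s * ln.size ** (-1.0 / 3.0) if s > 0 else 1.0
    edges = np.arange(ln.min(), ln.max() + h, h)
    if edges.size < 2:
        edges = np.array([ln.min() - h / 2, ln.min() + h / 2])
    which = np.clip(np.digitize(ln, edges) - 1, 0, edges.size - 2)
    centers, means = [], []
    for b in range(edges.size - 1):
        mask = which == b
        if mask.sum() >= 2:
            centers.append(0.5 * (edges[b] + edges[b + 1]))
            means.append(y_all[mask].mean())
    x, y = np.asarray(centers), np.asarray(means)
    n_b = x.size
    if n_b < 6:  # need n_b > K + 1 for the exponential (K=3)
        raise ValueError(f"only {n_b} populated ISI bins; cannot fit")

    # linear (K=2)
    m, b0 = np.polyfit(x, y, 1)
    yhat_lin = m * x + b0
    ssr_lin = float(((y - yhat_lin) ** 2).sum())
    aicc_lin = aicc(max(ssr_lin, 1e-300), n_b, 2)
    r_lin, t_lin, p_lin = _goodness(y, yhat_lin, 2)

    # exponential relaxation (K=3), multi-start on the time constant
    span = max(x.max() - x.min(), 1e-3)
    rng = np.random.default_rng(seed)
    best = None
    for t0 in (span / 10, span / 3, span, 3 * span):
        for jitter in range(2):
            a0 = (y[0] - y[-1]) * np.exp((x[0] - LN_REFRACTORY) / t0)
            p0 = np.array([y[-1], a0 if np.isfinite(a0) else y[0] - y[-1], t0])
            if jitter:
                p0 = p0 * (1 + 0.2 * rng.standard_normal(3))
            p0[2] = abs(p0[2]) or t0
            try:
                sol = optimize.least_squares(
                    lambda p: exponential_relaxation(x, p[0], p[1], p[2]) - y,
                    p0,
                    bounds=([-np.inf, -np.inf, 1e-4], [np.inf, np.inf, 100 * span]),
                    max_nfev=2000,
                )
            except Exception:
                continue
            ssr = float(2 * sol.cost)
            if best is None or ssr < best[0]:
                best = (ssr, sol.x)
    if best is not None:
        ssr_exp, (y0_e, a_e, t_e) = best
        yhat_exp = exponential_relaxation(x, y0_e, a_e, t_e)
        aicc_exp = aicc(max(ssr_exp, 1e-300), n_b, 3)
        r_exp, t_exp, p_exp = _goodness(y, yhat_exp, 3)
    else:
        aicc_exp, p_exp = np.inf, 1.0

    # model selection: lower AICc wins unless its goodness test fails
    cand = []
    if best is not None:
        cand.append(("exponential", aicc_exp, p_exp,
                     {"y0": float(y0_e), "a": float(a_e), "x0": LN_REFRACTORY, "t": float(t_e)},
                     (r_exp, t_exp, p_exp)))
    cand.append(("linear", aicc_lin, p_lin, {"m": float(m), "b": float(b0)},
                 (r_lin, t_lin, p_lin)))
    cand.sort(key=lambda c: c[1])
    chosen = cand[0]
    if chosen[2] >= alpha and len(cand) > 1 and cand[1][2] < alpha:
        chosen = cand[1]
    name, _, p_val, params, (r_s, t_s, p_s) = chosen
    model = name if p_s < alpha else "failed"
    return FeatureISIFit(
        feature_name=feature_name,
        model=model,
        params=params,
        aicc_exponential=float(aicc_exp),
        aicc_linear=float(aicc_lin),
        spearman_r=r_s,
        t_stat=t_s,
        p_value=p_s,
        n_bins=n_b,
    )


#: decline threshold: fitted density at ln(0.003) below this fraction of the
#: smallest-mode peak counts as "declined promptly"
DECLINE_RATIO = 0.10


def validate_unit(
    timestamps: np.ndarray,
    feature_table: pd.DataFrame | None = None,
    max_modes: int = 3,
    decline_ratio: float = DECLINE_RATIO,
    seed: int = 0,
) -> ValidationReport:
    """Run the full single-fiber battery on one unit activity.

    With fewer than 30 spikes only the refractory check runs and the
    verdict is ``partial``.  The verdict is ``single-fiber`` when the unit
    is refractory-clean and its fitted ISI density declines toward the
    refractory bound; successful feature-vs-ISI fits are reported as
    supporting evidence (their absence does not veto).
    """
    timestamps = np.asarray(timestamps, dtype=float)
    reasons: list[str] = []
    n_viol, frac, cls = refractory_check(timestamps)
    if timestamps.size < 30:
        return ValidationReport(
            n_spikes=timestamps.size,
            refractory_violations=n_viol,
            refractory_fraction=frac,
            refractory_class=cls,
            best_isi_k=None, isi_fits={}, delta_aicc={},
            leftward_decline=None, decline_ratio=None,
            feature_fits={}, features_supporting=0,
            single_fiber_verdict="partial",
            reasons=[f"only {timestamps.size} spikes; full battery needs >= 30"],
        )

    hist = isi_histogram(timestamps)
    fits: dict[int, GaussianCurveFit] = {}
    for k in range(1, max_modes + 1):
        try:
            fits[k] = fit_gaussian_curve(hist, k, seed=seed)
        except ValueError:
            continue
    best_k, deltas = select_isi_model(fits)

    decline = None
    ratio = None
    if best_k is not None:
        fit = fits[best_k]
        left_val = float(fit.predict(np.array([LN_REFRACTORY]))[0])
        smallest_peak = float(fit.amplitudes.min())
        ratio = left_val / smallest_peak if smallest_peak > 0 else np.inf
        decline = ratio < decline_ratio
        if not decline:
            reasons.append(
                f"ISI density at ln(3 ms) is {ratio:.2f} of the smallest mode peak"
            )
    else:
        reasons.append("no converged ISI Gaussian fit")

    feature_fits: dict[str, FeatureISIFit] = {}
    supporting = 0
    if feature_table is not None and len(feature_table) == timestamps.size:
        order = np.argsort(timestamps)
        isis_prec = np.diff(timestamps[order])
        for name in feature_table.columns:
            if name == "ref_correlation":
                continue
            vals = np.asarray(feature_table[name], dtype=float)[order][1:]
            try:
                ff = fit_feature_vs_isi(vals, isis_prec, feature_name=name, seed=seed)
            except ValueError:
                continue
            feature_fits[name] = ff
            if ff.model != "failed":
                supporting += 1

    if cls != "clean":
        reasons.append(f"refractory class {cls} ({frac:.2%} ISIs < 3 ms)")
    verdict = (
        "single-fiber"
        if cls == "clean" and decline is True
        else "not-single-fiber"
    )
    return ValidationReport(
        n_spikes=timestamps.size,
        refractory_violations=n_viol,
        refractory_fraction=frac,
        refractory_class=cls,
        best_isi_k=best_k,
        isi_fits=fits,
        delta_aicc=deltas,
        leftward_decline=decline,
        decline_ratio=ratio,
        feature_fits=feature_fits,
        features_supporting=supporting,
        single_fiber_verdict=verdict,
        reasons=reasons,
    )
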