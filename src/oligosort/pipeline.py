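"""End-to-end orchestration: detect -> features -> cluster -> T² -> SA.

`sort_recording` runs the whole chain on one continuous recording and
returns a `SortResult` holding every intermediate product, the per-cluster
unit activities (T²-selected plus SA-retrieved spikes), and the bookkeeping
counts (spikes detected, cluster sizes, T²-unselected, SA-retrieved).  The
`RunConfig` dataclass carries every tunable with its default and
round-trips through YAML for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import detection, features
from .clustering import ClusterModel, kmeans, silhouette
from .detection import NoiseEstimate, ReferenceWaveform, WaveformSet
from .features import FEATURE_NAMES, FeatureTable
from .homogeneity import pca_fit, select_by_t2
from .io import ContinuousRecording
from .overlap import SADecision, UnitActivity, apply_sa, assemble_unit

__all__ = ["RunConfig", "SortResult", "sort_recording"]


@dataclass
class RunConfig:
    """Every pipeline tunable, with the defaults used throughout."""

    # detection
    threshold_multiplier: float = 5.0
    min_separation_s: float = 0.001
    polarity: str = "positive"
    # windows (ms)
    snippet_pre_ms: float = 12.0
    snippet_post_ms: float = 13.0
    # clustering
    k: int = 2
    metric: str = "cityblock"
    representation: str = "features"  # "features" | "full-waveform"
    active_features: tuple = FEATURE_NAMES
    n_restarts: int = 10
    seed: int = 0
    # homogeneity
    scope: float = 0.9999
    t2_iterate: bool = False
    # subtraction algorithm
    sa_enabled: bool = True
    sa_r_min: float = 0.95
    sa_mag_tol: float = 0.30
    sa_sigma_ceiling: float = 4.0
    sa_epoch_s: float = 600.0
    sa_criteria: str = "or"
    # validation
    refractory_s: float = 0.003
    clean_fraction: float = 0.001
    max_modes: int = 3

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "active_features" in data:
            data["active_features"] = tuple(data["active_features"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["active_features"] = list(d["active_features"])
        return d

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class SortResult:
    """All products of one pipeline run."""

    noise: NoiseEstimate
    events: list
    waveforms: WaveformSet
    feature_table: FeatureTable
    z: np.ndarray
    cluster_model: ClusterModel
    references: dict  # cluster -> ReferenceWaveform
    t2_selected: dict  # cluster -> indices into the waveform set
    t2_unselected: dict
    sa_decisions: dict  # cluster -> list[SADecision]
    units: list  # UnitActivity per cluster (ordered by cluster id)
    silhouette_mean: float
    config: RunConfig

    def counts(self) -> dict:
        """Stage-by-stage bookkeeping, cluster by cluster."""
        per_cluster = {}
        for unit in self.units:
            c = unit.cluster_id
            per_cluster[str(c)] = {
                "cluster_size": unit.cluster_size,
                "t2_selected": unit.n_t2,
                "t2_unselected": unit.cluster_size - unit.n_t2,
                "sa_retrieved": unit.n_sa,
                "unit_spikes": unit.n_spikes,
            }
        return {
            "spikes_detected": len(self.events),
            "clusters": int(self.cluster_model.k),
            "silhouette_mean": self.silhouette_mean,
            "per_cluster": per_cluster,
        }


def _provisional_reference(ws: WaveformSet, n_avg: int = 20) -> ReferenceWaveform:
    """Reference for feature extraction before clusters exist.

    Averages the ``n_avg`` waveforms most similar (by correlation) to the
    overall mean -- a stand-in for the manual pick of similarly shaped
    spikes.
    """
    mean = ws.waveforms.mean(axis=0)
    mc = mean - mean.mean()
    w = ws.waveforms - ws.waveforms.mean(axis=1, keepdims=True)
    denom = np.linalg.norm(w, axis=1) * np.linalg.norm(mc)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 0, w @ mc / denom, 0.0)
    pick = np.argsort(corr)[::-1][: min(n_avg, ws.n_spikes)]
    return detection.build_reference(ws, pick, source_cluster="provisional")


def sort_recording(
    rec: ContinuousRecording,
    config: RunConfig | None = None,
    noise: NoiseEstimate | None = None,
) -> SortResult:
    """Run the full sorting chain on one recording."""
    cfg = config or RunConfig()
    if noise is None:
        noise = detection.estimate_noise_sigma(rec)
        if cfg.threshold_multiplier != detection.THRESHOLD_MULTIPLIER:
            noise = NoiseEstimate(
                sigma_n=noise.sigma_n,
                threshold=cfg.threshold_multiplier * noise.sigma_n,
                method_window=noise.method_window,
            )
    events = detection.detect_spikes(
        rec, noise, min_separation=cfg.min_separation_s, polarity=cfg.polarity
    )
    if len(events) < max(cfg.k + 1, 8):
        raise ValueError(
            f"only {len(events)} spikes detected; too few to sort with k={cfg.k}"
        )
    ws = detection.extract_waveforms(
        rec, events, pre_ms=cfg.snippet_pre_ms, post_ms=cfg.snippet_post_ms
    )

    ref0 = _provisional_reference(ws)
    ft = features.extract_features(ws, ref0)
    if cfg.representation == "features":
        ft = features.zscore_features(ft, active=cfg.active_features)
        z = ft.zscores.to_numpy()
    elif cfg.representation == "full-waveform":
        z = features.zscore_matrix(features.full_waveform_vectors(ws))
    else:
        raise ValueError(f"unknown representation {cfg.representation!r}")

    model = kmeans(
        z, cfg.k, metric=cfg.metric, seed=cfg.seed, n_restarts=cfg.n_restarts,
        representation=cfg.representation,
    )
    sil = silhouette(z, model.labels, metric=cfg.metric) if cfg.k > 1 else None

    references: dict = {}
    t2_sel: dict = {}
    t2_unsel: dict = {}
    sa_decisions: dict = {}
    units: list[UnitActivity] = []
    for c in range(cfg.k):
        idx = model.cluster_indices(c)
        if idx.size <= z.shape[1] + 1:
            # too small for a T² model: keep everything, skip SA
            warnings.warn(f"cluster {c}: only {idx.size} spikes; T² selection skipped")
            references[c] = detection.build_reference(ws, idx, source_cluster=c)
            t2_sel[c], t2_unsel[c], sa_decisions[c] = idx, np.array([], int), []
            units.append(
                assemble_unit(idx, np.array([], int), ws, cluster_id=c,
                              cluster_size=idx.size)
            )
            continue
        sel_local, unsel_local, _ = select_by_t2(
            z[idx], scope=cfg.scope, iterate=cfg.t2_iterate
        )
        sel, unsel = idx[sel_local], idx[unsel_local]
        ref = detection.build_reference(ws, sel, source_cluster=c)
        references[c] = ref
        t2_sel[c], t2_unsel[c] = sel, unsel
        if cfg.sa_enabled and unsel.size:
            unit, decisions = apply_sa(
                ws, sel, unsel, ref, rec, noise,
                epoch_s=cfg.sa_epoch_s, r_min=cfg.sa_r_min,
                mag_tol=cfg.sa_mag_tol, sigma_ceiling=cfg.sa_sigma_ceiling,
                criteria=cfg.sa_criteria, cluster_id=c,
            )
        else:
            decisions = []
            unit = assemble_unit(sel, np.array([], int), ws, cluster_id=c,
                                 cluster_size=idx.size)
        sa_decisions[c] = decisions
        units.append(unit)

    return SortResult(
        noise=noise,
        events=events,
        waveforms=ws,
        feature_table=ft,
        z=z,
        cluster_model=model,
        references=references,
        t2_selected=t2_sel,
        t2_unselected=t2_unsel,
        sa_decisions=sa_decisions,
        units=units,
        silhouette_mean=sil.overall_mean if sil else 0.0,
        config=cfg,
    )
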