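"""End-to-end orchestration: audio/scene -> LTSA -> separation -> ecology.

``run_pipeline`` chains every stage — input acquisition (WAV directory,
saved grid, or synthetic scene), prewhitening, PC-NMF training with optional
manual indicator overrides, activation prediction and ratio-mask
reconstruction, intensity/phenology analysis, and event detection plus
clustering — writing per-stage artifacts and a machine-readable JSON report
stamped with a configuration hash for reproducibility.
"""

from __future__ import annotations

import configparser
import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import diversity, ltsa, pcnmf, phenology, synthetic

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("soundscapeir.pipeline")


@dataclass
class PipelineConfig:
    """Flat configuration for a full run; defaults follow the study settings.

    Exactly one input among ``audio_dir``, ``ltsa_file``, ``synthetic`` must
    be provided.  ``mask_ranges`` are (start_iso, end_iso) pairs zeroed out
    of the intensity series before analysis.
    """

    # input
    audio_dir: str | None = None
    ltsa_file: str | None = None
    synthetic: bool = False
    scene_days: float = 7.0
    scene_seed: int = 0
    scene_sources: int = 4
    # LTSA
    fft_size: int = 4096
    fmax: float | None = None
    clip_seconds: float = 30.0
    # PC-NMF
    n_features: int = 90
    n_sources: int = 4
    sparseness: float = 0.5
    patch_minutes: float = 15.0
    train_iters: int = 200
    predict_iters: int = 200
    seed: int = 0
    overrides: dict[int, int] = field(default_factory=dict)
    # phenology
    max_lag_days: float = 2.0
    envelope_window_days: float = 1.0
    # (source_label_or_*, start_iso, end_iso): zeroed before normalization
    mask_ranges: list[tuple[str, str, str]] = field(default_factory=list)
    # diversity
    detection_threshold: float = 0.05
    k_min: int = 1
    k_max: int = 8
    pca_variance: float = 0.90
    r_threshold: float = 93.0

    def config_hash(self) -> str:
        payload = json.dumps(
            dataclasses.asdict(self), sort_keys=True, default=str
        ).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    @classmethod
    def from_ini(cls, path: str | Path) -> "PipelineConfig":
        parser = configparser.ConfigParser()
        parser.read(str(path))
        kwargs = {}
        fields = {f.name: f for f in dataclasses.fields(cls)}
        for section in parser.sections():
            for key, raw in parser.items(section):
                if key not in fields:
                    raise ValueError(f"unknown config key: {key}")
                if key == "overrides":
                    kwargs[key] = {
                        int(a): int(b)
                        for a, b in (p.split("=") for p in raw.split(",") if p.strip())
                    }
                elif key == "mask_ranges":
                    kwargs[key] = [
                        tuple(p.split("/")) for p in raw.split(",") if p.strip()
                    ]
                else:
                    ftype = fields[key].type
                    if raw.lower() in {"true", "false"}:
                        kwargs[key] = raw.lower() == "true"
                    elif "int" in str(ftype):
                        kwargs[key] = int(raw)
                    elif "float" in str(ftype):
                        kwargs[key] = float(raw)
                    else:
                        kwargs[key] = raw
        return cls(**kwargs)

    def to_ini(self, path: str | Path) -> None:
        parser = configparser.ConfigParser()
        parser["pipeline"] = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if v is None:
                continue
            if f.name == "overrides":
                v = ",".join(f"{a}={b}" for a, b in sorted(v.items()))
            elif f.name == "mask_ranges":
                v = ",".join("/".join(r) for r in v)
            parser["pipeline"][f.name] = str(v)
        with open(path, "w") as fh:
            parser.write(fh)


class PipelineError(RuntimeError):
    """Raised when a stage fails; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            log.info("stage %s", name)
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - rewrap with stage name
                raise PipelineError(name, exc) from exc

        return wrapped

    return deco


@_stage("input")
def _acquire(config: PipelineConfig, workdir: Path):
    if config.synthetic:
        sources = synthetic.default_sources()[: config.scene_sources]
        scene = synthetic.SceneConfig(
            duration_days=config.scene_days,
            sources=sources,
            clip_seconds=config.clip_seconds,
            seed=config.scene_seed,
        )
        grid, truth = synthetic.generate_ltsa_scene(scene)
        labels = list(truth.source_names)
        return grid, labels
    if config.ltsa_file:
        loaded = ltsa.load_grid(config.ltsa_file)
        if isinstance(loaded, ltsa.LTSA):
            loaded, _ = ltsa.prewhiten(loaded)
        return loaded, None
    if config.audio_dir:
        paths = sorted(Path(config.audio_dir).glob("*.wav"))
        built = ltsa.build_ltsa(paths, fft_size=config.fft_size, fmax=config.fmax)
        pre, _ = ltsa.prewhiten(built)
        return pre, None
    raise ValueError("config must set one of audio_dir, ltsa_file, synthetic")


@_stage("separation")
def _separate(config: PipelineConfig, grid, labels):
    frames = max(1, int(round(config.patch_minutes * 60.0 / config.clip_seconds)))
    folded = pcnmf.fold(grid, frames)
    model = pcnmf.train(
        folded,
        n_features=config.n_features,
        n_sources=config.n_sources,
        sparseness_target=config.sparseness,
        iterations=config.train_iters,
        seed=config.seed,
    )
    if config.overrides:
        model = pcnmf.adjust_indicators(model, config.overrides)
    H = pcnmf.predict_activations(
        model, folded, iterations=config.predict_iters, seed=config.seed + 1
    )
    if labels is None:
        labels = [f"source_{s}" for s in range(config.n_sources)]
    separated = pcnmf.reconstruct(model, folded, H, source_labels=labels)
    return model, separated


@_stage("phenology")
def _phenology(config: PipelineConfig, separated):
    series = {}
    for label, grid in zip(separated.labels, separated.grids):
        ranges = [
            (start, end)
            for who, start, end in config.mask_ranges
            if who in ("*", label)
        ]
        series[label] = phenology.intensity_series(
            grid,
            mask_ranges=ranges,
            label=label,
            time_axis=separated.time_axis,
        )
    correlations = {}
    labels = list(series)
    max_lag = config.max_lag_days * 86400.0
    window = config.envelope_window_days * 86400.0
    for i, a in enumerate(labels):
        lc = phenology.lag_correlation(series[a], max_lag=max_lag, envelope_window=window)
        correlations[f"{a}~{a}"] = lc
        for b in labels[i + 1 :]:
            lc = phenology.lag_correlation(
                series[a], series[b], max_lag=max_lag, envelope_window=window
            )
            correlations[f"{a}~{b}"] = lc
    return series, correlations


@_stage("diversity")
def _diversity(config: PipelineConfig, series, separated):
    out = {}
    for label, grid in zip(separated.labels, separated.grids):
        events = diversity.detect_events(
            series[label], grid, threshold=config.detection_threshold
        )
        entry = {"events": events, "results": None, "chosen_k": None}
        k_hi = min(config.k_max, len(events))
        if len(events) >= 2 and k_hi >= config.k_min:
            results = diversity.cluster_events(
                events,
                range(config.k_min, k_hi + 1),
                pca_variance=config.pca_variance,
                seed=config.seed,
            )
            entry["results"] = results
            entry["chosen_k"] = diversity.choose_k(results, config.r_threshold)
        out[label] = entry
    return out


def run_pipeline(config: PipelineConfig, workdir: str | Path) -> dict:
    """Execute every stage and return the machine-readable run report.

    Artifacts (separated grids, intensity CSVs, event tables, report JSON)
    land under ``workdir``; every output carries the configuration hash.
    The report is deterministic for a fixed config, so its SHA-256 hash
    certifies end-to-end reproducibility.
    """
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    config.to_ini(workdir / f"config_{chash}.ini")

    grid, labels = _acquire(config, workdir)
    model, separated = _separate(config, grid, labels)
    pcnmf.save_model(workdir / f"model_{chash}.npz", model)
    np.savez(
        workdir / f"separated_{chash}.npz",
        **{lbl: g for lbl, g in zip(separated.labels, separated.grids)},
    )
    series, correlations = _phenology(config, separated)
    for label, s in series.items():
        s.to_frame().to_csv(workdir / f"intensity_{label}_{chash}.csv", index=False)
    div = _diversity(config, series, separated)

    report = {
        "config_hash": chash,
        "seed": config.seed,
        "n_sources": config.n_sources,
        "n_features": config.n_features,
        "source_labels": list(separated.labels),
        "event_counts": {},
        "r_vs_k": {},
        "chosen_k": {},
        "correlation_peaks": {},
    }
    for label, entry in div.items():
        events = entry["events"]
        report["event_counts"][label] = len(events)
        if entry["results"] is not None:
            report["r_vs_k"][label] = [
                [r.k, round(r.R, 6)] for r in entry["results"]
            ]
            report["chosen_k"][label] = entry["chosen_k"]
            best = entry["results"][-1]
            diversity.events_to_frame(events, best.assignments).to_csv(
                workdir / f"events_{label}_{chash}.csv", index=False
            )
        elif events:
            diversity.events_to_frame(events).to_csv(
                workdir / f"events_{label}_{chash}.csv", index=False
            )
    for pair, lc in correlations.items():
        report["correlation_peaks"][pair] = [
            [round(lag / 86400.0, 6), round(score, 6)] for lag, score in lc.peaks
        ]
    text = json.dumps(report, sort_keys=True, indent=1)
    report["report_hash"] = hashlib.sha256(text.encode()).hexdigest()
    with open(workdir / f"report_{chash}.json", "w") as fh:
        json.dump(report, fh, sort_keys=True, indent=1)
    return report
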