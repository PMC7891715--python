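"""Synthetic soundscape scenes with known source structure.

Emulates the statistical structure the separation pipeline assumes: several
additive sources, each with a fixed spectral envelope and a source-specific
occupancy schedule (diurnal, nocturnal-transient, aperiodic, or constant
tonal), mixed on top of an optional stationary noise floor.  Scenes can be
materialized either directly as a prewhitened-LTSA-shaped grid (the fast
path used by all downstream analyses) or as timestamped mono WAV clips.

The default four-source scene mirrors a deep-water continental-shelf
soundscape: aperiodic broadband abiotic sound (wind, rain, shipping), a
dusk-peaking fish chorus confined to 0.5-3 kHz with spectral peaks near
750 Hz and 2.5 kHz, nocturnal cetacean transients at >= 4 kHz, and
electrical noise with fixed-frequency tonal peaks.  Ground truth (per-frame
activity labels, true intensities, and per-source grids) is returned
alongside every scene so separation quality can be scored.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .ltsa import PrewhitenedLTSA

__all__ = [
    "BandProfile",
    "DiurnalSchedule",
    "ConstantSchedule",
    "SmoothedNoiseSchedule",
    "SeasonalSchedule",
    "ProductSchedule",
    "SourceSpec",
    "SceneConfig",
    "GroundTruth",
    "generate_ltsa_scene",
    "generate_wav_scene",
    "default_sources",
    "ACTIVITY_FLOOR",
]

#: A frame counts as "active" for a source when its true integrated energy
#: exceeds this fraction of the source's maximum — the same 0.05 relative
#: threshold convention used for event detection downstream.
ACTIVITY_FLOOR = 0.05


# ---------------------------------------------------------------------------
# spectral envelopes


@dataclass(frozen=True)
class BandProfile:
    """Nonnegative spectral envelope: a cosine-tapered band plus Gaussian peaks.

    ``decay_hz`` adds an exponential low-frequency emphasis (broadband abiotic
    sound is reddest at low frequency); ``peaks`` are (center_hz, width_hz,
    gain) Gaussian bumps on top of the band plateau.
    """

    f_lo: float
    f_hi: float
    base: float = 1.0
    peaks: tuple[tuple[float, float, float], ...] = ()
    decay_hz: float | None = None
    taper_frac: float = 0.15

    def __call__(self, freqs: np.ndarray) -> np.ndarray:
        f = np.asarray(freqs, dtype=np.float64)
        width = max(self.f_hi - self.f_lo, 1e-9)
        taper = self.taper_frac * width
        env = np.zeros_like(f)
        inside = (f >= self.f_lo) & (f <= self.f_hi)
        env[inside] = self.base
        if taper > 0:
            lo_edge = inside & (f < self.f_lo + taper)
            env[lo_edge] *= 0.5 - 0.5 * np.cos(np.pi * (f[lo_edge] - self.f_lo) / taper)
            hi_edge = inside & (f > self.f_hi - taper)
            env[hi_edge] *= 0.5 - 0.5 * np.cos(np.pi * (self.f_hi - f[hi_edge]) / taper)
        if self.decay_hz is not None:
            env *= np.exp(-np.maximum(f - self.f_lo, 0.0) / self.decay_hz)
        for center, width_hz, gain in self.peaks:
            env += gain * np.exp(-0.5 * ((f - center) / width_hz) ** 2)
        return env


# ---------------------------------------------------------------------------
# occupancy schedules (absolute time in hours since scene start -> [0, 1])


@dataclass(frozen=True)
class DiurnalSchedule:
    """Gaussian occupancy bump centered at a given hour of day (24 h period)."""

    peak_hour: float
    width_hours: float = 1.5
    floor: float = 0.0

    def __call__(self, t_hours: np.ndarray) -> np.ndarray:
        hod = np.mod(t_hours, 24.0)
        # circular distance to the peak hour
        d = np.abs(hod - self.peak_hour)
        d = np.minimum(d, 24.0 - d)
        return self.floor + (1.0 - self.floor) * np.exp(-0.5 * (d / self.width_hours) ** 2)


@dataclass(frozen=True)
class ConstantSchedule:
    level: float = 1.0

    def __call__(self, t_hours: np.ndarray) -> np.ndarray:
        return np.full_like(np.asarray(t_hours, dtype=np.float64), self.level)


@dataclass(frozen=True)
class SmoothedNoiseSchedule:
    """Aperiodic occupancy: low-pass-filtered uniform noise, deterministic per seed.

    Knots are drawn every ``correlation_hours`` on an absolute-time grid and
    interpolated, so evaluation is reproducible and independent of the query
    grid's resolution.  Because generated grids represent *prewhitened*
    (above-ambient) levels, the schedule is floor-referenced: values below
    the ``floor_quantile`` of the raw noise map to exactly 0, so an aperiodic
    source appears as episodic excursions above its own ambient level — the
    structure percentile noise-floor subtraction produces on real data.
    """

    seed: int = 0
    correlation_hours: float = 6.0
    low: float = 0.0
    high: float = 1.0
    floor_quantile: float = 0.35

    def __call__(self, t_hours: np.ndarray) -> np.ndarray:
        t = np.asarray(t_hours, dtype=np.float64)
        rng = np.random.default_rng(self.seed)
        n_knots = int(math.floor(t.max() / self.correlation_hours)) + 3
        knots_t = (np.arange(n_knots) - 1) * self.correlation_hours
        knots_v = rng.uniform(self.low, self.high, size=n_knots)
        raw = np.interp(t, knots_t, knots_v)
        floor = self.low + self.floor_quantile * (self.high - self.low)
        span = max(self.high - floor, 1e-12)
        return np.clip((raw - floor) / span, 0.0, 1.0)


@dataclass(frozen=True)
class SeasonalSchedule:
    """Gaussian occupancy bump on the yearly cycle, centered at a day of year."""

    peak_day: float
    width_days: float = 30.0
    floor: float = 0.1
    start_day_of_year: float = 0.0

    def __call__(self, t_hours: np.ndarray) -> np.ndarray:
        doy = np.mod(self.start_day_of_year + np.asarray(t_hours) / 24.0, 365.25)
        d = np.abs(doy - self.peak_day)
        d = np.minimum(d, 365.25 - d)
        return self.floor + (1.0 - self.floor) * np.exp(-0.5 * (d / self.width_days) ** 2)


@dataclass(frozen=True)
class ProductSchedule:
    """Pointwise product of schedules (e.g. diurnal bump x seasonal modulation)."""

    factors: tuple

    def __call__(self, t_hours: np.ndarray) -> np.ndarray:
        out = np.ones_like(np.asarray(t_hours, dtype=np.float64))
        for s in self.factors:
            out = out * s(t_hours)
        return out


# ---------------------------------------------------------------------------
# scene specification


@dataclass(frozen=True)
class SourceSpec:
    """One sound source: spectral envelope, occupancy schedule, and statistics.

    ``amplitude`` is the source's peak level in the same relative-dB-above-
    floor units as a prewhitened LTSA.  ``event_rate`` is the expected
    fraction of scheduled frames in which the source is actually active
    (1 for a continuous chorus, < 1 for intermittent transients).
    ``waveform`` selects the time-domain synthesis style for WAV scenes:
    band-filtered Gaussian noise ("noise", chorus-like) or exponentially
    decaying tone pulses ("pulses", transient/click-like).
    """

    name: str
    band_profile: Callable[[np.ndarray], np.ndarray]
    schedule: Callable[[np.ndarray], np.ndarray]
    amplitude: float = 1.0
    amplitude_jitter: float = 0.3
    event_rate: float = 1.0
    waveform: str = "noise"

    def validate(self, freqs: np.ndarray) -> None:
        if not 0.0 <= self.event_rate <= 1.0:
            raise ValueError(f"source {self.name!r}: event_rate must be in [0, 1]")
        if self.amplitude_jitter < 0:
            raise ValueError(f"source {self.name!r}: amplitude_jitter must be >= 0")
        prof = np.asarray(self.band_profile(freqs))
        if (prof < 0).any():
            raise ValueError(f"source {self.name!r}: band_profile must be >= 0")
        sched = np.asarray(self.schedule(np.linspace(0.0, 48.0, 97)))
        if (sched < -1e-12).any() or (sched > 1 + 1e-12).any():
            raise ValueError(f"source {self.name!r}: schedule values must lie in [0, 1]")


@dataclass(frozen=True)
class SceneConfig:
    """Full description of a synthetic scene; fixed seed => bit-reproducible."""

    duration_days: float
    sources: tuple[SourceSpec, ...]
    clip_seconds: float = 30.0
    sample_rate: float = 16_000.0
    fft_size: int = 256
    noise_floor_profile: Callable[[np.ndarray], np.ndarray] | None = None
    cell_jitter: float = 0.05
    start_time: np.datetime64 = np.datetime64("2012-06-01T00:00:00", "s")
    seed: int = 0

    def __post_init__(self):
        if self.duration_days <= 0:
            raise ValueError("duration_days must be > 0")
        if self.clip_seconds <= 0:
            raise ValueError("clip_seconds must be > 0")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be > 0")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_days * 86400.0 / self.clip_seconds))

    @property
    def freq_axis(self) -> np.ndarray:
        return np.fft.rfftfreq(self.fft_size, d=1.0 / self.sample_rate)

    @property
    def time_axis(self) -> np.ndarray:
        step = np.timedelta64(int(round(self.clip_seconds)), "s")
        return self.start_time + np.arange(self.n_frames) * step


@dataclass
class GroundTruth:
    """Per-frame truth for a generated scene."""

    source_names: list[str]
    labels: np.ndarray  # (n_frames, n_sources) bool: active frames
    intensities: np.ndarray  # (n_frames, n_sources) true integrated energy
    grids: list[np.ndarray]  # per-source (n_freq, n_frames) contribution
    time_axis: np.ndarray
    freq_axis: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.intensities, columns=self.source_names, index=self.time_axis
        )
        df.index.name = "time"
        return df


def _source_amplitudes(config: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-frame amplitude A_s(t) for every source: schedule x activity x jitter."""
    t_hours = np.arange(config.n_frames) * (config.clip_seconds / 3600.0)
    A = np.empty((len(config.sources), config.n_frames))
    for i, src in enumerate(config.sources):
        sched = np.clip(np.asarray(src.schedule(t_hours), dtype=np.float64), 0.0, 1.0)
        active = rng.random(config.n_frames) < src.event_rate
        jitter = np.exp(
            src.amplitude_jitter * rng.standard_normal(config.n_frames)
            - 0.5 * src.amplitude_jitter**2
        )
        A[i] = src.amplitude * sched * active * jitter
    return A


def generate_ltsa_scene(config: SceneConfig) -> tuple[PrewhitenedLTSA, GroundTruth]:
    """Generate an additive prewhitened-LTSA-shaped scene plus ground truth.

    The mixture is ``sum_s A_s(t) * band_profile_s(f) * speckle`` with no
    noise-floor term (the grid is "already prewhitened": background excluded).
    A frame is labelled active for a source when the source's true integrated
    energy exceeds :data:`ACTIVITY_FLOOR` of its maximum.
    """
    if len(config.sources) == 0:
        raise ValueError("scene needs at least one source")
    freqs = config.freq_axis
    profiles = []
    for src in config.sources:
        src.validate(freqs)
        profiles.append(np.asarray(src.band_profile(freqs), dtype=np.float64))
    for i in range(len(profiles)):
        for j in range(i + 1, len(profiles)):
            if np.allclose(profiles[i], profiles[j]):
                warnings.warn(
                    f"sources {config.sources[i].name!r} and "
                    f"{config.sources[j].name!r} have identical band profiles",
                    stacklevel=2,
                )
    rng = np.random.default_rng(config.seed)
    A = _source_amplitudes(config, rng)
    grids: list[np.ndarray] = []
    for i, prof in enumerate(profiles):
        X = np.outer(prof, A[i])
        if config.cell_jitter > 0:
            X = X * np.exp(
                config.cell_jitter * rng.standard_normal(X.shape)
                - 0.5 * config.cell_jitter**2
            )
        grids.append(X)
    M = np.sum(grids, axis=0)
    intensities = np.stack([g.sum(axis=0) for g in grids], axis=1)
    peak = intensities.max(axis=0)
    labels = intensities > ACTIVITY_FLOOR * np.where(peak > 0, peak, 1.0)
    truth = GroundTruth(
        source_names=[s.name for s in config.sources],
        labels=labels,
        intensities=intensities,
        grids=grids,
        time_axis=config.time_axis,
        freq_axis=freqs,
    )
    grid = PrewhitenedLTSA(Pw=M, freq_axis=freqs, time_axis=config.time_axis)
    return grid, truth


# ---------------------------------------------------------------------------
# waveform synthesis


def _shaped_noise(rng: np.random.Generator, n: int, profile: np.ndarray) -> np.ndarray:
    """Gaussian noise spectrally shaped by an envelope sampled on rfft bins."""
    spectrum = np.fft.rfft(rng.standard_normal(n))
    return np.fft.irfft(spectrum * profile, n=n)


def _tone_pulses(
    rng: np.random.Generator,
    n: int,
    sample_rate: float,
    centers: Sequence[float],
    n_pulses: int = 8,
    decay_s: float = 0.05,
) -> np.ndarray:
    """A train of exponentially decaying sinusoid pulses (click/whistle-like)."""
    out = np.zeros(n)
    t = np.arange(n) / sample_rate
    for _ in range(n_pulses):
        start = rng.uniform(0.0, max(n / sample_rate - 5 * decay_s, 1e-3))
        f0 = float(rng.choice(np.asarray(centers, dtype=np.float64)))
        phase = rng.uniform(0, 2 * np.pi)
        rel = t - start
        env = np.where(rel >= 0, np.exp(-np.maximum(rel, 0.0) / decay_s), 0.0)
        out += env * np.sin(2 * np.pi * f0 * rel + phase)
    return out


def _pulse_centers(src: SourceSpec, nyquist: float) -> list[float]:
    prof = src.band_profile
    if isinstance(prof, BandProfile) and prof.peaks:
        return [p[0] for p in prof.peaks]
    if isinstance(prof, BandProfile):
        return [0.5 * (prof.f_lo + min(prof.f_hi, nyquist))]
    return [0.25 * nyquist]


def generate_wav_scene(
    config: SceneConfig, out_dir: str | Path
) -> tuple[pd.DataFrame, GroundTruth]:
    """Write one mono 16-bit PCM WAV per clip and return the manifest + truth.

    Filenames follow the ``YYYYMMDD_HHMMSS.wav`` convention so the clips can
    be fed straight back into :func:`soundscapeir.ltsa.build_ltsa`.  The clip
    content is statistical, not a reproduction of real signals: shaped noise
    and decaying tone pulses with the configured band envelopes, on top of a
    stationary colored background.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    nyquist = config.sample_rate / 2.0
    for src in config.sources:
        prof = src.band_profile
        if isinstance(prof, BandProfile) and prof.f_lo >= nyquist:
            raise ValueError(
                f"source {src.name!r}: band {prof.f_lo:.0f}-{prof.f_hi:.0f} Hz "
                f"exceeds the Nyquist frequency {nyquist:.0f} Hz"
            )
    n = int(round(config.clip_seconds * config.sample_rate))
    clip_freqs = np.fft.rfftfreq(n, d=1.0 / config.sample_rate)
    profiles = [np.asarray(s.band_profile(clip_freqs)) for s in config.sources]
    background = (
        np.asarray(config.noise_floor_profile(clip_freqs))
        if config.noise_floor_profile is not None
        else None
    )
    rng = np.random.default_rng(config.seed)
    A = _source_amplitudes(config, rng)
    active_frames = A > 0
    rows = []
    step = np.timedelta64(int(round(config.clip_seconds)), "s")
    for k in range(config.n_frames):
        start = config.start_time + k * step
        samples = np.zeros(n)
        if background is not None:
            samples += 0.01 * _shaped_noise(rng, n, background)
        for i, src in enumerate(config.sources):
            if A[i, k] <= 0:
                continue
            if src.waveform == "pulses":
                sig = _tone_pulses(rng, n, config.sample_rate, _pulse_centers(src, nyquist))
            else:
                sig = _shaped_noise(rng, n, profiles[i])
            rms = np.sqrt(np.mean(sig**2))
            if rms > 0:
                sig = sig / rms
            samples += 0.01 * A[i, k] * sig
        stamp = (
            np.datetime_as_string(start, unit="s").replace("-", "").replace(":", "")
        ).replace("T", "_")
        path = out_dir / f"{stamp}.wav"
        peak_allowed = 0.99 * np.iinfo(np.int16).max
        scaled = np.clip(samples * 1000.0, -peak_allowed, peak_allowed)
        wavfile.write(str(path), int(config.sample_rate), scaled.astype(np.int16))
        rows.append(
            {
                "file": path.name,
                "iso_start_time": np.datetime_as_string(start, unit="s"),
                "active_sources": ";".join(
                    src.name
                    for i, src in enumerate(config.sources)
                    if active_frames[i, k]
                ),
            }
        )
    # truth intensities mirror the LTSA-scene convention: envelope-integrated
    profiles_ltsa = [np.asarray(s.band_profile(config.freq_axis)) for s in config.sources]
    grids = [np.outer(p, A[i]) for i, p in enumerate(profiles_ltsa)]
    if grids:
        intensities = np.stack([g.sum(axis=0) for g in grids], axis=1)
    else:
        intensities = np.zeros((config.n_frames, 0))
    peak = intensities.max(axis=0) if grids else np.zeros(0)
    labels = intensities > ACTIVITY_FLOOR * np.where(peak > 0, peak, 1.0)
    truth = GroundTruth(
        source_names=[s.name for s in config.sources],
        labels=labels,
        intensities=intensities,
        grids=grids,
        time_axis=config.time_axis,
        freq_axis=config.freq_axis,
    )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest, truth


# ---------------------------------------------------------------------------
# default study scene


def default_sources(
    sample_rate: float = 16_000.0, aperiodic_seed: int = 7
) -> tuple[SourceSpec, ...]:
    """The canonical four-source scene, rescaled to the desk-scale band.

    At the default 16 kHz rate the biotic bands fit the analysis band
    unchanged (fish chorus 0.5-3 kHz with 750/2500 Hz peaks, cetacean
    transients >= 4 kHz capped just below Nyquist); broadband abiotic sound
    spans the whole band with low-frequency emphasis, and electrical noise
    contributes fixed-frequency tonal peaks.  Amplitudes are relative-dB-
    above-floor levels with the biotic sources standing clearly above the
    abiotic continuum when active.
    """
    nyq = sample_rate / 2.0
    return (
        SourceSpec(
            name="abiotic",
            band_profile=BandProfile(f_lo=0.0, f_hi=nyq, base=1.0, decay_hz=0.4 * nyq),
            schedule=SmoothedNoiseSchedule(seed=aperiodic_seed, correlation_hours=6.0),
            amplitude=10.0,
            amplitude_jitter=0.3,
            event_rate=1.0,
            waveform="noise",
        ),
        SourceSpec(
            name="fish_chorus",
            band_profile=BandProfile(
                f_lo=500.0,
                f_hi=3000.0,
                base=0.4,
                peaks=((750.0, 150.0, 1.0), (2500.0, 200.0, 0.8)),
            ),
            schedule=DiurnalSchedule(peak_hour=20.0, width_hours=1.5),
            amplitude=18.0,
            amplitude_jitter=0.3,
            event_rate=1.0,
            waveform="noise",
        ),
        SourceSpec(
            name="cetacean",
            band_profile=BandProfile(f_lo=4000.0, f_hi=0.98 * nyq, base=1.0),
            schedule=DiurnalSchedule(peak_hour=1.0, width_hours=3.0),
            amplitude=18.0,
            amplitude_jitter=0.5,
            event_rate=0.5,
            waveform="pulses",
        ),
        SourceSpec(
            name="electrical",
            band_profile=BandProfile(
                f_lo=0.0,
                f_hi=nyq,
                base=0.0,
                peaks=((1500.0, 40.0, 1.0), (3500.0, 40.0, 0.8), (6000.0, 40.0, 0.6)),
            ),
            schedule=ConstantSchedule(0.8),
            amplitude=12.0,
            amplitude_jitter=0.5,
            event_rate=0.9,
            waveform="noise",
        ),
    )
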