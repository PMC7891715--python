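"""Long-term spectral average (LTSA) construction and percentile prewhitening.

An LTSA compresses days to years of audio into a single time-frequency grid:
each fixed-duration clip (nominally 30 s) contributes one column, the
log-scaled mean of its magnitude spectrogram.  Subtracting the per-frequency
10th-percentile noise floor ("prewhitening") and clipping negatives to zero
yields a nonnegative signal-above-background grid, which is the input to all
downstream separation and phenology analyses.

Levels are uncalibrated relative dB throughout; absolute sound pressure is
not needed by the pipeline.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.io import wavfile

__all__ = [
    "ClipSpectrogram",
    "LTSA",
    "NoiseFloor",
    "PrewhitenedLTSA",
    "clip_spectrogram",
    "mean_log_spectrum",
    "build_ltsa",
    "prewhiten",
    "parse_clip_timestamp",
    "read_wav_clip",
    "save_grid",
    "load_grid",
    "plot_ltsa",
]

#: dB value assigned to bins whose mean magnitude is exactly zero.  Keeps the
#: grid bounded; prewhitening later maps these cells to zero anyway.
LOG_FLOOR_DB = -120.0


@dataclass
class ClipSpectrogram:
    """Magnitude spectrogram of one audio clip (non-overlapping frames)."""

    S: np.ndarray  # (n_freq_bins, n_frames), magnitude, >= 0
    freq_axis: np.ndarray  # Hz
    frame_axis: np.ndarray  # seconds within the clip (frame start times)


@dataclass
class LTSA:
    """Log-scaled mean-spectrum grid; one column per clip."""

    P: np.ndarray  # (n_freq_bins, n_clips), relative dB
    freq_axis: np.ndarray  # Hz
    time_axis: np.ndarray  # datetime64[s] clip start times, strictly increasing


@dataclass
class NoiseFloor:
    """Per-frequency-bin noise floor estimate (percentile of the LTSA rows)."""

    level: np.ndarray  # dB, same freq axis as the source LTSA
    freq_axis: np.ndarray
    percentile: float = 0.10


@dataclass
class PrewhitenedLTSA:
    """Nonnegative signal-above-noise-floor grid."""

    Pw: np.ndarray  # (n_freq_bins, n_clips), >= 0
    freq_axis: np.ndarray
    time_axis: np.ndarray
    noise_floor: NoiseFloor | None = None


_TIMESTAMP_RE = re.compile(r"(\d{8})_(\d{6})")


def parse_clip_timestamp(name: str | Path) -> np.datetime64:
    """Parse a ``YYYYMMDD_HHMMSS`` timestamp out of a clip filename."""
    m = _TIMESTAMP_RE.search(Path(name).stem)
    if m is None:
        raise ValueError(f"no YYYYMMDD_HHMMSS timestamp in filename: {name!r}")
    d, t = m.groups()
    iso = f"{d[:4]}-{d[4:6]}-{d[6:]}T{t[:2]}:{t[2:4]}:{t[4:]}"
    return np.datetime64(iso, "s")


def read_wav_clip(path: str | Path) -> tuple[np.ndarray, float]:
    """Read a mono PCM WAV clip, returning (float samples, sample_rate)."""
    rate, data = wavfile.read(str(path))
    if data.ndim != 1:
        raise ValueError(f"expected mono audio, got {data.ndim} channels: {path}")
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float64) / float(np.iinfo(data.dtype).max)
    else:
        data = data.astype(np.float64)
    return data, float(rate)


def clip_spectrogram(
    samples: np.ndarray,
    sample_rate: float,
    fft_size: int = 4096,
    window: str = "hamming",
) -> ClipSpectrogram:
    """Non-overlapping windowed DFT magnitude spectrogram of one clip.

    Frames are exactly ``fft_size`` samples with zero overlap; a trailing
    partial frame is discarded.
    """
    samples = np.asarray(samples, dtype=np.float64)
    if samples.ndim != 1:
        raise ValueError("samples must be a 1-D mono waveform")
    n_frames = len(samples) // fft_size
    if n_frames < 1:
        raise ValueError(
            f"clip too short: {len(samples)} samples < one FFT frame ({fft_size})"
        )
    frames = samples[: n_frames * fft_size].reshape(n_frames, fft_size)
    if window == "hamming":
        win = np.hamming(fft_size)
    else:
        from scipy.signal import get_window

        win = get_window(window, fft_size, fftbins=True)
    S = np.abs(np.fft.rfft(frames * win, axis=1)).T  # (n_bins, n_frames)
    freq_axis = np.fft.rfftfreq(fft_size, d=1.0 / sample_rate)
    frame_axis = np.arange(n_frames) * (fft_size / sample_rate)
    return ClipSpectrogram(S=S, freq_axis=freq_axis, frame_axis=frame_axis)


def mean_log_spectrum(spec: ClipSpectrogram, floor_db: float = LOG_FLOOR_DB) -> np.ndarray:
    """Log-scaled mean spectrum of a clip: 10*log10(mean over time of |S|).

    Bins whose time-mean magnitude is exactly zero map to ``floor_db``.
    """
    mean = spec.S.mean(axis=1)
    out = np.full(mean.shape, floor_db, dtype=np.float64)
    pos = mean > 0
    out[pos] = 10.0 * np.log10(mean[pos])
    return np.maximum(out, floor_db)


def build_ltsa(
    clips: Iterable[str | Path] | Sequence[tuple[np.datetime64, np.ndarray, float]],
    fft_size: int = 4096,
    fmax: float | None = None,
    window: str = "hamming",
    timestamp_parser: Callable[[str | Path], np.datetime64] = parse_clip_timestamp,
) -> LTSA:
    """Assemble an LTSA from time-ordered audio clips.

    ``clips`` is either an iterable of WAV paths (timestamps parsed from the
    filename) or of ``(start_time, samples, sample_rate)`` tuples.  One column
    per clip; missing clips simply leave gaps in ``time_axis`` — nothing is
    imputed.  The frequency axis is truncated at ``fmax`` (the analysis limit;
    the full band is kept if None).
    """
    columns: list[np.ndarray] = []
    times: list[np.datetime64] = []
    freq_axis: np.ndarray | None = None
    rate0: float | None = None
    for clip in clips:
        if isinstance(clip, (str, Path)):
            samples, rate = read_wav_clip(clip)
            t = timestamp_parser(clip)
            label = str(clip)
        else:
            t, samples, rate = clip
            label = str(t)
        if rate0 is None:
            rate0 = rate
        elif rate != rate0:
            raise ValueError(
                f"inconsistent sample rate in {label}: {rate} Hz (expected {rate0})"
            )
        spec = clip_spectrogram(samples, rate, fft_size=fft_size, window=window)
        if freq_axis is None:
            freq_axis = spec.freq_axis
        columns.append(mean_log_spectrum(spec))
        times.append(np.datetime64(t, "s"))
    if not columns:
        raise ValueError("empty clip list: cannot build an LTSA")
    order = np.argsort(np.asarray(times))
    P = np.stack([columns[i] for i in order], axis=1)
    time_axis = np.asarray(times)[order]
    if fmax is not None:
        keep = freq_axis <= fmax
        P = P[keep]
        freq_axis = freq_axis[keep]
    return LTSA(P=P, freq_axis=freq_axis, time_axis=time_axis)


def prewhiten(ltsa: LTSA, percentile: float = 0.10) -> tuple[PrewhitenedLTSA, NoiseFloor]:
    """Subtract the per-frequency percentile noise floor, clipping at zero.

    The noise floor is the ``percentile`` (default 10th) order statistic of
    each frequency row, computed with linear interpolation.  Output cells are
    ``max(P - floor, 0)``; by construction roughly the lowest ``percentile``
    fraction of every row becomes exactly zero.
    """
    if not 0.0 < percentile < 1.0:
        raise ValueError("percentile must be in (0, 1)")
    if ltsa.P.shape[1] < 10:
        raise ValueError(
            f"need >= 10 columns for a meaningful percentile floor, got {ltsa.P.shape[1]}"
        )
    level = np.percentile(ltsa.P, percentile * 100.0, axis=1)
    floor = NoiseFloor(level=level, freq_axis=ltsa.freq_axis, percentile=percentile)
    Pw = np.maximum(ltsa.P - level[:, None], 0.0)
    return (
        PrewhitenedLTSA(
            Pw=Pw, freq_axis=ltsa.freq_axis, time_axis=ltsa.time_axis, noise_floor=floor
        ),
        floor,
    )


def save_grid(path: str | Path, grid: LTSA | PrewhitenedLTSA, **metadata) -> None:
    """Persist an LTSA or prewhitened grid as a NumPy array archive."""
    arrays = {
        "grid": grid.P if isinstance(grid, LTSA) else grid.Pw,
        "freq_axis": grid.freq_axis,
        "time_axis": grid.time_axis.astype("datetime64[s]").astype(np.int64),
        "prewhitened": np.array(isinstance(grid, PrewhitenedLTSA)),
    }
    if isinstance(grid, PrewhitenedLTSA) and grid.noise_floor is not None:
        arrays["noise_floor"] = grid.noise_floor.level
    for k, v in metadata.items():
        arrays[f"meta_{k}"] = np.asarray(v)
    np.savez(str(path), **arrays)


def load_grid(path: str | Path) -> LTSA | PrewhitenedLTSA:
    """Load a grid saved by :func:`save_grid`."""
    with np.load(str(path), allow_pickle=False) as z:
        grid = z["grid"]
        freq_axis = z["freq_axis"]
        time_axis = z["time_axis"].astype("datetime64[s]")
        if bool(z["prewhitened"]):
            floor = None
            if "noise_floor" in z:
                floor = NoiseFloor(level=z["noise_floor"], freq_axis=freq_axis)
            return PrewhitenedLTSA(
                Pw=grid, freq_axis=freq_axis, time_axis=time_axis, noise_floor=floor
            )
        return LTSA(P=grid, freq_axis=freq_axis, time_axis=time_axis)


def plot_ltsa(grid: LTSA | PrewhitenedLTSA, ax=None, cmap: str = "viridis"):
    """Render a grid as a time-frequency heatmap (basic visualization)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 4))
    data = grid.P if isinstance(grid, LTSA) else grid.Pw
    t = grid.time_axis.astype("datetime64[s]").astype("O")
    im = ax.pcolormesh(
        np.arange(data.shape[1] + 1),
        np.concatenate([grid.freq_axis, [2 * grid.freq_axis[-1] - grid.freq_axis[-2]]]),
        data,
        cmap=cmap,
        shading="flat",
    )
    ax.set_xlabel(f"clip index ({t[0]} .. {t[-1]})")
    ax.set_ylabel("frequency (Hz)")
    ax.figure.colorbar(im, ax=ax, label="relative dB")
    return ax
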