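"""Acoustic-diversity assessment: event detection, clustering, summaries.

Acoustic events are contiguous above-threshold runs of a separated source's
relative intensity (threshold 0.05), merged across silent gaps of at most
10 minutes and discarded when shorter than 1 minute.  Each event carries a
min-max-normalized mean spectrum pooled over its detected frames.  Event
spectra are reduced by PCA (components explaining > 90% of variance) and
clustered with k-means; the quality of a k-cluster solution is scored by

    R_k = 100 * (1 - sum_i D_i / D_1)

the percent of total dispersion (D_1, squared distances to the global
centroid) represented by the cluster centroids (D_i, within-cluster squared
distances).  R_1 = 0 and R_n = 100 by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .phenology import IntensitySeries

__all__ = [
    "AcousticEvent",
    "ClusteringResult",
    "ClusterSummary",
    "detect_events",
    "cluster_events",
    "choose_k",
    "summarize_clusters",
    "events_to_frame",
]


@dataclass
class AcousticEvent:
    """A contiguous detection of one source with its pooled mean spectrum."""

    source: str
    start: np.datetime64
    end: np.datetime64  # exclusive (last frame start + frame duration)
    duration_min: float
    frame_times: np.ndarray  # detected frame start times within the event
    mean_spectrum: np.ndarray  # min-max normalized per-frequency vector


@dataclass
class ClusteringResult:
    k: int
    assignments: np.ndarray  # event index -> cluster id
    centroids: np.ndarray  # in PCA space
    dispersions: np.ndarray  # per-cluster within-cluster squared distances D_i
    total_dispersion: float  # D_1: squared distances to the global centroid
    R: float  # percent of dispersion represented
    pca_components_kept: int
    variance_explained_by_pca: float


@dataclass
class ClusterSummary:
    """Per-cluster mean spectra and duration-weighted detection probabilities."""

    mean_spectra: np.ndarray  # (k, n_freq)
    hourly_probability: np.ndarray  # (k, 24), rows sum to 1
    monthly_probability: np.ndarray  # (k, 12), rows sum to 1


def detect_events(
    series: IntensitySeries,
    source_grid: np.ndarray,
    threshold: float = 0.05,
    merge_gap_min: float = 10.0,
    min_duration_min: float = 1.0,
) -> list[AcousticEvent]:
    """Detect acoustic events from a relative-intensity series.

    Frames with intensity >= ``threshold`` are detections.  Consecutive
    detection runs merge when the silent gap between them is at most
    ``merge_gap_min`` minutes (a gap must *exceed* the limit to split);
    events lasting less than ``min_duration_min`` minutes are discarded.
    The mean spectrum pools the source grid over the event's detected
    frames, then min-max normalizes.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    grid = np.asarray(source_grid)
    if grid.shape[1] != len(series.values):
        raise ValueError("series and grid must share the time axis")
    t = series.time_axis.astype("datetime64[s]")
    dt = series.dt_seconds
    det = np.nonzero(np.asarray(series.values) >= threshold)[0]
    if det.size == 0:
        return []
    # split detected frames into runs, merging across gaps <= merge_gap_min
    groups: list[list[int]] = [[int(det[0])]]
    for i in det[1:]:
        prev = groups[-1][-1]
        gap_s = (i - prev - 1) * dt  # silent time between frame ends/starts
        if gap_s > merge_gap_min * 60.0:
            groups.append([int(i)])
        else:
            groups[-1].append(int(i))
    events = []
    for g in groups:
        start = t[g[0]]
        end = t[g[-1]] + np.timedelta64(int(round(dt)), "s")
        duration_min = float((end - start) / np.timedelta64(1, "s")) / 60.0
        if duration_min < min_duration_min:
            continue
        spec = grid[:, g].mean(axis=1)
        lo, hi = spec.min(), spec.max()
        if hi - lo > 0:
            spec = (spec - lo) / (hi - lo)
        else:
            warnings.warn("constant event spectrum; normalized to zeros", stacklevel=2)
            spec = np.zeros_like(spec)
        events.append(
            AcousticEvent(
                source=series.label,
                start=start,
                end=end,
                duration_min=duration_min,
                frame_times=t[g],
                mean_spectrum=spec,
            )
        )
    return events


def cluster_events(
    events: Sequence[AcousticEvent],
    k_range: Sequence[int],
    pca_variance: float = 0.90,
    seed: int = 0,
    n_restarts: int = 10,
) -> list[ClusteringResult]:
    """PCA + k-means over event mean spectra for each k in ``k_range``.

    PCA keeps the smallest number of components explaining more than
    ``pca_variance`` of the variance; k-means runs ``n_restarts`` seeded
    restarts per k and keeps the best objective.  Dispersions are recomputed
    from the final assignments (mean centroids) so R is exactly consistent
    with its definition.
    """
    k_range = sorted(set(int(k) for k in k_range))
    if not k_range:
        raise ValueError("empty k_range")
    if k_range[-1] > len(events):
        raise ValueError(f"k={k_range[-1]} exceeds number of events ({len(events)})")
    X = np.stack([e.mean_spectrum for e in events])
    if np.allclose(X, X[0]):
        warnings.warn("all event spectra identical; R undefined for k > 1", stacklevel=2)
    n_comp = min(len(events), X.shape[1])
    pca = PCA(n_components=n_comp, random_state=seed)
    Z_full = pca.fit_transform(X)
    cum = np.cumsum(pca.explained_variance_ratio_)
    kept = int(np.searchsorted(cum, pca_variance) + 1)
    kept = min(kept, n_comp)
    Z = Z_full[:, :kept]
    center = Z.mean(axis=0)
    D1 = float(np.sum((Z - center) ** 2))
    results = []
    for k in k_range:
        if k == 1:
            # single cluster: dispersion is D_1 itself, so R is exactly zero
            results.append(
                ClusteringResult(
                    k=1,
                    assignments=np.zeros(len(events), dtype=int),
                    centroids=center[None, :],
                    dispersions=np.array([D1]),
                    total_dispersion=D1,
                    R=0.0,
                    pca_components_kept=kept,
                    variance_explained_by_pca=float(cum[kept - 1]),
                )
            )
            continue
        else:
            km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
            assign = km.fit_predict(Z)
            centroids = np.stack([Z[assign == c].mean(axis=0) for c in range(k)])
        D = np.array(
            [float(np.sum((Z[assign == c] - centroids[c]) ** 2)) for c in range(k)]
        )
        R = 100.0 * (1.0 - D.sum() / D1) if D1 > 0 else float("nan")
        results.append(
            ClusteringResult(
                k=k,
                assignments=assign,
                centroids=centroids,
                dispersions=D,
                total_dispersion=D1,
                R=R,
                pca_components_kept=kept,
                variance_explained_by_pca=float(cum[kept - 1]),
            )
        )
    return results


def choose_k(results: Sequence[ClusteringResult], r_threshold: float = 93.0) -> int:
    """Smallest k whose R meets the threshold, else the elbow of the R-vs-k curve."""
    if not results:
        raise ValueError("no clustering results")
    by_k = sorted(results, key=lambda r: r.k)
    for r in by_k:
        if r.R >= r_threshold:
            return r.k
    ks = np.array([r.k for r in by_k], dtype=float)
    Rs = np.array([r.R for r in by_k])
    if len(by_k) < 3:
        warnings.warn(
            f"R never reached {r_threshold}%; returning the largest k tried",
            stacklevel=2,
        )
        return by_k[-1].k
    curvature = Rs[:-2] - 2 * Rs[1:-1] + Rs[2:]
    elbow = int(ks[1:-1][np.argmin(curvature)])
    warnings.warn(
        f"R never reached {r_threshold}%; returning elbow k={elbow}", stacklevel=2
    )
    return elbow


def summarize_clusters(
    events: Sequence[AcousticEvent], result: ClusteringResult
) -> ClusterSummary:
    """Duration-weighted per-cluster spectra and hour/month detection profiles.

    Probabilities divide the detected duration in each time category by the
    cluster's total detected duration, so each row sums to 1.
    """
    k = result.k
    n_freq = events[0].mean_spectrum.size
    spectra = np.zeros((k, n_freq))
    hourly = np.zeros((k, 24))
    monthly = np.zeros((k, 12))
    weights = np.zeros(k)
    for e, c in zip(events, result.assignments):
        w = e.duration_min
        spectra[c] += w * e.mean_spectrum
        idx = pd.DatetimeIndex(e.frame_times)
        for h, cnt in zip(*np.unique(idx.hour, return_counts=True)):
            hourly[c, h] += cnt
        for m, cnt in zip(*np.unique(idx.month, return_counts=True)):
            monthly[c, m - 1] += cnt
        weights[c] += w
    for c in range(k):
        if weights[c] == 0:
            warnings.warn(f"cluster {c} is empty; zero summary row", stacklevel=2)
            continue
        spectra[c] /= weights[c]
        if hourly[c].sum() > 0:
            hourly[c] /= hourly[c].sum()
        if monthly[c].sum() > 0:
            monthly[c] /= monthly[c].sum()
    return ClusterSummary(
        mean_spectra=spectra, hourly_probability=hourly, monthly_probability=monthly
    )


def events_to_frame(
    events: Sequence[AcousticEvent], assignments: np.ndarray | None = None
) -> pd.DataFrame:
    """Tabulate events (source, start, end, duration, optional cluster id)."""
    rows = []
    for i, e in enumerate(events):
        row = {
            "source": e.source,
            "start_iso": np.datetime_as_string(e.start, unit="s"),
            "end_iso": np.datetime_as_string(e.end, unit="s"),
            "duration_min": e.duration_min,
        }
        if assignments is not None:
            row["cluster_id"] = int(assignments[i])
        rows.append(row)
    return pd.DataFrame(rows)
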