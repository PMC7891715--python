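"""Periodicity-coded NMF (PC-NMF) for monaural blind source separation.

Two stacked nonnegative factorizations separate a prewhitened LTSA into
sound sources without labels:

* **Layer 1 (feature learning).**  The grid, folded into fixed-length time
  patches, is factorized as ``V ~ W H`` with a Hoyer sparseness constraint
  on every spectral-feature column of ``W``.  ``H`` follows the standard
  multiplicative Euclidean update; ``W`` takes projected-gradient steps with
  backtracking so the squared reconstruction error never increases.

* **Layer 2 (source recognition).**  Each feature's activation row is mapped
  to the periodicity domain (magnitude DFT, DC removed, unit-sum normalized)
  and the resulting periodicity matrix is factorized by plain NMF into a few
  periodicity features and per-feature source indicators.  Features are
  assigned to the source with the largest indicator; assignments can be
  overridden manually after inspection.

Reconstruction distributes the mixture's energy among sources through a
ratio time-frequency mask, so per-source grids sum back to the input
wherever the model has support.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import roc_curve

from .ltsa import PrewhitenedLTSA

__all__ = [
    "FoldedLTSA",
    "PCNMFModel",
    "SeparatedSources",
    "fold",
    "unfold",
    "sparseness",
    "project_sparseness",
    "periodicity_matrix",
    "train",
    "adjust_indicators",
    "predict_activations",
    "reconstruct",
    "evaluate_detection",
    "match_channels",
    "channel_purity",
    "training_days",
    "save_model",
    "load_model",
]


# ---------------------------------------------------------------------------
# folding


@dataclass
class FoldedLTSA:
    """Grid folded into vectorized non-overlapping B-frame patches.

    Columns are patches; within a column the layout is frequency-major per
    frame, frames concatenated.  The final partial patch is zero-padded and
    the original frame count retained so unfolding is exact.
    """

    V: np.ndarray  # (n_freq * frames_per_patch, n_patches), >= 0
    n_freq: int
    frames_per_patch: int
    n_frames: int  # original time extent before padding
    freq_axis: np.ndarray | None = None
    time_axis: np.ndarray | None = None


def fold(grid: PrewhitenedLTSA | np.ndarray, frames_per_patch: int) -> FoldedLTSA:
    """Fold a (freq x time) grid into patch columns of ``frames_per_patch`` frames."""
    if frames_per_patch < 1:
        raise ValueError("frames_per_patch must be >= 1")
    if isinstance(grid, PrewhitenedLTSA):
        X, freq_axis, time_axis = grid.Pw, grid.freq_axis, grid.time_axis
    else:
        X, freq_axis, time_axis = np.asarray(grid), None, None
    F, T = X.shape
    B = frames_per_patch
    n_patches = -(-T // B)
    padded = np.zeros((F, n_patches * B))
    padded[:, :T] = X
    # (F, n_patches, B) -> frequency-major within each frame, frames stacked
    V = padded.reshape(F, n_patches, B).transpose(0, 2, 1).reshape(F * B, n_patches, order="F")
    return FoldedLTSA(
        V=V,
        n_freq=F,
        frames_per_patch=B,
        n_frames=T,
        freq_axis=freq_axis,
        time_axis=time_axis,
    )


def unfold(folded: FoldedLTSA, V: np.ndarray | None = None) -> np.ndarray:
    """Inverse of :func:`fold`; padding frames are discarded."""
    X = folded.V if V is None else V
    F, B = folded.n_freq, folded.frames_per_patch
    n_patches = X.shape[1]
    grid = (
        X.reshape(F, B, n_patches, order="F").transpose(0, 2, 1).reshape(F, n_patches * B)
    )
    return grid[:, : folded.n_frames]


# ---------------------------------------------------------------------------
# Hoyer sparseness


def sparseness(x: np.ndarray) -> float:
    """Hoyer sparseness (sqrt(n) - L1/L2) / (sqrt(n) - 1), in [0, 1].

    0 for a constant positive vector, 1 for a one-hot vector; roughly the
    fraction of (near-)zero elements.
    """
    x = np.asarray(x, dtype=np.float64)
    n = x.size
    if n < 2:
        raise ValueError("sparseness needs a vector of length >= 2")
    l2 = np.sqrt(np.sum(x * x))
    if l2 == 0:
        raise ValueError("sparseness undefined for the zero vector")
    l1 = np.sum(np.abs(x))
    rn = np.sqrt(n)
    return float((rn - l1 / l2) / (rn - 1.0))


def _project_l1_l2(x: np.ndarray, l1: float, l2: float) -> np.ndarray:
    """Closest nonnegative vector with the given L1 and L2 norms (Hoyer 2004)."""
    x = np.asarray(x, dtype=np.float64)
    n = x.size
    free = np.ones(n, dtype=bool)
    v = x + (l1 - x.sum()) / n
    for _ in range(n + 1):
        n_free = int(free.sum())
        m = np.where(free, l1 / n_free, 0.0)
        w = v - m
        a = float(np.sum(w * w))
        if a <= 0:
            v = m
        else:
            b = 2.0 * float(np.sum(m * w))
            c = float(np.sum(m * m)) - l2 * l2
            disc = max(b * b - 4.0 * a * c, 0.0)
            alpha = (-b + np.sqrt(disc)) / (2.0 * a)
            v = m + alpha * w
        neg = v < 0
        if not neg.any():
            return v
        free &= ~neg
        if not free.any():
            break
        v = np.where(free, v, 0.0)
        v[free] += (l1 - v.sum()) / free.sum()
    return np.maximum(v, 0.0)


def project_sparseness(x: np.ndarray, target: float) -> np.ndarray:
    """Project a vector onto the nonnegative set with the target sparseness.

    The L2 norm is preserved exactly and the L1 norm set to the value the
    target sparseness implies; the result is the closest such vector to
    ``|x|`` in the Euclidean sense.
    """
    if not 0.0 < target < 1.0:
        raise ValueError("sparseness target must be in (0, 1)")
    x = np.abs(np.asarray(x, dtype=np.float64))
    n = x.size
    if n < 2:
        raise ValueError("need a vector of length >= 2")
    l2 = float(np.sqrt(np.sum(x * x)))
    if l2 == 0:
        raise ValueError("cannot project the zero vector")
    rn = np.sqrt(n)
    l1 = l2 * (rn - target * (rn - 1.0))
    return _project_l1_l2(x, l1, l2)


# ---------------------------------------------------------------------------
# model containers


@dataclass
class PCNMFModel:
    """Persistent state of a trained PC-NMF: dictionary + source indicators.

    Only the spectral features ``W`` and the indicator state carry over into
    the prediction and reconstruction phases; activations are relearned per
    dataset.
    """

    W: np.ndarray  # (folded_dim, n_features), columns L2-normalized
    Wp: np.ndarray  # (n_periodicity_bins, n_sources) periodicity features
    Hs: np.ndarray  # (n_sources, n_features) source indicators
    assignment: np.ndarray  # per-feature source id (argmax of Hs)
    overrides: dict[int, int] = field(default_factory=dict)
    n_freq: int = 0
    frames_per_patch: int = 1
    sparseness_target: float = 0.5
    iterations: int = 200
    seed: int = 0
    objective_trace: np.ndarray | None = None

    @property
    def n_features(self) -> int:
        return self.W.shape[1]

    @property
    def n_sources(self) -> int:
        return self.Hs.shape[0]

    def effective_assignment(self) -> np.ndarray:
        """Per-feature source id with manual overrides applied."""
        out = self.assignment.copy()
        for feat, src in self.overrides.items():
            out[feat] = src
        return out


@dataclass
class SeparatedSources:
    """Per-source reconstructed grids, shaped like the input LTSA."""

    grids: list[np.ndarray]  # each (n_freq, n_frames)
    labels: list[str]
    freq_axis: np.ndarray | None = None
    time_axis: np.ndarray | None = None

    def __getitem__(self, key: int | str) -> np.ndarray:
        if isinstance(key, str):
            key = self.labels.index(key)
        return self.grids[key]


# ---------------------------------------------------------------------------
# update rules


def _objective(V: np.ndarray, W: np.ndarray, H: np.ndarray) -> float:
    R = V - W @ H
    return 0.5 * float(np.sum(R * R))


def _update_h(V: np.ndarray, W: np.ndarray, H: np.ndarray) -> np.ndarray:
    """Multiplicative Euclidean update for H (monotone non-increasing)."""
    num = W.T @ V
    den = W.T @ W @ H
    eps = 1e-12 * max(den.max(), 1e-300)
    return H * num / (den + eps)


def _project_columns(W: np.ndarray, target: float) -> np.ndarray:
    out = np.empty_like(W)
    for j in range(W.shape[1]):
        col = W[:, j]
        if not np.any(col > 0):
            # resurrect a dead feature with a tiny flat column before projecting
            col = np.full(col.shape, 1e-10)
        out[:, j] = project_sparseness(col, target)
    return out


def _sparse_nmf(
    V: np.ndarray,
    n_features: int,
    sparseness_target: float,
    iterations: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sparseness-constrained Euclidean NMF with a monotone objective.

    H: multiplicative update.  W: projected gradient step with backtracking
    (halve the step until the objective does not increase), each column
    re-projected to the target sparseness at its pre-step L2 norm.
    """
    m, T = V.shape
    scale = V.mean() if V.mean() > 0 else 1.0
    W = _project_columns(rng.random((m, n_features)) + 0.1, sparseness_target)
    H = (rng.random((n_features, T)) + 0.1) * (scale / n_features)
    # scale-aware initial stepsize keeps the whole iteration path homogeneous
    # in the input scale (so separation commutes with rescaling the grid)
    step = None
    trace = np.empty(iterations)
    obj = _objective(V, W, H)
    for it in range(iterations):
        H = _update_h(V, W, H)
        obj = _objective(V, W, H)
        grad = (W @ H - V) @ H.T
        if step is None:
            g = float(np.linalg.norm(grad))
            step = 1.0 / g if g > 0 else 1.0
        norms = np.sqrt(np.sum(W * W, axis=0))
        accepted = False
        for _ in range(30):
            Wn = W - step * grad
            Wn = _project_columns(np.maximum(Wn, 0.0) * norms / np.maximum(
                np.sqrt(np.sum(np.maximum(Wn, 0.0) ** 2, axis=0)), 1e-300
            ), sparseness_target)
            new_obj = _objective(V, Wn, H)
            if new_obj <= obj:
                W, obj = Wn, new_obj
                step *= 1.2
                accepted = True
                break
            step *= 0.5
        # if no step improved, W stays put: objective still non-increasing
        trace[it] = obj
    return W, H, trace


def _plain_nmf(
    V: np.ndarray,
    rank: int,
    iterations: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Unconstrained Euclidean NMF by multiplicative updates."""
    m, n = V.shape
    scale = np.sqrt(max(V.mean(), 1e-300) / rank)
    W = rng.random((m, rank)) * scale + 1e-4
    H = rng.random((rank, n)) * scale + 1e-4
    for _ in range(iterations):
        num = W.T @ V
        den = W.T @ W @ H
        H *= num / (den + 1e-12 * max(den.max(), 1e-300))
        num = V @ H.T
        den = W @ H @ H.T
        W *= num / (den + 1e-12 * max(den.max(), 1e-300))
    return W, H


def periodicity_matrix(H: np.ndarray) -> np.ndarray:
    """Map activation rows to the periodicity domain.

    Magnitude DFT of each feature's activation row with the DC bin removed
    (DC encodes overall loudness, not recurrence) and each column normalized
    to unit sum so layer 2 is scale-invariant.  Returns (n_periodicity_bins,
    n_features).
    """
    spec = np.abs(np.fft.rfft(H, axis=1))[:, 1:]  # drop DC
    total = spec.sum(axis=1, keepdims=True)
    spec = spec / np.where(total > 0, total, 1.0)
    return spec.T


# ---------------------------------------------------------------------------
# training / prediction / reconstruction


def train(
    folded: FoldedLTSA,
    n_features: int = 90,
    n_sources: int = 4,
    sparseness_target: float = 0.5,
    iterations: int = 200,
    seed: int = 0,
    layer2_iterations: int = 2000,
    layer2_restarts: int = 10,
) -> PCNMFModel:
    """Learn spectral features and source indicators from a folded grid.

    Layer 2 is a small factorization but its local minimum determines the
    feature-to-source grouping, so it is restarted from several seeded
    initializations and the solution with the lowest reconstruction error
    kept.
    """
    V = folded.V
    if not np.any(V > 0):
        raise ValueError("cannot train on an all-zero grid")
    if np.isnan(V).any():
        raise ValueError("input grid contains NaNs")
    if n_features >= min(V.shape):
        warnings.warn(
            f"n_features={n_features} >= min(matrix dims)={min(V.shape)}; "
            "the factorization is overcomplete",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    W, H, trace = _sparse_nmf(V, n_features, sparseness_target, iterations, rng)
    # fold scale into H so indicator magnitudes are comparable across features
    norms = np.sqrt(np.sum(W * W, axis=0))
    norms = np.where(norms > 0, norms, 1.0)
    W = W / norms
    H = H * norms[:, None]
    Q = periodicity_matrix(H)
    best_err = np.inf
    Wp = Hs = None
    for _ in range(max(layer2_restarts, 1)):
        Wp_r, Hs_r = _plain_nmf(Q, n_sources, layer2_iterations, rng)
        err = float(np.linalg.norm(Q - Wp_r @ Hs_r))
        if err < best_err:
            best_err, Wp, Hs = err, Wp_r, Hs_r
    assignment = np.argmax(Hs, axis=0)
    # np.argmax already breaks ties toward the lowest source index; log them
    top = np.take_along_axis(Hs, assignment[None, :], axis=0)[0]
    ties = (np.isclose(Hs, top[None, :])).sum(axis=0) > 1
    if ties.any():
        warnings.warn(
            f"tied source indicators for features {np.nonzero(ties)[0].tolist()}; "
            "lowest source index wins",
            stacklevel=2,
        )
    return PCNMFModel(
        W=W,
        Wp=Wp,
        Hs=Hs,
        assignment=assignment,
        overrides={},
        n_freq=folded.n_freq,
        frames_per_patch=folded.frames_per_patch,
        sparseness_target=sparseness_target,
        iterations=iterations,
        seed=seed,
        objective_trace=trace,
    )


def adjust_indicators(model: PCNMFModel, overrides: Mapping[int, int]) -> PCNMFModel:
    """Return a model with manual feature-to-source overrides applied.

    The automatic argmax assignment is retained for audit; overrides win
    wherever present.
    """
    for feat, src in overrides.items():
        if not 0 <= feat < model.n_features:
            raise ValueError(f"unknown feature id {feat}")
        if not 0 <= src < model.n_sources:
            raise ValueError(f"unknown source id {src}")
    merged = dict(model.overrides)
    merged.update(overrides)
    return replace(model, overrides=merged)


def predict_activations(
    model: PCNMFModel,
    folded: FoldedLTSA,
    iterations: int = 200,
    seed: int = 0,
    return_trace: bool = False,
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Learn activations for a new grid with the dictionary fixed.

    H starts from seeded random values and follows the multiplicative
    Euclidean rule for the stated number of iterations; the objective is
    non-increasing throughout.
    """
    V = folded.V
    if V.shape[0] != model.W.shape[0]:
        raise ValueError(
            f"folded grid rows {V.shape} do not match dictionary {model.W.shape}"
        )
    rng = np.random.default_rng(seed)
    scale = V.mean() if V.mean() > 0 else 1.0
    H = (rng.random((model.n_features, V.shape[1])) + 0.1) * (scale / model.n_features)
    trace = np.empty(iterations)
    for it in range(iterations):
        H = _update_h(V, model.W, H)
        if return_trace:
            trace[it] = _objective(V, model.W, H)
    if return_trace:
        return H, trace
    return H


def reconstruct(
    model: PCNMFModel,
    folded: FoldedLTSA,
    activations: np.ndarray,
    source_labels: Sequence[str] | None = None,
) -> SeparatedSources:
    """Reconstruct per-source grids through the ratio time-frequency mask.

    ``P_s = P * (W_s H_s) / (W H)`` on the folded grid (mask set to 0 where
    the model support ``W H`` is at the numerical floor), then unfolded.
    Masks sum to one wherever the model has support, so the per-source grids
    conserve the mixture.
    """
    V = folded.V
    if activations.shape != (model.n_features, V.shape[1]):
        raise ValueError(
            f"activations shape {activations.shape} does not match "
            f"(n_features={model.n_features}, n_patches={V.shape[1]})"
        )
    WH = model.W @ activations
    eps = 1e-12 * max(WH.max(), 1e-300)
    support = WH > eps
    assignment = model.effective_assignment()
    grids = []
    for s in range(model.n_sources):
        idx = np.nonzero(assignment == s)[0]
        if idx.size == 0:
            warnings.warn(f"source {s} has no assigned features; channel is zero",
                          stacklevel=2)
            part = np.zeros_like(V)
        else:
            num = model.W[:, idx] @ activations[idx, :]
            mask = np.where(support, num / np.where(support, WH, 1.0), 0.0)
            part = V * mask
        grids.append(unfold(folded, part))
    labels = (
        list(source_labels)
        if source_labels is not None
        else [f"source_{s}" for s in range(model.n_sources)]
    )
    return SeparatedSources(
        grids=grids,
        labels=labels,
        freq_axis=folded.freq_axis,
        time_axis=folded.time_axis,
    )


# ---------------------------------------------------------------------------
# evaluation


def evaluate_detection(
    intensity: np.ndarray, truth: np.ndarray, fpr: float = 0.05
) -> tuple[float, float]:
    """Best true-positive rate at a capped false-positive rate.

    Sweeps all thresholds of the score series against the binary labels and
    returns ``(tpr, threshold)`` for the highest TPR whose FPR does not
    exceed ``fpr``.
    """
    intensity = np.asarray(intensity, dtype=np.float64)
    truth = np.asarray(truth).astype(bool)
    if intensity.shape != truth.shape:
        raise ValueError("intensity and truth must have equal length")
    if truth.all() or not truth.any():
        raise ValueError("truth must contain both classes")
    fprs, tprs, thresholds = roc_curve(truth.astype(int), intensity)
    ok = fprs <= fpr
    best = np.argmax(tprs[ok])
    idx = np.nonzero(ok)[0][best]
    return float(tprs[idx]), float(thresholds[idx])


def match_channels(
    separated: SeparatedSources, true_intensities: np.ndarray
) -> dict[int, int]:
    """Optimal channel-to-true-source matching by shared frame energy.

    ``true_intensities`` is the (n_frames, n_sources) matrix of true
    per-frame integrated energies.  Returns a map from true-source index to
    separated-channel index via a linear assignment maximizing the channel
    energy placed in frames in proportion to each source's share of the
    true mixture.
    """
    I = np.asarray(true_intensities, dtype=np.float64)
    total = I.sum(axis=1)
    total = np.where(total > 0, total, 1.0)
    energies = np.stack([g.sum(axis=0) for g in separated.grids])
    overlap = (I / total[:, None]).T @ energies.T  # (n_true, n_channels)
    rows, cols = linear_sum_assignment(-overlap)
    return {int(r): int(c) for r, c in zip(rows, cols)}


def channel_purity(channel: np.ndarray, active: np.ndarray) -> float:
    """Fraction of a channel's integrated energy in truly active frames.

    ``channel`` is a separated grid (freq x time) or a per-frame energy
    series; ``active`` the source's binary frame labels.  1.0 means the
    channel carries energy only while its source is genuinely present.
    """
    channel = np.asarray(channel, dtype=np.float64)
    energy = channel.sum(axis=0) if channel.ndim == 2 else channel
    active = np.asarray(active).astype(bool)
    if energy.shape != active.shape:
        raise ValueError("channel frames and labels must align")
    denom = float(energy.sum())
    if denom == 0:
        return 0.0
    return float(energy[active].sum()) / denom


def training_days(start_month: str, n_months: int, day: int = 1) -> list[np.datetime64]:
    """First-day-of-each-month training subset selector.

    ``training_days("2011-11", 12)`` gives the first day of each month from
    November 2011 through October 2012.
    """
    first = np.datetime64(start_month, "M")
    return [
        (m + np.timedelta64(day - 1, "D")).astype("datetime64[D]")
        for m in (first + np.arange(n_months).astype("timedelta64[M]")).astype(
            "datetime64[D]"
        )
    ]


# ---------------------------------------------------------------------------
# persistence


def save_model(path: str | Path, model: PCNMFModel) -> None:
    """Persist a model as a NumPy array archive."""
    ov = np.array(sorted(model.overrides.items()), dtype=np.int64).reshape(-1, 2)
    np.savez(
        str(path),
        W=model.W,
        Wp=model.Wp,
        Hs=model.Hs,
        assignment=model.assignment,
        overrides=ov,
        config=np.array(
            [
                model.n_freq,
                model.frames_per_patch,
                model.iterations,
                model.seed,
            ],
            dtype=np.int64,
        ),
        sparseness_target=np.array(model.sparseness_target),
    )


def load_model(path: str | Path) -> PCNMFModel:
    with np.load(str(path), allow_pickle=False) as z:
        cfg = z["config"]
        return PCNMFModel(
            W=z["W"],
            Wp=z["Wp"],
            Hs=z["Hs"],
            assignment=z["assignment"],
            overrides={int(a): int(b) for a, b in z["overrides"]},
            n_freq=int(cfg[0]),
            frames_per_patch=int(cfg[1]),
            iterations=int(cfg[2]),
            seed=int(cfg[3]),
            sparseness_target=float(z["sparseness_target"]),
        )
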