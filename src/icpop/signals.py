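"""Fluorescence conditioning: neuropil correction, dF/F, drift removal,
trial alignment, and motion quality-control summaries.

The processing chain mirrors standard two-photon practice for somatic ROI
traces: subtract 0.7x the neuropil trace, normalise by the whole-trace
median (F0), remove slow drift with a Gaussian + min/max morphological
baseline, then slice the trace into trials aligned on stimulus onset over
a -2 s..+5 s window (193-197 frames at ~28 Hz).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d, maximum_filter1d, minimum_filter1d

log = logging.getLogger(__name__)

__all__ = [
    "DffMatrix",
    "TrialTensor",
    "OutcomeAverages",
    "neuropil_correct",
    "compute_dff",
    "remove_slow_baseline",
    "extract_trials",
    "exclude_lick_contaminated_hits",
    "outcome_averages",
    "resample_linear",
    "zmotion_pc_check",
    "lick_triggered_movie",
]


@dataclass
class DffMatrix:
    """dF/F traces (ROIs x frames) plus the provenance of the normalisation."""

    values: np.ndarray
    frame_rate: float
    neuropil_coefficient: float = 0.7
    f0_definition: str = "whole-trace median"
    roi_indices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __post_init__(self) -> None:
        if self.roi_indices.size == 0:
            self.roi_indices = np.arange(self.values.shape[0])


@dataclass
class TrialTensor:
    """Trial-aligned dF/F: (trials x neurons x frames) on a -2..+5 s window."""

    values: np.ndarray
    frame_rate: float
    window: tuple[float, float] = (-2.0, 5.0)
    onset_frame_index: int = 0
    trial_indices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    dropped_trials: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.values.shape[1]

    @property
    def n_frames(self) -> int:
        return self.values.shape[2]

    @property
    def frame_times(self) -> np.ndarray:
        """Frame times (s) relative to stimulus onset."""
        return (np.arange(self.n_frames) - self.onset_frame_index) / self.frame_rate


@dataclass
class OutcomeAverages:
    """Per-neuron trial-averaged hit and miss traces, resampled to L points."""

    hit_avg: np.ndarray  # (neurons, L)
    miss_avg: np.ndarray  # (neurons, L)
    L: int = 193
    neuron_indices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __post_init__(self) -> None:
        if self.neuron_indices.size == 0:
            self.neuron_indices = np.arange(self.hit_avg.shape[0])


def neuropil_correct(F: np.ndarray, Fneu: np.ndarray, r: float = 0.7) -> np.ndarray:
    """Subtract the scaled neuropil trace: corrected = F - r * Fneu."""
    F = np.asarray(F, dtype=float)
    Fneu = np.asarray(Fneu, dtype=float)
    if F.shape != Fneu.shape:
        raise ValueError(f"shape mismatch: F {F.shape} vs Fneu {Fneu.shape}")
    return F - r * Fneu


def compute_dff(
    corrected: np.ndarray, frame_rate: float, neuropil_coefficient: float = 0.7
) -> DffMatrix:
    """dF/F with F0 = per-ROI whole-trace median.

    ROIs whose median is not strictly positive cannot be normalised; they
    are excluded with a warning and recorded via ``roi_indices``.
    """
    corrected = np.atleast_2d(np.asarray(corrected, dtype=float))
    f0 = np.median(corrected, axis=1)
    good = f0 > 0
    if not good.all():
        bad = np.flatnonzero(~good)
        warnings.warn(f"excluding {bad.size} ROI(s) with non-positive median F0: {bad.tolist()}")
        log.warning("compute_dff: excluded ROIs %s (non-positive F0)", bad.tolist())
    vals = (corrected[good] - f0[good, None]) / f0[good, None]
    return DffMatrix(
        values=vals,
        frame_rate=frame_rate,
        neuropil_coefficient=neuropil_coefficient,
        roi_indices=np.flatnonzero(good),
    )


def remove_slow_baseline(
    dff: DffMatrix,
    gaussian_sigma_s: float = 10.0,
    min_window_s: float = 60.0,
    max_window_s: float = 60.0,
) -> DffMatrix:
    """Subtract a slow baseline: max-filter(min-filter(gaussian-filter(trace))).

    The Gaussian removes fast structure before the minimum filter tracks the
    lower envelope; the maximum filter undoes the erosion of that envelope.
    Defaults (sigma 10 s, 60 s windows) follow common practice for slow
    drift on minutes-long recordings and are configurable.
    """
    if gaussian_sigma_s <= 0 or min_window_s <= 0 or max_window_s <= 0:
        raise ValueError("filter windows must be positive")
    x = np.atleast_2d(dff.values)
    if x.shape[1] == 0:
        raise ValueError("empty trace")
    fs = dff.frame_rate
    win_min = int(round(min_window_s * fs))
    win_max = int(round(max_window_s * fs))
    if win_min > x.shape[1] or win_max > x.shape[1]:
        raise ValueError("baseline windows longer than the recording")
    smoothed = gaussian_filter1d(x, gaussian_sigma_s * fs, axis=1)
    baseline = maximum_filter1d(minimum_filter1d(smoothed, win_min, axis=1), win_max, axis=1)
    return DffMatrix(
        values=x - baseline,
        frame_rate=fs,
        neuropil_coefficient=dff.neuropil_coefficient,
        f0_definition=dff.f0_definition,
        roi_indices=dff.roi_indices.copy(),
    )


def extract_trials(
    dff: DffMatrix, schedule: pd.DataFrame, pre_s: float = 2.0, post_s: float = 5.0
) -> TrialTensor:
    """Slice dF/F into trial-aligned windows of -pre_s..+post_s around onsets.

    Time zero maps to the first frame with timestamp >= the stimulus onset.
    Trials whose window would run outside the recording are dropped (and
    listed in ``dropped_trials``), not padded.
    """
    if dff.frame_rate is None or dff.frame_rate <= 0:
        raise ValueError("frame rate missing")
    fs = dff.frame_rate
    n_pre = int(np.floor(pre_s * fs))
    n_total = int(np.floor((pre_s + post_s) * fs))
    n_frames = dff.values.shape[1]

    kept, dropped, slices = [], [], []
    for j, onset in enumerate(schedule["onset_s"].to_numpy()):
        onset_idx = int(np.ceil(onset * fs))  # first frame at/after onset
        lo = onset_idx - n_pre
        hi = lo + n_total
        if lo < 0 or hi > n_frames:
            dropped.append(j)
            continue
        kept.append(j)
        slices.append(dff.values[:, lo:hi])
    if dropped:
        log.info("extract_trials: dropped %d trial(s) outside recording: %s", len(dropped), dropped)
    values = np.stack(slices, axis=0) if slices else np.empty((0, dff.values.shape[0], n_total))
    return TrialTensor(
        values=values,
        frame_rate=fs,
        window=(-pre_s, post_s),
        onset_frame_index=n_pre,
        trial_indices=np.asarray(kept, dtype=int),
        dropped_trials=np.asarray(dropped, dtype=int),
    )


def exclude_lick_contaminated_hits(
    outcomes: pd.DataFrame,
    licks: np.ndarray,
    window: tuple[float, float] = (-0.5, 0.12),
) -> np.ndarray:
    """Boolean keep-mask removing hit trials with peri-onset licks.

    A hit trial is dropped if any lick falls between -500 ms and +120 ms
    (the animals' minimum lick latency) relative to stimulus onset, so that
    pre-stimulus activity differences cannot be a direct licking artefact.
    Miss and catch trials are always kept.
    """
    licks = np.asarray(licks, dtype=float)
    keep = np.ones(len(outcomes), dtype=bool)
    is_hit = (outcomes["label"] == "hit").to_numpy()
    onsets = outcomes["onset_s"].to_numpy()
    for j in np.flatnonzero(is_hit):
        lo, hi = onsets[j] + window[0], onsets[j] + window[1]
        if np.any((licks >= lo) & (licks <= hi)):
            keep[j] = False
    return keep


def resample_linear(trace: np.ndarray, L: int) -> np.ndarray:
    """Linear resampling to exactly L points, preserving both endpoints."""
    trace = np.asarray(trace, dtype=float)
    n = trace.shape[-1]
    if L < 2 or n < 2:
        raise ValueError("need at least 2 samples")
    if n == L:
        return trace.copy()
    x_new = np.linspace(0.0, n - 1.0, L)
    x_old = np.arange(n)
    if trace.ndim == 1:
        return np.interp(x_new, x_old, trace)
    return np.vstack([np.interp(x_new, x_old, row) for row in trace])


def outcome_averages(
    tensor: TrialTensor, outcomes: pd.DataFrame, L: int = 193
) -> OutcomeAverages:
    """Per-neuron hit and miss trial averages, resampled to L points.

    Averages pool all sound levels (stimulus trials only). Neurons come
    from sessions, so a session lacking either outcome yields no usable
    averages: an error is raised and the caller excludes those neurons
    from clustering.
    """
    labels = outcomes["label"].to_numpy()[tensor.trial_indices]
    hit_m = labels == "hit"
    miss_m = labels == "miss"
    if hit_m.sum() < 1 or miss_m.sum() < 1:
        raise ValueError("session lacks hit or miss trials; neurons excluded from clustering")
    hit_avg = tensor.values[hit_m].mean(axis=0)  # (neurons, frames)
    miss_avg = tensor.values[miss_m].mean(axis=0)
    return OutcomeAverages(
        hit_avg=resample_linear(hit_avg, L),
        miss_avg=resample_linear(miss_avg, L),
        L=L,
    )


def zmotion_pc_check(
    frame_stack: np.ndarray, n_extreme: int = 500, n_components: int = 3
) -> tuple[np.ndarray, np.ndarray]:
    """Z-motion check: top-minus-bottom extreme-frame averages per spatial PC.

    For each spatial principal component of the registered stack, the mean
    image over the ``n_extreme`` highest-scoring frames minus the mean over
    the ``n_extreme`` lowest is returned, together with a scalar
    displacement score (mean absolute difference). Large scores indicate
    frames at opposite ends of a PC look systematically different, i.e.
    z-axis displacement.

    Returns ``(diff_images [n_components, h, w], scores [n_components])``.
    """
    stack = np.asarray(frame_stack, dtype=float)
    n_frames = stack.shape[0]
    if n_frames <= 2 * n_extreme:
        raise ValueError("need more than 2*n_extreme frames")
    flat = stack.reshape(n_frames, -1)
    from sklearn.decomposition import PCA

    n_components = min(n_components, n_frames - 1, flat.shape[1])
    scores = PCA(n_components=n_components).fit_transform(flat - flat.mean(axis=0))
    diffs, disp = [], []
    for c in range(n_components):
        order = np.argsort(scores[:, c])
        bottom = stack[order[:n_extreme]].mean(axis=0)
        top = stack[order[-n_extreme:]].mean(axis=0)
        d = top - bottom
        diffs.append(d)
        disp.append(np.abs(d).mean())
    return np.stack(diffs), np.asarray(disp)


def lick_triggered_movie(
    frame_stack: np.ndarray,
    lick_times: np.ndarray,
    frame_rate: float,
    window_s: float = 2.0,
) -> np.ndarray:
    """Average movie aligned on lick events (window +/- ``window_s``).

    Only licks whose full window fits inside the stack contribute. Reveals
    stereotyped, lick-locked displacement of the imaging plane.
    """
    stack = np.asarray(frame_stack, dtype=float)
    n_frames = stack.shape[0]
    half = int(round(window_s * frame_rate))
    clips = []
    for t in np.asarray(lick_times, dtype=float):
        c = int(round(t * frame_rate))
        if c - half >= 0 and c + half + 1 <= n_frames:
            clips.append(stack[c - half : c + half + 1])
    if not clips:
        raise ValueError("no lick with a full window inside the stack")
    return np.mean(clips, axis=0)
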