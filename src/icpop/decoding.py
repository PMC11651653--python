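"""Frame-by-frame population decoding of trial outcome (hit vs miss).

For every imaging frame in the -2 s..+5 s trial window, an L2-regularised
logistic regression is trained on the single-frame population dF/F vector
to classify hit vs miss trials. Class imbalance is handled twice: during
training with class weights W_i = N_T / (N_C * N_i), and during evaluation
with balanced accuracy, the mean of the true-positive and true-negative
rates (chance = 0.5 at any imbalance). Scores are estimated by nested
stratified cross-validation (outer 5-fold evaluation, inner 4-fold
randomised search for the regularisation strength over a log-uniform range
1e-4..1e2) and compared against stratified dummy models that guess labels
at their empirical frequencies.

Only trials of intermediate difficulty enter the analysis: the five sound
levels centred on the lowest level whose d' exceeds 1.5, and only sessions
with at least 15 hit and 15 miss trials.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .behavior import psychometric
from .signals import TrialTensor, resample_linear

log = logging.getLogger(__name__)

__all__ = [
    "ClassWeights",
    "ConfusionCounts",
    "DecoderConfig",
    "DecodingResult",
    "select_trials",
    "session_gate",
    "class_weights",
    "balanced_accuracy",
    "confusion_counts",
    "fit_frame_decoder",
    "dummy_decoder",
    "decode_session",
    "interpolate_timecourse",
    "roi_count_correlation",
    "subsample_neurons_control",
    "level_matched_control",
]


@dataclass(frozen=True)
class ClassWeights:
    """Training-loss class weights W_i = N_T / (N_C * N_i)."""

    weights: dict
    n_total: int
    n_classes: int
    counts: dict

    def as_dict(self) -> dict:
        return dict(self.weights)


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion-matrix cells (positive class = hit)."""

    tp: int
    fn: int
    tn: int
    fp: int

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


@dataclass(frozen=True)
class DecoderConfig:
    """Knobs of the nested-CV decoding procedure.

    ``n_outer``/``n_inner`` are the stratified fold counts; ``n_search``
    randomised draws of the L2 strength C are taken per outer fold from a
    log-uniform distribution on [c_low, c_high]. ``dummy_repeats`` sets the
    averaging of the stratified guessing baseline. ``frame_stride``
    decodes every k-th frame (1 = all frames). Optimiser tolerance and
    iteration cap are pinned so reruns are reproducible.
    """

    n_outer: int = 5
    n_inner: int = 4
    n_search: int = 25
    c_low: float = 1e-4
    c_high: float = 1e2
    dummy_repeats: int = 100
    frame_stride: int = 1
    max_iter: int = 1000
    tol: float = 1e-4
    min_trials_per_class: int = 15


def select_trials(
    outcomes: pd.DataFrame,
    dprime_threshold: float = 1.5,
    n_below: int = 2,
    n_above: int = 2,
    keep_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Pick intermediate-difficulty trials for decoding.

    The anchor is the lowest sound level whose d' exceeds
    ``dprime_threshold``; the selection spans the anchor plus the two
    levels below and the two above (by level rank), i.e. five levels when
    the anchor is interior. A window truncated at the edge of the level
    range is used with a warning. Raises if no level exceeds the threshold
    (the session is excluded from decoding).

    Returns ``(trial_mask, selected_levels)`` over rows of ``outcomes``.
    """
    if keep_mask is None:
        keep_mask = np.ones(len(outcomes), dtype=bool)
    summ = psychometric(outcomes[keep_mask])
    per_level = summ.per_level
    levels = per_level["level_db"].to_numpy()
    dps = per_level["dprime"].to_numpy()
    exceed = np.flatnonzero(dps > dprime_threshold)
    if exceed.size == 0:
        raise ValueError(
            f"no sound level exceeds d' = {dprime_threshold}; session excluded from decoding"
        )
    anchor = exceed[0]
    lo, hi = anchor - n_below, anchor + n_above
    if lo < 0 or hi > levels.size - 1:
        log.warning(
            "select_trials: window truncated at level-range edge (anchor rank %d of %d)",
            anchor,
            levels.size,
        )
    sel = levels[max(lo, 0) : min(hi, levels.size - 1) + 1]
    mask = keep_mask & outcomes["level_db"].isin(sel).to_numpy()
    return mask, sel


def session_gate(n_hit: int, n_miss: int, min_each: int = 15) -> bool:
    """Session inclusion rule: at least ``min_each`` hit AND miss trials."""
    return n_hit >= min_each and n_miss >= min_each


def class_weights(labels: np.ndarray) -> ClassWeights:
    """W_i = N_T / (N_C * N_i): inverse-frequency weights over the classes."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ValueError("both classes must be present")
    n_total = int(labels.size)
    w = {c: n_total / (classes.size * n) for c, n in zip(classes.tolist(), counts.tolist())}
    return ClassWeights(
        weights=w,
        n_total=n_total,
        n_classes=int(classes.size),
        counts=dict(zip(classes.tolist(), counts.tolist())),
    )


def confusion_counts(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    """Confusion cells with class 1 (hit) as the positive class."""
    y_true = np.asarray(y_true).astype(bool)
    y_pred = np.asarray(y_pred).astype(bool)
    return ConfusionCounts(
        tp=int(np.sum(y_true & y_pred)),
        fn=int(np.sum(y_true & ~y_pred)),
        tn=int(np.sum(~y_true & ~y_pred)),
        fp=int(np.sum(~y_true & y_pred)),
    )


def balanced_accuracy(counts: ConfusionCounts) -> float:
    """Arithmetic mean of the true-positive and true-negative rates."""
    if counts.tp + counts.fn == 0 or counts.tn + counts.fp == 0:
        raise ValueError("each class needs at least one evaluated trial")
    tpr = counts.tp / (counts.tp + counts.fn)
    tnr = counts.tn / (counts.tn + counts.fp)
    return 0.5 * (tpr + tnr)


def _score(y_true, y_pred) -> float:
    return balanced_accuracy(confusion_counts(y_true, y_pred))


def _loguniform(rng: np.random.Generator, low: float, high: float, size: int) -> np.ndarray:
    return 10.0 ** rng.uniform(np.log10(low), np.log10(high), size=size)


def _fit_lr(X, y, C, cfg: DecoderConfig) -> LogisticRegression:
    cw = class_weights(y).as_dict()
    model = LogisticRegression(  # default penalty is L2
        C=float(C),
        class_weight=cw,
        solver="lbfgs",
        max_iter=cfg.max_iter,
        tol=cfg.tol,
    )
    model.fit(X, y)
    return model


def fit_frame_decoder(
    X: np.ndarray,
    y: np.ndarray,
    cv_seed: int = 0,
    config: DecoderConfig | None = None,
) -> np.ndarray:
    """Nested-CV balanced accuracies of a single-frame decoder.

    ``X`` is (trials x neurons) activity at one frame, ``y`` the binary
    outcome (1 = hit). Outer stratified 5-fold evaluation; within each
    outer training set, a randomised search over the L2 strength (inner
    stratified 4-fold, ``n_search`` log-uniform draws) picks C by mean
    inner balanced accuracy; the winner is refit on the full outer
    training set with class weights and scored on the held-out fold.

    Returns the per-outer-fold held-out balanced accuracies (length
    ``n_outer``); identical inputs and seed give identical scores.
    """
    cfg = config or DecoderConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    rng = np.random.default_rng(cv_seed)
    outer = StratifiedKFold(n_splits=cfg.n_outer, shuffle=True, random_state=cv_seed)
    scores = []
    for train_idx, test_idx in outer.split(X, y):
        Xtr, ytr = X[train_idx], y[train_idx]
        cs = _loguniform(rng, cfg.c_low, cfg.c_high, cfg.n_search)
        inner = StratifiedKFold(
            n_splits=cfg.n_inner, shuffle=True, random_state=int(rng.integers(2**31))
        )
        inner_splits = list(inner.split(Xtr, ytr))
        mean_inner = np.empty(cs.size)
        for ci, C in enumerate(cs):
            accs = []
            for itr, ite in inner_splits:
                m = _fit_lr(Xtr[itr], ytr[itr], C, cfg)
                accs.append(_score(ytr[ite], m.predict(Xtr[ite])))
            mean_inner[ci] = np.mean(accs)
        best_c = cs[int(np.argmax(mean_inner))]
        model = _fit_lr(Xtr, ytr, best_c, cfg)
        scores.append(_score(y[test_idx], model.predict(X[test_idx])))
    return np.asarray(scores)


def dummy_decoder(
    labels: np.ndarray, seed: int = 0, n_repeats: int = 100
) -> tuple[float, np.ndarray]:
    """Stratified guessing baseline.

    Predictions are drawn independently with the empirical class
    probability and scored by balanced accuracy; the expectation is 0.5
    whatever the class balance. Returns ``(mean, per_repeat_scores)``.
    """
    y = np.asarray(labels).astype(bool)
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    rng = np.random.default_rng(seed)
    p = y.mean()
    scores = np.empty(n_repeats)
    for r in range(n_repeats):
        pred = rng.random(y.size) < p
        scores[r] = _score(y, pred)
    return float(scores.mean()), scores


@dataclass
class DecodingResult:
    """Per-frame cross-validated decoding of one session."""

    frame_times: np.ndarray  # (n_eval_frames,) seconds relative to onset
    trained: np.ndarray  # (n_eval_frames,) mean balanced accuracy
    trained_folds: np.ndarray  # (n_eval_frames, n_outer)
    dummy: np.ndarray  # (n_eval_frames,)
    n_rois: int
    n_hit: int
    n_miss: int
    session_id: str = "session"
    group: str = "non-lesioned"
    selected_levels: np.ndarray = field(default_factory=lambda: np.empty(0))

    def windowed_mean(self, lo: float, hi: float) -> float:
        m = (self.frame_times >= lo) & (self.frame_times < hi)
        return float(self.trained[m].mean())


def decode_session(
    tensor: TrialTensor,
    labels: np.ndarray,
    seed: int = 0,
    config: DecoderConfig | None = None,
    session_id: str = "session",
    group: str = "non-lesioned",
    selected_levels: np.ndarray | None = None,
) -> DecodingResult:
    """Run the frame-by-frame decoder over a trial tensor.

    ``labels`` is the binary hit(1)/miss(0) vector over the tensor's
    trials. Each evaluated frame gets its own nested-CV decoder and its
    own stratified dummy baseline; per-frame means are assembled into a
    :class:`DecodingResult`.
    """
    cfg = config or DecoderConfig()
    y = np.asarray(labels).astype(int)
    if y.size != tensor.n_trials:
        raise ValueError("labels must match the tensor's trial count")
    n_hit, n_miss = int(y.sum()), int((1 - y).sum())
    if not session_gate(n_hit, n_miss, cfg.min_trials_per_class):
        raise ValueError(
            f"session gate failed: {n_hit} hits / {n_miss} misses (need >= "
            f"{cfg.min_trials_per_class} each)"
        )
    frames = np.arange(0, tensor.n_frames, cfg.frame_stride)
    ss = np.random.SeedSequence(seed)
    frame_seeds = ss.generate_state(2 * frames.size) % (2**31)
    trained_folds = np.empty((frames.size, cfg.n_outer))
    dummy = np.empty(frames.size)
    for k, f in enumerate(frames):
        trained_folds[k] = fit_frame_decoder(
            tensor.values[:, :, f], y, cv_seed=int(frame_seeds[2 * k]), config=cfg
        )
        dummy[k], _ = dummy_decoder(
            y, seed=int(frame_seeds[2 * k + 1]), n_repeats=cfg.dummy_repeats
        )
    return DecodingResult(
        frame_times=tensor.frame_times[frames],
        trained=trained_folds.mean(axis=1),
        trained_folds=trained_folds,
        dummy=dummy,
        n_rois=tensor.n_neurons,
        n_hit=n_hit,
        n_miss=n_miss,
        session_id=session_id,
        group=group,
        selected_levels=np.asarray(selected_levels if selected_levels is not None else []),
    )


def interpolate_timecourse(values: np.ndarray, target_len: int) -> np.ndarray:
    """Linearly resample a per-frame score series to ``target_len`` points,
    preserving the endpoints — used to align sessions recorded at slightly
    different frame rates before timewise statistics."""
    if target_len < 2:
        raise ValueError("target_len must be >= 2")
    return resample_linear(np.asarray(values, dtype=float), target_len)


def roi_count_correlation(
    results: list[DecodingResult],
    window_edges: np.ndarray | None = None,
) -> pd.DataFrame:
    """Spearman correlation between session ROI count and windowed accuracy.

    Windows default to 1-s bins spanning -2..+5 s. Windows where accuracy
    (or ROI count) is constant across sessions have an undefined rank
    correlation; they are reported with ``rho`` = NaN and flagged.
    """
    if len(results) < 4:
        raise ValueError("need at least 4 sessions")
    if window_edges is None:
        window_edges = np.arange(-2.0, 5.0 + 1e-9, 1.0)
    n_rois = np.array([r.n_rois for r in results])
    rows = []
    for lo, hi in zip(window_edges[:-1], window_edges[1:]):
        acc = np.array([r.windowed_mean(lo, hi) for r in results])
        constant = np.allclose(acc, acc[0]) or np.all(n_rois == n_rois[0])
        if constant:
            rows.append(
                {"window_lo": lo, "window_hi": hi, "rho": np.nan, "p": np.nan, "constant": True}
            )
            continue
        rho, p = spearmanr(n_rois, acc)
        rows.append(
            {"window_lo": lo, "window_hi": hi, "rho": float(rho), "p": float(p), "constant": False}
        )
    return pd.DataFrame(rows)


def subsample_neurons_control(
    tensor: TrialTensor,
    labels: np.ndarray,
    target_n: int,
    n_draws: int = 10,
    seed: int = 0,
    config: DecoderConfig | None = None,
) -> np.ndarray:
    """Decoding accuracy at a matched population size.

    Repeats the frame-by-frame decode with ``target_n`` randomly drawn
    neurons, ``n_draws`` times, and returns the per-frame mean across
    draws — the control showing group differences are not an ROI-count
    artefact.
    """
    if target_n < 2:
        raise ValueError("target_n must be >= 2")
    if target_n > tensor.n_neurons:
        raise ValueError("target_n exceeds the session's neuron count")
    rng = np.random.default_rng(seed)
    curves = []
    for d in range(n_draws):
        pick = np.sort(rng.choice(tensor.n_neurons, size=target_n, replace=False))
        sub = TrialTensor(
            values=tensor.values[:, pick, :],
            frame_rate=tensor.frame_rate,
            window=tensor.window,
            onset_frame_index=tensor.onset_frame_index,
            trial_indices=tensor.trial_indices.copy(),
        )
        # decode seed held fixed across draws: the neuron pick is the only
        # varying factor, and target_n == n_rois reproduces the full decode
        res = decode_session(sub, labels, seed=seed, config=config)
        curves.append(res.trained)
    return np.mean(curves, axis=0)


def level_matched_control(
    tensor: TrialTensor,
    outcomes_kept: pd.DataFrame,
    labels: np.ndarray,
    seed: int = 0,
    config: DecoderConfig | None = None,
) -> DecodingResult | None:
    """Decode on sound-level-balanced hit/miss trial sets.

    Equalises hit and miss counts at every sound level (reusing the
    modulation module's balanced subsampling) before decoding, removing
    any level/outcome confound. Returns None (logged) if the session gate
    fails after matching.
    """
    from .modulation import balanced_subsample

    cfg = config or DecoderConfig()
    hit_idx, miss_idx = balanced_subsample(outcomes_kept, seed=seed)
    keep = np.sort(np.concatenate([hit_idx, miss_idx]))
    y = np.asarray(labels).astype(int)[keep]
    if not session_gate(int(y.sum()), int((1 - y).sum()), cfg.min_trials_per_class):
        log.info("level_matched_control: session gate failed after matching; control skipped")
        return None
    sub = TrialTensor(
        values=tensor.values[keep],
        frame_rate=tensor.frame_rate,
        window=tensor.window,
        onset_frame_index=tensor.onset_frame_index,
        trial_indices=tensor.trial_indices[keep],
    )
    return decode_session(sub, y, seed=seed, config=cfg)
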