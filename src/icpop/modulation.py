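"""Per-neuron task-modulation and sound-responsiveness statistics.

A neuron is outcome-modulated if its single-trial response magnitude (mean
dF/F over the 5 s after the stimulus minus the mean over the 2 s before)
differs between hit and miss trials by a Mann-Whitney U test, computed on
sound-level-balanced trial subsets so outcome is not confounded with
stimulus intensity. Sound-driven neurons are identified on miss trials
(53-65 dB SPL) by a Wilcoxon signed-rank test of pre- (2 s) vs post- (1 s)
stimulus means. Both families are Benjamini-Hochberg corrected at q=0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .signals import TrialTensor

log = logging.getLogger(__name__)

__all__ = [
    "response_magnitude",
    "balanced_subsample",
    "hit_miss_test",
    "sound_response_test",
    "bh_adjust",
    "analyze_session",
    "ModulationResult",
]


def response_magnitude(tensor: TrialTensor, post_s: float = 5.0, pre_s: float = 2.0) -> np.ndarray:
    """Per-trial, per-neuron response magnitude: mean(post) - mean(pre).

    ``post_s`` seconds after and ``pre_s`` seconds before stimulus onset;
    returns an array of shape (trials, neurons).
    """
    t = tensor.frame_times
    pre = (t >= -pre_s) & (t < 0)
    post = (t >= 0) & (t < post_s)
    if pre.sum() == 0 or post.sum() == 0:
        raise ValueError("trial window does not cover the requested pre/post periods")
    return tensor.values[:, :, post].mean(axis=2) - tensor.values[:, :, pre].mean(axis=2)


def balanced_subsample(
    outcomes: pd.DataFrame, seed: int, keep_mask: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Sound-level-balanced hit/miss trial index sets.

    At every sound level the more numerous outcome is randomly downsampled
    (without replacement) to match the rarer one; levels lacking either
    outcome are dropped. Returns ``(hit_idx, miss_idx)`` as positional
    indices into ``outcomes``.
    """
    rng = np.random.default_rng(seed)
    labels = outcomes["label"].to_numpy()
    levels = outcomes["level_db"].to_numpy()
    if keep_mask is None:
        keep_mask = np.ones(len(outcomes), dtype=bool)
    hit_out, miss_out = [], []
    for lv in np.unique(levels[~pd.isna(levels)]):
        at = (levels == lv) & keep_mask
        hits = np.flatnonzero(at & (labels == "hit"))
        misses = np.flatnonzero(at & (labels == "miss"))
        k = min(hits.size, misses.size)
        if k == 0:
            continue
        hit_out.append(rng.choice(hits, size=k, replace=False))
        miss_out.append(rng.choice(misses, size=k, replace=False))
    if not hit_out:
        raise ValueError("no sound level has both hit and miss trials")
    return np.sort(np.concatenate(hit_out)), np.sort(np.concatenate(miss_out))


def hit_miss_test(
    magnitudes_hit: np.ndarray, magnitudes_miss: np.ndarray, min_n: int = 3
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test of hit vs miss response magnitudes.

    Exact null distribution for small samples (both n <= 20, no ties),
    normal approximation with tie correction otherwise. Returns ``(U, p)``.
    """
    x = np.asarray(magnitudes_hit, dtype=float)
    y = np.asarray(magnitudes_miss, dtype=float)
    if x.size < min_n or y.size < min_n:
        raise ValueError(f"need at least {min_n} trials per outcome")
    pooled = np.concatenate([x, y])
    if np.unique(pooled).size == 1:
        return float(x.size * y.size / 2.0), 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (max(x.size, y.size) <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def sound_response_test(
    tensor: TrialTensor,
    outcomes: pd.DataFrame,
    neuron: int,
    level_range: tuple[float, float] = (53.0, 65.0),
    pre_s: float = 2.0,
    post_s: float = 1.0,
    min_pairs: int = 5,
) -> tuple[float, float]:
    """Wilcoxon signed-rank test for a sound-evoked response on miss trials.

    Pairs the mean activity over the 2 s before with the mean over the 1 s
    after stimulus onset, restricted to miss trials at moderate click
    intensities (53-65 dB SPL, where misses are plentiful). Returns (W, p);
    raises if fewer than ``min_pairs`` qualifying trials exist.
    """
    labels = outcomes["label"].to_numpy()[tensor.trial_indices]
    levels = outcomes["level_db"].to_numpy()[tensor.trial_indices]
    qual = (
        (labels == "miss")
        & ~pd.isna(levels)
        & (levels >= level_range[0])
        & (levels <= level_range[1])
    )
    if qual.sum() < min_pairs:
        raise ValueError(
            f"only {int(qual.sum())} qualifying miss trials (< {min_pairs}); neuron excluded"
        )
    t = tensor.frame_times
    pre = (t >= -pre_s) & (t < 0)
    post = (t >= 0) & (t < post_s)
    a = tensor.values[qual, neuron][:, pre].mean(axis=1)
    b = tensor.values[qual, neuron][:, post].mean(axis=1)
    if np.allclose(a, b):
        return 0.0, 1.0
    res = stats.wilcoxon(b, a, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def bh_adjust(p_values: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjustment.

    Returns ``(adjusted_p, significant)`` with ``significant`` meaning
    adjusted p < q.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy(), np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    _, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, p_adj < q


@dataclass
class ModulationResult:
    """Per-neuron outcome-modulation statistics for one session."""

    table: pd.DataFrame  # neuron_id, U, p_raw, p_bh, significant, direction, n_hit_used, n_miss_used
    seed: int

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())


def analyze_session(
    tensor: TrialTensor,
    outcomes: pd.DataFrame,
    seed: int = 0,
    q: float = 0.05,
    keep_mask: np.ndarray | None = None,
    min_n: int = 3,
    n_draws: int = 1,
) -> ModulationResult:
    """Outcome-modulation screen over all neurons in a session.

    By default one balanced subsample is drawn per session (seed logged)
    and all neurons are tested on the same trial subset, then BH-corrected
    together. With ``n_draws`` > 1 the subsampling is repeated and the
    median p (and U) across draws is reported per neuron, damping
    single-draw sampling flukes. Direction is the sign of the
    hit-minus-miss median difference.
    """
    mags = response_magnitude(tensor)
    out_kept = outcomes.iloc[tensor.trial_indices].reset_index(drop=True)
    km = None if keep_mask is None else np.asarray(keep_mask)[tensor.trial_indices]
    draw_seeds = np.random.SeedSequence(seed).generate_state(n_draws) % (2**31)

    stats_per_draw = []
    for ds in draw_seeds:
        hit_idx, miss_idx = balanced_subsample(out_kept, seed=int(ds), keep_mask=km)
        draw = []
        for n in range(tensor.n_neurons):
            h, m = mags[hit_idx, n], mags[miss_idx, n]
            U, p = hit_miss_test(h, m, min_n=min_n)
            draw.append((U, p, np.median(h) - np.median(m), h.size, m.size))
        stats_per_draw.append(draw)

    arr = np.array(stats_per_draw)  # (draws, neurons, 5)
    med = np.median(arr, axis=0)
    rows = []
    for n in range(tensor.n_neurons):
        rows.append(
            {
                "neuron_id": n,
                "U": med[n, 0],
                "p_raw": med[n, 1],
                "direction": "facilitated" if med[n, 2] >= 0 else "suppressed",
                "n_hit_used": int(med[n, 3]),
                "n_miss_used": int(med[n, 4]),
            }
        )
    table = pd.DataFrame(rows)
    table["p_bh"], table["significant"] = bh_adjust(table["p_raw"].to_numpy(), q=q)
    return ModulationResult(table=table, seed=seed)
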