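"""Behavioural scoring and detection-performance summaries.

Trials are scored from lick timestamps with the standard go/no-go rule: a
lick within the response window after a stimulus onset is a hit, silence a
miss; on catch trials a lick is a false alarm, silence a correct rejection.
Sensitivity is summarised as d' = Phi^-1(HR) - Phi^-1(FAR) with a
log-linear correction (0.5 added to every cell) so extreme rates stay
finite, overall and within 10-dB sound-level bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtri
from statsmodels.stats.proportion import proportions_chisquare

__all__ = [
    "score_trials",
    "dprime",
    "dprime_from_rates",
    "psychometric",
    "BehavioralSummary",
    "opto_proportion_test",
    "peri_event_lick_rate",
]

LABELS = ("hit", "miss", "false_alarm", "correct_rejection")


def score_trials(
    schedule: pd.DataFrame, licks: np.ndarray, response_window: float = 1.5
) -> pd.DataFrame:
    """Assign hit/miss/false-alarm/correct-rejection labels to every trial.

    Parameters
    ----------
    schedule : trial table with ``onset_s``, ``is_catch``, ``level_db``.
    licks : sorted lick times (s).
    response_window : s after onset within which a lick counts as a response.

    Returns a DataFrame aligned with ``schedule``: ``label``, ``latency_s``
    (first lick after onset within the window; NaN if none), ``level_db``.
    """
    licks = np.asarray(licks, dtype=float)
    if licks.size and np.any(np.diff(licks) < 0):
        raise ValueError("licks must be sorted ascending")
    onsets = schedule["onset_s"].to_numpy()
    if np.any(np.diff(onsets) < response_window):
        raise ValueError("response windows overlap: schedule invalid")

    # first lick strictly after each onset
    idx = np.searchsorted(licks, onsets, side="right")
    latency = np.full(len(schedule), np.nan)
    has = idx < licks.size
    latency[has] = licks[idx[has]] - onsets[has]
    responded = has & (latency <= response_window)
    latency[~responded] = np.nan

    is_catch = schedule["is_catch"].to_numpy()
    label = np.where(
        is_catch,
        np.where(responded, "false_alarm", "correct_rejection"),
        np.where(responded, "hit", "miss"),
    )
    out = pd.DataFrame(
        {
            "label": label,
            "latency_s": latency,
            "level_db": schedule["level_db"].to_numpy(),
            "onset_s": onsets,
        },
        index=schedule.index,
    )
    out.attrs["response_window_s"] = response_window
    return out


def dprime(n_hit: int, n_miss: int, n_fa: int, n_cr: int) -> float:
    """Detection sensitivity d' from trial counts.

    Uses the log-linear correction (add 0.5 to each cell) so 0% and 100%
    rates give finite values: HR = (n_hit + 0.5)/(n_hit + n_miss + 1), and
    likewise for the false-alarm rate.
    """
    if n_hit + n_miss < 1 or n_fa + n_cr < 1:
        raise ValueError("need at least one stimulus and one catch trial")
    hr = (n_hit + 0.5) / (n_hit + n_miss + 1.0)
    far = (n_fa + 0.5) / (n_fa + n_cr + 1.0)
    return float(ndtri(hr) - ndtri(far))


def dprime_from_rates(hit_rate: float, fa_rate: float) -> float:
    """d' straight from rates (no correction); rates must be in (0, 1)."""
    return float(ndtri(hit_rate) - ndtri(fa_rate))


@dataclass
class BehavioralSummary:
    """Session-level detection performance."""

    hit_rate: float
    fa_rate: float
    dprime: float
    per_bin: pd.DataFrame  # bin_lo, bin_hi, n_hit, n_miss, hit_rate, dprime
    per_level: pd.DataFrame  # level_db, n_hit, n_miss, hit_rate, dprime

    def to_row(self, session_id: str = "session") -> pd.DataFrame:
        """One-row frame suitable for a cohort summary CSV."""
        return pd.DataFrame(
            {
                "session_id": [session_id],
                "hit_rate": [self.hit_rate],
                "fa_rate": [self.fa_rate],
                "dprime": [self.dprime],
                "per_bin_dprime": [self.per_bin.to_json(orient="records")],
            }
        )


def _counts(outcomes: pd.DataFrame) -> tuple[int, int, int, int]:
    c = outcomes["label"].value_counts()
    return (
        int(c.get("hit", 0)),
        int(c.get("miss", 0)),
        int(c.get("false_alarm", 0)),
        int(c.get("correct_rejection", 0)),
    )


def psychometric(outcomes: pd.DataFrame, bin_width_db: float = 10.0) -> BehavioralSummary:
    """Hit rate, false-alarm rate and d' overall, per level, and in dB bins.

    Sound-level bins of width ``bin_width_db`` are anchored at the lowest
    presented level; the last bin is closed on the right. Catch trials carry
    no level, so the session-wide false-alarm counts are reused for every
    bin's d'. Empty bins are omitted.
    """
    n_hit, n_miss, n_fa, n_cr = _counts(outcomes)
    overall = dprime(n_hit, n_miss, n_fa, n_cr)
    hit_rate = n_hit / max(n_hit + n_miss, 1)
    fa_rate = n_fa / max(n_fa + n_cr, 1)

    stim = outcomes[~outcomes["level_db"].isna()]
    levels = np.sort(stim["level_db"].unique())

    def _stats(sub: pd.DataFrame) -> tuple[int, int, float, float]:
        h = int((sub["label"] == "hit").sum())
        m = int((sub["label"] == "miss").sum())
        return h, m, h / max(h + m, 1), dprime(h, m, n_fa, n_cr)

    per_level_rows = []
    for lv in levels:
        h, m, r, d = _stats(stim[stim["level_db"] == lv])
        per_level_rows.append({"level_db": lv, "n_hit": h, "n_miss": m, "hit_rate": r, "dprime": d})
    per_level = pd.DataFrame(per_level_rows)

    per_bin_rows = []
    if levels.size:
        # last bin is closed on the right: levels 41..71 at width 10 give
        # exactly [41,51), [51,61), [61,71]
        n_bins = max(1, int(np.ceil((levels[-1] - levels[0]) / bin_width_db)))
        edges = [
            (levels[0] + k * bin_width_db, levels[0] + (k + 1) * bin_width_db)
            for k in range(n_bins)
        ]
        for k, (b0, b1) in enumerate(edges):
            last = k == len(edges) - 1
            m = (stim["level_db"] >= b0) & (
                (stim["level_db"] <= b1) if last else (stim["level_db"] < b1)
            )
            sub = stim[m]
            if len(sub) == 0:
                continue
            h, mm, r, d = _stats(sub)
            per_bin_rows.append(
                {"bin_lo": b0, "bin_hi": b1, "n_hit": h, "n_miss": mm, "hit_rate": r, "dprime": d}
            )
    per_bin = pd.DataFrame(per_bin_rows)

    return BehavioralSummary(
        hit_rate=hit_rate, fa_rate=fa_rate, dprime=overall, per_bin=per_bin, per_level=per_level
    )


def opto_proportion_test(
    hits_on: int, total_on: int, hits_off: int, total_off: int
) -> tuple[float, float]:
    """Two-sided chi-squared test (1 df) of equal hit proportions on vs off.

    Returns ``(statistic, p_value)``.
    """
    if total_on < 1 or total_off < 1:
        raise ValueError("totals must be >= 1")
    stat, p, _ = proportions_chisquare(
        count=np.array([hits_on, hits_off]), nobs=np.array([total_on, total_off])
    )
    return float(stat), float(p)


def peri_event_lick_rate(
    licks: np.ndarray,
    reference_times: np.ndarray,
    window: tuple[float, float] = (0.0, 16.0),
    bin_width: float = 0.25,
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram-based lick rate (Hz) around reference events.

    Returns ``(bin_centers, rate_hz)`` where ``rate_hz[k]`` is the mean lick
    rate at lag ``bin_centers[k]`` relative to the reference events — the
    curve compared against the inter-trial-interval density to reveal
    anticipatory licking.
    """
    reference_times = np.asarray(reference_times, dtype=float)
    if reference_times.size == 0:
        raise ValueError("need at least one reference event")
    licks = np.asarray(licks, dtype=float)
    edges = np.arange(window[0], window[1] + bin_width / 2, bin_width)
    counts = np.zeros(edges.size - 1)
    for t0 in reference_times:
        rel = licks - t0
        rel = rel[(rel >= window[0]) & (rel < window[1])]
        counts += np.histogram(rel, bins=edges)[0]
    rate = counts / (reference_times.size * bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, rate
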