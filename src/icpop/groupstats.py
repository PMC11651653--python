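"""Timewise statistics on decoding timecourses.

Per timepoint, trained-vs-dummy scores are compared with a one-sided
paired test (Wilcoxon signed-rank or paired t) and group-vs-group scores
with a one-sided unpaired test (Mann-Whitney U or t); the parametric
branch is taken only when a Shapiro-Wilk test does not reject normality
(p >= 0.05 — on the paired differences for paired tests, on both groups
for unpaired). Significance is Bonferroni-corrected across the tested
(optionally binned) timepoints.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = ["normality_gate", "compare_to_dummy", "compare_groups", "TimecourseComparison"]


def normality_gate(*samples: np.ndarray, alpha: float = 0.05) -> bool:
    """True if every sample looks Gaussian by a Shapiro-Wilk test.

    Constant samples make the test undefined; they fall back to the
    nonparametric branch (returns False, logged).
    """
    for x in samples:
        x = np.asarray(x, dtype=float)
        if x.size < 3:
            raise ValueError("normality gate needs n >= 3")
        if np.allclose(x, x[0]):
            log.info("normality_gate: constant sample; nonparametric fallback")
            return False
        if stats.shapiro(x).pvalue < alpha:
            return False
    return True


@dataclass
class TimecourseComparison:
    """Per-timepoint test outcomes for one comparison."""

    table: pd.DataFrame  # time_s, test_used, p_raw, significant
    comparison: str
    alpha: float = 0.05
    bin_factor: int = 1

    @property
    def n_tests(self) -> int:
        return len(self.table)

    @property
    def corrected_alpha(self) -> float:
        return self.alpha / max(self.n_tests, 1)

    @property
    def significant_times(self) -> np.ndarray:
        return self.table.loc[self.table["significant"], "time_s"].to_numpy()


def _bin_scores(scores: np.ndarray, times: np.ndarray, bin_factor: int):
    """Average every ``bin_factor`` consecutive timepoints (trailing
    remainder dropped)."""
    if bin_factor <= 1:
        return scores, times
    n = (scores.shape[1] // bin_factor) * bin_factor
    s = scores[:, :n].reshape(scores.shape[0], -1, bin_factor).mean(axis=2)
    t = times[:n].reshape(-1, bin_factor).mean(axis=1)
    return s, t


def compare_to_dummy(
    trained: np.ndarray,
    dummy: np.ndarray,
    times: np.ndarray,
    alpha: float = 0.05,
    comparison: str = "trained_vs_dummy",
) -> TimecourseComparison:
    """One-sided paired comparison of trained vs dummy scores per frame.

    ``trained`` and ``dummy`` are (sessions x frames), paired by session.
    Per frame: Shapiro gate on the paired differences, then a one-sided
    paired t-test or Wilcoxon signed-rank testing trained > dummy;
    Bonferroni across frames.
    """
    trained = np.atleast_2d(np.asarray(trained, dtype=float))
    dummy = np.atleast_2d(np.asarray(dummy, dtype=float))
    if trained.shape != dummy.shape:
        raise ValueError("trained and dummy must be paired (same sessions x frames)")
    if trained.shape[0] < 5:
        raise ValueError("need at least 5 sessions")
    m = trained.shape[1]
    rows = []
    for f in range(m):
        d = trained[:, f] - dummy[:, f]
        if np.allclose(d, 0):
            rows.append({"time_s": times[f], "test_used": "signed-rank", "p_raw": 1.0})
            continue
        if normality_gate(d):
            t_res = stats.ttest_rel(trained[:, f], dummy[:, f], alternative="greater")
            rows.append({"time_s": times[f], "test_used": "paired-t", "p_raw": float(t_res.pvalue)})
        else:
            w = stats.wilcoxon(d, alternative="greater")
            rows.append({"time_s": times[f], "test_used": "signed-rank", "p_raw": float(w.pvalue)})
    table = pd.DataFrame(rows)
    table["significant"] = table["p_raw"] < alpha / m
    return TimecourseComparison(table=table, comparison=comparison, alpha=alpha)


def compare_groups(
    scores_a: np.ndarray,
    scores_b: np.ndarray,
    times: np.ndarray,
    bin_factor: int = 1,
    alpha: float = 0.05,
    comparison: str = "group_a_vs_group_b",
) -> TimecourseComparison:
    """One-sided unpaired comparison (A > B) per (binned) timepoint.

    ``scores_a``/``scores_b`` are (sessions x frames). With ``bin_factor``
    > 1 every that many consecutive timepoints are averaged before testing
    (used for small samples), which also shrinks the Bonferroni family.
    The parametric branch requires both groups to pass the Shapiro gate;
    if either fails, a Mann-Whitney U test is used (logged when the groups
    disagree).
    """
    a = np.atleast_2d(np.asarray(scores_a, dtype=float))
    b = np.atleast_2d(np.asarray(scores_b, dtype=float))
    if a.shape[0] < 3 or b.shape[0] < 3:
        raise ValueError("both groups need at least 3 sessions")
    if a.shape[1] != b.shape[1]:
        raise ValueError("groups must share the frame axis (interpolate first)")
    times = np.asarray(times, dtype=float)
    a, ta = _bin_scores(a, times, bin_factor)
    b, _ = _bin_scores(b, times, bin_factor)
    m = a.shape[1]
    rows = []
    for f in range(m):
        xa, xb = a[:, f], b[:, f]
        ga = normality_gate(xa)
        gb = normality_gate(xb)
        if ga != gb:
            log.info("compare_groups: groups disagree on normality at t=%.3f; nonparametric", ta[f])
        if ga and gb:
            res = stats.ttest_ind(xa, xb, alternative="greater")
            rows.append({"time_s": ta[f], "test_used": "t", "p_raw": float(res.pvalue)})
        else:
            if np.allclose(np.concatenate([xa, xb]), xa[0]):
                rows.append({"time_s": ta[f], "test_used": "mann-whitney", "p_raw": 1.0})
                continue
            res = stats.mannwhitneyu(xa, xb, alternative="greater")
            rows.append({"time_s": ta[f], "test_used": "mann-whitney", "p_raw": float(res.pvalue)})
    table = pd.DataFrame(rows)
    table["significant"] = table["p_raw"] < alpha / m
    return TimecourseComparison(table=table, comparison=comparison, alpha=alpha, bin_factor=bin_factor)
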