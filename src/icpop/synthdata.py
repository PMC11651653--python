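"""Synthetic go/no-go detection-task sessions with full ground truth.

Generates the three ingredients of a two-photon session recorded during a
sound-detection task: a trial schedule (stimulus and catch trials separated
by truncated-normal inter-trial intervals), a lick train produced by a
psychometric behaviour model, and per-ROI fluorescence traces built from
cluster-prototype hit/miss response profiles convolved with a calcium-like
kernel, plus neuropil contamination, slow drift and Gaussian noise.

Every sampler takes an explicit seed and is bit-reproducible; the ground
truth (cluster identity, outcome-coding flag, generating parameters) is
returned alongside the data so downstream statistics can be validated
against a known answer.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml
from scipy import signal as sps
from scipy.stats import truncnorm

__all__ = [
    "ScheduleParams",
    "PsychModel",
    "NeuronPrototype",
    "DriftParams",
    "SessionRecording",
    "SyntheticGroundTruth",
    "KERNEL_RATE_HZ",
    "kernel_time_grid",
    "truncated_normal_pdf",
    "sample_schedule",
    "hit_probability",
    "sample_behavior",
    "default_prototypes",
    "synthesize_session",
    "write_session_bundle",
    "read_session_bundle",
]

#: Internal sampling rate (Hz) of prototype kernels over the -2 s..+5 s window.
KERNEL_RATE_HZ = 50.0

#: Trial window relative to stimulus onset, seconds.
TRIAL_WINDOW = (-2.0, 5.0)


def kernel_time_grid() -> np.ndarray:
    """Time grid (s, relative to onset) on which prototype kernels live."""
    t0, t1 = TRIAL_WINDOW
    n = int(round((t1 - t0) * KERNEL_RATE_HZ)) + 1
    return np.linspace(t0, t1, n)


@dataclass(frozen=True)
class ScheduleParams:
    """Trial-schedule parameters.

    Inter-trial intervals are drawn from a normal distribution truncated
    below: mean ``iti_mean`` s, SD ``iti_sd`` s, floor ``iti_floor`` s
    (defaults 8/2/3 s). Roughly one in ten trials is a catch (no-stimulus)
    trial; each stimulus trial carries one sound level. A lick inside
    ``response_window`` seconds of a stimulus onset counts as a response.
    """

    iti_mean: float = 8.0
    iti_sd: float = 2.0
    iti_floor: float = 3.0
    n_trials: int = 400
    catch_fraction: float = 0.1
    sound_levels: tuple[float, ...] = (41.0, 44.0, 47.0, 50.0, 53.0, 56.0, 59.0, 62.0, 65.0)
    response_window: float = 1.5

    def __post_init__(self) -> None:
        if self.n_trials <= 0:
            raise ValueError("n_trials must be positive")
        if self.iti_floor <= 0:
            raise ValueError("iti_floor must be positive")
        if self.iti_sd < 0:
            raise ValueError("iti_sd must be non-negative")
        if not 0 <= self.catch_fraction < 1:
            raise ValueError("catch_fraction must be in [0, 1)")
        if self.response_window <= 0:
            raise ValueError("response_window must be positive")
        if list(self.sound_levels) != sorted(self.sound_levels):
            raise ValueError("sound_levels must be sorted ascending")


@dataclass(frozen=True)
class PsychModel:
    """Generative psychometric model of the animal.

    Hit probability on a stimulus trial at sound level x is

        p(x) = fa + (1 - fa - lapse) * sigmoid(slope * (x - midpoint))

    so performance rises from the false-alarm floor to 1 - lapse. Response
    latencies are bounded below by ``lick_latency_floor`` (the animals'
    minimum lick latency, 120 ms). ``anticipation_rate`` is the expected
    number of spontaneous anticipatory licks per trial, timed like the
    upcoming trial onset (the animal has learned the ITI distribution).
    """

    midpoint: float = 53.0
    slope: float = 0.5
    lapse_rate: float = 0.05
    false_alarm_rate: float = 0.1
    lick_latency_floor: float = 0.12
    anticipation_rate: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.lapse_rate <= 1:
            raise ValueError("lapse_rate must be in [0, 1]")
        if not 0 <= self.false_alarm_rate <= 1:
            raise ValueError("false_alarm_rate must be in [0, 1]")
        if self.lick_latency_floor < 0.12:
            raise ValueError("lick_latency_floor must be >= 0.12 s")


@dataclass
class NeuronPrototype:
    """Cluster prototype: hit/miss response time-courses on the trial window.

    ``hit_kernel`` and ``miss_kernel`` are the underlying activity drives
    over -2 s..+5 s (sampled on :func:`kernel_time_grid`); they are convolved
    with a calcium impulse response when a session is synthesised.
    ``prestim_state_gain`` adds a pre-stimulus offset of +gain/2 on hit and
    -gain/2 on miss trials, planting outcome information before the sound.
    """

    cluster_id: int
    hit_kernel: np.ndarray
    miss_kernel: np.ndarray
    prestim_state_gain: float = 0.0

    def __post_init__(self) -> None:
        n = kernel_time_grid().size
        self.hit_kernel = np.asarray(self.hit_kernel, dtype=float)
        self.miss_kernel = np.asarray(self.miss_kernel, dtype=float)
        if self.hit_kernel.shape != (n,) or self.miss_kernel.shape != (n,):
            raise ValueError(f"kernels must cover the full trial window ({n} samples)")

    @property
    def codes_outcome(self) -> bool:
        """True if hit and miss trials are distinguishable from this neuron."""
        return (
            not np.array_equal(self.hit_kernel, self.miss_kernel)
            or self.prestim_state_gain != 0.0
        )


@dataclass(frozen=True)
class DriftParams:
    """Slow multiplicative-free additive drift: amplitude * sin(2*pi*t/period + phase)."""

    amplitude: float = 5.0
    period_s: float = 300.0


@dataclass
class SessionRecording:
    """Raw per-ROI fluorescence with matched neuropil traces."""

    F: np.ndarray  # (n_rois, n_frames)
    Fneu: np.ndarray  # (n_rois, n_frames)
    frame_rate: float  # Hz
    session_id: str = "session"
    group: str = "non-lesioned"

    @property
    def n_rois(self) -> int:
        return self.F.shape[0]

    @property
    def n_frames(self) -> int:
        return self.F.shape[1]

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate


@dataclass
class SyntheticGroundTruth:
    """Everything needed to check downstream analyses against the generator."""

    cluster_ids: np.ndarray  # (n_neurons,)
    outcome_coding: np.ndarray  # (n_neurons,) bool
    psych_model: PsychModel | None
    schedule_params: ScheduleParams | None
    seed: int
    prototypes: list[NeuronPrototype] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "cluster_ids": self.cluster_ids.tolist(),
            "outcome_coding": self.outcome_coding.astype(bool).tolist(),
            "psych_model": dataclasses.asdict(self.psych_model) if self.psych_model else None,
            "schedule_params": dataclasses.asdict(self.schedule_params)
            if self.schedule_params
            else None,
            "seed": int(self.seed),
        }


def truncated_normal_pdf(x, mean: float = 8.0, sd: float = 2.0, floor: float = 3.0):
    """Density of the inter-trial-interval distribution (normal truncated below)."""
    a = (floor - mean) / sd
    return truncnorm.pdf(x, a, np.inf, loc=mean, scale=sd)


def sample_schedule(params: ScheduleParams, seed: int) -> pd.DataFrame:
    """Sample a trial schedule.

    Inter-trial intervals are exact truncated-normal draws (never clipped,
    so the floor does not pile up probability mass). Catch trials are
    interleaved at random positions; stimulus trials get sound levels in
    a shuffled balanced assignment.

    Returns a trial table with columns ``onset_s``, ``is_catch``,
    ``level_db`` (NaN on catch trials) and ``opto``; the response window is
    stored in ``DataFrame.attrs["response_window_s"]``.
    """
    rng = np.random.default_rng(seed)
    n = params.n_trials
    if params.iti_sd == 0:
        itis = np.full(n, max(params.iti_mean, params.iti_floor))
    else:
        a = (params.iti_floor - params.iti_mean) / params.iti_sd
        itis = truncnorm.rvs(
            a, np.inf, loc=params.iti_mean, scale=params.iti_sd, size=n, random_state=rng
        )
    onsets = np.cumsum(itis)  # first onset one ITI after session start

    n_catch = int(round(params.catch_fraction * n))
    is_catch = np.zeros(n, dtype=bool)
    is_catch[rng.choice(n, size=n_catch, replace=False)] = True

    n_stim = n - n_catch
    levels = np.asarray(params.sound_levels, dtype=float)
    # balanced assignment of levels across stimulus trials, then shuffled
    reps = np.tile(levels, n_stim // levels.size + 1)[:n_stim]
    rng.shuffle(reps)
    level_db = np.full(n, np.nan)
    level_db[~is_catch] = reps

    trials = pd.DataFrame(
        {
            "onset_s": onsets,
            "is_catch": is_catch,
            "level_db": level_db,
            "opto": np.zeros(n, dtype=bool),
        }
    )
    trials.attrs["response_window_s"] = params.response_window
    trials.attrs["iti_params"] = (params.iti_mean, params.iti_sd, params.iti_floor)
    return trials


def hit_probability(level_db, model: PsychModel) -> np.ndarray:
    """Sigmoid hit probability at the given sound level(s)."""
    from scipy.special import expit

    x = np.asarray(level_db, dtype=float)
    fa, lapse = model.false_alarm_rate, model.lapse_rate
    with np.errstate(over="ignore"):
        core = expit(model.slope * (x - model.midpoint))
    return fa + (1.0 - fa - lapse) * core


def _response_latency(rng: np.random.Generator, floor: float, window: float, size: int):
    """Latencies in (floor, window): floor plus a right-skewed beta spread."""
    return floor + (window - floor) * rng.beta(2.0, 6.0, size=size)


def sample_behavior(schedule: pd.DataFrame, model: PsychModel, seed: int) -> np.ndarray:
    """Simulate the animal's licking for a trial schedule.

    On stimulus trials a response lick is emitted with the psychometric hit
    probability; on catch trials with the false-alarm rate. Latencies lie in
    (lick_latency_floor, response_window]. Spontaneous anticipatory licks
    are placed after each trial at lags drawn from the ITI distribution
    (the learned expectation of the next trial), then any spontaneous lick
    falling inside a response window is removed so scoring is governed
    solely by the psychometric model.

    Returns a sorted array of lick times (s).
    """
    if len(schedule) == 0:
        raise ValueError("schedule is empty")
    rng = np.random.default_rng(seed)
    window = schedule.attrs.get("response_window_s", 1.5)
    iti_mean, iti_sd, iti_floor = schedule.attrs.get("iti_params", (8.0, 2.0, 3.0))

    onsets = schedule["onset_s"].to_numpy()
    is_catch = schedule["is_catch"].to_numpy()
    levels = schedule["level_db"].to_numpy()

    licks: list[np.ndarray] = []

    p = np.where(is_catch, model.false_alarm_rate, hit_probability(levels, model))
    responds = rng.random(len(schedule)) < p
    lat = _response_latency(rng, model.lick_latency_floor, window, len(schedule))
    licks.append(onsets[responds] + lat[responds])

    # anticipatory licks: Poisson count per trial, lag ~ ITI distribution
    if model.anticipation_rate > 0:
        counts = rng.poisson(model.anticipation_rate, size=len(schedule))
        total = int(counts.sum())
        if total:
            if iti_sd > 0:
                a = (iti_floor - iti_mean) / iti_sd
                lags = truncnorm.rvs(
                    a, np.inf, loc=iti_mean, scale=iti_sd, size=total, random_state=rng
                )
            else:
                lags = np.full(total, iti_mean)
            spont = np.repeat(onsets, counts) + lags
            # spontaneous licks never intrude into a response window
            in_window = np.zeros(spont.size, dtype=bool)
            for t0 in onsets:
                in_window |= (spont >= t0) & (spont <= t0 + window)
            licks.append(spont[~in_window])

    out = np.sort(np.concatenate(licks)) if licks else np.empty(0)
    return out


def _sharp(t: np.ndarray, amp: float, latency: float = 0.05, width: float = 0.15) -> np.ndarray:
    """Sharp short-latency onset transient."""
    k = np.zeros_like(t)
    m = t >= latency
    k[m] = amp * np.exp(-(t[m] - latency) / width)
    return k


def _gradual(t: np.ndarray, amp: float, peak_s: float = 3.0, rise: float = 1.2) -> np.ndarray:
    """Gradual change peaking seconds after trial onset."""
    k = np.zeros_like(t)
    m = t >= 0
    tt = t[m] / rise
    k[m] = amp * (tt**2) * np.exp(-t[m] / (peak_s / 2.0))
    k /= max(np.abs(k).max(), 1e-12)
    return amp * k


def default_prototypes(amplitude: float = 1.0) -> list[NeuronPrototype]:
    """Five response-profile prototypes mirroring the variety seen in vivo.

    0: sharp onset increase on hits, weak on misses;
    1: suppression on hits, flat on misses;
    2: gradual late-peaking ramp on hits only;
    3: behaviour-invariant sound response (hit == miss);
    4: flat kernels but a pre-stimulus state offset (outcome coded before
       the sound arrives).
    """
    t = kernel_time_grid()
    a = amplitude
    sustained = np.where((t >= 0) & (t < 3.0), 1.0, 0.0)
    short_box = 0.7 * a * np.where((t >= 0) & (t < 1.2), 1.0, 0.0)
    protos = [
        NeuronPrototype(0, _sharp(t, a), _sharp(t, 0.25 * a)),
        NeuronPrototype(1, -a * sustained, np.zeros_like(t)),
        NeuronPrototype(2, _gradual(t, a), _gradual(t, 0.1 * a)),
        NeuronPrototype(3, short_box.copy(), short_box.copy()),
        NeuronPrototype(4, np.zeros_like(t), np.zeros_like(t), prestim_state_gain=1.2 * a),
    ]
    return protos


def _calcium_convolve(drive: np.ndarray, tau_s: float = 0.5) -> np.ndarray:
    """Smooth a drive with a unit-area single-exponential calcium kernel (GCaMP6f-like)."""
    dt = 1.0 / KERNEL_RATE_HZ
    th = np.arange(0.0, 5.0 * tau_s, dt)
    h = np.exp(-th / tau_s)
    h /= h.sum()
    return sps.fftconvolve(drive, h)[: drive.size]


def synthesize_session(
    schedule: pd.DataFrame,
    licks: np.ndarray,
    prototypes: list[NeuronPrototype],
    n_neurons: int = 50,
    noise_sd: float = 0.05,
    neuropil_gain: float = 0.7,
    drift_params: DriftParams | None = None,
    frame_rate_hz: float = 28.0,
    seed: int = 0,
    baseline: float = 100.0,
    calcium_tau_s: float = 0.5,
    session_id: str = "session",
    group: str = "non-lesioned",
) -> tuple[SessionRecording, SyntheticGroundTruth]:
    """Synthesise fluorescence traces for a behaving session.

    Each neuron is assigned a prototype (round-robin over ``prototypes``);
    on every stimulus trial its hit or miss kernel — chosen by the scored
    trial outcome — is convolved with a single-exponential calcium impulse
    response (tau = ``calcium_tau_s``) and added to the trace. On top of
    that: a per-neuron constant baseline, sinusoidal slow drift, a shared
    neuropil background scaled by ``neuropil_gain``, and iid Gaussian noise
    of SD ``noise_sd`` (in baseline-fluorescence units; signal kernels have
    unit-order amplitude on the same scale after scaling by ``baseline``).

    Returns the recording (F, Fneu) and the ground truth. Identical
    arguments and seed give bit-identical output.
    """
    if not prototypes:
        raise ValueError("prototype list is empty")
    if not 27.0 <= frame_rate_hz <= 30.0:
        raise ValueError("frame_rate_hz must lie in [27, 30]")
    if n_neurons < 1:
        raise ValueError("n_neurons must be >= 1")
    if drift_params is None:
        drift_params = DriftParams()

    from .behavior import score_trials

    rng = np.random.default_rng(seed)
    window = schedule.attrs.get("response_window_s", 1.5)
    outcomes = score_trials(schedule, licks, response_window=window)

    duration = float(schedule["onset_s"].iloc[-1]) + TRIAL_WINDOW[1] + 3.0
    n_frames = int(np.ceil(duration * frame_rate_hz))
    t = np.arange(n_frames) / frame_rate_hz

    proto_idx = np.arange(n_neurons) % len(prototypes)
    rng.shuffle(proto_idx)
    cluster_ids = np.array([prototypes[i].cluster_id for i in proto_idx])

    kt = kernel_time_grid()
    # per-prototype convolved hit/miss responses (scaled to fluorescence units)
    conv: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for i, p in enumerate(prototypes):
        pre = kt < 0
        hit_drive = p.hit_kernel + np.where(pre, p.prestim_state_gain / 2.0, 0.0)
        miss_drive = p.miss_kernel - np.where(pre, p.prestim_state_gain / 2.0, 0.0)
        conv[i] = (_calcium_convolve(hit_drive, calcium_tau_s), _calcium_convolve(miss_drive, calcium_tau_s))

    F = np.empty((n_neurons, n_frames))
    baselines = baseline * rng.uniform(0.8, 1.2, size=n_neurons)
    phases = rng.uniform(0, 2 * np.pi, size=n_neurons)

    # shared neuropil background: slow filtered noise around a positive mean
    from scipy.ndimage import gaussian_filter1d

    neuro_raw = rng.standard_normal(n_frames)
    sigma_frames = max(1.0, 2.0 * frame_rate_hz)
    background = 20.0 + 8.0 * gaussian_filter1d(neuro_raw, sigma_frames) * np.sqrt(
        2.0 * np.sqrt(np.pi) * sigma_frames
    )
    Fneu = np.tile(background, (n_neurons, 1))

    stim = ~schedule["is_catch"].to_numpy()
    onsets = schedule["onset_s"].to_numpy()
    is_hit = (outcomes["label"] == "hit").to_numpy()

    signal_track = np.zeros((n_neurons, n_frames))
    for j in range(len(schedule)):
        if not stim[j]:
            continue
        t0 = onsets[j]
        lo = max(0, int(np.floor((t0 + TRIAL_WINDOW[0]) * frame_rate_hz)))
        hi = min(n_frames, int(np.ceil((t0 + TRIAL_WINDOW[1]) * frame_rate_hz)) + 1)
        rel = t[lo:hi] - t0
        which = 0 if is_hit[j] else 1
        for i in range(n_neurons):
            resp = conv[proto_idx[i]][which]
            signal_track[i, lo:hi] += np.interp(rel, kt, resp, left=0.0, right=0.0)

    drift = drift_params.amplitude * np.sin(
        2 * np.pi * t[None, :] / max(drift_params.period_s, 1e-9) + phases[:, None]
    )
    F = (
        baselines[:, None]
        + baseline * signal_track
        + drift
        + neuropil_gain * Fneu
        + baseline * noise_sd * rng.standard_normal((n_neurons, n_frames))
    )

    recording = SessionRecording(
        F=F, Fneu=Fneu, frame_rate=frame_rate_hz, session_id=session_id, group=group
    )
    outcome_coding = np.array([prototypes[i].codes_outcome for i in proto_idx])
    truth = SyntheticGroundTruth(
        cluster_ids=cluster_ids,
        outcome_coding=outcome_coding,
        psych_model=None,
        schedule_params=None,
        seed=seed,
        prototypes=prototypes,
    )
    return recording, truth


# ---------------------------------------------------------------------------
# session bundle I/O


def write_session_bundle(
    out_dir: str | Path,
    recording: SessionRecording,
    schedule: pd.DataFrame,
    licks: np.ndarray,
    truth: SyntheticGroundTruth | None = None,
    config: dict | None = None,
) -> Path:
    """Write a session bundle: session.h5 + trials.csv + licks.csv (+ truth/config)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with h5py.File(out / "session.h5", "w") as f:
        f.create_dataset("F", data=recording.F, track_times=False)
        f.create_dataset("Fneu", data=recording.Fneu, track_times=False)
        f.attrs["frame_rate"] = recording.frame_rate
        f.attrs["session_id"] = recording.session_id
        f.attrs["group"] = recording.group
    trials = schedule.copy()
    trials.to_csv(out / "trials.csv", index=False)
    pd.DataFrame({"time_s": licks}).to_csv(out / "licks.csv", index=False)
    meta = {"response_window_s": schedule.attrs.get("response_window_s", 1.5)}
    if "iti_params" in schedule.attrs:
        meta["iti_params"] = list(schedule.attrs["iti_params"])
    (out / "meta.json").write_text(json.dumps(meta))
    if truth is not None:
        (out / "ground_truth.json").write_text(json.dumps(truth.to_dict()))
    if config is not None:
        (out / "config.yaml").write_text(yaml.safe_dump(config))
    return out


def read_session_bundle(bundle_dir: str | Path):
    """Read a bundle written by :func:`write_session_bundle`.

    Returns ``(recording, schedule, licks)``.
    """
    d = Path(bundle_dir)
    with h5py.File(d / "session.h5", "r") as f:
        rec = SessionRecording(
            F=f["F"][()],
            Fneu=f["Fneu"][()],
            frame_rate=float(f.attrs["frame_rate"]),
            session_id=str(f.attrs.get("session_id", d.name)),
            group=str(f.attrs.get("group", "non-lesioned")),
        )
    schedule = pd.read_csv(d / "trials.csv")
    meta_path = d / "meta.json"
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        schedule.attrs["response_window_s"] = meta.get("response_window_s", 1.5)
        if "iti_params" in meta:
            schedule.attrs["iti_params"] = tuple(meta["iti_params"])
    licks = pd.read_csv(d / "licks.csv")["time_s"].to_numpy()
    return rec, schedule, licks
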