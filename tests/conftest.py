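import numpy as np
import pytest

from icpop import behavior, signals, synthdata


@pytest.fixture(scope="session")
def session_chain():
    """One synthetic session taken through scoring and trial alignment.

    Shared (read-only) across test modules: 200 trials, 40 neurons drawn
    from the five default prototypes at moderate noise.
    """
    params = synthdata.ScheduleParams(n_trials=200)
    schedule = synthdata.sample_schedule(params, seed=11)
    licks = synthdata.sample_behavior(schedule, synthdata.PsychModel(), seed=12)
    outcomes = behavior.score_trials(schedule, licks, response_window=params.response_window)
    rec, truth = synthdata.synthesize_session(
        schedule,
        licks,
        synthdata.default_prototypes(),
        n_neurons=40,
        noise_sd=0.05,
        seed=13,
    )
    dff = signals.compute_dff(signals.neuropil_correct(rec.F, rec.Fneu), rec.frame_rate)
    dff = signals.remove_slow_baseline(dff)
    tensor = signals.extract_trials(dff, schedule)
    return {
        "params": params,
        "schedule": schedule,
        "licks": licks,
        "outcomes": outcomes,
        "recording": rec,
        "truth": truth,
        "dff": dff,
        "tensor": tensor,
    }


def subset_tensor(tensor, row_mask):
    """Restrict a trial tensor to a boolean mask over its kept trials."""
    return signals.TrialTensor(
        values=tensor.values[row_mask],
        frame_rate=tensor.frame_rate,
        window=tensor.window,
        onset_frame_index=tensor.onset_frame_index,
        trial_indices=tensor.trial_indices[row_mask],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
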