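import numpy as np
import pytest

from trialaudit.data import DayRecord, SessionRecord, TrialDataset


def make_dataset(
    yes_by_session,
    no_by_session=None,
    sampling_rate=2.0,
    t0=-1.0,
    patient_id="p",
    n_days=1,
):
    """Build a one-day dataset from per-session (trial, channel, time) arrays.

    ``yes_by_session`` / ``no_by_session`` are lists of 3-D arrays; ``no``
    defaults to zeros of the same shape as ``yes``.
    """
    yes_by_session = [np.asarray(a, dtype=float) for a in yes_by_session]
    if no_by_session is None:
        no_by_session = [np.zeros_like(a) for a in yes_by_session]
    else:
        no_by_session = [np.asarray(a, dtype=float) for a in no_by_session]
    n_channels = yes_by_session[0].shape[1]
    n_tp = yes_by_session[0].shape[2]
    time_axis = t0 + np.arange(n_tp) / sampling_rate
    if n_tp == 1:
        # a single sample still needs a valid axis; use a 2-sample axis trick
        time_axis = np.asarray([t0])
    sessions = [
        SessionRecord(session_id=f"s{i}", trials_yes=y, trials_no=n)
        for i, (y, n) in enumerate(zip(yes_by_session, no_by_session))
    ]
    days = [DayRecord(day_id=f"d{k}", sessions=sessions if k == 0 else [
        SessionRecord(session_id=f"d{k}s{i}", trials_yes=y.copy(), trials_no=n.copy())
        for i, (y, n) in enumerate(zip(yes_by_session, no_by_session))
    ]) for k in range(n_days)]
    return TrialDataset(
        patient_id=patient_id,
        days=days,
        n_channels=n_channels,
        time_axis=time_axis,
        sampling_rate=sampling_rate,
    )


def random_dataset(rng, n_sessions=2, n_trials=(2, 2), n_channels=3, n_tp=4, n_days=1):
    """Random valid dataset; ``n_trials`` is (yes, no) per session."""
    days = []
    for d in range(n_days):
        sessions = []
        for s in range(n_sessions):
            sessions.append(
                SessionRecord(
                    session_id=f"s{s}",
                    trials_yes=rng.standard_normal((n_trials[0], n_channels, n_tp)),
                    trials_no=rng.standard_normal((n_trials[1], n_channels, n_tp)),
                )
            )
        days.append(DayRecord(day_id=f"d{d}", sessions=sessions))
    return TrialDataset(
        patient_id="rand",
        days=days,
        n_channels=n_channels,
        time_axis=np.arange(n_tp) / 2.0 - 1.0,
        sampling_rate=2.0,
    )


@pytest.fixture
def worked_example():
    """2 sessions x 2 trials x 2 channels x 1 timepoint yes-data with known
    collapse results: method-A replicates [4, 6], method-B replicates [3, 7]."""
    s1 = np.array([[[1.0], [3.0]], [[3.0], [5.0]]])  # trials x channels x 1
    s2 = np.array([[[5.0], [7.0]], [[7.0], [9.0]]])
    return make_dataset([s1, s2])


@pytest.fixture
def all_ones():
    shape = (3, 2, 5)
    return make_dataset(
        [np.ones(shape), np.ones(shape)],
        [np.ones(shape), np.ones(shape)],
    )
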