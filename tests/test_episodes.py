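"""Episode -> counting-process conversion, transition counting, rare-event
filtering and the six-state merge."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import worklife as wl
from worklife.episodes import (count_transitions, episodes_to_process,
                               filter_rare_transitions, merge_states,
                               observation_window, validate_episodes)
from worklife.states import FULL_STATES


def test_observation_window_arithmetic():
    entry, exit_ = observation_window(np.array([1980, 1972, 1950]))
    assert entry.tolist() == [20.0, 20.0, 42.0]
    assert exit_.tolist() == [28.0, 36.0, 58.0]


def test_single_episode_gives_two_transitions_three_intervals():
    episodes = pd.DataFrame([(0, 2, 24.0, 25.0)],
                            columns=["person_id", "state", "start_age",
                                     "end_age"])
    windows = pd.DataFrame({"person_id": [0], "entry_age": [20.0],
                            "exit_age": [30.0]})
    events, intervals = episodes_to_process(episodes, windows)
    assert [tuple(r) for r in events.itertuples(index=False)] == \
        [(0, 24.0, 1, 2), (0, 25.0, 2, 1)]
    assert [tuple(r) for r in intervals.itertuples(index=False)] == \
        [(0, 1, 20.0, 24.0, "transition"), (0, 2, 24.0, 25.0, "transition"),
         (0, 1, 25.0, 30.0, "censored")]


def test_toy_cohort_hand_enumeration(toy_processed):
    events, intervals = toy_processed
    got = sorted(map(tuple, events.itertuples(index=False)))
    assert got == [
        (0, 24.0, 1, 2), (0, 25.0, 2, 1),
        (1, 22.0, 1, 2), (1, 23.0, 2, 1), (1, 26.0, 1, 3),
        (1, 27.5, 3, 1), (1, 29.0, 1, 8),
    ]
    # death terminates observation: last interval of p1 ends at 29
    p1 = intervals[intervals["person_id"] == 1]
    assert p1["exit_age"].max() == 29.0
    assert (p1["exit_reason"] == "transition").all()
    # the unregistered person is employed (and censored) throughout
    p2 = intervals[intervals["person_id"] == 2]
    assert [tuple(r) for r in p2.itertuples(index=False)] == \
        [(2, 1, 20.0, 30.0, "censored")]


def test_same_state_reepisode_counted_but_interval_unbroken():
    episodes = pd.DataFrame([(0, 2, 22.0, 23.0), (0, 2, 23.0, 24.5)],
                            columns=["person_id", "state", "start_age",
                                     "end_age"])
    windows = pd.DataFrame({"person_id": [0], "entry_age": [20.0],
                            "exit_age": [30.0]})
    events, intervals = episodes_to_process(episodes, windows)
    assert (0, 23.0, 2, 2) in set(map(tuple, events.itertuples(index=False)))
    sick = intervals[intervals["state"] == 2]
    assert len(sick) == 1
    assert (sick["entry_age"].iloc[0], sick["exit_age"].iloc[0]) == (22.0, 24.5)
    counts = count_transitions(events, intervals)
    assert counts.counts.loc[2, 2] == 1


def test_overlapping_episodes_rejected():
    episodes = pd.DataFrame([(0, 2, 22.0, 25.0), (0, 3, 24.0, 26.0)],
                            columns=["person_id", "state", "start_age",
                                     "end_age"])
    with pytest.raises(ValueError, match="overlap"):
        validate_episodes(episodes)


def test_episode_outside_window_rejected():
    episodes = pd.DataFrame([(0, 2, 18.0, 21.0)],
                            columns=["person_id", "state", "start_age",
                                     "end_age"])
    windows = pd.DataFrame({"person_id": [0], "entry_age": [20.0],
                            "exit_age": [30.0]})
    with pytest.raises(ValueError, match="window"):
        episodes_to_process(episodes, windows)


def test_count_transitions_toy(toy_processed):
    events, intervals = toy_processed
    cm = count_transitions(events, intervals)
    assert cm.counts.loc[1, 2] == 2 and cm.counts.loc[2, 1] == 2
    assert cm.counts.loc[1, 3] == 1 and cm.counts.loc[3, 1] == 1
    assert cm.counts.loc[1, 8] == 1
    assert cm.counts.loc[1, "censored"] == 2
    assert cm.total_transitions == 7 and cm.total_censored == 2
    # row-sum identity: matrix total = events + censored spells
    assert cm.counts.to_numpy().sum() == len(events) + 2
    assert cm.n_persons == 3


def test_empty_event_list_gives_zero_matrix():
    events = pd.DataFrame(columns=["person_id", "time", "from_state",
                                   "to_state"])
    intervals = pd.DataFrame([(0, 1, 20.0, 30.0, "censored")],
                             columns=["person_id", "state", "entry_age",
                                      "exit_age", "exit_reason"])
    cm = count_transitions(events, intervals)
    assert cm.total_transitions == 0
    assert cm.counts.loc[1, "censored"] == 1


@pytest.mark.parametrize("n_events, removed", [(9, True), (10, False)])
def test_rare_transition_threshold_boundary(n_events, removed):
    rows, wins = [], []
    for pid in range(n_events):
        rows.append((pid, 3, 22.0, 23.0))
        wins.append((pid, 20.0, 30.0))
    episodes = pd.DataFrame(rows, columns=["person_id", "state", "start_age",
                                           "end_age"])
    windows = pd.DataFrame(wins, columns=["person_id", "entry_age",
                                          "exit_age"])
    events, intervals = episodes_to_process(episodes, windows)
    res = filter_rare_transitions(events, intervals, min_count=10)
    if removed:
        assert (1, 3) in res.removed and (3, 1) in res.removed
        assert res.events.empty
        # spells continue unbroken: one employed-censored spell per person
        assert len(res.intervals) == n_events
        assert (res.intervals["state"] == 1).all()
        assert (res.intervals["exit_age"] == 30.0).all()
    else:
        assert res.removed == []
        pd.testing.assert_frame_equal(
            res.events.reset_index(drop=True),
            events.sort_values(["person_id", "time"]).reset_index(drop=True))


def test_filter_respects_min_count_validation(toy_processed):
    events, intervals = toy_processed
    with pytest.raises(ValueError):
        filter_rare_transitions(events, intervals, min_count=0)


def test_filter_removes_exact_subthreshold_pairs(small_processed):
    co, events, intervals = small_processed
    cm = count_transitions(events, intervals)
    res = filter_rare_transitions(events, intervals, cm, min_count=10)
    cnt = cm.counts.drop(columns="censored")
    expect = sorted((j, k) for j in cnt.index for k in cnt.columns
                    if 0 < cnt.loc[j, k] < 10)
    assert res.removed == expect
    surviving = set(map(tuple, res.events[["from_state",
                                           "to_state"]].to_numpy()))
    assert not (surviving & set(expect))
    # tiling is preserved after re-closing the spells
    for pid, grp in res.intervals.groupby("person_id"):
        g = grp.sort_values("entry_age")
        assert np.allclose(g["entry_age"].to_numpy()[1:],
                           g["exit_age"].to_numpy()[:-1], atol=1e-9)


def test_merge_conserves_transitions(small_processed):
    co, events, intervals = small_processed
    ev6, iv6, merged = merge_states(events, intervals)
    mm = FULL_STATES.merge_map
    becomes_same = sum(mm[j] == mm[k] for j, k in
                       events[["from_state", "to_state"]].to_numpy())
    assert len(ev6) == len(events) - becomes_same
    # person-years conserved under the merge
    py_full = (intervals["exit_age"] - intervals["entry_age"]).sum()
    py_merged = (iv6["exit_age"] - iv6["entry_age"]).sum()
    assert py_full == pytest.approx(py_merged, abs=1e-9)


@st.composite
def cohort_episodes(draw):
    persons = []
    for pid in range(draw(st.integers(1, 4))):
        cuts = draw(st.lists(st.integers(1, 63), unique=True, max_size=8))
        cuts = sorted(20.0 + c * 0.25 for c in cuts)
        eps = [(pid, draw(st.sampled_from([2, 3, 4, 5, 6, 7])), a, b)
               for a, b in zip(cuts[::2], cuts[1::2])]
        if draw(st.booleans()):
            last_end = eps[-1][3] if eps else 20.0
            d = draw(st.integers(1, 60)) * 0.25 + last_end
            if d < 36.0:
                eps.append((pid, 8, d, 36.0))
        persons.extend(eps)
    return pd.DataFrame(persons, columns=["person_id", "state", "start_age",
                                          "end_age"])


@settings(max_examples=60, deadline=None, derandomize=True)
@given(cohort_episodes())
def test_intervals_tile_observation_window(episodes):
    """Union of at-risk intervals equals the window (up to death) exactly."""
    pids = sorted(set(episodes["person_id"])) or [0]
    windows = pd.DataFrame({"person_id": pids,
                            "entry_age": [20.0] * len(pids),
                            "exit_age": [36.0] * len(pids)})
    events, intervals = episodes_to_process(episodes, windows)
    for pid in pids:
        grp = intervals[intervals["person_id"] == pid].sort_values(
            "entry_age")
        assert grp["entry_age"].iloc[0] == 20.0
        assert (grp["entry_age"].to_numpy()[1:]
                == grp["exit_age"].to_numpy()[:-1]).all()
        deaths = episodes[(episodes["person_id"] == pid)
                          & (episodes["state"] == 8)]
        expected_end = float(deaths["start_age"].iloc[0]) if len(deaths) \
            else 36.0
        assert abs(grp["exit_age"].iloc[-1] - expected_end) < 1e-9
    cm = count_transitions(events, intervals)
    assert cm.counts.to_numpy().sum() == len(events) + cm.total_censored
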