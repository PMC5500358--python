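"""Nelson-Aalen / Aalen-Johansen estimators, occupation curves and
restricted means, checked against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy.linalg import expm

import worklife as wl
from worklife.estimators import (aalen_johansen, integrate_step_curve,
                                 nelson_aalen, occupation_probabilities,
                                 restricted_mean_times)
from worklife.states import FULL_STATES

from conftest import two_state_config


def _frames(events, intervals):
    return events, intervals


def brute_force_nelson_aalen(events, intervals, j, k):
    """Independent O(n^2) loop over sorted event times for one pair."""
    ev = events[(events["from_state"] == j) & (events["to_state"] == k)]
    times = np.sort(ev["time"].unique())
    H, V = [], []
    h = v = 0.0
    ivs = intervals[intervals["state"] == j]
    for t in times:
        n = int((ev["time"] == t).sum())
        y = int(((ivs["entry_age"] < t) & (ivs["exit_age"] >= t)).sum())
        h += n / y
        v += n / y ** 2
        H.append(h)
        V.append(v)
    return times, np.array(H), np.array(V)


def test_single_event_increment_and_variance():
    # two at risk, one transition: dH = 1/2, dVar = 1/4
    events = pd.DataFrame([(0, 25.0, 1, 2)],
                          columns=["person_id", "time", "from_state",
                                   "to_state"])
    intervals = pd.DataFrame(
        [(0, 1, 20.0, 25.0, "transition"), (0, 2, 25.0, 30.0, "censored"),
         (1, 1, 20.0, 30.0, "censored")],
        columns=["person_id", "state", "entry_age", "exit_age",
                 "exit_reason"])
    H = nelson_aalen(events, intervals)
    idx, dh, dvar = H.increments[(1, 2)]
    assert dh.tolist() == [0.5] and dvar.tolist() == [0.25]


def test_no_events_gives_zero_step_functions():
    events = pd.DataFrame(columns=["person_id", "time", "from_state",
                                   "to_state"])
    intervals = pd.DataFrame([(0, 1, 20.0, 30.0, "censored")],
                             columns=["person_id", "state", "entry_age",
                                      "exit_age", "exit_reason"])
    H = nelson_aalen(events, intervals)
    assert len(H.times) == 0 and H.increments == {}


def test_nelson_aalen_matches_brute_force(small_processed):
    co, events, intervals = small_processed
    H = nelson_aalen(events, intervals)
    for (j, k) in H.pairs():
        t_o, H_o, V_o = brute_force_nelson_aalen(events, intervals, j, k)
        t_e, H_e = H.cumulative(j, k)
        _, V_e = H.cumulative_variance(j, k)
        np.testing.assert_allclose(t_e, t_o)
        np.testing.assert_allclose(H_e, H_o, rtol=1e-12)
        np.testing.assert_allclose(V_e, V_o, rtol=1e-12)


def test_increment_invariants(small_processed):
    co, events, intervals = small_processed
    H = nelson_aalen(events, intervals)
    for (j, k), (idx, dh, dvar) in H.increments.items():
        assert j != 8  # nothing leaves the absorbing state
        assert ((dh > 0) & (dh <= 1)).all()
        assert (dvar >= 0).all()


def test_event_with_empty_risk_set_rejected():
    events = pd.DataFrame([(0, 25.0, 3, 1)],
                          columns=["person_id", "time", "from_state",
                                   "to_state"])
    intervals = pd.DataFrame([(0, 1, 20.0, 30.0, "censored")],
                             columns=["person_id", "state", "entry_age",
                                      "exit_age", "exit_reason"])
    with pytest.raises(ValueError):
        nelson_aalen(events, intervals)


def test_aalen_johansen_empty_product_is_identity(small_processed):
    co, events, intervals = small_processed
    H = nelson_aalen(events, intervals)
    P = aalen_johansen(H, 25.0, 25.0)
    np.testing.assert_array_equal(P.P, np.eye(8))


def test_two_state_reduction_equals_one_minus_kaplan_meier():
    """Alive->dead reduction: P_12(20, t) = 1 - KM survival, machine
    precision, on 500 simulated subjects (lifelines oracle)."""
    from lifelines import KaplanMeierFitter

    co = wl.generate_cohort(two_state_config(n=500, lam=0.09, seed=11))
    events, intervals = wl.episodes_to_process(co.episodes, co.windows)
    H = nelson_aalen(events, intervals)

    durations = intervals["exit_age"] - 20.0
    observed = (intervals["exit_reason"] == "transition").astype(int)
    km = KaplanMeierFitter().fit(durations, observed)

    dead_idx = FULL_STATES.index(8)
    for t in [22.0, 25.0, 28.0, 31.9]:
        P = aalen_johansen(H, 20.0, t)
        surv = float(km.predict(t - 20.0))
        assert P.P[0, dead_idx] == pytest.approx(1.0 - surv, abs=1e-12)
        assert P.row_sums() == pytest.approx(np.ones(8), abs=1e-12)


def test_illness_death_matches_forward_recursion():
    """Three-state illness-death cohort: the product limit agrees with an
    explicit step-by-step matrix recursion built directly from raw counts."""
    cfg = wl.SimulationConfig(
        n_persons=300,
        baseline_intensities={(1, 2): 0.4, (2, 1): 0.7, (1, 8): 0.03,
                              (2, 8): 0.10},
        calendar_window=None, fixed_window=(20.0, 30.0),
        age_band_breaks=(), reepisode_prob=0.0, seed=5)
    co = wl.generate_cohort(cfg)
    events, intervals = wl.episodes_to_process(co.episodes, co.windows)
    H = nelson_aalen(events, intervals)
    t2 = 29.0

    # oracle: walk raw event times, building one factor per time from
    # scratch (counts and risk sets recomputed with pandas masks)
    ev = events[events["from_state"] != events["to_state"]]
    times = np.sort(ev[ev["time"] <= t2]["time"].unique())
    codes = FULL_STATES.codes
    P = np.eye(8)
    for t in times:
        dH = np.zeros((8, 8))
        at_t = ev[ev["time"] == t]
        for (j, k), grp in at_t.groupby(["from_state", "to_state"]):
            ivs = intervals[intervals["state"] == j]
            y = int(((ivs["entry_age"] < t) & (ivs["exit_age"] >= t)).sum())
            a, b = codes.index(j), codes.index(k)
            dH[a, b] = len(grp) / y
            dH[a, a] -= len(grp) / y
        P = P @ (np.eye(8) + dH)
    got = aalen_johansen(H, 20.0, t2)
    np.testing.assert_allclose(got.P, P, atol=1e-12)


def test_occupation_at_origin_equals_weights(small_processed):
    co, events, intervals = small_processed
    H = nelson_aalen(events, intervals)
    W = np.zeros(8)
    W[0] = 0.7
    W[1] = 0.3
    curve = occupation_probabilities(H, 20.0, weights=W)
    np.testing.assert_array_equal(curve.at(20.0)[0], W)


def test_occupation_with_no_events_is_constant():
    events = pd.DataFrame(columns=["person_id", "time", "from_state",
                                   "to_state"])
    intervals = pd.DataFrame([(0, 1, 20.0, 30.0, "censored")],
                             columns=["person_id", "state", "entry_age",
                                      "exit_age", "exit_reason"])
    H = nelson_aalen(events, intervals)
    curve = occupation_probabilities(H, 20.0)
    np.testing.assert_array_equal(curve.at([20.0, 27.0, 99.0]),
                                  np.tile(curve.weights, (3, 1)))


def test_occupation_rejects_bad_weights(small_processed):
    co, events, intervals = small_processed
    H = nelson_aalen(events, intervals)
    with pytest.raises(ValueError):
        occupation_probabilities(H, 20.0, weights=np.full(8, 0.5))


def test_restricted_mean_rectangles():
    # constant occupancy integrates to the window span; a single 0 -> 1
    # step at age 30 integrates to the remaining 15 years
    times = np.array([20.0, 30.0])
    vals = np.array([[1.0, 0.0], [0.0, 1.0]])
    areas = integrate_step_curve(times, vals, 20.0, 45.0)
    assert areas.tolist() == [10.0, 15.0]
    assert integrate_step_curve(np.array([20.0]), np.array([[1.0]]),
                                20.0, 45.0).tolist() == [25.0]


def test_restricted_mean_rejects_inverted_window(small_processed):
    co, events, intervals = small_processed
    H = nelson_aalen(events, intervals)
    curve = occupation_probabilities(H, 20.0)
    with pytest.raises(ValueError):
        restricted_mean_times(curve, 30.0, 30.0)


def test_restricted_means_equal_person_year_tally_without_censoring():
    """In a censoring-free cohort (everyone followed over the full window)
    the occupation integral must reproduce the mean observed person-years
    per state."""
    cfg = wl.SimulationConfig(
        n_persons=400,
        baseline_intensities={(1, 2): 0.5, (2, 1): 1.2},
        calendar_window=None, fixed_window=(20.0, 30.0),
        age_band_breaks=(), reepisode_prob=0.0, seed=9)
    co = wl.generate_cohort(cfg)
    events, intervals = wl.episodes_to_process(co.episodes, co.windows)
    H = nelson_aalen(events, intervals)
    curve = occupation_probabilities(H, 20.0)
    rm = restricted_mean_times(curve, 20.0, 30.0)
    tally = intervals.assign(py=intervals["exit_age"]
                             - intervals["entry_age"]) \
        .groupby("state")["py"].sum() / co.n_persons
    for code in (1, 2):
        assert rm.E[FULL_STATES.index(code)] == pytest.approx(
            tally[code], abs=1e-9)
    assert rm.E.sum() == pytest.approx(10.0, abs=1e-8)


def test_occupation_conservation_and_monotone_absorbing(small_processed):
    co, events, intervals = small_processed
    H = nelson_aalen(events, intervals)
    curve = occupation_probabilities(H, 20.0)
    np.testing.assert_allclose(curve.Q.sum(axis=1), 1.0, atol=1e-10)
    dead = curve.Q[:, FULL_STATES.index(8)]
    assert (np.diff(dead) >= -1e-12).all()
    for (j, k) in H.pairs():
        _, Hjk = H.cumulative(j, k)
        assert (np.diff(Hjk) >= 0).all()


def test_occupation_matches_matrix_exponential_solution():
    """Constant-intensity chain: the estimated occupation probabilities lie
    within Monte-Carlo error of the forward-equation solution exp(At)."""
    lam = {(1, 2): 0.45, (2, 1): 0.9, (1, 8): 0.02, (2, 8): 0.06}
    cfg = wl.SimulationConfig(
        n_persons=2000, baseline_intensities=lam, calendar_window=None,
        fixed_window=(20.0, 30.0), age_band_breaks=(), reepisode_prob=0.0,
        seed=17)
    co = wl.generate_cohort(cfg)
    events, intervals = wl.episodes_to_process(co.episodes, co.windows)
    H = nelson_aalen(events, intervals)
    curve = occupation_probabilities(H, 20.0)

    A = np.zeros((8, 8))
    codes = FULL_STATES.codes
    for (j, k), rate in lam.items():
        a, b = codes.index(j), codes.index(k)
        A[a, b] = rate
        A[a, a] -= rate
    for t in [24.0, 29.5]:
        truth = expm(A * (t - 20.0))[0]
        got = curve.at(t)[0]
        # binomial MC error on each occupation probability
        se = np.sqrt(truth * (1 - truth) / co.n_persons)
        assert (np.abs(got - truth) <= 3.5 * se + 1e-12).all()
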