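"""Conversion of registry benefit episodes into a counting process.

A person's raw record is a set of non-overlapping benefit/emigration/death
episodes on an age axis, observed only inside a calendar window (benefits
registered 1992-2008, so each birth cohort contributes a different age
span, at most 16 years).  Employment is defined by absence: every gap
between recorded episodes, and the time before the first / after the last
episode inside the window, is an employment spell.

The conversion yields two tables:

* ``events`` — one row per observed transition (person, age, from, to).
  Consecutive episodes of the same state that abut exactly are kept as
  *same-state* events: they are part of the registry bookkeeping (a new
  benefit spell was granted) but carry no information about transition
  intensities.
* ``intervals`` — at-risk intervals, half-open [entry, exit): the spells a
  person spends in each state, with same-state re-episodes merged into one
  unbroken spell.  Each interval ends either in a transition or by
  right-censoring at the end of the person's observation window.  For every
  person the intervals tile the observation window exactly (up to death).

All ages are fractional years.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .states import FULL_STATES, StateSpace, EMPLOYMENT

EVENT_COLUMNS = ["person_id", "time", "from_state", "to_state"]
INTERVAL_COLUMNS = ["person_id", "state", "entry_age", "exit_age", "exit_reason"]

OBS_CALENDAR_START = 1992
OBS_CALENDAR_END = 2008
BASELINE_AGE = 20.0

_TOL = 1e-9


def observation_window(birth_year: int | np.ndarray,
                       baseline_age: float = BASELINE_AGE
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Age window in which a birth cohort is observable.

    Registry coverage runs over calendar years [1992, 2008]; follow-up starts
    no earlier than the baseline age (20).  Returns (entry_age, exit_age);
    a window with entry >= exit means the person is never observed.
    """
    by = np.asarray(birth_year, dtype=float)
    entry = np.maximum(baseline_age, OBS_CALENDAR_START - by)
    exit_ = OBS_CALENDAR_END - by
    return entry, exit_


@dataclass
class TransitionCountMatrix:
    """Counts of observed transitions: transient from-states x (to-states +
    a right-censored column), as in the published registry tabulation."""

    counts: pd.DataFrame  # index: from codes, columns: to codes + "censored"
    n_persons: int

    @property
    def total_transitions(self) -> int:
        return int(self.counts.drop(columns="censored").to_numpy().sum())

    @property
    def total_censored(self) -> int:
        return int(self.counts["censored"].sum())


def validate_episodes(episodes: pd.DataFrame, space: StateSpace = FULL_STATES
                      ) -> None:
    """Raise on malformed episode tables (bad codes, inverted or overlapping
    spells, activity after absorption)."""
    if not set(episodes["state"]).issubset(set(space.codes)):
        bad = set(episodes["state"]) - set(space.codes)
        raise ValueError(f"unknown state codes: {sorted(bad)}")
    if (episodes["start_age"] >= episodes["end_age"] - _TOL).any():
        raise ValueError("episode with start_age >= end_age")
    absorbing = space.absorbing_code
    for pid, grp in episodes.groupby("person_id", sort=False):
        g = grp.sort_values("start_age")
        starts = g["start_age"].to_numpy()
        ends = g["end_age"].to_numpy()
        if (starts[1:] < ends[:-1] - _TOL).any():
            raise ValueError(f"overlapping episodes for person {pid}")
        states = g["state"].to_numpy()
        if (states[:-1] == absorbing).any():
            raise ValueError(f"episode after absorbing state for person {pid}")


def episodes_to_process(episodes: pd.DataFrame, windows: pd.DataFrame,
                        space: StateSpace = FULL_STATES,
                        validate: bool = True
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fill employment gaps and emit (events, at-risk intervals).

    Parameters
    ----------
    episodes
        Columns person_id, state, start_age, end_age.  May omit employment
        spells entirely (they are reconstructed from gaps) and may omit
        persons with no registered benefit (they are employed throughout).
    windows
        Columns person_id, entry_age, exit_age — the observable age span per
        person.  Persons with entry >= exit are dropped.
    """
    if validate:
        validate_episodes(episodes, space)
    absorbing = space.absorbing_code

    win = windows.set_index("person_id")
    ev_rows: list[tuple] = []
    iv_rows: list[tuple] = []

    grouped = {pid: grp for pid, grp in episodes.groupby("person_id", sort=False)}
    for pid in win.index:
        entry = float(win.at[pid, "entry_age"])
        exit_ = float(win.at[pid, "exit_age"])
        if entry >= exit_ - _TOL:
            continue
        grp = grouped.get(pid)
        spells: list[tuple[int, float, float]] = []  # (state, start, end)
        death_age: float | None = None
        if grp is not None:
            g = grp.sort_values("start_age")
            if (g["start_age"].to_numpy() < entry - _TOL).any() or \
               (g["end_age"].to_numpy() > exit_ + _TOL).any():
                raise ValueError(f"episode outside observation window "
                                 f"for person {pid}")
            cursor = entry
            for state, start, end in zip(g["state"], g["start_age"],
                                         g["end_age"]):
                if start > cursor + _TOL:
                    spells.append((EMPLOYMENT, cursor, float(start)))
                if state == absorbing:
                    death_age = float(start)
                    break
                spells.append((int(state), float(start), float(end)))
                cursor = float(end)
            else:
                if cursor < exit_ - _TOL:
                    spells.append((EMPLOYMENT, cursor, exit_))
        else:
            spells.append((EMPLOYMENT, entry, exit_))

        if not spells:
            # death exactly at window entry: never at risk
            continue

        # events at spell junctions (same-state junctions included)
        for (s0, a0, b0), (s1, a1, b1) in zip(spells, spells[1:]):
            ev_rows.append((pid, b0, s0, s1))
        # merged at-risk intervals: same-state adjacency is one spell
        cur_state, cur_start, cur_end = spells[0]
        for s1, a1, b1 in spells[1:]:
            if s1 == cur_state:
                cur_end = b1
            else:
                iv_rows.append((pid, cur_state, cur_start, cur_end,
                                "transition"))
                cur_state, cur_start, cur_end = s1, a1, b1
        if death_age is not None:
            ev_rows.append((pid, death_age, cur_state, absorbing))
            iv_rows.append((pid, cur_state, cur_start, death_age,
                            "transition"))
        else:
            iv_rows.append((pid, cur_state, cur_start, exit_, "censored"))

    events = pd.DataFrame(ev_rows, columns=EVENT_COLUMNS)
    intervals = pd.DataFrame(iv_rows, columns=INTERVAL_COLUMNS)
    if not events.empty:
        events = events.astype({"time": float, "from_state": int,
                                "to_state": int})
    return events, intervals


def count_transitions(events: pd.DataFrame, intervals: pd.DataFrame,
                      space: StateSpace = FULL_STATES) -> TransitionCountMatrix:
    """Tabulate observed transitions per (from, to) pair plus a censored
    column (persons alive and under observation at window end)."""
    from_codes = space.transient_codes
    to_codes = space.codes
    counts = pd.DataFrame(0, index=pd.Index(from_codes, name="from"),
                          columns=pd.Index(list(to_codes) + ["censored"],
                                           name="to"), dtype=np.int64)
    if not events.empty:
        tab = events.groupby(["from_state", "to_state"]).size()
        for (j, k), n in tab.items():
            counts.loc[j, k] = n
    cens = intervals[intervals["exit_reason"] == "censored"]
    if not cens.empty:
        for j, n in cens.groupby("state").size().items():
            counts.loc[j, "censored"] = n
    n_persons = int(intervals["person_id"].nunique())
    return TransitionCountMatrix(counts=counts, n_persons=n_persons)


@dataclass
class FilterResult:
    events: pd.DataFrame
    intervals: pd.DataFrame
    removed: list[tuple[int, int]]


def filter_rare_transitions(events: pd.DataFrame, intervals: pd.DataFrame,
                            matrix: TransitionCountMatrix | None = None,
                            min_count: int = 10,
                            space: StateSpace = FULL_STATES) -> FilterResult:
    """Drop transition types observed fewer than ``min_count`` times.

    Events whose (from, to) pair falls below the threshold are deleted from
    the event stream; the at-risk spell is treated as unbroken, i.e. the
    origin-state interval continues through the destination spell as if the
    removed transition had not occurred (follow-on events are re-attributed
    to the continuing state; re-attributed events that become same-state
    merge their spells, and ones whose re-attributed pair is itself below
    the threshold are suppressed as well, so no surviving event carries a
    sub-threshold transition type).
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    if matrix is None:
        matrix = count_transitions(events, intervals, space)
    cnt = matrix.counts.drop(columns="censored")
    removed = sorted((int(j), int(k))
                     for j in cnt.index for k in cnt.columns
                     if 0 < cnt.loc[j, k] < min_count)
    if not removed:
        return FilterResult(events.copy(), intervals.copy(), [])
    removed_set = set(removed)

    ev_rows: list[tuple] = []
    iv_rows: list[tuple] = []
    ev_by_person = {pid: g for pid, g in events.groupby("person_id",
                                                        sort=False)}
    for pid, ivs in intervals.groupby("person_id", sort=False):
        ivs = ivs.sort_values("entry_age")
        evs = ev_by_person.get(pid)
        evs = evs.sort_values("time") if evs is not None else None
        boundary: dict[float, tuple[int, int]] = {}
        if evs is not None:
            for t, j, k in zip(evs["time"], evs["from_state"],
                               evs["to_state"]):
                if j != k:
                    boundary[float(t)] = (int(j), int(k))
                elif (int(j), int(k)) not in removed_set:
                    ev_rows.append((pid, float(t), int(j), int(k)))

        rows = list(ivs.itertuples(index=False))
        eff_state = int(rows[0].state)
        cur_start = float(rows[0].entry_age)
        for prev, nxt in zip(rows, rows[1:]):
            t = float(prev.exit_age)
            raw_pair = boundary.get(t, (int(prev.state), int(nxt.state)))
            if raw_pair in removed_set or int(nxt.state) == eff_state or \
                    (eff_state, int(nxt.state)) in removed_set:
                continue  # spell continues unbroken
            ev_rows.append((pid, t, eff_state, int(nxt.state)))
            iv_rows.append((pid, eff_state, cur_start, t, "transition"))
            eff_state = int(nxt.state)
            cur_start = float(nxt.entry_age)
        last = rows[-1]
        reason = str(last.exit_reason)
        t_end = float(last.exit_age)
        if reason == "transition":
            # terminal transition (into the absorbing state)
            raw_pair = boundary.get(t_end)
            if raw_pair is not None and (
                    raw_pair in removed_set
                    or (eff_state, raw_pair[1]) in removed_set):
                reason = "censored"
            else:
                if raw_pair is not None:
                    ev_rows.append((pid, t_end, eff_state, raw_pair[1]))
                iv_rows.append((pid, eff_state, cur_start, t_end,
                                "transition"))
        if reason == "censored":
            iv_rows.append((pid, eff_state, cur_start, t_end, "censored"))

    out_events = pd.DataFrame(ev_rows, columns=EVENT_COLUMNS)
    out_events = out_events.sort_values(["person_id", "time"],
                                        kind="stable").reset_index(drop=True)
    out_intervals = pd.DataFrame(iv_rows, columns=INTERVAL_COLUMNS)
    return FilterResult(out_events, out_intervals, removed)


def merge_states(events: pd.DataFrame, intervals: pd.DataFrame,
                 space: StateSpace = FULL_STATES
                 ) -> tuple[pd.DataFrame, pd.DataFrame, StateSpace]:
    """Project events and intervals onto the merged (six-state) space.

    Events whose endpoints coincide under the merge map become same-state
    and are dropped; the corresponding at-risk spells are joined.
    """
    mm = space.merge_map
    merged = space.merged_space()
    ev = events.copy()
    ev["from_state"] = ev["from_state"].map(mm)
    ev["to_state"] = ev["to_state"].map(mm)
    ev = ev[ev["from_state"] != ev["to_state"]].reset_index(drop=True)

    iv_rows: list[tuple] = []
    for pid, grp in intervals.groupby("person_id", sort=False):
        grp = grp.sort_values("entry_age")
        cur = None
        for row in grp.itertuples(index=False):
            state = mm[int(row.state)]
            if cur is not None and state == cur[1] and \
                    abs(float(row.entry_age) - cur[3]) < _TOL:
                cur = (cur[0], cur[1], cur[2], float(row.exit_age),
                       str(row.exit_reason))
            else:
                if cur is not None:
                    iv_rows.append(cur)
                cur = (pid, state, float(row.entry_age), float(row.exit_age),
                       str(row.exit_reason))
        if cur is not None:
            iv_rows.append(cur)
    iv = pd.DataFrame(iv_rows, columns=INTERVAL_COLUMNS)
    return ev, iv, merged
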