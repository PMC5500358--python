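"""Non-parametric multi-state estimation.

Given the counting process (events and at-risk intervals) of a cohort
moving among states, the cumulative transition intensities H_jk(t) are
estimated with the Nelson-Aalen estimator

    H_jk(t) = sum_{T_s <= t} n_jk(T_s) / Y_j(T_s),

where n_jk(T_s) is the number of j->k transitions at event time T_s and
Y_j(T_s) the number of persons at risk in j just before T_s (left-limit
convention: a person leaving j at T_s still counts).  Its variance is
estimated by sum n_jk / Y_j^2.  Transition probabilities over (t1, t2]
follow by the Aalen-Johansen product-limit estimator

    P(t1, t2) = prod_{s in (t1, t2]} (I + dH(s)),

one matrix factor per distinct event time, with the diagonal of dH(s) set
to minus the row sums.  State-occupation probabilities are the initial
distribution propagated through P, and restricted mean times in state are
exact integrals of the resulting piecewise-constant occupation curves.

Both estimators accommodate delayed entry (left truncation) and right
censoring through the risk sets; the product-limit step assumes the
process is Markov.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .states import FULL_STATES, StateSpace


@dataclass
class CumulativeIntensitySet:
    """Nelson-Aalen increments on the pooled grid of distinct event times.

    ``increments`` maps each ordered pair (j, k), j != k, to
    (time_index, dH, dVar): positions into ``times`` where j->k events
    occur, the intensity increments n/Y and their variance increments
    n/Y^2.
    """

    times: np.ndarray
    space: StateSpace
    increments: dict[tuple[int, int], tuple[np.ndarray, np.ndarray, np.ndarray]]
    _dense: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_states(self) -> int:
        return len(self.space.states)

    def pairs(self) -> list[tuple[int, int]]:
        return sorted(self.increments)

    def cumulative(self, j: int, k: int) -> tuple[np.ndarray, np.ndarray]:
        """Step function of H_jk: (event times of the pair, cumulative H)."""
        idx, dh, _ = self.increments[(j, k)]
        return self.times[idx], np.cumsum(dh)

    def cumulative_variance(self, j: int, k: int
                            ) -> tuple[np.ndarray, np.ndarray]:
        idx, _, dvar = self.increments[(j, k)]
        return self.times[idx], np.cumsum(dvar)

    def increment_matrices(self) -> np.ndarray:
        """Dense (n_times, J, J) array of dH(s) with diagonal -row-sum."""
        if self._dense is None:
            J = self.n_states
            pos = {c: i for i, c in enumerate(self.space.codes)}
            A = np.zeros((len(self.times), J, J))
            for (j, k), (idx, dh, _) in self.increments.items():
                np.add.at(A, (idx, pos[j], pos[k]), dh)
            d = A.sum(axis=2)
            A[:, np.arange(J), np.arange(J)] -= d
            self._dense = A
        return self._dense

    def with_increments(self, new: dict[tuple[int, int],
                                        tuple[np.ndarray, np.ndarray,
                                              np.ndarray]]
                        ) -> "CumulativeIntensitySet":
        return CumulativeIntensitySet(times=self.times, space=self.space,
                                      increments=new)


def nelson_aalen(events: pd.DataFrame, intervals: pd.DataFrame,
                 space: StateSpace = FULL_STATES) -> CumulativeIntensitySet:
    """Nelson-Aalen cumulative transition intensities with variances.

    Same-state events (from == to) carry no intensity and are ignored.
    Ties at one time are aggregated: n_jk(T_s) counts all j->k events at
    exactly T_s.  Raises if an event occurs while the risk set of its
    origin state is empty (inconsistent input).
    """
    ev = events[events["from_state"] != events["to_state"]]
    absorbing = space.absorbing_code
    if (ev["from_state"] == absorbing).any():
        raise ValueError("transition out of the absorbing state")

    times = np.unique(ev["time"].to_numpy()) if len(ev) else np.empty(0)

    # risk-set lookup per origin state: Y_j(t) = #{entry < t} - #{exit < t}
    entries: dict[int, np.ndarray] = {}
    exits: dict[int, np.ndarray] = {}
    for j, grp in intervals.groupby("state"):
        entries[int(j)] = np.sort(grp["entry_age"].to_numpy())
        exits[int(j)] = np.sort(grp["exit_age"].to_numpy())

    increments: dict[tuple[int, int],
                     tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for (j, k), grp in ev.groupby(["from_state", "to_state"]):
        j, k = int(j), int(k)
        t_pair, n_pair = np.unique(grp["time"].to_numpy(), return_counts=True)
        if j not in entries:
            raise ValueError(f"events from state {j} but no at-risk "
                             f"intervals in that state")
        y = (np.searchsorted(entries[j], t_pair, side="left")
             - np.searchsorted(exits[j], t_pair, side="left"))
        if (y < n_pair).any():
            bad = t_pair[y < n_pair][0]
            raise ValueError(f"risk set of state {j} smaller than event "
                             f"count at t={bad}")
        dh = n_pair / y
        dvar = n_pair / y ** 2
        idx = np.searchsorted(times, t_pair)
        increments[(j, k)] = (idx, dh, dvar)
    return CumulativeIntensitySet(times=times, space=space,
                                  increments=increments)


@dataclass
class TransitionProbabilityMatrix:
    t1: float
    t2: float
    P: np.ndarray
    space: StateSpace

    def to_frame(self) -> pd.DataFrame:
        codes = self.space.codes
        return pd.DataFrame(self.P, index=pd.Index(codes, name="from"),
                            columns=pd.Index(codes, name="to"))

    def row_sums(self) -> np.ndarray:
        return self.P.sum(axis=1)


def aalen_johansen(H: CumulativeIntensitySet, t1: float, t2: float
                   ) -> TransitionProbabilityMatrix:
    """Product-limit transition probability matrix P(t1, t2).

    The product runs over distinct event times in (t1, t2], one factor
    (I + dH(s)) per time; an empty product gives the identity.  A negative
    diagonal entry of a factor (risk set smaller than the number of
    simultaneous exits) is rejected.
    """
    if t1 > t2:
        raise ValueError("t1 must be <= t2")
    J = H.n_states
    P = np.eye(J)
    A = H.increment_matrices()
    lo = np.searchsorted(H.times, t1, side="right")
    hi = np.searchsorted(H.times, t2, side="right")
    eye = np.eye(J)
    for s in range(lo, hi):
        factor = eye + A[s]
        if (np.diag(factor) < 0).any():
            raise ValueError(f"negative diagonal in product factor at "
                             f"t={H.times[s]}: simultaneous exits exceed "
                             f"the risk set")
        P = P @ factor
    return TransitionProbabilityMatrix(t1=t1, t2=t2, P=P, space=H.space)


@dataclass
class OccupationCurve:
    """Right-continuous piecewise-constant state-occupation probabilities.

    ``Q[i]`` is the occupation distribution on [times[i], times[i+1]);
    times[0] is the origin age and Q[0] the initial weights.
    """

    times: np.ndarray
    Q: np.ndarray  # (n_breaks, J)
    space: StateSpace
    weights: np.ndarray

    @property
    def origin(self) -> float:
        return float(self.times[0])

    def at(self, ages: float | np.ndarray) -> np.ndarray:
        """Evaluate Q at the given ages (constant beyond the last event)."""
        ages = np.atleast_1d(np.asarray(ages, dtype=float))
        if (ages < self.origin - 1e-12).any():
            raise ValueError("age before the curve origin")
        pos = np.searchsorted(self.times, ages, side="right") - 1
        return self.Q[np.clip(pos, 0, len(self.times) - 1)]

    def to_frame(self, grid: np.ndarray | None = None) -> pd.DataFrame:
        """Tidy (state, age, estimate) frame on the curve's own breakpoints
        or a supplied age grid."""
        ages = self.times if grid is None else np.asarray(grid, dtype=float)
        vals = self.at(ages)
        labels = self.space.labels
        frames = []
        for i, code in enumerate(self.space.codes):
            frames.append(pd.DataFrame({"state": labels[code], "age": ages,
                                        "estimate": vals[:, i]}))
        return pd.concat(frames, ignore_index=True)


def occupation_probabilities(H: CumulativeIntensitySet, origin_age: float,
                             weights: np.ndarray | dict[int, float]
                             | None = None,
                             grid: np.ndarray | None = None
                             ) -> OccupationCurve:
    """Occupation probabilities Q_k(t) = sum_j W_j P_jk(origin, t).

    ``weights`` is the state distribution at the origin age (default: point
    mass on the first state, employment).  The curve is computed exactly at
    every event time past the origin; ``grid`` only adds breakpoints so the
    curve can be exported on a regular grid, it does not affect the values.
    """
    J = H.n_states
    if weights is None:
        W = np.zeros(J)
        W[0] = 1.0
    elif isinstance(weights, dict):
        W = np.zeros(J)
        for code, w in weights.items():
            W[H.space.index(code)] = w
    else:
        W = np.asarray(weights, dtype=float)
    if W.shape != (J,) or (W < 0).any() or abs(W.sum() - 1.0) > 1e-8:
        raise ValueError("weights must be a probability vector over states")

    A = H.increment_matrices()
    lo = np.searchsorted(H.times, origin_age, side="right")
    ev_times = H.times[lo:]
    breaks = [origin_age]
    qs = [W.copy()]
    w = W.copy()
    for s in range(lo, len(H.times)):
        w = w + w @ A[s]
        breaks.append(H.times[s])
        qs.append(w.copy())
    times = np.asarray(breaks)
    Q = np.vstack(qs)
    if grid is not None:
        grid = np.asarray(grid, dtype=float)
        extra = np.setdiff1d(grid[grid >= origin_age], times)
        if len(extra):
            all_t = np.concatenate([times, extra])
            order = np.argsort(all_t, kind="stable")
            pos = np.searchsorted(times, all_t[order], side="right") - 1
            Q = Q[np.clip(pos, 0, len(times) - 1)]
            times = all_t[order]
    return OccupationCurve(times=times, Q=Q, space=H.space, weights=W)


@dataclass
class RestrictedMeanTimes:
    """Expected years per state over [t0, t1]; entries sum to t1 - t0."""

    t0: float
    t1: float
    E: np.ndarray
    space: StateSpace

    def to_series(self) -> pd.Series:
        labels = [self.space.labels[c] for c in self.space.codes]
        return pd.Series(self.E, index=pd.Index(labels, name="state"),
                         name="expected_years")


def integrate_step_curve(times: np.ndarray, values: np.ndarray,
                         t0: float, t1: float) -> np.ndarray:
    """Exact integral over [t0, t1] of a right-continuous step function
    given by breakpoints ``times`` and values on [times[i], times[i+1])."""
    if t0 >= t1:
        raise ValueError("t0 must be < t1")
    cuts = np.concatenate([[t0], times[(times > t0) & (times < t1)], [t1]])
    pos = np.clip(np.searchsorted(times, cuts[:-1], side="right") - 1, 0,
                  len(times) - 1)
    lengths = np.diff(cuts)
    return lengths @ values[pos]


def restricted_mean_times(curve: OccupationCurve, t0: float, t1: float
                          ) -> RestrictedMeanTimes:
    """Restricted mean years in each state: E_k = int_{t0}^{t1} Q_k(u) du,
    computed as the exact area under the piecewise-constant curve."""
    if t0 < curve.origin - 1e-12:
        raise ValueError("t0 precedes the occupation-curve origin")
    E = integrate_step_curve(curve.times, curve.Q, t0, t1)
    return RestrictedMeanTimes(t0=t0, t1=t1, E=E, space=curve.space)
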