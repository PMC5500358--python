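"""State spaces for the multi-state work-life model.

The full model has eight states on an age axis: employment (1), sick leave
(2), vocational rehabilitation (3), medical rehabilitation (4), time-limited
disability benefits (5), disability benefits (6), emigrated (7) and dead (8).
Dead is the only absorbing state.  For restricted-mean and regression
analyses the three intermediate benefit states (3, 4, 5) are merged into a
single *time limited benefits* state, giving a six-state space.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class State:
    code: int
    label: str
    absorbing: bool = False


@dataclass(frozen=True)
class StateSpace:
    """An ordered set of states plus an optional merge onto a coarser space.

    ``merge_map`` sends each code of this space onto the code of the merged
    (six-state) space; it must be total and map the absorbing state onto an
    absorbing state.
    """

    states: tuple[State, ...]
    merge_map: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        codes = [s.code for s in self.states]
        if len(set(codes)) != len(codes):
            raise ValueError("duplicate state codes")
        n_abs = sum(s.absorbing for s in self.states)
        if n_abs != 1:
            raise ValueError(f"exactly one absorbing state required, got {n_abs}")
        if self.merge_map and set(self.merge_map) != set(codes):
            raise ValueError("merge_map must be total over the state codes")

    @property
    def codes(self) -> list[int]:
        return [s.code for s in self.states]

    @property
    def labels(self) -> dict[int, str]:
        return {s.code: s.label for s in self.states}

    @property
    def absorbing_code(self) -> int:
        return next(s.code for s in self.states if s.absorbing)

    @property
    def transient_codes(self) -> list[int]:
        return [s.code for s in self.states if not s.absorbing]

    def index(self, code: int) -> int:
        return self.codes.index(code)

    def merged_space(self) -> "StateSpace":
        if not self.merge_map:
            raise ValueError("state space has no merge_map")
        return merged_state_space()


#: Full eight-state space with the 3,4,5 -> time-limited-benefits merge.
FULL_STATES = StateSpace(
    states=(
        State(1, "employment"),
        State(2, "sick leave"),
        State(3, "vocational rehabilitation"),
        State(4, "medical rehabilitation"),
        State(5, "time limited disability benefits"),
        State(6, "disability benefits"),
        State(7, "emigrated"),
        State(8, "dead", absorbing=True),
    ),
    merge_map={1: 1, 2: 2, 3: 3, 4: 3, 5: 3, 6: 4, 7: 5, 8: 6},
)


def merged_state_space() -> StateSpace:
    """Six-state space used for restricted means and regression models."""
    return StateSpace(
        states=(
            State(1, "employment"),
            State(2, "sick leave"),
            State(3, "time limited benefits"),
            State(4, "disability benefits"),
            State(5, "emigrated"),
            State(6, "dead", absorbing=True),
        ),
    )


EMPLOYMENT = 1
SICK_LEAVE = 2
VOCATIONAL_REHAB = 3
MEDICAL_REHAB = 4
TIME_LIMITED_DISABILITY = 5
DISABILITY = 6
EMIGRATED = 7
DEAD = 8
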