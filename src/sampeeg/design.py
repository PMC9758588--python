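"""Choice-problem construction for the two-option sampling task.

Each trial of the task presents two options (left/right). An option is a
two-outcome lottery over the digits 1..9: it returns ``outcome_a`` with
probability ``p_a`` and ``outcome_b`` otherwise. The design constrains every
trial so that (i) all four outcome values across the two options are pairwise
distinct and (ii) the expected values of the two options differ by exactly
0.9 points. Probabilities live on a 0.1-step grid and are stored internally
as integer tenths, so grid membership and the EV-difference constraint are
checked in exact integer arithmetic.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "OptionSpec",
    "ChoiceProblem",
    "enumerate_choice_problems",
    "build_session",
    "sample_outcome",
    "session_to_frame",
    "session_from_frame",
]

VALUE_MIN = 1
VALUE_MAX = 9
DEFAULT_PROB_GRID = tuple(t / 10 for t in range(1, 10))
DEFAULT_EV_DIFF = 0.9
EV_TOL = 1e-9


def _prob_to_tenths(p: float) -> int:
    """Convert a grid probability to integer tenths, rejecting off-grid values."""
    t = round(p * 10)
    if not (1 <= t <= 9) or abs(p * 10 - t) > 1e-6:
        raise ValueError(f"probability {p!r} is not a multiple of 0.1 in [0.1, 0.9]")
    return int(t)


@dataclass(frozen=True)
class OptionSpec:
    """A two-outcome lottery: ``outcome_a`` with probability ``pa_tenths``/10."""

    outcome_a: int
    outcome_b: int
    pa_tenths: int

    def __post_init__(self) -> None:
        for v in (self.outcome_a, self.outcome_b):
            if not (VALUE_MIN <= int(v) <= VALUE_MAX) or int(v) != v:
                raise ValueError(f"outcome {v!r} outside integer range 1..9")
        if self.outcome_a == self.outcome_b:
            raise ValueError("the two outcomes of an option must differ")
        if not (1 <= self.pa_tenths <= 9):
            raise ValueError("pa_tenths must lie in 1..9 (probability 0.1..0.9)")

    @property
    def p_a(self) -> float:
        return self.pa_tenths / 10.0

    @property
    def ev_tenths(self) -> int:
        """Expected value in exact tenths of a point."""
        return self.pa_tenths * self.outcome_a + (10 - self.pa_tenths) * self.outcome_b

    @property
    def expected_value(self) -> float:
        return self.ev_tenths / 10.0

    @property
    def outcomes(self) -> tuple[int, int]:
        return (self.outcome_a, self.outcome_b)

    def canonical(self) -> "OptionSpec":
        """Equivalent lottery with the smaller outcome listed first."""
        if self.outcome_a < self.outcome_b:
            return self
        return OptionSpec(self.outcome_b, self.outcome_a, 10 - self.pa_tenths)


@dataclass(frozen=True)
class ChoiceProblem:
    """One trial's pair of options with the design invariants enforced."""

    left: OptionSpec
    right: OptionSpec
    ev_diff: float = field(default=DEFAULT_EV_DIFF)

    def __post_init__(self) -> None:
        values = {
            self.left.outcome_a,
            self.left.outcome_b,
            self.right.outcome_a,
            self.right.outcome_b,
        }
        if len(values) != 4:
            raise ValueError("the four outcome values must be pairwise distinct")
        observed = abs(self.left.ev_tenths - self.right.ev_tenths) / 10.0
        if abs(observed - self.ev_diff) > EV_TOL:
            raise ValueError(
                f"|EV difference| is {observed}, required {self.ev_diff}"
            )

    @property
    def ev_left(self) -> float:
        return self.left.expected_value

    @property
    def ev_right(self) -> float:
        return self.right.expected_value

    @property
    def better_side(self) -> str:
        return "left" if self.ev_left > self.ev_right else "right"

    def flipped(self) -> "ChoiceProblem":
        return ChoiceProblem(self.right, self.left, self.ev_diff)


def enumerate_choice_problems(
    value_range=range(VALUE_MIN, VALUE_MAX + 1),
    prob_grid=DEFAULT_PROB_GRID,
    ev_diff: float = DEFAULT_EV_DIFF,
) -> list[ChoiceProblem]:
    """Enumerate every unordered option pair meeting the design constraints.

    Options are canonicalized (smaller outcome first) so that each lottery is
    represented once, and each unordered pair appears exactly once with the
    lexicographically smaller option on the left; left/right orientation is
    randomized later, at session-build time. The returned list is in
    deterministic lexicographic order.
    """
    values = sorted(set(int(v) for v in value_range))
    if not values or values[0] < VALUE_MIN or values[-1] > VALUE_MAX:
        raise ValueError("value_range must be a subset of 1..9")
    if ev_diff < 0:
        raise ValueError("ev_diff must be nonnegative")
    tenths = sorted({_prob_to_tenths(p) for p in prob_grid})
    target = round(ev_diff * 10)
    if abs(ev_diff * 10 - target) > 1e-6:
        raise ValueError("ev_diff must be a multiple of 0.1 for the tenths grid")

    options = [
        OptionSpec(a, b, t)
        for a, b in itertools.combinations(values, 2)
        for t in tenths
    ]
    problems: list[ChoiceProblem] = []
    for o1, o2 in itertools.combinations(options, 2):
        if {o1.outcome_a, o1.outcome_b} & {o2.outcome_a, o2.outcome_b}:
            continue
        if abs(o1.ev_tenths - o2.ev_tenths) != target:
            continue
        problems.append(ChoiceProblem(o1, o2, ev_diff))
    return problems


def sample_outcome(option: OptionSpec, rng: np.random.Generator) -> int:
    """Draw one outcome from an option's lottery."""
    return option.outcome_a if rng.random() < option.p_a else option.outcome_b


def _occurrence_weights(problem: ChoiceProblem) -> np.ndarray:
    """Expected share of each sample value 1..9 when one sample is drawn.

    Assumes the two options are sampled equally often on average.
    """
    w = np.zeros(9)
    for opt in (problem.left, problem.right):
        w[opt.outcome_a - 1] += 0.5 * opt.p_a
        w[opt.outcome_b - 1] += 0.5 * (1.0 - opt.p_a)
    return w


def build_session(
    n_trials: int = 100,
    n_blocks: int = 5,
    rng_seed: int = 0,
    n_candidates: int = 20,
    ev_diff: float = DEFAULT_EV_DIFF,
) -> list[ChoiceProblem]:
    """Draw a balanced pseudorandom session of choice problems.

    Trials are drawn greedily: for each slot several candidate problems are
    sampled from the full enumeration, and the one whose expected per-value
    occurrence counts stay closest to uniform (each value 1..9 appearing with
    share 1/9) is kept. Left/right orientation is randomized per trial. The
    session is a pure function of ``(n_trials, n_blocks, rng_seed)``.
    """
    if n_trials <= 0:
        raise ValueError("n_trials must be positive")
    if n_blocks <= 0 or n_trials % n_blocks != 0:
        raise ValueError("n_trials must be divisible by n_blocks")
    rng = np.random.default_rng(rng_seed)
    pool = enumerate_choice_problems(ev_diff=ev_diff)
    if not pool:
        raise ValueError("no feasible choice problems for the requested ev_diff")
    weights = np.stack([_occurrence_weights(p) for p in pool])

    running = np.zeros(9)
    target = np.full(9, 1.0 / 9.0)
    session: list[ChoiceProblem] = []
    for i in range(n_trials):
        cand = rng.integers(0, len(pool), size=n_candidates)
        # deviation of expected occurrence shares from uniform after adding each candidate
        tentative = (running[None, :] + weights[cand]) / (i + 1)
        dev = np.sum((tentative - target[None, :]) ** 2, axis=1)
        best = cand[int(np.argmin(dev))]
        running += weights[best]
        problem = pool[best]
        if rng.random() < 0.5:
            problem = problem.flipped()
        session.append(problem)
    return session


def expected_value_shares(session: list[ChoiceProblem]) -> np.ndarray:
    """Expected occurrence share of each value 1..9 under the generating measure."""
    w = np.sum([_occurrence_weights(p) for p in session], axis=0)
    return w / w.sum()


def session_to_frame(session: list[ChoiceProblem], n_blocks: int = 5) -> pd.DataFrame:
    """Serialize a session to the trial-design table layout."""
    block_len = len(session) // n_blocks
    rows = []
    for i, p in enumerate(session):
        rows.append(
            {
                "trial": i + 1,
                "block": i // block_len + 1,
                "left_a": p.left.outcome_a,
                "left_b": p.left.outcome_b,
                "left_pa": p.left.p_a,
                "right_a": p.right.outcome_a,
                "right_b": p.right.outcome_b,
                "right_pa": p.right.p_a,
                "ev_left": p.ev_left,
                "ev_right": p.ev_right,
            }
        )
    return pd.DataFrame(rows)


def session_from_frame(frame: pd.DataFrame) -> list[ChoiceProblem]:
    session = []
    for _, row in frame.iterrows():
        left = OptionSpec(int(row.left_a), int(row.left_b), _prob_to_tenths(row.left_pa))
        right = OptionSpec(
            int(row.right_a), int(row.right_b), _prob_to_tenths(row.right_pa)
        )
        ev_diff = abs(left.ev_tenths - right.ev_tenths) / 10.0
        session.append(ChoiceProblem(left, right, ev_diff))
    return session
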