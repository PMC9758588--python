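"""Generative sampling agents for the two-option experience task.

The study reports participants' behavior but no generative model; the agent
here is an explicit stand-in built to reproduce the qualitative signatures of
that behavior: recency (leaky accumulation), self-terminated sampling (a
threshold on the accumulated evidence, capped at 19 samples), a tendency to
stop right after large sample values (an extra stop probability above a value
cut-off), and stereotypical left/right routines (alternating or single-switch
side policies).

Evidence accumulates leakily over the signed, rescaled sample values
(1..9 -> -4..4, right positive, left negative):

    A_n = sum_i  lambda**(n - i) * s_i

and the final choice is a softmax (logistic) read-out of ``A_n / tau``.
Yoked trials replay a previously recorded sequence verbatim and only the
final choice is re-generated.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .design import ChoiceProblem, sample_outcome

__all__ = [
    "AgentParams",
    "Sample",
    "TrialRecord",
    "simulate_trial",
    "simulate_session",
    "replay_yoked",
    "trials_to_frame",
    "fraction_stereotypical",
    "rescale_value",
]

MAX_SAMPLES_FULL = 19
N_SAMPLES_PARTIAL = 12
SELF_CONDITIONS = ("full", "partial")
YOKED_OF = {"full": "yoked_full", "partial": "yoked_partial"}


def rescale_value(value) -> np.ndarray | float:
    """Map sample values 1..9 onto the signed scale -4..4."""
    return np.asarray(value) - 5


@dataclass(frozen=True)
class AgentParams:
    """Parameters of the leaky-accumulator sampling agent.

    leak:            per-sample retention factor lambda in (0, 1]; 1 = perfect
                     integration, smaller values forget earlier samples and
                     produce recency.
    choice_noise:    softmax temperature tau > 0 in rescaled-value units.
    stop_threshold:  |accumulated difference| at which sampling stops (full
                     control only); np.inf disables threshold stopping.
    stop_bias_large: extra probability of stopping immediately after observing
                     a sample >= stop_value_cut (full control only).
    side_policy:     'alternate' (a-b-a-b...), 'blocked' (a-a-..-b-b, one
                     switch) or 'random'.
    """

    leak: float = 0.85
    choice_noise: float = 0.5
    stop_threshold: float = 6.0
    stop_bias_large: float = 0.05
    stop_value_cut: int = 8
    side_policy: str = "random"

    def __post_init__(self) -> None:
        if not (0.0 < self.leak <= 1.0):
            raise ValueError("leak must lie in (0, 1]")
        if self.choice_noise <= 0:
            raise ValueError("choice_noise (softmax temperature) must be > 0")
        if self.stop_threshold < 0:
            raise ValueError("stop_threshold must be >= 0")
        if not (0.0 <= self.stop_bias_large <= 1.0):
            raise ValueError("stop_bias_large is a probability")
        if self.side_policy not in ("alternate", "blocked", "random"):
            raise ValueError(f"unknown side_policy {self.side_policy!r}")


@dataclass(frozen=True)
class Sample:
    side: str  # 'left' or 'right'
    value: int  # 1..9
    index: int  # 1-based position within the trial


@dataclass(frozen=True)
class TrialRecord:
    problem: ChoiceProblem
    samples: tuple[Sample, ...]
    condition: str
    choice: str  # 'left' or 'right'
    participant: int = 0
    trial: int = 0

    def __post_init__(self) -> None:
        n = len(self.samples)
        if self.condition in ("partial", "yoked_partial"):
            if n != N_SAMPLES_PARTIAL:
                raise ValueError(f"partial-control trials have exactly 12 samples, got {n}")
        elif not (1 <= n <= MAX_SAMPLES_FULL):
            raise ValueError(f"full-control trials have 1..19 samples, got {n}")
        if self.choice not in ("left", "right"):
            raise ValueError("choice must be 'left' or 'right'")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def sides(self) -> tuple[str, ...]:
        return tuple(s.side for s in self.samples)

    @property
    def values(self) -> tuple[int, ...]:
        return tuple(s.value for s in self.samples)


def _signed(sample: Sample) -> float:
    s = float(rescale_value(sample.value))
    return s if sample.side == "right" else -s


def accumulate(samples, leak: float) -> float:
    """Leaky accumulation A_n = sum_i leak**(n-i) * s_i over a sample sequence."""
    a = 0.0
    for s in samples:
        a = leak * a + _signed(s)
    return a


def _draw_choice(a: float, tau: float, rng: np.random.Generator) -> str:
    p_right = float(expit(a / tau))
    return "right" if rng.random() < p_right else "left"


def _side_iter(policy: str, n_max: int, rng: np.random.Generator):
    start = "left" if rng.random() < 0.5 else "right"
    other = "right" if start == "left" else "left"
    if policy == "alternate":
        return [start if i % 2 == 0 else other for i in range(n_max)]
    if policy == "blocked":
        switch = int(rng.integers(1, n_max)) if n_max > 1 else 1
        return [start if i < switch else other for i in range(n_max)]
    return [("left", "right")[rng.integers(0, 2)] for _ in range(n_max)]


def simulate_trial(
    params: AgentParams,
    problem: ChoiceProblem,
    condition: str,
    rng: np.random.Generator,
    participant: int = 0,
    trial: int = 0,
) -> TrialRecord:
    """Simulate one self-controlled trial (full or partial control).

    Under full control the agent stops after sample n >= 1 once
    |A_n| >= stop_threshold, with an optional extra stop probability after
    samples >= stop_value_cut, and always at n = 19. Under partial control
    exactly 12 samples are drawn. Yoked conditions must go through
    :func:`replay_yoked`.
    """
    if condition not in SELF_CONDITIONS:
        raise ValueError(
            f"simulate_trial handles self-controlled conditions {SELF_CONDITIONS}; "
            f"use replay_yoked for {condition!r}"
        )
    n_max = MAX_SAMPLES_FULL if condition == "full" else N_SAMPLES_PARTIAL
    sides = _side_iter(params.side_policy, n_max, rng)
    samples: list[Sample] = []
    a = 0.0
    for i in range(n_max):
        side = sides[i]
        option = problem.left if side == "left" else problem.right
        value = sample_outcome(option, rng)
        sample = Sample(side=side, value=value, index=i + 1)
        samples.append(sample)
        a = params.leak * a + _signed(sample)
        if condition == "full":
            if abs(a) >= params.stop_threshold:
                break
            if (
                params.stop_bias_large > 0
                and value >= params.stop_value_cut
                and rng.random() < params.stop_bias_large
            ):
                break
    choice = _draw_choice(a, params.choice_noise, rng)
    return TrialRecord(
        problem=problem,
        samples=tuple(samples),
        condition=condition,
        choice=choice,
        participant=participant,
        trial=trial,
    )


def simulate_session(
    params: AgentParams,
    session,
    condition: str,
    rng: np.random.Generator,
    participant: int = 0,
) -> list[TrialRecord]:
    """Simulate every trial of a session under one self-controlled condition."""
    return [
        simulate_trial(params, problem, condition, rng, participant=participant, trial=t + 1)
        for t, problem in enumerate(session)
    ]


def replay_yoked(
    source_trials: list[TrialRecord],
    params: AgentParams,
    rng: np.random.Generator,
    participant: int | None = None,
) -> list[TrialRecord]:
    """Re-decide previously recorded sampling streams without control.

    The sample sequences (sides, values, lengths) are copied verbatim from the
    source trials; only the final choice is re-generated from ``params``.
    Pass the agent's own trials for yoke-to-self, another agent's for
    yoke-to-other.
    """
    if not source_trials:
        raise ValueError("replay_yoked needs at least one source trial")
    out = []
    for t in source_trials:
        if t.condition not in SELF_CONDITIONS:
            raise ValueError("source trials for yoking must be self-controlled")
        a = accumulate(t.samples, params.leak)
        choice = _draw_choice(a, params.choice_noise, rng)
        out.append(
            replace(
                t,
                condition=YOKED_OF[t.condition],
                choice=choice,
                participant=t.participant if participant is None else participant,
            )
        )
    return out


def trials_to_frame(trials: list[TrialRecord]) -> pd.DataFrame:
    """Long-format behavioral table: one row per sample event."""
    rows = []
    for t in trials:
        for s in t.samples:
            rows.append(
                {
                    "participant": t.participant,
                    "condition": t.condition,
                    "trial": t.trial,
                    "sample_index": s.index,
                    "side": s.side,
                    "value": s.value,
                    "choice": t.choice,
                    "n_samples": t.n_samples,
                }
            )
    return pd.DataFrame(rows)


def _n_switches(sides) -> int:
    return sum(1 for a, b in zip(sides, sides[1:]) if a != b)


def fraction_stereotypical(trials: list[TrialRecord]) -> float:
    """Share of trials with an alternating (a-b-a-b) or single-switch
    (a-a-..-b-b) left/right sampling routine."""
    if not trials:
        raise ValueError("no trials")
    flags = []
    for t in trials:
        sides = t.sides
        n_sw = _n_switches(sides)
        alternating = n_sw == len(sides) - 1
        blocked = n_sw <= 1
        flags.append(alternating or blocked)
    return float(np.mean(flags))
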