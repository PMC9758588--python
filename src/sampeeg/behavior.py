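"""Behavioral analyses: accuracy, reverse-correlation decision weights,
recency, and the stop-position trend.

Accuracy follows the ideal-observer criterion: a choice is correct when the
arithmetic mean of the experienced samples of the chosen option exceeds that
of the other option. Decision weights come from a logistic reverse
correlation: sample values are rescaled to -4..4, left-option samples are
sign-flipped, trials shorter than 5 samples are discarded, and the choice
(left=0, right=1) is regressed on the summed signed evidence in the early
(first 2), mid (middle), and late (last 2) windows. Recency is the late
minus early weight difference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .agents import TrialRecord, rescale_value

__all__ = [
    "DecisionWeights",
    "StopPositionTrend",
    "accuracy",
    "decision_weights",
    "stop_position_trend",
    "participant_summary",
]

MIN_SAMPLES_PER_TRIAL = 5
N_EARLY = 2
N_LATE = 2
RIDGE_FALLBACK_ALPHA = 1e-4


@dataclass(frozen=True)
class DecisionWeights:
    """Reverse-correlation decision weights (log-odds per rescaled value unit)."""

    w_early: float
    w_mid: float
    w_late: float
    n_trials_used: int
    flagged: bool = False  # True when the ridge fallback was needed

    @property
    def recency(self) -> float:
        return self.w_late - self.w_early


@dataclass(frozen=True)
class StopPositionTrend:
    """Linear trend of mean relative sample position on numerical value."""

    slope: float
    pvalue: float
    mean_positions: dict
    missing_values: tuple


def _trial_option_means(trial: TrialRecord):
    by_side = {"left": [], "right": []}
    for s in trial.samples:
        by_side[s.side].append(s.value)
    return (
        np.mean(by_side["left"]) if by_side["left"] else None,
        np.mean(by_side["right"]) if by_side["right"] else None,
    )


def accuracy(trials: list[TrialRecord]) -> float:
    """Proportion of trials on which the option with the larger experienced
    sample mean was chosen.

    Trials where one option was never sampled, or the two experienced means
    tie, are excluded from the denominator (the ideal-observer criterion is
    undefined there).
    """
    n_correct = 0
    n_used = 0
    for t in trials:
        m_left, m_right = _trial_option_means(t)
        if m_left is None or m_right is None or m_left == m_right:
            continue
        better = "left" if m_left > m_right else "right"
        n_used += 1
        n_correct += t.choice == better
    if n_used == 0:
        raise ValueError("accuracy undefined: every trial was excluded")
    return n_correct / n_used


def _window_regressors(trial: TrialRecord, window_stat: str) -> np.ndarray:
    """Signed early/mid/late evidence for one trial (>= 5 samples)."""
    signed = np.array(
        [
            (1.0 if s.side == "right" else -1.0) * rescale_value(s.value)
            for s in trial.samples
        ],
        dtype=float,
    )
    n = len(signed)
    agg = np.sum if window_stat == "sum" else np.mean
    early = agg(signed[:N_EARLY])
    late = agg(signed[n - N_LATE :])
    mid = agg(signed[N_EARLY : n - N_LATE])
    return np.array([early, mid, late])


def _fit_logistic(X: np.ndarray, y: np.ndarray):
    """Maximum-likelihood logistic fit with a small ridge fallback on
    separation / non-convergence. Returns (coefs_without_intercept, flagged)."""
    Xc = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
            converged = bool(res.mle_retvals.get("converged", False))
            if converged and np.all(np.isfinite(res.bse)) and np.max(np.abs(res.params)) < 50:
                return np.asarray(res.params[1:]), False
        except Exception:
            pass
    from sklearn.linear_model import LogisticRegression

    clf = LogisticRegression(C=1.0 / RIDGE_FALLBACK_ALPHA, max_iter=5000)
    clf.fit(X, y)
    return clf.coef_.ravel(), True


def decision_weights(
    trials: list[TrialRecord],
    choices=None,
    window_stat: str = "sum",
    joint: bool = True,
    min_samples: int = MIN_SAMPLES_PER_TRIAL,
) -> DecisionWeights:
    """Logistic reverse correlation of choice on windowed signed evidence.

    Parameters
    ----------
    trials : trial records carrying their final choices.
    choices : optional override of the choices (same length as ``trials``).
    window_stat : 'sum' (default) or 'mean' evidence per window.
    joint : fit one regression with all three window regressors (default) or
        three separate single-regressor fits.
    """
    if window_stat not in ("sum", "mean"):
        raise ValueError("window_stat must be 'sum' or 'mean'")
    if choices is None:
        choices = [t.choice for t in trials]
    kept = [(t, c) for t, c in zip(trials, choices) if t.n_samples >= min_samples]
    if len(kept) < 10:
        raise ValueError(
            f"only {len(kept)} trials survive the <{min_samples}-sample filter; >=10 needed"
        )
    X = np.stack([_window_regressors(t, window_stat) for t, _ in kept])
    y = np.array([1.0 if c == "right" else 0.0 for _, c in kept])

    if joint:
        coefs, flagged = _fit_logistic(X, y)
        w_early, w_mid, w_late = coefs
    else:
        ws, flagged = [], False
        for j in range(3):
            cj, fj = _fit_logistic(X[:, [j]], y)
            ws.append(cj[0])
            flagged |= fj
        w_early, w_mid, w_late = ws
    return DecisionWeights(
        w_early=float(w_early),
        w_mid=float(w_mid),
        w_late=float(w_late),
        n_trials_used=len(kept),
        flagged=flagged,
    )


def stop_position_trend(trials: list[TrialRecord]) -> StopPositionTrend:
    """OLS slope of mean relative within-sequence position on sample value.

    Per trial the relative position of each sample is index / n_samples;
    positions are averaged per value 1..9 across all trials and regressed on
    value, with a two-tailed t-test on the slope. Values never observed are
    dropped from the regression and reported.
    """
    if not trials:
        raise ValueError("no trials")
    positions: dict[int, list[float]] = {v: [] for v in range(1, 10)}
    for t in trials:
        n = t.n_samples
        for s in t.samples:
            positions[s.value].append(s.index / n)
    means = {v: float(np.mean(p)) for v, p in positions.items() if p}
    missing = tuple(v for v in range(1, 10) if v not in means)
    if len(means) < 3:
        raise ValueError("too few distinct values observed for a trend")
    xs = np.array(sorted(means))
    ys = np.array([means[v] for v in xs])
    fit = stats.linregress(xs, ys)
    return StopPositionTrend(
        slope=float(fit.slope),
        pvalue=float(fit.pvalue),
        mean_positions=means,
        missing_values=missing,
    )


def participant_summary(trials_by_participant: dict) -> pd.DataFrame:
    """Per-participant behavioral summary table.

    ``trials_by_participant`` maps (participant, condition) -> list of trials.
    """
    rows = []
    for (participant, condition), trials in sorted(trials_by_participant.items()):
        row = {"participant": participant, "condition": condition}
        row["accuracy"] = accuracy(trials)
        try:
            dw = decision_weights(trials)
            row.update(
                w_early=dw.w_early,
                w_mid=dw.w_mid,
                w_late=dw.w_late,
                recency=dw.recency,
                n_trials_used=dw.n_trials_used,
            )
        except ValueError:
            row.update(w_early=np.nan, w_mid=np.nan, w_late=np.nan, recency=np.nan,
                       n_trials_used=0)
        trend = stop_position_trend(trials)
        row["stop_slope"] = trend.slope
        row["stop_slope_p"] = trend.pvalue
        rows.append(row)
    return pd.DataFrame(rows)
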