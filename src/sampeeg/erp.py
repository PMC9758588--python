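"""Univariate ERP window analyses: baseline correction, lateralized visual
evoked potentials (P1/N1), and centro-parietal positivity by trial window.

All window means are inclusive of both endpoints on the sample grid.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .epochs import CPP_CHANNELS, LEFT_VISUAL, RIGHT_VISUAL, EpochSet

__all__ = [
    "WindowSpec",
    "P1_WINDOW",
    "N1_WINDOW",
    "CPP_WINDOW",
    "baseline_correct",
    "lateralized_vep",
    "cpp_by_window",
    "LateralizedVEP",
    "CppByWindow",
]


@dataclass(frozen=True)
class WindowSpec:
    name: str
    t_start: float
    t_end: float
    channels: tuple

    def __post_init__(self) -> None:
        if not (-0.2 <= self.t_start < self.t_end <= 0.8):
            raise ValueError("window must satisfy -0.2 <= t_start < t_end <= 0.8")
        if not self.channels:
            raise ValueError("window needs at least one channel")


P1_WINDOW = WindowSpec("P1", 0.080, 0.130, LEFT_VISUAL + RIGHT_VISUAL)
N1_WINDOW = WindowSpec("N1", 0.140, 0.200, LEFT_VISUAL + RIGHT_VISUAL)
CPP_WINDOW = WindowSpec("CPP", 0.300, 0.600, CPP_CHANNELS)


def baseline_correct(epochs: EpochSet) -> EpochSet:
    """Subtract each epoch's per-channel mean over [-0.2, 0) from the whole
    epoch. Idempotent."""
    baseline = epochs.times < 0
    mean = epochs.data[:, :, baseline].mean(axis=-1, keepdims=True)
    return replace(epochs, data=epochs.data - mean)


@dataclass(frozen=True)
class LateralizedVEP:
    timecourse: np.ndarray  # lateralized difference wave over the epoch
    times: np.ndarray
    p1_mean: float
    n1_mean: float


def lateralized_vep(epochs: EpochSet) -> LateralizedVEP:
    """Double-subtraction lateralized visual ERP.

    ERP(left stimuli) - ERP(right stimuli), then mean over left-hemisphere
    occipitoparietal channels minus mean over the corresponding
    right-hemisphere channels. Window means are extracted for P1 (80-130 ms)
    and N1 (140-200 ms).
    """
    sides = epochs.events["side"].to_numpy()
    if not (np.any(sides == "left") and np.any(sides == "right")):
        raise ValueError("both left- and right-side events are required")
    li = epochs.channel_index(LEFT_VISUAL)
    ri = epochs.channel_index(RIGHT_VISUAL)
    erp_left = epochs.data[sides == "left"].mean(axis=0)
    erp_right = epochs.data[sides == "right"].mean(axis=0)
    diff = erp_left - erp_right
    lateral = diff[li].mean(axis=0) - diff[ri].mean(axis=0)
    p1 = float(lateral[epochs.time_mask(P1_WINDOW.t_start, P1_WINDOW.t_end)].mean())
    n1 = float(lateral[epochs.time_mask(N1_WINDOW.t_start, N1_WINDOW.t_end)].mean())
    return LateralizedVEP(
        timecourse=lateral, times=epochs.times.copy(), p1_mean=p1, n1_mean=n1
    )


@dataclass(frozen=True)
class CppByWindow:
    early: float
    mid: float
    late: float
    missing_classes: tuple = ()

    @property
    def late_minus_early(self) -> float:
        return self.late - self.early


def cpp_by_window(epochs: EpochSet, min_samples: int = 5) -> CppByWindow:
    """Mean CPP amplitude (centro-parietal channels, 300-600 ms) per
    early/mid/late within-trial window.

    Events from trials with fewer than ``min_samples`` samples are excluded,
    matching the behavioral early/mid/late definition. A window class with no
    surviving events yields NaN and is flagged in ``missing_classes``.
    """
    keep = epochs.events["n_samples"].to_numpy() >= min_samples
    if not np.any(keep):
        raise ValueError("no events survive the minimum-samples filter")
    sub = epochs.subset(keep)
    ci = sub.channel_index(CPP_WINDOW.channels)
    tm = sub.time_mask(CPP_WINDOW.t_start, CPP_WINDOW.t_end)
    amp = sub.data[:, ci][:, :, tm].mean(axis=(1, 2))
    classes = sub.events["window_class"].to_numpy()
    out = {}
    missing = []
    for w in ("early", "mid", "late"):
        mask = classes == w
        if np.any(mask):
            out[w] = float(amp[mask].mean())
        else:
            out[w] = float("nan")
            missing.append(w)
    return CppByWindow(
        early=out["early"], mid=out["mid"], late=out["late"],
        missing_classes=tuple(missing),
    )
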