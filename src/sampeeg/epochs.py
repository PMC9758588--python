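"""Synthetic sample-locked EEG epochs with a planted multivariate structure.

Each sample event yields one epoch of 64 channels (10% system, actiCap-style
layout) by 250 time points (-0.2 to 0.8 s at 250 Hz). On top of spatially
correlated Gaussian noise the generator plants, per event:

* a *numberline* pattern: a participant-specific unit topography scaled by
  the distorted value v = sign(x + b) |x + b|^k of the event's sample value
  (x is the value 1..9 normalized to [-1, 1]), with a raised-cosine temporal
  envelope over 160-800 ms;
* an *extremity* pattern: a second topography, constructed orthogonal to the
  first, scaled by the distorted extremity |v - v(5)| with a 260-800 ms
  envelope (for k = 1, b = 0 this is proportional to |value - 5|);
* a ramping centro-parietal positivity at 300-600 ms whose amplitude steps up
  from early to mid to late samples within a trial;
* a lateralized visual component at 80-200 ms on occipitoparietal channels
  contralateral to the stimulus side.

Condition-specific gain multipliers implement "full-control amplification"
of the numberline and CPP components.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import h5py
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .agents import TrialRecord

__all__ = [
    "CHANNELS",
    "EpochSet",
    "GenParams",
    "generate_epochs",
    "smooth_erp",
    "save_epochs_h5",
    "load_epochs_h5",
]

# 64-channel actiCap layout on the extended international 10% system
# (recording reference FCz is not part of the data channels).
CHANNELS = (
    "Fp1 Fp2 F7 F3 Fz F4 F8 FC5 FC1 FC2 FC6 T7 C3 Cz C4 T8 TP9 CP5 CP1 CP2 "
    "CP6 TP10 P7 P3 Pz P4 P8 PO9 O1 Oz O2 PO10 AF7 AF3 AF4 AF8 F5 F1 F2 F6 "
    "FT9 FT7 FC3 FC4 FT8 FT10 C5 C1 C2 C6 TP7 CP3 CPz CP4 TP8 P5 P1 P2 P6 "
    "PO7 PO3 POz PO4 PO8"
).split()

SFREQ = 250.0
TMIN = -0.2
N_TIMES = 250
TIMES = TMIN + np.arange(N_TIMES) / SFREQ

CPP_CHANNELS = ("Cz", "C1", "C2", "CPz", "CP1", "CP2", "CP3", "CP4", "Pz", "P1", "P2")
LEFT_VISUAL = ("O1", "PO3", "PO7", "PO9")
RIGHT_VISUAL = ("O2", "PO4", "PO8", "PO10")

EVENT_COLUMNS = (
    "participant",
    "condition",
    "trial",
    "sample_index",
    "value",
    "side",
    "window_class",
    "half",
    "n_samples",
)


@dataclass
class EpochSet:
    """Sample-locked epochs: ``data`` is (n_events, n_channels, n_times)."""

    data: np.ndarray
    events: pd.DataFrame
    channels: tuple = tuple(CHANNELS)
    times: np.ndarray = field(default_factory=lambda: TIMES.copy())

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("data must be (events, channels, times)")
        n_ev, n_ch, n_t = self.data.shape
        if n_ch != len(self.channels) or n_t != len(self.times):
            raise ValueError("data shape does not match channels/times")
        if len(self.events) != n_ev:
            raise ValueError("events table length does not match data")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("time axis must be strictly increasing")
        if not np.any(self.times < 0):
            raise ValueError("baseline window [-0.2, 0) missing from time axis")
        vals = self.events["value"].to_numpy()
        if not np.all((vals >= 1) & (vals <= 9)):
            raise ValueError("event values must lie in 1..9")

    @property
    def n_events(self) -> int:
        return self.data.shape[0]

    def channel_index(self, names) -> np.ndarray:
        missing = [n for n in names if n not in self.channels]
        if missing:
            raise ValueError(f"unknown channel name(s): {missing}")
        lookup = {c: i for i, c in enumerate(self.channels)}
        return np.array([lookup[n] for n in names])

    def time_mask(self, t_start: float, t_end: float) -> np.ndarray:
        """Boolean mask over the time grid, inclusive of both endpoints."""
        return (self.times >= t_start - 1e-9) & (self.times <= t_end + 1e-9)

    def subset(self, mask) -> "EpochSet":
        mask = np.asarray(mask)
        return EpochSet(
            data=self.data[mask],
            events=self.events.iloc[mask].reset_index(drop=True),
            channels=self.channels,
            times=self.times,
        )


@dataclass(frozen=True)
class GenParams:
    """Generator parameters (amplitudes in arbitrary microvolt-scale units).

    ``k_true``/``b_true`` parameterize the planted numberline distortion;
    ``condition_gains`` multiplies the numberline and CPP gains per condition
    and defaults to an amplified full-control condition.
    """

    k_true: float = 1.0
    b_true: float = 0.0
    gain_distance: float = 1.0
    gain_extremity: float = 1.0
    gain_cpp: float = 0.5
    gain_lat: float = 1.0
    noise_sd: float = 1.0
    spatial_corr: float = 2.0
    condition_gains: dict = field(
        default_factory=lambda: {
            "full": 1.5,
            "yoked_full": 1.0,
            "partial": 1.0,
            "yoked_partial": 1.0,
        }
    )

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for g in (self.gain_distance, self.gain_extremity, self.gain_cpp, self.gain_lat):
            if not np.isfinite(g):
                raise ValueError("gains must be finite")
        if self.k_true <= 0:
            raise ValueError("k_true must be > 0")


def distort_values(values, k: float, b: float) -> np.ndarray:
    """Power-law numberline transform of values 1..9 normalized to [-1, 1]."""
    x = (np.asarray(values, dtype=float) - 5.0) / 4.0
    return np.sign(x + b) * np.abs(x + b) ** k


def _raised_cosine(times: np.ndarray, t0: float, t1: float) -> np.ndarray:
    env = np.zeros_like(times)
    inside = (times >= t0) & (times <= t1)
    phase = (times[inside] - t0) / (t1 - t0)
    env[inside] = 0.5 * (1.0 - np.cos(2.0 * np.pi * phase))
    return env

ENV_DISTANCE = (0.16, 0.80)
ENV_EXTREMITY = (0.26, 0.80)
ENV_CPP = (0.30, 0.60)
ENV_LATERAL = (0.08, 0.20)
CPP_WINDOW_STEP = {"early": 1.0, "mid": 2.0, "late": 3.0}


def _window_class(index: int, n: int) -> str:
    """Early = first 2, late = last 2, mid = rest; late wins on overlap."""
    if index > n - 2:
        return "late"
    if index <= 2:
        return "early"
    return "mid"


def events_from_trials(trials: list[TrialRecord]) -> pd.DataFrame:
    rows = []
    for t in trials:
        n = t.n_samples
        for s in t.samples:
            rows.append(
                {
                    "participant": t.participant,
                    "condition": t.condition,
                    "trial": t.trial,
                    "sample_index": s.index,
                    "value": s.value,
                    "side": s.side,
                    "window_class": _window_class(s.index, n),
                    "half": "first" if s.index <= n / 2 else "second",
                    "n_samples": n,
                }
            )
    return pd.DataFrame(rows, columns=list(EVENT_COLUMNS))


def participant_topographies(rng: np.random.Generator, n_channels: int = len(CHANNELS)):
    """Draw a unit numberline topography and an orthogonal unit extremity
    topography for one synthetic participant."""
    u = rng.standard_normal(n_channels)
    u /= np.linalg.norm(u)
    w = rng.standard_normal(n_channels)
    w -= (w @ u) * u
    w /= np.linalg.norm(w)
    return u, w


def _noise_mixing(rng: np.random.Generator, n_channels: int, corr_length: float) -> np.ndarray:
    """Cholesky factor of an exponential-decay channel covariance over a
    random 3D channel embedding (stands in for head geometry)."""
    pos = rng.standard_normal((n_channels, 3))
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    cov = np.exp(-d / corr_length)
    return np.linalg.cholesky(cov + 1e-9 * np.eye(n_channels))


def generate_epochs(
    params: GenParams,
    trials: list[TrialRecord],
    rng: np.random.Generator,
    dtype=np.float64,
) -> EpochSet:
    """Generate one participant's synthetic epochs for a list of trials."""
    events = events_from_trials(trials)
    n_ev = len(events)
    if n_ev == 0:
        raise ValueError("no sample events in the given trials")
    n_ch = len(CHANNELS)
    times = TIMES

    u_dist, u_ext = participant_topographies(rng, n_ch)
    L = _noise_mixing(rng, n_ch, params.spatial_corr)

    env_dist = _raised_cosine(times, *ENV_DISTANCE)
    env_ext = _raised_cosine(times, *ENV_EXTREMITY)
    env_cpp = _raised_cosine(times, *ENV_CPP)
    env_lat = _raised_cosine(times, *ENV_LATERAL)

    cond = events["condition"].to_numpy()
    cond_gain = np.array([params.condition_gains.get(c, 1.0) for c in cond])
    values = events["value"].to_numpy()
    v = distort_values(values, params.k_true, params.b_true)
    v_mid = distort_values(5, params.k_true, params.b_true)

    gen_dtype = np.float32 if np.dtype(dtype) == np.float32 else np.float64
    if params.noise_sd > 0:
        z = rng.standard_normal((n_ev * N_TIMES, n_ch), dtype=gen_dtype)
        z = (params.noise_sd * (z @ L.T.astype(gen_dtype))).reshape(n_ev, N_TIMES, n_ch)
        data = np.ascontiguousarray(z.transpose(0, 2, 1)).astype(dtype, copy=False)
    else:
        data = np.zeros((n_ev, n_ch, N_TIMES), dtype=dtype)

    # numberline pattern
    amp = (params.gain_distance * cond_gain * v).astype(dtype)
    data += amp[:, None, None] * (u_dist[:, None] * env_dist[None, :]).astype(dtype)

    # extremity pattern (orthogonal topography)
    ext = np.abs(v - v_mid)
    amp = (params.gain_extremity * ext).astype(dtype)
    data += amp[:, None, None] * (u_ext[:, None] * env_ext[None, :]).astype(dtype)

    # ramping CPP over early/mid/late samples
    cpp_idx = [CHANNELS.index(c) for c in CPP_CHANNELS]
    steps = events["window_class"].map(CPP_WINDOW_STEP).to_numpy(dtype=float)
    amp = (params.gain_cpp * cond_gain * steps).astype(dtype)
    cpp_topo = np.zeros(n_ch)
    cpp_topo[cpp_idx] = 1.0
    data += amp[:, None, None] * (cpp_topo[:, None] * env_cpp[None, :]).astype(dtype)

    # lateralized visual component, contralateral to the stimulus side
    left_idx = [CHANNELS.index(c) for c in LEFT_VISUAL]
    right_idx = [CHANNELS.index(c) for c in RIGHT_VISUAL]
    is_left = events["side"].to_numpy() == "left"
    lat = np.zeros((n_ev, n_ch))
    lat[np.ix_(is_left, right_idx)] = params.gain_lat
    lat[np.ix_(~is_left, left_idx)] = params.gain_lat
    data += lat.astype(dtype)[:, :, None] * env_lat.astype(dtype)[None, None, :]

    return EpochSet(data=data, events=events)


def value_mean_epochs(epochs: EpochSet) -> EpochSet:
    """Collapse an EpochSet to the 9 per-value mean topography time courses.

    Baseline correction, temporal smoothing, and the ERP-RDM all act linearly
    on (or only through) the per-value means, so downstream RSA on the
    collapsed set is exactly equivalent to RSA on the full set and much
    cheaper. Raises if any value 1..9 has no events.
    """
    values = epochs.events["value"].to_numpy()
    missing = [v for v in range(1, 10) if not np.any(values == v)]
    if missing:
        raise ValueError(f"no events for sample value(s) {missing}")
    data = np.stack([epochs.data[values == v].mean(axis=0) for v in range(1, 10)])
    events = pd.DataFrame({"value": np.arange(1, 10)})
    return EpochSet(data=data, events=events, channels=epochs.channels, times=epochs.times)


def smooth_erp(epochs: EpochSet, half_duration_ms: float = 35.0) -> EpochSet:
    """Temporal Gaussian smoothing parameterized by half duration at half
    maximum (default 35 ms); edges handled by reflection."""
    if half_duration_ms <= 0:
        raise ValueError("half_duration_ms must be > 0")
    sfreq = 1.0 / float(np.mean(np.diff(epochs.times)))
    sigma_samples = half_duration_ms / np.sqrt(2.0 * np.log(2.0)) / 1000.0 * sfreq
    if sigma_samples > len(epochs.times):
        raise ValueError("smoothing kernel longer than the epoch")
    smoothed = gaussian_filter1d(epochs.data, sigma_samples, axis=-1, mode="reflect")
    return replace(epochs, data=smoothed)


def save_epochs_h5(epochs: EpochSet, h5_path, events_tsv_path=None) -> None:
    """Persist an EpochSet: HDF5 dataset "data" (channels x time x events)
    plus channel/time attributes, and a BIDS-events-like TSV sidecar."""
    with h5py.File(h5_path, "w") as f:
        f.create_dataset("data", data=np.transpose(epochs.data, (1, 2, 0)))
        f.attrs["channels"] = list(epochs.channels)
        f.attrs["times"] = epochs.times
    if events_tsv_path is not None:
        epochs.events.to_csv(events_tsv_path, sep="\t", index=False)


def load_epochs_h5(h5_path, events_tsv_path) -> EpochSet:
    with h5py.File(h5_path, "r") as f:
        data = np.transpose(f["data"][()], (2, 0, 1))
        channels = tuple(str(c) for c in f.attrs["channels"])
        times = np.asarray(f.attrs["times"])
    events = pd.read_csv(events_tsv_path, sep="\t")
    return EpochSet(data=data, events=events, channels=channels, times=times)
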