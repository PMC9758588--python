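"""Time-resolved representational similarity analysis of numerical magnitude
and neurometric distortion fitting.

The representational geometry of the nine sample values is summarized, at
each time point, by the 9x9 matrix of Euclidean distances between the mean
64-channel topographies of the values (the "ERP-RDM"). Model RDMs encode
numerical distance (|v_i - v_j|) and extremity (||v_i - v(5)| - |v_j - v(5)||)
of power-law-distorted values

    v = sign(x + b) * |x + b| ** k,      x = (value - 5) / 4 in [-1, 1],

where k < 1 compresses, k > 1 anti-compresses, and b biases the neural
numberline toward larger (b > 0) or smaller (b < 0) magnitudes. Model-data
agreement is the Pearson correlation over the 36 lower-triangle entries,
after the model has been orthogonalized to a sample-frequency RDM. The
neurometric fit grids (k, b) over k in [0.5, 10], b in [-0.75, 0.75] and
takes the per-participant argmax of the correlation averaged over the
distance and extremity model families.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .epochs import EpochSet, distort_values

__all__ = [
    "RDM",
    "NeurometricMap",
    "model_rdm",
    "frequency_rdm",
    "value_frequencies",
    "erp_rdm_timecourse",
    "window_average_rdm",
    "orthogonalize_model",
    "rsa_timecourse",
    "neurometric_fit",
    "default_k_grid",
    "default_b_grid",
]

VALUES = np.arange(1, 10)
N_PAIRS = 36
RAW_UNIT_SCALE = 4.0  # maps the normalized span [-1, 1] back to raw value units

K_BOUNDS = (0.5, 10.0)
B_BOUNDS = (-0.75, 0.75)


def default_k_grid(n: int = 40) -> np.ndarray:
    """Log-spaced exponent grid over [0.5, 10] with k = 1 inserted so the
    linear parameterization lies exactly on the grid."""
    grid = np.geomspace(K_BOUNDS[0], K_BOUNDS[1], n)
    return np.unique(np.concatenate([grid, [1.0]]))


def default_b_grid(n: int = 31) -> np.ndarray:
    return np.linspace(B_BOUNDS[0], B_BOUNDS[1], n)


@dataclass(frozen=True)
class RDM:
    """Symmetric 9x9 dissimilarity matrix over sample values 1..9."""

    matrix: np.ndarray
    labels: np.ndarray = field(default_factory=lambda: VALUES.copy())

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("RDM must be square over its labels")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("RDM must be symmetric")
        if not np.allclose(np.diag(m), 0.0, atol=1e-10):
            raise ValueError("RDM diagonal must be zero")
        object.__setattr__(self, "matrix", m)

    @property
    def lower_triangle(self) -> np.ndarray:
        """The 36 below-diagonal entries, row-major."""
        i, j = np.tril_indices(len(self.labels), k=-1)
        return self.matrix[i, j]


def _pack_lower(vec: np.ndarray, n: int = 9) -> np.ndarray:
    m = np.zeros((n, n))
    i, j = np.tril_indices(n, k=-1)
    m[i, j] = vec
    m[j, i] = vec
    return m


def model_rdm(kind: str, k: float = 1.0, b: float = 0.0) -> RDM:
    """Distance or extremity model RDM of power-law-distorted values.

    Entries are reported on the raw value scale (span 1..9), so the
    untransformed distance model (k=1, b=0) gives the literal numerical
    difference: entry(3, 7) = 4, entry(4, 6) = 2. Pearson correlation is
    scale-invariant, so this convention is presentational only.
    """
    if k <= 0:
        raise ValueError("exponent k must be > 0")
    v = RAW_UNIT_SCALE * distort_values(VALUES, k, b)
    if kind == "distance":
        m = np.abs(v[:, None] - v[None, :])
    elif kind == "extremity":
        v_mid = RAW_UNIT_SCALE * distort_values(5, k, b)
        e = np.abs(v - v_mid)
        m = np.abs(e[:, None] - e[None, :])
    else:
        raise ValueError("kind must be 'distance' or 'extremity'")
    return RDM(m)


def value_frequencies(events) -> np.ndarray:
    """Relative occurrence frequencies f_1..f_9 of sample values."""
    counts = np.array([(events["value"].to_numpy() == v).sum() for v in VALUES], float)
    total = counts.sum()
    if total == 0:
        raise ValueError("no events")
    return counts / total


def frequency_rdm(frequencies) -> RDM:
    """RDM over relative sample-occurrence frequencies, entry |f_i - f_j|."""
    f = np.asarray(frequencies, dtype=float)
    if f.shape != (9,) or not np.isclose(f.sum(), 1.0):
        raise ValueError("frequencies must be 9 shares summing to 1")
    return RDM(np.abs(f[:, None] - f[None, :]))


def erp_rdm_timecourse(epochs: EpochSet) -> np.ndarray:
    """ERP-RDM at every time point: (n_times, 9, 9) Euclidean distances
    between per-value mean topographies."""
    values = epochs.events["value"].to_numpy()
    missing = [int(v) for v in VALUES if not np.any(values == v)]
    if missing:
        raise ValueError(f"no events for sample value(s) {missing}")
    means = np.stack([epochs.data[values == v].mean(axis=0) for v in VALUES])
    # (9, 9, n_times) pairwise channel-space distances
    diff = means[:, None, :, :] - means[None, :, :, :]
    rdms = np.sqrt(np.sum(diff**2, axis=2))
    return np.transpose(rdms, (2, 0, 1))


def window_average_rdm(rdms: np.ndarray, times: np.ndarray, t_start: float, t_end: float) -> RDM:
    """Average the RDM time course over a window (endpoints inclusive)."""
    mask = (times >= t_start - 1e-9) & (times <= t_end + 1e-9)
    if not np.any(mask):
        raise ValueError("window contains no time points")
    return RDM(rdms[mask].mean(axis=0))


def orthogonalize_model(model: RDM, freq: RDM) -> RDM:
    """Residualize the model RDM on the frequency RDM (plus intercept) over
    the lower triangle; the residual has exactly zero correlation with the
    frequency vector."""
    if not np.array_equal(model.labels, freq.labels):
        raise ValueError("model and frequency RDMs must share labels")
    y = model.lower_triangle
    f = freq.lower_triangle
    if np.allclose(f, f.mean()):
        warnings.warn("frequency RDM has zero variance; model returned unchanged")
        return model
    X = np.column_stack([np.ones_like(f), f])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return RDM(_pack_lower(resid, n=len(model.labels)), labels=model.labels)


def _pearson_lower(data_vecs: np.ndarray, model_vec: np.ndarray) -> np.ndarray:
    """Row-wise Pearson r between data lower-triangle vectors and one model
    vector; rows with zero variance yield NaN."""
    d = data_vecs - data_vecs.mean(axis=-1, keepdims=True)
    m = model_vec - model_vec.mean()
    denom = np.sqrt(np.sum(d**2, axis=-1) * np.sum(m**2))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (d @ m) / denom
    return r


def rsa_timecourse(erp_rdms: np.ndarray, model: RDM) -> np.ndarray:
    """Pearson correlation between model and ERP-RDM lower triangles at each
    time point. Time points with a constant ERP-RDM are returned as NaN."""
    i, j = np.tril_indices(model.matrix.shape[0], k=-1)
    data_vecs = erp_rdms[:, i, j]
    return _pearson_lower(data_vecs, model.lower_triangle)


@dataclass(frozen=True)
class NeurometricMap:
    """Correlation surface over the (k, b) grid and its argmax."""

    k_grid: np.ndarray
    b_grid: np.ndarray
    corr: np.ndarray  # (len(k_grid), len(b_grid))
    argmax_k: float
    argmax_b: float


def neurometric_fit(
    erp_rdm_window: RDM,
    freq: RDM | None = None,
    k_grid=None,
    b_grid=None,
    kinds: tuple = ("distance", "extremity"),
) -> NeurometricMap:
    """Grid search of the neurometric distortion parameters (k, b).

    For each grid point the parameterized model RDMs in ``kinds`` (by default
    both the distance and the extremity family) are built, orthogonalized to
    the frequency RDM, and correlated with the window-averaged ERP-RDM; the
    surface is the mean correlation across families. Ties at the maximum
    break toward the point closest to (1, 0), then lexicographically.
    """
    if not kinds:
        raise ValueError("at least one model family is required")
    k_grid = default_k_grid() if k_grid is None else np.asarray(k_grid, dtype=float)
    b_grid = default_b_grid() if b_grid is None else np.asarray(b_grid, dtype=float)
    if k_grid.size == 0 or b_grid.size == 0:
        raise ValueError("parameter grids must be nonempty")
    if np.any(k_grid < K_BOUNDS[0] - 1e-12) or np.any(k_grid > K_BOUNDS[1] + 1e-12):
        raise ValueError(f"k grid must lie within {K_BOUNDS}")
    if np.any(b_grid < B_BOUNDS[0] - 1e-12) or np.any(b_grid > B_BOUNDS[1] + 1e-12):
        raise ValueError(f"b grid must lie within {B_BOUNDS}")

    data_vec = erp_rdm_window.lower_triangle
    if np.allclose(data_vec, data_vec.mean()):
        raise ValueError("ERP-RDM has zero variance in the fitting window")

    def _corr_with(model: RDM) -> float:
        m = model if freq is None else orthogonalize_model(model, freq)
        return float(_pearson_lower(data_vec[None, :], m.lower_triangle)[0])

    surface = np.empty((k_grid.size, b_grid.size))
    for ik, k in enumerate(k_grid):
        for ib, b in enumerate(b_grid):
            surface[ik, ib] = np.mean(
                [_corr_with(model_rdm(kind, k, b)) for kind in kinds]
            )

    best = np.nanmax(surface)
    ties = np.argwhere(np.isclose(surface, best, rtol=0, atol=1e-12))
    # prefer the tie closest to the linear/unbiased point, then lexicographic
    order = sorted(
        (np.hypot(k_grid[ik] - 1.0, b_grid[ib]), k_grid[ik], b_grid[ib], ik, ib)
        for ik, ib in ties
    )
    _, _, _, ik, ib = order[0]
    return NeurometricMap(
        k_grid=k_grid,
        b_grid=b_grid,
        corr=surface,
        argmax_k=float(k_grid[ik]),
        argmax_b=float(b_grid[ib]),
    )
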