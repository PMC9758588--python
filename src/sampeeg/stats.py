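"""Group inference: mixed 2x2 ANOVA, Bonferroni post hoc t-tests, and
cluster-based permutation tests over time courses.

The mixed design has one two-level within-participant factor (self-controlled
vs yoked) and one two-level between-participant factor (full vs partial
control group). For two levels each, the ANOVA reduces exactly to ordinary
regressions on per-participant sums and differences, which is how it is
computed here; effect sizes are partial eta squared.

Cluster tests follow the standard mass-univariate recipe: a t statistic per
time point, clusters defined as maximal runs of same-signed supra-threshold
points, cluster mass = summed t, and a permutation null distribution of the
maximum |mass| (sign flips for one-sample tests, group-label permutation for
the interaction). Cluster p = (1 + #{null >= observed}) / (1 + n_perm).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "AnovaResult",
    "EffectStat",
    "ClusterResult",
    "Cluster",
    "mixed_anova_2x2",
    "posthoc_t",
    "cluster_test_1samp",
    "cluster_test_interaction",
]


@dataclass(frozen=True)
class EffectStat:
    F: float
    p: float
    eta_p2: float
    df1: int
    df2: int


@dataclass(frozen=True)
class AnovaResult:
    within: EffectStat
    between: EffectStat | None
    interaction: EffectStat | None


def _one_df_effect(t: float, df_err: int) -> EffectStat:
    F = float(t**2)
    p = float(2.0 * sps.t.sf(abs(t), df_err))
    return EffectStat(F=F, p=p, eta_p2=F / (F + df_err), df1=1, df2=df_err)


def _ols_2group(y: np.ndarray, code: np.ndarray):
    """OLS of y on [1, code] with classical (homoskedastic) t statistics.

    With code = +/-0.5 group indicators, beta0 is the unweighted mean of the
    two group means and beta1 their difference, matching the Type III mixed
    ANOVA cell-means parameterization for (possibly) unbalanced groups.
    """
    X = np.column_stack([np.ones_like(y), code])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df = len(y) - 2
    s2 = float(resid @ resid) / df
    cov = s2 * np.linalg.inv(X.T @ X)
    t = beta / np.sqrt(np.diag(cov))
    return t, df


def mixed_anova_2x2(scores: np.ndarray, group) -> AnovaResult:
    """Mixed 2x2 ANOVA on a participants x 2 within-level score table.

    Parameters
    ----------
    scores : array (n_participants, 2); column order fixes the within levels.
        A missing (NaN) cell is a validation error.
    group : between-participant labels, exactly 2 distinct values with >= 2
        participants each. If only one label is present, the between and
        interaction effects are undefined (None) and the within effect
        reduces to the paired t-test (F = t^2).
    """
    y = np.asarray(scores, dtype=float)
    if y.ndim != 2 or y.shape[1] != 2:
        raise ValueError("scores must be (n_participants, 2)")
    if np.any(~np.isfinite(y)):
        raise ValueError("missing within-participant cell (NaN) in scores")
    group = np.asarray(group)
    if len(group) != len(y):
        raise ValueError("group labels must match the number of participants")
    labels = np.unique(group)

    d = y[:, 1] - y[:, 0]  # within-participant contrast
    m = y.mean(axis=1)  # participant means (between-subject part)

    if labels.size == 1:
        t, df = float(np.mean(d) / sps.sem(d)), len(d) - 1
        return AnovaResult(within=_one_df_effect(t, df), between=None, interaction=None)
    if labels.size != 2:
        raise ValueError("the between factor must have exactly 2 levels")
    if min((group == g).sum() for g in labels) < 2:
        raise ValueError("each group needs at least 2 participants")

    code = np.where(group == labels[0], 0.5, -0.5)
    t_d, df = _ols_2group(d, code)
    t_m, _ = _ols_2group(m, code)
    return AnovaResult(
        within=_one_df_effect(float(t_d[0]), df),
        between=_one_df_effect(float(t_m[1]), df),
        interaction=_one_df_effect(float(t_d[1]), df),
    )


@dataclass(frozen=True)
class PairwiseT:
    name: str
    t: float
    p_corrected: float
    cohen_d: float
    flagged: bool = False


def posthoc_t(pairs, correction: str = "bonferroni") -> list[PairwiseT]:
    """Two-tailed paired t-tests with Bonferroni correction.

    ``pairs`` is a list of (name, a, b) paired-sample tuples; the correction
    factor is the number of comparisons. Cohen's d = mean difference / SD of
    the differences. Zero-variance differences give an infinite t and are
    flagged.
    """
    if correction not in ("bonferroni", "none"):
        raise ValueError("correction must be 'bonferroni' or 'none'")
    m = len(pairs)
    out = []
    for name, a, b in pairs:
        diff = np.asarray(a, float) - np.asarray(b, float)
        sd = diff.std(ddof=1)
        if sd == 0:
            if np.all(diff == 0):
                out.append(PairwiseT(name, 0.0, 1.0, 0.0, flagged=False))
            else:
                t = np.inf if diff.mean() > 0 else -np.inf
                out.append(PairwiseT(name, float(t), 0.0, float(np.sign(diff.mean()) * np.inf),
                                     flagged=True))
            continue
        t, p = sps.ttest_rel(a, b)
        if correction == "bonferroni":
            p = min(1.0, m * p)
        d = float(diff.mean() / sd)
        out.append(PairwiseT(name, float(t), float(p), d))
    return out


@dataclass(frozen=True)
class Cluster:
    t_start: float
    t_end: float
    mass: float
    start_idx: int
    end_idx: int  # inclusive


@dataclass(frozen=True)
class ClusterResult:
    clusters: tuple
    p_values: tuple
    n_permutations: int
    threshold_p: float

    @property
    def min_attainable_p(self) -> float:
        return 1.0 / (self.n_permutations + 1)

    def significant(self, alpha: float = 0.05):
        return [
            (c, p) for c, p in zip(self.clusters, self.p_values) if p <= alpha
        ]


def _find_cluster_masses(t: np.ndarray, crit: float):
    """Maximal runs of supra-threshold points sharing the sign of t.

    Returns a list of (start, end_inclusive, mass).
    """
    supra = np.abs(t) > crit
    sign = np.sign(t)
    clusters = []
    i = 0
    n = len(t)
    while i < n:
        if not supra[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and supra[j + 1] and sign[j + 1] == sign[i]:
            j += 1
        clusters.append((i, j, float(t[i : j + 1].sum())))
        i = j + 1
    return clusters


def _max_mass(t: np.ndarray, crit: float) -> float:
    clusters = _find_cluster_masses(t, crit)
    if not clusters:
        return 0.0
    return max(abs(c[2]) for c in clusters)


def _onesample_t_matrix(X: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """One-sample t per time point for each row of sign flips.

    X is (n, T); signs is (P, n) of +/-1. Sign flips leave X**2 unchanged, so
    the flipped variance follows from the flipped mean alone.
    """
    n = X.shape[0]
    ssq = np.sum(X**2, axis=0)  # (T,)
    mean = signs @ X / n  # (P, T)
    var = (ssq[None, :] - n * mean**2) / (n - 1)
    var = np.maximum(var, 1e-300)
    return mean / np.sqrt(var / n)


def cluster_test_1samp(
    effect_timecourses: np.ndarray,
    threshold_p: float = 0.05,
    n_perm: int = 10000,
    rng: np.random.Generator | None = None,
    times: np.ndarray | None = None,
) -> ClusterResult:
    """Cluster-based sign-flip permutation test of time courses against zero.

    Per time point a two-tailed one-sample t (df = n-1) is computed; clusters
    are maximal same-signed runs with |t| above the two-tailed critical value
    at ``threshold_p``; the null is the distribution of the maximum absolute
    cluster mass over random per-participant sign flips.
    """
    X = np.asarray(effect_timecourses, dtype=float)
    if X.ndim != 2:
        raise ValueError("effect_timecourses must be (participants, time)")
    n, T = X.shape
    if n < 5:
        raise ValueError("at least 5 participants are required")
    if n_perm < 100:
        warnings.warn("fewer than 100 permutations gives a coarse null")
    rng = np.random.default_rng() if rng is None else rng
    times = np.arange(T, dtype=float) if times is None else np.asarray(times)
    if times.shape != (T,):
        raise ValueError("times must match the time axis length")

    crit = sps.t.ppf(1.0 - threshold_p / 2.0, n - 1)
    t_obs = _onesample_t_matrix(X, np.ones((1, n)))[0]
    observed = _find_cluster_masses(t_obs, crit)

    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    t_null = _onesample_t_matrix(X, signs)
    null_max = np.array([_max_mass(row, crit) for row in t_null])

    clusters, pvals = [], []
    for i0, i1, mass in observed:
        p = (1.0 + np.sum(null_max >= abs(mass))) / (1.0 + n_perm)
        clusters.append(Cluster(float(times[i0]), float(times[i1]), mass, i0, i1))
        pvals.append(float(p))
    return ClusterResult(tuple(clusters), tuple(pvals), n_perm, threshold_p)


def _welch_t_matrix(X: np.ndarray, member: np.ndarray) -> np.ndarray:
    """Welch two-sample t per time point for each 0/1 membership row."""
    n = X.shape[0]
    n1 = member.sum(axis=1)  # (P,)
    n0 = n - n1
    tot = X.sum(axis=0)  # (T,)
    tot_sq = np.sum(X**2, axis=0)
    s1 = member @ X  # (P, T)
    s1_sq = member @ (X**2)
    m1 = s1 / n1[:, None]
    m0 = (tot[None, :] - s1) / n0[:, None]
    v1 = (s1_sq - n1[:, None] * m1**2) / (n1[:, None] - 1)
    v0 = (tot_sq[None, :] - s1_sq - n0[:, None] * m0**2) / (n0[:, None] - 1)
    v1 = np.maximum(v1, 1e-300)
    v0 = np.maximum(v0, 1e-300)
    return (m1 - m0) / np.sqrt(v1 / n1[:, None] + v0 / n0[:, None])


def cluster_test_interaction(
    self_minus_yoked: np.ndarray,
    group,
    threshold_p: float = 0.05,
    n_perm: int = 10000,
    rng: np.random.Generator | None = None,
    times: np.ndarray | None = None,
) -> ClusterResult:
    """Cluster permutation test of the 2x2 interaction over time.

    With two levels per factor the interaction equals the between-group
    difference of the within-participant (self - yoked) difference time
    courses, so a per-time-point Welch two-sample t on those differences is
    clustered exactly as in :func:`cluster_test_1samp`, with the null built by
    permuting group labels. The cluster-forming threshold uses the pooled
    df = n - 2 critical value.
    """
    X = np.asarray(self_minus_yoked, dtype=float)
    if X.ndim != 2:
        raise ValueError("self_minus_yoked must be (participants, time)")
    n, T = X.shape
    group = np.asarray(group)
    labels = np.unique(group)
    if labels.size != 2:
        raise ValueError("exactly 2 groups are required")
    member = (group == labels[0]).astype(float)
    if member.sum() < 3 or (n - member.sum()) < 3:
        raise ValueError("each group needs at least 3 participants")
    if n_perm < 100:
        warnings.warn("fewer than 100 permutations gives a coarse null")
    rng = np.random.default_rng() if rng is None else rng
    times = np.arange(T, dtype=float) if times is None else np.asarray(times)

    crit = sps.t.ppf(1.0 - threshold_p / 2.0, n - 2)
    t_obs = _welch_t_matrix(X, member[None, :])[0]
    observed = _find_cluster_masses(t_obs, crit)

    perm_members = np.stack([rng.permutation(member) for _ in range(n_perm)])
    t_null = _welch_t_matrix(X, perm_members)
    null_max = np.array([_max_mass(row, crit) for row in t_null])

    clusters, pvals = [], []
    for i0, i1, mass in observed:
        p = (1.0 + np.sum(null_max >= abs(mass))) / (1.0 + n_perm)
        clusters.append(Cluster(float(times[i0]), float(times[i1]), mass, i0, i1))
        pvals.append(float(p))
    return ClusterResult(tuple(clusters), tuple(pvals), n_perm, threshold_p)
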