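"""Temporal cluster-based permutation test on change-score time courses.

The intervention-driven change (post minus pre) in a condition contrast,
e.g. (Words - Cars), is compared between the two intervention groups with
an independent-samples t-test at every timepoint.  Contiguous runs of
supra-threshold t values form candidate clusters whose mass (the sum of t
over the run) is referred to a permutation null distribution built by
randomly reassigning subjects to groups and recording, per permutation, the
maximum absolute cluster mass.  This max-mass construction controls the
family-wise error rate over all timepoints.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "ChangeScoreSeries",
    "Cluster",
    "ClusterResult",
    "pointwise_t",
    "form_clusters",
    "permutation_test",
]


@dataclass
class ChangeScoreSeries:
    """Per-subject change time series for one group."""

    group: str
    data: np.ndarray  # (n_subjects, n_times)
    times: np.ndarray  # seconds
    subject_ids: list[str] | None = None

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        self.times = np.asarray(self.times, dtype=float)
        if self.data.shape[1] != self.times.shape[0]:
            raise ValueError("data columns must match times")
        if self.subject_ids is not None and len(self.subject_ids) != self.data.shape[0]:
            raise ValueError("subject_ids length must match data rows")


@dataclass(frozen=True)
class Cluster:
    start_time: float
    end_time: float
    mass: float
    p_value: float
    sign: int


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    observed_t_course: np.ndarray
    times: np.ndarray
    threshold_used: float
    n_permutations: int
    seed: int | None
    null_max_mass: np.ndarray = field(default=None, repr=False)

    @property
    def min_p(self) -> float:
        return min((c.p_value for c in self.clusters), default=1.0)

    def to_dict(self) -> dict:
        return {
            "clusters": [
                {
                    "start_time": c.start_time,
                    "end_time": c.end_time,
                    "mass": c.mass,
                    "p_value": c.p_value,
                    "sign": c.sign,
                }
                for c in self.clusters
            ],
            "threshold_used": float(self.threshold_used),
            "n_permutations": int(self.n_permutations),
            "seed": self.seed,
        }


def _t_course(data: np.ndarray, is_a: np.ndarray) -> np.ndarray:
    """Pooled-variance two-sample t at each timepoint; 0 where the pooled
    variance vanishes."""
    a = data[is_a]
    b = data[~is_a]
    na, nb = a.shape[0], b.shape[0]
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    denom = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    diff = a.mean(axis=0) - b.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, diff / np.where(denom > 0, denom, 1.0), 0.0)
    return t


def pointwise_t(
    group_a: ChangeScoreSeries, group_b: ChangeScoreSeries
) -> np.ndarray:
    """Two-sample pooled-variance t statistic at every sample.

    Zero-pooled-variance timepoints yield t = 0 with a warning (they cannot
    seed clusters).
    """
    if group_a.data.shape[0] < 2 or group_b.data.shape[0] < 2:
        raise ValueError("need >= 2 subjects per group")
    if not np.array_equal(group_a.times, group_b.times):
        raise ValueError("groups must share one time grid")
    data = np.vstack([group_a.data, group_b.data])
    is_a = np.zeros(data.shape[0], dtype=bool)
    is_a[: group_a.data.shape[0]] = True
    sp_zero = np.all(data == data[0], axis=0)
    if sp_zero.any():
        warnings.warn(
            f"{int(sp_zero.sum())} timepoint(s) with zero pooled variance; t set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
    return _t_course(data, is_a)


def form_clusters(
    t_course: np.ndarray, threshold: float, times: np.ndarray | None = None
) -> list[tuple[int, int, float, int]]:
    """Maximal contiguous runs of supra-threshold samples.

    Returns a list of ``(start_index, end_index, mass, sign)`` with end
    inclusive; positive clusters have ``t > threshold``, negative clusters
    ``t < -threshold``; mass is the sum of t over the run.
    """
    if not threshold > 0:
        raise ValueError("threshold must be > 0")
    t = np.asarray(t_course, dtype=float)
    out = []
    for sign in (1, -1):
        supra = (sign * t) > threshold
        if not supra.any():
            continue
        edges = np.diff(supra.astype(int))
        starts = list(np.nonzero(edges == 1)[0] + 1)
        ends = list(np.nonzero(edges == -1)[0])
        if supra[0]:
            starts.insert(0, 0)
        if supra[-1]:
            ends.append(t.size - 1)
        for s, e in zip(starts, ends):
            out.append((int(s), int(e), float(t[s : e + 1].sum()), sign))
    out.sort(key=lambda c: c[0])
    return out


def _max_abs_mass(t: np.ndarray, threshold: float) -> float:
    clusters = form_clusters(t, threshold)
    return max((abs(c[2]) for c in clusters), default=0.0)


def permutation_test(
    group_a: ChangeScoreSeries,
    group_b: ChangeScoreSeries,
    threshold: float | None = None,
    n_permutations: int = 1024,
    seed: int = 0,
    method: str = "montecarlo",
) -> ClusterResult:
    """Cluster-based permutation test between two groups of change series.

    The cluster-forming threshold defaults to the two-sided p < 0.05
    quantile of Student's t with ``n_a + n_b - 2`` degrees of freedom.  The
    null distribution is the maximum absolute cluster mass under random
    reassignment of subjects to groups (label counts preserved), pooling
    positive and negative clusters into one two-sided null.  Each observed
    cluster's p-value is ``(1 + #{null >= |mass|}) / (1 + n_permutations)``.

    With ``method="exact"`` all distinct label assignments are enumerated
    and p-values are exact proportions over the enumeration.
    """
    na, nb = group_a.data.shape[0], group_b.data.shape[0]
    if method == "montecarlo" and n_permutations < 99:
        raise ValueError("n_permutations must be >= 99")
    data = np.vstack([group_a.data, group_b.data])
    n = na + nb
    if threshold is None:
        threshold = float(stats.t.ppf(0.975, n - 2))
    observed_idx = np.zeros(n, dtype=bool)
    observed_idx[:na] = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t_obs = pointwise_t(group_a, group_b)
    obs_clusters = form_clusters(t_obs, threshold)

    if method == "exact":
        null = np.array(
            [
                _max_abs_mass(_t_course(data, _mask(n, combo)), threshold)
                for combo in combinations(range(n), na)
            ]
        )
        n_eff = null.size
        pvals = [float(np.mean(null >= abs(mass))) for _s, _e, mass, _sg in obs_clusters]
    elif method == "montecarlo":
        rng = np.random.default_rng(seed)
        null = np.empty(n_permutations)
        for i in range(n_permutations):
            perm = rng.permutation(n)
            is_a = np.zeros(n, dtype=bool)
            is_a[perm[:na]] = True
            null[i] = _max_abs_mass(_t_course(data, is_a), threshold)
        n_eff = n_permutations
        pvals = [
            float((1 + np.sum(null >= abs(mass))) / (1 + n_permutations))
            for _s, _e, mass, _sg in obs_clusters
        ]
    else:
        raise ValueError("method must be 'montecarlo' or 'exact'")

    times = group_a.times
    clusters = [
        Cluster(
            start_time=float(times[s]),
            end_time=float(times[e]),
            mass=mass,
            p_value=p,
            sign=sg,
        )
        for (s, e, mass, sg), p in zip(obs_clusters, pvals)
    ]
    logger.info(
        "cluster permutation: threshold %.3f, %d clusters, min p %.4f",
        threshold, len(clusters), min(pvals, default=1.0),
    )
    return ClusterResult(
        clusters=clusters,
        observed_t_course=t_obs,
        times=times,
        threshold_used=float(threshold),
        n_permutations=n_eff,
        seed=seed if method == "montecarlo" else None,
        null_max_mass=null,
    )


def _mask(n: int, combo: tuple[int, ...]) -> np.ndarray:
    m = np.zeros(n, dtype=bool)
    m[list(combo)] = True
    return m
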