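"""Reliability-maximizing epoch rejection.

Trials contaminated by high-amplitude artifacts (movement, muscle, sensor
jumps) are removed by thresholding the peak-to-peak amplitude of every
channel within the epoch, with one threshold per channel type (gradiometer
and magnetometer signals live on very different scales).  Rather than fixing
thresholds a priori, the thresholds are tuned by a grid search that
maximizes the test-retest reliability of the evoked response: the mean,
across subjects, of the Pearson correlation between each subject's
pre-intervention and post-intervention grand-average evoked time course in a
tuning ROI.  Threshold pairs that empty any subject x session x condition
cell are "untenable" and excluded from the search.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "EpochsSet",
    "ThresholdPair",
    "GridSearchResult",
    "peak_to_peak",
    "apply_rejection",
    "reliability_objective",
    "tune_thresholds",
    "make_threshold_grid",
]


@dataclass
class EpochsSet:
    """Trial-resolved epoched data for one subject and session.

    Parameters
    ----------
    subject_id : str
        Subject identifier.
    session : str
        ``"pre"`` or ``"post"``.
    group : str
        Intervention arm, ``"Letter"`` or ``"Language"``.
    data : ndarray, shape (n_trials, n_channels, n_times)
        Epoched signal, arbitrary units.
    condition_labels : ndarray of str, shape (n_trials,)
        Stimulus category per trial (``Words`` / ``Faces`` / ``Cars``).
    channel_types : ndarray of str, shape (n_channels,)
        Channel type per channel, from a two-type vocabulary
        (``grad`` / ``mag``).
    times : ndarray, shape (n_times,)
        Sample times in seconds, uniform, stimulus onset at 0.
    sfreq : float
        Sampling frequency in Hz.
    """

    subject_id: str
    session: str
    group: str
    data: np.ndarray
    condition_labels: np.ndarray
    channel_types: np.ndarray
    times: np.ndarray
    sfreq: float

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.condition_labels = np.asarray(self.condition_labels)
        self.channel_types = np.asarray(self.channel_types)
        self.times = np.asarray(self.times, dtype=float)
        self.validate()

    def validate(self):
        if self.data.ndim != 3:
            raise ValueError("data must be (n_trials, n_channels, n_times)")
        n_trials, n_channels, n_times = self.data.shape
        if n_times == 0:
            raise ValueError("empty time axis")
        if len(self.condition_labels) != n_trials:
            raise ValueError("condition_labels length must equal n_trials")
        if len(self.channel_types) != n_channels:
            raise ValueError("channel_types length must equal n_channels")
        if len(self.times) != n_times:
            raise ValueError("times length must equal n_times")
        dt = np.diff(self.times)
        if n_times > 1 and (np.any(dt <= 0) or not np.allclose(dt, dt[0])):
            raise ValueError("times must be strictly increasing and uniform")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def conditions(self) -> np.ndarray:
        return np.unique(self.condition_labels)


@dataclass(frozen=True)
class ThresholdPair:
    """One positive peak-to-peak rejection threshold per channel type.

    ``inf`` means "never reject" for that type.
    """

    threshold_by_type: Mapping[str, float]

    def __post_init__(self):
        for ctype, thr in self.threshold_by_type.items():
            if not thr > 0:
                raise ValueError(
                    f"threshold for {ctype!r} must be > 0, got {thr}"
                )


@dataclass
class GridSearchResult:
    """Outcome of the rejection-threshold grid search.

    ``objective[i, j]`` is the mean cross-subject pre/post correlation for
    thresholds ``(grid_values_by_type[type0][i], grid_values_by_type[type1][j])``;
    untenable cells hold NaN.
    """

    grid_values_by_type: dict[str, np.ndarray]
    objective: np.ndarray
    tenable_mask: np.ndarray
    optimal_cells: list[tuple[int, int]]
    chosen: ThresholdPair
    retained_counts: np.ndarray = field(default=None, repr=False)

    @property
    def channel_type_order(self) -> list[str]:
        return list(self.grid_values_by_type)

    def to_dict(self) -> dict:
        return {
            "grid_values_by_type": {
                k: list(map(float, v)) for k, v in self.grid_values_by_type.items()
            },
            "objective": [
                [None if not np.isfinite(v) else float(v) for v in row]
                for row in self.objective
            ],
            "tenable_mask": self.tenable_mask.astype(bool).tolist(),
            "optimal_cells": [list(map(int, c)) for c in self.optimal_cells],
            "chosen": {k: float(v) for k, v in self.chosen.threshold_by_type.items()},
        }


def peak_to_peak(epochs: EpochsSet) -> np.ndarray:
    """Per-trial, per-channel peak-to-peak amplitude (max - min over time).

    Returns
    -------
    ndarray, shape (n_trials, n_channels)
        Non-negative amplitudes.
    """
    epochs.validate()
    return epochs.data.max(axis=2) - epochs.data.min(axis=2)


def _per_type_max_ptp(epochs: EpochsSet) -> dict[str, np.ndarray]:
    """Max peak-to-peak over channels of each type, per trial."""
    ptp = peak_to_peak(epochs)
    out = {}
    for ctype in np.unique(epochs.channel_types):
        out[str(ctype)] = ptp[:, epochs.channel_types == ctype].max(axis=1)
    return out


def apply_rejection(epochs: EpochsSet, thresholds: ThresholdPair) -> np.ndarray:
    """Boolean mask of retained trials.

    A trial is rejected iff any channel's peak-to-peak amplitude exceeds the
    threshold for that channel's type.
    """
    present = set(map(str, np.unique(epochs.channel_types)))
    missing = present - set(thresholds.threshold_by_type)
    if missing:
        raise ValueError(f"no threshold for channel type(s): {sorted(missing)}")
    retained = np.ones(epochs.n_trials, dtype=bool)
    for ctype, maxptp in _per_type_max_ptp(epochs).items():
        retained &= maxptp <= thresholds.threshold_by_type[ctype]
    return retained


def reliability_objective(
    pre_evoked: Mapping[str, np.ndarray],
    post_evoked: Mapping[str, np.ndarray],
) -> float:
    """Mean across subjects of the pre/post evoked Pearson correlation.

    Subjects whose pre or post time course has zero variance contribute no
    correlation and are excluded with a logged warning.
    """
    if set(pre_evoked) != set(post_evoked):
        raise ValueError("pre and post must cover the same subjects")
    rs = []
    for subj in pre_evoked:
        x = np.asarray(pre_evoked[subj], dtype=float)
        y = np.asarray(post_evoked[subj], dtype=float)
        if x.shape != y.shape:
            raise ValueError(f"shape mismatch for subject {subj!r}")
        if np.std(x) == 0 or np.std(y) == 0:
            logger.warning(
                "subject %s has a zero-variance evoked time course; "
                "excluded from the reliability objective", subj
            )
            continue
        rs.append(np.corrcoef(x, y)[0, 1])
    if not rs:
        raise ValueError("no subject with nondegenerate evoked time courses")
    return float(np.mean(rs))


def make_threshold_grid(
    all_epochs: Sequence[EpochsSet],
    n_points: int = 5,
    lo_percentile: float = 50.0,
    hi_percentile: float = 100.0,
) -> dict[str, np.ndarray]:
    """Log-spaced candidate thresholds spanning the observed peak-to-peak
    distribution between two percentiles, separately per channel type."""
    pooled: dict[str, list[np.ndarray]] = {}
    for es in all_epochs:
        ptp = peak_to_peak(es)
        for ctype in np.unique(es.channel_types):
            pooled.setdefault(str(ctype), []).append(
                ptp[:, es.channel_types == ctype].ravel()
            )
    grid = {}
    for ctype, chunks in sorted(pooled.items()):
        vals = np.concatenate(chunks)
        lo = np.percentile(vals, lo_percentile)
        hi = np.percentile(vals, hi_percentile)
        if lo <= 0:
            lo = vals[vals > 0].min() if np.any(vals > 0) else 1.0
        grid[ctype] = np.geomspace(lo, hi, n_points)
    return grid


def tune_thresholds(
    all_epochs: Sequence[EpochsSet],
    grid_by_type: Mapping[str, Sequence[float]],
    tuning_roi_weights: np.ndarray | None = None,
    baseline_end: float = 0.0,
) -> GridSearchResult:
    """Grid search over threshold pairs maximizing evoked reliability.

    For every grid cell, rejection is applied to every subject/session; the
    cell is untenable if any subject x session x condition loses all trials.
    Otherwise each subject's grand-average evoked time course (all conditions
    pooled over retained trials, aggregated over the tuning ROI by weighted
    channel mean, restricted to post-stimulus samples) feeds the reliability
    objective.  ``optimal_cells`` are the tenable argmax cells; ``chosen`` is
    the most permissive of them (largest total retained-trial count, ties
    broken toward larger thresholds in channel-type order).

    Parameters
    ----------
    all_epochs : sequence of EpochsSet
        Both sessions for every subject.
    grid_by_type : mapping of channel type -> candidate thresholds
        Candidates are used in the order given; the objective matrix axes
        follow ``sorted(grid_by_type)``.
    tuning_roi_weights : ndarray, shape (n_channels,), optional
        Channel weights of the tuning ROI (default: uniform over channels).
    baseline_end : float
        Samples with ``t < baseline_end`` are excluded from the correlation
        (default drops the pre-stimulus baseline).
    """
    types = sorted(grid_by_type)
    if len(types) != 2:
        raise ValueError("grid_by_type must cover exactly two channel types")
    g0 = np.asarray(grid_by_type[types[0]], dtype=float)
    g1 = np.asarray(grid_by_type[types[1]], dtype=float)
    if g0.size == 0 or g1.size == 0:
        raise ValueError("empty threshold grid")

    subjects = sorted({es.subject_id for es in all_epochs})
    by_key = {(es.subject_id, es.session): es for es in all_epochs}
    for subj in subjects:
        for sess in ("pre", "post"):
            if (subj, sess) not in by_key:
                raise ValueError(f"subject {subj!r} is missing session {sess!r}")

    # Precompute, per subject/session: per-trial max ptp by type, per-trial
    # ROI course, and condition labels.  Grid cells then reduce to masked
    # averages of the precomputed courses.
    pre_computed = {}
    for key, es in by_key.items():
        w = (
            np.full(es.data.shape[1], 1.0 / es.data.shape[1])
            if tuning_roi_weights is None
            else np.asarray(tuning_roi_weights, dtype=float)
        )
        if w.shape[0] != es.data.shape[1]:
            raise ValueError("tuning_roi_weights length must equal n_channels")
        wsum = w.sum()
        if wsum == 0:
            raise ValueError("tuning_roi_weights sum to zero")
        tsel = es.times >= baseline_end
        roi_course = np.einsum("tcs,c->ts", es.data[:, :, tsel], w) / wsum
        pre_computed[key] = (_per_type_max_ptp(es), roi_course, es.condition_labels)

    n0, n1 = len(g0), len(g1)
    objective = np.full((n0, n1), np.nan)
    tenable = np.zeros((n0, n1), dtype=bool)
    retained_counts = np.zeros((n0, n1), dtype=int)
    first_offender = {}

    for i, t0 in enumerate(g0):
        for j, t1 in enumerate(g1):
            thr = {types[0]: t0, types[1]: t1}
            ok = True
            total_retained = 0
            evoked = {"pre": {}, "post": {}}
            for subj in subjects:
                for sess in ("pre", "post"):
                    maxptp, roi_course, labels = pre_computed[(subj, sess)]
                    mask = np.ones(len(labels), dtype=bool)
                    for ctype, vals in maxptp.items():
                        mask &= vals <= thr[ctype]
                    for cond in np.unique(labels):
                        if not np.any(mask & (labels == cond)):
                            ok = False
                            first_offender.setdefault(
                                (i, j), (subj, sess, str(cond))
                            )
                    if not ok:
                        break
                    total_retained += int(mask.sum())
                    evoked[sess][subj] = roi_course[mask].mean(axis=0)
                if not ok:
                    break
            if not ok:
                continue
            tenable[i, j] = True
            retained_counts[i, j] = total_retained
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # zero-variance corrcoef
                objective[i, j] = reliability_objective(
                    evoked["pre"], evoked["post"]
                )

    if not tenable.any():
        subj, sess, cond = next(iter(first_offender.values()))
        raise ValueError(
            "every grid cell is untenable; first offending cell: "
            f"subject {subj!r}, session {sess!r}, condition {cond!r}"
        )

    best = np.nanmax(np.where(tenable, objective, -np.inf))
    optimal = [
        (i, j)
        for i in range(n0)
        for j in range(n1)
        if tenable[i, j] and objective[i, j] >= best - 1e-12
    ]
    # Most permissive tie-break: retained-trial count, then threshold values.
    chosen_ij = max(
        optimal, key=lambda ij: (retained_counts[ij], g0[ij[0]], g1[ij[1]])
    )
    chosen = ThresholdPair({types[0]: g0[chosen_ij[0]], types[1]: g1[chosen_ij[1]]})
    logger.info(
        "grid search: %d/%d tenable cells, best objective %.4f, chosen %s",
        int(tenable.sum()), tenable.size, best, chosen.threshold_by_type,
    )
    return GridSearchResult(
        grid_values_by_type={types[0]: g0, types[1]: g1},
        objective=objective,
        tenable_mask=tenable,
        optimal_cells=optimal,
        chosen=chosen,
        retained_counts=retained_counts,
    )
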