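"""ROI time-course extraction and analysis-window definition.

A region of interest contains many vertices (or channels) whose signals
share a waveform up to orientation-dependent sign and noise.  The region is
collapsed to a single time course with the first right-singular vector of
the vertex x time matrix, scaled to match the mean per-vertex power and
sign-flipped toward the dominant source orientation.  The analysis window
is then derived from the data: the first sufficiently prominent peak of the
grand-average waveform defines a +/- 50 ms window, and all downstream
statistics are computed on the mean response inside that window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "VertexTimecourses",
    "ROITimecourse",
    "TimeWindow",
    "svd_flip_aggregate",
    "find_first_peak",
    "define_window",
    "window_mean",
]

#: half-width of the analysis window in seconds
WINDOW_HALF_WIDTH = 0.050

#: default post-stimulus range searched for the first peak, seconds
DEFAULT_SEARCH_RANGE = (0.050, 0.500)

#: minimum peak prominence, as a fraction of the grand-average range
PROMINENCE_FRACTION = 0.10


@dataclass
class VertexTimecourses:
    """Vertex-resolved ROI activity with dominant orientation signs."""

    data: np.ndarray  # (n_vertices, n_times)
    flip_vector: np.ndarray  # +/-1 per vertex
    times: np.ndarray  # seconds

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        self.flip_vector = np.asarray(self.flip_vector, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if not np.all(np.isin(self.flip_vector, (-1.0, 1.0))):
            raise ValueError("flip_vector entries must be +1 or -1")
        if self.data.shape[0] != self.flip_vector.shape[0]:
            raise ValueError("data row count must equal flip_vector length")
        if self.data.shape[1] != self.times.shape[0]:
            raise ValueError("data column count must equal times length")


@dataclass
class ROITimecourse:
    """Aggregated evoked time course for one subject/session/condition."""

    subject_id: str
    session: str
    condition: str
    course: np.ndarray
    times: np.ndarray

    def __post_init__(self):
        self.course = np.asarray(self.course, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.course.shape != self.times.shape:
            raise ValueError("course and times must have the same shape")
        if not np.all(np.isfinite(self.course)):
            raise ValueError("course must be finite")


@dataclass(frozen=True)
class TimeWindow:
    """Analysis window of fixed 100 ms width centred on the peak."""

    peak_latency: float
    start: float
    end: float

    def __post_init__(self):
        if not np.isclose(self.end - self.start, 2 * WINDOW_HALF_WIDTH):
            raise ValueError("window must be 100 ms wide")
        if not (
            np.isclose(self.start, self.peak_latency - WINDOW_HALF_WIDTH)
            and np.isclose(self.end, self.peak_latency + WINDOW_HALF_WIDTH)
        ):
            raise ValueError("window must be centred on the peak latency")


def svd_flip_aggregate(v: VertexTimecourses) -> np.ndarray:
    """Collapse vertex time courses to one ROI time course.

    With the singular-value decomposition ``data = U S Vt`` (singular values
    decreasing), the output is ``sign * scale * Vt[0]`` where
    ``scale = ||S||_2 / sqrt(n_vertices)`` matches the mean per-vertex power
    and ``sign`` is the sign of the inner product between the first left
    singular vector and the flip (dominant-orientation) vector.  All-zero
    input yields an all-zero output.
    """
    data = v.data
    if not np.any(data):
        return np.zeros(data.shape[1])
    U, s, Vt = np.linalg.svd(data, full_matrices=False)
    scale = np.linalg.norm(s) / np.sqrt(data.shape[0])
    sign = np.sign(U[:, 0] @ v.flip_vector)
    if sign == 0:
        sign = 1.0
    return sign * scale * Vt[0]


def find_first_peak(
    grand_average: np.ndarray,
    times: np.ndarray,
    search_range: tuple[float, float] = DEFAULT_SEARCH_RANGE,
    prominence_fraction: float = PROMINENCE_FRACTION,
) -> float:
    """Latency of the earliest prominent local maximum of the grand average.

    The grand average is the waveform pooled over subjects and conditions.
    Only samples inside ``search_range`` qualify, and a local maximum counts
    as a peak only if its prominence exceeds ``prominence_fraction`` of the
    grand-average range (peaks are ill-defined under noise otherwise).

    Returns
    -------
    float
        Peak latency in seconds, on the sampling grid.
    """
    y = np.asarray(grand_average, dtype=float)
    t = np.asarray(times, dtype=float)
    if y.shape != t.shape:
        raise ValueError("grand_average and times must have the same shape")
    floor = prominence_fraction * (y.max() - y.min())
    idx, _ = find_peaks(y, prominence=floor)
    in_range = idx[(t[idx] >= search_range[0]) & (t[idx] <= search_range[1])]
    if in_range.size == 0:
        raise ValueError(
            f"no peak with prominence >= {floor:.3g} in "
            f"{search_range[0]*1e3:.0f}-{search_range[1]*1e3:.0f} ms; widen the "
            "search range or lower the prominence floor"
        )
    return float(t[in_range[0]])


def define_window(
    peak_latency: float,
    epoch_span: tuple[float, float] | None = None,
) -> TimeWindow:
    """+/- 50 ms analysis window around the peak latency (seconds)."""
    start = peak_latency - WINDOW_HALF_WIDTH
    end = peak_latency + WINDOW_HALF_WIDTH
    if epoch_span is not None and (start < epoch_span[0] or end > epoch_span[1]):
        raise ValueError(
            f"window [{start:.3f}, {end:.3f}] s exceeds the epoch span "
            f"[{epoch_span[0]:.3f}, {epoch_span[1]:.3f}] s"
        )
    return TimeWindow(peak_latency=peak_latency, start=start, end=end)


def window_mean(course, window: TimeWindow, times=None) -> float:
    """Mean of the samples with ``start <= t <= end`` (closed interval).

    ``course`` may be a :class:`ROITimecourse` or a plain array (then
    ``times`` is required).
    """
    if isinstance(course, ROITimecourse):
        y, t = course.course, course.times
    else:
        if times is None:
            raise ValueError("times required for plain-array input")
        y = np.asarray(course, dtype=float)
        t = np.asarray(times, dtype=float)
    mask = (t >= window.start - 1e-12) & (t <= window.end + 1e-12)
    if not mask.any():
        raise ValueError("no samples inside the window")
    return float(y[mask].mean())
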