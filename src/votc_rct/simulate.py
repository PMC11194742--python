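"""Synthetic multi-subject MEG-style data with known ground truth.

The generator emulates the statistical structure of a two-arm randomized
controlled trial probing category-selective visual cortex: two intervention
groups (Letter vs Language), two sessions (pre / post intervention), three
stimulus conditions (Words / Faces / Cars) with 30 trials each, an evoked
response peaking ~175 ms after stimulus onset, two channel types on very
different amplitude scales (standing in for gradiometers and magnetometers),
per-trial white noise, a multiplicative per-subject gain, and rare
high-amplitude artifact trials.  Every downstream stage of the pipeline is
testable against the returned ground truth without any real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .rejection import EpochsSet
from .roi import VertexTimecourses

__all__ = [
    "GROUPS",
    "CONDITIONS",
    "SESSIONS",
    "SimulationConfig",
    "GroundTruth",
    "simulate_epochs",
    "simulate_vertex_timecourses",
    "simulate_behavioral",
    "simulate_response_table",
    "within_subject_response_sd",
    "planted_config",
]

GROUPS = ("Letter", "Language")
CONDITIONS = ("Words", "Faces", "Cars")
SESSIONS = ("pre", "post")
CHANNEL_TYPES = ("grad", "mag")

#: duration of the square artifact transient, seconds
ARTIFACT_DURATION = 0.050
#: fraction of one type's channels hit by an artifact transient
ARTIFACT_CHANNEL_FRACTION = 0.10


def _default_amplitudes() -> np.ndarray:
    # group x condition x session mean evoked amplitudes, arbitrary units;
    # equal cells = the pre-intervention "no category selectivity" state.
    return np.full((len(GROUPS), len(CONDITIONS), len(SESSIONS)), 5.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Design constants and noise/effect parameters of a synthetic study.

    ``amplitude_matrix`` has shape (group, condition, session) in the order
    (Letter, Language) x (Words, Faces, Cars) x (pre, post).
    """

    n_subjects_per_group: int = 24
    n_trials_per_condition: int = 30
    n_channels: int = 6  # per channel type
    sfreq: float = 100.0
    tmin: float = -0.100
    tmax: float = 1.000
    peak_latency: float = 0.180
    peak_width: float = 0.040  # Gaussian kernel sigma, seconds
    amplitude_matrix: np.ndarray = field(default_factory=_default_amplitudes)
    subject_gain_sd: float = 0.15  # multiplicative per-subject gain SD
    trial_noise_sd: float = 3.0
    #: lag-1 temporal autocorrelation of the trial noise (AR(1)).  The
    #: default is the theoretical lag-1 autocorrelation of ideal 40-Hz
    #: low-passed noise sampled at 100 Hz, sinc(2 * 40 * 0.01) ~ 0.234;
    #: set 0 for white noise.
    noise_ar1: float = 0.234
    artifact_rate: float = 0.05
    artifact_amplitude: float = 250.0
    channel_type_scales: tuple[float, float] = (1.0, 20.0)
    rng_seed: int = 0

    def __post_init__(self):
        for name in ("n_subjects_per_group", "n_trials_per_condition", "n_channels"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (0.0 <= self.artifact_rate <= 1.0):
            raise ValueError("artifact_rate must be in [0, 1]")
        for name in ("trial_noise_sd", "peak_width", "subject_gain_sd"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative")
        if self.peak_width <= 0:
            raise ValueError("peak_width must be positive")
        if not (-1.0 < self.noise_ar1 < 1.0):
            raise ValueError("noise_ar1 must be in (-1, 1)")
        amp = np.asarray(self.amplitude_matrix, dtype=float)
        if amp.shape != (len(GROUPS), len(CONDITIONS), len(SESSIONS)):
            raise ValueError(
                "amplitude_matrix must be group x condition x session, shape "
                f"{(len(GROUPS), len(CONDITIONS), len(SESSIONS))}"
            )
        if not (self.tmin <= self.peak_latency <= self.tmax):
            raise ValueError("epoch span must contain peak_latency")
        if self.artifact_rate > 0:
            # ~7 noise SDs bounds the peak-to-peak range of a few hundred
            # white-noise samples; artifacts must clear the clean signal.
            clean_ptp = amp.max() + 7.0 * self.trial_noise_sd
            if self.artifact_amplitude <= clean_ptp:
                raise ValueError(
                    "artifact_amplitude must exceed the clean-signal "
                    f"peak-to-peak (~{clean_ptp:.1f})"
                )

    @property
    def times(self) -> np.ndarray:
        n = int(round((self.tmax - self.tmin) * self.sfreq)) + 1
        return self.tmin + np.arange(n) / self.sfreq

    @property
    def kernel(self) -> np.ndarray:
        """Unimodal Gaussian temporal kernel, unit peak amplitude."""
        t = self.times
        return np.exp(-0.5 * ((t - self.peak_latency) / self.peak_width) ** 2)


@dataclass
class GroundTruth:
    """Everything the generator knows that an analyst would not."""

    amplitude_matrix: np.ndarray
    artifact_trial_index: list[tuple[str, str, str, int]]
    true_peak_latency: float
    subject_gains: dict[str, float]
    behavioral_effects: dict[str, float] = field(default_factory=dict)
    #: (subject, session, trial) -> channel indices carrying the transient
    artifact_channels: dict[tuple[str, str, int], np.ndarray] = field(
        default_factory=dict
    )

    def artifact_trials_for(self, subject_id: str, session: str) -> np.ndarray:
        """Sorted trial indices of planted artifacts in one EpochsSet."""
        return np.array(
            sorted(
                idx
                for subj, sess, _cond, idx in self.artifact_trial_index
                if subj == subject_id and sess == session
            ),
            dtype=int,
        )


def _ar1_noise(rng: np.random.Generator, shape: tuple, rho: float) -> np.ndarray:
    """Stationary unit-variance AR(1) noise along the last axis."""
    eps = rng.standard_normal(shape)
    if rho == 0.0:
        return eps
    from scipy.signal import lfilter

    innov = np.sqrt(1.0 - rho**2) * eps
    innov[..., 0] = eps[..., 0]
    return lfilter([1.0], [1.0, -rho], innov, axis=-1)


def _subject_ids(config: SimulationConfig) -> list[tuple[str, str]]:
    out = []
    for g, group in enumerate(GROUPS):
        for s in range(config.n_subjects_per_group):
            out.append((f"sub{g * config.n_subjects_per_group + s:03d}", group))
    return out


def simulate_epochs(
    config: SimulationConfig,
) -> tuple[list[EpochsSet], GroundTruth]:
    """Generate one :class:`EpochsSet` per subject x session.

    Each trial is ``gain * amplitude * kernel`` on every channel plus i.i.d.
    Gaussian noise, the whole trial multiplied by its channel-type scale.
    Artifact trials additionally carry a square transient of
    ``artifact_amplitude`` on a random 10% of the channels of one randomly
    chosen type.  Generation is a pure function of ``rng_seed``.
    """
    rng = np.random.default_rng(config.rng_seed)
    times = config.times
    kernel = config.kernel
    n_t = times.size
    n_ch = 2 * config.n_channels
    channel_types = np.repeat(CHANNEL_TYPES, config.n_channels)
    scales = np.repeat(config.channel_type_scales, config.n_channels)
    amp = np.asarray(config.amplitude_matrix, dtype=float)
    n_trials = len(CONDITIONS) * config.n_trials_per_condition
    labels = np.repeat(CONDITIONS, config.n_trials_per_condition)

    art_samples = max(1, int(round(ARTIFACT_DURATION * config.sfreq)))
    n_art_ch = max(1, int(np.ceil(ARTIFACT_CHANNEL_FRACTION * config.n_channels)))

    epochs_sets: list[EpochsSet] = []
    artifacts: list[tuple[str, str, str, int]] = []
    artifact_channels: dict[tuple[str, str, int], "np.ndarray"] = {}
    gains: dict[str, float] = {}
    for g, (subject_id, group) in enumerate(_subject_ids(config)):
        gain = 1.0 + config.subject_gain_sd * rng.standard_normal()
        gains[subject_id] = gain
        gidx = GROUPS.index(group)
        for sidx, session in enumerate(SESSIONS):
            signal = np.empty((n_trials, n_ch, n_t))
            cell_amp = gain * amp[gidx, :, sidx]  # per condition
            trial_amp = np.repeat(cell_amp, config.n_trials_per_condition)
            signal[:] = trial_amp[:, None, None] * kernel[None, None, :]
            signal += config.trial_noise_sd * _ar1_noise(
                rng, signal.shape, config.noise_ar1
            )
            if config.artifact_rate > 0:
                art_mask = rng.random(n_trials) < config.artifact_rate
                for trial in np.nonzero(art_mask)[0]:
                    ctype_idx = rng.integers(2)
                    chans = ctype_idx * config.n_channels + rng.choice(
                        config.n_channels, size=n_art_ch, replace=False
                    )
                    onset = rng.integers(0, max(1, n_t - art_samples))
                    signal[trial, chans[:, None], onset + np.arange(art_samples)] += (
                        config.artifact_amplitude
                    )
                    artifacts.append(
                        (subject_id, session, str(labels[trial]), int(trial))
                    )
                    artifact_channels[(subject_id, session, int(trial))] = chans
            signal *= scales[None, :, None]
            epochs_sets.append(
                EpochsSet(
                    subject_id=subject_id,
                    session=session,
                    group=group,
                    data=signal,
                    condition_labels=labels.copy(),
                    channel_types=channel_types.copy(),
                    times=times,
                    sfreq=config.sfreq,
                )
            )
    truth = GroundTruth(
        amplitude_matrix=amp,
        artifact_trial_index=artifacts,
        true_peak_latency=config.peak_latency,
        subject_gains=gains,
        artifact_channels=artifact_channels,
    )
    return epochs_sets, truth


def simulate_vertex_timecourses(
    n_vertices: int,
    base_course: np.ndarray,
    times: np.ndarray | None = None,
    orientation_signs: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> VertexTimecourses:
    """Vertex-level fixture: each vertex is ``sign * base_course + noise``."""
    if n_vertices < 1:
        raise ValueError("n_vertices must be >= 1")
    if not np.isfinite(noise_sd) or noise_sd < 0:
        raise ValueError("noise_sd must be finite and non-negative")
    base = np.asarray(base_course, dtype=float)
    if times is None:
        times = np.arange(base.size) / float(base.size)
    if orientation_signs is None:
        orientation_signs = np.ones(n_vertices)
    signs = np.asarray(orientation_signs, dtype=float)
    if signs.shape[0] != n_vertices:
        raise ValueError("orientation_signs length must equal n_vertices")
    rng = np.random.default_rng(seed)
    data = signs[:, None] * base[None, :]
    if noise_sd > 0:
        data = data + noise_sd * rng.standard_normal(data.shape)
    return VertexTimecourses(data=data, flip_vector=signs, times=np.asarray(times))


def simulate_behavioral(
    n_per_group: int,
    baseline_mean: float = 10.0,
    baseline_sd: float = 3.0,
    group_time_effect: float = 0.0,
    within_subject_sd: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Long behavioral score table (subject, group, time, score).

    Only the Letter (treatment) group's post scores receive
    ``group_time_effect`` on average; everything else is a stable
    per-subject baseline plus within-subject measurement noise.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    for name, v in (("baseline_sd", baseline_sd), ("within_subject_sd", within_subject_sd)):
        if not np.isfinite(v) or v < 0:
            raise ValueError(f"{name} must be finite and non-negative")
    rng = np.random.default_rng(seed)
    rows = []
    for g, group in enumerate(GROUPS):
        baselines = baseline_mean + baseline_sd * rng.standard_normal(n_per_group)
        for s in range(n_per_group):
            subj = f"sub{g * n_per_group + s:03d}"
            for time in SESSIONS:
                score = baselines[s] + within_subject_sd * rng.standard_normal()
                if time == "post" and group == "Letter":
                    score += group_time_effect
                rows.append((subj, group, time, score))
    return pd.DataFrame(rows, columns=["subject", "group", "time", "score"])


def simulate_response_table(
    n_per_group: int = 24,
    cell_means: np.ndarray | None = None,
    subject_intercept_sd: float = 1.0,
    subject_slope_sd: float = 0.3,
    resid_sd: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Window-averaged response table straight from a mixed-model truth.

    Response = cell mean + subject intercept + subject slopes on the
    within-subject dummy columns (condition, time and their interaction)
    + residual.  ``cell_means`` follows the (group, condition, session)
    layout of :class:`SimulationConfig.amplitude_matrix`; the default (all
    cells equal) is an exact null for every group-involving effect.
    """
    if cell_means is None:
        cell_means = _default_amplitudes()
    cell_means = np.asarray(cell_means, dtype=float)
    rng = np.random.default_rng(seed)
    rows = []
    for g, group in enumerate(GROUPS):
        for s in range(n_per_group):
            subj = f"sub{g * n_per_group + s:03d}"
            b0 = subject_intercept_sd * rng.standard_normal()
            slopes = subject_slope_sd * rng.standard_normal(5)
            for c, cond in enumerate(CONDITIONS):
                for t, time in enumerate(SESSIONS):
                    # dummy columns: Faces, Cars, post, Faces:post, Cars:post
                    z = np.array(
                        [c == 1, c == 2, t == 1, (c == 1) & (t == 1), (c == 2) & (t == 1)],
                        dtype=float,
                    )
                    resp = (
                        cell_means[g, c, t]
                        + b0
                        + z @ slopes
                        + resid_sd * rng.standard_normal()
                    )
                    rows.append((subj, group, cond, time, resp))
    return pd.DataFrame(
        rows, columns=["subject", "group", "condition", "time", "response"]
    )


def within_subject_response_sd(config: SimulationConfig) -> float:
    """Trial-to-trial SD of the window-averaged ROI response.

    The tuning/analysis ROI averages the ``n_channels`` independent
    unit-scale channels and the analysis window averages ``W`` samples whose
    noise has AR(1) autocorrelation ``rho``, so trial noise of SD ``sigma``
    contributes ``sigma * sqrt(f / (n_channels * W))`` to a single trial's
    window response, with the correlation inflation
    ``f = 1 + (2/W) * sum_{k<W} (W-k) rho^k``.  This is the "within-subject
    SD" unit in which planted intervention effects are expressed.
    """
    w = int(round(2 * 0.050 * config.sfreq)) + 1
    rho = config.noise_ar1
    k = np.arange(1, w)
    inflation = 1.0 + 2.0 * np.sum((w - k) * rho**k) / w
    return config.trial_noise_sd * np.sqrt(inflation / (config.n_channels * w))


def planted_config(
    effect_size: float = 1.0,
    base_amplitude: float = 5.0,
    rng_seed: int = 0,
    **overrides,
) -> SimulationConfig:
    """Study config with a Letter-group-only Words enhancement at post.

    ``effect_size`` is in units of the within-subject SD (see
    :func:`within_subject_response_sd`).
    """
    cfg = SimulationConfig(rng_seed=rng_seed, **overrides)
    amp = np.full_like(np.asarray(cfg.amplitude_matrix, float), base_amplitude)
    delta = effect_size * within_subject_response_sd(cfg)
    amp[GROUPS.index("Letter"), CONDITIONS.index("Words"), SESSIONS.index("post")] += delta
    return replace(cfg, amplitude_matrix=amp)
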