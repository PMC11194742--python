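import numpy as np
import pytest

from votc_rct import EpochsSet, SimulationConfig


@pytest.fixture
def times_100hz():
    return -0.1 + np.arange(111) / 100.0


@pytest.fixture
def make_epochs(times_100hz):
    """Factory for small hand-built EpochsSet objects."""

    def _make(data, conditions=None, channel_types=None, subject="s0",
              session="pre", group="Letter"):
        data = np.asarray(data, dtype=float)
        n_trials, n_channels, n_times = data.shape
        if conditions is None:
            conditions = np.array(["Words"] * n_trials)
        if channel_types is None:
            half = n_channels // 2
            channel_types = np.array(
                ["grad"] * (n_channels - half) + ["mag"] * half
            )
        times = -0.1 + np.arange(n_times) / 100.0
        return EpochsSet(
            subject_id=subject, session=session, group=group, data=data,
            condition_labels=np.asarray(conditions),
            channel_types=np.asarray(channel_types),
            times=times, sfreq=100.0,
        )

    return _make


@pytest.fixture
def small_config():
    """Small but structurally complete study configuration."""
    return SimulationConfig(
        n_subjects_per_group=4, n_trials_per_condition=8, n_channels=3,
        rng_seed=11,
    )
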