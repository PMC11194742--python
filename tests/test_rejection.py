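"""Peak-to-peak rejection rule, reliability objective, and grid search."""

import numpy as np
import pytest
from dataclasses import replace
from hypothesis import given, settings, strategies as st

from votc_rct import (
    SimulationConfig,
    ThresholdPair,
    apply_rejection,
    make_threshold_grid,
    peak_to_peak,
    reliability_objective,
    simulate_epochs,
    tune_thresholds,
)
from votc_rct.pipeline import _whitened_weights


def _clean_max_ptp(config):
    sets, _ = simulate_epochs(replace(config, artifact_rate=0.0))
    out = {"grad": 0.0, "mag": 0.0}
    for es in sets:
        ptp = peak_to_peak(es)
        for ct in out:
            out[ct] = max(out[ct], ptp[:, es.channel_types == ct].max())
    return out


class TestPeakToPeak:
    def test_constant_trial_is_zero(self, make_epochs):
        es = make_epochs(np.full((3, 4, 20), 7.0))
        assert np.array_equal(peak_to_peak(es), np.zeros((3, 4)))

    def test_single_sample_spike_height(self, make_epochs):
        data = np.zeros((1, 2, 30))
        data[0, 1, 12] = 4.5
        es = make_epochs(data)
        assert peak_to_peak(es)[0, 0] == 0.0
        assert peak_to_peak(es)[0, 1] == 4.5

    def test_matches_brute_force(self, make_epochs):
        rng = np.random.default_rng(3)
        data = rng.standard_normal((5, 6, 40))
        es = make_epochs(data)
        expected = np.array(
            [[max(data[t, c]) - min(data[t, c]) for c in range(6)] for t in range(5)]
        )
        assert np.allclose(peak_to_peak(es), expected)

    def test_empty_time_axis_errors(self, make_epochs):
        with pytest.raises(ValueError):
            make_epochs(np.zeros((2, 2, 0)))


class TestApplyRejection:
    def test_infinite_thresholds_retain_all(self, make_epochs):
        es = make_epochs(np.random.default_rng(0).standard_normal((6, 4, 20)))
        thr = ThresholdPair({"grad": np.inf, "mag": np.inf})
        assert apply_rejection(es, thr).all()

    def test_tiny_threshold_rejects_nonconstant(self, make_epochs):
        data = np.zeros((3, 4, 20))
        data[1] = np.random.default_rng(1).standard_normal((4, 20))
        es = make_epochs(data)
        thr = ThresholdPair({"grad": 1e-12, "mag": 1e-12})
        assert list(apply_rejection(es, thr)) == [True, False, True]

    def test_missing_channel_type_errors(self, make_epochs):
        es = make_epochs(np.zeros((2, 4, 20)))
        with pytest.raises(ValueError, match="mag"):
            apply_rejection(es, ThresholdPair({"grad": 1.0}))

    def test_zero_threshold_invalid(self):
        with pytest.raises(ValueError):
            ThresholdPair({"grad": 0.0, "mag": 1.0})

    def test_planted_artifacts_recovered_exactly(self, small_config):
        """A threshold between clean and artifact amplitudes rejects the
        planted trials and nothing else."""
        clean = _clean_max_ptp(small_config)
        cfg = replace(
            small_config, artifact_rate=0.1, artifact_amplitude=10 * clean["grad"]
        )
        sets, truth = simulate_epochs(cfg)
        thr = ThresholdPair({ct: 1.5 * clean[ct] for ct in clean})
        for es in sets:
            mask = apply_rejection(es, thr)
            assert set(np.nonzero(~mask)[0]) == set(
                truth.artifact_trials_for(es.subject_id, es.session)
            )

    @settings(max_examples=25, deadline=None)
    @given(
        t_grad=st.floats(0.1, 50.0),
        t_mag=st.floats(0.1, 1000.0),
        f_grad=st.floats(1.0, 5.0),
        f_mag=st.floats(1.0, 5.0),
    )
    def test_monotone_retention(self, t_grad, t_mag, f_grad, f_mag):
        """Enlarging either threshold never rejects more trials."""
        rng = np.random.default_rng(7)
        data = rng.standard_normal((20, 4, 30)) * np.array([1, 1, 20, 20])[None, :, None]
        from votc_rct import EpochsSet

        es = EpochsSet(
            "s", "pre", "Letter", data, np.array(["Words"] * 20),
            np.array(["grad", "grad", "mag", "mag"]),
            -0.1 + np.arange(30) / 100.0, 100.0,
        )
        small = apply_rejection(es, ThresholdPair({"grad": t_grad, "mag": t_mag}))
        large = apply_rejection(
            es, ThresholdPair({"grad": t_grad * f_grad, "mag": t_mag * f_mag})
        )
        assert np.all(large[small])  # retained set only grows


class TestReliabilityObjective:
    def test_identical_sessions_give_one(self):
        rng = np.random.default_rng(0)
        pre = {f"s{i}": rng.standard_normal(50) for i in range(5)}
        assert reliability_objective(pre, pre) == pytest.approx(1.0)

    def test_negated_sessions_give_minus_one(self):
        rng = np.random.default_rng(0)
        pre = {f"s{i}": rng.standard_normal(50) for i in range(5)}
        post = {k: -v for k, v in pre.items()}
        assert reliability_objective(pre, post) == pytest.approx(-1.0)

    def test_zero_variance_subject_excluded(self, caplog):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(30)
        pre = {"a": x, "b": np.zeros(30)}
        post = {"a": x.copy(), "b": np.zeros(30)}
        with caplog.at_level("WARNING"):
            r = reliability_objective(pre, post)
        assert r == pytest.approx(1.0)
        assert "zero-variance" in caplog.text

    def test_objective_decreases_with_noise(self):
        """Mean pre/post correlation falls monotonically as independent
        noise grows (seeded replicates)."""
        rng = np.random.default_rng(5)
        base = {f"s{i}": np.sin(np.linspace(0, 4, 80) + i) for i in range(8)}
        means = []
        for sd in (0.0, 0.5, 2.0, 8.0):
            reps = []
            for rep in range(20):
                pre = {k: v + sd * rng.standard_normal(80) for k, v in base.items()}
                post = {k: v + sd * rng.standard_normal(80) for k, v in base.items()}
                reps.append(reliability_objective(pre, post))
            means.append(np.mean(reps))
        assert all(a > b for a, b in zip(means, means[1:]))


class TestTuneThresholds:
    def test_artifact_free_noise_free_all_tenable_score_one(self):
        cfg = SimulationConfig(
            n_subjects_per_group=2, n_trials_per_condition=3, n_channels=2,
            trial_noise_sd=0.0, subject_gain_sd=0.0, artifact_rate=0.0,
        )
        sets, _ = simulate_epochs(cfg)
        grid = {"grad": [20.0, 40.0], "mag": [400.0, 800.0]}
        gsr = tune_thresholds(sets, grid)
        assert gsr.tenable_mask.all()
        assert np.allclose(gsr.objective, 1.0)
        # most permissive cell chosen among the (all-optimal) cells
        assert gsr.chosen.threshold_by_type == {"grad": 40.0, "mag": 800.0}

    def test_zero_like_threshold_row_untenable(self, small_config):
        sets, _ = simulate_epochs(small_config)
        grid = {"grad": [1e-9, 1e9], "mag": [1e-9, 1e9]}
        gsr = tune_thresholds(sets, grid)
        assert not gsr.tenable_mask[0].any()
        assert not gsr.tenable_mask[:, 0].any()
        assert gsr.tenable_mask[1, 1]

    def test_all_untenable_raises_with_offender(self, small_config):
        sets, _ = simulate_epochs(small_config)
        with pytest.raises(ValueError, match="untenable"):
            tune_thresholds(sets, {"grad": [1e-12], "mag": [1e-12]})

    def test_planted_artifacts_chosen_threshold_beats_no_rejection(
        self, small_config
    ):
        """With planted artifacts and a separating grid value, the chosen
        cell rejects exactly the artifacts and its objective is at least
        the no-rejection objective."""
        clean = _clean_max_ptp(small_config)
        cfg = replace(
            small_config, artifact_rate=0.1, artifact_amplitude=10 * clean["grad"]
        )
        sets, truth = simulate_epochs(cfg)
        grid = {ct: np.array([1.5 * clean[ct], 1e9]) for ct in clean}
        gsr = tune_thresholds(sets, grid, tuning_roi_weights=_whitened_weights(sets))
        assert gsr.optimal_cells == [(0, 0)]
        for es in sets:
            mask = apply_rejection(es, gsr.chosen)
            assert set(np.nonzero(~mask)[0]) == set(
                truth.artifact_trials_for(es.subject_id, es.session)
            )
        assert gsr.objective[0, 0] >= gsr.objective[1, 1]

    def test_grid_search_equals_naive_recomputation(self, small_config):
        """Exhaustive independent recomputation of a 3x3 grid reproduces
        the objective matrix, tenability mask and argmax."""
        clean = _clean_max_ptp(small_config)
        cfg = replace(
            small_config, artifact_rate=0.08, artifact_amplitude=10 * clean["grad"]
        )
        sets, _ = simulate_epochs(cfg)
        grid = {
            "grad": np.array([0.5 * clean["grad"], 1.5 * clean["grad"], 1e9]),
            "mag": np.array([0.5 * clean["mag"], 1.5 * clean["mag"], 1e9]),
        }
        w = _whitened_weights(sets)
        gsr = tune_thresholds(sets, grid, tuning_roi_weights=w)

        # naive path: no shared precomputation, plain loops
        subjects = sorted({es.subject_id for es in sets})
        by_key = {(es.subject_id, es.session): es for es in sets}
        naive_obj = np.full((3, 3), np.nan)
        naive_ten = np.zeros((3, 3), dtype=bool)
        for i, tg in enumerate(grid["grad"]):
            for j, tm in enumerate(grid["mag"]):
                thr = ThresholdPair({"grad": tg, "mag": tm})
                ok = True
                evoked = {"pre": {}, "post": {}}
                for subj in subjects:
                    for sess in ("pre", "post"):
                        es = by_key[(subj, sess)]
                        mask = apply_rejection(es, thr)
                        for cond in np.unique(es.condition_labels):
                            if not (mask & (es.condition_labels == cond)).any():
                                ok = False
                        if not ok:
                            break
                        tsel = es.times >= 0.0
                        course = (es.data[mask][:, :, tsel] * w[None, :, None]).sum(
                            axis=1
                        ) / w.sum()
                        evoked[sess][subj] = course.mean(axis=0)
                    if not ok:
                        break
                if ok:
                    naive_ten[i, j] = True
                    rs = [
                        np.corrcoef(evoked["pre"][s], evoked["post"][s])[0, 1]
                        for s in subjects
                    ]
                    naive_obj[i, j] = np.mean(rs)
        assert np.array_equal(gsr.tenable_mask, naive_ten)
        assert np.allclose(
            gsr.objective[naive_ten], naive_obj[naive_ten], atol=1e-12
        )
        best = np.nanmax(naive_obj)
        naive_opt = [
            (i, j) for i in range(3) for j in range(3)
            if naive_ten[i, j] and naive_obj[i, j] >= best - 1e-12
        ]
        assert gsr.optimal_cells == naive_opt

    def test_objective_invariant_to_trial_and_channel_order(self, small_config):
        sets, _ = simulate_epochs(small_config)
        grid = make_threshold_grid(sets, n_points=2)
        gsr1 = tune_thresholds(sets, grid)
        rng = np.random.default_rng(0)
        shuffled = []
        from votc_rct import EpochsSet

        for es in sets:
            tperm = rng.permutation(es.n_trials)
            cperm = rng.permutation(es.data.shape[1])
            shuffled.append(
                EpochsSet(
                    es.subject_id, es.session, es.group,
                    es.data[tperm][:, cperm, :],
                    es.condition_labels[tperm], es.channel_types[cperm],
                    es.times, es.sfreq,
                )
            )
        gsr2 = tune_thresholds(shuffled, grid)
        mask = gsr1.tenable_mask
        assert np.array_equal(mask, gsr2.tenable_mask)
        assert np.allclose(gsr1.objective[mask], gsr2.objective[mask])

    def test_grid_spans_percentiles_per_type(self, small_config):
        sets, _ = simulate_epochs(small_config)
        grid = make_threshold_grid(sets, n_points=4)
        assert set(grid) == {"grad", "mag"}
        for ct in grid:
            assert len(grid[ct]) == 4
            assert np.all(np.diff(grid[ct]) > 0)
        # mag scale ~20x grad scale
        assert grid["mag"][0] > 5 * grid["grad"][0]
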