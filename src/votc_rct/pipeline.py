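"""End-to-end orchestration of the RCT analysis.

Stages: rejection-threshold tuning -> per-condition evoked extraction with
the chosen thresholds -> SVD ROI aggregation -> data-driven analysis window
-> mixed-effects contrasts on window means -> temporal cluster permutation
on change scores -> competition correlations.  Every artifact carries the
seed and a configuration hash, and re-running with the same configuration
and seed reproduces byte-identical JSON.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import cluster as clu
from . import competition as comp
from .io import StudyConfig, config_hash, read_epochs, write_json
from .lme import (
    fit_condition_by_group_single_time,
    fit_group_by_time,
    fit_threeway,
)
from .rejection import (
    EpochsSet,
    apply_rejection,
    make_threshold_grid,
    tune_thresholds,
)
from .roi import (
    VertexTimecourses,
    define_window,
    find_first_peak,
    svd_flip_aggregate,
    window_mean,
)
from .simulate import CONDITIONS, SimulationConfig, planted_config, simulate_epochs

logger = logging.getLogger(__name__)

__all__ = ["extract_courses", "courses_to_response_table", "run_pipeline"]


def _whitened_weights(all_epochs: list[EpochsSet]) -> np.ndarray:
    """Scale-equalized tuning-ROI weights: 1 / per-type median peak-to-peak."""
    from .rejection import peak_to_peak

    ctypes = all_epochs[0].channel_types
    pooled = {str(ct): [] for ct in np.unique(ctypes)}
    for es in all_epochs:
        ptp = peak_to_peak(es)
        for ct in pooled:
            pooled[ct].append(ptp[:, es.channel_types == ct].ravel())
    med = {ct: np.median(np.concatenate(v)) for ct, v in pooled.items()}
    return np.array([1.0 / med[str(ct)] for ct in ctypes])


def _analysis_roi_channels(es: EpochsSet) -> np.ndarray:
    """Channels feeding the ROI aggregation: the unit-scale ('grad') type."""
    return np.nonzero(es.channel_types == "grad")[0]


def extract_courses(
    all_epochs: list[EpochsSet],
    retained_masks: dict[tuple[str, str], np.ndarray],
) -> pd.DataFrame:
    """Per subject/session/condition SVD-aggregated ROI time courses.

    The per-condition evoked (channels x time mean over retained trials) is
    collapsed over the analysis-ROI channels with the power-scaled,
    sign-flipped first right-singular vector.  Returns the wide table with
    one ``t_<seconds>`` column per sample.
    """
    rows = []
    times = all_epochs[0].times
    tcols = [f"t_{t:.4f}" for t in times]
    for es in all_epochs:
        mask = retained_masks[(es.subject_id, es.session)]
        chans = _analysis_roi_channels(es)
        for cond in CONDITIONS:
            sel = mask & (es.condition_labels == cond)
            if not sel.any():
                raise ValueError(
                    f"no retained trials for {es.subject_id}/{es.session}/{cond}"
                )
            evoked = es.data[sel][:, chans, :].mean(axis=0)
            course = svd_flip_aggregate(
                VertexTimecourses(
                    data=evoked, flip_vector=np.ones(len(chans)), times=times
                )
            )
            rows.append(
                {
                    "subject": es.subject_id,
                    "group": es.group,
                    "session": es.session,
                    "condition": cond,
                    **dict(zip(tcols, course)),
                }
            )
        n_kept = int(mask.sum())
        logger.info(
            "retention %s/%s: %d/%d trials", es.subject_id, es.session,
            n_kept, es.n_trials,
        )
    return pd.DataFrame(rows)


def courses_to_response_table(courses: pd.DataFrame, window) -> pd.DataFrame:
    """Window-average the wide course table into the long response table."""
    tcols = [c for c in courses.columns if c.startswith("t_")]
    times = np.array([float(c[2:]) for c in tcols])
    resp = [
        window_mean(row, window, times=times)
        for row in courses[tcols].to_numpy(dtype=float)
    ]
    out = courses[["subject", "group", "condition", "session"]].copy()
    out = out.rename(columns={"session": "time"})
    out["response"] = resp
    return out


def _change_series(courses: pd.DataFrame, cond_a: str, cond_b: str, tmin, tmax):
    """Per-group per-subject change in the (cond_a - cond_b) contrast."""
    tcols = [c for c in courses.columns if c.startswith("t_")]
    times = np.array([float(c[2:]) for c in tcols])
    tsel = (times >= tmin) & (times <= tmax)
    series = {"Letter": [], "Language": []}
    ids = {"Letter": [], "Language": []}
    wide = courses.set_index(["subject", "session", "condition"])[tcols]
    for subj, sub in courses.groupby("subject", sort=True):
        group = sub["group"].iloc[0]
        contrast = {}
        for session in ("pre", "post"):
            a = wide.loc[(subj, session, cond_a)].to_numpy(dtype=float)
            b = wide.loc[(subj, session, cond_b)].to_numpy(dtype=float)
            contrast[session] = a - b
        series[group].append((contrast["post"] - contrast["pre"])[tsel])
        ids[group].append(subj)
    return {
        g: clu.ChangeScoreSeries(
            group=g, data=np.array(series[g]), times=times[tsel], subject_ids=ids[g]
        )
        for g in series
    }


def run_pipeline(config: StudyConfig, out_dir: str | None = None) -> dict:
    """Run the full analysis and return (and optionally write) the report."""
    out = Path(out_dir or config.output_dir) if (out_dir or config.output_dir) else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    if config.epochs_paths:
        all_epochs = [read_epochs(p) for p in config.epochs_paths]
    else:
        sim_cfg = planted_config(
            effect_size=config.effect_size,
            rng_seed=config.seed,
            **config.simulation,
        )
        all_epochs, _truth = simulate_epochs(sim_cfg)

    # Stage 1: rejection-threshold tuning.  The tuning ROI pools both
    # channel types with scale-equalized weights (1 / per-type median
    # peak-to-peak), so artifacts on either sensor type degrade the
    # reliability objective.
    tuning_w = _whitened_weights(all_epochs)
    grid = make_threshold_grid(all_epochs, n_points=config.grid_points)
    gsr = tune_thresholds(all_epochs, grid, tuning_roi_weights=tuning_w)
    masks = {
        (es.subject_id, es.session): apply_rejection(es, gsr.chosen)
        for es in all_epochs
    }

    # Stage 2: ROI time courses and the analysis window.
    courses = extract_courses(all_epochs, masks)
    tcols = [c for c in courses.columns if c.startswith("t_")]
    times = np.array([float(c[2:]) for c in tcols])
    if config.window_mode == "auto":
        # pre-intervention grand average only, to avoid circularity with
        # post-only effects
        ga = courses[courses["session"] == "pre"][tcols].to_numpy(float).mean(axis=0)
        peak = find_first_peak(ga, times)
    else:
        lo, hi = map(float, config.window_mode.split(":"))
        peak = (lo + hi) / 2.0
    window = define_window(peak, epoch_span=(times[0], times[-1]))

    # Stage 3: mixed-effects contrasts on window means.
    table = courses_to_response_table(courses, window)
    res_threeway = fit_threeway(table)
    words = table[table["condition"] == "Words"]
    res_words_gt = fit_group_by_time(words)
    res_pre = fit_condition_by_group_single_time(table[table["time"] == "pre"])
    res_post = fit_condition_by_group_single_time(table[table["time"] == "post"])

    # Stage 4: temporal cluster permutation on change scores.
    clusters = {}
    for name, (ca, cb) in {
        "words_vs_cars": ("Words", "Cars"),
        "words_vs_faces": ("Words", "Faces"),
    }.items():
        ser = _change_series(courses, ca, cb, config.cluster_tmin, config.cluster_tmax)
        res = clu.permutation_test(
            ser["Letter"], ser["Language"],
            n_permutations=config.n_permutations, seed=config.seed,
        )
        clusters[name] = res.to_dict()

    # Stage 5: competition correlations.
    ctab = comp.change_table(courses, window)
    correlations = {}
    for other in ("faces", "cars"):
        for subset in ("all", "letter_only"):
            r, p, n = comp.change_correlation(ctab, other, subset)
            correlations[f"words_{other}_{subset}"] = {"r": r, "p": p, "n": n}

    retention = {
        f"{k[0]}/{k[1]}": int(m.sum()) for k, m in sorted(masks.items())
    }
    report = {
        "seed": config.seed,
        "config_hash": config_hash(config),
        "rejection": gsr.to_dict(),
        "window": {
            "peak_latency": window.peak_latency,
            "start": window.start,
            "end": window.end,
        },
        "retained_trials": retention,
        "lme": {
            "threeway": res_threeway.to_dict(),
            "words_group_by_time": res_words_gt.to_dict(),
            "pre_condition_by_group": res_pre.to_dict(),
            "post_condition_by_group": res_post.to_dict(),
        },
        "clusters": clusters,
        "correlations": correlations,
    }
    if out is not None:
        write_json(report, out / "report.json")
        write_json(dataclasses.asdict(config), out / "config_used.json")
        courses.to_csv(out / "roi_courses.csv", index=False)
        ctab.to_csv(out / "change_table.csv", index=False)
    return report
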