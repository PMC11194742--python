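"""Competition analysis: coupling between category change scores.

Neuronal recycling predicts that an intervention-driven increase in the
word response comes at the expense of other categories, which would appear
as a negative correlation between the per-subject change (post - pre) in
the window-averaged Words response and the change in the Faces or Cars
response.  A positive correlation instead indicates a shared gain factor
(e.g. alertness or signal quality) linking the categories.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .roi import TimeWindow, window_mean

logger = logging.getLogger(__name__)

__all__ = ["change_table", "change_correlation"]

_CONDS = ("words", "faces", "cars")


def change_table(courses: pd.DataFrame, window: TimeWindow) -> pd.DataFrame:
    """Per-subject window-averaged change scores for every condition.

    Parameters
    ----------
    courses : DataFrame
        Wide ROI time-course table with columns ``subject``, ``group``,
        ``session``, ``condition`` and one ``t_<seconds>`` column per time
        sample (the CSV layout written by the extraction stage).
    window : TimeWindow
        Analysis window for the response average.

    Returns
    -------
    DataFrame with one row per subject and columns ``subject``, ``group``,
    ``d_words``, ``d_faces``, ``d_cars``.  Subjects missing a session for
    any condition are dropped with a warning.
    """
    tcols = [c for c in courses.columns if c.startswith("t_")]
    if not tcols:
        raise ValueError("no time-sample columns (t_<seconds>) found")
    times = np.array([float(c[2:]) for c in tcols])
    rows = []
    for subj, sub in courses.groupby("subject", sort=True):
        rec = {"subject": subj, "group": sub["group"].iloc[0]}
        complete = True
        for cond in ("Words", "Faces", "Cars"):
            vals = {}
            for session in ("pre", "post"):
                sel = sub[(sub["condition"] == cond) & (sub["session"] == session)]
                if len(sel) != 1:
                    complete = False
                    break
                vals[session] = window_mean(
                    sel[tcols].to_numpy(dtype=float)[0], window, times=times
                )
            if not complete:
                break
            rec[f"d_{cond.lower()}"] = vals["post"] - vals["pre"]
        if complete:
            rows.append(rec)
        else:
            logger.warning("subject %s dropped: missing session/condition", subj)
    return pd.DataFrame(rows, columns=["subject", "group", "d_words", "d_faces", "d_cars"])


def change_correlation(
    table: pd.DataFrame, other: str, subset: str = "all"
) -> tuple[float, float, int]:
    """Pearson correlation between the Words change and another category's.

    Parameters
    ----------
    table : DataFrame
        Output of :func:`change_table`.
    other : {"faces", "cars"}
        The comparison category.
    subset : {"all", "letter_only"}
        Full sample or the Letter intervention arm only.

    Returns
    -------
    (r, p, n) : two-sided p from the exact t transform of r.
    """
    if other not in ("faces", "cars"):
        raise ValueError("other must be 'faces' or 'cars'")
    if subset == "letter_only":
        table = table[table["group"] == "Letter"]
    elif subset != "all":
        raise ValueError("subset must be 'all' or 'letter_only'")
    x = table["d_words"].to_numpy(dtype=float)
    y = table[f"d_{other}"].to_numpy(dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 subjects after subsetting")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in a change score")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), int(n)
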