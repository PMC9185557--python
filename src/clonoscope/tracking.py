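"""Longitudinal clonotype tracking and selection (log2 fold-change) analysis.

Clonotypes are matched across a patient's timepoints by exact key
identity (CDR3 aa, V, J).  A trajectory table holds the relative
frequency of each tracked clone at each timepoint (0 with an
"undetected" flag when absent).  Selection between a pre- and a
post-treatment repertoire is classified from log2(f_post / f_pre):
POSITIVE above the neutral band, NEGATIVE below, NEUTRAL inside it;
clones seen on only one side are INDETERMINATE unless one-template
imputation is enabled.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import Repertoire, Timepoint


class TrackSelection(str, enum.Enum):
    TOP_N_AT_BASELINE = "TOP_N_AT_BASELINE"
    TOP_N_ANY = "TOP_N_ANY"
    EXPLICIT_LIST = "EXPLICIT_LIST"


class SelectionClass(str, enum.Enum):
    POSITIVE = "POSITIVE"
    NEGATIVE = "NEGATIVE"
    NEUTRAL = "NEUTRAL"
    INDETERMINATE = "INDETERMINATE"


@dataclass
class TrajectoryTable:
    """Clone x timepoint frequency matrix plus a detection mask."""

    frequencies: pd.DataFrame  # index: clonotype key, columns: Timepoint
    detected: pd.DataFrame  # same shape, boolean

    @property
    def timepoints(self) -> list[Timepoint]:
        return list(self.frequencies.columns)


def track_clonotypes(
    reps: list[Repertoire],
    selection: TrackSelection | str = TrackSelection.TOP_N_AT_BASELINE,
    n: int = 10,
    clonotypes: list | None = None,
    level: str = "aa",
) -> TrajectoryTable:
    """Track a clone set across one patient's ordered timepoints.

    ``TOP_N_AT_BASELINE`` picks the ``n`` most abundant clones of the
    earliest timepoint (the default, matching top-clone trajectory
    plots); ``TOP_N_ANY`` the union of each timepoint's top ``n``;
    ``EXPLICIT_LIST`` uses ``clonotypes`` as given.
    """
    selection = TrackSelection(selection)
    if len(reps) < 2:
        raise ValueError("tracking requires at least 2 timepoints")
    patients = {r.patient_id for r in reps}
    if len(patients) > 1:
        raise ValueError(f"repertoires span multiple patients: {sorted(patients)}")
    reps = sorted(reps, key=lambda r: r.timepoint)
    if len({r.timepoint for r in reps}) != len(reps):
        raise ValueError("duplicate timepoints in tracking input")
    freq_by_tp = {r.timepoint: r.frequencies(level=level) for r in reps}

    if selection is TrackSelection.EXPLICIT_LIST:
        if not clonotypes:
            raise ValueError("EXPLICIT_LIST requires a clonotype list")
        keys = list(clonotypes)
    elif selection is TrackSelection.TOP_N_AT_BASELINE:
        keys = list(freq_by_tp[reps[0].timepoint].nlargest(n).index)
    else:
        keys = []
        seen = set()
        for r in reps:
            for key in freq_by_tp[r.timepoint].nlargest(n).index:
                if key not in seen:
                    seen.add(key)
                    keys.append(key)

    cols = [r.timepoint for r in reps]
    freq = pd.DataFrame(0.0, index=pd.Index(keys).unique(), columns=cols)
    det = pd.DataFrame(False, index=freq.index, columns=cols)
    for tp in cols:
        series = freq_by_tp[tp]
        present = freq.index.intersection(series.index)
        freq.loc[present, tp] = series.loc[present].to_numpy()
        det.loc[present, tp] = True
    if not det.any(axis=1).all() and selection is not TrackSelection.EXPLICIT_LIST:
        raise AssertionError("tracked clone undetected at every timepoint")
    return TrajectoryTable(frequencies=freq, detected=det)


def top_clonotype_mass(table: TrajectoryTable) -> pd.Series:
    """Summed relative frequency of the tracked clones per timepoint."""
    return table.frequencies.sum(axis=0)


def selection_analysis(
    pre: Repertoire,
    post: Repertoire,
    min_freq: float = 0.0,
    neutral_band: float = 1.0,
    impute: bool = False,
    level: str = "aa",
) -> pd.DataFrame:
    """Classify clones as under positive/negative selection across therapy.

    A clone is "detected" in a repertoire when its frequency is > 0 and
    >= ``min_freq``.  For clones detected on both sides, log2fc =
    log2(f_post/f_pre); |log2fc| <= ``neutral_band`` is NEUTRAL.
    One-sided detections are INDETERMINATE, unless ``impute=True``
    replaces the missing side by the one-template floor 1/T of that
    repertoire.  Returns one row per clone in the union of detected sets:
    columns clonotype, f_pre, f_post, log2fc, selection.
    """
    f_pre = pre.frequencies(level=level)
    f_post = post.frequencies(level=level)
    d_pre = f_pre[(f_pre > 0) & (f_pre >= min_freq)]
    d_post = f_post[(f_post > 0) & (f_post >= min_freq)]
    floor_pre = 1.0 / pre.total_templates()
    floor_post = 1.0 / post.total_templates()

    keys = d_pre.index.union(d_post.index)
    rows = []
    for key in keys:
        in_pre = key in d_pre.index
        in_post = key in d_post.index
        fp = float(d_pre[key]) if in_pre else 0.0
        fq = float(d_post[key]) if in_post else 0.0
        if in_pre and in_post:
            log2fc = float(np.log2(fq / fp))
            cls = _classify_fc(log2fc, neutral_band)
        elif impute:
            fp_eff = fp if in_pre else floor_pre
            fq_eff = fq if in_post else floor_post
            log2fc = float(np.log2(fq_eff / fp_eff))
            cls = _classify_fc(log2fc, neutral_band)
        else:
            log2fc = np.nan
            cls = SelectionClass.INDETERMINATE
        rows.append({"clonotype": key, "f_pre": fp, "f_post": fq,
                     "log2fc": log2fc, "selection": cls.value})
    return pd.DataFrame(rows, columns=["clonotype", "f_pre", "f_post", "log2fc", "selection"])


def _classify_fc(log2fc: float, band: float) -> SelectionClass:
    if log2fc > band:
        return SelectionClass.POSITIVE
    if log2fc < -band:
        return SelectionClass.NEGATIVE
    return SelectionClass.NEUTRAL
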