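"""Four-bin clonotype abundance spectrum and oligoclonal/polyclonal labels.

Every clone is placed in exactly one abundance bin by its relative
frequency X:

* HYPEREXPANDED: X > 0.01
* LARGE:         0.001 < X <= 0.01
* MEDIUM:        1e-4 < X <= 0.001
* SMALL_RARE:    X <= 1e-4

The boundary X == 1e-4 is closed downward into SMALL_RARE, consistent
with the closed upper bounds of the other bins.  A patient whose summed
LARGE + HYPEREXPANDED template mass (the "expanded fraction") exceeds
0.25 is labelled OLIGOCLONAL; exactly 0.25 falls to POLYCLONAL so the
oligoclonal label remains the strict >25% claim.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import RESPONSE_GROUPS, Repertoire, Timepoint

#: (small/rare | medium | large | hyperexpanded) frequency cut points.
DEFAULT_BIN_THRESHOLDS = (1e-4, 1e-3, 1e-2)
#: Expanded-fraction cut for the oligoclonal label.
DEFAULT_OLIGO_THRESHOLD = 0.25


class AbundanceBin(str, enum.Enum):
    HYPEREXPANDED = "HYPEREXPANDED"
    LARGE = "LARGE"
    MEDIUM = "MEDIUM"
    SMALL_RARE = "SMALL_RARE"


class PatientLabel(str, enum.Enum):
    OLIGOCLONAL = "OLIGOCLONAL"
    POLYCLONAL = "POLYCLONAL"


BIN_ORDER = [
    AbundanceBin.SMALL_RARE,
    AbundanceBin.MEDIUM,
    AbundanceBin.LARGE,
    AbundanceBin.HYPEREXPANDED,
]


@dataclass(frozen=True)
class SpectrumProfile:
    """Per-sample template-mass fractions of the four abundance bins."""

    sample_id: str
    bin_fractions: Mapping[AbundanceBin, float]
    expanded_fraction: float
    patient_label: PatientLabel | None = None


def classify_bin(x: float, thresholds: Sequence[float] = DEFAULT_BIN_THRESHOLDS) -> AbundanceBin:
    """Assign one abundance bin to a clone of relative frequency ``x``."""
    small, large, hyper = thresholds
    if not 0.0 < x <= 1.0:
        raise ValueError(f"clone frequency must be in (0, 1], got {x}")
    if x > hyper:
        return AbundanceBin.HYPEREXPANDED
    if x > large:
        return AbundanceBin.LARGE
    if x > small:
        return AbundanceBin.MEDIUM
    return AbundanceBin.SMALL_RARE


def spectrum_fractions(
    rep: Repertoire,
    thresholds: Sequence[float] = DEFAULT_BIN_THRESHOLDS,
    productive_only: bool = True,
) -> SpectrumProfile:
    """Summed template frequency per abundance bin for one sample."""
    freqs = rep.frequencies(productive_only=productive_only).to_numpy()
    return _fractions_from_freqs(rep.sample_id, freqs, thresholds)


def _fractions_from_freqs(
    sample_id: str, freqs: np.ndarray, thresholds: Sequence[float] = DEFAULT_BIN_THRESHOLDS
) -> SpectrumProfile:
    small, large, hyper = thresholds
    fractions = {
        AbundanceBin.HYPEREXPANDED: float(freqs[freqs > hyper].sum()),
        AbundanceBin.LARGE: float(freqs[(freqs > large) & (freqs <= hyper)].sum()),
        AbundanceBin.MEDIUM: float(freqs[(freqs > small) & (freqs <= large)].sum()),
        AbundanceBin.SMALL_RARE: float(freqs[freqs <= small].sum()),
    }
    expanded = fractions[AbundanceBin.LARGE] + fractions[AbundanceBin.HYPEREXPANDED]
    return SpectrumProfile(sample_id=sample_id, bin_fractions=fractions, expanded_fraction=expanded)


def stratify_patient(
    profile: SpectrumProfile, threshold: float = DEFAULT_OLIGO_THRESHOLD
) -> PatientLabel:
    """OLIGOCLONAL iff the expanded fraction strictly exceeds the threshold."""
    if profile.expanded_fraction > threshold:
        return PatientLabel.OLIGOCLONAL
    return PatientLabel.POLYCLONAL


def label_profile(
    profile: SpectrumProfile, threshold: float = DEFAULT_OLIGO_THRESHOLD
) -> SpectrumProfile:
    """Return a copy of ``profile`` with the patient label attached."""
    return SpectrumProfile(
        sample_id=profile.sample_id,
        bin_fractions=profile.bin_fractions,
        expanded_fraction=profile.expanded_fraction,
        patient_label=stratify_patient(profile, threshold),
    )


def cohort_spectrum_table(
    profiles: Mapping[str, SpectrumProfile],
    cohort: pd.DataFrame,
    response_groups: Mapping[str, str] = RESPONSE_GROUPS,
    threshold: float = DEFAULT_OLIGO_THRESHOLD,
) -> pd.DataFrame:
    """Per-response-group counts and proportions of oligoclonal patients.

    ``profiles`` maps patient_id -> that patient's baseline SpectrumProfile
    (one per patient).  Patients whose response does not map to a group
    (e.g. NOT_ASSESSED) are excluded.
    """
    rows = []
    for _, meta in cohort.iterrows():
        pid = meta["patient_id"]
        if pid not in profiles:
            continue
        group = response_groups.get(meta["best_response"])
        if group is None:
            continue
        label = stratify_patient(profiles[pid], threshold)
        rows.append({"patient_id": pid, "group": group,
                     "oligoclonal": label is PatientLabel.OLIGOCLONAL})
    if not rows:
        raise ValueError("no patients with both a baseline profile and a response group")
    df = pd.DataFrame(rows)
    out = (
        df.groupby("group")
        .agg(n=("oligoclonal", "size"), n_oligoclonal=("oligoclonal", "sum"))
        .reset_index()
    )
    out["proportion"] = out["n_oligoclonal"] / out["n"]
    return out


def baseline_profiles(
    reps: Sequence[Repertoire],
    baseline_timepoint: Timepoint = Timepoint.SCREENING,
    thresholds: Sequence[float] = DEFAULT_BIN_THRESHOLDS,
) -> dict[str, SpectrumProfile]:
    """One baseline SpectrumProfile per patient.

    Raises if a patient has more than one sample at the baseline
    timepoint (an explicit selector must then be applied upstream).
    """
    out: dict[str, SpectrumProfile] = {}
    for rep in reps:
        if rep.timepoint is not baseline_timepoint:
            continue
        if rep.patient_id in out:
            raise ValueError(f"patient {rep.patient_id}: multiple baseline samples")
        out[rep.patient_id] = spectrum_fractions(rep, thresholds)
    return out


def spectrum_concordance(
    profile_a: SpectrumProfile, profile_b: SpectrumProfile
) -> tuple[dict[AbundanceBin, float], AbundanceBin]:
    """Per-bin absolute difference between two spectra of the same sample,
    and the bin with the largest discrepancy (when sequencing depth
    differs, the rarest bins are the expected locus)."""
    deltas = {
        b: abs(profile_a.bin_fractions[b] - profile_b.bin_fractions[b]) for b in AbundanceBin
    }
    worst = max(deltas, key=lambda b: deltas[b])
    return deltas, worst
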