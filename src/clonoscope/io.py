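"""Repertoire I/O: parse, validate, filter and write TCR-beta clone tables.

The canonical in-memory container is :class:`Repertoire`, a thin wrapper
around a pandas DataFrame with one row per rearrangement (clonotype).  All
downstream modules (diversity, spectrum, usage, tracking, sharing) consume
this object.  Two on-disk dialects are supported: the AIRR Rearrangement
TSV standard and immunoSEQ-style export TSVs (column aliases configurable).
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("clonoscope")

# ---------------------------------------------------------------------------
# Constants and sentinels
# ---------------------------------------------------------------------------

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: Sentinel gene labels for calls that could not be resolved to one segment.
AMBIGUOUS = "AMBIGUOUS"
UNKNOWN = "UNKNOWN"
SENTINELS = frozenset({AMBIGUOUS, UNKNOWN})

#: Canonical column order of the internal table.
TABLE_COLUMNS = [
    "rearrangement_nt",
    "cdr3_aa",
    "v_gene",
    "d_gene",
    "j_gene",
    "templates",
    "productive",
]


class Timepoint(enum.IntEnum):
    """Ordered sample timepoints of the trial schedule."""

    SCREENING = 0
    LEAD_IN = 1
    C1D1 = 2
    C4D1 = 3
    EOT = 4


RESPONSE_LEVELS = ("CR", "PR", "SD", "PD", "NOT_ASSESSED")
#: Default collapsing of best response into the three analysis groups.
RESPONSE_GROUPS = {"CR": "CR/PR", "PR": "CR/PR", "SD": "SD", "PD": "PD"}


class RepertoireFormatError(ValueError):
    """A clone table violates the expected on-disk format."""


class EmptyRepertoireError(ValueError):
    """An operation requires at least one (productive) record."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClonotypeRecord:
    """One rearrangement row.

    ``templates`` counts sequenced input molecules; ``productive`` marks
    in-frame, stop-free rearrangements whose CDR3 encodes a functional
    peptide.  Gene labels follow IMGT-style naming (``TRBV12-1``,
    ``TRBJ2-7``) or a sentinel (:data:`AMBIGUOUS`, :data:`UNKNOWN`).
    """

    rearrangement_nt: str
    cdr3_aa: str
    v_gene: str
    d_gene: str
    j_gene: str
    templates: int
    productive: bool

    def __post_init__(self) -> None:
        if self.templates < 0:
            raise ValueError("templates must be >= 0")
        if self.productive:
            if not self.cdr3_aa:
                raise ValueError("productive records need a CDR3 aa sequence")
            bad = set(self.cdr3_aa) - set(AA_ALPHABET)
            if bad:
                raise ValueError(f"invalid amino acids in CDR3: {sorted(bad)}")


@dataclass
class Repertoire:
    """One sample's clonotype set with provenance.

    ``table`` has the columns in :data:`TABLE_COLUMNS`, one row per
    clonotype (duplicate keys are merged at construction with templates
    summed).  Frequencies are computed on demand via :meth:`frequencies`
    so the productive/all-template denominator choice stays explicit.
    """

    sample_id: str
    patient_id: str = ""
    timepoint: Timepoint = Timepoint.SCREENING
    table: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=TABLE_COLUMNS))

    def __post_init__(self) -> None:
        missing = [c for c in TABLE_COLUMNS if c not in self.table.columns]
        if missing:
            raise RepertoireFormatError(f"repertoire table missing columns: {missing}")
        self.table = _merge_duplicates(self.table, self.sample_id)

    # -- construction -----------------------------------------------------

    @classmethod
    def from_records(
        cls,
        records: Iterable[ClonotypeRecord],
        sample_id: str,
        patient_id: str = "",
        timepoint: Timepoint = Timepoint.SCREENING,
    ) -> "Repertoire":
        rows = [
            (r.rearrangement_nt, r.cdr3_aa, r.v_gene, r.d_gene, r.j_gene, r.templates, r.productive)
            for r in records
        ]
        table = pd.DataFrame(rows, columns=TABLE_COLUMNS)
        return cls(sample_id=sample_id, patient_id=patient_id, timepoint=timepoint, table=table)

    # -- accessors --------------------------------------------------------

    @property
    def records(self) -> list[ClonotypeRecord]:
        """Materialize rows as :class:`ClonotypeRecord` objects."""
        return [
            ClonotypeRecord(*row)
            for row in self.table[TABLE_COLUMNS].itertuples(index=False, name=None)
        ]

    def __len__(self) -> int:
        return len(self.table)

    @property
    def n_productive(self) -> int:
        return int(self.table["productive"].sum())

    def total_templates(self, productive_only: bool = True) -> int:
        t = self.table
        if productive_only:
            t = t[t["productive"]]
        return int(t["templates"].sum())

    def clonotype_keys(self, level: str = "aa") -> pd.Index:
        """Clonotype keys: aa level = (cdr3_aa, v_gene, j_gene); nt level =
        the nucleotide rearrangement."""
        if level == "aa":
            return pd.MultiIndex.from_frame(self.table[["cdr3_aa", "v_gene", "j_gene"]])
        if level == "nt":
            return pd.Index(self.table["rearrangement_nt"])
        raise ValueError(f"unknown key level {level!r}")

    def frequencies(self, level: str = "aa", productive_only: bool = True) -> pd.Series:
        """Relative clone frequencies keyed by clonotype.

        The denominator is the productive template count by default (the
        convention for productive clonality metrics); ``productive_only=
        False`` switches to the all-template denominator.
        """
        t = self.table
        if productive_only:
            t = t[t["productive"]]
        if t.empty:
            raise EmptyRepertoireError(f"sample {self.sample_id}: no records to normalize")
        if level == "aa":
            keys = pd.MultiIndex.from_frame(t[["cdr3_aa", "v_gene", "j_gene"]])
        else:
            keys = pd.Index(t["rearrangement_nt"])
        counts = pd.Series(t["templates"].to_numpy(), index=keys)
        total = counts.sum()
        if total <= 0:
            raise EmptyRepertoireError(f"sample {self.sample_id}: zero template mass")
        return counts / total


def _merge_duplicates(table: pd.DataFrame, sample_id: str) -> pd.DataFrame:
    """Collapse rows sharing (cdr3_aa, v, j, nt, productive) by summing templates."""
    if table.empty:
        return table.reset_index(drop=True)
    keys = ["rearrangement_nt", "cdr3_aa", "v_gene", "d_gene", "j_gene", "productive"]
    if not table.duplicated(subset=keys).any():
        return table.reset_index(drop=True)
    n_before = len(table)
    merged = table.groupby(keys, as_index=False, sort=False)["templates"].sum()
    merged = merged[TABLE_COLUMNS]
    logger.warning(
        "sample %s: merged %d duplicate clonotype rows", sample_id, n_before - len(merged)
    )
    return merged


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

#: immunoSEQ export dialect: canonical field -> accepted header aliases
#: (case-insensitive).  Exports vary by Analyzer version, hence a map.
IMMUNOSEQ_ALIASES: dict[str, tuple[str, ...]] = {
    "rearrangement_nt": ("rearrangement", "nucleotide", "nucleotide_sequence"),
    "cdr3_aa": ("amino_acid", "aminoacid", "cdr3_amino_acid", "aa_sequence"),
    "v_gene": ("v_resolved", "v_gene", "vgenename", "vmaxresolved"),
    "d_gene": ("d_resolved", "d_gene", "dgenename", "dmaxresolved"),
    "j_gene": ("j_resolved", "j_gene", "jgenename", "jmaxresolved"),
    "templates": ("templates", "count (templates/reads)", "count", "reads", "seq_reads"),
    "productive": ("frame_type", "sequencestatus", "frame type"),
}

#: Truthy/falsy spellings of the AIRR ``productive`` column.
_BOOL_MAP = {
    "t": True, "true": True, "1": True, "yes": True,
    "f": False, "false": False, "0": False, "no": False, "": False,
}

#: immunoSEQ frame_type values that mark a productive rearrangement.
_PRODUCTIVE_FRAMES = {"in", "in-frame", "inframe", "productive"}


def _normalize_gene(call: object) -> str:
    """Map a raw gene call to an IMGT-style label or a sentinel.

    Multi-assignments (``TCRBV12-03/12-04``, comma lists) and explicit
    'unresolved'/'ambiguous' markers become :data:`AMBIGUOUS`; blanks
    become :data:`UNKNOWN`.
    """
    if call is None or (isinstance(call, float) and np.isnan(call)):
        return UNKNOWN
    s = str(call).strip()
    if not s or s.lower() in {"na", "nan", "none", "unknown"}:
        return UNKNOWN
    if s in SENTINELS:
        return s
    low = s.lower()
    if "/" in s or "," in s or low in {"unresolved", "ambiguous"} or " or " in low:
        return AMBIGUOUS
    return s.replace("TCRB", "TRB")


def _parse_templates(value: object) -> int | None:
    try:
        n = int(float(value))
    except (TypeError, ValueError):
        return None
    return n if n >= 0 else None


def _find_column(columns: Sequence[str], aliases: tuple[str, ...]) -> str | None:
    lower = {c.lower().strip(): c for c in columns}
    for a in aliases:
        if a in lower:
            return lower[a]
    return None


def read_immunoseq_tsv(
    path: str | Path,
    sample_id: str | None = None,
    patient_id: str = "",
    timepoint: Timepoint = Timepoint.SCREENING,
    aliases: dict[str, tuple[str, ...]] | None = None,
) -> Repertoire:
    """Read an immunoSEQ-style export TSV into a :class:`Repertoire`.

    Mandatory fields (via the alias map) are the nucleotide rearrangement,
    template count and frame type; rows whose template count cannot be
    parsed are dropped with a row-indexed warning.
    """
    path = Path(path)
    aliases = aliases or IMMUNOSEQ_ALIASES
    raw = _read_table(path)
    colmap: dict[str, str] = {}
    for canonical, names in aliases.items():
        col = _find_column(list(raw.columns), names)
        if col is None:
            if canonical in {"rearrangement_nt", "templates", "productive"}:
                raise RepertoireFormatError(
                    f"{path.name}: missing mandatory column for {canonical!r} "
                    f"(accepted aliases: {list(names)})"
                )
        else:
            colmap[canonical] = col

    rows = []
    bad_rows = []
    for idx, row in enumerate(raw.itertuples(index=False)):
        rowd = dict(zip(raw.columns, row))
        templates = _parse_templates(rowd[colmap["templates"]])
        if templates is None:
            bad_rows.append(idx)
            continue
        frame = str(rowd[colmap["productive"]]).strip().lower()
        productive = frame in _PRODUCTIVE_FRAMES
        cdr3 = rowd.get(colmap.get("cdr3_aa", ""), "")
        cdr3 = "" if cdr3 is None or str(cdr3).lower() in {"nan", "na"} else str(cdr3).strip()
        rows.append(
            (
                str(rowd[colmap["rearrangement_nt"]]).strip().upper(),
                cdr3,
                _normalize_gene(rowd.get(colmap.get("v_gene", ""))),
                _normalize_gene(rowd.get(colmap.get("d_gene", ""))),
                _normalize_gene(rowd.get(colmap.get("j_gene", ""))),
                templates,
                productive,
            )
        )
    if bad_rows:
        logger.warning("%s: rejected %d rows with unparseable counts (rows %s)",
                       path.name, len(bad_rows), bad_rows[:20])
    table = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    return Repertoire(sample_id=sample_id or path.stem, patient_id=patient_id,
                      timepoint=timepoint, table=table)


#: AIRR Rearrangement standard columns used on read/write.
AIRR_COLUMNS = ["sequence", "junction_aa", "v_call", "d_call", "j_call",
                "duplicate_count", "productive"]


def read_airr_tsv(
    path: str | Path,
    sample_id: str | None = None,
    patient_id: str = "",
    timepoint: Timepoint = Timepoint.SCREENING,
) -> Repertoire:
    """Read an AIRR Rearrangement TSV (``junction_aa``, ``v_call``,
    ``j_call``, ``duplicate_count``, ``productive``) into a Repertoire."""
    path = Path(path)
    raw = _read_table(path)
    lower = {c.lower(): c for c in raw.columns}
    for required in ("junction_aa", "duplicate_count", "productive"):
        if required not in lower:
            raise RepertoireFormatError(f"{path.name}: missing mandatory AIRR column {required!r}")

    def col(name: str, default: object = "") -> pd.Series:
        if name in lower:
            return raw[lower[name]]
        return pd.Series([default] * len(raw))

    rows = []
    bad_rows = []
    seq = col("sequence")
    jaa = col("junction_aa")
    v = col("v_call")
    d = col("d_call")
    j = col("j_call")
    dup = col("duplicate_count")
    prod = col("productive")
    for idx in range(len(raw)):
        templates = _parse_templates(dup.iloc[idx])
        if templates is None:
            bad_rows.append(idx)
            continue
        p_raw = str(prod.iloc[idx]).strip().lower()
        if p_raw not in _BOOL_MAP:
            bad_rows.append(idx)
            continue
        cdr3 = str(jaa.iloc[idx]).strip()
        if cdr3.lower() in {"nan", "na"}:
            cdr3 = ""
        nt = str(seq.iloc[idx]).strip().upper()
        if nt.lower() == "nan":
            nt = ""
        rows.append(
            (nt, cdr3, _normalize_gene(v.iloc[idx]), _normalize_gene(d.iloc[idx]),
             _normalize_gene(j.iloc[idx]), templates, _BOOL_MAP[p_raw])
        )
    if bad_rows:
        logger.warning("%s: rejected %d unparseable rows (rows %s)",
                       path.name, len(bad_rows), bad_rows[:20])
    table = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    return Repertoire(sample_id=sample_id or path.stem, patient_id=patient_id,
                      timepoint=timepoint, table=table)


def _read_table(path: Path) -> pd.DataFrame:
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise EmptyRepertoireError(f"{path.name}: empty file") from exc
    return raw


def write_airr(rep: Repertoire, path: str | Path) -> None:
    """Write a Repertoire as an AIRR Rearrangement TSV.

    Sentinel gene labels are serialized as empty calls; an empty
    repertoire yields a header-only file.
    """
    t = rep.table
    out = pd.DataFrame(
        {
            "sequence": t["rearrangement_nt"],
            "junction_aa": t["cdr3_aa"],
            "v_call": t["v_gene"].where(~t["v_gene"].isin(SENTINELS), ""),
            "d_call": t["d_gene"].where(~t["d_gene"].isin(SENTINELS), ""),
            "j_call": t["j_gene"].where(~t["j_gene"].isin(SENTINELS), ""),
            "duplicate_count": t["templates"],
            "productive": np.where(t["productive"], "T", "F"),
        },
        columns=AIRR_COLUMNS,
    )
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Filtering and summary
# ---------------------------------------------------------------------------


def filter_productive(rep: Repertoire) -> Repertoire:
    """Retain only productive rearrangements.

    Raises :class:`EmptyRepertoireError` when nothing survives; idempotent
    on already-filtered repertoires.
    """
    kept = rep.table[rep.table["productive"]].reset_index(drop=True)
    if kept.empty:
        raise EmptyRepertoireError(f"sample {rep.sample_id}: no productive records")
    return Repertoire(sample_id=rep.sample_id, patient_id=rep.patient_id,
                      timepoint=rep.timepoint, table=kept)


def total_rearrangements(rep: Repertoire, level: str = "aa") -> int:
    """Repertoire richness: number of unique productive clonotype keys.

    ``level='aa'`` counts (CDR3 aa, V, J) identities (default); ``'nt'``
    counts unique nucleotide rearrangements.
    """
    t = rep.table[rep.table["productive"]]
    if t.empty:
        logger.warning("sample %s: no productive records, richness 0", rep.sample_id)
        return 0
    if level == "aa":
        return int(len(t[["cdr3_aa", "v_gene", "j_gene"]].drop_duplicates()))
    if level == "nt":
        return int(t["rearrangement_nt"].nunique())
    raise ValueError(f"unknown key level {level!r}")


# ---------------------------------------------------------------------------
# Cohort metadata
# ---------------------------------------------------------------------------

COHORT_COLUMNS = ["patient_id", "best_response", "p16_status", "smoking", "os_time", "os_event"]


def read_cohort_table(path: str | Path) -> pd.DataFrame:
    """Read and validate the per-patient clinical metadata CSV.

    Expected columns: patient_id, best_response (CR/PR/SD/PD/NOT_ASSESSED),
    p16_status (POS/NEG), smoking (CURRENT/PREVIOUS/NEVER), os_time (days),
    os_event (0/1).
    """
    df = pd.read_csv(path)
    return validate_cohort_table(df)


def validate_cohort_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise RepertoireFormatError(f"cohort table missing columns: {missing}")
    if df["patient_id"].duplicated().any():
        dupes = df.loc[df["patient_id"].duplicated(), "patient_id"].tolist()
        raise RepertoireFormatError(f"duplicate patient ids: {dupes}")
    bad = df.loc[~df["best_response"].isin(RESPONSE_LEVELS), "best_response"]
    if len(bad):
        raise RepertoireFormatError(f"invalid best_response values: {sorted(set(bad))}")
    if (df["os_time"] <= 0).any():
        raise RepertoireFormatError("os_time must be positive")
    df = df.copy()
    df["os_event"] = df["os_event"].astype(bool)
    return df
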