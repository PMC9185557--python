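"""End-to-end orchestration: ingest -> diversity -> spectrum -> usage ->
tracking -> sharing -> survival, with a reproducibility manifest.

The pipeline consumes a sample manifest CSV (sample_id, patient_id,
timepoint, file) pointing at AIRR TSVs, plus the cohort metadata CSV,
and writes one CSV/JSON artifact per stage into the output directory.
The manifest.json echoes the full effective configuration and the
SHA-256 of every output, so two runs on identical inputs are
hash-identical and auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diversity as dv
from . import io as rio
from . import sharing, spectrum, tracking, usage
from . import survival as surv

logger = logging.getLogger("clonoscope")


@dataclass
class PipelineConfig:
    """Everything a full run needs; defaults are the published thresholds."""

    sample_manifest: str = ""
    cohort_table: str = ""
    output_dir: str = "clonoscope_out"
    key_level: str = "aa"
    productive_denominator: bool = True
    bin_thresholds: tuple[float, float, float] = spectrum.DEFAULT_BIN_THRESHOLDS
    oligo_threshold: float = spectrum.DEFAULT_OLIGO_THRESHOLD
    hill_q_grid: tuple[float, ...] = dv.DEFAULT_Q_GRID
    usage_segment: str = "J"
    usage_weighting: str = "TEMPLATE"
    cluster_k: int = 2
    tracking_top_n: int = 10
    sharing_max_dist: int = 1
    selection_band: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        t = self.bin_thresholds
        if not (0 < t[0] < t[1] < t[2] < 1):
            raise ValueError("bin thresholds must be strictly increasing in (0,1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("bin_thresholds", "hill_q_grid"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_samples(config: PipelineConfig) -> list[rio.Repertoire]:
    manifest = pd.read_csv(config.sample_manifest)
    required = {"sample_id", "patient_id", "timepoint", "file"}
    missing = required - set(manifest.columns)
    if missing:
        raise rio.RepertoireFormatError(f"sample manifest missing columns: {sorted(missing)}")
    base = Path(config.sample_manifest).parent
    reps = []
    for _, row in manifest.iterrows():
        path = Path(row["file"])
        if not path.is_absolute():
            path = base / path
        reps.append(
            rio.read_airr_tsv(
                path,
                sample_id=row["sample_id"],
                patient_id=row["patient_id"],
                timepoint=rio.Timepoint[row["timepoint"]],
            )
        )
    logger.info("loaded %d samples", len(reps))
    return reps


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the manifest dictionary."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = rio.read_cohort_table(config.cohort_table)
    reps = [rio.filter_productive(r) for r in _load_samples(config)]
    outputs: dict[str, Path] = {}

    # -- diversity ---------------------------------------------------------
    logger.info("stage diversity: %d samples", len(reps))
    div_rows = []
    for rep in reps:
        freqs = rep.frequencies(level=config.key_level,
                                productive_only=config.productive_denominator)
        res = dv.diversity_result(freqs.to_numpy(), config.hill_q_grid)
        row = {
            "sample_id": rep.sample_id,
            "patient_id": rep.patient_id,
            "timepoint": rep.timepoint.name,
            "total_rearrangements": rio.total_rearrangements(rep, config.key_level),
            "simpson_clonality": res.simpson_clonality,
            "shannon_entropy": res.shannon_entropy,
            "shannon_clonality": res.shannon_clonality,
        }
        row.update({f"hill_q{q:g}": v for q, v in res.hill_profile.items()})
        div_rows.append(row)
    outputs["diversity"] = out / "diversity.csv"
    pd.DataFrame(div_rows).to_csv(outputs["diversity"], index=False)

    # -- spectrum + stratification ----------------------------------------
    logger.info("stage spectrum")
    spec_rows = []
    baselines: dict[str, spectrum.SpectrumProfile] = {}
    for rep in reps:
        prof = spectrum.spectrum_fractions(rep, config.bin_thresholds,
                                           config.productive_denominator)
        label = spectrum.stratify_patient(prof, config.oligo_threshold)
        spec_rows.append(
            {
                "sample_id": rep.sample_id,
                "patient_id": rep.patient_id,
                "timepoint": rep.timepoint.name,
                **{b.value: prof.bin_fractions[b] for b in spectrum.BIN_ORDER},
                "expanded_fraction": prof.expanded_fraction,
                "patient_label": label.value,
            }
        )
        if rep.timepoint is rio.Timepoint.SCREENING:
            if rep.patient_id in baselines:
                raise ValueError(f"patient {rep.patient_id}: multiple baseline samples")
            baselines[rep.patient_id] = prof
    outputs["spectrum"] = out / "spectrum.csv"
    pd.DataFrame(spec_rows).to_csv(outputs["spectrum"], index=False)

    group_table = spectrum.cohort_spectrum_table(baselines, cohort,
                                                 threshold=config.oligo_threshold)
    outputs["spectrum_groups"] = out / "spectrum_groups.csv"
    group_table.to_csv(outputs["spectrum_groups"], index=False)

    # -- gene usage --------------------------------------------------------
    logger.info("stage usage")
    baseline_reps = [r for r in reps if r.timepoint is rio.Timepoint.SCREENING]
    profiles = [usage.usage_profile(r, config.usage_segment, config.usage_weighting)
                for r in baseline_reps]
    usage_df = pd.DataFrame([p.frequencies for p in profiles],
                            index=[p.sample_id for p in profiles]).fillna(0.0)
    outputs["usage"] = out / "usage.csv"
    usage_df.to_csv(outputs["usage"])
    jsd = usage.jsd_matrix(profiles)
    outputs["usage_jsd"] = out / "usage_jsd.csv"
    jsd.to_csv(outputs["usage_jsd"])
    if len(profiles) >= 3:
        clus = usage.usage_cluster(profiles, "HIERARCHICAL", k=config.cluster_k,
                                   seed=config.seed)
        cl_df = pd.DataFrame({
            "sample_id": clus.sample_ids, "cluster": clus.labels,
            "mds1": clus.embedding[:, 0], "mds2": clus.embedding[:, 1],
        })
        outputs["usage_clusters"] = out / "usage_clusters.csv"
        cl_df.to_csv(outputs["usage_clusters"], index=False)

    # -- clonotype tracking ------------------------------------------------
    logger.info("stage tracking")
    by_patient: dict[str, list[rio.Repertoire]] = {}
    for rep in reps:
        by_patient.setdefault(rep.patient_id, []).append(rep)
    track_rows = []
    for pid, prs in sorted(by_patient.items()):
        if len(prs) < 2:
            continue
        table = tracking.track_clonotypes(prs, n=config.tracking_top_n,
                                          level=config.key_level)
        mass = tracking.top_clonotype_mass(table)
        for key, row in table.frequencies.iterrows():
            for tp, freq in row.items():
                track_rows.append({
                    "patient_id": pid,
                    "clonotype": "|".join(map(str, key)) if isinstance(key, tuple) else key,
                    "timepoint": tp.name, "frequency": freq,
                    "detected": bool(table.detected.loc[key, tp]),
                    "top_mass": mass[tp],
                })
    outputs["tracking"] = out / "tracking.csv"
    pd.DataFrame(track_rows, columns=["patient_id", "clonotype", "timepoint",
                                      "frequency", "detected", "top_mass"]
                 ).to_csv(outputs["tracking"], index=False)

    # -- cross-sample sharing ---------------------------------------------
    logger.info("stage sharing")
    clusters = sharing.cluster_cdr3(baseline_reps, max_dist=config.sharing_max_dist)
    share_rows = [
        {
            "representative": c.representative,
            "n_sequences": len(c.sequences),
            "n_sources": len(c.sources),
            "max_pairwise_distance": c.max_pairwise_distance,
            "shared": c.shared,
            "sources": ";".join(c.sources),
        }
        for c in clusters
        if c.shared
    ]
    outputs["sharing"] = out / "shared_clusters.csv"
    pd.DataFrame(share_rows, columns=["representative", "n_sequences", "n_sources",
                                      "max_pairwise_distance", "shared", "sources"]
                 ).to_csv(outputs["sharing"], index=False)

    # -- survival ----------------------------------------------------------
    logger.info("stage survival")
    labels = {
        pid: spectrum.stratify_patient(prof, config.oligo_threshold).value
        for pid, prof in baselines.items()
    }
    report = surv.stratified_survival_report(cohort, labels)
    surv_json = {
        name: {"statistic": entry["statistic"], "p_value": entry["p_value"],
               "n": entry["n"]}
        for name, entry in report.items()
        if name != "covariates"
    }
    outputs["survival"] = out / "survival_tests.json"
    outputs["survival"].write_text(json.dumps(surv_json, indent=2, sort_keys=True))
    outputs["covariates"] = out / "cox_covariates.csv"
    report["covariates"].to_csv(outputs["covariates"], index=False)

    # -- manifest ----------------------------------------------------------
    manifest = {
        "config": asdict(config),
        "n_samples": len(reps),
        "outputs": {name: {"file": p.name, "sha256": _sha256(p)}
                    for name, p in sorted(outputs.items())},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("pipeline complete: %d artifacts in %s", len(outputs), out)
    return manifest
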