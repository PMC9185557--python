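"""Synthetic TCR-beta cohort generator.

Stands in for a non-deposited peripheral-blood immunoSEQ dataset.  Each
patient carries a latent clonal state (OLIGOCLONAL or POLYCLONAL) drawn
with a response-group-specific prevalence; the state sets the summed
mass of a handful of expanded "spike" clones (each above the LARGE-bin
floor), the rest of the repertoire being a truncated power-law tail of
rare clones.  Template counts are multinomial draws at a configured
sequencing depth, CDR3s follow the canonical CASS...F junction shape
with lengths centred on 13-15 aa, V/J genes are drawn from per-group
usage profiles (responders carry the TRBJ2-7-skewed profile), and
overall survival is exponential with a hazard multiplied for
oligoclonal patients.  Every sampled quantity is reproducible from one
cohort seed via deterministic per-patient substreams.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import AA_ALPHABET, Repertoire, Timepoint
from .spectrum import PatientLabel

# ---------------------------------------------------------------------------
# Default gene-usage and clinical profiles
# ---------------------------------------------------------------------------

TRBJ_GENES = [
    "TRBJ1-1", "TRBJ1-2", "TRBJ1-3", "TRBJ1-4", "TRBJ1-5", "TRBJ1-6",
    "TRBJ2-1", "TRBJ2-2", "TRBJ2-3", "TRBJ2-4", "TRBJ2-5", "TRBJ2-6", "TRBJ2-7",
]

TRBV_GENES = [
    "TRBV2", "TRBV4-1", "TRBV5-1", "TRBV6-1", "TRBV7-2", "TRBV9", "TRBV10-3",
    "TRBV11-2", "TRBV12-1", "TRBV15", "TRBV18", "TRBV19-1", "TRBV20-1",
    "TRBV28", "TRBV30",
]


def _normalize(weights: Mapping[str, float]) -> dict[str, float]:
    total = float(sum(weights.values()))
    return {g: w / total for g, w in weights.items()}


def _responder_j_profile() -> dict[str, float]:
    """TRBJ2-7-dominant profile (mass 0.175, within the 15-20% band seen
    in most responders), TRBJ2-1 and TRBJ2-3 next."""
    w = {g: 0.0565 for g in TRBJ_GENES}
    w["TRBJ2-7"] = 0.175
    w["TRBJ2-1"] = 0.14
    w["TRBJ2-3"] = 0.12
    return _normalize(w)


def _nonresponder_j_profile() -> dict[str, float]:
    """Near-uniform profile: several majors close to 10%, TRBJ2-7 still
    the single most frequent gene."""
    w = {g: 0.055 for g in TRBJ_GENES}
    for g in ("TRBJ1-1", "TRBJ1-2", "TRBJ2-1", "TRBJ2-3", "TRBJ2-5"):
        w[g] = 0.10
    w["TRBJ2-7"] = 0.115
    return _normalize(w)


def _shared_v_profile() -> dict[str, float]:
    """V usage shared across groups, TRBV12-1 and TRBV19-1 elevated."""
    w = {g: 1.0 for g in TRBV_GENES}
    w["TRBV12-1"] = 2.5
    w["TRBV19-1"] = 2.2
    return _normalize(w)


DEFAULT_J_PROFILES = {
    "CR/PR": _responder_j_profile(),
    "SD": _normalize({g: (_responder_j_profile()[g] + _nonresponder_j_profile()[g]) / 2
                      for g in TRBJ_GENES}),
    "PD": _nonresponder_j_profile(),
}

#: One fixed codon per amino acid, for deterministic aa -> nt back-translation.
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "AGC", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class SyntheticCohortConfig:
    """Generator parameters; defaults are the emulated study conditions.

    Group sizes mirror the analysed cohort (8 CR/PR, 20 SD, 10 PD) and
    the per-group oligoclonal prevalences its reported proportions
    (2/8, 9/20, 7/10).  Expanded-fraction ranges are disjoint so the
    latent state is recoverable by the >25% rule; ``hard_mode`` overlaps
    them for stress testing.  Hazards are per day.
    """

    seed: int = 0
    group_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"CR/PR": 8, "SD": 20, "PD": 10})
    oligo_prevalence: Mapping[str, float] = field(
        default_factory=lambda: {"CR/PR": 0.25, "SD": 0.45, "PD": 0.70})
    templates_per_sample: int = 20_000
    n_clones: int = 12_000
    oligo_expanded_range: tuple[float, float] = (0.30, 0.70)
    poly_expanded_range: tuple[float, float] = (0.02, 0.20)
    spike_min_freq: float = 4e-3
    max_spikes: int = 12
    tail_exponent: float = 2.0
    tail_freq_floor: float = 1e-7
    tail_freq_max: float = 3e-4
    nonproductive_fraction: float = 0.15
    n_nonproductive_clones: int = 300
    usage_profiles: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: dict(DEFAULT_J_PROFILES))
    v_profile: Mapping[str, float] = field(default_factory=_shared_v_profile)
    cdr3_length_dist: Mapping[int, float] = field(
        default_factory=lambda: {13: 0.3, 14: 0.4, 15: 0.3})
    baseline_hazard: float = np.log(2) / 600.0
    hazard_ratio_oligo: float = 2.0
    censoring_hazard: float = np.log(2) / 1200.0
    top_drift_log2: Mapping[str, float] = field(
        default_factory=lambda: {"CR/PR": 0.5, "SD": 0.0, "PD": 0.0})
    drift_volatility: float = 0.15
    n_drifted_clones: int = 10
    hard_mode: bool = False

    def __post_init__(self) -> None:
        for group, p in self.oligo_prevalence.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence for {group} outside [0,1]")
        if self.templates_per_sample <= 0:
            raise ValueError("templates_per_sample must be positive")
        if self.n_clones <= 0:
            raise ValueError("n_clones must be positive")
        lo_o, hi_o = self.effective_oligo_range
        lo_p, hi_p = self.effective_poly_range
        if not (0 < lo_o < hi_o <= 1 and 0 < lo_p < hi_p <= 1):
            raise ValueError("expanded-fraction ranges must be valid sub-intervals of (0,1]")
        if not self.hard_mode and hi_p >= lo_o:
            raise ValueError("oligo and poly expanded ranges must be disjoint")
        if hi_o + self.nonproductive_fraction >= 1.0 and hi_o >= 1.0:
            raise ValueError("infeasible spiked mass")
        for group, prof in self.usage_profiles.items():
            if abs(sum(prof.values()) - 1.0) > 1e-9:
                raise ValueError(f"usage profile for {group} not normalized")
        if abs(sum(self.cdr3_length_dist.values()) - 1.0) > 1e-9:
            raise ValueError("cdr3_length_dist not normalized")
        for length in self.cdr3_length_dist:
            if length < 7:
                raise ValueError("CDR3 lengths must leave room for the CASS...F frame")
        if not 0 < self.tail_freq_floor < self.tail_freq_max < 1e-3:
            raise ValueError("tail frequencies must stay below the LARGE-bin boundary")
        # the tail must be able to carry up to (1 - lo_p) mass with every
        # clone below ~1.5 * tail_freq_max
        if self.n_clones * self.tail_freq_max < 1.5 * (1.0 - min(lo_o, lo_p)):
            raise ValueError(
                "n_clones * tail_freq_max too small: the rare-clone tail cannot "
                "hold the non-spiked mass below the LARGE-bin boundary"
            )
        if not 1e-3 < self.spike_min_freq <= min(lo_o, lo_p):
            raise ValueError("spike_min_freq must exceed the LARGE-bin boundary "
                             "and fit inside both expanded ranges")

    @property
    def effective_oligo_range(self) -> tuple[float, float]:
        return (0.18, 0.45) if self.hard_mode else self.oligo_expanded_range

    @property
    def effective_poly_range(self) -> tuple[float, float]:
        return (0.05, 0.28) if self.hard_mode else self.poly_expanded_range


# ---------------------------------------------------------------------------
# Low-level vectorized helpers
# ---------------------------------------------------------------------------

_AA_BYTES = np.frombuffer(AA_ALPHABET.encode(), dtype="S1")
_AA_INDEX = {aa: i for i, aa in enumerate(AA_ALPHABET)}
_CODON_BYTES = np.array([list(_CODON[aa]) for aa in AA_ALPHABET], dtype="S1")


def _random_cdr3(n: int, length: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """n random CDR3s of one length: 'CASS' + random core + 'F'.

    Returns (aa array <U{length}>, nt array of back-translated codons).
    """
    core = length - 5
    idx = np.empty((n, length), dtype=np.int64)
    for pos, aa in enumerate("CASS"):
        idx[:, pos] = _AA_INDEX[aa]
    idx[:, 4:-1] = rng.integers(0, len(AA_ALPHABET), size=(n, core))
    idx[:, -1] = _AA_INDEX["F"]
    aa = _AA_BYTES[idx].view(f"S{length}").ravel().astype(str)
    nt = _CODON_BYTES[idx].reshape(n, 3 * length).view(f"S{3 * length}").ravel().astype(str)
    return aa, nt


def _sample_power_law(
    n: int, exponent: float, lo: float, hi: float, rng: np.random.Generator
) -> np.ndarray:
    """n i.i.d. draws from a power-law density f^-a truncated to [lo, hi]."""
    u = rng.random(n)
    if abs(exponent - 1.0) < 1e-12:
        return np.exp(np.log(lo) + u * (np.log(hi) - np.log(lo)))
    b = 1.0 - exponent
    return (lo**b + u * (hi**b - lo**b)) ** (1.0 / b)


def _power_law_mean(exponent: float, lo: float, hi: float) -> float:
    """E[f] of the truncated f^-a density."""
    a = exponent
    if abs(a - 1.0) < 1e-12:
        return (hi - lo) / np.log(hi / lo)
    if abs(a - 2.0) < 1e-12:
        return np.log(hi / lo) / (1.0 / lo - 1.0 / hi)
    norm = (hi ** (1 - a) - lo ** (1 - a)) / (1 - a)
    first = (hi ** (2 - a) - lo ** (2 - a)) / (2 - a)
    return first / norm


def _tail_frequencies(
    n: int,
    mass: float,
    exponent: float,
    f_floor: float,
    f_max: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Rare-clone tail: n power-law frequencies summing to ``mass`` with
    every clone well below the LARGE-bin boundary.

    The lower truncation is solved so that n i.i.d. draws naturally sum
    to ``mass`` (bounded below by ``f_floor``); the draws are then
    normalized exactly, with a capped redistribution guard so no clone
    can drift above 1.5 * f_max.  Keeping the support bounded away from
    1e-3 is what makes the latent clonal state recoverable from sampled
    templates, including under heavy depth thinning.
    """
    target_mean = mass / n
    lo, hi = f_floor, f_max * 0.999
    if _power_law_mean(exponent, hi * 0.999, hi) <= target_mean:
        lo = hi * 0.5
    elif _power_law_mean(exponent, lo, hi) < target_mean:
        for _ in range(80):  # bisect in log space for the matching truncation
            mid = float(np.sqrt(lo * hi))
            if _power_law_mean(exponent, mid, f_max) < target_mean:
                lo = mid
            else:
                hi = mid
        lo = float(np.sqrt(lo * hi))
    w = _sample_power_law(n, exponent, lo, f_max, rng)
    f = w / w.sum() * mass
    cap = 1.5 * f_max
    for _ in range(10):
        over = f > cap
        if not over.any():
            break
        if over.all():
            raise ValueError("tail mass infeasible below the frequency cap")
        excess = float((f[over] - cap).sum())
        f[over] = cap
        f[~over] *= 1.0 + excess / f[~over].sum()
    return f


def _draw_genes(n: int, profile: Mapping[str, float], rng: np.random.Generator) -> np.ndarray:
    genes = np.array(list(profile.keys()))
    probs = np.array(list(profile.values()), dtype=float)
    return genes[rng.choice(len(genes), size=n, p=probs / probs.sum())]


# ---------------------------------------------------------------------------
# Repertoire generation
# ---------------------------------------------------------------------------


@dataclass
class RepertoireTruth:
    """Ground-truth record for one generated repertoire (never consumed
    by the analysis stages)."""

    patient_id: str
    group: str
    latent_state: PatientLabel
    expanded_mass: float  # drawn spiked mass (true LARGE+HYPEREXPANDED target)
    clone_table: pd.DataFrame  # cdr3_aa, v_gene, j_gene, rearrangement_nt, true_freq


def generate_repertoire(
    latent_state: PatientLabel | str,
    config: SyntheticCohortConfig,
    rng: np.random.Generator,
    group: str = "CR/PR",
    patient_id: str = "",
    sample_id: str = "",
    timepoint: Timepoint = Timepoint.SCREENING,
) -> tuple[Repertoire, RepertoireTruth]:
    """One baseline repertoire drawn from a latent clonal state.

    The true clone-frequency vector is a set of spiked clones (each above
    ``spike_min_freq`` so it lands in the LARGE/HYPEREXPANDED bins) whose
    summed mass is uniform over the state's expanded-fraction range, plus
    a truncated power-law tail; ``templates_per_sample`` productive
    templates are drawn multinomially.  Non-productive rearrangements are
    appended as extra template mass (empty CDR3) at the configured
    fraction.
    """
    latent_state = PatientLabel(latent_state)
    lo, hi = (
        config.effective_oligo_range
        if latent_state is PatientLabel.OLIGOCLONAL
        else config.effective_poly_range
    )
    expanded_mass = float(rng.uniform(lo, hi))
    k_max = min(config.max_spikes, int(expanded_mass / config.spike_min_freq) - 1)
    n_spikes = int(rng.integers(1, max(k_max, 1) + 1))
    slack = expanded_mass - n_spikes * config.spike_min_freq
    spikes = config.spike_min_freq + rng.dirichlet(np.ones(n_spikes)) * slack

    tail = _tail_frequencies(
        config.n_clones, 1.0 - expanded_mass, config.tail_exponent,
        config.tail_freq_floor, config.tail_freq_max, rng,
    )
    true_freqs = np.concatenate([spikes, tail])

    # clone identities (vectorized per CDR3 length)
    n = true_freqs.size
    lengths = np.array(list(config.cdr3_length_dist.keys()))
    probs = np.array(list(config.cdr3_length_dist.values()), dtype=float)
    length_of = lengths[rng.choice(lengths.size, size=n, p=probs / probs.sum())]
    aa = np.empty(n, dtype=object)
    nt = np.empty(n, dtype=object)
    for length in lengths:
        mask = length_of == length
        m = int(mask.sum())
        if m:
            aa[mask], nt[mask] = _random_cdr3(m, int(length), rng)
    j_profile = config.usage_profiles.get(group) or next(iter(config.usage_profiles.values()))
    v_genes = _draw_genes(n, config.v_profile, rng)
    j_genes = _draw_genes(n, j_profile, rng)

    clone_table = pd.DataFrame(
        {"cdr3_aa": aa.astype(str), "v_gene": v_genes, "j_gene": j_genes,
         "rearrangement_nt": nt.astype(str), "true_freq": true_freqs}
    )
    truth = RepertoireTruth(
        patient_id=patient_id, group=group, latent_state=latent_state,
        expanded_mass=expanded_mass, clone_table=clone_table,
    )
    rep = _sample_templates(clone_table, config, rng, sample_id or patient_id or "sample",
                            patient_id, timepoint)
    return rep, truth


def _sample_templates(
    clone_table: pd.DataFrame,
    config: SyntheticCohortConfig,
    rng: np.random.Generator,
    sample_id: str,
    patient_id: str,
    timepoint: Timepoint,
    true_freqs: np.ndarray | None = None,
) -> Repertoire:
    """Multinomial template sampling of a true clone table, plus the
    non-productive overlay."""
    freqs = clone_table["true_freq"].to_numpy() if true_freqs is None else true_freqs
    counts = rng.multinomial(config.templates_per_sample, freqs / freqs.sum())
    observed = counts > 0
    sub = clone_table.loc[observed]
    table = pd.DataFrame(
        {
            "rearrangement_nt": sub["rearrangement_nt"].to_numpy(),
            "cdr3_aa": sub["cdr3_aa"].to_numpy(),
            "v_gene": sub["v_gene"].to_numpy(),
            "d_gene": "UNKNOWN",
            "j_gene": sub["j_gene"].to_numpy(),
            "templates": counts[observed],
            "productive": True,
        }
    )
    if config.nonproductive_fraction > 0 and config.n_nonproductive_clones > 0:
        t_np = int(round(config.templates_per_sample * config.nonproductive_fraction
                         / (1.0 - config.nonproductive_fraction)))
        if t_np > 0:
            np_freqs = _sample_power_law(
                config.n_nonproductive_clones, config.tail_exponent, 1e-5, 1e-2, rng)
            np_counts = rng.multinomial(t_np, np_freqs / np_freqs.sum())
            keep = np_counts > 0
            m = int(keep.sum())
            nt_idx = rng.integers(0, 4, size=(m, 45))
            nt = np.frombuffer(b"ACGT", dtype="S1")[nt_idx].view("S45").ravel().astype(str)
            np_table = pd.DataFrame(
                {
                    "rearrangement_nt": nt,
                    "cdr3_aa": "",
                    "v_gene": _draw_genes(m, config.v_profile, rng),
                    "d_gene": "UNKNOWN",
                    "j_gene": "UNKNOWN",
                    "templates": np_counts[keep],
                    "productive": False,
                }
            )
            table = pd.concat([table, np_table], ignore_index=True)
    return Repertoire(sample_id=sample_id, patient_id=patient_id,
                      timepoint=timepoint, table=table)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

_SMOKING_LEVELS = np.array(["NEVER", "PREVIOUS", "CURRENT"])
_SMOKING_PROBS = np.array([0.35, 0.45, 0.20])


@dataclass
class CohortBundle:
    repertoires: list[Repertoire]
    cohort: pd.DataFrame
    truth: pd.DataFrame  # per-patient scalars (latent state, expanded mass, ...)
    clone_truths: dict[str, RepertoireTruth]


def iter_cohort(
    config: SyntheticCohortConfig,
) -> Iterator[tuple[dict, Repertoire, RepertoireTruth]]:
    """Stream (patient metadata, baseline repertoire, ground truth) one
    patient at a time; deterministic per-patient substreams derived from
    the cohort seed, so results do not depend on consumption order."""
    ss = np.random.SeedSequence(config.seed)
    n_total = sum(config.group_sizes.values())
    children = ss.spawn(n_total)
    i = 0
    for group, size in config.group_sizes.items():
        prevalence = config.oligo_prevalence.get(group, 0.0)
        for _ in range(size):
            rng = np.random.default_rng(children[i])
            pid = f"P{i + 1:04d}"
            latent = (
                PatientLabel.OLIGOCLONAL
                if rng.random() < prevalence
                else PatientLabel.POLYCLONAL
            )
            rep, truth = generate_repertoire(
                latent, config, rng, group=group, patient_id=pid,
                sample_id=f"{pid}_SCREENING", timepoint=Timepoint.SCREENING,
            )
            hazard = config.baseline_hazard * (
                config.hazard_ratio_oligo if latent is PatientLabel.OLIGOCLONAL else 1.0
            )
            t_event = rng.exponential(1.0 / hazard)
            t_censor = rng.exponential(1.0 / config.censoring_hazard)
            os_time = float(max(1.0, np.ceil(min(t_event, t_censor))))
            os_event = bool(t_event <= t_censor)
            if group == "CR/PR":
                response = "CR" if rng.random() < 3 / 8 else "PR"
            else:
                response = group
            meta = {
                "patient_id": pid,
                "best_response": response,
                "response_group": group,
                "p16_status": "POS" if rng.random() < 0.5 else "NEG",
                "smoking": str(rng.choice(_SMOKING_LEVELS, p=_SMOKING_PROBS)),
                "os_time": os_time,
                "os_event": os_event,
            }
            yield meta, rep, truth
            i += 1


def generate_cohort(config: SyntheticCohortConfig) -> CohortBundle:
    """Materialize a full cohort bundle (see :func:`iter_cohort`)."""
    metas, reps, truths = [], [], {}
    rows = []
    for meta, rep, truth in iter_cohort(config):
        metas.append(meta)
        reps.append(rep)
        truths[meta["patient_id"]] = truth
        rows.append(
            {
                "patient_id": meta["patient_id"],
                "response_group": meta["response_group"],
                "latent_state": truth.latent_state.value,
                "expanded_mass": truth.expanded_mass,
            }
        )
    cohort = pd.DataFrame(metas)[
        ["patient_id", "best_response", "p16_status", "smoking", "os_time", "os_event"]
    ]
    return CohortBundle(
        repertoires=reps, cohort=cohort, truth=pd.DataFrame(rows), clone_truths=truths
    )


# ---------------------------------------------------------------------------
# Longitudinal dynamics
# ---------------------------------------------------------------------------

LONGITUDINAL_TIMEPOINTS = (
    Timepoint.SCREENING,
    Timepoint.C1D1,
    Timepoint.C4D1,
    Timepoint.EOT,
)


@dataclass
class LongitudinalTruth:
    drifts_log2: np.ndarray  # per clone, log2 frequency drift per step
    true_freqs: pd.DataFrame  # clone x timepoint true frequencies (pre-sampling)


def generate_longitudinal(
    truth: RepertoireTruth,
    config: SyntheticCohortConfig,
    rng: np.random.Generator,
    drifts_log2: np.ndarray | None = None,
) -> tuple[dict[Timepoint, Repertoire], LongitudinalTruth]:
    """Evolve a patient's true clone frequencies over the trial schedule.

    Per-clone geometric random walk in log2 frequency: one drift +
    volatility step between consecutive timepoints, then renormalization
    and fresh multinomial template sampling.  Default drifts put the
    group-configured drift on the ``n_drifted_clones`` largest baseline
    clones (zero elsewhere); pass ``drifts_log2`` to program arbitrary
    per-clone dynamics.
    """
    clones = truth.clone_table
    f0 = clones["true_freq"].to_numpy().copy()
    n = f0.size
    if drifts_log2 is None:
        drifts_log2 = np.zeros(n)
        top = np.argsort(f0)[::-1][: config.n_drifted_clones]
        drifts_log2[top] = config.top_drift_log2.get(truth.group, 0.0)
    else:
        drifts_log2 = np.asarray(drifts_log2, dtype=float)
        if drifts_log2.shape != (n,):
            raise ValueError("drifts_log2 must have one value per clone")

    freqs_by_tp: dict[Timepoint, np.ndarray] = {}
    reps: dict[Timepoint, Repertoire] = {}
    f = f0 / f0.sum()
    for step, tp in enumerate(LONGITUDINAL_TIMEPOINTS):
        if step > 0:
            noise = rng.normal(0.0, config.drift_volatility, size=n)
            f = f * np.exp2(drifts_log2 + noise)
            f = f / f.sum()
        freqs_by_tp[tp] = f.copy()
        reps[tp] = _sample_templates(
            clones, config, rng,
            sample_id=f"{truth.patient_id}_{tp.name}",
            patient_id=truth.patient_id, timepoint=tp, true_freqs=f,
        )
    true_freq_df = pd.DataFrame(freqs_by_tp, index=clones.index)
    return reps, LongitudinalTruth(drifts_log2=drifts_log2, true_freqs=true_freq_df)


# ---------------------------------------------------------------------------
# Depth thinning
# ---------------------------------------------------------------------------


def thin_repertoire(
    rep: Repertoire, factor: float, rng: np.random.Generator
) -> Repertoire:
    """Downsample templates without replacement by the given depth factor
    (hypergeometric thinning), emulating a shallower sequencing run."""
    if factor <= 1:
        raise ValueError("thinning factor must exceed 1")
    counts = rep.table["templates"].to_numpy().astype(np.int64)
    total = int(counts.sum())
    target = max(1, int(round(total / factor)))
    thinned = rng.multivariate_hypergeometric(counts, target, method="marginals")
    keep = thinned > 0
    table = rep.table.loc[keep].copy()
    table["templates"] = thinned[keep]
    return Repertoire(sample_id=rep.sample_id, patient_id=rep.patient_id,
                      timepoint=rep.timepoint, table=table.reset_index(drop=True))


def config_with_seed(config: SyntheticCohortConfig, seed: int) -> SyntheticCohortConfig:
    """A copy of ``config`` re-seeded (convenience for replicate runs)."""
    return replace(config, seed=int(seed))
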