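# Methods

This note records the statistical conventions, generator design and
numerical choices behind `clonoscope`, at the level of detail a
maintainer or reviewer needs to interpret a green test.

## Data model

A repertoire is one sample's set of rearrangements, one row per
clonotype. The default clonotype key is the amino-acid triple
(CDR3 aa, V gene, J gene); a nucleotide-level key (the rearrangement
sequence) is available everywhere via `level="nt"`, because public
reports are ambiguous about which uniqueness level "total
rearrangements" counts — both are therefore computable and the aa level
is the default (it is the level at which clone tracking and sharing
operate). Duplicate rows with one key are merged at construction with
templates summed, giving a deterministic canonical form. Frequencies
are normalized over **productive** template mass by default (matching
"productive clonality" conventions); an all-template denominator is a
flag, not a fork.

Gene calls that cannot be resolved to a single IMGT-style segment
(multi-assignments such as `TCRBV12-03/12-04`, or explicit
unresolved markers) become the `AMBIGUOUS` sentinel; blanks become
`UNKNOWN`. Sentinels are excluded — with renormalization — from every
gene-usage computation, and serialize as empty `v_call`/`j_call`
fields in AIRR output.

## Diversity and clonality

* Simpson index `λ = Σ pᵢ²`; **Simpson clonality** `= √λ`. The square
  root is the vendor-report convention and keeps the score comparable
  across depths.
* Shannon entropy in nats; **Shannon clonality** `= 1 − H/ln R`
  (defined as 1 for a monoclonal sample, R = 1). The normalization is
  not universal in the literature; this is the convention of the
  sequencing vendor's reports and is stated rather than assumed.
* **Hill numbers** `D_Q = (Σ pᵢ^Q)^{1/(1−Q)}`; `D_0` = richness,
  `D_1 = exp(H)` by the analytic limit (not numerical nearness),
  `D_2` = inverse Simpson. The default grid is Q ∈ {0,…,5}: orders 1–5
  are the usual profile range and Q = 0 is kept as the richness anchor.
* Group comparisons are rank-based: Mann–Whitney rank-sum for two
  unpaired groups, Wilcoxon signed-rank behind `paired=True`, and
  Kruskal–Wallis for three or more. Published descriptions of such
  comparisons sometimes say "signed-rank" for what are plainly
  unpaired patient groups; the package defaults to the unpaired test
  and leaves the paired variant an explicit option rather than guessing
  intent.

## Abundance spectrum and patient stratification

Bins on clone relative frequency X: hyperexpanded X > 0.01; large
0.001 < X ≤ 0.01; medium 10⁻⁴ < X ≤ 0.001; small/rare X ≤ 10⁻⁴.
Two boundary closures are deliberate package choices, since the
interval notation commonly quoted leaves them open:

* X exactly 10⁻⁴ → small/rare (downward closure, consistent with the
  closed upper bounds of the other bins);
* expanded fraction exactly 0.25 → polyclonal, so "oligoclonal"
  remains the strict > 25% claim.

The expanded fraction is the summed template mass of large +
hyperexpanded clones, computed over productive templates by default
(configurable). The bins and the 0.25 cut are config-overridable but
default to the published thresholds.

## Gene usage and divergence

Usage is template-weighted by default (fraction of sequenced mass);
clonotype weighting (each unique clone once) is implemented because the
field's phrasing is genuinely ambiguous between the two. Jensen–Shannon
divergence is computed in base 2 so it is bounded on [0, 1]; the
embedding for clustering uses √JSD, which is a true metric, under
classical (Torgerson) scaling. K-means runs 10 restarts with a fixed
seed; hierarchical clustering uses average linkage; the density method
takes a required `eps` (no published default exists) and returns
eps-neighborhood connected components of the JSD matrix, with
`min_samples` > 1 demoting sparse points to noise.

## Tracking and selection

Clone trajectories join repertoires by exact key across the ordered
schedule screening < lead-in < C1D1 < C4D1 < EOT; undetected cells are
0 with an explicit flag. Selection between two timepoints uses
`log2(f_post/f_pre)` with a neutral band of ±1 log₂ unit (2-fold) by
default — the band is a parameter, not a claim about any published
cutoff. Clones detected on only one side are INDETERMINATE by default;
opting into imputation substitutes the one-template floor `1/T` of the
missing side. The default avoids fabricating infinite fold-changes.

## CDR3 sharing

All sharing operations use the exact unit-cost Levenshtein distance.
Clusters are connected components of the graph with edges at distance
≤ `max_dist` (optionally restricted to equal V genes). No approximate
or embedding-based acceleration is used: a length-bucket prefilter
(|len(a) − len(b)| > max_dist ⇒ no edge) and a banded early-exit DP
make desk-scale inputs fast while the results stay exactly equal to a
brute-force all-pairs scan — which is how the tests verify them. The
composite reference library pools per-sample clone tables that contain
*more than* `min_clones` (default 3) detectable clones, and keeps both
the raw entries and a deduplicated sequence→sources index. Motif
matrices require equal-length input (callers group by length);
right-padding is available as an explicit option with the pad character
counted as its own column.

## Survival

Kaplan–Meier estimation and the log-rank test are delegated to
`lifelines` (standard tooling, verified in-test against hand-computed
product-limit and O/E/V tables). Tied event times use the standard
multi-event hypergeometric variance; censored subjects at an event time
are counted at risk at that time (censoring ordered after events).
Cox regression is deliberately not reimplemented: the survival stage
emits a covariate table (label, smoking, p16, templates, …) for
standard survival packages. Time origin is the baseline sample date.

## Synthetic cohort generator

The generator emulates the data structure the analyses assume, with
ground truth retained so every pipeline stage can be validated by
parameter recovery. Per patient:

* **Latent state.** Oligoclonal with the response group's prevalence —
  defaults 0.25 (CR/PR), 0.45 (SD), 0.70 (PD), the printed cohort
  proportions (2/8, 9/20, 7/10); group sizes default to 8/20/10.
* **Abundance.** 1–12 spiked clones, each ≥ 4×10⁻³ (safely inside the
  large/hyperexpanded bins even after 10× thinning), with summed mass
  drawn uniformly from [0.30, 0.70] (oligoclonal) or [0.02, 0.20]
  (polyclonal). The disjoint ranges make the latent state recoverable;
  a `hard_mode` flag overlaps them ([0.18, 0.45] vs [0.05, 0.28]) for
  stress-testing only. The remaining mass is a rare-clone tail of
  `n_clones` (default 12,000) i.i.d. draws from a power-law density
  f^(−2) whose lower truncation is solved so the draws naturally sum to
  the tail mass (hard floor 10⁻⁷), then normalized exactly, with the
  support capped at 4.5×10⁻⁴. Keeping the tail bounded away from the
  10⁻³ bin boundary is essential: multinomial sampling noise would
  otherwise push boundary clones across bins and destroy label
  recoverability at thinned depth.
* **Sampling.** 20,000 productive templates multinomially per sample
  (the deep-assay scale), plus ~15% non-productive template mass as
  empty-CDR3 rows, so the productive filter is exercised on realistic
  input.
* **Sequences.** CDR3s are `CASS` + random core + `F` with lengths
  13–15 aa (0.3/0.4/0.3); nucleotide rearrangements are deterministic
  one-codon-per-aa back-translations. V usage is shared across groups
  with TRBV12-1/TRBV19-1 elevated; J usage is group-specific —
  responders carry a TRBJ2-7-dominant profile (mass 0.175, inside the
  15–20% band reported for most responders), non-responders a
  near-uniform profile with several majors at ~10% and TRBJ2-7 still
  the single most frequent gene; SD is the midpoint.
* **Survival.** Exponential event times, baseline median 600 days,
  hazard ×2.0 for oligoclonal patients, independent exponential
  censoring with median 1,200 days (≈⅓ censored). The baseline median
  and censoring scale are package choices on the order of an advanced
  HNSCC trial; the hazard ratio 2 is the conventional effect size for
  the power checks.
* **Dynamics.** Between consecutive timepoints each clone's log₂
  frequency takes one drift + Gaussian-volatility (σ = 0.15) step,
  then renormalization and fresh template sampling. Default drifts put
  +0.5 log₂/step on the top 10 baseline clones of responders (top-clone
  expansion); arbitrary per-clone drifts can be programmed for
  recovery tests.
* **Reproducibility.** One cohort seed; per-patient substreams are
  spawned deterministically, so output is independent of consumption
  order and byte-identical across runs.

What the generator does **not** emulate: V(D)J recombination realism
(no insertion/deletion profiles or generation probabilities), antigen-
driven convergence, sequencing error, or PCR amplification bias. A
green recovery test therefore establishes that the analysis code
implements its definitions correctly and that the stratification rule
is depth-robust under multinomial resampling — not that the biological
effect sizes are realistic.

## Numerical conventions

* Frequency vectors must sum to 1 within 1e-9; metric identities
  (√λ vs clonality, Hill anchors) hold to 1e-12/1e-9.
* `0·log 0 ≡ 0` throughout; JSD uses union support with absent genes
  at 0.
* Multinomial thinning uses the multivariate hypergeometric
  (sampling without replacement), so thinned counts never exceed the
  originals. Depth-robustness experiments thin the *productive*
  repertoire, since the spectrum is computed on productive template
  mass. This matters more than it looks: at a thinned depth near
  T = 2,000, two-template clones sit at frequency 2/T right at the
  medium/large boundary (10⁻³). With T exactly 2,000 the closed upper
  bound keeps that entire count class in the medium bin; thinning the
  mixed productive+non-productive table instead makes the productive
  total fluctuate around 2,000, and whenever it lands below, the whole
  2-count class (often >0.1 of template mass) crosses into the large
  bin and the patient label flips. The depth-consistency claim is
  therefore genuinely sensitive to where count-quantization places the
  low-count classes relative to the bin boundaries — worth knowing
  before comparing spectra across assay depths near 2,000 templates.
* Classical scaling clips negative eigenvalues at 0 (the √JSD matrix
  is a metric but not always Euclidean).

## Known limitations

* Clustering of usage profiles assumes at least 3 samples; the 2-D
  embedding is for visualization and clustering, not inference.
* `cluster_cdr3` computes exact pairwise distances within components
  for the `max_pairwise_distance` field; pathological single-component
  inputs (thousands of near-identical sequences) make that field
  quadratic to fill.
* The selection analysis treats sampling zeros as non-detection; very
  deep repertoires with true zeros vs shallow detection limits are not
  distinguished.
* Survival machinery covers two-group comparisons; multi-level labels
  require pairwise calls by the user.
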