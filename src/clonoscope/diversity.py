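"""Richness, clonality and Hill-number diversity of a clone frequency vector.

Conventions
-----------
* Simpson index = sum(p_i^2); Simpson clonality = sqrt(Simpson index).
  The square root keeps clonality on a [0, 1] scale comparable across
  sequencing depths and is the convention of productive-clonality reports.
* Shannon entropy is in nats; Shannon clonality = 1 - H/ln(R) where R is
  richness (defined as 1 when R == 1, i.e. a single-clone repertoire is
  maximally clonal).
* Hill number of order Q: D_Q = (sum p_i^Q)^(1/(1-Q)); Q=0 gives richness,
  Q=1 is taken as the analytic limit exp(H), Q=2 the inverse Simpson index.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

_NORM_TOL = 1e-9

DEFAULT_Q_GRID = (0.0, 1.0, 2.0, 3.0, 4.0, 5.0)


def _as_freqs(freqs) -> np.ndarray:
    p = np.asarray(freqs, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("frequency vector must be a nonempty 1-D array")
    if (p < 0).any():
        raise ValueError("frequencies must be nonnegative")
    if abs(p.sum() - 1.0) > _NORM_TOL:
        raise ValueError(f"frequencies must sum to 1 (got {p.sum():.12f})")
    return p


def simpson_clonality(freqs) -> float:
    """sqrt(sum p_i^2): 1 for a monoclonal sample, 1/sqrt(R) when uniform."""
    p = _as_freqs(freqs)
    return float(np.sqrt(np.sum(p * p)))


def shannon_metrics(freqs) -> tuple[float, float]:
    """Return (entropy in nats, Shannon clonality = 1 - H/ln R)."""
    p = _as_freqs(freqs)
    nz = p[p > 0]
    entropy = float(-np.sum(nz * np.log(nz)))
    r = nz.size
    clonality = 1.0 if r < 2 else float(1.0 - entropy / np.log(r))
    return entropy, clonality


def hill_number(freqs, q: float) -> float:
    """Effective number of clones at diversity order ``q`` (>= 0)."""
    p = _as_freqs(freqs)
    if q < 0:
        raise ValueError("diversity order Q must be >= 0")
    nz = p[p > 0]
    if q == 0:
        return float(nz.size)
    if q == 1:  # analytic continuity limit
        return float(np.exp(-np.sum(nz * np.log(nz))))
    return float(np.sum(nz**q) ** (1.0 / (1.0 - q)))


def hill_profile(freqs, q_grid: Sequence[float] = DEFAULT_Q_GRID) -> dict[float, float]:
    """Hill number at each order of ``q_grid`` (default {0,...,5})."""
    return {float(q): hill_number(freqs, q) for q in q_grid}


@dataclass(frozen=True)
class DiversityResult:
    """Bundle of per-sample diversity metrics."""

    richness: int
    simpson_index: float
    simpson_clonality: float
    shannon_entropy: float
    shannon_clonality: float
    hill_profile: Mapping[float, float]


def diversity_result(freqs, q_grid: Sequence[float] = DEFAULT_Q_GRID) -> DiversityResult:
    p = _as_freqs(freqs)
    simpson = float(np.sum(p * p))
    entropy, sh_clon = shannon_metrics(p)
    return DiversityResult(
        richness=int(np.count_nonzero(p)),
        simpson_index=simpson,
        simpson_clonality=float(np.sqrt(simpson)),
        shannon_entropy=entropy,
        shannon_clonality=sh_clon,
        hill_profile=hill_profile(p, q_grid),
    )


def compare_groups(values, labels, paired: bool = False) -> tuple[float, float]:
    """Rank-based comparison of a metric across patient groups.

    Two groups: Wilcoxon rank-sum (Mann-Whitney U) by default, or the
    signed-rank test on paired differences when ``paired=True`` (requires
    equal group sizes).  More than two groups: Kruskal-Wallis.  Returns
    ``(statistic, two-sided p-value)``.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape != labels.shape:
        raise ValueError("values and labels must align")
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("need at least two groups")
    groups = [values[labels == g] for g in uniq]
    for g, v in zip(uniq, groups):
        if v.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
    if uniq.size == 2:
        if paired:
            if groups[0].size != groups[1].size:
                raise ValueError("paired test requires equal group sizes")
            res = stats.wilcoxon(groups[0], groups[1], alternative="two-sided")
        else:
            res = stats.mannwhitneyu(groups[0], groups[1], alternative="two-sided")
        return float(res.statistic), float(res.pvalue)
    res = stats.kruskal(*groups)
    return float(res.statistic), float(res.pvalue)
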