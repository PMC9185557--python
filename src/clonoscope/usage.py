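"""V/J gene-segment usage, CDR3 spectratyping and usage-profile clustering.

Usage is the relative frequency of each gene segment flanking the CDR3
sequences of a sample, template-weighted by default (fraction of the
sequenced template mass) or clonotype-weighted (each unique clonotype
counted once).  Ambiguous/unknown gene calls are excluded and the
remaining mass renormalized.  Profiles are compared with the base-2
Jensen-Shannon divergence (bounded on [0, 1]); sqrt(JSD) — a true
metric — drives the classical 2-D scaling used for clustering.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import jensenshannon, squareform
from sklearn.cluster import KMeans

from .io import SENTINELS, EmptyRepertoireError, Repertoire


class SegmentClass(str, enum.Enum):
    V = "V"
    J = "J"


class Weighting(str, enum.Enum):
    TEMPLATE = "TEMPLATE"
    CLONOTYPE = "CLONOTYPE"


@dataclass(frozen=True)
class UsageProfile:
    sample_id: str
    segment_class: SegmentClass
    frequencies: Mapping[str, float]
    weighting: Weighting


_GENE_COLUMN = {SegmentClass.V: "v_gene", SegmentClass.J: "j_gene"}


def usage_profile(
    rep: Repertoire,
    segment_class: SegmentClass | str = SegmentClass.J,
    weighting: Weighting | str = Weighting.TEMPLATE,
) -> UsageProfile:
    """Relative gene-segment frequencies of one (productive) sample."""
    segment_class = SegmentClass(segment_class)
    weighting = Weighting(weighting)
    t = rep.table[rep.table["productive"]]
    col = _GENE_COLUMN[segment_class]
    t = t[~t[col].isin(SENTINELS)]
    if t.empty:
        raise EmptyRepertoireError(
            f"sample {rep.sample_id}: no unambiguous {segment_class.value} gene calls"
        )
    if weighting is Weighting.TEMPLATE:
        counts = t.groupby(col)["templates"].sum()
    else:
        counts = t.groupby(col).size()
    freqs = (counts / counts.sum()).sort_index()
    return UsageProfile(
        sample_id=rep.sample_id,
        segment_class=segment_class,
        frequencies=dict(freqs),
        weighting=weighting,
    )


def spectratype(
    rep: Repertoire, segment_class: SegmentClass | str = SegmentClass.V
) -> pd.DataFrame:
    """CDR3-length x gene-segment template-frequency matrix.

    Rows are CDR3 amino-acid lengths, columns gene labels; cells sum to 1
    over the whole matrix.  The column marginal equals the
    template-weighted :func:`usage_profile`, the row marginal the CDR3
    length distribution (both after ambiguous-call exclusion).
    """
    segment_class = SegmentClass(segment_class)
    col = _GENE_COLUMN[segment_class]
    t = rep.table[rep.table["productive"]]
    t = t[~t[col].isin(SENTINELS)]
    if t.empty:
        raise EmptyRepertoireError(
            f"sample {rep.sample_id}: no unambiguous {segment_class.value} gene calls"
        )
    lengths = t["cdr3_aa"].str.len()
    mat = (
        t.assign(cdr3_length=lengths)
        .pivot_table(index="cdr3_length", columns=col, values="templates",
                     aggfunc="sum", fill_value=0)
        .astype(float)
    )
    return mat / mat.to_numpy().sum()


def js_divergence(p: UsageProfile, q: UsageProfile) -> float:
    """Base-2 Jensen-Shannon divergence between two usage profiles.

    The union of both supports is used, with absent genes at frequency 0
    (0*log 0 = 0), so the value lies in [0, 1]: 0 for identical profiles,
    1 for disjoint supports.
    """
    if p.segment_class is not q.segment_class:
        raise ValueError("profiles must cover the same segment class")
    genes = sorted(set(p.frequencies) | set(q.frequencies))
    pv = np.array([p.frequencies.get(g, 0.0) for g in genes])
    qv = np.array([q.frequencies.get(g, 0.0) for g in genes])
    # scipy returns the JS *distance* = sqrt(divergence)
    return float(jensenshannon(pv, qv, base=2) ** 2)


def jsd_matrix(profiles: Sequence[UsageProfile]) -> pd.DataFrame:
    ids = [p.sample_id for p in profiles]
    n = len(profiles)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = js_divergence(profiles[i], profiles[j])
    return pd.DataFrame(mat, index=ids, columns=ids)


def _classical_mds(dist: np.ndarray, n_components: int = 2) -> np.ndarray:
    """Classical (Torgerson) metric scaling of a distance matrix."""
    n = dist.shape[0]
    d2 = dist**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:n_components]
    vals = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(vals)


class ClusterMethod(str, enum.Enum):
    HIERARCHICAL = "HIERARCHICAL"
    KMEANS = "KMEANS"
    DENSITY = "DENSITY"


@dataclass
class UsageClusterResult:
    sample_ids: list[str]
    labels: np.ndarray
    embedding: np.ndarray
    distance: pd.DataFrame  # pairwise JSD (not its square root)
    method: ClusterMethod


def usage_cluster(
    profiles: Sequence[UsageProfile],
    method: ClusterMethod | str = ClusterMethod.HIERARCHICAL,
    k: int | None = None,
    eps: float | None = None,
    min_samples: int = 1,
    seed: int = 0,
) -> UsageClusterResult:
    """Cluster samples by gene-usage divergence.

    The pairwise JSD matrix is computed, embedded in 2-D by classical
    scaling of sqrt(JSD), then clustered: average-linkage hierarchical or
    k-means (``k`` clusters, 10 restarts, fixed seed) on the embedding,
    or eps-neighborhood components directly on the JSD matrix for the
    density method (``eps`` required; ``min_samples`` > 1 marks sparser
    points as noise, label -1).
    """
    method = ClusterMethod(method)
    if len(profiles) < 3:
        raise ValueError("need at least 3 profiles to cluster")
    dmat = jsd_matrix(profiles)
    dist = np.sqrt(dmat.to_numpy())
    embedding = _classical_mds(dist)

    if method is ClusterMethod.DENSITY:
        if eps is None:
            raise ValueError("density clustering requires eps")
        labels = _eps_components(dmat.to_numpy(), eps, min_samples)
    else:
        if k is None:
            raise ValueError(f"{method.value} clustering requires k")
        if k > len(profiles):
            raise ValueError("k cannot exceed the number of profiles")
        if method is ClusterMethod.HIERARCHICAL:
            condensed = squareform(dist, checks=False)
            link = hierarchy.linkage(condensed, method="average")
            labels = hierarchy.fcluster(link, t=k, criterion="maxclust") - 1
        else:
            km = KMeans(n_clusters=k, n_init=10, random_state=seed)
            labels = km.fit_predict(embedding)
    return UsageClusterResult(
        sample_ids=list(dmat.index), labels=np.asarray(labels), embedding=embedding,
        distance=dmat, method=method,
    )


def _eps_components(dmat: np.ndarray, eps: float, min_samples: int) -> np.ndarray:
    """Connected components of the JSD <= eps graph; points with fewer
    than ``min_samples`` neighbors (incl. self) are noise (-1)."""
    adj = dmat <= eps
    core = adj.sum(axis=1) >= min_samples
    keep = np.where(core)[0]
    labels = np.full(dmat.shape[0], -1, dtype=int)
    if keep.size:
        sub = csr_matrix(adj[np.ix_(keep, keep)])
        _, comp = connected_components(sub, directed=False)
        labels[keep] = comp
    return labels
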