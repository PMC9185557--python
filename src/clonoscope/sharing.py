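"""Cross-sample CDR3 sharing: edit-distance clustering and library queries.

CDR3 amino-acid sequences are compared with the unit-cost Levenshtein
(edit) distance.  Sharing analyses use exact distances throughout:
clusters are the connected components of the graph whose edges join
sequences within a maximum distance (typically 1), so results are
directly verifiable against a brute-force all-pairs scan.  A
length-bucketing prefilter (two sequences whose lengths differ by more
than the threshold cannot be within it) and a banded early-exit DP keep
desk-scale inputs fast without approximation.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import AA_ALPHABET, Repertoire


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance between two nonempty amino-acid strings."""
    if not a or not b:
        raise ValueError("sequences must be nonempty")
    if a == b:
        return 0
    if len(a) < len(b):
        a, b = b, a
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        cur = [i]
        for j, cb in enumerate(b, start=1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def _within_distance(a: str, b: str, max_dist: int) -> bool:
    """Banded DP deciding levenshtein(a, b) <= max_dist with early exit."""
    la, lb = len(a), len(b)
    if abs(la - lb) > max_dist:
        return False
    if max_dist == 0:
        return a == b
    if la < lb:
        a, b, la, lb = b, a, lb, la
    inf = max_dist + 1
    prev = list(range(min(lb, max_dist) + 1)) + [inf] * (lb - max_dist)
    for i in range(1, la + 1):
        lo = max(1, i - max_dist)
        hi = min(lb, i + max_dist)
        cur = [inf] * (lb + 1)
        if lo == 1:
            cur[0] = i if i <= max_dist else inf
        best = inf
        for j in range(lo, hi + 1):
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (a[i - 1] != b[j - 1]))
            best = min(best, cur[j])
        if best > max_dist:
            return False
        prev = cur
    return prev[lb] <= max_dist


@dataclass
class Cdr3Cluster:
    """A connected component of sequences under the distance threshold."""

    members: list[tuple[str, str]]  # (cdr3_aa, source sample/patient id)
    representative: str
    max_pairwise_distance: int
    shared: bool  # spans >= 2 distinct sources

    @property
    def sequences(self) -> list[str]:
        return sorted({seq for seq, _ in self.members})

    @property
    def sources(self) -> list[str]:
        return sorted({src for _, src in self.members})


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def cluster_cdr3(
    samples: Sequence[Repertoire],
    max_dist: int = 1,
    same_vgene: bool = False,
    min_sources: int = 1,
) -> list[Cdr3Cluster]:
    """Cluster all productive CDR3 aa sequences across samples.

    Clusters are connected components of the "levenshtein <= max_dist"
    graph (restricted to equal V genes when ``same_vgene``).  Components
    spanning at least two patients are flagged ``shared``; set
    ``min_sources=2`` to return only those.  Representative = the
    member with the highest pooled template count (ties broken
    lexicographically).  Output is independent of input order.
    """
    if max_dist < 0:
        raise ValueError("max_dist must be >= 0")
    # pooled per-sequence (and optional per-V) bookkeeping
    counts: dict[tuple, int] = defaultdict(int)
    sources: dict[tuple, set[str]] = defaultdict(set)
    for rep in samples:
        t = rep.table[rep.table["productive"]]
        source = rep.patient_id or rep.sample_id
        for cdr3, v, templates in zip(t["cdr3_aa"], t["v_gene"], t["templates"]):
            if not cdr3:
                continue
            node = (cdr3, v) if same_vgene else (cdr3,)
            counts[node] += int(templates)
            sources[node].add(source)

    nodes = sorted(counts)  # deterministic order
    index = {node: i for i, node in enumerate(nodes)}
    uf = _UnionFind(len(nodes))

    if max_dist <= 1:
        _link_by_deletion_index(nodes, uf, max_dist, same_vgene)
    else:
        _link_by_length_scan(nodes, uf, max_dist, same_vgene)

    return _components_to_clusters(nodes, uf, counts, sources, min_sources)


def _link_by_deletion_index(
    nodes: list[tuple], uf: "_UnionFind", max_dist: int, same_vgene: bool
) -> None:
    """Exact candidate generation for max_dist <= 1.

    Two sequences at edit distance <= 1 share a key in
    {sequence} | {single-character deletions}: a substitution at
    position i gives equal deletions at i, an indel makes the shorter
    string itself a deletion of the longer.  Candidates are verified
    with the banded DP, so hash collisions cost time, never
    correctness.  This scales to the hundreds of thousands of CDR3s a
    cohort pools, where an all-pairs scan within the few distinct CDR3
    lengths would be quadratic.
    """
    buckets: dict[int, list[int]] = defaultdict(list)
    for i, node in enumerate(nodes):
        seq = node[0]
        vkey = node[1] if same_vgene else ""
        keys = {hash((seq, vkey))}
        if max_dist >= 1:
            keys.update(
                hash((seq[:k] + seq[k + 1:], vkey)) for k in range(len(seq))
            )
        for key in keys:
            buckets[key].append(i)
    for idxs in buckets.values():
        if len(idxs) < 2:
            continue
        for ai in range(len(idxs)):
            i = idxs[ai]
            for bi in range(ai + 1, len(idxs)):
                j = idxs[bi]
                if uf.find(i) == uf.find(j):
                    continue
                if _within_distance(nodes[i][0], nodes[j][0], max_dist):
                    uf.union(i, j)


def _link_by_length_scan(
    nodes: list[tuple], uf: "_UnionFind", max_dist: int, same_vgene: bool
) -> None:
    """All-pairs scan restricted to compatible-length buckets."""
    buckets: dict[tuple, list[int]] = defaultdict(list)
    for i, node in enumerate(nodes):
        vkey = node[1] if same_vgene else None
        buckets[(len(node[0]), vkey)].append(i)
    for (length, vkey), idxs in buckets.items():
        partners: list[int] = []
        for dl in range(0, max_dist + 1):
            partners.extend(buckets.get((length + dl, vkey), []))
        for i in idxs:
            si = nodes[i][0]
            for j in partners:
                if j <= i and len(nodes[j][0]) == length:
                    continue  # same-length pairs handled once (i < j)
                if j == i:
                    continue
                if _within_distance(si, nodes[j][0], max_dist):
                    uf.union(i, j)


def _components_to_clusters(
    nodes: list[tuple],
    uf: "_UnionFind",
    counts: Mapping[tuple, int],
    sources: Mapping[tuple, set],
    min_sources: int,
) -> list[Cdr3Cluster]:
    comps: dict[int, list[int]] = defaultdict(list)
    for i in range(len(nodes)):
        comps[uf.find(i)].append(i)

    clusters = []
    for idxs in comps.values():
        members = sorted(
            (nodes[i][0], src) for i in idxs for src in sources[nodes[i]]
        )
        seqs = sorted({nodes[i][0] for i in idxs})
        # representative: highest pooled template count, ties lexicographic
        seq_count = defaultdict(int)
        for i in idxs:
            seq_count[nodes[i][0]] += counts[nodes[i]]
        rep_seq = min(seqs, key=lambda s: (-seq_count[s], s))
        maxd = 0
        for ai in range(len(seqs)):
            for bi in range(ai + 1, len(seqs)):
                maxd = max(maxd, levenshtein(seqs[ai], seqs[bi]))
        srcs = {src for _, src in members}
        clusters.append(
            Cdr3Cluster(members=members, representative=rep_seq,
                        max_pairwise_distance=maxd, shared=len(srcs) >= 2)
        )
    clusters.sort(key=lambda c: c.representative)
    if min_sources > 1:
        clusters = [c for c in clusters if len(c.sources) >= min_sources]
    return clusters


@dataclass
class CompositeLibrary:
    """Pooled reference CDR3 entries with a deduplicated index."""

    entries: list[tuple[str, str, int]]  # (cdr3_aa, source sample id, clone count)
    unique_index: dict[str, list[str]] = field(default_factory=dict)

    @property
    def n_entries(self) -> int:
        return len(self.entries)

    @property
    def n_unique(self) -> int:
        return len(self.unique_index)


def build_composite_library(
    clone_tables: Mapping[str, pd.DataFrame], min_clones: int = 3
) -> CompositeLibrary:
    """Pool per-sample CDR3 tables into one reference library.

    ``clone_tables`` maps sample id -> a table with ``cdr3_aa`` and
    ``count`` columns.  Samples with ``min_clones`` or fewer detectable
    clones are excluded (default keeps samples with *more than three*
    clones); the survivors' entries are pooled and deduplicated into
    ``unique_index`` (sequence -> sorted source sample ids).
    """
    entries: list[tuple[str, str, int]] = []
    unique: dict[str, set[str]] = defaultdict(set)
    n_kept = 0
    for sample_id in sorted(clone_tables):
        table = clone_tables[sample_id]
        if "cdr3_aa" not in table.columns or "count" not in table.columns:
            raise ValueError(f"sample {sample_id}: clone table needs cdr3_aa and count columns")
        detectable = table[(table["count"] > 0) & table["cdr3_aa"].astype(bool)]
        if len(detectable) <= min_clones:
            continue
        n_kept += 1
        for cdr3, count in zip(detectable["cdr3_aa"], detectable["count"]):
            entries.append((str(cdr3), sample_id, int(count)))
            unique[str(cdr3)].add(sample_id)
    if n_kept == 0:
        raise ValueError(f"no samples with more than {min_clones} detectable clones")
    return CompositeLibrary(
        entries=entries,
        unique_index={seq: sorted(srcs) for seq, srcs in sorted(unique.items())},
    )


def query_library(
    queries: Iterable[str], lib: CompositeLibrary, max_dist: int = 1
) -> pd.DataFrame:
    """All library sequences within ``max_dist`` edits of each query.

    Returns a table (query, match, distance, sources); exact scan with
    length bucketing, equivalent to brute force.
    """
    if max_dist < 0:
        raise ValueError("max_dist must be >= 0")
    by_length: dict[int, list[str]] = defaultdict(list)
    for seq in lib.unique_index:
        by_length[len(seq)].append(seq)
    rows = []
    for query in queries:
        if not query:
            raise ValueError("empty query sequence")
        for length in range(len(query) - max_dist, len(query) + max_dist + 1):
            for seq in by_length.get(length, ()):
                if _within_distance(query, seq, max_dist):
                    rows.append({
                        "query": query,
                        "match": seq,
                        "distance": levenshtein(query, seq),
                        "sources": ";".join(lib.unique_index[seq]),
                    })
    return pd.DataFrame(rows, columns=["query", "match", "distance", "sources"])


def motif_matrix(
    sequences: Sequence[str], pad: str | None = None
) -> pd.DataFrame:
    """Position x amino-acid frequency matrix for a set of CDR3s.

    Sequences must share one length (group by length upstream), unless a
    ``pad`` character is given, in which case shorter sequences are
    right-padded and the pad character is counted as its own column.
    Each position (row) sums to 1; ready for logo-plotting tools.
    """
    seqs = list(sequences)
    if not seqs:
        raise ValueError("need at least one sequence")
    lengths = {len(s) for s in seqs}
    if len(lengths) > 1:
        if pad is None:
            raise ValueError(
                "mixed CDR3 lengths: group sequences by length, or pass pad=<char>"
            )
        if len(pad) != 1 or pad in AA_ALPHABET:
            raise ValueError("pad must be a single non-amino-acid character")
        width = max(lengths)
        seqs = [s.ljust(width, pad) for s in seqs]
    width = len(seqs[0])
    alphabet = list(AA_ALPHABET) + ([pad] if pad and len(lengths) > 1 else [])
    mat = pd.DataFrame(0.0, index=pd.RangeIndex(1, width + 1, name="position"),
                       columns=alphabet)
    for s in seqs:
        for pos, aa in enumerate(s, start=1):
            if aa not in mat.columns:
                raise ValueError(f"invalid amino acid {aa!r} at position {pos}")
            mat.loc[pos, aa] += 1.0
    return mat / len(seqs)
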