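import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clonoscope import (
    build_composite_library,
    cluster_cdr3,
    levenshtein,
    motif_matrix,
    query_library,
)
from clonoscope.io import AA_ALPHABET

from conftest import make_repertoire

aa_strings = st.text(alphabet=AA_ALPHABET, min_size=1, max_size=12)


def brute_force_levenshtein(a, b):
    """Independent O(nm) reference: the full DP matrix, no banding or
    early exit (shares nothing with the implementation's shortcuts)."""
    table = [[0] * (len(b) + 1) for _ in range(len(a) + 1)]
    for i in range(len(a) + 1):
        table[i][0] = i
    for j in range(len(b) + 1):
        table[0][j] = j
    for i in range(1, len(a) + 1):
        for j in range(1, len(b) + 1):
            table[i][j] = min(
                table[i - 1][j] + 1,
                table[i][j - 1] + 1,
                table[i - 1][j - 1] + (a[i - 1] != b[j - 1]),
            )
    return table[-1][-1]


def random_cdr3s(rng, n, lengths=(10, 16)):
    """Random CDR3 pool with deliberate near-duplicates."""
    letters = np.array(list(AA_ALPHABET))
    seqs = []
    for _ in range(n):
        if seqs and rng.random() < 0.4:  # mutate an existing sequence
            base = list(seqs[int(rng.integers(len(seqs)))])
            op = rng.random()
            pos = int(rng.integers(len(base)))
            if op < 0.5:
                base[pos] = str(rng.choice(letters))
            elif op < 0.75 and len(base) > 8:
                del base[pos]
            else:
                base.insert(pos, str(rng.choice(letters)))
            seqs.append("".join(base))
        else:
            length = int(rng.integers(*lengths))
            seqs.append("".join(rng.choice(letters, size=length)))
    return seqs


class TestLevenshtein:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("CASSARTGELFF", "CASSARTGELFF", 0),
            ("CASSARTGELFF", "CASSARTGELFG", 1),
            ("CASSF", "CAF", 2),  # verified by exhaustive edit-script search
            ("CASS", "SSAC", 4),  # all four positions differ; no cheaper indel path
            ("A", "AAAA", 3),
        ],
    )
    def test_known_distances(self, a, b, expected):
        assert levenshtein(a, b) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            levenshtein("", "CASSF")

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(aa_strings, aa_strings, aa_strings)
    def test_metric_axioms(self, a, b, c):
        """Symmetry, identity of indiscernibles, triangle inequality."""
        dab = levenshtein(a, b)
        assert dab == levenshtein(b, a)
        assert (dab == 0) == (a == b)
        assert dab <= levenshtein(a, c) + levenshtein(c, b)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(aa_strings, aa_strings)
    def test_matches_reference_dp(self, a, b):
        assert levenshtein(a, b) == brute_force_levenshtein(a, b)


class TestClusterCdr3:
    def _reps_from(self, seqs_by_patient):
        return [
            make_repertoire([(s, 10) for s in seqs], sample_id=pid, patient_id=pid)
            for pid, seqs in seqs_by_patient.items()
        ]

    def test_identical_sequence_across_patients_shared(self):
        reps = self._reps_from({"P1": ["CASSLGNQPQHF"], "P2": ["CASSLGNQPQHF"]})
        clusters = cluster_cdr3(reps, max_dist=0)
        assert len(clusters) == 1
        assert clusters[0].shared
        assert clusters[0].sources == ["P1", "P2"]

    def test_distant_sequences_all_singletons(self):
        reps = self._reps_from({"P1": ["CASSAAAAAAAF", "CASSWWWWWWWF"],
                                "P2": ["CASSYYYYYYYF"]})
        clusters = cluster_cdr3(reps, max_dist=1)
        assert len(clusters) == 3
        assert not any(c.shared for c in clusters)

    def _brute_components(self, seqs, max_dist):
        """O(n^2) oracle: full pairwise scan + union-find on a sorted pool."""
        seqs = sorted(set(seqs))
        parent = list(range(len(seqs)))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i, j in itertools.combinations(range(len(seqs)), 2):
            if brute_force_levenshtein(seqs[i], seqs[j]) <= max_dist:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
        comps = {}
        for i in range(len(seqs)):
            comps.setdefault(find(i), set()).add(seqs[i])
        return {frozenset(c) for c in comps.values()}

    @pytest.mark.parametrize("max_dist", [0, 1, 2])
    def test_matches_brute_force_components(self, rng, max_dist):
        seqs = random_cdr3s(rng, 150)
        half = len(seqs) // 2
        reps = self._reps_from({"P1": seqs[:half], "P2": seqs[half:]})
        clusters = cluster_cdr3(reps, max_dist=max_dist)
        got = {frozenset(c.sequences) for c in clusters}
        assert got == self._brute_components(seqs, max_dist)

    def test_order_invariance(self, rng):
        seqs = random_cdr3s(rng, 60)
        fwd = cluster_cdr3(self._reps_from({"P1": seqs}), max_dist=1)
        rev = cluster_cdr3(self._reps_from({"P1": seqs[::-1]}), max_dist=1)
        assert [c.sequences for c in fwd] == [c.sequences for c in rev]

    def test_same_vgene_restriction_splits_clusters(self):
        reps = [
            make_repertoire([("CASSLGNQPQHF", 10, True, "TRBV9", "TRBJ2-1")],
                            sample_id="P1", patient_id="P1"),
            make_repertoire([("CASSLGNQPQHF", 10, True, "TRBV28", "TRBJ2-1")],
                            sample_id="P2", patient_id="P2"),
        ]
        unrestricted = cluster_cdr3(reps, max_dist=0, same_vgene=False)
        restricted = cluster_cdr3(reps, max_dist=0, same_vgene=True)
        assert len(unrestricted) == 1 and unrestricted[0].shared
        assert len(restricted) == 2 and not any(c.shared for c in restricted)


class TestCompositeLibrary:
    @staticmethod
    def _aa_name(j):
        """Distinct CDR3-like name for index j over the aa alphabet."""
        core = ""
        while True:
            core += AA_ALPHABET[j % 20]
            j //= 20
            if j == 0:
                return f"CASS{core}F"

    def _tables(self, clone_counts):
        return {
            f"S{i}": pd.DataFrame(
                {"cdr3_aa": [self._aa_name(j) for j in range(n)], "count": [1] * n}
            )
            for i, n in enumerate(clone_counts)
        }

    def test_min_clones_rule_keeps_strictly_more_than_three(self):
        lib = build_composite_library(self._tables([2, 3, 4, 10, 1]), min_clones=3)
        kept_sources = {src for _, src, _ in lib.entries}
        assert kept_sources == {"S2", "S3"}  # only the 4- and 10-clone samples

    def test_unique_index_deduplicates(self):
        tables = {
            "S0": pd.DataFrame({"cdr3_aa": ["CASSAF", "CASSAF", "CASSCF",
                                            "CASSDF", "CASSEF"],
                                "count": [1, 2, 1, 1, 1]}),
        }
        lib = build_composite_library(tables, min_clones=3)
        assert lib.n_entries == 5
        assert set(lib.unique_index) == {"CASSAF", "CASSCF", "CASSDF", "CASSEF"}
        assert lib.n_unique <= lib.n_entries

    def test_synthetic_502_sample_cohort_retains_484(self, rng):
        """A 502-table pool with 18 at-or-below threshold -> 484 retained."""
        sizes = [int(rng.integers(4, 40)) for _ in range(484)]
        sizes += [int(rng.integers(1, 4)) for _ in range(18)]
        rng.shuffle(sizes)
        lib = build_composite_library(self._tables(sizes), min_clones=3)
        assert len({src for _, src, _ in lib.entries}) == 484

    def test_no_survivors_raises(self):
        with pytest.raises(ValueError, match="more than 3"):
            build_composite_library(self._tables([1, 2]), min_clones=3)


class TestQueryLibrary:
    def _lib(self, seqs):
        tables = {"S0": pd.DataFrame({"cdr3_aa": seqs, "count": [1] * len(seqs)})}
        return build_composite_library(tables, min_clones=min(3, len(seqs) - 1))

    def test_verbatim_query_distance_zero(self):
        lib = self._lib(["CASSARTGELFF", "CASSPDRGTEAF", "CASSLSRSSYNF", "CASSLGNQPQHF"])
        out = query_library(["CASSARTGELFF"], lib, max_dist=1)
        assert ("CASSARTGELFF", 0) in list(zip(out["match"], out["distance"]))

    def test_no_matches_beyond_max_dist(self):
        lib = self._lib(["CASSAAAAAAAF", "CASSCCCCCCCF", "CASSDDDDDDDF", "CASSEEEEEEEF"])
        out = query_library(["CASSWWWWWWWF"], lib, max_dist=1)
        assert out.empty

    def test_matches_brute_force_scan(self, rng):
        seqs = list(dict.fromkeys(random_cdr3s(rng, 1000)))
        lib = self._lib(seqs)
        queries = random_cdr3s(rng, 50)
        for max_dist in (0, 1, 2):
            got = query_library(queries, lib, max_dist=max_dist)
            got_pairs = set(zip(got["query"], got["match"]))
            expected = {
                (q, s)
                for q in queries
                for s in lib.unique_index
                if brute_force_levenshtein(q, s) <= max_dist
            }
            assert got_pairs == expected


class TestMotifMatrix:
    def test_single_sequence_one_hot(self):
        mat = motif_matrix(["CASSF"])
        assert mat.shape == (5, 20)
        assert (mat.sum(axis=1) == 1.0).all()
        assert mat.loc[1, "C"] == 1.0 and mat.loc[5, "F"] == 1.0

    def test_two_sequences_split_column(self):
        mat = motif_matrix(["CASSF", "CASTF"])
        assert mat.loc[4, "S"] == 0.5 and mat.loc[4, "T"] == 0.5

    def test_positions_sum_to_one_random(self, rng):
        letters = np.array(list(AA_ALPHABET))
        seqs = ["".join(rng.choice(letters, size=12)) for _ in range(20)]
        mat = motif_matrix(seqs)
        assert np.allclose(mat.sum(axis=1), 1.0)

    def test_mixed_lengths_rejected_without_pad(self):
        with pytest.raises(ValueError, match="group"):
            motif_matrix(["CASSF", "CASSFF"])

    def test_padding_counts_pad_separately(self):
        mat = motif_matrix(["CASSF", "CASSFF"], pad="-")
        assert mat.loc[6, "-"] == 0.5
        assert np.allclose(mat.sum(axis=1), 1.0)
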