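import numpy as np
import pandas as pd
import pytest

from clonoscope import ClonotypeRecord, Repertoire, Timepoint


def make_record(
    cdr3="CASSLGNQPQHF",
    v="TRBV12-1",
    j="TRBJ2-7",
    d="TRBD1",
    nt=None,
    templates=10,
    productive=True,
):
    if nt is None:
        nt = "AA" + "".join("ACGT"[hash((cdr3, v, j)) >> i & 3] for i in range(0, 30, 2))
    return ClonotypeRecord(
        rearrangement_nt=nt, cdr3_aa=cdr3 if productive else "",
        v_gene=v, d_gene=d, j_gene=j, templates=templates, productive=productive,
    )


def make_repertoire(clones, sample_id="S1", patient_id="P1",
                    timepoint=Timepoint.SCREENING):
    """clones: list of (cdr3, templates) or (cdr3, templates, productive) or
    (cdr3, templates, productive, v, j) tuples."""
    records = []
    for i, clone in enumerate(clones):
        cdr3, templates = clone[0], clone[1]
        productive = clone[2] if len(clone) > 2 else True
        v = clone[3] if len(clone) > 3 else "TRBV12-1"
        j = clone[4] if len(clone) > 4 else "TRBJ2-7"
        records.append(make_record(cdr3=cdr3, templates=templates, productive=productive,
                                   v=v, j=j, nt=f"NT{i:04d}" + "ACGT" * 5))
    return Repertoire.from_records(records, sample_id=sample_id,
                                   patient_id=patient_id, timepoint=timepoint)


@pytest.fixture
def rng():
    return np.random.default_rng(20260918)


@pytest.fixture
def toy_repertoire():
    """Six productive clones spanning all four abundance bins plus one
    non-productive row; 100,000 productive templates."""
    return make_repertoire(
        [
            ("CASSAAAAAAAAF", 40_000),   # 0.4    HYPEREXPANDED
            ("CASSCCCCCCCCF", 30_000),   # 0.3    HYPEREXPANDED
            ("CASSDDDDDDDDF", 500),      # 5e-3   LARGE
            ("CASSEEEEEEEEF", 50),       # 5e-4   MEDIUM
            ("CASSGGGGGGGGF", 10),       # 1e-4   SMALL_RARE (boundary)
            ("CASSHHHHHHHHF", 29_440),   # 0.2944 HYPEREXPANDED
            ("", 5_000, False),          # non-productive
        ]
    )


@pytest.fixture
def random_freq_vectors(rng):
    """1,000 random normalized frequency vectors of varying size."""
    vectors = []
    for _ in range(1000):
        n = int(rng.integers(1, 200))
        w = rng.gamma(shape=rng.uniform(0.1, 3.0), size=n)
        w = np.maximum(w, 1e-12)
        vectors.append(w / w.sum())
    return vectors


def write_airr_text(path, rows):
    """Write a minimal AIRR TSV from (seq, junction_aa, v, d, j, count, prod)."""
    header = "sequence\tjunction_aa\tv_call\td_call\tj_call\tduplicate_count\tproductive\n"
    body = "".join("\t".join(str(x) for x in row) + "\n" for row in rows)
    path.write_text(header + body)
    return path
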