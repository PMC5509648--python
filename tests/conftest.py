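"""Shared fixtures: handcrafted toy repertoires and brute-force oracles."""

from __future__ import annotations

import random

import pytest
from hypothesis import settings

from haystack.motif import AA_ALPHABET, MotifVector
from haystack.store import RepertoireStore, SequenceRecord, SubjectTable

settings.register_profile("ci", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("ci")


# -- independent oracles ---------------------------------------------------

def naive_matches(motif: MotifVector, record) -> bool:
    """Literal per-position oracle, independent of the store's matrix path."""
    for comp in motif.components:
        for i, residue in enumerate(comp.ems):
            idx = record.cdr3_start - comp.offset + i
            if idx < 0 or idx >= len(record.aa_sequence):
                return False
            if record.aa_sequence[idx] != residue:
                return False
    return True


def naive_query(store: RepertoireStore, motif: MotifVector):
    """Brute-force scan returning (record_ids, subjects_a, subjects_b)."""
    ids, subj_a, subj_b = [], set(), set()
    for rec in store.records:
        if naive_matches(motif, rec):
            ids.append(rec.record_id)
            if store.subjects.category(rec.subject_id) == "A":
                subj_a.add(rec.subject_id)
            else:
                subj_b.add(rec.subject_id)
    return ids, subj_a, subj_b


# -- store builders --------------------------------------------------------

def build_store(rows, category_a=("MS",)) -> RepertoireStore:
    """rows: (record_id, subject_id, diagnosis, sequence, cdr3_start)."""
    records = [
        SequenceRecord(rid, sid, diag, seq, c3, min(c3 + 10, len(seq)))
        for rid, sid, diag, seq, c3 in rows
    ]
    subjects = SubjectTable.from_records(records, set(category_a))
    return RepertoireStore(records, subjects)


def random_store(seed: int, n_subjects: int = 10, n_records: int = 60,
                 seq_len: int = 40, cdr3_start: int = 25) -> RepertoireStore:
    """A diverse random repertoire, half MS half HC subjects."""
    rng = random.Random(seed)
    rows = []
    for i in range(n_records):
        s = i % n_subjects
        diag = "MS" if s < n_subjects // 2 else "HC"
        seq = "".join(rng.choice(AA_ALPHABET) for _ in range(seq_len))
        rows.append((f"r{i}", f"subj{s}", diag, seq, cdr3_start))
    return build_store(rows)


def random_motif(rng: random.Random, max_components: int = 3) -> MotifVector:
    """A random canonical motif with non-touching components."""
    n = rng.randint(1, max_components)
    comps, taken = [], set()
    attempts = 0
    while len(comps) < n and attempts < 50:
        attempts += 1
        length = rng.randint(3, 5)
        offset = rng.randint(-8, 25)
        span = set(range(-offset - 1, -offset + length + 1))  # incl. adjacency
        if span & taken:
            continue
        taken |= set(range(-offset, -offset + length))
        taken |= {-offset - 1, -offset + length}
        comps.append(
            ("".join(rng.choice(AA_ALPHABET) for _ in range(length)), offset)
        )
    return MotifVector.from_components(comps)


@pytest.fixture
def toy_store() -> RepertoireStore:
    """Four subjects (2 MS, 2 HC); every MS CDR3 begins with CAR."""
    rows = [
        ("r1", "p1", "MS", "AAATNEAAAAAAADTAAACARSSDGYW", 18),
        ("r2", "p1", "MS", "AAAAAAAAAAAAAAAAAACARTTTGYW", 18),
        ("r3", "p2", "MS", "CCCTNECCCCCCCDTACCCARSSDGYW", 18),
        ("r4", "h1", "HC", "AAAAAAAAAAAAAAAAAAGGGSSDGYW", 18),
        ("r5", "h2", "HC", "CCCCCCCCCCCCCCCCCCWWWTTTGYW", 18),
    ]
    return build_store(rows)


@pytest.fixture(scope="session")
def conjunction_store() -> RepertoireStore:
    """A cohort where only the *conjunction* of two components is
    disease-only.

    Component X = (DEF, 8) appears in all 10 MS subjects and 4 HC subjects
    (so X alone separates but is not a DOM); component Y = (KLM, 2)
    appears in every subject somewhere, but only MS subjects carry X and Y
    on the same sequence.  Finding the DOM therefore requires restriction
    on X followed by a merge.
    """
    rows = []
    pad = "G" * 10
    for i in range(10):  # MS subjects: X and Y co-occur on one sequence
        sid = f"ms{i}"
        rows.append((f"{sid}-a", sid, "MS", pad + "AADEFAAAKLMQRSTVW" + pad, 18))
        rows.append((f"{sid}-b", sid, "MS", pad + "AAAAAAAAAAAQRSTVW" + pad, 18))
    for i in range(4):  # HC subjects with X but never Y on the same read
        sid = f"hcx{i}"
        rows.append((f"{sid}-a", sid, "HC", pad + "AADEFAAAAAAQRSTVW" + pad, 18))
        rows.append((f"{sid}-b", sid, "HC", pad + "AAAAAAAAKLMQRSTVW" + pad, 18))
    for i in range(6):  # HC subjects with Y only
        sid = f"hcy{i}"
        rows.append((f"{sid}-a", sid, "HC", pad + "AAAAAAAAKLMQRSTVW" + pad, 18))
        rows.append((f"{sid}-b", sid, "HC", pad + "AAAAAAAAAAAQRSTVW" + pad, 18))
    return build_store(rows)
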