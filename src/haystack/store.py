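"""In-memory annotated-repertoire store with CDR3-aligned motif queries.

The store plays the role a relational sequence database plays in a
production deployment: it holds validated, CDR3-annotated amino-acid
sequences with subject and diagnosis metadata, supports motif queries
grouped by subject, and can be restricted to the sub-repertoire matching a
motif ("temporary database") for the recursive step of the search.

Internally all sequences are packed into a single uint8 matrix whose
columns are CDR3-relative positions (column ``left_pad`` is the first CDR3
residue of every record), so a motif query is a handful of vectorized
equality tests.  Restricted stores share the parent's column geometry and
— critically — inherit the parent's category denominators |A| and |B|:
thresholds are always measured against the original cohort.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .motif import AA_ALPHABET, MotifVector

_AA_SET = frozenset(AA_ALPHABET)
_AA_CODE = {aa: i for i, aa in enumerate(AA_ALPHABET)}
_PAD = 255

AIRR_COLUMNS = (
    "sequence_id",
    "subject_id",
    "diagnosis",
    "sequence_aa",
    "cdr3_start",
    "cdr3_end",
)


class DataError(ValueError):
    """Fatal input-data problem (missing columns, no valid records, ...)."""


@dataclass(frozen=True)
class SequenceRecord:
    """One annotated antibody amino-acid sequence.

    ``cdr3_start``/``cdr3_end`` are a 0-based half-open interval into
    ``aa_sequence``.
    """

    record_id: str
    subject_id: str
    diagnosis: str
    aa_sequence: str
    cdr3_start: int
    cdr3_end: int
    v_call: str | None = None
    j_call: str | None = None

    def validation_error(self) -> str | None:
        """Reason this record is invalid, or None if it passes."""
        if not self.aa_sequence:
            return "empty sequence"
        if not (0 <= self.cdr3_start < self.cdr3_end <= len(self.aa_sequence)):
            return (
                f"CDR3 interval [{self.cdr3_start}, {self.cdr3_end}) outside "
                f"sequence of length {len(self.aa_sequence)}"
            )
        if set(self.aa_sequence) - _AA_SET:
            return "non-standard residues (ambiguity codes are rejected)"
        return None


@dataclass(frozen=True)
class SubjectTable:
    """Subject → (diagnosis, category) with the cohort denominators.

    Category A membership is a pure function of the configured category-A
    diagnosis set; every other subject falls into category B.
    """

    categories: Mapping[str, str]  # subject_id -> "A" | "B"
    diagnoses: Mapping[str, str]  # subject_id -> diagnosis label

    @property
    def size_a(self) -> int:
        return sum(1 for c in self.categories.values() if c == "A")

    @property
    def size_b(self) -> int:
        return sum(1 for c in self.categories.values() if c == "B")

    def category(self, subject_id: str) -> str:
        return self.categories[subject_id]

    @classmethod
    def from_records(
        cls,
        records: Iterable[SequenceRecord],
        category_a_diagnoses: Iterable[str],
    ) -> "SubjectTable":
        a_set = set(category_a_diagnoses)
        cats: dict[str, str] = {}
        diags: dict[str, str] = {}
        for rec in records:
            diags[rec.subject_id] = rec.diagnosis
            cats[rec.subject_id] = "A" if rec.diagnosis in a_set else "B"
        return cls(cats, diags)


@dataclass(frozen=True)
class MatchResult:
    """Per-motif query outcome, grouped by unique subject.

    ``a`` and ``b`` count *distinct* matched subjects in categories A and
    B; duplicate sequences within one subject cannot inflate them.
    ``separation`` is the raw score a − b.
    """

    motif: MotifVector
    matched_record_ids: tuple[str, ...]
    matched_subjects_a: frozenset[str]
    matched_subjects_b: frozenset[str]

    @property
    def a(self) -> int:
        return len(self.matched_subjects_a)

    @property
    def b(self) -> int:
        return len(self.matched_subjects_b)

    @property
    def separation(self) -> int:
        return self.a - self.b


class TripletStats:
    """Per-store tallies of (triplet, offset) occurrence by distinct subject.

    ``a_subjects_by_triplet[code]`` counts distinct category-A subjects
    whose repertoire contains the triplet at any position; the per-offset
    arrays back optimal-coordinate selection and separation filtering for
    atomic vectors.  Offsets use the leftward convention (offset =
    residues left of the first CDR3 residue).
    """

    def __init__(self, codes, offsets, a_counts, b_counts, tri_a, tri_occ):
        order = np.lexsort((offsets, codes))
        self.codes = codes[order]
        self.offsets = offsets[order]
        self.a_counts = a_counts[order]
        self.b_counts = b_counts[order]
        self.a_subjects_by_triplet = tri_a  # shape (8000,)
        self.occurrences_by_triplet = tri_occ  # raw occurrence tally, shape (8000,)

    def rows_for(self, code: int):
        lo = np.searchsorted(self.codes, code, side="left")
        hi = np.searchsorted(self.codes, code, side="right")
        return self.offsets[lo:hi], self.a_counts[lo:hi], self.b_counts[lo:hi]


def triplet_code(triplet: str) -> int:
    c0, c1, c2 = (_AA_CODE[ch] for ch in triplet)
    return (c0 * 20 + c1) * 20 + c2


def code_to_triplet(code: int) -> str:
    return (
        AA_ALPHABET[code // 400] + AA_ALPHABET[(code // 20) % 20] + AA_ALPHABET[code % 20]
    )


class RepertoireStore:
    """Validated, indexed repertoire with inherited cohort denominators."""

    def __init__(
        self,
        records: Sequence[SequenceRecord],
        subjects: SubjectTable,
        *,
        dropped_count: int = 0,
        _parent: "RepertoireStore | None" = None,
        _row_subset: np.ndarray | None = None,
    ):
        self.records: tuple[SequenceRecord, ...] = tuple(records)
        self.subjects = subjects
        self.dropped_count = dropped_count
        self._stats: TripletStats | None = None
        if _parent is not None:
            # restricted store: share geometry, slice rows
            self._left = _parent._left
            self._matrix = _parent._matrix[_row_subset]
            self._subj_idx = _parent._subj_idx[_row_subset]
            self._subj_ids = _parent._subj_ids
            self._subj_is_a = _parent._subj_is_a
        else:
            self._build_matrix()

    # -- construction -----------------------------------------------------
    def _build_matrix(self) -> None:
        recs = self.records
        self._subj_ids = sorted({r.subject_id for r in recs})
        subj_pos = {s: i for i, s in enumerate(self._subj_ids)}
        self._subj_is_a = np.array(
            [self.subjects.category(s) == "A" for s in self._subj_ids], dtype=bool
        )
        self._subj_idx = np.array([subj_pos[r.subject_id] for r in recs], dtype=np.int32)
        left = max((r.cdr3_start for r in recs), default=0)
        right = max((len(r.aa_sequence) - r.cdr3_start for r in recs), default=1)
        self._left = left
        mat = np.full((len(recs), left + right), _PAD, dtype=np.uint8)
        lut = np.full(256, _PAD, dtype=np.uint8)
        for aa, code in _AA_CODE.items():
            lut[ord(aa)] = code
        for i, r in enumerate(recs):
            row = lut[np.frombuffer(r.aa_sequence.encode("ascii"), dtype=np.uint8)]
            start = left - r.cdr3_start
            mat[i, start : start + len(row)] = row
        self._matrix = mat

    # -- basic facts ------------------------------------------------------
    def __len__(self) -> int:
        return len(self.records)

    @property
    def size_a(self) -> int:
        return self.subjects.size_a

    @property
    def size_b(self) -> int:
        return self.subjects.size_b

    # -- queries ----------------------------------------------------------
    def match_mask(self, motif: MotifVector) -> np.ndarray:
        """Boolean row mask of records matching ``motif``."""
        n, width = self._matrix.shape
        mask = np.ones(n, dtype=bool)
        for comp in motif.components:
            for rel, residue in comp.positions():
                col = self._left + rel
                if col < 0 or col >= width:
                    return np.zeros(n, dtype=bool)
                mask &= self._matrix[:, col] == _AA_CODE[residue]
                if not mask.any():
                    return mask
        return mask

    def query_motif(self, motif: MotifVector) -> MatchResult:
        """Match ``motif`` against every record, grouping hits by subject."""
        mask = self.match_mask(motif)
        idx = np.flatnonzero(mask)
        subj = np.unique(self._subj_idx[idx])
        subj_a = frozenset(self._subj_ids[i] for i in subj if self._subj_is_a[i])
        subj_b = frozenset(self._subj_ids[i] for i in subj if not self._subj_is_a[i])
        return MatchResult(
            motif=motif,
            matched_record_ids=tuple(self.records[i].record_id for i in idx),
            matched_subjects_a=subj_a,
            matched_subjects_b=subj_b,
        )

    def restrict(self, motif: MotifVector) -> "RepertoireStore":
        """Sub-store of exactly the records matching ``motif``.

        The parent is unchanged; |A| and |B| denominators are inherited
        (they count people in the cohort, not people retained).
        """
        mask = self.match_mask(motif)
        idx = np.flatnonzero(mask)
        return RepertoireStore(
            [self.records[i] for i in idx],
            self.subjects,
            _parent=self,
            _row_subset=idx,
        )

    def flank_residues(self, motif: MotifVector, rel_position: int) -> list[str]:
        """Distinct residues observed at a CDR3-relative position among the
        records matching ``motif`` (used to enumerate one-residue extensions)."""
        col = self._left + rel_position
        if col < 0 or col >= self._matrix.shape[1]:
            return []
        vals = np.unique(self._matrix[self.match_mask(motif), col])
        return [AA_ALPHABET[v] for v in vals if v != _PAD]

    # -- triplet statistics ----------------------------------------------
    def triplet_stats(self) -> TripletStats:
        """Distinct-subject tallies for every (triplet, offset) present."""
        if self._stats is not None:
            return self._stats
        mat, left = self._matrix, self._left
        n, width = mat.shape
        if n == 0 or width < 3:
            empty = np.zeros(0, dtype=np.int64)
            self._stats = TripletStats(
                empty, empty, empty, empty,
                np.zeros(8000, dtype=np.int64), np.zeros(8000, dtype=np.int64),
            )
            return self._stats
        c0 = mat[:, :-2].astype(np.int64)
        c1 = mat[:, 1:-1].astype(np.int64)
        c2 = mat[:, 2:].astype(np.int64)
        valid = (c0 != _PAD) & (c1 != _PAD) & (c2 != _PAD)
        code = (c0 * 20 + c1) * 20 + c2  # garbage where invalid; masked below
        ncols = width - 2
        cols = np.broadcast_to(np.arange(ncols, dtype=np.int64), (n, ncols))
        rows = np.broadcast_to(
            self._subj_idx.astype(np.int64)[:, None], (n, ncols)
        )
        code_v = code[valid]
        cols_v = cols[valid]
        subj_v = rows[valid]
        # raw occurrence tally over the whole database (all categories)
        tri_occ = np.bincount(code_v, minlength=8000)
        # distinct (subject, offset, triplet)
        key = (subj_v * ncols + cols_v) * 8000 + code_v
        uniq = np.unique(key)
        u_subj = uniq // (ncols * 8000)
        rem = uniq % (ncols * 8000)
        u_col = rem // 8000
        u_code = rem % 8000
        is_a = self._subj_is_a[u_subj]
        # per (triplet, offset): distinct subject counts by category
        pair = u_code * ncols + u_col
        pair_u, inv = np.unique(pair, return_inverse=True)
        a_counts = np.bincount(inv[is_a], minlength=len(pair_u))
        b_counts = np.bincount(inv[~is_a], minlength=len(pair_u))
        codes = pair_u // ncols
        offsets = left - (pair_u % ncols)  # leftward-offset convention
        # per triplet: distinct category-A subjects at any offset
        sc = np.unique(u_subj[is_a] * 8000 + u_code[is_a]) % 8000
        tri_a = np.bincount(sc, minlength=8000)
        self._stats = TripletStats(
            codes, offsets, a_counts, b_counts, tri_a, tri_occ
        )
        return self._stats


# -- loaders ---------------------------------------------------------------

def _records_from_frame(df: pd.DataFrame) -> tuple[list[SequenceRecord], int]:
    kept: list[SequenceRecord] = []
    dropped = 0
    has_v = "v_call" in df.columns
    has_j = "j_call" in df.columns
    for row in df.itertuples(index=False):
        try:
            rec = SequenceRecord(
                record_id=str(row.sequence_id),
                subject_id=str(row.subject_id),
                diagnosis=str(row.diagnosis),
                aa_sequence=str(row.sequence_aa),
                cdr3_start=int(row.cdr3_start),
                cdr3_end=int(row.cdr3_end),
                v_call=str(row.v_call) if has_v else None,
                j_call=str(row.j_call) if has_j else None,
            )
        except (TypeError, ValueError):
            dropped += 1
            continue
        if rec.validation_error() is None:
            kept.append(rec)
        else:
            dropped += 1
    return kept, dropped


def store_from_frame(
    df: pd.DataFrame, category_a_diagnoses: Iterable[str]
) -> RepertoireStore:
    """Build a store from an AIRR-dialect DataFrame (columns as in
    :data:`AIRR_COLUMNS`; extras ignored, invalid rows dropped and counted)."""
    missing = [c for c in AIRR_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"missing required column(s): {', '.join(missing)}")
    records, dropped = _records_from_frame(df)
    if not records:
        raise DataError("no valid records after validation")
    subjects = SubjectTable.from_records(records, category_a_diagnoses)
    return RepertoireStore(records, subjects, dropped_count=dropped)


def load_airr(
    path: str | Path, category_a_diagnoses: Iterable[str]
) -> RepertoireStore:
    """Load an AIRR-style rearrangement TSV.

    Required columns: sequence_id, subject_id, diagnosis, sequence_aa,
    cdr3_start, cdr3_end (0-based half-open).  Records failing validation
    are dropped and counted in ``store.dropped_count``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return store_from_frame(df, category_a_diagnoses)


def load_fasta(
    fasta_path: str | Path,
    subject_metadata: str | Path,
    annotations: str | Path,
    category_a_diagnoses: Iterable[str],
) -> RepertoireStore:
    """Secondary loader: FASTA sequences plus two metadata TSVs.

    ``subject_metadata`` maps subject_id → diagnosis; ``annotations`` maps
    record_id → (subject_id, cdr3_start, cdr3_end).  The FASTA header's
    first whitespace token is the record_id.
    """
    from Bio import SeqIO

    meta = pd.read_csv(subject_metadata, sep="\t", dtype=str)
    for col in ("subject_id", "diagnosis"):
        if col not in meta.columns:
            raise DataError(f"missing required column(s): {col}")
    ann = pd.read_csv(annotations, sep="\t", dtype=str)
    for col in ("record_id", "subject_id", "cdr3_start", "cdr3_end"):
        if col not in ann.columns:
            raise DataError(f"missing required column(s): {col}")
    diag = dict(zip(meta["subject_id"], meta["diagnosis"]))
    ann_map = {
        r.record_id: (r.subject_id, int(r.cdr3_start), int(r.cdr3_end))
        for r in ann.itertuples(index=False)
    }
    rows = []
    for seq in SeqIO.parse(str(fasta_path), "fasta"):
        if seq.id not in ann_map:
            continue
        subject_id, c_start, c_end = ann_map[seq.id]
        rows.append(
            {
                "sequence_id": seq.id,
                "subject_id": subject_id,
                "diagnosis": diag.get(subject_id, ""),
                "sequence_aa": str(seq.seq).upper(),
                "cdr3_start": c_start,
                "cdr3_end": c_end,
            }
        )
    if not rows:
        raise DataError("no FASTA records with annotations found")
    return store_from_frame(pd.DataFrame(rows), category_a_diagnoses)


def query_motif(store: RepertoireStore, motif: MotifVector) -> MatchResult:
    """Functional form of :meth:`RepertoireStore.query_motif`."""
    return store.query_motif(motif)


def restrict(store: RepertoireStore, motif: MotifVector) -> RepertoireStore:
    """Functional form of :meth:`RepertoireStore.restrict`."""
    return store.restrict(motif)
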