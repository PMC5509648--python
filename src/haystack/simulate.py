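"""Synthetic case-control IgG-VH repertoires with a planted motif.

The generator emulates the statistical shape the search assumes: diverse
germline-templated heavy-chain amino-acid sequences (~100-130 residues,
CDR3 annotated) across two diagnostic categories, with a low-frequency
position-specific motif carried by a controlled fraction of case subjects
and (by default) no controls.  Each subject is assigned a framework
template from a small pool of IGHV3-like allelic variants (germline
variation is a property of the person, not the sequence); each sequence
is that framework, followed by a CDR3 of random length that begins with
the germline-templated "CAR", followed by a fixed FR4; point
substitutions at a per-residue rate model somatic hypermutation.  Carrier
status is drawn per subject from the category prevalence; each carrier
gets a deterministic count of motif-bearing sequences
(max(1, round(carrier_seq_fraction * n_sequences))), and planted positions
are protected from background mutation so the ground truth is exact.

What this emulates and what it does not: the motif-in-noise structure,
subject grouping, CDR3-anchored coordinates and realistic per-carrier hit
counts are faithful; V(D)J recombination, insertion/deletion events,
clonal lineage structure and nucleotide space are not modeled.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .motif import AA_ALPHABET, MotifVector, parse_motif
from .store import AIRR_COLUMNS, RepertoireStore, store_from_frame

_AA = np.frombuffer(AA_ALPHABET.encode(), dtype=np.uint8)

# IGHV3-style frameworks (FR1-FR3), ending on the germline "...AVYY" that
# precedes the CDR3's opening cysteine.  The default is a single shared
# framework: at desk-scale cohorts (tens of subjects), splitting subjects
# across template variants shrinks the effective control denominator for
# template-private positions and turns ordinary mutation noise into
# apparent disease-only signal — an artifact of scale, not of the method.
# TEMPLATE_VARIANTS provides allelic variants for multi-template cohorts.
DEFAULT_TEMPLATES = (
    "EVQLLESGGGLVQPGGSLRLSCAASGFTFSSYAMSWVRQAPGKGLEWVSAISGSGGSTYYADSVKGRFTISRDNSKNTLYLQMNSLRAEDTAVYY",
)
TEMPLATE_VARIANTS = DEFAULT_TEMPLATES + (
    "EVQLVESGGGLVQPGGSLRLSCAASGFTFSSYWMSWVRQAPGKGLEWVANIKQDGSEKYYVDSVKGRFTISRDNAKNSLYLQMNSLRAEDTAVYY",
    "QVQLVESGGGVVQPGRSLRLSCAASGFTFSSYGMHWVRQAPGKGLEWVAVISYDGSNKYYADSVKGRFTISRDNSKNTLYLQMNSLRAEDTAVYY",
)
FR4 = "WGQGTLVTVSS"
CDR3_PREFIX = "CAR"


class GeneratorError(ValueError):
    """Invalid generator configuration."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic cohort.

    Defaults give 20+20 subjects x ~500 sequences (~20,000 records): large
    enough to exercise recursive restriction, small enough for
    minutes-scale runs.  ``prevalence_case``/``prevalence_control`` are
    per-subject carrier probabilities; ``carrier_seq_fraction`` is the
    fraction of a carrier's sequences bearing the motif (default 0.01,
    i.e. a handful of hits per carrier, mirroring a biomarker-scale signal
    that touches well under 0.1% of all sequences).
    ``point_mutation_rate`` (default 0.05 per residue) is an
    IgG-plausible amino-acid-level hypermutation load.
    """

    n_case: int = 20
    n_control: int = 20
    seqs_per_subject: float = 500.0  # Poisson mean
    germline_templates: tuple[str, ...] = DEFAULT_TEMPLATES
    cdr3_length_min: int = 10
    cdr3_length_max: int = 17
    point_mutation_rate: float = 0.05
    planted_motif: str | None = "(TNE, 14), (DTA, 6), (CAR, 0)"
    prevalence_case: float = 0.7
    prevalence_control: float = 0.0
    carrier_seq_fraction: float = 0.01
    planting: str = "exact"  # "exact" | "bernoulli"
    case_diagnosis: str = "MS"
    control_diagnosis: str = "HC"
    seed: int = 0

    def motif(self) -> MotifVector | None:
        if self.planted_motif is None:
            return None
        if isinstance(self.planted_motif, MotifVector):
            return self.planted_motif
        return parse_motif(self.planted_motif)

    def validate(self) -> None:
        if self.n_case < 1 or self.n_control < 1:
            raise GeneratorError("both categories need at least one subject")
        if self.seqs_per_subject <= 0:
            raise GeneratorError("seqs_per_subject must be positive")
        for p_name in ("point_mutation_rate", "prevalence_case",
                       "prevalence_control", "carrier_seq_fraction"):
            p = getattr(self, p_name)
            if not (0.0 <= p <= 1.0):
                raise GeneratorError(f"{p_name} must be in [0, 1], got {p}")
        if not self.germline_templates:
            raise GeneratorError("at least one germline template is required")
        if not (3 <= self.cdr3_length_min <= self.cdr3_length_max):
            raise GeneratorError("need 3 <= cdr3_length_min <= cdr3_length_max")
        if self.planting not in ("exact", "bernoulli"):
            raise GeneratorError(f"unknown planting mode {self.planting!r}")
        motif = self.motif()
        if motif is not None:
            for template in self.germline_templates:
                for pos in motif.position_map():
                    if pos < -len(template):
                        raise GeneratorError(
                            f"template of length {len(template)} too short to "
                            f"host motif position {pos}"
                        )
                    if pos >= self.cdr3_length_min:
                        raise GeneratorError(
                            f"motif position {pos} falls beyond the shortest "
                            f"CDR3 (length {self.cdr3_length_min})"
                        )


@dataclass
class TruthManifest:
    """Ground truth for a generated cohort."""

    motif: str | None
    subjects: dict[str, dict]  # subject_id -> category/diagnosis/carrier/...
    planted_record_ids: list[str]
    n_records: int
    config: dict

    @property
    def carriers(self) -> list[str]:
        return [s for s, info in self.subjects.items() if info["carrier"]]

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "TruthManifest":
        return cls(**json.loads(Path(path).read_text()))


def _mutate(codes: np.ndarray, n_germline: int, rate: float,
            protected: set[int], rng: np.random.Generator) -> None:
    """Substitute germline-derived positions in place at ``rate``; planted
    positions stay untouched so prevalence parameters are exact."""
    if rate <= 0:
        return
    hits = np.flatnonzero(rng.random(n_germline) < rate)
    for pos in hits:
        if int(pos) in protected:
            continue
        current = codes[pos]
        repl = rng.integers(0, 19)
        codes[pos] = _AA[repl if _AA[repl] != current else 19]


def generate(config: GeneratorConfig) -> tuple[pd.DataFrame, TruthManifest]:
    """Generate one cohort: an AIRR-dialect DataFrame plus its manifest.

    Deterministic given ``config.seed``.  Every planted record is
    self-checked against the motif at generation time.
    """
    config.validate()
    # independent substreams so that one draw category (e.g. carrier flags)
    # is stable under changes to the others
    root = np.random.default_rng(config.seed)
    rng_carrier, rng_size, rng = root.spawn(3)
    motif = config.motif()
    pmap = motif.position_map() if motif is not None else {}

    templates = [
        np.frombuffer(t.encode(), dtype=np.uint8) for t in config.germline_templates
    ]
    fr4 = np.frombuffer(FR4.encode(), dtype=np.uint8)
    prefix = np.frombuffer(CDR3_PREFIX.encode(), dtype=np.uint8)

    groups = [
        ("case", config.n_case, config.case_diagnosis, config.prevalence_case),
        ("ctrl", config.n_control, config.control_diagnosis, config.prevalence_control),
    ]
    rows: list[tuple] = []
    subjects: dict[str, dict] = {}
    planted_ids: list[str] = []
    check_records: list[tuple[str, int]] = []  # (sequence, cdr3_start) planted

    for label, count, diagnosis, prevalence in groups:
        for s in range(1, count + 1):
            subject_id = f"{label}{s:03d}"
            t_idx = int(rng_size.integers(0, len(templates)))
            fw = templates[t_idx]
            cdr3_start = len(fw)
            n_seqs = max(1, int(rng_size.poisson(config.seqs_per_subject)))
            carrier = bool(rng_carrier.random() < prevalence) and motif is not None
            if not carrier:
                n_planted = 0
            elif config.planting == "exact":
                # exact ground truth: every carrier bears at least one hit
                n_planted = max(1, round(config.carrier_seq_fraction * n_seqs))
            else:
                # per-sequence Bernoulli: carriers can draw zero hits, which
                # is what makes the detection limit observable
                n_planted = int(rng.binomial(n_seqs, config.carrier_seq_fraction))
            planted_flags = np.zeros(n_seqs, dtype=bool)
            if n_planted:
                planted_flags[
                    rng.choice(n_seqs, size=min(n_planted, n_seqs), replace=False)
                ] = True
            for i in range(n_seqs):
                cdr3_len = int(
                    rng.integers(config.cdr3_length_min, config.cdr3_length_max + 1)
                )
                cdr3_tail = _AA[rng.integers(0, 20, size=cdr3_len - len(prefix))]
                codes = np.concatenate([fw, prefix, cdr3_tail, fr4])
                protected: set[int] = set()
                if planted_flags[i]:
                    for rel, residue in pmap.items():
                        idx = cdr3_start + rel
                        codes[idx] = ord(residue)
                        protected.add(idx)
                # germline-derived stretch: framework + CDR3 prefix; the
                # random CDR3 tail carries its diversity already, FR4 is
                # held constant as a J-segment stand-in
                _mutate(codes, cdr3_start + len(prefix),
                        config.point_mutation_rate, protected, rng)
                seq = codes.tobytes().decode("ascii")
                record_id = f"{subject_id}-{i + 1:05d}"
                if planted_flags[i]:
                    planted_ids.append(record_id)
                    check_records.append((seq, cdr3_start))
                rows.append(
                    (
                        record_id,
                        subject_id,
                        diagnosis,
                        seq,
                        cdr3_start,
                        cdr3_start + cdr3_len,
                        f"IGHV3-syn{t_idx + 1}*01",
                        "IGHJ4*02",
                    )
                )
            subjects[subject_id] = {
                "category": "A" if label == "case" else "B",
                "diagnosis": diagnosis,
                "carrier": bool(carrier),
                "n_sequences": n_seqs,
                "n_planted": int(n_planted if carrier else 0),
            }

    if motif is not None:
        for seq, cdr3_start in check_records:
            rec = _Probe(seq, cdr3_start)
            if not motif.matches(rec):  # pragma: no cover - generation self-check
                raise AssertionError("planted record fails to match the motif")

    df = pd.DataFrame(rows, columns=list(AIRR_COLUMNS) + ["v_call", "j_call"])
    manifest = TruthManifest(
        motif=str(motif) if motif is not None else None,
        subjects=subjects,
        planted_record_ids=planted_ids,
        n_records=len(df),
        config={
            **{
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in dataclasses.asdict(config).items()
            },
            "planted_motif": str(motif) if motif is not None else None,
        },
    )
    return df, manifest


class _Probe:
    """Minimal record-like object for generation-time self-checks."""

    __slots__ = ("aa_sequence", "cdr3_start")

    def __init__(self, aa_sequence: str, cdr3_start: int):
        self.aa_sequence = aa_sequence
        self.cdr3_start = cdr3_start


def null_cohort(config: GeneratorConfig) -> tuple[pd.DataFrame, TruthManifest]:
    """Generate a cohort with no planted motif (negative-control runs)."""
    return generate(dataclasses.replace(config, planted_motif=None))


def to_store(df: pd.DataFrame, category_a_diagnoses=("MS",)) -> RepertoireStore:
    """Convenience: build a repertoire store straight from generator output."""
    return store_from_frame(df, category_a_diagnoses)


def write_airr(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
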