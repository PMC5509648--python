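"""Position-specific gapped amino-acid motifs anchored to the CDR3.

A motif is an ordered set of components, each an explicit motif subsequence
(EMS) — a contiguous run of specified residues — plus an integer *offset*:
the number of residues the component's leftmost character sits to the left
of the first CDR3 residue.  Offset 0 means the component begins on the
first CDR3 residue; components may start inside the CDR3 (negative offset)
or extend past it.  Runs of unspecified positions between components are
*gaps*, so a motif with ``n`` gaps has ``n + 1`` components.

Coordinates throughout are CDR3-relative: position 0 is the first CDR3
residue, position ``-offset`` is where a component starts.  A sequence
matches a motif iff every specified position lies inside the sequence and
carries exactly the specified residue; there is no similarity scoring.

Motifs are written in parenthesis notation, e.g.
``(TNE, 14), (DTA, 6), (CAR, 0)`` — three EMSs anchored 14, 6 and 0
residues left of the CDR3 start.  Canonical form sorts components by
decreasing offset (leftmost first) and fuses components that touch or
overlap consistently, so gap counting is well defined and
``parse_motif(str(m)) == m``.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AA_ALPHABET)

#: minimum EMS length at component creation (standard short-linear-motif floor)
MIN_EMS_LENGTH = 3


class MotifError(ValueError):
    """Invalid motif construction or parse input."""


class MotifConflictError(MotifError):
    """Two specified positions demand different residues.

    Raised by extension and merge operators; the search layer treats it as
    a prune signal rather than an error condition.
    """


def all_triplets() -> list[str]:
    """Enumerate every possible atomic EMS: the 20**3 = 8,000 residue triplets."""
    return ["".join(t) for t in itertools.product(AA_ALPHABET, repeat=3)]


@dataclass(frozen=True, order=True)
class MotifComponent:
    """One explicit subsequence with its CDR3-relative anchor.

    ``offset`` counts residues to the *left* of the first CDR3 residue, so
    the component occupies CDR3-relative positions ``-offset`` through
    ``-offset + len(ems) - 1``.
    """

    ems: str
    offset: int

    def __post_init__(self) -> None:
        if len(self.ems) < MIN_EMS_LENGTH:
            raise MotifError(
                f"EMS {self.ems!r} shorter than the minimum length {MIN_EMS_LENGTH}"
            )
        bad = set(self.ems) - _AA_SET
        if bad:
            raise MotifError(
                f"EMS {self.ems!r} contains non-standard residues {sorted(bad)}"
            )

    @property
    def start(self) -> int:
        """First occupied CDR3-relative position."""
        return -self.offset

    @property
    def end(self) -> int:
        """One past the last occupied CDR3-relative position."""
        return -self.offset + len(self.ems)

    def positions(self) -> Iterator[tuple[int, str]]:
        for i, residue in enumerate(self.ems):
            yield self.start + i, residue

    def __str__(self) -> str:
        return f"({self.ems}, {self.offset})"


def _canonical_components(
    position_map: dict[int, str],
) -> tuple[MotifComponent, ...]:
    """Group a position→residue map into maximal contiguous components."""
    out: list[MotifComponent] = []
    positions = sorted(position_map)
    run_start = None
    prev = None
    chars: list[str] = []
    for p in positions:
        if prev is None or p != prev + 1:
            if chars:
                out.append(MotifComponent("".join(chars), -run_start))
            run_start, chars = p, []
        chars.append(position_map[p])
        prev = p
    if chars:
        out.append(MotifComponent("".join(chars), -run_start))
    # leftmost (largest offset) first, matching the reported-motif convention
    return tuple(sorted(out, key=lambda c: -c.offset))


@dataclass(frozen=True)
class MotifVector:
    """A canonical gapped motif: disjoint, non-adjacent components sorted
    by decreasing offset."""

    components: tuple[MotifComponent, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.components:
            raise MotifError("a motif needs at least one component")
        pmap = _merge_position_maps(
            [dict(c.positions()) for c in self.components], context="component"
        )
        canon = _canonical_components(pmap)
        if canon != self.components:
            object.__setattr__(self, "components", canon)

    # -- construction -----------------------------------------------------
    @classmethod
    def from_components(
        cls, components: Iterable[MotifComponent | tuple[str, int]]
    ) -> "MotifVector":
        comps = [
            c if isinstance(c, MotifComponent) else MotifComponent(*c)
            for c in components
        ]
        return cls(tuple(comps))

    @classmethod
    def atomic(cls, triplet: str, offset: int) -> "MotifVector":
        return cls((MotifComponent(triplet, offset),))

    # -- structure --------------------------------------------------------
    @property
    def cardinality(self) -> int:
        return len(self.components)

    @property
    def gap_count(self) -> int:
        return len(self.components) - 1

    @property
    def explicit_length(self) -> int:
        return sum(len(c.ems) for c in self.components)

    def position_map(self) -> dict[int, str]:
        return {p: r for c in self.components for p, r in c.positions()}

    # -- match semantics --------------------------------------------------
    def matches(self, record) -> bool:
        """Exact match against an annotated sequence.

        ``record`` needs ``aa_sequence`` and ``cdr3_start`` attributes.
        Out-of-bounds specified positions mean no match, never an error.
        """
        seq = record.aa_sequence
        anchor = record.cdr3_start
        n = len(seq)
        for comp in self.components:
            for rel, residue in comp.positions():
                idx = anchor + rel
                if idx < 0 or idx >= n or seq[idx] != residue:
                    return False
        return True

    # -- serialization ----------------------------------------------------
    def __str__(self) -> str:
        return ", ".join(str(c) for c in self.components)

    def to_dict(self) -> dict:
        return {
            "components": [
                {"ems": c.ems, "offset": c.offset} for c in self.components
            ]
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "MotifVector":
        return cls.from_components(
            (c["ems"], c["offset"]) for c in payload["components"]
        )


def _merge_position_maps(maps, context="motif") -> dict[int, str]:
    """Union position→residue maps, raising on conflicting residues."""
    out: dict[int, str] = {}
    for m in maps:
        for p, r in m.items():
            if p in out and out[p] != r:
                raise MotifConflictError(
                    f"conflicting residues {out[p]!r} vs {r!r} at "
                    f"CDR3-relative position {p} while merging {context}s"
                )
            out[p] = r
    return out


_GROUP_RE = re.compile(r"\(\s*([A-Za-z]*)\s*,\s*(-?\d+)\s*\)")


def parse_motif(text: str) -> MotifVector:
    """Parse parenthesis notation, e.g. ``"(TNE, 14), (DTA, 6), (CAR, 0)"``.

    Returns the canonical motif.  Raises :class:`MotifError` naming the
    offending group for malformed input, non-residue characters, or
    conflicting duplicate positions.
    """
    if not isinstance(text, str) or not text.strip():
        raise MotifError("empty motif string")
    stripped = _GROUP_RE.sub("", text)
    if stripped.strip(" ,\t\n"):
        raise MotifError(
            f"malformed motif string near {stripped.strip()[:20]!r}; expected "
            "comma-separated '(EMS, offset)' groups"
        )
    comps = []
    for ems, offset in _GROUP_RE.findall(text):
        try:
            comps.append(MotifComponent(ems.upper(), int(offset)))
        except MotifError as exc:
            raise MotifError(f"bad group ({ems}, {offset}): {exc}") from exc
    if not comps:
        raise MotifError("no '(EMS, offset)' groups found")
    try:
        return MotifVector.from_components(comps)
    except MotifConflictError as exc:
        raise MotifError(f"inconsistent motif {text!r}: {exc}") from exc


def format_motif(motif: MotifVector) -> str:
    """Canonical parenthesis notation (inverse of :func:`parse_motif`)."""
    return str(motif)


def matches(motif: MotifVector, record) -> bool:
    """Functional form of :meth:`MotifVector.matches`."""
    return motif.matches(record)


def gap_count(motif: MotifVector) -> int:
    return motif.gap_count


def explicit_length(motif: MotifVector) -> int:
    return motif.explicit_length


def ems_extend(
    motif: MotifVector, component_index: int, side: str, residue: str
) -> MotifVector:
    """Lengthen one component by a single residue.

    ``side`` is ``"N"`` (leftward; the component's offset grows by one) or
    ``"C"`` (rightward; offset unchanged).  If the new position touches
    another component consistently the two fuse during canonicalization;
    an inconsistent residue at a shared position raises
    :class:`MotifConflictError` (a prune signal for the search).
    """
    if side not in ("N", "C"):
        raise MotifError(f"side must be 'N' or 'C', got {side!r}")
    if residue not in _AA_SET:
        raise MotifError(f"not a standard residue: {residue!r}")
    comp = motif.components[component_index]
    pos = comp.start - 1 if side == "N" else comp.end
    pmap = motif.position_map()
    if pos in pmap and pmap[pos] != residue:
        raise MotifConflictError(
            f"extension residue {residue!r} collides with {pmap[pos]!r} at "
            f"position {pos}"
        )
    pmap[pos] = residue
    return MotifVector(_canonical_components(pmap))


def cardinality_extend(motif: MotifVector, atomic) -> MotifVector:
    """Append a new atomic component, adding one gap and one dimension.

    The atomic's occupied range must be disjoint from and non-adjacent to
    every existing component; overlap or adjacency raises
    :class:`MotifError` directing the caller to :func:`merge`.
    """
    if isinstance(atomic, MotifVector):
        if atomic.cardinality != 1:
            raise MotifError("cardinality extension takes a single atomic component")
        atomic = atomic.components[0]
    for comp in motif.components:
        if atomic.start <= comp.end and comp.start <= atomic.end:
            # touching ranges (shared or adjacent positions)
            raise MotifError(
                f"component {atomic} overlaps or touches {comp}; use merge()"
            )
    return MotifVector(motif.components + (atomic,))


def merge(m1: MotifVector, m2: MotifVector) -> MotifVector:
    """Fold the components of ``m2`` into ``m1``.

    Disjoint components are appended (cardinality extension); components
    that overlap consistently or sit adjacent are fused into longer EMSs
    (the multi-residue analogue of EMS extension).  Conflicting residues
    raise :class:`MotifConflictError`.
    """
    pmap = _merge_position_maps([m1.position_map(), m2.position_map()])
    return MotifVector(_canonical_components(pmap))
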