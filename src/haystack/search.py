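"""Breadth-first local search for disease-only motifs (DOMs).

The heuristic walks a network whose nodes are canonical gapped motifs and
whose edges are single-residue EMS extensions, cardinality extensions and
merges.  One run:

1. *Triplet extraction* — tally every residue triplet; keep those carried
   by at least floor(Dt * |A|) distinct category-A subjects.
2. *Atomic vector generation* — give each surviving triplet the
   CDR3-relative offset that maximizes its category-A subject count a;
   drop vectors whose objective score falls below St.
3. *Non-gapped EMS extension* — add every one-residue N/C-side extension
   supported by at least one record; St-filter.  The survivors are the
   seed frontier L.
4. *Recursive restriction* — for each frontier motif M, restrict the
   store to the sub-repertoire matching M and rerun steps 1-3 there
   (thresholds still measured against the original |A|), yielding short
   non-gapped motifs L' that co-occur with M.
5. *Motif merging* — fold each element of L' into M: disjoint components
   append (cardinality extension), overlapping/adjacent consistent ones
   fuse (EMS extension); conflicts prune.  Candidates exceeding the gap
   budget Gc are discarded.
6. *Iteration* — the merged survivors form the next frontier.

A motif is a DOM when it matches zero category-B subjects and at least
floor(Dt * |A|) category-A subjects.  Every unique canonical motif scored
against the main store counts toward the traversal total C, which feeds
the Mev significance bound.  The search is fully deterministic: frontiers
are processed in canonical-string order and a visited set guarantees no
motif is scored twice.

The St pruning is greedy: a DOM whose individual components score poorly
in the full cohort can be missed (the separating signal may only emerge
after restriction).  That trade-off buys the scalability that makes
million-sequence repertoires searchable at all.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable

import numpy as np

from .motif import MotifConflictError, MotifVector, merge
from .significance import SignificanceReport
from .store import MatchResult, RepertoireStore, code_to_triplet, triplet_code


class _StopSearch(Exception):
    """Internal control flow for the first_dom stop policy."""


@dataclass(frozen=True)
class SearchConfig:
    """Thresholds and policies for one heuristic run.

    dt
        DOM-determining threshold: minimum fraction of category-A subjects
        a DOM must match (with zero category-B matches).  Default 0.6.
    st
        Separation threshold compared against the objective score; motifs
        scoring below it are pruned from further traversal.  Default 15.
    gc
        Maximum gap count (= components - 1) of any output motif.
        Default 2.
    objective
        "separation" scores a - b; "category_blind" scores
        -(a + b - k)**2, maximized when the total match count hits the
        center k (k defaults to |A| at run time).  St is compared against
        whichever objective is active.
    stop_policy
        "finish_level" (default) completes the BFS level in which the
        first DOM appears and reports every DOM found by then;
        "first_dom" stops at the first DOM; "exhaust" ignores DOMs as a
        stopping condition and runs the frontier dry.
    tally_mode
        "subjects" (default) thresholds the triplet tally on distinct
        category-A subjects; "occurrences" thresholds on raw occurrence
        counts over the whole database (fidelity switch).
    """

    dt: float = 0.6
    st: int = 15
    gc: int = 2
    objective: str = "separation"
    k: int | None = None
    stop_policy: str = "finish_level"
    tally_mode: str = "subjects"

    def __post_init__(self) -> None:
        if not (0.0 < self.dt <= 1.0):
            raise ValueError("dt must be in (0, 1]")
        if self.st < 0 and self.objective == "separation":
            raise ValueError("st must be >= 0 for the separation objective")
        if self.gc < 0:
            raise ValueError("gc must be >= 0")
        if self.objective not in ("separation", "category_blind"):
            raise ValueError(f"unknown objective {self.objective!r}")
        if self.stop_policy not in ("finish_level", "first_dom", "exhaust"):
            raise ValueError(f"unknown stop_policy {self.stop_policy!r}")
        if self.tally_mode not in ("subjects", "occurrences"):
            raise ValueError(f"unknown tally_mode {self.tally_mode!r}")


@dataclass
class SearchResult:
    """Outcome of one run: DOMs with their evidence, plus traversal stats."""

    doms: list[tuple[MotifVector, MatchResult, SignificanceReport]]
    traversed_count: int
    levels: list[dict] = field(default_factory=list)
    config: SearchConfig | None = None
    dom_threshold: int = 0


def dom_count_threshold(dt: float, size_a: int) -> int:
    """Minimum category-A match count for DOM status: floor(Dt * |A|).

    Floor (not ceiling) reconciles a fractional threshold with integer
    match counts at cohort sizes where Dt * |A| is not integral.
    """
    return math.floor(dt * size_a)


def separation_score(match: MatchResult, config: SearchConfig) -> int:
    """Objective score of a match result (higher is better).

    "separation" returns a - b; "category_blind" returns
    -(a + b - k)**2 with k defaulting to |A| (resolved by the caller via
    ``config.k``)."""
    if config.objective == "category_blind":
        if config.k is None:
            raise ValueError("category_blind objective requires k to be resolved")
        return -((match.a + match.b - config.k) ** 2)
    return match.separation


def _resolved(config: SearchConfig, store: RepertoireStore) -> SearchConfig:
    if config.objective == "category_blind" and config.k is None:
        return replace(config, k=store.size_a)
    return config


def tally_triplets(store: RepertoireStore, config: SearchConfig) -> dict[str, int]:
    """Triplet tally filtered by the DOM-count threshold.

    In "subjects" mode the value is the number of distinct category-A
    subjects whose repertoire contains the triplet anywhere; in
    "occurrences" mode it is the raw occurrence count over all records.
    """
    stats = store.triplet_stats()
    thr = dom_count_threshold(config.dt, store.size_a)
    counts = (
        stats.a_subjects_by_triplet
        if config.tally_mode == "subjects"
        else stats.occurrences_by_triplet
    )
    keep = np.flatnonzero(counts >= max(thr, 1))
    return {code_to_triplet(int(c)): int(counts[c]) for c in keep}


def make_atomic_vector(
    triplet: str, store: RepertoireStore, config: SearchConfig
) -> MotifVector | None:
    """Assign the triplet the offset maximizing the category-A subject
    count a (ties broken toward the smallest offset, i.e. closest to the
    CDR3).  Returns None if the triplet occurs nowhere."""
    offsets, a_counts, _ = store.triplet_stats().rows_for(triplet_code(triplet))
    if len(offsets) == 0:
        return None
    best = np.lexsort((offsets, -a_counts))[0]  # max a, then min offset
    return MotifVector.atomic(triplet, int(offsets[best]))


def extend_nongapped(
    vectors: Iterable[MotifVector],
    store: RepertoireStore,
    config: SearchConfig,
    score: Callable[[MotifVector], MatchResult | None] | None = None,
) -> list[MotifVector]:
    """Step 3: the input vectors plus every supported one-residue
    N/C-side extension, all filtered by St.

    ``score`` lets the caller observe/count each query (main-store path);
    when omitted the store is queried directly (sub-database path).
    Assumes the input vectors already passed the St filter.
    """
    config = _resolved(config, store)
    if score is None:
        seen: set[str] = set()

        def score(m: MotifVector, _seen=seen) -> MatchResult | None:
            key = str(m)
            if key in seen:
                return None
            seen.add(key)
            return store.query_motif(m)

    out: list[MotifVector] = []
    for vec in sorted(vectors, key=str):
        out.append(vec)
        comp = vec.components[0]
        for side, rel in (("N", comp.start - 1), ("C", comp.end)):
            for residue in store.flank_residues(vec, rel):
                if side == "N":
                    ext = MotifVector.atomic(residue + comp.ems, comp.offset + 1)
                else:
                    ext = MotifVector.atomic(comp.ems + residue, comp.offset)
                result = score(ext)
                if result is None or not result.matched_record_ids:
                    continue
                if separation_score(result, config) >= config.st:
                    out.append(ext)
    return out


def _seed_vectors(
    store: RepertoireStore,
    config: SearchConfig,
    score: Callable[[MotifVector], MatchResult | None],
) -> list[MotifVector]:
    """Steps 1-2: St-surviving atomic vectors."""
    survivors: list[MotifVector] = []
    for triplet in sorted(tally_triplets(store, config)):
        vec = make_atomic_vector(triplet, store, config)
        if vec is None:
            continue
        result = score(vec)
        if result is None:
            continue
        if separation_score(result, config) >= config.st:
            survivors.append(vec)
    return survivors


def recursive_restriction(
    motif: MotifVector, store: RepertoireStore, config: SearchConfig
) -> list[MotifVector]:
    """Steps 1-3 rerun on the sub-repertoire matching ``motif``.

    Returns short non-gapped motifs L' that co-occur with ``motif``;
    thresholds are computed against the original |A| and |B| because the
    restricted store inherits the parent's denominators.
    """
    config = _resolved(config, store)
    sub = store.restrict(motif)
    if len(sub) == 0:
        return []

    def sub_score(m: MotifVector) -> MatchResult:
        return sub.query_motif(m)

    seed = _seed_vectors(sub, config, lambda m: sub_score(m))
    return extend_nongapped(seed, sub, config, score=lambda m: sub_score(m))


def run(store: RepertoireStore, config: SearchConfig | None = None) -> SearchResult:
    """Execute the full heuristic on ``store``.

    Deterministic given identical inputs.  The traversal count C is the
    number of unique canonical motifs scored against ``store``;
    sub-database queries inside recursive restriction are not counted.
    Each reported DOM carries a significance report computed with this
    run's own final C.
    """
    config = _resolved(config or SearchConfig(), store)
    thr = max(1, dom_count_threshold(config.dt, store.size_a))
    visited: set[str] = set()
    doms: dict[str, tuple[MotifVector, MatchResult]] = {}
    levels: list[dict] = []

    def score(motif: MotifVector) -> MatchResult | None:
        key = str(motif)
        if key in visited:
            return None
        visited.add(key)
        result = store.query_motif(motif)
        if result.b == 0 and result.a >= thr:
            doms[key] = (motif, result)
            if config.stop_policy == "first_dom":
                raise _StopSearch
        return result

    def log_level(level: int, frontier: list[MotifVector]) -> None:
        levels.append(
            {
                "level": level,
                "frontier_size": len(frontier),
                "scored_total": len(visited),
                "doms_total": len(doms),
            }
        )

    frontier: list[MotifVector] = []
    try:
        seed = _seed_vectors(store, config, score)
        frontier = extend_nongapped(seed, store, config, score=score)
        log_level(0, frontier)
        level = 0
        while frontier and not (doms and config.stop_policy != "exhaust"):
            level += 1
            next_frontier: list[MotifVector] = []
            for motif in sorted(frontier, key=str):
                for piece in recursive_restriction(motif, store, config):
                    try:
                        merged = merge(motif, piece)
                    except MotifConflictError:
                        continue  # inconsistent overlap: prune
                    if merged == motif or merged.gap_count > config.gc:
                        continue
                    result = score(merged)
                    if result is None:
                        continue
                    if separation_score(result, config) >= config.st:
                        next_frontier.append(merged)
            frontier = next_frontier
            log_level(level, frontier)
    except _StopSearch:
        log_level(-1, frontier)

    c = len(visited)
    reported = []
    for key in sorted(doms, key=lambda k: (-doms[k][1].a, k)):
        motif, result = doms[key]
        report = SignificanceReport.compute(
            a=result.a, size_a=store.size_a, size_b=store.size_b, c=c
        )
        reported.append((motif, result, report))
    return SearchResult(
        doms=reported,
        traversed_count=c,
        levels=levels,
        config=config,
        dom_threshold=thr,
    )
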