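"""The local search: thresholds, seeding, restriction, merging, full runs."""

import random
from collections import defaultdict

import pytest

from haystack.motif import MotifVector, parse_motif
from haystack.search import (
    SearchConfig,
    dom_count_threshold,
    extend_nongapped,
    make_atomic_vector,
    recursive_restriction,
    run,
    separation_score,
    tally_triplets,
)
from haystack.store import MatchResult

from conftest import build_store, random_store

CONJ_CONFIG = SearchConfig(dt=0.6, st=5, gc=2)


class TestDomCountThreshold:
    @pytest.mark.parametrize("dt,size_a,expected", [
        (0.6, 51, 30),   # production-scale cutoff: 30 of 51 patients
        (1.0, 10, 10),
        (0.6, 10, 6),
    ])
    def test_floor_semantics(self, dt, size_a, expected):
        assert dom_count_threshold(dt, size_a) == expected


class TestSeparationScore:
    def _match(self, a, b):
        return MatchResult(
            MotifVector.atomic("AAA", 0), (),
            frozenset(f"a{i}" for i in range(a)),
            frozenset(f"b{i}" for i in range(b)))

    def test_separation_objective(self):
        cfg = SearchConfig()
        assert separation_score(self._match(20, 3), cfg) == 17
        assert separation_score(self._match(0, 0), cfg) == 0

    def test_category_blind_objective(self):
        cfg = SearchConfig(objective="category_blind", k=51)
        assert separation_score(self._match(30, 21), cfg) == 0  # at center
        assert separation_score(self._match(30, 26), cfg) == -25


class TestTallyTriplets:
    def test_distinct_subject_counting(self, toy_store):
        cfg = SearchConfig(dt=0.5, st=0)  # threshold floor(0.5*2) = 1
        tally = tally_triplets(toy_store, cfg)
        assert tally["CAR"] == 2  # both MS subjects, dedup within p1
        assert tally["TNE"] == 2
        assert "WWW" not in tally  # HC-only triplet never counts toward A

    def test_equals_bruteforce_per_subject_scan(self):
        store = random_store(3, n_subjects=10, n_records=60)
        cfg = SearchConfig(dt=0.2, st=0)
        tally = tally_triplets(store, cfg)
        by_triplet = defaultdict(set)
        for rec in store.records:
            if store.subjects.category(rec.subject_id) != "A":
                continue
            for i in range(len(rec.aa_sequence) - 2):
                by_triplet[rec.aa_sequence[i:i + 3]].add(rec.subject_id)
        thr = max(1, dom_count_threshold(cfg.dt, store.size_a))
        expected = {t: len(s) for t, s in by_triplet.items() if len(s) >= thr}
        assert tally == expected

    def test_closure_within_triplet_space(self, toy_store):
        cfg = SearchConfig(dt=0.1, st=0)
        assert len(tally_triplets(toy_store, cfg)) <= 8000


class TestMakeAtomicVector:
    def test_unique_offset(self, toy_store):
        cfg = SearchConfig(dt=0.5, st=0)
        vec = make_atomic_vector("CAR", toy_store, cfg)
        assert vec == MotifVector.atomic("CAR", 0)

    def test_maximizes_a_over_offsets(self):
        # AAA at offset 3 in 4 MS subjects, at offset 9 in only 2
        rows = []
        for i in range(4):
            rows.append((f"m{i}", f"ms{i}", "MS", "G" * 7 + "AAA" + "G" * 3 + "CARWW", 10))
        for i in range(2):
            rows.append((f"n{i}", f"ms{i}", "MS", "G" + "AAA" + "G" * 6 + "CARWW", 10))
        store = build_store(rows)
        vec = make_atomic_vector("AAA", store, SearchConfig(dt=0.1, st=0))
        assert vec.components[0].offset == 3

    def test_tie_breaks_toward_smaller_offset(self):
        rows = [("r0", "ms0", "MS", "AAAGGGAAAGGCARWW", 11)]
        store = build_store(rows)
        # AAA occurs at offsets 11 and 5 in the same single subject: tie
        vec = make_atomic_vector("AAA", store, SearchConfig(dt=0.1, st=0))
        assert vec.components[0].offset == 5


class TestExtendNongapped:
    def test_supported_extension_appears(self, toy_store):
        cfg = SearchConfig(dt=0.5, st=1)
        out = extend_nongapped([MotifVector.atomic("CAR", 0)], toy_store, cfg)
        assert MotifVector.atomic("CAR", 0) in out
        # N-side: every CAR is preceded by A or C in MS subjects only at...
        exts = [m for m in out if m.explicit_length == 4]
        for m in exts:
            assert set(store_ids(toy_store, m)) <= set(
                store_ids(toy_store, MotifVector.atomic("CAR", 0)))

    def test_unsupported_vector_survives_alone(self):
        rows = [(f"r{i}", f"ms{i}", "MS", "GGGGGTTTCARWW", 8) for i in range(3)]
        store = build_store(rows)
        cfg = SearchConfig(dt=0.5, st=1)
        out = extend_nongapped([MotifVector.atomic("TTT", 3)], store, cfg)
        # extensions exist (GTTT / TTTC); all match subsets of the parent
        parent = set(store_ids(store, MotifVector.atomic("TTT", 3)))
        assert all(set(store_ids(store, m)) <= parent for m in out)


def store_ids(store, motif):
    return store.query_motif(motif).matched_record_ids


class TestRecursiveRestriction:
    def test_restriction_exposes_co_occurring_component(self, conjunction_store):
        pieces = recursive_restriction(
            parse_motif("(DEF, 6)"), conjunction_store, CONJ_CONFIG)
        assert MotifVector.atomic("KLM", 0) in pieces

    def test_single_subject_motif_yields_nothing(self):
        rows = [("r0", "ms0", "MS", "GGGGGTTTCARWW", 8),
                ("r1", "ms1", "MS", "GGGGGAAACARWW", 8)]
        store = build_store(rows)
        cfg = SearchConfig(dt=0.4, st=2)
        assert recursive_restriction(
            MotifVector.atomic("TTT", 3), store, cfg) == []

    def test_re_restriction_is_fixed_point(self, conjunction_store):
        m = parse_motif("(DEF, 6)")
        sub = conjunction_store.restrict(m)
        assert len(sub.restrict(m)) == len(sub)


class TestRun:
    def test_conjunction_dom_found_via_merge(self, conjunction_store):
        result = run(conjunction_store, CONJ_CONFIG)
        target = parse_motif("(DEF, 6), (KLM, 0)")
        found = {str(m) for m, _, _ in result.doms}
        assert any(str(target) in f or f == str(target) for f in found), found
        for motif, match, report in result.doms:
            # independent re-verification of DOM status
            re_match = conjunction_store.query_motif(motif)
            assert re_match.b == 0
            assert re_match.a >= result.dom_threshold
            assert report.c == result.traversed_count

    def test_component_alone_is_not_reported(self, conjunction_store):
        result = run(conjunction_store, CONJ_CONFIG)
        reported = {str(m) for m, _, _ in result.doms}
        assert "(DEF, 6)" not in reported  # b = 4: not disease-only
        # every reported DOM constrains more than the shared X component
        for motif, _, _ in result.doms:
            assert motif.explicit_length > 3

    def test_gap_budget_zero_limits_components(self, conjunction_store):
        # with no gaps allowed, only fully fused (gapless) motifs may be
        # reported; they must still be genuinely disease-only
        result = run(conjunction_store, SearchConfig(dt=0.6, st=5, gc=0))
        for motif, match, _ in result.doms:
            assert motif.cardinality == 1
            re_match = conjunction_store.query_motif(motif)
            assert re_match.b == 0 and re_match.a >= result.dom_threshold

    def test_deterministic_and_no_double_scoring(self, conjunction_store):
        r1 = run(conjunction_store, CONJ_CONFIG)
        r2 = run(conjunction_store, CONJ_CONFIG)
        assert [str(m) for m, _, _ in r1.doms] == [str(m) for m, _, _ in r2.doms]
        assert r1.traversed_count == r2.traversed_count
        assert r1.levels == r2.levels

    def test_traversal_counts_at_least_the_seeds(self, conjunction_store):
        result = run(conjunction_store, CONJ_CONFIG)
        n_tally = len(tally_triplets(conjunction_store, CONJ_CONFIG))
        assert result.traversed_count >= n_tally

    def test_first_dom_policy_stops_early(self, conjunction_store):
        full = run(conjunction_store, CONJ_CONFIG)
        first = run(conjunction_store,
                    SearchConfig(dt=0.6, st=5, gc=2, stop_policy="first_dom"))
        assert len(first.doms) == 1
        assert first.traversed_count <= full.traversed_count

    def test_empty_dom_list_is_legal(self):
        rows = [(f"r{i}", f"s{i}", "MS" if i < 3 else "HC",
                 "GGGGGTTTCARWW", 8) for i in range(6)]
        store = build_store(rows)
        result = run(store, SearchConfig(dt=0.6, st=0))
        assert result.doms == []  # every triplet matches both categories


class TestGreedyPruningCaveat:
    def test_sep_zero_components_hide_a_dom(self):
        """St pruning is greedy: when each component of a true DOM scores
        zero separation on the full cohort, the seed stage prunes them and
        the DOM is never assembled — even though a direct query proves it
        exists.  This mirrors the method's documented hill-climbing
        trade-off."""
        rows = []
        pad = "G" * 8
        for i in range(6):  # MS: X and Y on the same sequence
            rows.append((f"ms{i}", f"ms{i}", "MS",
                         pad + "DEFAAAKLM" + pad, 14))
        for i in range(6):  # HC: X and Y on *different* sequences
            rows.append((f"hx{i}", f"hc{i}", "HC", pad + "DEFAAAAAA" + pad, 14))
            rows.append((f"hy{i}", f"hc{i}", "HC", pad + "AAAAAAKLM" + pad, 14))
        store = build_store(rows)
        dom = parse_motif("(DEF, 6), (KLM, 0)")
        direct = store.query_motif(dom)
        assert direct.b == 0 and direct.a == 6  # the DOM is real
        result = run(store, SearchConfig(dt=0.5, st=2))
        assert all(str(m) != str(dom) for m, _, _ in result.doms)
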