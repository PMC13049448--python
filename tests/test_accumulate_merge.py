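"""Bucketing, linear overlap merge, validation and coordinate lifting."""

import numpy as np
import pytest

from ibdscan import (
    GeneticMap,
    MatchRecord,
    MergedInterval,
    PairKey,
    Projection,
    bucket_matches,
    finalize_calls,
    merge_n_lists,
    sort_bucket,
    to_original,
    validate,
)

from conftest import make_panel
from oracles import interval_union_bruteforce, random_panel


def rec(A, B, r, S, E):
    return MatchRecord(A, B, r, S, E)


class TestBucketing:
    def test_single_bucket_is_identity(self):
        records = [rec(0, 1, 0, 0, 5), rec(3, 4, 1, 2, 9)]
        assert bucket_matches(records, 1) == [records]

    def test_modulus_routing(self):
        records = [rec(a, a + 1, 0, 0, 1) for a in range(4)]
        b0, b1 = bucket_matches(records, 2)
        assert {r.A for r in b0} == {0, 2}
        assert {r.A for r in b1} == {1, 3}

    def test_pairs_colocated_and_content_preserved(self, rng):
        records = [
            rec(int(a), int(a) + 1 + int(b), int(r), int(s), int(s) + 3)
            for a, b, r, s in zip(
                rng.integers(0, 12, 60),
                rng.integers(0, 5, 60),
                rng.integers(0, 4, 60),
                rng.integers(0, 50, 60),
            )
        ]
        buckets = bucket_matches(records, 5)
        assert sorted(map(tuple, (r for b in buckets for r in b))) == sorted(
            map(tuple, records)
        )
        for (A, B) in {(r.A, r.B) for r in records}:
            holders = [
                i for i, b in enumerate(buckets)
                if any(x.A == A and x.B == B for x in b)
            ]
            assert len(holders) == 1

    def test_sort_bucket_orders_by_pair_projection_start(self, rng):
        records = [
            rec(int(a), int(a) + 1, int(r), int(s), int(s) + 2)
            for a, r, s in zip(
                rng.integers(0, 4, 40),
                rng.integers(0, 3, 40),
                rng.integers(0, 30, 40),
            )
        ]
        out = sort_bucket(records)
        assert [tuple(r) for r in out] == sorted(
            (tuple(r) for r in records), key=lambda t: (t[0], t[1], t[2], t[3])
        )


class TestMergeNLists:
    def test_worked_two_list_example(self):
        got = merge_n_lists([[(1, 3), (10, 12)], [(2, 5), (20, 22)]])
        assert [(m.S, m.E) for m in got] == [(1, 5), (10, 12), (20, 22)]
        assert [set(m.supporting) for m in got] == [{0, 1}, {0}, {1}]

    def test_one_empty_list_passthrough(self):
        got = merge_n_lists([[], [(2, 5), (8, 9)]])
        assert [(m.S, m.E) for m in got] == [(2, 5), (8, 9)]
        assert all(m.supporting == frozenset({1}) for m in got)

    def test_identical_lists_fully_supported(self):
        lists = [[(0, 4), (10, 12)]] * 4
        got = merge_n_lists(lists)
        assert [(m.S, m.E) for m in got] == [(0, 4), (10, 12)]
        assert all(m.supporting == frozenset(range(4)) for m in got)

    def test_adjacent_but_not_touching_stay_separate(self):
        got = merge_n_lists([[(1, 3)], [(4, 5)]])
        assert [(m.S, m.E) for m in got] == [(1, 3), (4, 5)]

    def test_contract_violations_rejected(self):
        with pytest.raises(ValueError):
            merge_n_lists([[(5, 6), (0, 2)]])
        with pytest.raises(ValueError):
            merge_n_lists([[(0, 4), (4, 8)]])
        with pytest.raises(ValueError):
            merge_n_lists([[(3, 2)]])

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_flatten_sort_union_oracle(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(50):
            n = int(rng.integers(1, 10))
            lists = []
            for _li in range(n):
                count = int(rng.integers(0, 12))
                lst, cursor = [], 0
                for _ in range(count):
                    s = cursor + int(rng.integers(1, 8))
                    e = s + int(rng.integers(0, 6))
                    lst.append((s, e))
                    cursor = e
                lists.append(lst)
            got = [(m.S, m.E, m.supporting) for m in merge_n_lists(lists)]
            assert got == interval_union_bruteforce(lists)
            # output sorted, non-overlapping, no mergeable neighbours
            for (s0, e0, _), (s1, _e1, _) in zip(got, got[1:]):
                assert s1 > e0 + 0  # strict: no shared endpoints remain


class TestValidate:
    def test_threshold_one_is_identity(self):
        merged = [MergedInterval(0, 3, frozenset({2}))]
        assert validate(merged, 1) == merged

    def test_singleton_support_dropped_at_two(self):
        assert validate([MergedInterval(0, 3, frozenset({0}))], 2) == []

    def test_mixed_supports(self):
        merged = [
            MergedInterval(0, 1, frozenset({0, 1})),
            MergedInterval(3, 4, frozenset({2})),
            MergedInterval(6, 9, frozenset({0, 2, 3})),
        ]
        assert validate(merged, 2) == [merged[0], merged[2]]

    def test_support_monotone_in_s(self, rng):
        merged = [
            MergedInterval(int(s), int(s) + 2,
                           frozenset(map(int, rng.choice(6, size=int(k) + 1, replace=False))))
            for s, k in zip(rng.integers(0, 100, 30), rng.integers(0, 5, 30))
        ]
        prev = validate(merged, 1)
        for s in range(2, 7):
            cur = validate(merged, s)
            assert set(cur) <= set(prev)
            prev = cur


class TestToOriginal:
    def make_projection(self, n, cm_per_site=0.1):
        panel = make_panel(random_panel(np.random.default_rng(0), 4, n), bp_per_site=1000)
        gmap = GeneticMap(
            bp=np.array([panel.positions[0], panel.positions[-1]], dtype=float),
            cm=np.array([0.0, cm_per_site * (n - 1)]),
        )
        proj = Projection(
            index_r=0,
            seed=0,
            selected_sites=np.arange(n),
            projected_alleles=panel.alleles,
        )
        return panel, gmap, proj

    def test_degenerate_single_window_span(self):
        panel, gmap, proj = self.make_projection(30)
        seg = to_original(
            MergedInterval(0, 0, frozenset({0})), proj, panel, gmap, PairKey(0, 1)
        )
        assert seg.start_site == seg.end_site == 0
        assert seg.length_cm == 0.0

    def test_uniform_spacing_length_arithmetic(self):
        panel, gmap, proj = self.make_projection(30)
        seg = to_original(
            MergedInterval(0, 20, frozenset({0, 1})), proj, panel, gmap, PairKey(0, 3)
        )
        assert seg.start_site == 0 and seg.end_site == 20
        assert seg.length_cm == pytest.approx(2.0)
        assert seg.support == 2
        assert (seg.sample_a, seg.hap_a, seg.sample_b, seg.hap_b) == (
            "s000000", 0, "s000001", 1,
        )


class TestFinalizeCalls:
    def setup_inputs(self, rng, n=40):
        panel = make_panel(random_panel(rng, 8, n))
        gmap = GeneticMap(
            bp=np.array([panel.positions[0], panel.positions[-1]], dtype=float),
            cm=np.array([0.0, 0.01 * (n - 1)]),
        )
        projections = [
            Projection(index_r=i, seed=i, selected_sites=np.arange(n),
                       projected_alleles=panel.alleles)
            for i in range(3)
        ]
        records = [
            rec(int(a), int(a) + 1 + int(db), int(r), int(s), int(s) + int(w))
            for a, db, r, s, w in zip(
                rng.integers(0, 6, 50), rng.integers(0, 2, 50),
                rng.integers(0, 3, 50), rng.integers(0, n - 8, 50),
                rng.integers(0, 8, 50),
            )
        ]
        # same (A,B,r) lists must be non-overlapping: deduplicate aggressively
        seen, cleaned = {}, []
        for m in sorted(records, key=lambda m: (m.A, m.B, m.r, m.S)):
            key = (m.A, m.B, m.r)
            if key in seen and m.S <= seen[key]:
                continue
            seen[key] = m.E
            cleaned.append(m)
        return panel, gmap, projections, cleaned

    def test_arrival_order_invariance(self, rng):
        panel, gmap, projections, records = self.setup_inputs(rng)
        base = finalize_calls(records, projections, panel, gmap, s=2)
        for perm_seed in range(3):
            perm = list(records)
            np.random.default_rng(perm_seed).shuffle(perm)
            assert finalize_calls(perm, projections, panel, gmap, s=2) == base

    def test_bucket_count_does_not_change_calls(self, rng):
        panel, gmap, projections, records = self.setup_inputs(rng)
        base = finalize_calls(records, projections, panel, gmap, s=2, n_buckets=1)
        alt = finalize_calls(records, projections, panel, gmap, s=2, n_buckets=4)
        assert sorted(map(repr, alt)) == sorted(map(repr, base))

    def test_support_threshold_monotone(self, rng):
        panel, gmap, projections, records = self.setup_inputs(rng)
        s1 = finalize_calls(records, projections, panel, gmap, s=1)
        s2 = finalize_calls(records, projections, panel, gmap, s=2)
        s3 = finalize_calls(records, projections, panel, gmap, s=3)
        key = lambda seg: (seg.sample_a, seg.hap_a, seg.sample_b, seg.hap_b,
                           seg.start_site, seg.end_site)
        assert {key(x) for x in s3} <= {key(x) for x in s2} <= {key(x) for x in s1}
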