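"""Grouping, cross-projection validation and interval merging of matches.

Raw match records from all projections are bucketed by the lower haplotype
index, ordered by ``(A, B, r, S)``, and, per haplotype pair, the per-
projection interval lists are merged by a linear sweep (a heap selects the
list with the smallest current start; overlapping or endpoint-sharing
intervals are absorbed into one run).  A merged run is validated when it
was supported by at least ``s`` distinct projections, then lifted from
window coordinates back to original site/bp/cM coordinates.
"""

from __future__ import annotations

import dataclasses
import heapq
from itertools import groupby
from typing import Iterable, Sequence

import numpy as np

from .match_detection import MatchRecord
from .panel_io import GeneticMap, HaplotypePanel, IBDSegment
from .projection import Projection

__all__ = [
    "PairKey",
    "MergedInterval",
    "bucket_matches",
    "sort_bucket",
    "merge_n_lists",
    "validate",
    "to_original",
    "finalize_calls",
]


@dataclasses.dataclass(frozen=True)
class PairKey:
    A: int
    B: int

    def __post_init__(self) -> None:
        if not self.A < self.B:
            raise ValueError("pair key requires A < B")


@dataclasses.dataclass(frozen=True)
class MergedInterval:
    """Inclusive projected-coordinate run with its supporting projections."""

    S: int
    E: int
    supporting: frozenset

    def __post_init__(self) -> None:
        if self.S > self.E:
            raise ValueError("inverted interval")
        if not self.supporting:
            raise ValueError("merged interval without support")


def bucket_matches(
    records: Iterable[MatchRecord], n_buckets: int
) -> list[list[MatchRecord]]:
    """Coarse bucket sort: record with pair key ``A`` goes to ``A % n_buckets``.

    All records of any given (A, B) pair share a bucket, so buckets can be
    processed independently.
    """
    if n_buckets < 1:
        raise ValueError("need at least one bucket")
    buckets: list[list[MatchRecord]] = [[] for _ in range(n_buckets)]
    for rec in records:
        buckets[rec.A % n_buckets].append(rec)
    return buckets


def sort_bucket(bucket: Sequence[MatchRecord]) -> list[MatchRecord]:
    """Stable order by (A, B, r, S): pair groups contiguous, starts sorted."""
    return sorted(bucket, key=lambda m: (m.A, m.B, m.r, m.S))


def _check_list(lst: Sequence[tuple[int, int]], idx: int) -> None:
    prev_end = None
    for S, E in lst:
        if S > E:
            raise ValueError(f"list {idx}: inverted interval [{S}, {E}]")
        if prev_end is not None and S <= prev_end:
            raise ValueError(
                f"list {idx}: intervals unsorted or overlapping at [{S}, {E}]"
            )
        prev_end = E


def merge_n_lists(
    lists: Sequence[Sequence[tuple[int, int]]],
) -> list[MergedInterval]:
    """Linear overlap merge of n sorted non-overlapping interval lists.

    Output is the interval union (overlap includes shared endpoints:
    intervals merge iff the next start is <= the current end), sorted and
    non-overlapping, with each merged run recording which input lists
    contributed.  Work is linear in the total interval count plus the
    log(n) heap selection.
    """
    for idx, lst in enumerate(lists):
        _check_list(lst, idx)
    heap: list[tuple[int, int, int]] = []  # (start, list index, position)
    for li, lst in enumerate(lists):
        if lst:
            heapq.heappush(heap, (lst[li_start := 0][0], li, li_start))
    merged: list[MergedInterval] = []
    cur_S = cur_E = None
    cur_sup: set[int] = set()
    while heap:
        S, li, pos = heapq.heappop(heap)
        E = lists[li][pos][1]
        if pos + 1 < len(lists[li]):
            heapq.heappush(heap, (lists[li][pos + 1][0], li, pos + 1))
        if cur_S is None:
            cur_S, cur_E, cur_sup = S, E, {li}
        elif S <= cur_E:  # overlap or shared endpoint: absorb
            cur_E = max(cur_E, E)
            cur_sup.add(li)
        else:
            merged.append(MergedInterval(cur_S, cur_E, frozenset(cur_sup)))
            cur_S, cur_E, cur_sup = S, E, {li}
    if cur_S is not None:
        merged.append(MergedInterval(cur_S, cur_E, frozenset(cur_sup)))
    return merged


def validate(merged: Sequence[MergedInterval], s: int) -> list[MergedInterval]:
    """Keep runs supported by at least ``s`` distinct projections."""
    if s < 1:
        raise ValueError("support threshold must be >= 1")
    return [m for m in merged if len(m.supporting) >= s]


def to_original(
    interval: MergedInterval,
    projection: Projection,
    panel: HaplotypePanel,
    gmap: GeneticMap,
    key: PairKey,
    support: int | None = None,
) -> IBDSegment:
    """Lift a merged window-coordinate run to original panel coordinates."""
    sel = projection.selected_sites
    if interval.E >= sel.size:
        raise ValueError("interval outside projection bounds")
    start_site = int(sel[interval.S])
    end_site = int(sel[interval.E])
    start_bp = int(panel.positions[start_site])
    end_bp = int(panel.positions[end_site])
    length_cm = float(gmap.cm_at(end_bp) - gmap.cm_at(start_bp))
    sample_a, hap_a = panel.hap_label(key.A)
    sample_b, hap_b = panel.hap_label(key.B)
    return IBDSegment(
        sample_a=sample_a,
        hap_a=hap_a,
        sample_b=sample_b,
        hap_b=hap_b,
        chrom=panel.chrom,
        start_site=start_site,
        end_site=end_site,
        start_bp=start_bp,
        end_bp=end_bp,
        length_cm=length_cm,
        support=len(interval.supporting) if support is None else support,
    )


def finalize_calls(
    records: Iterable[MatchRecord],
    projections: Sequence[Projection],
    panel: HaplotypePanel,
    gmap: GeneticMap,
    s: int,
    n_buckets: int = 1,
) -> list[IBDSegment]:
    """Full accumulation stage: bucket, sort, merge, validate, lift.

    The result is independent of the arrival order of ``records`` and is
    returned sorted by (A, B, start window) in haplotype-index order.
    Window coordinates are shared across projections (one window set), so
    runs from different projections are directly comparable; merged runs
    are lifted via the lowest-indexed supporting projection.
    """
    keyed: list[tuple[int, int, list[IBDSegment]]] = []
    for bucket in bucket_matches(records, n_buckets):
        for (A, B), group in groupby(
            sort_bucket(bucket), key=lambda m: (m.A, m.B)
        ):
            group = list(group)
            proj_ids = sorted({m.r for m in group})
            lists = [
                [(m.S, m.E) for m in group if m.r == ri] for ri in proj_ids
            ]
            merged = merge_n_lists(lists)
            # remap positional list ids back to projection indices
            merged = [
                MergedInterval(
                    m.S, m.E, frozenset(proj_ids[i] for i in m.supporting)
                )
                for m in merged
            ]
            segs = [
                to_original(
                    m,
                    projections[min(m.supporting)],
                    panel,
                    gmap,
                    PairKey(A, B),
                )
                for m in validate(merged, s)
            ]
            if segs:
                keyed.append((A, B, segs))
    out: list[IBDSegment] = []
    for _A, _B, segs in sorted(keyed, key=lambda t: (t[0], t[1])):
        out.extend(sorted(segs, key=lambda sg: sg.start_site))
    return out
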