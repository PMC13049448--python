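"""Long-match detection over a projected panel.

A long match is a shared contiguous run of projected sites that spans at
least the minimum genetic length and ends where the pair's alleles next
diverge (or at the end of the panel).  Detection piggybacks on the PBWT
divergence array: at projected site ``k`` a run between ranks ``i-1`` and
``i`` is long enough exactly when ``D[i] <= k - L_sites``, where
``L_sites`` is the number of inter-site gaps needed to span the genetic
threshold ending at ``k``.  Maximal rank intervals satisfying that
condition are regions of interest (ROIs); pair enumeration happens only
inside ROIs, and a pair is reported once, at the site where its match
terminates.
"""

from __future__ import annotations

import dataclasses
from typing import NamedTuple, Sequence

import numpy as np

from .panel_io import GeneticMap
from .pbwt_core import PBWTState, advance, init_state

__all__ = [
    "MatchRecord",
    "ROI",
    "site_length_threshold",
    "site_length_thresholds",
    "detect_rois",
    "report_long_matches",
    "long_matches_in_projection",
]

# Slack (cM) for genetic-distance comparisons so exactly spaced maps hit
# their nominal thresholds (0.1 cM spacing, 2 cM cut-off -> 20 gaps).
_CM_EPS = 1e-9


class MatchRecord(NamedTuple):
    """Raw exact match: haplotypes ``A < B`` share projected sites [S, E]
    in projection ``r`` (inclusive projected coordinates)."""

    A: int
    B: int
    r: int
    S: int
    E: int


@dataclasses.dataclass(frozen=True)
class ROI:
    """Maximal prefix-rank interval [rank_start, rank_end] (inclusive) in
    which every adjacent pair satisfies the long-match condition at
    projected site ``site``."""

    rank_start: int
    rank_end: int
    site: int


def site_length_thresholds(
    gmap: GeneticMap,
    selected_sites: np.ndarray,
    panel_positions: np.ndarray,
    min_cm: float,
) -> np.ndarray:
    """Per-site thresholds ``L_sites[k]`` for a whole projection at once.

    ``L_sites[k]`` is the smallest gap count ``c`` such that the genetic
    distance from projected site ``k - c`` to projected site ``k`` reaches
    ``min_cm`` (so a qualifying run holds ``c + 1`` projected sites).  When
    even the full prefix spans less than ``min_cm`` the unreachable
    sentinel ``k + 1`` is returned: no match ending at ``k`` can qualify.
    """
    if min_cm <= 0:
        raise ValueError("min_cm must be positive")
    cm = np.asarray(gmap.cm_at(panel_positions[np.asarray(selected_sites)]))
    n = cm.size
    ks = np.arange(n)
    j = np.searchsorted(cm, cm - min_cm + _CM_EPS, side="right") - 1
    return np.where(j >= 0, ks - j, ks + 1).astype(np.int64)


def site_length_threshold(
    gmap: GeneticMap,
    selected_sites: np.ndarray,
    panel_positions: np.ndarray,
    k: int,
    min_cm: float,
) -> int:
    """Threshold at one projected site, by reverse linear scan.

    Equivalent to ``site_length_thresholds(...)[k]``; kept as the direct
    transcription of the reverse-scan definition.
    """
    if min_cm <= 0:
        raise ValueError("min_cm must be positive")
    sel = np.asarray(selected_sites)
    if not 0 <= k < sel.size:
        raise ValueError(f"projected site {k} out of range")
    cm = np.asarray(gmap.cm_at(panel_positions[sel]))
    target = cm[k] - min_cm + _CM_EPS
    # scan from k downward for the largest j with cm[j] <= cm[k] - min_cm
    j = k - 1
    while j >= 0 and cm[j] > target:
        j -= 1
    if j < 0:
        return k + 1
    return k - j


def detect_rois(state: PBWTState, L_sites: int) -> list[ROI]:
    """Maximal rank runs where adjacent divergences pass the threshold.

    The scan is over the divergence array in prefix-array order; the
    block-parallel variant of this scan would differ only in splitting the
    boolean run-finding, which is associative, so the sequential scan is
    the semantic contract.
    """
    k_site = state.k - 1
    thr = k_site - L_sites
    if thr < 0 or state.n_hap < 2:
        return []
    mask = state.D[1:] <= thr
    if not mask.any():
        return []
    edges = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    starts, ends = edges[::2], edges[1::2]
    # mask index m corresponds to the adjacent pair (rank m, rank m+1)
    return [ROI(int(s), int(e), k_site) for s, e in zip(starts, ends)]


def report_long_matches(
    state: PBWTState,
    next_column,
    L_sites: int,
    partition: tuple[int, int] = (0, 1),
    proj_index: int = 0,
    rois: Sequence[ROI] | None = None,
) -> list[MatchRecord]:
    """Emit matches terminating at the current projected site.

    Within each ROI, ordered rank pairs (a before b) are enumerated while
    maintaining the running maximum of the intervening divergence values
    (equivalently, the running minimum match length).  A pair is emitted
    iff its normalized ``A`` lands in this partition (``A % P == p``) and
    the match terminates here: the pair's alleles differ in
    ``next_column``, or ``next_column is None`` (end-of-panel marker).
    The emitted segment is ``S = max intervening divergence``, ``E = k``.
    """
    p, P = partition
    if rois is None:
        rois = detect_rois(state, L_sites)
    if not rois:
        return []
    k_site = state.k - 1
    nc = None if next_column is None else np.asarray(next_column)
    Parr, D = state.P, state.D
    out: list[MatchRecord] = []
    for roi in rois:
        for ai in range(roi.rank_start, roi.rank_end):
            ha = int(Parr[ai])
            run_start = 0
            for bi in range(ai + 1, roi.rank_end + 1):
                run_start = max(run_start, int(D[bi]))
                hb = int(Parr[bi])
                A, B = (ha, hb) if ha < hb else (hb, ha)
                if A % P != p:
                    continue
                if nc is None or nc[ha] != nc[hb]:
                    out.append(MatchRecord(A, B, proj_index, run_start, k_site))
    return out


def long_matches_in_projection(
    proj_alleles: np.ndarray,
    thresholds,
    proj_index: int = 0,
    partition: tuple[int, int] = (0, 1),
    states: Sequence[PBWTState] | None = None,
) -> list[MatchRecord]:
    """Sweep a whole projected panel and collect every long match.

    ``thresholds`` is either an integer (fixed site threshold, the
    map-free scheme) or a per-site array from
    :func:`site_length_thresholds`.  If ``states`` is given (one state per
    consumed column, e.g. cached by a memory-retentive run) the PBWT is
    not recomputed; otherwise the states are built on the fly.  Matches
    still open at the last site are flushed by an end-marker pass.
    """
    proj_alleles = np.asarray(proj_alleles)
    n_proj, M = proj_alleles.shape
    if np.isscalar(thresholds) or isinstance(thresholds, (int, np.integer)):
        thr = np.full(n_proj, int(thresholds), dtype=np.int64)
    else:
        thr = np.asarray(thresholds, dtype=np.int64)
        if thr.size != n_proj:
            raise ValueError("one threshold per projected site required")
    records: list[MatchRecord] = []
    state = init_state(M) if states is None else None
    for ks in range(n_proj):
        if states is None:
            state = advance(state, proj_alleles[ks])
        else:
            state = states[ks]
        nxt = proj_alleles[ks + 1] if ks + 1 < n_proj else None
        records.extend(
            report_long_matches(
                state, nxt, int(thr[ks]), partition=partition, proj_index=proj_index
            )
        )
    return records
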