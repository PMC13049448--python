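"""Positional Burrows-Wheeler transform core: prefix and divergence arrays.

At each site the panel's haplotypes are kept sorted by their reversed
prefixes (the prefix array ``P``), and for every adjacent pair in that
order the start of their longest common suffix is tracked (the divergence
array ``D``).  Two update paths are provided:

``advance``
    the classical sequential single-column update;
``advance_blocked``
    a block-decomposed update (per-block counting, an exclusive offset
    scan, placement, and per-block divergence seeds propagated to the next
    block).  It is contractually element-wise equal to ``advance`` for
    every block count; the decomposition exists so the work can be
    partitioned across workers without changing semantics.

Conventions: ``state.k`` is the number of columns consumed; ``D[0] = k``
is the sentinel for the rank with no predecessor, and after each update
every allele-group head gets the fresh sentinel ``k+1``.  Ties between
equal reversed prefixes are broken stably (input order preserved).
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = ["PBWTState", "init_state", "advance", "advance_blocked", "block_bounds"]

_DTYPE = np.int32


@dataclasses.dataclass
class PBWTState:
    k: int
    P: np.ndarray
    D: np.ndarray

    @property
    def n_hap(self) -> int:
        return self.P.size


def init_state(M: int) -> PBWTState:
    """State before any column: identity permutation, all-zero divergence."""
    if M < 1:
        raise ValueError("need at least one haplotype")
    return PBWTState(k=0, P=np.arange(M, dtype=_DTYPE), D=np.zeros(M, dtype=_DTYPE))


def _group_heads(D: np.ndarray, idx: np.ndarray, k: int) -> np.ndarray:
    """Divergence values for one allele group, in rank order.

    The group head gets the sentinel ``k+1``; member ``j`` gets the running
    maximum of ``D`` over the old ranks since the previous group member,
    i.e. ``max(D[idx[j-1]+1 .. idx[j]])`` -- the standard PBWT recurrence
    with the reset-at-emission running maximum evaluated per segment.
    """
    out = np.empty(idx.size, dtype=D.dtype)
    if idx.size == 0:
        return out
    out[0] = k + 1
    if idx.size > 1:
        starts = idx[:-1] + 1
        out[1:] = np.maximum.reduceat(D[: idx[-1] + 1], starts)
    return out


def advance(state: PBWTState, column) -> PBWTState:
    """Consume one 0/1 column (indexed by haplotype id) sequentially."""
    col = np.asarray(column)
    M = state.P.size
    if col.shape != (M,):
        raise ValueError(f"column length {col.shape} != haplotype count {M}")
    a = col[state.P]
    zero = a == 0
    zi = np.flatnonzero(zero)
    oi = np.flatnonzero(~zero)
    newP = np.concatenate((state.P[zi], state.P[oi]))
    newD = np.concatenate(
        (_group_heads(state.D, zi, state.k), _group_heads(state.D, oi, state.k))
    )
    return PBWTState(k=state.k + 1, P=newP.astype(_DTYPE), D=newD.astype(_DTYPE))


def block_bounds(M: int, T: int) -> list[tuple[int, int]]:
    """Split ranks [0, M) into T contiguous, near-equal blocks."""
    return [(t * M // T, (t + 1) * M // T) for t in range(T)]


def advance_blocked(state: PBWTState, column, n_blocks: int) -> PBWTState:
    """Block-decomposed column update; equals :func:`advance` exactly.

    Prefix-array stage: (i) per-block zero counts, (ii) exclusive scan of
    the counts into placement offsets, (iii) per-block placement.
    Divergence stage: each block computes its local divergence values and a
    compact seed (the running maximum pending at its right edge); seeds are
    propagated once across blocks and patched into each block's first
    group member, avoiding any backward scan across block boundaries.
    """
    col = np.asarray(column)
    M = state.P.size
    T = n_blocks
    if not 1 <= T <= M:
        raise ValueError(f"block count must be in [1, {M}], got {T}")
    if col.shape != (M,):
        raise ValueError(f"column length {col.shape} != haplotype count {M}")

    a = col[state.P]
    D = state.D
    k = state.k
    bounds = block_bounds(M, T)

    # --- prefix array: count / scan / place ---------------------------------
    zero_counts = [int(np.count_nonzero(a[lo:hi] == 0)) for lo, hi in bounds]
    Z = sum(zero_counts)
    zero_off = np.concatenate(([0], np.cumsum(zero_counts)[:-1])).astype(np.int64)
    newP = np.empty(M, dtype=_DTYPE)
    block_zidx: list[np.ndarray] = []
    block_oidx: list[np.ndarray] = []
    for b, (lo, hi) in enumerate(bounds):
        zi = lo + np.flatnonzero(a[lo:hi] == 0)
        oi = lo + np.flatnonzero(a[lo:hi] == 1)
        block_zidx.append(zi)
        block_oidx.append(oi)
        zo = int(zero_off[b])
        oo = Z + lo - zo  # ones before this block = lo - zeros before it
        newP[zo : zo + zi.size] = state.P[zi]
        newP[oo : oo + oi.size] = state.P[oi]

    # --- divergence: local values + seed propagation ------------------------
    def local_parts(idx: np.ndarray, lo: int, hi: int):
        """(values-with-unpatched-head, head prefix max, seed-out pieces)."""
        if idx.size == 0:
            seg_max = int(D[lo:hi].max()) if hi > lo else 0
            return np.empty(0, dtype=D.dtype), None, (False, seg_max)
        vals = np.empty(idx.size, dtype=D.dtype)
        head_prefix = int(D[lo : idx[0] + 1].max())
        if idx.size > 1:
            starts = idx[:-1] + 1
            vals[1:] = np.maximum.reduceat(D[: idx[-1] + 1], starts)
        tail = int(D[idx[-1] + 1 : hi].max()) if idx[-1] + 1 < hi else 0
        return vals, head_prefix, (True, tail)

    def assemble(block_idx: list[np.ndarray]) -> np.ndarray:
        pieces = []
        carry = k + 1  # sentinel: no emission yet anywhere to the left
        for b, (lo, hi) in enumerate(bounds):
            vals, head_prefix, (has, summary) = local_parts(block_idx[b], lo, hi)
            if has:
                vals[0] = max(carry, head_prefix)
                carry = summary  # running max restarts after the last emission
            else:
                carry = max(carry, summary)  # block only accumulates
            pieces.append(vals)
        return np.concatenate(pieces) if pieces else np.empty(0, dtype=D.dtype)

    newD = np.concatenate((assemble(block_zidx), assemble(block_oidx)))
    return PBWTState(k=k + 1, P=newP, D=newD.astype(_DTYPE))
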