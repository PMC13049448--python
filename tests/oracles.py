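"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own data paths: reversed-prefix
order comes from a plain lexicographic sort of reversed prefix tuples,
divergence from a direct backward scan, long matches from all-pairs run
scanning, and interval union from flatten-and-sweep.
"""

from __future__ import annotations

import numpy as np


def reversed_prefix_order(X: np.ndarray, k: int) -> list[int]:
    """Haplotype indices sorted by reversed prefix x[0:k][::-1], stable."""
    M = X.shape[1]
    return sorted(range(M), key=lambda h: tuple(int(v) for v in X[:k, h][::-1]))


def divergence_bruteforce(X: np.ndarray, k: int, order: list[int]) -> list[int]:
    """D[i] = smallest j with x_{order[i-1]}[j:k] == x_{order[i]}[j:k]."""
    D = [k]
    for i in range(1, len(order)):
        a, b = order[i - 1], order[i]
        j = k
        while j > 0 and X[j - 1, a] == X[j - 1, b]:
            j -= 1
        D.append(j)
    return D


def long_matches_bruteforce(X: np.ndarray, thresholds) -> set[tuple[int, int, int, int]]:
    """All (A, B, S, E): maximal shared runs with S <= E - L[E].

    ``thresholds`` is an int or a per-site array of gap-count thresholds;
    a run qualifies by the threshold at its terminal site.
    """
    N, M = X.shape
    thr = np.broadcast_to(np.asarray(thresholds, dtype=np.int64), (N,))
    out: set[tuple[int, int, int, int]] = set()
    for a in range(M):
        for b in range(a + 1, M):
            eq = np.concatenate(([0], (X[:, a] == X[:, b]).view(np.int8), [0]))
            edges = np.flatnonzero(np.diff(eq))
            for s, e in zip(edges[::2], edges[1::2] - 1):
                if s <= e - thr[e]:
                    out.add((a, b, int(s), int(e)))
    return out


def interval_union_bruteforce(lists):
    """Flatten-sort-sweep union with per-run contributing list ids.

    Intervals sharing an endpoint merge (S2 <= E1). Returns a list of
    (S, E, frozenset of list ids).
    """
    flat = sorted(
        (S, E, li) for li, lst in enumerate(lists) for S, E in lst
    )
    out = []
    for S, E, li in flat:
        if out and S <= out[-1][1]:
            pS, pE, sup = out[-1]
            out[-1] = (pS, max(pE, E), sup | {li})
        else:
            out.append((S, E, frozenset({li})))
    return [(S, E, sup) for S, E, sup in out]


def random_panel(rng: np.random.Generator, M: int, N: int) -> np.ndarray:
    """Unstructured 0/1 panel, site-major (N, M)."""
    return rng.integers(0, 2, size=(N, M)).astype(np.int8)


def panel_with_shared_runs(
    rng: np.random.Generator, M: int, N: int, n_runs: int
) -> np.ndarray:
    """Random panel with planted shared runs so long matches exist."""
    X = random_panel(rng, M, N)
    for _ in range(n_runs):
        a, b = rng.choice(M, size=2, replace=False)
        s = int(rng.integers(0, N))
        e = int(rng.integers(s, N))
        X[s : e + 1, b] = X[s : e + 1, a]
    return X
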