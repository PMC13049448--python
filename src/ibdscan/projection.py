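"""Window construction and seeded random downsampling of a panel.

A projection keeps one uniformly chosen site per window, trading site-level
resolution for robustness: a genotyping error only corrupts a projection if
the erroneous site happens to be the one selected for its window.  Running
``r`` independent projections and requiring support from at least ``s`` of
them is what turns exact PBWT matching into an error-tolerant IBD detector.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .panel_io import GeneticMap, HaplotypePanel

__all__ = ["WindowSet", "Projection", "make_windows", "project"]

# Relative slack when comparing cumulative cM values, so that exactly-spaced
# maps (e.g. 0.01 cM per site with a 0.05 cM window) tile without float fuzz.
_CM_EPS = 1e-9


@dataclasses.dataclass(frozen=True)
class WindowSet:
    """A contiguous tiling of the site axis into half-open windows."""

    boundaries: tuple[tuple[int, int], ...]
    mode: str
    params: dict

    def __post_init__(self) -> None:
        b = self.boundaries
        if not b:
            raise ValueError("empty window set")
        if b[0][0] != 0:
            raise ValueError("first window must start at site 0")
        for (s0, e0), (s1, _e1) in zip(b, b[1:]):
            if e0 != s1:
                raise ValueError("windows must abut")
        for s, e in b:
            if e <= s:
                raise ValueError("empty window")

    @property
    def n_windows(self) -> int:
        return len(self.boundaries)

    @property
    def n_sites(self) -> int:
        return self.boundaries[-1][1]

    def sizes(self) -> np.ndarray:
        return np.array([e - s for s, e in self.boundaries], dtype=np.int64)


@dataclasses.dataclass(frozen=True)
class Projection:
    """One randomized downsampling: a selected site per window."""

    index_r: int
    seed: int
    selected_sites: np.ndarray
    projected_alleles: np.ndarray

    @property
    def n_proj_sites(self) -> int:
        return self.selected_sites.size


def _merge_min_sites(bounds: list[list[int]], min_sites: int) -> list[list[int]]:
    """Merge windows below the site floor into their left neighbour.

    A deficient leading window (no left neighbour) merges right instead, so
    window 0 stays anchored at site 0.
    """
    i = 0
    while i < len(bounds) and len(bounds) > 1:
        if bounds[i][1] - bounds[i][0] < min_sites:
            if i > 0:
                bounds[i - 1][1] = bounds[i][1]
                del bounds[i]
            else:
                bounds[1][0] = bounds[0][0]
                del bounds[0]
        else:
            i += 1
    return bounds


def make_windows(
    panel: HaplotypePanel,
    gmap: GeneticMap | None = None,
    mode: str = "dynamic",
    window_sites: int | None = None,
    window_cm: float | None = None,
    min_sites: int = 1,
) -> WindowSet:
    """Tile the site axis into fixed, dynamic or hybrid windows.

    fixed
        consecutive blocks of ``window_sites`` sites.
    dynamic
        each window extends until the next site lies at least ``window_cm``
        of genetic distance past the window's first site; on a uniformly
        spaced map this yields equal genetic-width windows.
    hybrid
        the dynamic rule plus a ``min_sites`` floor per window.

    Any window left below ``min_sites`` merges into its left neighbour.
    """
    N = panel.n_sites
    if N == 0:
        raise ValueError("cannot window an empty panel")
    if min_sites < 1:
        raise ValueError("min_sites must be >= 1")
    if min_sites > N:
        raise ValueError(f"min_sites={min_sites} exceeds panel size N={N}")

    if mode == "fixed":
        if window_sites is None or window_sites < 1:
            raise ValueError("fixed windows require window_sites >= 1")
        bounds = [
            [s, min(s + window_sites, N)] for s in range(0, N, window_sites)
        ]
        params = {"window_sites": window_sites, "min_sites": min_sites}
    elif mode in ("dynamic", "hybrid"):
        if gmap is None:
            raise ValueError(f"{mode} windows require a genetic map")
        if window_cm is None or window_cm <= 0:
            raise ValueError(f"{mode} windows require window_cm > 0")
        cm = np.asarray(gmap.cm_at(panel.positions), dtype=np.float64)
        bounds = []
        s = 0
        while s < N:
            e = int(np.searchsorted(cm, cm[s] + window_cm - _CM_EPS, side="left"))
            e = max(e, s + 1)
            e = min(e, N)
            bounds.append([s, e])
            s = e
        params = {"window_cm": window_cm, "min_sites": min_sites}
    else:
        raise ValueError(f"unknown window mode {mode!r}")

    bounds = _merge_min_sites(bounds, min_sites)
    return WindowSet(
        boundaries=tuple((s, e) for s, e in bounds), mode=mode, params=params
    )


def projection_seed(master_seed: int, index_r: int) -> int:
    """Deterministic per-projection seed from (master_seed, index_r).

    Uses numpy's SeedSequence spawn-key mixing, so projections are mutually
    independent streams yet insensitive to the order they are generated in.
    """
    ss = np.random.SeedSequence(master_seed, spawn_key=(index_r,))
    return int(ss.generate_state(1)[0])


def project(
    panel: HaplotypePanel,
    windows: WindowSet,
    index_r: int,
    master_seed: int,
    freq_weighted: bool = False,
) -> Projection:
    """Select one site at random in every window.

    Selection is uniform by default; with ``freq_weighted`` each site's
    chance is proportional to its minor-allele frequency, favouring the
    informative sites (monomorphic-heavy windows fall back to uniform).
    Identical ``(panel, windows, index_r, master_seed, freq_weighted)``
    always yields the identical projection.
    """
    if windows.n_sites != panel.n_sites:
        raise ValueError("window set does not cover this panel")
    rng = np.random.default_rng(
        np.random.SeedSequence(master_seed, spawn_key=(index_r,))
    )
    starts = np.array([s for s, _ in windows.boundaries], dtype=np.int64)
    ends = np.array([e for _, e in windows.boundaries], dtype=np.int64)
    if freq_weighted:
        f = panel.alleles.mean(axis=1)
        maf = np.minimum(f, 1.0 - f)
        selected = np.empty(len(windows.boundaries), dtype=np.int64)
        for w, (s, e) in enumerate(windows.boundaries):
            weights = maf[s:e]
            total = weights.sum()
            p = weights / total if total > 0 else None
            selected[w] = s + rng.choice(e - s, p=p)
    else:
        selected = rng.integers(starts, ends)
    return Projection(
        index_r=index_r,
        seed=projection_seed(master_seed, index_r),
        selected_sites=selected,
        projected_alleles=panel.alleles[selected],
    )
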