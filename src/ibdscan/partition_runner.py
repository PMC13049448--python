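"""Pipeline orchestration across haplotype-pair partitions.

The all-vs-all pair space is decomposed by ``min(a, b) % P == p``, which
covers the upper-triangular pair space exactly once.  Two execution modes
share the identical algorithmic path and contractually produce identical
calls:

memory-retentive
    load the panel once, compute each projection's PBWT trajectory once,
    and reuse the cached arrays for every partition's long-match pass;
memory-stable
    reload the panel and recompute projections and PBWT trajectories
    afresh for every partition, holding only one partition's state at a
    time.

``PassCounters`` records how many times each stage ran, making the
time/space trade-off between the modes auditable.
"""

from __future__ import annotations

import copy
import dataclasses
import logging

import numpy as np

from .accumulate_merge import finalize_calls
from .match_detection import long_matches_in_projection, site_length_thresholds
from .panel_io import (
    GeneticMap,
    HaplotypePanel,
    IBDSegment,
    read_genetic_map,
    read_vcf,
)
from .pbwt_core import advance, init_state
from .projection import Projection, make_windows, project

__all__ = ["RunConfig", "PassCounters", "assign_partition", "run"]

logger = logging.getLogger("ibdscan")


@dataclasses.dataclass
class RunConfig:
    """Everything one detection run needs.

    Inputs may be given as paths (``vcf``/``genetic_map``) or passed
    in-memory to :func:`run`.  ``min_cm`` is the minimum reportable IBD
    length in centimorgans; ``r`` the number of random projections; ``s``
    the cross-projection support threshold; ``partitions`` the pair-space
    partition count; ``l_sites`` optionally overrides the map-derived
    per-site threshold with a fixed projected-gap count.
    """

    min_cm: float = 2.0
    r: int = 10
    s: int = 2
    partitions: int = 1
    mode: str = "retentive"
    master_seed: int = 0
    window_mode: str = "dynamic"
    window_sites: int | None = None
    window_cm: float | None = 0.05
    min_sites: int = 2
    l_sites: int | None = None
    n_buckets: int = 1
    vcf: str | None = None
    genetic_map: str | None = None

    def __post_init__(self) -> None:
        if self.min_cm <= 0:
            raise ValueError("min_cm must be positive")
        if not self.r >= self.s >= 1:
            raise ValueError("need r >= s >= 1")
        if self.partitions < 1:
            raise ValueError("need at least one partition")
        if self.mode not in ("retentive", "stable"):
            raise ValueError("mode must be 'retentive' or 'stable'")


@dataclasses.dataclass
class PassCounters:
    """Per-stage execution counts (the modes differ only here)."""

    panel_loads: int = 0
    p_array_passes: int = 0
    d_array_passes: int = 0
    long_match_passes: int = 0
    validate_merge_passes: int = 0

    def as_dict(self) -> dict[str, int]:
        return dataclasses.asdict(self)


def assign_partition(a: int, b: int, P: int) -> int:
    """Deterministic partition of pair (a, b): ``min(a, b) % P``."""
    if a == b:
        raise ValueError("a haplotype does not pair with itself")
    if P < 1:
        raise ValueError("need at least one partition")
    return min(a, b) % P


def _load_inputs(
    config: RunConfig,
    panel: HaplotypePanel | None,
    gmap: GeneticMap | None,
    counters: PassCounters,
) -> tuple[HaplotypePanel, GeneticMap]:
    """One 'load panel' pass; in-memory inputs are copied to model a fresh load."""
    counters.panel_loads += 1
    if config.vcf is not None:
        panel = read_vcf(config.vcf)
    elif panel is not None:
        panel = copy.deepcopy(panel)
    else:
        raise ValueError("no panel: provide config.vcf or an in-memory panel")
    if config.genetic_map is not None:
        gmap = read_genetic_map(config.genetic_map)
    elif gmap is None:
        raise ValueError("no genetic map: provide config.genetic_map or pass one")
    return panel, gmap


def _build_projections(
    config: RunConfig, panel: HaplotypePanel, gmap: GeneticMap
) -> list[Projection]:
    windows = make_windows(
        panel,
        gmap=gmap,
        mode=config.window_mode,
        window_sites=config.window_sites,
        window_cm=config.window_cm,
        min_sites=config.min_sites,
    )
    return [
        project(panel, windows, i, config.master_seed) for i in range(config.r)
    ]


def _thresholds(
    config: RunConfig, proj: Projection, panel: HaplotypePanel, gmap: GeneticMap
) -> np.ndarray:
    if config.l_sites is not None:
        return np.full(proj.n_proj_sites, config.l_sites, dtype=np.int64)
    return site_length_thresholds(
        gmap, proj.selected_sites, panel.positions, config.min_cm
    )


def _trajectory(proj_alleles: np.ndarray) -> list:
    """PBWT states after each consumed column of one projection."""
    state = init_state(proj_alleles.shape[1])
    states = []
    for col in proj_alleles:
        state = advance(state, col)
        states.append(state)
    return states


def _sort_calls(keyed: list[tuple[int, int, int, IBDSegment]]) -> list[IBDSegment]:
    return [seg for *_, seg in sorted(keyed, key=lambda t: t[:3])]


def run(
    config: RunConfig,
    panel: HaplotypePanel | None = None,
    gmap: GeneticMap | None = None,
) -> tuple[list[IBDSegment], PassCounters]:
    """Execute the full detection pipeline; calls are identical across
    modes and across any partition count for fixed seeds."""
    counters = PassCounters()
    P = config.partitions
    per_partition: list[list[IBDSegment]] = []

    if config.mode == "retentive":
        panel, gmap = _load_inputs(config, panel, gmap, counters)
        projections = _build_projections(config, panel, gmap)
        thresholds = [_thresholds(config, pr, panel, gmap) for pr in projections]
        trajectories = []
        for pr in projections:
            logger.info("P: prefix arrays, projection %d", pr.index_r)
            logger.info("D: divergence arrays, projection %d", pr.index_r)
            trajectories.append(_trajectory(pr.projected_alleles))
            counters.p_array_passes += 1
            counters.d_array_passes += 1
        for p in range(P):
            records = []
            for pr, states, thr in zip(projections, trajectories, thresholds):
                logger.info("L: long matches, partition %d projection %d", p, pr.index_r)
                records.extend(
                    long_matches_in_projection(
                        pr.projected_alleles,
                        thr,
                        proj_index=pr.index_r,
                        partition=(p, P),
                        states=states,
                    )
                )
                counters.long_match_passes += 1
            logger.info("V/O: validate and merge, partition %d", p)
            per_partition.append(
                finalize_calls(
                    records, projections, panel, gmap, config.s, config.n_buckets
                )
            )
            counters.validate_merge_passes += 1
    else:  # stable: fresh context per partition, nothing retained across
        for p in range(P):
            panel_p, gmap_p = _load_inputs(config, panel, gmap, counters)
            projections = _build_projections(config, panel_p, gmap_p)
            records = []
            for pr in projections:
                logger.info(
                    "P/D/L: recompute + match, partition %d projection %d",
                    p,
                    pr.index_r,
                )
                thr = _thresholds(config, pr, panel_p, gmap_p)
                records.extend(
                    long_matches_in_projection(
                        pr.projected_alleles,
                        thr,
                        proj_index=pr.index_r,
                        partition=(p, P),
                    )
                )
                counters.p_array_passes += 1
                counters.d_array_passes += 1
                counters.long_match_passes += 1
            logger.info("V/O: validate and merge, partition %d", p)
            per_partition.append(
                finalize_calls(
                    records, projections, panel_p, gmap_p, config.s, config.n_buckets
                )
            )
            counters.validate_merge_passes += 1
        panel = panel_p  # for the final global ordering below

    # deterministic global order: haplotype-pair index order, then start site
    sample_pos = {sid: i for i, sid in enumerate(panel.sample_ids)}
    keyed = [
        (
            2 * sample_pos[seg.sample_a] + seg.hap_a,
            2 * sample_pos[seg.sample_b] + seg.hap_b,
            seg.start_site,
            seg,
        )
        for calls in per_partition
        for seg in calls
    ]
    return _sort_calls(keyed), counters
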