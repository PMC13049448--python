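"""Phased-panel, genetic-map and IBD-call input/output.

The on-disk formats are deliberately minimal: phased biallelic VCF for the
haplotype panel, the two common genetic-map dialects (3-column
``chrom bp cM`` and 4-column PLINK ``chrom rsid cM bp``), and a
tab-separated table for the final IBD calls.  Everything is held in memory;
this package targets desk-scale panels, not biobank-scale streaming.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "HaplotypePanel",
    "GeneticMap",
    "IBDSegment",
    "read_vcf",
    "read_genetic_map",
    "write_ibd",
    "read_ibd",
    "IBD_COLUMNS",
]

IBD_COLUMNS = (
    "sample_a",
    "hap_a",
    "sample_b",
    "hap_b",
    "chrom",
    "start_site",
    "end_site",
    "start_bp",
    "end_bp",
    "length_cm",
    "support",
)


@dataclasses.dataclass
class HaplotypePanel:
    """A phased panel of M haplotypes over N biallelic sites.

    ``alleles`` is site-major (shape ``(N, M)``, entries 0/1) so that one
    row is one PBWT column.  Haplotype ``h`` belongs to sample ``h // 2``
    with phase ``h % 2``.
    """

    alleles: np.ndarray
    positions: np.ndarray
    sample_ids: list[str]
    chrom: str = "1"

    def __post_init__(self) -> None:
        self.alleles = np.ascontiguousarray(self.alleles, dtype=np.int8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be a 2-D (sites x haplotypes) matrix")
        n_sites, n_hap = self.alleles.shape
        if n_hap != 2 * len(self.sample_ids):
            raise ValueError(
                f"haplotype count {n_hap} != 2 x {len(self.sample_ids)} samples"
            )
        if self.positions.shape != (n_sites,):
            raise ValueError("positions length must equal the number of sites")
        if n_sites > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("site positions must be strictly increasing")
        if self.alleles.size and not np.isin(self.alleles, (0, 1)).all():
            raise ValueError("alleles must be 0/1")

    @property
    def n_hap(self) -> int:
        return self.alleles.shape[1]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[0]

    def hap_of(self, h: int) -> tuple[int, int]:
        """Map haplotype index to (sample index, phase)."""
        return h // 2, h % 2

    def hap_label(self, h: int) -> tuple[str, int]:
        """Map haplotype index to (sample identifier, phase)."""
        s, ph = self.hap_of(h)
        return self.sample_ids[s], ph


@dataclasses.dataclass
class GeneticMap:
    """Monotone bp -> cM mapping with piecewise-linear interpolation."""

    bp: np.ndarray
    cm: np.ndarray
    chrom: str = "1"

    def __post_init__(self) -> None:
        self.bp = np.asarray(self.bp, dtype=np.float64)
        self.cm = np.asarray(self.cm, dtype=np.float64)
        if self.bp.ndim != 1 or self.bp.shape != self.cm.shape:
            raise ValueError("bp and cm must be 1-D arrays of equal length")
        if self.bp.size < 2:
            raise ValueError("genetic map needs at least 2 rows")
        if not np.all(np.diff(self.bp) > 0):
            raise ValueError("genetic map bp column must be strictly increasing")
        if not np.all(np.diff(self.cm) >= 0):
            raise ValueError("genetic map cM column must be non-decreasing")

    def cm_at(self, bp) -> np.ndarray | float:
        """Interpolated cM position; out-of-range bp clamp to the ends."""
        out = np.interp(bp, self.bp, self.cm)
        return float(out) if np.isscalar(bp) else out


@dataclasses.dataclass(frozen=True)
class IBDSegment:
    """A validated, merged IBD call in original panel coordinates.

    Site indices are 0-based inclusive; ``support`` is the number of random
    projections contributing to the merged call.
    """

    sample_a: str
    hap_a: int
    sample_b: str
    hap_b: int
    chrom: str
    start_site: int
    end_site: int
    start_bp: int
    end_bp: int
    length_cm: float
    support: int

    def __post_init__(self) -> None:
        if self.start_site > self.end_site:
            raise ValueError("start_site > end_site")
        if self.start_bp > self.end_bp:
            raise ValueError("start_bp > end_bp")
        if self.length_cm < 0:
            raise ValueError("negative genetic length")


def read_vcf(path: str) -> HaplotypePanel:
    """Read a phased, biallelic single-chromosome VCF into a panel.

    Hard errors on unphased separators, multiallelic records and missing
    alleles: the matching engine has no model for them, and silently
    imputing would corrupt matches.  Users are expected to pre-filter.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    columns: list[np.ndarray] = []
    positions: list[int] = []
    chrom: str | None = None
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ValueError(
                f"multiallelic record at {rec.CHROM}:{rec.POS}; split or drop it first"
            )
        if chrom is None:
            chrom = rec.CHROM
        elif rec.CHROM != chrom:
            raise ValueError(
                f"multiple chromosomes in one file ({chrom} and {rec.CHROM}); "
                "run one chromosome at a time"
            )
        col = np.empty(2 * len(sample_ids), dtype=np.int8)
        for i, gt in enumerate(rec.genotypes):
            a, b, phased = gt[0], gt[1], gt[2]
            if a < 0 or b < 0:
                raise ValueError(
                    f"missing genotype at {rec.CHROM}:{rec.POS} sample "
                    f"{sample_ids[i]}; impute or drop it first"
                )
            if not phased:
                raise ValueError(
                    f"unphased genotype ('/') at {rec.CHROM}:{rec.POS} sample "
                    f"{sample_ids[i]}; the panel must be phased"
                )
            col[2 * i] = a
            col[2 * i + 1] = b
        columns.append(col)
        positions.append(rec.POS)
    vcf.close()
    n_hap = 2 * len(sample_ids)
    alleles = (
        np.stack(columns) if columns else np.empty((0, n_hap), dtype=np.int8)
    )
    return HaplotypePanel(
        alleles=alleles,
        positions=np.asarray(positions, dtype=np.int64),
        sample_ids=sample_ids,
        chrom=chrom if chrom is not None else "1",
    )


def read_genetic_map(path: str) -> GeneticMap:
    """Read a genetic map table, auto-detecting the dialect by column count.

    3 columns are taken as ``chrom bp cM``; 4 columns as the PLINK layout
    ``chrom rsid cM bp``.  A single non-numeric leading row is treated as a
    header and skipped.
    """
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#", dtype=str)
    if df.shape[1] == 3:
        cols = {"bp": 1, "cm": 2}
    elif df.shape[1] == 4:
        cols = {"bp": 3, "cm": 2}
    else:
        raise ValueError(
            f"genetic map must have 3 (chrom bp cM) or 4 (chrom rsid cM bp) "
            f"columns, got {df.shape[1]}"
        )
    first_bp = df.iloc[0, cols["bp"]]
    try:
        float(first_bp)
    except (TypeError, ValueError):
        df = df.iloc[1:].reset_index(drop=True)
    if len(df) < 2:
        raise ValueError("genetic map needs at least 2 data rows")
    bp = df.iloc[:, cols["bp"]].astype(float).to_numpy()
    cm = df.iloc[:, cols["cm"]].astype(float).to_numpy()
    chrom = str(df.iloc[0, 0])
    return GeneticMap(bp=bp, cm=cm, chrom=chrom)


def _segment_sort_key(seg: IBDSegment):
    return (seg.sample_a, seg.hap_a, seg.sample_b, seg.hap_b, seg.start_site)


def write_ibd(segments: Iterable[IBDSegment], path: str) -> None:
    """Write IBD calls as a sorted, tab-separated table with a ``#`` header.

    Output is byte-identical across reruns with identical inputs and seeds
    (fixed column order, fixed float formatting, deterministic sort).
    """
    rows = sorted(segments, key=_segment_sort_key)
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(IBD_COLUMNS) + "\n")
        for seg in rows:
            fh.write(
                f"{seg.sample_a}\t{seg.hap_a}\t{seg.sample_b}\t{seg.hap_b}\t"
                f"{seg.chrom}\t{seg.start_site}\t{seg.end_site}\t"
                f"{seg.start_bp}\t{seg.end_bp}\t{seg.length_cm:.6f}\t"
                f"{seg.support}\n"
            )


def read_ibd(path: str) -> list[IBDSegment]:
    """Read back a call table written by :func:`write_ibd`."""
    out: list[IBDSegment] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != len(IBD_COLUMNS):
                raise ValueError(f"expected {len(IBD_COLUMNS)} fields, got {len(f)}")
            out.append(
                IBDSegment(
                    sample_a=f[0],
                    hap_a=int(f[1]),
                    sample_b=f[2],
                    hap_b=int(f[3]),
                    chrom=f[4],
                    start_site=int(f[5]),
                    end_site=int(f[6]),
                    start_bp=int(f[7]),
                    end_bp=int(f[8]),
                    length_cm=float(f[9]),
                    support=int(f[10]),
                )
            )
    return out
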