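"""Planted-IBD simulation and detection metrics.

The generator builds a panel of independent biallelic sites (no background
linkage disequilibrium — a conservative, analytically tractable null for
false-positive behaviour), plants pairwise IBD segments of known
coordinates by copying one haplotype onto another over a site range, and
optionally flips alleles at a fixed genotyping-error rate.  The metrics
mirror the standard IBD benchmarking definitions: accuracy, recall, power,
length discrepancy, length accuracy and accumulated recall, with a 50%
genetic-length overlap rule on both the call side (accuracy) and the truth
side (recall/power).
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np

from .panel_io import GeneticMap, HaplotypePanel, IBDSegment

__all__ = [
    "TruthSegment",
    "EvalReport",
    "DEFAULT_LENGTH_BINS",
    "simulate_panel",
    "plant_ibd",
    "add_error",
    "evaluate",
    "write_vcf",
    "write_truth",
    "read_truth",
]

#: Length bins (cM) for per-bin and accumulated recall; the last bin is
#: open-ended.  Chosen to bracket the usual 2 / 3 / 5 cM reporting grid.
DEFAULT_LENGTH_BINS = ((2.0, 3.0), (3.0, 4.0), (4.0, 5.0), (5.0, math.inf))


@dataclasses.dataclass(frozen=True)
class TruthSegment:
    """A planted segment: before error injection, haplotypes ``hap_a`` and
    ``hap_b`` are identical on sites [start_site, end_site]."""

    hap_a: int
    hap_b: int
    start_site: int
    end_site: int
    start_bp: int
    end_bp: int
    length_cm: float

    def __post_init__(self) -> None:
        if not self.hap_a < self.hap_b:
            raise ValueError("truth pair must satisfy hap_a < hap_b")
        if self.start_site > self.end_site:
            raise ValueError("inverted truth segment")


@dataclasses.dataclass
class EvalReport:
    """Detection metrics; proportions are in [0, 1], lengths in cM.

    ``recall_by_bin`` maps a bin to (recall, n_truth_in_bin); recall fields
    are NaN when the truth set is empty.
    """

    accuracy: float
    recall: float
    power: float
    length_accuracy: float
    length_discrepancy: float
    accumulated_recall: float
    n_calls: int
    n_truth: int
    recall_by_bin: dict[tuple[float, float], tuple[float, int]]

    @property
    def false_positive_rate(self) -> float:
        return 1.0 - self.accuracy


def simulate_panel(
    M: int,
    N: int,
    maf_range: tuple[float, float] = (0.4, 0.5),
    seed: int = 0,
    cm_per_site: float = 0.01,
    bp_per_site: int = 100,
    chrom: str = "1",
) -> tuple[HaplotypePanel, GeneticMap]:
    """Panel of M haplotypes x N sites with a uniform genetic map.

    Per site an alternate-allele frequency is drawn uniformly from
    ``maf_range`` and alleles are sampled independently across haplotypes.
    The default MAF floor of 0.4 emulates a panel restricted to common,
    IBD-informative markers.  The map is linear: ``cm_per_site`` per site,
    ``bp_per_site`` base pairs between sites.
    """
    if M % 2 or M <= 0:
        raise ValueError("M must be positive and even (two haplotypes per sample)")
    if N < 2:
        raise ValueError("need at least two sites to carry a genetic map")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    freq = rng.uniform(maf_range[0], maf_range[1], size=N)
    alleles = (rng.random((N, M)) < freq[:, None]).astype(np.int8)
    positions = 1 + bp_per_site * np.arange(N, dtype=np.int64)
    panel = HaplotypePanel(
        alleles=alleles,
        positions=positions,
        sample_ids=[f"s{i:06d}" for i in range(M // 2)],
        chrom=chrom,
    )
    gmap = GeneticMap(
        bp=np.array([positions[0], positions[-1]], dtype=np.float64),
        cm=np.array([0.0, cm_per_site * (N - 1)], dtype=np.float64),
        chrom=chrom,
    )
    return panel, gmap


def plant_ibd(
    panel: HaplotypePanel,
    gmap: GeneticMap,
    n_segments: int,
    length_cm_range: tuple[float, float],
    seed: int = 0,
    max_retries: int = 1000,
) -> list[TruthSegment]:
    """Plant pairwise IBD segments by copying hap_a onto hap_b in place.

    Pairs and start sites are uniform; the end site is the first site at
    the drawn genetic length from the start, so the recorded ``length_cm``
    is exact on the map.  A pair is planted at most once (double planting
    is resampled), and a placement whose site range overlaps an earlier
    planted segment on a shared haplotype is resampled too — copying onto
    a haplotype inside an existing planted region would silently destroy
    that region's truth.  Placement failure after ``max_retries`` draws
    raises.  Every planted segment holds at least two sites.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    cm = np.asarray(gmap.cm_at(panel.positions))
    N, M = panel.alleles.shape
    used_pairs: set[tuple[int, int]] = set()
    hap_spans: dict[int, list[tuple[int, int]]] = {}
    truth: list[TruthSegment] = []
    for _ in range(n_segments):
        for attempt in range(max_retries):
            a, b = rng.choice(M, size=2, replace=False)
            a, b = (int(a), int(b)) if a < b else (int(b), int(a))
            if (a, b) in used_pairs:
                continue
            length = float(rng.uniform(*length_cm_range))
            s = int(rng.integers(0, N))
            e = int(np.searchsorted(cm, cm[s] + length, side="left"))
            e = max(e, s + 1)
            if e >= N:
                continue
            if any(
                s <= pe and ps <= e
                for h in (a, b)
                for ps, pe in hap_spans.get(h, ())
            ):
                continue
            used_pairs.add((a, b))
            hap_spans.setdefault(a, []).append((s, e))
            hap_spans.setdefault(b, []).append((s, e))
            panel.alleles[s : e + 1, b] = panel.alleles[s : e + 1, a]
            truth.append(
                TruthSegment(
                    hap_a=a,
                    hap_b=b,
                    start_site=s,
                    end_site=e,
                    start_bp=int(panel.positions[s]),
                    end_bp=int(panel.positions[e]),
                    length_cm=float(cm[e] - cm[s]),
                )
            )
            break
        else:
            raise RuntimeError(
                f"could not place segment after {max_retries} attempts"
            )
    return truth


def add_error(panel: HaplotypePanel, rate: float, seed: int = 0) -> HaplotypePanel:
    """Return a copy with each allele flipped independently with ``rate``."""
    if not 0 <= rate < 1:
        raise ValueError("error rate must be in [0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    flips = rng.random(panel.alleles.shape) < rate
    return HaplotypePanel(
        alleles=np.where(flips, 1 - panel.alleles, panel.alleles).astype(np.int8),
        positions=panel.positions.copy(),
        sample_ids=list(panel.sample_ids),
        chrom=panel.chrom,
    )


def _call_pair(seg: IBDSegment, sample_index: Mapping[str, int] | None) -> tuple[int, int]:
    def hap(sample: str, phase: int) -> int:
        if sample_index is not None:
            si = sample_index[sample]
        else:
            digits = "".join(ch for ch in sample if ch.isdigit())
            if not digits:
                raise ValueError(
                    f"cannot infer sample index from {sample!r}; pass sample_index"
                )
            si = int(digits)
        return 2 * si + phase

    a = hap(seg.sample_a, seg.hap_a)
    b = hap(seg.sample_b, seg.hap_b)
    return (a, b) if a < b else (b, a)


def _overlap_cm(
    call: IBDSegment, truth: TruthSegment, gmap: GeneticMap
) -> float:
    lo = max(call.start_bp, truth.start_bp)
    hi = min(call.end_bp, truth.end_bp)
    if lo > hi:
        return -1.0
    return float(gmap.cm_at(hi) - gmap.cm_at(lo))


def evaluate(
    calls: Sequence[IBDSegment],
    truth: Sequence[TruthSegment],
    gmap: GeneticMap,
    length_bins: Sequence[tuple[float, float]] = DEFAULT_LENGTH_BINS,
    sample_index: Mapping[str, int] | None = None,
) -> EvalReport:
    """Score calls against planted truth.

    * accuracy: fraction of calls whose genetic overlap with some same-pair
      truth segment is at least half the call's length;
    * power: fraction of truth segments with some same-pair call covering
      at least half the truth's length;
    * recall: as power, but under a greedy one-to-one call/truth matching
      (by descending overlap), so one call cannot satisfy two truths;
    * length discrepancy / accuracy: mean |call - truth| length and mean
      call/truth length ratio over the greedily matched pairs;
    * accumulated recall: mean per-bin recall over the non-empty length
      bins (truth binned by its own length).
    """
    if not truth:
        if calls:
            warnings.warn("non-empty call set with empty truth: recall undefined")
        nan = float("nan")
        return EvalReport(
            accuracy=0.0 if calls else nan,
            recall=nan,
            power=nan,
            length_accuracy=nan,
            length_discrepancy=nan,
            accumulated_recall=nan,
            n_calls=len(calls),
            n_truth=0,
            recall_by_bin={tuple(b): (nan, 0) for b in length_bins},
        )

    truth_by_pair: dict[tuple[int, int], list[int]] = {}
    for ti, t in enumerate(truth):
        truth_by_pair.setdefault((t.hap_a, t.hap_b), []).append(ti)

    overlaps: list[tuple[float, int, int]] = []  # (overlap_cm, call idx, truth idx)
    accurate = np.zeros(len(calls), dtype=bool)
    hit = np.zeros(len(truth), dtype=bool)  # any-call 50% rule -> power
    for ci, call in enumerate(calls):
        pair = _call_pair(call, sample_index)
        for ti in truth_by_pair.get(pair, ()):
            ov = _overlap_cm(call, truth[ti], gmap)
            if ov < 0:
                continue
            overlaps.append((ov, ci, ti))
            if ov >= 0.5 * call.length_cm:
                accurate[ci] = True
            if ov >= 0.5 * truth[ti].length_cm:
                hit[ti] = True

    # greedy one-to-one matching by descending overlap (ties by index)
    matched_call: set[int] = set()
    matched_truth: dict[int, tuple[int, float]] = {}
    for ov, ci, ti in sorted(overlaps, key=lambda t: (-t[0], t[1], t[2])):
        if ci in matched_call or ti in matched_truth:
            continue
        matched_call.add(ci)
        matched_truth[ti] = (ci, ov)

    detected = np.zeros(len(truth), dtype=bool)
    for ti, (_ci, ov) in matched_truth.items():
        if ov >= 0.5 * truth[ti].length_cm:
            detected[ti] = True

    tlen = np.array([t.length_cm for t in truth])
    by_bin: dict[tuple[float, float], tuple[float, int]] = {}
    bin_recalls = []
    for lo, hi in length_bins:
        in_bin = (tlen >= lo) & (tlen < hi)
        n = int(in_bin.sum())
        r = float(detected[in_bin].mean()) if n else float("nan")
        by_bin[(lo, hi)] = (r, n)
        if n:
            bin_recalls.append(r)

    if matched_truth:
        pairs = [(calls[ci].length_cm, truth[ti].length_cm)
                 for ti, (ci, _ov) in sorted(matched_truth.items())]
        clen = np.array([p[0] for p in pairs])
        tl = np.array([p[1] for p in pairs])
        length_discrepancy = float(np.mean(np.abs(clen - tl)))
        length_accuracy = float(np.mean(clen / tl))
    else:
        length_discrepancy = float("nan")
        length_accuracy = float("nan")

    return EvalReport(
        accuracy=float(accurate.mean()) if calls else float("nan"),
        recall=float(detected.mean()),
        power=float(hit.mean()),
        length_accuracy=length_accuracy,
        length_discrepancy=length_discrepancy,
        accumulated_recall=float(np.mean(bin_recalls)) if bin_recalls else float("nan"),
        n_calls=len(calls),
        n_truth=len(truth),
        recall_by_bin=by_bin,
    )


def write_vcf(panel: HaplotypePanel, path: str) -> None:
    """Write the panel as a minimal phased VCF 4.2 file."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        end = int(panel.positions[-1]) + 1 if panel.n_sites else 2
        fh.write(f"##contig=<ID={panel.chrom},length={end}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.sample_ids)
            + "\n"
        )
        for j in range(panel.n_sites):
            row = panel.alleles[j]
            gts = "\t".join(
                f"{row[2 * i]}|{row[2 * i + 1]}" for i in range(len(panel.sample_ids))
            )
            fh.write(
                f"{panel.chrom}\t{panel.positions[j]}\t.\tA\tC\t.\tPASS\t.\tGT\t{gts}\n"
            )


_TRUTH_COLUMNS = (
    "hap_a",
    "hap_b",
    "start_site",
    "end_site",
    "start_bp",
    "end_bp",
    "length_cm",
)


def write_truth(truth: Iterable[TruthSegment], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(_TRUTH_COLUMNS) + "\n")
        for t in truth:
            fh.write(
                f"{t.hap_a}\t{t.hap_b}\t{t.start_site}\t{t.end_site}\t"
                f"{t.start_bp}\t{t.end_bp}\t{t.length_cm:.6f}\n"
            )


def read_truth(path: str) -> list[TruthSegment]:
    out: list[TruthSegment] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            out.append(
                TruthSegment(
                    hap_a=int(f[0]),
                    hap_b=int(f[1]),
                    start_site=int(f[2]),
                    end_site=int(f[3]),
                    start_bp=int(f[4]),
                    end_bp=int(f[5]),
                    length_cm=float(f[6]),
                )
            )
    return out
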