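# ibdscan

Detection of identity-by-descent (IBD) segments in phased haplotype panels
by exact matching over random projections of a positional Burrows–Wheeler
transform (PBWT).

IBD segments — long stretches of chromosome that two haplotypes inherit
from a common ancestor — underpin relatedness estimation, fine-scale
population structure and demographic inference.  Exact-match methods such
as the PBWT find shared haplotype runs in linear time, but a single
genotyping error breaks an exact run in two, so raw exact matching badly
under-calls IBD on real data.  `ibdscan` detects approximate matches by
running the exact machinery on several *random projections* of the panel
and requiring agreement between them.

## Method

Given a phased panel of `M` haplotypes over `N` biallelic sites and a
genetic map:

1. **Random projection.**  The site axis is tiled into windows — a fixed
   number of sites, a fixed genetic span (e.g. 0.05 cM), or a hybrid of
   both with a minimum-site floor — and, per projection `r`, one site per
   window is chosen uniformly at random from a seeded stream.  An allele
   error only corrupts a projection when the flipped site is the selected
   one, so independent projections fail independently.
2. **PBWT sweep.**  For each projection, the prefix array `P_k`
   (haplotypes in co-lexicographic order of reversed prefixes) and
   divergence array `D_k` (start of the longest common suffix between
   rank-adjacent haplotypes) are maintained per site.  A block-decomposed
   update — per-block counts, an exclusive offset scan, placement, and
   per-block divergence seeds propagated between blocks — is provided and
   is exactly equivalent to the sequential update, certifying that the
   work can be partitioned without changing results.
3. **Long-match detection.**  At projected site `k`, the minimum genetic
   length `L` cM is converted to a site threshold `L_sites` by a reverse
   scan on the map (e.g. 20 projected sites for 2 cM at 0.1 cM spacing).
   Maximal rank intervals with `D[m] <= k − L_sites` (regions of interest)
   are enumerated pairwise, and a pair's match `(A, B, r, S, E)` is
   reported once, at the site where the pair's alleles next diverge or at
   the panel end.
4. **Validation and merging.**  Matches are bucketed by pair, sorted, and
   per-pair interval lists (one per projection) are merged by a linear
   sweep; a merged run supported by at least `s` projections (default 2)
   becomes a call, lifted back to base-pair and centimorgan coordinates.
5. **Partitioned execution.**  Pairs are deterministically assigned to
   partition `min(A,B) mod P`, covering the pair space exactly once.  A
   *memory-retentive* run caches all PBWT trajectories and reuses them
   across partitions; a *memory-stable* run reloads and recomputes per
   partition.  Both produce byte-identical output; per-stage pass
   counters expose the time/space trade-off (retentive: 1 panel load,
   `r` P/D passes, `r·P` match passes; stable: `P` loads, `r·P` P/D
   passes).

A synthetic-data module generates panels with planted ground-truth IBD
segments and genotyping error, plus the standard evaluation metrics
(accuracy, recall, power, length accuracy/discrepancy, accumulated
recall) so the whole system is testable without external data.

## Worked example

Simulate a 40-haplotype, 2000-site panel with five planted segments and
0.1% allele error, detect at a 2 cM threshold, and score the calls:

```sh
ibdscan simulate --haplotypes 40 --sites 2000 --segments 5 --seed 3 --out-prefix demo
ibdscan detect --vcf demo.vcf --map demo.map --min-cm 2 --projections 10 \
       --support 2 --partitions 4 --mode stable --seed 1 --out demo.calls.tsv
ibdscan evaluate --calls demo.calls.tsv --truth demo.truth.tsv --map demo.map
```

The detect step prints its stage pass counts —

```
5 calls written to demo.calls.tsv (0.7s; passes {'panel_loads': 4,
'p_array_passes': 40, 'd_array_passes': 40, 'long_match_passes': 40,
'validate_merge_passes': 4})
```

(4 partitions × 10 projections in stable mode recompute everything per
partition) — and the call table holds one row per validated segment:

```
#sample_a  hap_a  sample_b  hap_b  chrom  start_site  end_site  start_bp  end_bp  length_cm  support
s000003    1      s000011   0      1      1214        1783      121401    178301  5.690000   10
```

`support 10` means all ten projections recovered the segment.  The
evaluation reports

```
"accuracy": 1.0, "recall": 1.0, "power": 1.0,
"length_accuracy": 1.0395..., "length_discrepancy_cm": 0.198...
```

i.e. all five planted segments were found by exactly one call each, with
call lengths on average ~4% longer than truth (window-boundary
quantization extends calls by up to one window per side).

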