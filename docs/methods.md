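# Methods

## Model and assumptions

`ibdscan` calls a segment IBD for a haplotype pair when the pair shares an
exact allele run, of at least the minimum genetic length, in enough
independently downsampled copies of the panel.  The underlying assumptions
are the usual ones for projection-based IBD detection:

* the panel is phased and biallelic, with one chromosome per run;
* genotyping errors are sparse and site-independent, so a true IBD
  segment survives intact in most projections while a chance run rarely
  recurs at the same place in two projections;
* the genetic map is trusted: all length thresholds and reported lengths
  are map-interpolated centimorgans, and bp positions outside the map
  range clamp to its terminal cM values (no extrapolation — extrapolated
  rates would invent recombination).

Missing genotypes, unphased separators and multiallelic records are hard
errors rather than being imputed: the matching engine has no error model
for them, and silent imputation would manufacture or destroy matches.

## Pipeline stages and the parameters that matter

**Windows.**  `window.mode` ∈ {fixed, dynamic, hybrid}.  Dynamic windows
(default 0.05 cM) end at the first site lying at least `window.cm` past
the window's first site; on a uniformly spaced map this tiles the panel
into equal-width windows with no remainder (20 sites at 0.01 cM spacing
and a 0.05 cM window give exactly four 5-site windows).  Windows below
`min_sites` (default 2) merge into their left neighbour, keeping window 0
anchored at site 0; a deficient leading window merges right.  One window
set is shared by all projections, so projected (window) coordinates are
directly comparable across projections — this is what lets validation and
merging operate on window indices.

**Projections.**  `projections.count` r = 10 by default, matching common
practice for this family of detectors.  Site choice within a window is
uniform.  Per-projection streams derive from
`SeedSequence(master_seed, spawn_key=(r,))`, so projections are mutually
independent, reproducible, and insensitive to generation order.

**Threshold lookup.**  The minimum length `min_cm` (2 cM default; 2/3/5 cM
are the conventional operating points) is converted, per projected site
`k`, to the smallest gap count `c` with `cm[k] − cm[k−c] ≥ min_cm`; a
qualifying run therefore carries `c+1` projected sites and at least
`min_cm` of genetic span.  At 0.1 cM projected spacing and 2 cM this gives
the textbook 20-site window.  When even the full prefix is shorter than
`min_cm` the sentinel `k+1` makes the divergence condition
`D[m] ≤ k − L_sites` unsatisfiable, so early-chromosome runs cannot
qualify spuriously.  Thresholds are recomputed per site (correctness
first); caching per region would be a pure optimization.  Genetic
comparisons carry a 1e-9 cM slack so exactly spaced maps hit their nominal
thresholds instead of falling one ulp short.

**Match reporting.**  Matches are emitted once, at the projected site
where the pair's alleles next differ (or via an explicit end-marker pass
at the last site, a case the per-site loop cannot see).  Within a region
of interest every rank pair already satisfies the length condition, so
enumeration is O(run²) with the running maximum of intervening divergence
values supplying the match start.

**Validation and merging.**  "Consistent across projections" is
operationalized as: per pair, the per-projection interval lists are merged
into maximal runs (intervals merge iff the next start ≤ the current end —
shared endpoints merge, mere adjacency does not), and a run's support is
the number of distinct projections contributing to it.  A run passes with
support ≥ s (default 2).  Union-then-count makes the validate/merge order
immaterial and the result independent of record arrival order.  Merged
runs are lifted to original coordinates through the selected sites of the
lowest-indexed supporting projection; since windows are shared, any other
choice differs by at most one window span.  Calls are not trimmed back to
`min_cm` when boundary windows over-extend; boundary quantization of up to
one window per side is visible as a length-accuracy ratio slightly above 1.

**Partitioned execution.**  `min(A,B) mod P` covers the pair space exactly
once; empty partitions are legal.  The memory-retentive mode keeps all
projections' PBWT trajectories (O(M·n·r) memory) and runs `r·P` match
passes; the memory-stable mode reloads and recomputes per partition
(O(M) working state beyond the match holder).  "Program restart" between
stable partitions is modelled as a fresh pipeline context (inputs re-read
or deep-copied); true process isolation is an orchestration concern, not a
semantic one — the contract is byte-identical output, which the suite
checks across modes and partition counts.  No thread runtime is shipped:
the blocked PBWT update and the associative ROI scan certify that the
per-stage work decomposes into independent blocks, which is the
correctness content of a parallel deployment.

## Numerical and degenerate-input choices

* PBWT sentinel: after each update the divergence at every allele-group
  head is `k+1` ("no common suffix with predecessor"), the classical
  convention; ties between equal reversed prefixes stay in input order
  (stable partition).
* Sites are 0-based; segment site ranges are inclusive `[S, E]`; window
  intervals are half-open `[start, end)`.
* Output floats are fixed-format (`%.6f`) and rows fully sorted, so
  equal runs produce byte-identical files.
* Degenerate inputs: an empty VCF body yields an N=0 panel; a panel
  cannot be windowed at N=0; `min_sites > N`, self-pairs, zero-length
  maps and inverted intervals raise immediately.

## What the synthetic generator does and does not emulate

`simulate_panel` draws per-site alternate-allele frequencies uniformly
from (0.4, 0.5) by default — a panel of common, IBD-informative markers —
and samples alleles independently across sites and haplotypes.  With
independent sites the chance that a pair matches at one site is ≈ 0.51,
so a 20-projected-site chance run has probability ~1e-6 and the support
requirement s=2 suppresses essentially all background calls; this makes
the no-LD background a clean specificity null.  `plant_ibd` copies one
haplotype onto another over a site range chosen to span an exact map
length, rejecting same-pair double planting and any placement that would
overwrite an earlier planted region on a shared haplotype (which would
silently falsify that region's truth).  `add_error` flips each allele
independently (0.1% in the validation studies).

Deliberately not emulated: background linkage disequilibrium, coalescent
segment-length distributions, phasing switch errors, and allele-frequency
spectra of real arrays.  Real panels have LD, so chance runs are longer
there than under this null; passing the null-specificity test bounds the
machinery's false-call behaviour under independence, not the biological
false-positive rate of array data.  Power numbers on planted segments
show that the detector recovers exact planted sharing at the stated
lengths and error rate; they are not estimates of power on
coalescent-simulated or real cohorts.

## Problem sizes used in the checks

The test suite and the acceptance script run at desk scale, chosen so a
full pass stays in minutes while every contract is exercised well beyond
its edge cases: PBWT brute-force equivalence on 200 random panels (M ≤ 64,
N ≤ 40) at every column; blocked-update equivalence for every block count
T ∈ {1..M} on the same panels; long-match brute-force equivalence on 200
projected panels; 1000 random merge instances; the planted study at
M=200, N=5000 with 48 segments of 2–7 cM; and 50 unplanted M=100, N=2000
null replicates.

## Known limitations

* In-memory only; no BCF/indexed access, no multi-chromosome batching
  (run per chromosome), no binary panel cache.
* The retentive mode's trajectory cache is O(M·n·r) 32-bit integers;
  desk-scale panels fit easily, biobank panels are out of scope.
* The orchestrated pipeline requires a genetic map (calls carry cM
  lengths).  The map-free fixed-threshold scheme is available at library
  level (`long_matches_in_projection` with an integer threshold,
  `RunConfig.l_sites`).
* Pair enumeration within a region of interest is O(run²); panels with
  very large identical groups (e.g. long monomorphic stretches under a
  permissive threshold) will be slow.
* Site selection within windows is uniform by default;
  minor-allele-frequency weighting is available (`project(...,
  freq_weighted=True)`) but off, since uniform selection is the
  behaviour the validation studies characterize.
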