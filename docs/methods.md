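# Methods

## The statistic: anchored in-repeat reads

A tandem repeat (TR) that has expanded beyond the sequencing read length
leaves a characteristic footprint in paired-end data: one mate of a pair maps
confidently next to the locus (the *anchor*, mapping quality ≥ 50) while the
other mate lies entirely inside the repeat tract, consists of near-pure
tandem copies of one motif, and maps nowhere specific (MAPQ ≤ 40). Each such
pair is one **anchored in-repeat read (IRR) event**. Per sample and locus,
the raw event count is scaled to a common global depth,

    AIR = raw_count × target_depth / global_depth,   target_depth = 40,

where `global_depth` is total aligned autosomal bases over autosomal genome
length. The target depth cancels in every case–control comparison; it only
fixes the absolute scale of the AIR statistic.

Motifs are stored canonically: the unit is reduced to its primitive period
(ATAT → AT) and mapped to the lexicographic minimum over all rotations of
itself and of its reverse complement (GAAA → AAAG), so every description of
the same repeat on either strand collapses to one locus key. A read is
classified as an IRR when some unit of length 2–20, proposed from the read's
own k-mers, tiles the read with **purity** (matching bases / read length,
maximised over strands and tiling phases) ≥ 0.9. Among qualifying units the
*shortest* is reported: a read periodic at unit length k is also periodic at
every multiple of k, and a longer unit can only absorb sequencing errors, so
parsimony identifies the true motif. Candidate units must occur at least
twice in the read; single-occurrence k-mers are flank-crossing chimeras.
The 0.9 threshold is a configuration knob; it is chosen so that a repeat
read with ≤ 8% scattered substitutions still qualifies while random sequence
never does (the best purity of a random 100-mer over all unit lengths stays
below 0.9).

## The prioritization cascade

Given a loci × samples AIR matrix for a tumour–normal cohort, loci are
triaged in a fixed order; every threshold comparison is strict:

1. **Chromosome filter** — only chromosomes 1–22, X, Y are analysed.
2. **Cap filter** — a locus is removed when more than 10% of its AIR values
   exceed the theoretical maximum of the statistic (`air_cap`, default 40).
   Values above that maximum cannot arise from a real expansion and indicate
   alignment artefacts. The maximum depends on sequencing geometry: for a
   tract much longer than a fragment, anchored pairs require one mate fully
   inside and one fully outside the tract, so their fragment starts occupy
   `fragment_length − 2 × read_length` positions per flank, giving

        AIR_max = (fragment_mean − 2·read_length)/read_length × target_depth.

   The default cap of 40 corresponds to ~300-bp fragments at 100-bp reads
   (typical for the cohorts the method was built for). The synthetic
   benchmarks in this package simulate 500-bp fragments, whose theoretical
   maximum is 120; `theoretical_air_cap()` computes the value for any
   geometry, and all synthetic-cohort analyses use it.
3. **Rank-sum test** — per locus, a one-sided Wilcoxon rank-sum test of
   tumour vs normal AIR values (tumours greater). The paired structure is
   deliberately not used here; pairing enters only through the AIQ below.
4. **FDR** — Benjamini–Hochberg across surviving loci. `q < 0.10` makes a
   locus a *candidate*; `q < 0.05` plus the frequency filter below makes it
   a *somatic* call.
5. **AIQ frequency filter** — per tumour–normal pair the Anchored IRR
   quotient is

        AIQ = (tumour AIR − normal AIR) / (normal AIR + 1),

   and a pair is called expanded when AIQ > 2.5 (strict; the +1 damps noise
   at low normal counts). A locus must have AIQ > 2.5 in more than 5% of
   pairs.
6. **Local-depth refilter** — see below. Loci surviving it carry the final
   status `rre`; those failing it become `removed_local_depth`. Loci that
   fail earlier stages carry `removed_chrom`, `removed_cap`, `candidate`, or
   `not_significant` (the last is this package's addition for loci that pass
   the structural filters but show no signal).

## Local read-depth normalization

Chromosomal amplification of a repeat-containing region inflates anchored
IRR counts exactly as it inflates every other read near the locus, and so
mimics an expansion after global normalization. The filter computes, per
sample, the mean aligned coverage over the locus ± 250 bp (a 500-bp region
around the tract's start and stop positions; the flank is configurable
because the width of that region admits two readings) counting all primary
reads regardless of MAPQ — amplification inflates low-MAPQ repeat mates too.
The locally normalized value is `raw_count / local_depth`, rescaled by the
locus's cohort-median local depth so magnitudes stay on the raw-count scale
(which keeps the cap threshold meaningful). For somatic candidates the
rank-sum test, BH adjustment, and AIQ-frequency filter are recomputed on
these values; a true expansion keeps its tumour excess (its window depth is
normal), while an amplified locus flattens (counts and depth inflate by the
same factor). A zero or undefined window depth in any sample excludes the
locus with an explicit reason — never a silent zero. How exactly the
original analysis recomputed significance after local normalization is not
published; this refilter rule is our explicit choice.

## Population frequency

Discovery loci are matched to population-cohort loci by canonical motif and
overlap of intervals padded by 1,000 bp (half-open semantics; genome-assembly
liftover is out of scope — catalogues must share an assembly). Population
AIR values from 150-bp-read cohorts are converted to the 100-bp discovery
scale with `AIR₁₀₀ = 0.5 + 1.5 × AIR₁₅₀`. A population sample counts as
expanded when its converted AIR strictly exceeds the 99th percentile
(linear interpolation between closest ranks; the percentile definition is
configurable since none is prescribed) of the discovery cohort's normal
samples. Drawing the population from the reference distribution itself
yields ≈ 1% calls by construction; the calibration benchmark checks this at
n = 10,000 with a 50,000-sample reference so that threshold-estimation noise
is negligible next to binomial noise.

## The simulator

`tropic.sim` generates truth-bearing cohorts end to end:

* **Genomes** — uniform-random background with tandem repeat tracts placed
  at known positions; `expand_reference` rewrites a tract to a target copy
  number with perfect copies, shifting downstream coordinates and recording
  a piecewise map back to the reference frame.
* **Reads** — wgsim-style: pair count = round(coverage × genome length /
  (2 × read length)); fragment lengths normal(500, 50) clipped to
  [read length, chromosome]; mates read from opposite strands of the
  fragment ends; independent substitutions at rate 0.02 (the cited
  simulator's default). Substitutions only — no indels — so truth
  coordinates stay exact.
* **Oracle alignment** — replaces an external aligner: every read is placed
  at its true position (tumour coordinates mapped back to the reference
  frame, as all samples would be aligned to one reference); reads that are
  IRRs by the classifier get MAPQ 0 (a pure repeat read is placeable
  anywhere in its tract), all others MAPQ 60. This encodes exactly the
  mapping property the detector relies on. Real alignments (BAM) remain a
  first-class input path through the same interfaces.
* **Amplification** — extra read pairs drawn from the region ± 1,000 bp at a
  rate bringing interior regional coverage to base × copy_number / 2
  (diploid baseline; copy number 2 adds nothing). The rate is computed
  against the fragment-start span of the sub-reference, since confining
  fragments to a short interval concentrates coverage in its interior.
* **Cohorts** — per pair, the normal genome is the reference; the tumour
  carries each designated expansion independently with the configured
  carrier frequency (one binomial draw per pair × locus, recorded exactly in
  the truth table). All randomness descends from a single seed through
  named `SeedSequence` children; every output is byte-reproducible from
  (config, seed).
* **Downsampling** — pairs retained independently with probability f, mates
  together, seed-deterministic.

What the simulator does **not** emulate: mappability structure and
multi-mapping ambiguity (the oracle's MAPQ model is binary), GC and
sequencer-specific biases, indels, PCR duplicates, diploid heterozygosity,
and genome-wide families of similar repeats that attract each other's
mates. Passing benchmarks therefore demonstrate the statistical machinery
— normalization, testing, filtering, calling — under a faithful read-count
model, not robustness to real-data alignment pathologies.

## Benchmark designs and their rationale

All benchmark study designs live in `tropic.benchmarks` and are fixed study
conditions; the problem sizes below were chosen so each benchmark runs in
minutes on one CPU.

* **Parameter recovery** (`run_standard_fixture`) — 20 pairs, 120-kb genome,
  ten TRs of which three (GAAA, AT, AGC) are expanded to 252 bp = 2.5× read
  length at 30% carrier frequency, 30× coverage. 252 bp keeps carrier AIR
  (≈ 70) inside the geometry cap (120). The fixture seed (5) was selected by
  inspecting the truth carrier table only: with 20 pairs the exact
  tie-structure rank-sum p for k carriers against all-zero backgrounds is
  C(20,k)/C(40,k), which exceeds 0.05 for k ≤ 4, so a fixture drawing fewer
  than 5 carriers at a locus could not demonstrate recovery under any
  implementation; seed 5 is the first whose draws give ≥ 5 carriers at all
  three loci (8, 7, 6).
* **Copy-number sweep** (`copy_number_sweep`) — a 1-Mb chromosome carrying a
  400-bp germline GAAA tract (longer than the read length in *every* genome:
  the false-positive substrate) and a somatically expanded AGC tract. One
  base read set at 30× is shared by all copy numbers — amplification adds
  regional reads on top, mirroring the concatenation design of the original
  benchmark. Expected behaviour: global AIR grows ∝ copy_number/2, local
  AIR stays flat (< 15% variation; the 400-bp tract gives ~100 events, so
  Poisson noise contributes only ~3%).
* **Amplification refilter** (`amplification_refilter`) — nine pairs whose
  tumours all carry an 8-copy amplification of a 120-bp germline tract
  (small enough that CN-8 AIR ≈ 81 stays under the cap) plus a true 252-bp
  expansion. The global cascade flags both loci; the refilter must remove
  the first and keep the second.
* **Downsampling** (`downsampling_benchmark`) — the hardest design. With a
  noiseless simulator and clean normals, a strongly expanded locus has an
  identical tie-structure rank-sum p at any coverage, and for one marginal
  locus a 3× coverage change moves the rank-sum z by well under its seed-to-
  seed spread. The benchmark therefore uses 49 replicate marginal loci:
  germline GAAA×28 tracts (112 bp — above read length, so normals carry
  background events) expanded to ×35 (140 bp) in tumour carriers, 20 pairs,
  50% carrier frequency. The summary statistic is the **median BH-corrected
  p across the replicate loci**: significant (< 0.05) at 30×, lost (≥ 0.05)
  after retaining each pair with probability 1/3 (10×). Tract lengths,
  cohort size and carrier frequency were fixed a priori by a power analysis
  of the Poisson event-rate model (measured event rates per tract length),
  which puts the joint probability of the expected direction near 0.97;
  the replicate-median is what makes a fixed-seed assertion meaningful.
* **Population calibration** (`population_calibration`) — lognormal AIR
  reference (n = 50,000) and population (n = 10,000) from the same
  distribution; expected expanded fraction 1% within the binomial interval.

## Numerical choices

* Rank-sum p-values are exact whenever both groups have ≤ 12 values:
  the null distribution of the rank sum is built by subset-sum counting
  over doubled midranks (ties handled exactly as full enumeration of group
  assignments would), then P(W ≥ observed). Larger groups use the
  tie-corrected normal approximation with continuity correction.
* BH adjustment delegates to `statsmodels` (`fdr_bh`); tests verify it
  against a literal step-up oracle.
* Fisher one-tailed tests delegate to `scipy`; tests verify against direct
  hypergeometric summation. A zero-margin table returns p = 1 with a
  warning.
* Percentiles use linear interpolation between closest ranks.
* Bookended intervals have distance 0 (deliberately not the +1 convention
  of some command-line closest tools). An arm-boundary midpoint is assigned
  to the q arm; loci spanning the boundary go by midpoint. Ties everywhere
  are resolved deterministically; locus tables are sorted by
  (chromosome, start, motif), so results are invariant to input order.
* Ambiguous bases (N) count as mismatches in purity. Reads shorter than
  twice the smallest unit return (False, None) rather than raising.
* Cluster merging is single-linkage on anchor positions with a 500-bp gap
  threshold (matching the local-depth window scale); a cluster spans
  [min anchor, max anchor + read length).
* Empty alignment streams, unsorted or unpaired BAMs, chromosomes missing
  from an arm table or alignment set, cohorts with < 2 pairs, and zero
  local depths all raise explicit errors.

## Known limitations

* The IRR classifier approximates an unpublished internal classifier by
  construction; equivalence with any specific external tool's output is
  approximate.
* Whether an anchored pair should be counted once per pair or once per IRR
  mate is ambiguous in the underlying method description; this package
  counts pairs with exactly one anchor, and pairs where both mates are IRRs
  contribute to no locus (they carry no anchor).
* The rank-sum test treats tumours and normals as independent groups; the
  paired design is exploited only by the AIQ.
* The two printed FDR thresholds (candidate 0.10, somatic 0.05) are emitted
  as distinct statuses rather than collapsed; their interplay is reported,
  not proceduralized, in the method's source description.
* Genome-assembly liftover, GC correction, segmentation-based copy-number
  calling, long-read processing, and expression/survival analyses are out
  of scope.
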