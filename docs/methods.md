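# Methods

This note records the models behind `ampliscreen`, the defaults and why
they were chosen, what the synthetic universe does and does not emulate,
and the numerical conventions a maintainer needs.

## Scope and deliberate substitutions

The pipeline reproduces a targeted carrier screen at desk scale. Two
industrial components are deliberately replaced by transparent equivalents:

* **Read mapping.** Whole-genome alignment plus realignment/recalibration
  is replaced by *primer-anchored assignment*: a read pair belongs to the
  amplicon whose forward or reverse primer it begins with (≤ 1 mismatch;
  conflicting primer evidence → ambiguous, counted off-target). For
  amplicon sequencing this is exact, deterministic, and auditable.
* **Variant calling.** A general haplotype caller is replaced by a
  *haplotype vote*: each fragment is matched exactly against the ±15 bp
  reference and mutant context strings of every target its amplicon
  covers. Indels use the identical mechanism over the adjacent interval,
  which subsumes local realignment for panel-anchored positions. Fragments
  matching neither context count as `other` and still contribute to DP, so
  `ref + Σalt + other = DP` holds for every pileup.

Thermodynamic primer design (Tm, hairpins, primer–primer dimers) is not
modelled; the pool multiplexer implements only the published compatibility
constraints, with dimer scoring noted as an extension point.

## Coordinates and representation

Panel TSV and VCF are 1-based; BED and all internal interval arithmetic are
0-based half-open. Indels are left-anchored (VCF convention): an insertion
is `ref = anchor`, `alt = anchor + inserted`; a deletion is
`ref = anchor + deleted`, `alt = anchor`. A free-text `label` preserves
human-readable mutation names. Multi-allelic collapsing keys on
`(chrom, pos)` only — alleles that would co-locate only after indel
normalization are *not* merged.

## Junction references

For a deletion of `[b1, b2]` the chimeric sequence is the `flank_len`
reference bases ending at `b1−1` joined to those starting at `b2+1`; for an
insertion at `b`, left flank + insert + right flank. Defaults
`flank_len = 60`, `min_anchor = 20`: a 150 bp read spanning the junction
always carries both 20 bp anchors of the 40-mer core, and the core's
absence from the reference (both strands) is verified at build time. For
large insertions the core straddles the *left* breakpoint, because the full
insert cannot fit in one read. Junction detection is exact substring
matching of the core k-mer; the default carrier threshold is 10 supporting
fragments, far below the ~250 a heterozygous carrier yields at mean assay
depth 500 (junction amplicons amplify only the mutant haplotype, so
non-carriers yield zero).

## Pool multiplexing

Hard conflicts (same-chromosome overlap, gap < 5,000 bp — strictly less;
5,000 exactly is compatible) form a graph; assignment is greedy first-fit
in (conflict degree desc, product length desc, id asc) order, re-checking
on every insertion: pool size ≤ 12, pools ≤ 48, every member length within
20 % of the *pool's* mean (the pool-level reading of the size rule; a
panel-level switch exists), and GC span ≤ 15 percentage points. The GC
bound quantifies an otherwise vague "high GC variability" exclusion and is
exposed in `PoolingParams`. Ties are broken lexically so plans are
byte-reproducible. The validator re-derives every constraint exhaustively
and is the oracle the tests and the greedy's soundness check share. On the
345-amplicon paper-scale fixture the greedy needs ~31–36 pools depending on
seed, comfortably inside the 48-inlet chip and the 45 sub-groups a
proprietary multiplexer achieved on the corresponding real design.

## The synthetic universe

`generate_reference` draws i.i.d. bases at GC 0.41 (human-like) over 4 ×
1.2 Mb chromosomes — large enough for realistic amplicon spacing, small
enough that exact-substring uniqueness checks are cheap. What i.i.d.
sequence does **not** emulate: repeats, homopolymer error hotspots, and
true pseudogene homology. Paralog interference is therefore modelled at the
*capture* level (below) rather than by sequence similarity, and indel
placement rejects the rare site whose mutant context also occurs elsewhere
in the reference.

The paper-scale fixture preset fixes the structure of the study: 370 small
mutations (two same-position allele pairs → 368 targets) in 148 genes; 345
standard amplicons of 64–200 bp — 46 covering two close targets, 24 targets
redundantly covered by two amplicons — plus one 418 bp outlier and 4
junction amplicons; 48 samples. Intra-gene target spacing (0.6–2.5 kb)
deliberately creates proximity conflicts for the multiplexer. Variant bases
never fall inside primer landing sites (a primer carries reference
sequence, so a variant under a primer would be invisible — a real design
rule), and context windows are kept within a single read even for the
outlier product.

**Depth.** Fragment count per (amplicon, sample) is NegBin(mean 500,
shape 8): heavy-tailed like real per-assay depths, with essentially zero
mass below 50 at full efficiency. DP is counted in fragments (read pairs).
The real experiment's ~2500× mean is not reproduced; 500× preserves every
threshold regime at a fraction of the cost. Eight "weak" amplicons at 5 %
efficiency emulate the consistently low-covered targets real primer sets
show, putting the share of conclusive assays near 98 %.

**Reads.** 150 bp paired ends from each product's two extremities, uniform
haplotype choice per fragment (het targets ⇒ Binomial(n, ½) mutant
fragments), i.i.d. substitution errors at 10⁻³ per base (no indel errors,
no per-cycle quality profile — qualities are constant Q40), and 5 % of
fragments drawn from random genome positions as off-target. Read names
encode the ground-truth amplicon so callers can be scored against the
manifest alone.

**Paralog interference.** For designated loci, each fragment first chooses
with probability ½ between the locus and a co-captured paralog haplotype.
In `dilute` mode the paralog carries the reference base: a het carrier's
expected mutant fraction is 0.25, the regime where real pseudogene-shadowed
mutations fall below a 30 % het threshold. In `enrich` mode the paralog
carries the mutant base (expected het AF 0.75, and AF 0.5 in
non-carriers — the false-positive direction). The two modes bracket the two
published descriptions of such events, which are mutually inconsistent on
arithmetic; the default is `dilute`, the only model consistent with an
observed ~26 % carrier AF under even-ratio capture.

**Pilot planting.** 50 known heterozygotes over 40 of the 45 clean samples
(two on paralog loci), 15 unexpected singletons, four recurrent variants in
7/8/11/23 samples (2 and 6 of them homozygous), five rearrangement carriers
over three of the four junctions (one junction deliberately carrier-free),
and three engineered QC failures: two starved samples (0.4 % and 0.05 % of
normal yield) and one sample with 44 amplicons killed. Plantings sit on
mutually distinct amplicons away from weak or killed ones, so every planted
call is decided by the caller, not by coverage luck. Technical replicates
(same genotypes, independent noise) are supported and tested, but are not
part of the 48-sample pilot so that the sample accounting stays
370 × 48 / 370 × 45.

## Calling thresholds

`min_dp = 50` and the 30–70 % het band follow the screening criteria this
implements; all three bounds are inclusive ("at least", and symmetric
treatment of the band edges). No homozygote criterion is published for this
assay, so `hom_af_min = 0.85` (configurable) keeps a deliberate gap above
the het band; AF in (0.70, 0.85) is reported as REF + `AF_BAND_GAP` and
AF in [0.15, 0.30) as REF + `LOW_AF_SUSPECT` — information is flagged,
never silently dropped. Votes are unweighted exact matches; at the
simulator's error rate a base-quality model would change nothing, and
determinism is worth more here. Calls outside the expected-known list are
flagged `VALIDATION_REQUIRED`, modelling orthogonal (Sanger) confirmation
as a flag rather than chemistry. All samples are treated as diploid;
X-linkage is metadata only.

## QC conventions

The assay-count headline uses mutations × samples (370 × 48 = 17,760;
370 × 45 = 16,650 after exclusions) while the matrix has one row per
collapsed position (368 × 48 = 17,664); the two conventions disagree in
the source material, so both are always reported with explicit labels.
Sample exclusion compares each sample's reads to the *median of the
others* (robust stand-in for "less than 1 % of each other sample") with
`low_read_fraction = 0.01`, and `max_low_targets = 40` sub-10× targets
(the engineered failure has 44); LOW_READS takes precedence when both
fire, and exclusion is idempotent. The recurrent-variant flag threshold is
a 10 % cohort fraction — mirroring the population-frequency evidence that
marks a "pathogenic" panel entry as a common polymorphism — or
homozygosity in ≥ 2 samples. Specificity is reported as the on-target
read-pair fraction, the only definition the assay supports.

## Problem sizes and determinism

Default verification sizes: the full pilot (48 samples × ~350 amplicons ×
500 fragments ≈ 8.5 M read pairs) simulates and genotypes in ~3 minutes on
one CPU; unit tests use a tiny structural preset and a hand-built
two-amplicon micro-universe. Every random draw descends from one seed via
spawned generator streams (per-sample streams make outputs independent of
sample iteration order), gzip members carry a fixed mtime, and a repeated
run is byte-identical down to the FASTQs and VCF. Degenerate inputs are
defined behaviour: empty panels load with a warning, an empty FASTQ yields
all-NO_CALL, an uncovered target yields a structured zero-depth pileup,
and an infeasible pooling instance raises with the unplaceable amplicons
named.

## Known limitations

i.i.d. reference sequence (no repeats/homology); substitution-only error
model; no barcode demultiplexing (the simulator emits per-sample FASTQs);
no primer thermodynamics; junction calls are reported in TSV/JSON but not
as symbolic VCF records; passing on synthetic data demonstrates the
pipeline's logic and accounting, not performance on real capture chemistry.
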