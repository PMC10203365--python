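# Methods

## Coordinate conventions

All internal coordinates are 0-based half-open; GFF3, VCF and depth tables
(1-based) are converted at the I/O boundary, BED needs none. Interval size
is `end − start` — for the region tables consumed here this matches the
printed sizes (e.g. chr22:49,411,085–51,244,066 → 1,832,981 bp → 1.83 Mb).
Percentages and Kb/Mb sizes are rounded half-up to two decimals (169.169 →
169.17), because the reference tables round rather than truncate.
Chromosome names are compared after stripping an optional `chr` prefix, so
bare-name and prefixed tables join.

## Panel design

*Representative transcript.* One transcript represents each gene. With no
usage-frequency source available, "most common or longest" is resolved to
the largest summed CDS length, ties broken by lexicographically smallest
transcript ID, which makes the choice independent of input order.

*Gene capture.* Every CDS of the representative transcript is widened by
`flank_bp` (default 10 bp, clamped at position 0 only — chromosome lengths
are not an input) to catch splice-site variation; overlapping or
book-ended widened spans are merged. UTRs are never captured.

*Region marker tiles.* Non-major genes inside a chromosomal-abnormality
region get at most one random tile of `tile_bp` (default 100 bp) on a CDS.
Gene density decides how many: all genes when the region holds ≤ 15, the
first two of every consecutive group of three (genes sorted by CDS start,
a partial final group contributes up to its first two) when 16–39, and
every other gene — even 0-based indices, so the first gene is always kept
— when ≥ 40. The closed forms are n, ⌈2n/3⌉ and ⌈n/2⌉. The tile's CDS is
chosen with probability proportional to CDS length, the offset uniformly
among valid starts; a CDS shorter than the tile is captured whole. Gene
ordering and selection are deterministic; only tile placement consumes
randomness, so changing the seed never changes tile counts or which genes
are tiled. Which genes are "major" (captured in full) is an explicit
input, not guessed.

*Panel statistics* report the merged interval union; the genome fraction
uses a configurable genome length (default 3 Gb).

## Coverage QC

"Coverage" of a CDS is the percent of bases in the CDS ± flank (the same
span the panel captures) at depth ≥ `cover_threshold`; the threshold is a
knob with default 1 because no canonical value exists. Depth bins on the
mean deduplicated depth are half-open with 30 and 100 in the upper bin:
[0, 30), [30, 100), [100, ∞). Duplicate removal itself is upstream of this
package; depth tables are assumed deduplicated. A `meets_recommended_depth`
helper encodes the operational floor of a 100× mean. The zero-coverage
report counts CDSs at exactly 0% coverage and the whole-percent share with
translation ordinal 1, the signature of GC-driven 5′ capture dropout.

## Replicate stability and concordance

Stability = 100 · (sites with identical genotypes in all three technical
replicates) / (sites covered and genotyped in all three). Sites absent,
uncovered or missing (./.) in *any* replicate leave the denominator
entirely rather than counting as discordant — the conservative reading
that also explains why totals run slightly below the capture-region size.
Genotypes compare as unordered allele multisets (phasing ignored); alleles
are compared as literal strings, assuming upstream left-alignment. A
missing genotype equals nothing, including another missing genotype. Array
concordance applies the same equality at loci genotyped on both platforms
and is undefined (an error) with no shared loci.

## Depth-ratio CNV detection

For each target (panel interval) and sample, the mean per-base depth is
computed; a sample's library size factor is its median target depth. To
keep everything on the read scale while making a sample's own ratios
exactly invariant to rescaling its library, depths are first made unitless
per sample, then both the sample and its reference are rescaled by the
median library size of the *other* batch samples. The reference per target
is the leave-one-out median across the batch, which keeps a sample's own
event from polluting its reference. Ratio = log2 with a 0.5-read
pseudocount on both sides; targets with zero depth in every sample are
pinned at log2 = 0 and flagged rather than left undefined.

Segmentation is a deliberately simple threshold-and-merge: consecutive
same-chromosome targets at log2 ≤ −0.4 (deletion) or ≥ +0.32 (duplication)
form one call; runs shorter than `min_targets` (default 3) are suppressed
as single-target noise. The thresholds are generous heterozygous
single-copy expectations (−1 and +0.58 in the noiseless limit); no
circular binary segmentation, GC correction or B-allele information is
used — this caller is a declared replacement for heavier CNV machinery,
not an emulation of it.

Downsampling replaces each per-base depth with a Binomial(depth, fraction)
draw — expectation-equivalent to re-extracting that fraction of reads,
without needing reads. Benchmarking uses reciprocal overlap
(|intersection| / longer interval, match at ≥ 0.5, the common CNV
convention) and signed breakpoint deltas (truth − called).

The sensitivity curve plants one heterozygous deletion per replicate in a
target geometry emulating exonic capture (150 bp targets every 60 kb over
a 20 Mb segment, four batch samples, 300× mean depth — the middle of the
post-deduplication range the panel operates at), thins to each depth
fraction, and reports recall per (size, fraction) cell. With 3-target
minimum support and 60 kb spacing the detection floor sits near 200 kb:
events of ~100 kb overlap at most two targets and are structurally
undetectable at any depth.

## Variant triage

Rule order and semantics: R1 retains known high-frequency pathogenic
variants and skips the frequency and evidence screens (they are already
established calls) but *not* the phenotype/inheritance gate. R2 requires
population frequency < 1% (configurable); an unknown frequency passes —
absence of evidence. R3–R5 (database pathogenicity, clarified deleterious
mechanism, ≥ 2 of 3 damaging prediction votes) combine as OR by default
because the source criteria list them as successive screens without
stating conjunction; a strict AND mode is available. Raw prediction scores
are never recomputed — flags arrive pre-annotated. R6 requires a phenotype
match and a genotype sufficient for the gene's inheritance model: AD any
het/hom; AR a hom or ≥ 2 distinct surviving hets in the gene (phase
unknown, so compound heterozygosity is claimed from two distinct
surviving hets only); XL hemi/hom, with an XL het retained but flagged as
a carrier finding. Every record ends in exactly one of kept/dropped with
an ordered rule trace.

ΔΔG significance uses a strict cutoff: significant ⇔ ΔΔG > 1.6 kcal/mol;
missing or non-finite values are unknown, never significant.

## Synthetic data

Generators are pure functions of (spec, seed). Depth is negative binomial
(dispersion default 10) rather than Poisson to mimic capture
overdispersion; the default mean (300×) sits in the 157–380×
post-deduplication range the panel targets. CNV carriers scale the local
mean by copy/2. First-exon dropout zeroes a CDS1 target in *all* samples
(capture failure is a property of the region, not the library). Replicate
tables perturb exactly ⌊εn⌋ sites in exactly one replicate each (default
ε = 0.0022, the observed technical discordance scale), so recovered
stability is exactly 100·(1 − ⌊εn⌋/n). Triage tables plant records that
satisfy the whole cascade and decoys that each fail one named rule; truth
tables are first-class outputs so tests never re-derive ground truth from
the generated files.

What the generators do *not* emulate: read-level errors, GC tracks,
mappability, correlated probe-level noise, segmental duplications. Passing
parameter-recovery tests therefore demonstrates the correctness of the
statistics and the pipeline plumbing, not the field performance of the
laboratory assay.

## Problem sizes

The test suite and evaluation script run at desk scale by design: the
stability arithmetic uses the published site counts directly; constructed
experiments use 10³–10⁴ sites, tens of genes, and 20-replicate sensitivity
grids over a ~330-target emulated panel. These sizes give exact
(constructive) or low-variance (5σ) checks while keeping the whole suite
in seconds.

## Known limitations

* The bundled 148-region table is a best-effort transcription; a few
  Start/End boundaries are approximate where the source formatting was
  ambiguous, and the source never states whether they are 0- or 1-based —
  they are stored verbatim and sized by subtraction.
* The CNV caller's breakpoint resolution is one target spacing; published
  benchmark breakpoints are comparison fixtures, not reproduction targets.
* Multi-allelic genotype comparison assumes upstream normalization.
* The GFF3 reader supports the gene/mRNA/CDS subset only (no CDS phase
  use, no multi-parent CDS sharing beyond the first parent); BAM/CRAM are
  out of scope — per-base depth tables are the ingestion boundary.
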