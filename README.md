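# panelsmith

Design and evaluate clinical targeted-capture sequencing panels that screen
monogenic disease genes and recurrent chromosomal abnormalities in one assay.

Diagnostic laboratories increasingly replace whole-exome sequencing with a
custom capture chip: the coding regions of a few thousand disease genes plus
sparse "marker" probes across recurrent microdeletion/microduplication
regions. `panelsmith` implements the full design-and-validation loop for such
a panel:

* **Panel design** — pick one representative transcript per gene (largest
  total CDS), capture every CDS ± 10 bp of flank (UTRs excluded), and mark
  each chromosomal-abnormality region with short random CDS tiles whose
  density depends on the region's gene count (every gene when ≤ 15 genes,
  two of every three genes when 16–39, every other gene when ≥ 40). Major
  pathogenic genes of a region are captured in full. A bundled table of 148
  recurrent chromosomal-abnormality regions ships with the package.
* **Coverage QC** — per-CDS mean depth and percent of bases covered, binned
  at [0, 30), [30, 100) and [100, ∞) reads, plus an accounting of
  zero-coverage CDSs and how many are first coding exons (CDS1, which drop
  out preferentially because of GC-rich 5′ gene ends).
* **Replicate stability and array concordance** — for three technical
  replicates, stability = fraction of jointly covered sites whose unordered
  genotypes agree in all three; for an orthogonal SNP array, concordance at
  shared genotyped loci.
* **Depth-ratio CNV detection** — per-target log2 copy ratios against a
  leave-one-out in-batch median reference
  (`log2((d_i/s_i + 0.5) / (median_{j≠i} d_j/s_j + 0.5))`, all on the read
  scale), threshold-and-merge segmentation, binomial downsampling to emulate
  lower sequencing throughput, and truth-set benchmarking by reciprocal
  overlap and breakpoint deltas.
* **Variant triage** — a six-rule Mendelian cascade: known pathogenic (R1,
  overrides the frequency gate), population frequency < 1% (R2), evidence
  screen (database / mechanism / prediction votes, R3–R5), and
  phenotype-plus-inheritance fit including compound-heterozygote logic (R6).
  A predicted protein-stability change is "significant" when
  ΔΔG > 1.6 kcal/mol.
* **Synthetic data** — seeded generators for every input (gene models,
  depth profiles with planted CNVs, replicate site tables with a known
  discordance rate, triage tables with planted pathogenic records), each
  returning its ground truth for parameter-recovery testing.

## Worked example

```python
>>> import panelsmith as ps
>>> ps.stability(9_881_645, 9_903_792)   # all-three-identical / total sites
99.78
>>> ps.region_size(ps.GenomicInterval("chr7", 69_783_279, 69_952_448), "Kb")
169.17
```

The first number is a replicate-stability percentage: of 9,903,792 sites
emitted in all three technical replicates of one sample, 9,881,645 had
identical genotypes (99.78%). The second is the size convention used for CNV
reporting: end − start, scaled and rounded half-up to two decimals.

A miniature end-to-end CNV run on simulated data:

```python
>>> from panelsmith.synth_data import SimSpec, simulate_gene_models, simulate_depth_profiles
>>> from panelsmith.panel_design import merged_track
>>> from panelsmith.cnv_depth import target_depth_matrix, normalize_target_depths, call_depth_cnv
>>> gff, models = simulate_gene_models(SimSpec(seed=42, n_genes=12))
>>> by_gene = {}
>>> for m in models: by_gene.setdefault(m.gene_id, []).append(m)
>>> reps = [ps.select_representative_transcript(c) for c in by_gene.values()]
>>> panel = merged_track(t for r in reps for t in ps.design_gene_capture(r))
>>> spec = SimSpec(seed=42, mean_depth=300, cnv_events=[(panel[3], 1)])
>>> profiles, truth = simulate_depth_profiles(panel, spec, n_samples=4)
>>> ratios, _ = normalize_target_depths(target_depth_matrix(profiles, panel))
>>> call_depth_cnv(panel, ratios.iloc[0].to_numpy(), min_targets=1)[0]
CnvCall(interval=GenomicInterval(chrom='chr1', start=2161, end=2360,
        label='del:1targets'), kind='del', mean_log2=-0.97..., n_targets=1)
```

The single-copy deletion planted on target 3 of the carrier sample comes
back as a `del` call at log2 ≈ −1, the expected ratio for one copy against
a diploid batch reference.

Every command is also exposed on the CLI: `panelsmith design`,
`panelsmith qc-coverage`, `panelsmith concordance`, `panelsmith cnv
{call,downsample,compare}`, `panelsmith triage`, `panelsmith simulate`,
`panelsmith abnormalities`. See `panelsmith --help`.

## Layout

```
src/panelsmith/
  genomic_io.py     formats + coordinate conventions (GFF3, BED, VCF, TSV)
  panel_design.py   capture-region rules and panel statistics
  coverage_qc.py    per-CDS depth/coverage bins, zero-coverage report
  concordance.py    replicate stability, array concordance
  cnv_depth.py      log2-ratio CNV calling, downsampling, benchmarking
  variant_triage.py six-rule cascade, ddG significance, summaries
  synth_data.py     seeded generators with ground truth
  cli.py            command-line surface
  data/table2_regions.tsv  bundled 148-region abnormality table
```

See `docs/methods.md` for the statistical model, parameter defaults and
known limitations.
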