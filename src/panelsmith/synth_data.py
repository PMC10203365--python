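"""Seeded generators for every input the toolkit consumes.

Each generator is a pure function of its spec and seed (same inputs, same
bytes) and emits both ready-to-parse text artifacts and the ground truth
used by parameter-recovery tests. The defaults emulate the conditions a
clinical capture panel sees: a few hundred x deduplicated depth with
capture-style overdispersion (negative binomial), diploid baseline with
planted single-copy events, ~0.2% technical-replicate genotype
discordance, and 5'-biased capture dropout of first coding exons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from panelsmith.genomic_io import (
    DepthProfile,
    GenomicInterval,
    SiteGenotype,
    TranscriptModel,
    read_gene_models,
)


@dataclass
class SimSpec:
    seed: int = 0
    n_genes: int = 30
    cds_per_gene: tuple[int, int] = (2, 6)       # inclusive range
    cds_len: tuple[int, int] = (80, 300)         # bp, inclusive range
    mean_depth: float = 300.0                    # reads, post-dedup scale
    depth_dispersion: float = 10.0               # negative-binomial size
    cnv_events: list[tuple[GenomicInterval, int]] = field(default_factory=list)
    replicate_discordance: float = 0.0022        # epsilon
    fivep_dropout_prob: float = 0.0              # P(CDS1 has zero capture)
    planted_pathogenic: int = 5
    n_variant_rows: int = 100

    def __post_init__(self):
        for p in (self.replicate_discordance, self.fivep_dropout_prob):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

def simulate_gene_models(
    spec: SimSpec, chrom: str = "chr1", chrom_length: int = 5_000_000,
    intergenic_gap: int = 2_000, cds_gap: int = 50,
) -> tuple[str, list[TranscriptModel]]:
    """Non-overlapping genes with 1-3 transcripts each, as GFF3 + models.

    Transcript counts >1 exercise representative-transcript selection.
    Returns (gff3_text, models) where the models are obtained by parsing
    the emitted text, so the two can never disagree.
    """
    rng = np.random.default_rng(spec.seed)
    lines = ["##gff-version 3"]
    cursor = 1_000
    lo_n, hi_n = spec.cds_per_gene
    lo_l, hi_l = spec.cds_len
    for g in range(1, spec.n_genes + 1):
        gid = f"G{g:03d}"
        strand = "+" if rng.random() < 0.5 else "-"
        n_tx = int(rng.integers(1, 4))
        tx_blocks = []
        gene_end = cursor
        for t in range(1, n_tx + 1):
            n_cds = int(rng.integers(lo_n, hi_n + 1))
            pos = cursor
            cds = []
            for _ in range(n_cds):
                length = int(rng.integers(lo_l, hi_l + 1))
                cds.append((pos, pos + length))  # 0-based half-open
                pos += length + cds_gap + int(rng.integers(0, 200))
            tx_blocks.append(cds)
            gene_end = max(gene_end, cds[-1][1])
        if gene_end + intergenic_gap > chrom_length:
            raise ValueError(
                f"cannot pack {spec.n_genes} genes into {chrom_length} bp"
            )
        lines.append("\t".join([
            chrom, "panelsmith_sim", "gene", str(cursor + 1), str(gene_end),
            ".", strand, ".", f"ID={gid}",
        ]))
        for t, cds in enumerate(tx_blocks, 1):
            tid = f"{gid}.T{t}"
            lines.append("\t".join([
                chrom, "panelsmith_sim", "mRNA", str(cds[0][0] + 1),
                str(cds[-1][1]), ".", strand, ".",
                f"ID={tid};Parent={gid}",
            ]))
            for k, (s, e) in enumerate(cds, 1):
                lines.append("\t".join([
                    chrom, "panelsmith_sim", "CDS", str(s + 1), str(e),
                    ".", strand, "0", f"ID={tid}.c{k};Parent={tid}",
                ]))
        cursor = gene_end + intergenic_gap
    text = "\n".join(lines) + "\n"
    return text, read_gene_models(text)


# ---------------------------------------------------------------------------
# depth profiles
# ---------------------------------------------------------------------------

def simulate_depth_profiles(
    panel: Sequence[GenomicInterval],
    spec: SimSpec,
    n_samples: int = 4,
    carrier: int = 0,
) -> tuple[list[DepthProfile], list[tuple[str, GenomicInterval, int]]]:
    """Per-base negative-binomial depths over panel targets, with truth.

    Sample ``carrier`` holds every event in ``spec.cnv_events`` (copy
    number scales the local mean as copy/2); everyone else is diploid.
    Targets whose label marks a first coding exon (``CDS1``) are zeroed in
    every sample with probability ``fivep_dropout_prob``, emulating
    GC-driven capture failure at the 5' end of genes. Returns (profiles,
    truth) with truth rows (sample_id, interval, copy_number).
    """
    if not panel:
        raise ValueError("panel must be non-empty")
    rng = np.random.default_rng(spec.seed)
    size = spec.depth_dispersion
    def is_first_cds(iv: GenomicInterval) -> bool:
        return any(part.split(".")[-1] == "CDS1"
                   for part in iv.label.split(","))

    dropout = [
        spec.fivep_dropout_prob > 0 and is_first_cds(iv)
        and rng.random() < spec.fivep_dropout_prob
        for iv in panel
    ]
    profiles = []
    truth: list[tuple[str, GenomicInterval, int]] = []
    for i in range(n_samples):
        sid = f"S{i + 1:02d}"
        depths: dict[tuple[str, int], int] = {}
        for iv, drop in zip(panel, dropout):
            n = len(iv)
            if drop:
                vals = np.zeros(n, dtype=np.int64)
            else:
                copies = np.full(n, 2.0)
                if i == carrier:
                    for ev, cn in spec.cnv_events:
                        if ev.overlaps(iv):
                            lo = max(iv.start, ev.start) - iv.start
                            hi = min(iv.end, ev.end) - iv.start
                            copies[lo:hi] = cn
                mu = spec.mean_depth * copies / 2.0
                vals = rng.negative_binomial(size, size / (size + mu))
            chrom = iv.chrom[3:] if iv.chrom.startswith("chr") else iv.chrom
            for off, d in enumerate(vals):
                depths[(chrom, iv.start + off)] = int(d)
        profiles.append(DepthProfile(sample_id=sid, depths=depths))
        if i == carrier:
            truth.extend((sid, ev, cn) for ev, cn in spec.cnv_events)
    return profiles, truth


# ---------------------------------------------------------------------------
# replicate site tables
# ---------------------------------------------------------------------------

_GENOTYPES = (("A", "A"), ("A", "G"), ("G", "G"))
_VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    "##contig=<ID={chrom},length={length}>\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n"
)


@dataclass
class SimulatedReplicates:
    sites: tuple[list[SiteGenotype], ...]   # three replicates
    vcf_texts: tuple[str, str, str]
    perturbed_positions: list[int]          # 1-based, exactly floor(eps*n)

    @property
    def n_perturbed(self) -> int:
        return len(self.perturbed_positions)


def simulate_replicate_sites(
    n_sites: int, eps: float, seed: int = 0, chrom: str = "chr1",
) -> SimulatedReplicates:
    """Three technical-replicate site tables with a known discordance rate.

    Exactly ``floor(eps * n_sites)`` distinct sites receive a perturbed
    genotype in exactly one randomly chosen replicate; every site is
    covered in all replicates, so the recovered stability is exactly
    ``100 * (1 - floor(eps*n)/n)`` percent.
    """
    if not 0 <= eps <= 1:
        raise ValueError("eps must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    base = rng.integers(0, 3, size=n_sites)
    n_pert = int(np.floor(eps * n_sites))
    perturbed = np.sort(rng.choice(n_sites, size=n_pert, replace=False))
    which_rep = rng.integers(0, 3, size=n_pert)
    reps: list[list[SiteGenotype]] = [[], [], []]
    pert_map = dict(zip(perturbed.tolist(), which_rep.tolist()))
    for i in range(n_sites):
        pos = i + 1
        for r in range(3):
            gi = int(base[i])
            if pert_map.get(i) == r:
                gi = (gi + 1) % 3  # any different genotype
            reps[r].append(SiteGenotype(
                chrom=chrom, pos=pos,
                genotype=tuple(sorted(_GENOTYPES[gi])), covered=True,
            ))
    texts = tuple(_sites_to_vcf(r, chrom, n_sites, f"rep{k+1}")
                  for k, r in enumerate(reps))
    return SimulatedReplicates(
        sites=tuple(reps),
        vcf_texts=texts,  # type: ignore[arg-type]
        perturbed_positions=[int(p) + 1 for p in perturbed],
    )


def _sites_to_vcf(sites, chrom, length, sample):
    rows = [_VCF_HEADER.format(chrom=chrom, length=max(length, 1),
                               sample=sample)]
    for s in sites:
        if s.genotype is None:
            gt = "./."
            ref, alt = "A", "G"
        else:
            alleles = ["A", "G"]
            idx = [alleles.index(a) for a in s.genotype]
            gt = "/".join(str(i) for i in sorted(idx))
            ref, alt = "A", "G"
        rows.append(f"{s.chrom}\t{s.pos}\t.\t{ref}\t{alt}\t.\t.\t.\tGT\t{gt}\n")
    return "".join(rows)


# ---------------------------------------------------------------------------
# variant tables
# ---------------------------------------------------------------------------

@dataclass
class SimulatedVariants:
    records: list  # VariantRecord
    tsv: str
    inheritance_map: dict[str, str]
    planted_ids: list[str]
    decoy_rules: dict[str, str]  # variant_id -> rule it fails


def simulate_variant_table(spec: SimSpec) -> SimulatedVariants:
    """A triage input table with known planted pathogenic records.

    Planted records satisfy the whole cascade under the emitted
    inheritance map; each decoy fails exactly one named rule (freq,
    prediction, phenotype, or ar-single-het), recorded in the truth.
    """
    from panelsmith.variant_triage import VariantRecord

    if spec.planted_pathogenic > spec.n_variant_rows:
        raise ValueError("planted_pathogenic exceeds n_variant_rows")
    rng = np.random.default_rng(spec.seed)
    records: list[VariantRecord] = []
    inheritance: dict[str, str] = {}
    planted_ids: list[str] = []
    decoy_rules: dict[str, str] = {}
    vtypes = ("missense", "frameshift", "splicing", "intragenic_cnv",
              "whole_gene_del")

    def common(i, gene):
        return dict(
            gene_id=gene,
            variant_id=f"v{i:04d}",
            vtype=vtypes[int(rng.integers(0, len(vtypes)))],
            pop_freq=float(rng.uniform(0, 0.005)),
            reported_before=bool(rng.random() < 0.5),
        )

    i = 0
    for _ in range(spec.planted_pathogenic):
        i += 1
        gene = f"PG{i:03d}"
        inheritance[gene] = "AD"
        rec = VariantRecord(
            **common(i, gene),
            known_pathogenic_hf=bool(rng.random() < 0.3),
            db_pathogenic=True,
            prediction_damaging_votes=3,
            zygosity="het",
            phenotype_match=True,
        )
        records.append(rec)
        planted_ids.append(rec.variant_id)

    kinds = ("freq", "prediction", "phenotype", "ar-single-het")
    while len(records) < spec.n_variant_rows:
        i += 1
        kind = kinds[(i - 1) % len(kinds)]
        gene = f"DG{i:03d}"
        base = common(i, gene)
        if kind == "freq":
            inheritance[gene] = "AD"
            base.update(pop_freq=float(rng.uniform(0.02, 0.3)))
            rec = VariantRecord(**base, db_pathogenic=True,
                                prediction_damaging_votes=3,
                                zygosity="het", phenotype_match=True)
        elif kind == "prediction":
            inheritance[gene] = "AD"
            rec = VariantRecord(**base, db_pathogenic=False,
                                mechanism_deleterious=False,
                                prediction_damaging_votes=int(rng.integers(0, 2)),
                                zygosity="het", phenotype_match=True)
        elif kind == "phenotype":
            inheritance[gene] = "AD"
            rec = VariantRecord(**base, db_pathogenic=True,
                                prediction_damaging_votes=3,
                                zygosity="het", phenotype_match=False)
        else:  # ar-single-het: one passing het in an AR gene
            inheritance[gene] = "AR"
            rec = VariantRecord(**base, db_pathogenic=True,
                                prediction_damaging_votes=3,
                                zygosity="het", phenotype_match=True)
        records.append(rec)
        decoy_rules[rec.variant_id] = kind

    header = ["gene_id", "variant_id", "vtype", "pop_freq",
              "known_pathogenic_hf", "db_pathogenic", "mechanism_deleterious",
              "prediction_damaging_votes", "zygosity", "phenotype_match",
              "reported_before"]
    rows = ["\t".join(header)]
    for r in records:
        rows.append("\t".join([
            r.gene_id, r.variant_id, r.vtype, f"{r.pop_freq:.6f}",
            str(int(r.known_pathogenic_hf)), str(int(r.db_pathogenic)),
            str(int(r.mechanism_deleterious)),
            str(r.prediction_damaging_votes), r.zygosity,
            str(int(r.phenotype_match)), str(int(r.reported_before)),
        ]))
    return SimulatedVariants(
        records=records,
        tsv="\n".join(rows) + "\n",
        inheritance_map=inheritance,
        planted_ids=planted_ids,
        decoy_rules=decoy_rules,
    )
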