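"""Capture-region design for a combined monogenic + chromosomal panel.

Two kinds of content go on the chip:

* **gene capture** — for every panel gene, all CDS of one representative
  transcript, each extended by a small flank to catch splice-site variants
  (UTRs are never captured);
* **region marker tiles** — inside each recurrent-abnormality region, short
  (<=100 bp) randomly placed CDS tiles that mark gene presence without
  paying for full capture. How many genes get a tile depends on how
  gene-dense the region is: every gene up to 15 genes, two of every three
  genes between 16 and 39, and every other gene from 40 up. Major
  pathogenic genes of a region are always captured in full.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from panelsmith.genomic_io import (
    AbnormalityRegion,
    GenomicInterval,
    TranscriptModel,
)
from panelsmith._util import normalize_chrom


@dataclass
class PanelDesignConfig:
    flank_bp: int = 10
    tile_bp: int = 100
    small_region_max_genes: int = 15   # inclusive upper bound for rule (i)
    medium_region_max_genes: int = 40  # exclusive upper bound for rule (ii)
    genome_length: int = 3_000_000_000
    seed: int = 0

    def __post_init__(self):
        if self.flank_bp < 0:
            raise ValueError("flank_bp must be >= 0")
        if self.tile_bp < 1:
            raise ValueError("tile_bp must be >= 1")
        if not 0 < self.small_region_max_genes < self.medium_region_max_genes:
            raise ValueError(
                "need 0 < small_region_max_genes < medium_region_max_genes"
            )


@dataclass(frozen=True)
class CaptureTarget:
    """One designed interval with its provenance."""

    interval: GenomicInterval
    provenance: str  # gene_cds | cnv_full_gene | cnv_tile
    gene_id: str

    def __post_init__(self):
        if self.provenance not in ("gene_cds", "cnv_full_gene", "cnv_tile"):
            raise ValueError(f"unknown provenance {self.provenance!r}")


@dataclass
class PanelStats:
    n_targets: int
    total_bp: int
    genome_fraction_pct: float
    per_provenance_bp: dict[str, int] = field(default_factory=dict)


def select_representative_transcript(
    candidates: Sequence[TranscriptModel],
) -> TranscriptModel:
    """Pick the transcript with the largest total CDS length.

    Ties break to the lexicographically smallest transcript_id, so the
    choice is independent of input order.
    """
    if not candidates:
        raise ValueError("no candidate transcripts")
    genes = {t.gene_id for t in candidates}
    if len(genes) > 1:
        raise ValueError(f"candidates span multiple genes: {sorted(genes)}")
    return min(candidates, key=lambda t: (-t.cds_length, t.transcript_id))


def merge_intervals(
    intervals: Iterable[GenomicInterval],
) -> list[GenomicInterval]:
    """Sort and merge overlapping or book-ended intervals per chromosome.

    The union of covered bases is preserved exactly; adjacent intervals
    (end == next start) coalesce. Labels of merged runs are joined with
    commas (de-duplicated, order of first appearance).
    """
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out: list[GenomicInterval] = []
    for chrom in sorted(by_chrom, key=lambda c: (normalize_chrom(c).zfill(2))):
        run: Optional[list] = None  # [start, end, labels]
        for iv in sorted(by_chrom[chrom], key=lambda v: (v.start, v.end)):
            if run is not None and iv.start <= run[1]:
                run[1] = max(run[1], iv.end)
                if iv.label and iv.label not in run[2]:
                    run[2].append(iv.label)
            else:
                if run is not None:
                    out.append(GenomicInterval(chrom, run[0], run[1],
                                               ",".join(run[2])))
                run = [iv.start, iv.end, [iv.label] if iv.label else []]
        if run is not None:
            out.append(GenomicInterval(chrom, run[0], run[1],
                                       ",".join(run[2])))
    return out


def design_gene_capture(
    transcript: TranscriptModel, cfg: PanelDesignConfig | None = None,
    provenance: str = "gene_cds",
) -> list[CaptureTarget]:
    """All CDS of a transcript, each widened by ``flank_bp`` and merged.

    A transcript with no CDS (UTR-only) yields nothing: UTRs are not
    captured. Flanks clamp at position 0.
    """
    cfg = cfg or PanelDesignConfig()
    spans = [
        GenomicInterval(
            transcript.chrom,
            max(0, c.start - cfg.flank_bp),
            c.end + cfg.flank_bp,
            f"{transcript.gene_id}.{transcript.transcript_id}.CDS{k}",
        )
        for c, k in zip(transcript.cds, transcript.cds_ordinals)
    ]
    return [
        CaptureTarget(iv, provenance, transcript.gene_id)
        for iv in merge_intervals(spans)
    ]


def _tile_rule_indices(n: int, small_max: int, medium_max: int) -> list[int]:
    """Which of n position-sorted genes receive a tile.

    n <= small_max: all; small_max < n < medium_max: the first two of each
    consecutive group of three; n >= medium_max: every other gene starting
    with the first.
    """
    if n <= small_max:
        return list(range(n))
    if n < medium_max:
        return [i for i in range(n) if i % 3 != 2]
    return list(range(0, n, 2))


def sample_region_tiles(
    region: AbnormalityRegion,
    genes_in_region: Sequence[TranscriptModel],
    cfg: PanelDesignConfig | None = None,
    rng: Optional[np.random.Generator] = None,
) -> list[CaptureTarget]:
    """Draw one marker tile per selected non-major gene of a region.

    Genes are sorted by the genomic start of their CDS span, the density
    rule picks which get tiles, and each tile is placed uniformly at random
    inside one CDS of its gene (CDS chosen with probability proportional to
    length). A CDS shorter than ``tile_bp`` is captured whole. Genes with
    no CDS are skipped.
    """
    cfg = cfg or PanelDesignConfig()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    genes = [t for t in genes_in_region if t.cds]
    genes.sort(key=lambda t: (t.cds[0].start, t.gene_id))
    chosen = _tile_rule_indices(
        len(genes), cfg.small_region_max_genes, cfg.medium_region_max_genes
    )
    tiles = []
    for i in chosen:
        tx = genes[i]
        lengths = np.array([len(c) for c in tx.cds], dtype=float)
        cds = tx.cds[int(rng.choice(len(tx.cds), p=lengths / lengths.sum()))]
        span = min(cfg.tile_bp, len(cds))
        offset = int(rng.integers(0, len(cds) - span + 1))
        iv = GenomicInterval(
            tx.chrom, cds.start + offset, cds.start + offset + span,
            f"{region.disease}|{tx.gene_id}.tile",
        )
        tiles.append(CaptureTarget(iv, "cnv_tile", tx.gene_id))
    return tiles


def expected_tile_count(n: int, cfg: PanelDesignConfig | None = None) -> int:
    """Closed-form tile count for n genes: n, ceil(2n/3), or ceil(n/2)."""
    cfg = cfg or PanelDesignConfig()
    if n <= cfg.small_region_max_genes:
        return n
    if n < cfg.medium_region_max_genes:
        return math.ceil(2 * n / 3)
    return math.ceil(n / 2)


def build_panel(
    gene_table: Mapping[str, Sequence[TranscriptModel]],
    regions: Sequence[AbnormalityRegion] = (),
    region_gene_index: Optional[Mapping[str, Mapping[str, bool]]] = None,
    cfg: PanelDesignConfig | None = None,
) -> list[CaptureTarget]:
    """Compose the full panel: per-gene capture, full major genes, tiles.

    ``gene_table`` maps gene_id to its candidate transcripts (panel genes).
    ``region_gene_index`` maps region disease name to {gene_id: is_major}
    for the genes lying inside that region; every referenced gene_id must
    appear in ``gene_table``. Tiles for all regions share one RNG seeded
    with ``cfg.seed``, so the whole design is reproducible.
    """
    cfg = cfg or PanelDesignConfig()
    region_gene_index = region_gene_index or {}
    reps = {
        gid: select_representative_transcript(cands)
        for gid, cands in gene_table.items()
    }
    targets: list[CaptureTarget] = []
    for gid in sorted(reps):
        targets.extend(design_gene_capture(reps[gid], cfg))
    rng = np.random.default_rng(cfg.seed)
    for region in regions:
        index = region_gene_index.get(region.disease, {})
        missing = [g for g in index if g not in reps]
        if missing:
            raise KeyError(
                f"region {region.disease!r} references unknown gene(s) "
                f"{sorted(missing)}"
            )
        majors = [g for g, is_major in index.items() if is_major]
        for gid in sorted(majors):
            targets.extend(
                design_gene_capture(reps[gid], cfg, provenance="cnv_full_gene")
            )
        non_major = [reps[g] for g, is_major in index.items() if not is_major]
        targets.extend(sample_region_tiles(region, non_major, cfg, rng))
    return targets


def merged_track(targets: Iterable[CaptureTarget]) -> list[GenomicInterval]:
    """The merged per-chromosome interval union of a target list."""
    return merge_intervals(t.interval for t in targets)


def summarize_panel(
    targets: Sequence[CaptureTarget], genome_length: Optional[int] = None,
) -> PanelStats:
    """Merged-union size and genome fraction of a designed panel."""
    if genome_length is None:
        genome_length = PanelDesignConfig().genome_length
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    merged = merged_track(targets)
    total = sum(len(iv) for iv in merged)
    pct = float(
        (Decimal(100 * total) / Decimal(genome_length))
        .quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)
    )
    per_prov: dict[str, int] = {}
    for t in targets:
        per_prov[t.provenance] = per_prov.get(t.provenance, 0) + len(t.interval)
    return PanelStats(
        n_targets=len(targets), total_bp=total, genome_fraction_pct=pct,
        per_provenance_bp=per_prov,
    )
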