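"""Readers and writers for every format the toolkit touches.

Internal convention is 0-based half-open coordinates everywhere; 1-based
inputs (GFF3, VCF, depth tables, the abnormality-region table) are
converted here, at the boundary, and BED output needs no conversion.
"""

from __future__ import annotations

import importlib.resources
import os
import tempfile
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional

import pysam
from gffutils.feature import feature_from_line

from panelsmith._util import as_text, normalize_chrom


class FormatError(ValueError):
    """Raised for malformed input files (bad coordinates, missing fields)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic span [start, end) with a free-text label."""

    chrom: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start <= self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            normalize_chrom(self.chrom) == normalize_chrom(other.chrom)
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class TranscriptModel:
    """A gene transcript as an ordered list of CDS intervals.

    ``cds`` is in genomic order; ``cds_ordinals[i]`` is the 1-based index of
    ``cds[i]`` in translation order (so ordinal 1 is the 5'-most CDS on the
    plus strand and the 3'-most on the minus strand).
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    cds: list[GenomicInterval] = field(default_factory=list)
    cds_ordinals: list[int] = field(default_factory=list)

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not self.cds_ordinals and self.cds:
            n = len(self.cds)
            self.cds_ordinals = (
                list(range(1, n + 1)) if self.strand == "+"
                else list(range(n, 0, -1))
            )
        if sorted(self.cds_ordinals) != list(range(1, len(self.cds) + 1)):
            raise ValueError("cds_ordinals must be a permutation of 1..n")
        for a, b in zip(self.cds, self.cds[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"CDS overlap or disorder in {self.transcript_id}"
                )

    @property
    def cds_length(self) -> int:
        """Total coding length in bp."""
        return sum(len(c) for c in self.cds)

    @property
    def span(self) -> GenomicInterval:
        """Genomic span from first CDS start to last CDS end."""
        if not self.cds:
            raise ValueError(f"{self.transcript_id} has no CDS")
        return GenomicInterval(
            self.chrom, self.cds[0].start, self.cds[-1].end, self.transcript_id
        )


@dataclass
class AbnormalityRegion:
    """One recurrent chromosomal abnormality: a disease name and its span."""

    disease: str
    region: GenomicInterval
    major_genes: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.region.end <= self.region.start:
            raise ValueError(f"empty region for {self.disease!r}")


@dataclass
class DepthProfile:
    """Per-base read depth for one sample over the panel's targets.

    Positions absent from ``depths`` are depth 0 by contract, so sparse
    storage over the capture region is lossless.
    """

    sample_id: str
    depths: dict[tuple[str, int], int] = field(default_factory=dict)
    source_reads: Optional[int] = None

    def depth_at(self, chrom: str, pos: int) -> int:
        return self.depths.get((normalize_chrom(chrom), pos), 0)

    def mean_depth(self, intervals: Iterable[GenomicInterval]) -> float:
        """Mean per-base depth over a set of intervals (absent bases = 0)."""
        total = n = 0
        for iv in intervals:
            c = normalize_chrom(iv.chrom)
            n += len(iv)
            total += sum(self.depths.get((c, p), 0) for p in range(iv.start, iv.end))
        return total / n if n else 0.0


@dataclass
class SiteGenotype:
    """One emitted site's unordered diploid genotype.

    ``genotype`` is a sorted tuple of allele strings, or None when the call
    is missing (./.). A missing genotype is never equal to anything,
    including another missing genotype.
    """

    chrom: str
    pos: int  # 1-based, as in VCF
    genotype: Optional[tuple[str, ...]]
    covered: bool = True

    def same_genotype(self, other: "SiteGenotype") -> bool:
        if self.genotype is None or other.genotype is None:
            return False
        return self.genotype == other.genotype


# ---------------------------------------------------------------------------
# gene models (GFF3 subset: gene / mRNA / CDS)
# ---------------------------------------------------------------------------

def read_gene_models(source) -> list[TranscriptModel]:
    """Parse a GFF3 stream (gene/mRNA/CDS features) into transcript models.

    1-based closed GFF coordinates become 0-based half-open. CDS rows are
    grouped under their first Parent; a CDS whose Parent is not a declared
    transcript raises :class:`FormatError` naming the offending line.
    """
    text = as_text(source)
    transcripts: dict[str, TranscriptModel] = {}
    tx_gene: dict[str, str] = {}
    cds_rows: list[tuple[str, GenomicInterval, str, int]] = []
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        try:
            feat = feature_from_line(line)
        except Exception as exc:
            raise FormatError(f"line {lineno}: unparseable GFF3 ({exc})")
        if feat.end < feat.start:
            raise FormatError(f"line {lineno}: end < start")
        ftype = feat.featuretype.lower()
        if ftype in ("mrna", "transcript"):
            tid = feat.attributes.get("ID", [None])[0]
            if tid is None:
                raise FormatError(f"line {lineno}: transcript without ID")
            gid = feat.attributes.get("Parent", [tid])[0]
            tx_gene[tid] = gid
            transcripts[tid] = TranscriptModel(
                gene_id=gid, transcript_id=tid,
                chrom=feat.seqid, strand=feat.strand, cds=[],
                cds_ordinals=[],
            )
        elif ftype == "cds":
            parent = feat.attributes.get("Parent", [None])[0]
            if parent is None:
                raise FormatError(f"line {lineno}: CDS without Parent")
            iv = GenomicInterval(feat.seqid, feat.start - 1, feat.end, "")
            cds_rows.append((parent, iv, feat.strand, lineno))
        # gene rows carry no information the mRNA rows do not repeat
    for parent, iv, strand, lineno in cds_rows:
        if parent not in transcripts:
            raise FormatError(
                f"line {lineno}: CDS Parent {parent!r} is not a known transcript"
            )
        transcripts[parent].cds.append(iv)
    out = []
    for tx in transcripts.values():
        tx.cds.sort(key=lambda iv: iv.start)
        n = len(tx.cds)
        tx.cds_ordinals = (
            list(range(1, n + 1)) if tx.strand == "+" else list(range(n, 0, -1))
        )
        # re-validate through the constructor invariants
        out.append(TranscriptModel(tx.gene_id, tx.transcript_id, tx.chrom,
                                   tx.strand, tx.cds, tx.cds_ordinals))
    return out


# ---------------------------------------------------------------------------
# abnormality-region table
# ---------------------------------------------------------------------------

def read_abnormality_table(source) -> list[AbnormalityRegion]:
    """Read a TSV with columns Disease, Chromosome, Start, End[, MajorGenes].

    Coordinates are stored verbatim (sizes are End - Start; see
    :func:`region_size`). Row order is preserved and duplicate disease names
    stay distinct records.
    """
    text = as_text(source)
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        return []
    header = lines[0].rstrip("\n").split("\t")
    required = ["Disease", "Chromosome", "Start", "End"]
    if header[: len(required)] != required:
        raise FormatError(
            f"expected columns {required}, got {header[:4]}"
        )
    has_majors = len(header) > 4 and header[4] == "MajorGenes"
    out = []
    for lineno, line in enumerate(lines[1:], 2):
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 4:
            raise FormatError(f"row {lineno}: expected >=4 columns")
        disease, chrom = fields[0], fields[1]
        try:
            start, end = int(fields[2]), int(fields[3])
        except ValueError:
            raise FormatError(f"row {lineno}: non-integer coordinate")
        if start >= end:
            raise FormatError(f"row {lineno}: Start >= End ({start} >= {end})")
        majors = []
        if has_majors and len(fields) > 4 and fields[4]:
            majors = [g for g in fields[4].split(",") if g]
        out.append(AbnormalityRegion(
            disease=disease,
            region=GenomicInterval(chrom, start, end, disease),
            major_genes=majors,
        ))
    return out


def bundled_abnormality_table() -> list[AbnormalityRegion]:
    """The packaged transcription of the 148 recurrent-abnormality regions."""
    ref = importlib.resources.files("panelsmith").joinpath(
        "data/table2_regions.tsv"
    )
    return read_abnormality_table(ref.read_text())


# ---------------------------------------------------------------------------
# depth tables (samtools-depth style)
# ---------------------------------------------------------------------------

def read_depth_table(source, sample_id: str = "sample",
                     source_reads: Optional[int] = None) -> DepthProfile:
    """Read a 3-column TSV (chrom, 1-based pos, depth) into a DepthProfile."""
    text = as_text(source)
    depths: dict[tuple[str, int], int] = {}
    for lineno, line in enumerate(text.splitlines(), 1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise FormatError(f"row {lineno}: expected 3 columns")
        try:
            pos, depth = int(fields[1]), int(fields[2])
        except ValueError:
            raise FormatError(f"row {lineno}: non-integer pos or depth")
        if depth < 0:
            raise FormatError(f"row {lineno}: negative depth {depth}")
        depths[(normalize_chrom(fields[0]), pos - 1)] = depth
    return DepthProfile(sample_id=sample_id, depths=depths,
                        source_reads=source_reads)


def write_depth_table(profile: DepthProfile) -> str:
    """Inverse of :func:`read_depth_table` (positions back to 1-based)."""
    rows = sorted(profile.depths.items())
    return "".join(f"{c}\t{p + 1}\t{d}\n" for (c, p), d in rows)


# ---------------------------------------------------------------------------
# site tables (minimal single-sample VCF)
# ---------------------------------------------------------------------------

def read_site_table(source) -> list[SiteGenotype]:
    """Read a minimal single-sample VCF into site genotypes.

    Phased and unphased separators are treated identically (genotypes are
    unordered allele pairs); ./. becomes a missing, uncovered site. A record
    without GT raises :class:`FormatError`.
    """
    text = as_text(source)
    if "\tGT" not in text and ":GT" not in text and "GT\t" not in text:
        # cheap pre-check: FORMAT column must mention GT somewhere
        raise FormatError("no GT field found in VCF FORMAT columns")
    with tempfile.NamedTemporaryFile("w", suffix=".vcf", delete=False) as fh:
        fh.write(text)
        path = fh.name
    try:
        out = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            save = pysam.set_verbosity(0)  # htslib chatter on minimal headers
            try:
                vf = pysam.VariantFile(path)
                for rec in vf:
                    if not rec.samples:
                        raise FormatError(f"{rec.chrom}:{rec.pos}: no sample column")
                    sample = rec.samples[0]
                    if "GT" not in sample:
                        raise FormatError(f"{rec.chrom}:{rec.pos}: missing GT")
                    gt = sample["GT"]
                    alleles = [rec.ref] + list(rec.alts or ())
                    if gt is None or any(a is None for a in gt):
                        out.append(SiteGenotype(rec.chrom, rec.pos, None,
                                                covered=False))
                    else:
                        called = tuple(sorted(alleles[i] for i in gt))
                        out.append(SiteGenotype(rec.chrom, rec.pos, called,
                                                covered=True))
            finally:
                pysam.set_verbosity(save)
        return out
    finally:
        os.unlink(path)


# ---------------------------------------------------------------------------
# BED3+1
# ---------------------------------------------------------------------------

def write_bed(intervals: Iterable[GenomicInterval]) -> str:
    """Serialize intervals as BED3+1 text (chrom, start, end, label)."""
    return "".join(
        f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label}\n" for iv in intervals
    )


def read_bed(source) -> list[GenomicInterval]:
    """Read BED3+1 text back into intervals (inverse of :func:`write_bed`)."""
    out = []
    for lineno, line in enumerate(as_text(source).splitlines(), 1):
        if not line.strip() or line.startswith(("track", "browser", "#")):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise FormatError(f"row {lineno}: expected >=3 BED columns")
        label = fields[3] if len(fields) > 3 else ""
        try:
            out.append(GenomicInterval(fields[0], int(fields[1]),
                                       int(fields[2]), label))
        except ValueError as exc:
            raise FormatError(f"row {lineno}: {exc}")
    return out


# ---------------------------------------------------------------------------
# sizes
# ---------------------------------------------------------------------------

def region_size(interval: GenomicInterval, unit: str = "bp") -> float | int:
    """Interval size as bp (exact), Kb or Mb (two decimals, half-up).

    Size is end - start: the number of integer positions in [start, end).
    """
    size = interval.end - interval.start
    if unit == "bp":
        return size
    if unit == "Kb":
        scaled = Decimal(size) / Decimal(1000)
    elif unit == "Mb":
        scaled = Decimal(size) / Decimal(1000000)
    else:
        raise ValueError(f"unit must be bp, Kb or Mb, got {unit!r}")
    return float(scaled.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))
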