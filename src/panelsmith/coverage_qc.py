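"""Per-CDS depth and coverage QC.

Each CDS (plus its capture flank) is scored with a mean deduplicated depth
and the percentage of bases at or above a coverage threshold, then binned
by mean depth into [0,30), [30,100) and [100,inf) reads. The bin summary
mirrors the usual panel-validation plot: what fraction of CDS regions sit
in each depth bin, and how well covered each bin is. Zero-coverage CDSs
are reported with the share attributable to first coding exons (CDS1),
which drop out preferentially because of the GC-rich 5' end of genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from panelsmith._util import normalize_chrom, round_half_up
from panelsmith.genomic_io import DepthProfile, TranscriptModel

BIN_EDGES = (30.0, 100.0)
BIN_NAMES = ("low", "mid", "high")


@dataclass
class CdsCoverageStat:
    cds_id: str          # gene.transcript.CDSk
    ordinal: int         # k, in translation order
    mean_depth: float
    covered_fraction_pct: float
    depth_bin: str

    def __post_init__(self):
        if not 0 <= self.covered_fraction_pct <= 100:
            raise ValueError("covered_fraction_pct outside [0, 100]")


@dataclass
class DepthBinSummary:
    fraction_of_cds_pct: dict[str, float]
    mean_coverage_pct: dict[str, float]
    n_cds_total: int


def _bin_of(mean_depth: float) -> str:
    """Half-open bins: 30 and 100 fall in the upper bin."""
    if mean_depth < BIN_EDGES[0]:
        return "low"
    if mean_depth < BIN_EDGES[1]:
        return "mid"
    return "high"


def cds_coverage_stats(
    profile: DepthProfile,
    transcripts: Sequence[TranscriptModel],
    cover_threshold: int = 1,
    flank_bp: int = 10,
) -> list[CdsCoverageStat]:
    """Score every CDS (+/- flank, the same span the panel captures).

    Positions absent from the profile count as depth 0. ``cover_threshold``
    is the depth a base needs to count as covered (default 1: any read).
    """
    if cover_threshold < 1:
        raise ValueError("cover_threshold must be >= 1")
    out = []
    for tx in transcripts:
        chrom = normalize_chrom(tx.chrom)
        for cds, k in zip(tx.cds, tx.cds_ordinals):
            lo = max(0, cds.start - flank_bp)
            hi = cds.end + flank_bp
            n = hi - lo
            total = covered = 0
            for pos in range(lo, hi):
                d = profile.depths.get((chrom, pos), 0)
                total += d
                if d >= cover_threshold:
                    covered += 1
            mean = total / n if n else 0.0
            pct = 100.0 * covered / n if n else 0.0
            out.append(CdsCoverageStat(
                cds_id=f"{tx.gene_id}.{tx.transcript_id}.CDS{k}",
                ordinal=k,
                mean_depth=mean,
                covered_fraction_pct=pct,
                depth_bin=_bin_of(mean),
            ))
    return out


def bin_depth_summary(stats: Sequence[CdsCoverageStat]) -> DepthBinSummary:
    """Fraction of CDSs per depth bin and each bin's mean coverage."""
    if not stats:
        raise ValueError("no CDS statistics to summarize")
    counts = {b: 0 for b in BIN_NAMES}
    cover = {b: 0.0 for b in BIN_NAMES}
    for s in stats:
        counts[s.depth_bin] += 1
        cover[s.depth_bin] += s.covered_fraction_pct
    n = len(stats)
    return DepthBinSummary(
        fraction_of_cds_pct={
            b: round_half_up(100.0 * counts[b] / n) for b in BIN_NAMES
        },
        mean_coverage_pct={
            b: round_half_up(cover[b] / counts[b]) if counts[b] else 0.0
            for b in BIN_NAMES
        },
        n_cds_total=n,
    )


def zero_coverage_report(
    stats: Sequence[CdsCoverageStat],
) -> tuple[list[str], int]:
    """IDs of zero-coverage CDSs and the whole-percent share that are CDS1."""
    zero = [s for s in stats if s.covered_fraction_pct == 0]
    if not zero:
        return [], 0
    n_first = sum(1 for s in zero if s.ordinal == 1)
    return [s.cds_id for s in zero], round(100 * n_first / len(zero))


def count_not_fully_covered(stats: Sequence[CdsCoverageStat]) -> int:
    """How many CDS regions fall short of 100% coverage."""
    return sum(1 for s in stats if s.covered_fraction_pct < 100.0)


def meets_recommended_depth(mean_sample_depth: float,
                            recommended: float = 100.0) -> bool:
    """Whether a sample's mean deduplicated depth reaches the recommended
    floor (100x) for reliable panel calling."""
    return mean_sample_depth >= recommended
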