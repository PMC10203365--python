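"""Genotype stability across technical replicates and array concordance.

Stability is the fraction of jointly covered sites whose genotypes are
identical in all three technical replicates of a sample. Sites that are
not covered and genotyped in every replicate are removed from the
denominator entirely (which is why totals run slightly below the capture
region size). Genotypes compare as unordered allele pairs, so 0/1 and 1|0
are the same call.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from panelsmith._util import normalize_chrom, round_half_up
from panelsmith.genomic_io import SiteGenotype


@dataclass
class ConcordanceResult:
    n_total: int
    n_all_same: int
    n_two_same: int
    n_all_diff: int
    stability_pct: float

    def __post_init__(self):
        if self.n_all_same + self.n_two_same + self.n_all_diff != self.n_total:
            raise ValueError("concordance counts do not sum to n_total")


def stability(n_all_same: int, n_total: int) -> float:
    """Percentage of sites identical in all three replicates (2 dp, half-up)."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_all_same <= n_total:
        raise ValueError("need 0 <= n_all_same <= n_total")
    return round_half_up(100.0 * n_all_same / n_total)


def _index(sites: Sequence[SiteGenotype]):
    return {(normalize_chrom(s.chrom), s.pos): s for s in sites}


def classify_sites(
    rep1: Sequence[SiteGenotype],
    rep2: Sequence[SiteGenotype],
    rep3: Sequence[SiteGenotype],
) -> ConcordanceResult:
    """Classify each jointly genotyped site as all-same/two-same/all-different.

    The denominator is the set of sites present, covered and non-missing in
    all three replicates; a site absent or missing in any replicate changes
    no counts. Classification is symmetric in the replicate order.
    """
    idx = [_index(r) for r in (rep1, rep2, rep3)]
    keys = set(idx[0]) & set(idx[1]) & set(idx[2])
    n_same = n_two = n_diff = n_total = 0
    for key in keys:
        trio = [d[key] for d in idx]
        if not all(s.covered and s.genotype is not None for s in trio):
            continue
        n_total += 1
        g = [s.genotype for s in trio]
        distinct = len(set(g))
        if distinct == 1:
            n_same += 1
        elif distinct == 2:
            n_two += 1
        else:
            n_diff += 1
    return ConcordanceResult(
        n_total=n_total,
        n_all_same=n_same,
        n_two_same=n_two,
        n_all_diff=n_diff,
        stability_pct=stability(n_same, n_total) if n_total else 0.0,
    )


def array_concordance(
    ngs_sites: Sequence[SiteGenotype],
    array_sites: Sequence[SiteGenotype],
) -> tuple[int, int, float]:
    """Genotype agreement at loci shared between sequencing and an array.

    Returns (n_shared, n_concordant, percent). Shared loci are positions
    with a non-missing genotype on both platforms; agreement is unordered
    allele-pair equality. No shared loci is an error (the percentage would
    be undefined).
    """
    a = {k: s for k, s in _index(ngs_sites).items()
         if s.genotype is not None}
    b = {k: s for k, s in _index(array_sites).items()
         if s.genotype is not None}
    shared = sorted(set(a) & set(b))
    if not shared:
        raise ValueError("no loci shared between the two genotype sets")
    n_conc = sum(1 for k in shared if a[k].same_genotype(b[k]))
    return len(shared), n_conc, round_half_up(100.0 * n_conc / len(shared))
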