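"""Read-depth CNV detection within a sequencing batch.

Copy-number events inside the capture footprint are found by comparing a
sample's per-target mean depths with the other samples of the same batch:
depths are library-size normalized (median-of-targets size factor), each
target's reference is the leave-one-out median across the batch, and the
sample/reference ratio is reported as a log2 copy ratio (0 = diploid,
about -1 = single-copy loss, about +0.58 = single-copy gain). Consecutive
targets beyond a threshold merge into calls; short runs are suppressed.

Lower sequencing throughput is emulated by binomial thinning of per-base
depths, and calls are benchmarked against truth intervals by reciprocal
overlap and signed breakpoint deltas.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from panelsmith._util import normalize_chrom
from panelsmith.genomic_io import DepthProfile, GenomicInterval

DEL_THRESHOLD = -0.4   # ~log2 of a generous heterozygous-loss expectation
DUP_THRESHOLD = 0.32   # ~log2(1.25), below the 1.5x single-copy-gain mean
MIN_TARGETS = 3
PSEUDOCOUNT = 0.5      # reads, added to both numerator and reference


@dataclass
class TargetDepthMatrix:
    """Per-sample, per-target mean depths with library size factors."""

    targets: list[GenomicInterval]
    samples: list[str]
    mean_depth: np.ndarray            # shape (n_samples, n_targets)
    size_factor: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.mean_depth = np.asarray(self.mean_depth, dtype=float)
        if self.mean_depth.shape != (len(self.samples), len(self.targets)):
            raise ValueError("mean_depth shape mismatch")
        if self.size_factor is None:
            med = np.median(self.mean_depth, axis=1)
            med[med <= 0] = 1.0
            self.size_factor = med
        self.size_factor = np.asarray(self.size_factor, dtype=float)
        if np.any(self.size_factor <= 0):
            raise ValueError("size factors must be positive")


def target_depth_matrix(
    profiles: Sequence[DepthProfile], targets: Sequence[GenomicInterval],
) -> TargetDepthMatrix:
    """Mean per-base depth of every profile over every target."""
    if not targets:
        raise ValueError("no targets")
    mat = np.zeros((len(profiles), len(targets)))
    for i, prof in enumerate(profiles):
        for j, iv in enumerate(targets):
            mat[i, j] = prof.mean_depth([iv])
    return TargetDepthMatrix(
        targets=list(targets),
        samples=[p.sample_id for p in profiles],
        mean_depth=mat,
    )


def normalize_target_depths(
    matrix: TargetDepthMatrix,
) -> tuple[pd.DataFrame, list[int]]:
    """Log2 copy ratios against a leave-one-out in-batch median reference.

    Returns (ratios, zero_targets): a samples x targets DataFrame and the
    indices of targets with zero depth in every sample, whose ratios are
    pinned at 0 rather than left undefined.
    """
    if len(matrix.samples) < 2:
        raise ValueError("need at least 2 samples for an in-batch reference")
    # Depths are first made unitless per sample (divide by that sample's
    # median target depth), then both the sample and its leave-one-out
    # reference are rescaled to the read-depth scale of the *other* batch
    # samples. Everything the sample contributes cancels exactly, so
    # rescaling one library leaves its own ratios untouched, and the
    # 0.5-read pseudocount stays negligible at real depths.
    raw = matrix.size_factor
    n = raw.shape[0]
    unitless = matrix.mean_depth / raw[:, None]
    ratios = np.zeros_like(unitless)
    for i in range(n):
        scale = np.median(np.delete(raw, i))
        norm_i = unitless[i] * scale
        ref = np.median(np.delete(unitless, i, axis=0), axis=0) * scale
        ratios[i] = np.log2((norm_i + PSEUDOCOUNT) / (ref + PSEUDOCOUNT))
    zero_targets = [
        j for j in range(matrix.mean_depth.shape[1])
        if np.all(matrix.mean_depth[:, j] == 0)
    ]
    ratios[:, zero_targets] = 0.0
    labels = [t.label or f"{t.chrom}:{t.start}-{t.end}" for t in matrix.targets]
    return (
        pd.DataFrame(ratios, index=list(matrix.samples), columns=labels),
        zero_targets,
    )


@dataclass
class CnvCall:
    interval: GenomicInterval
    kind: str                 # del | dup
    mean_log2: float
    n_targets: int

    def __post_init__(self):
        if self.kind not in ("del", "dup"):
            raise ValueError(f"kind must be del or dup, got {self.kind!r}")


def call_depth_cnv(
    targets: Sequence[GenomicInterval],
    log2_ratios: Sequence[float],
    del_threshold: float = DEL_THRESHOLD,
    dup_threshold: float = DUP_THRESHOLD,
    min_targets: int = MIN_TARGETS,
) -> list[CnvCall]:
    """Threshold-and-merge segmentation of one sample's log2 ratios.

    Consecutive same-chromosome targets beyond the same threshold become a
    single call spanning the first target's start to the last target's end;
    runs shorter than ``min_targets`` are suppressed as noise.
    """
    if not (del_threshold < 0 < dup_threshold):
        raise ValueError("need del_threshold < 0 < dup_threshold")
    if min_targets < 1:
        raise ValueError("min_targets must be >= 1")
    if len(targets) != len(log2_ratios):
        raise ValueError("targets and ratios differ in length")

    def state(x: float) -> Optional[str]:
        if x <= del_threshold:
            return "del"
        if x >= dup_threshold:
            return "dup"
        return None

    calls: list[CnvCall] = []
    run: list[int] = []
    run_state: Optional[str] = None

    def flush():
        nonlocal run, run_state
        if run_state is not None and len(run) >= min_targets:
            ivs = [targets[k] for k in run]
            vals = [log2_ratios[k] for k in run]
            calls.append(CnvCall(
                interval=GenomicInterval(
                    ivs[0].chrom, ivs[0].start, ivs[-1].end,
                    f"{run_state}:{len(run)}targets",
                ),
                kind=run_state,
                mean_log2=float(np.mean(vals)),
                n_targets=len(run),
            ))
        run, run_state = [], None

    prev_chrom = None
    for j, (iv, x) in enumerate(zip(targets, log2_ratios)):
        s = state(x)
        chrom = normalize_chrom(iv.chrom)
        if s != run_state or chrom != prev_chrom:
            flush()
            run_state = s
        if s is not None:
            run.append(j)
        prev_chrom = chrom
    flush()
    return calls


@dataclass
class DownsampleSpec:
    """Binomial thinning to a target read count (or a direct fraction)."""

    target_reads: Optional[int] = None
    source_reads: Optional[int] = None
    fraction: Optional[float] = None
    seed: int = 0

    def __post_init__(self):
        if self.fraction is None:
            if self.target_reads is None or not self.source_reads:
                raise ValueError(
                    "give fraction, or target_reads with source_reads"
                )
            self.fraction = self.target_reads / self.source_reads
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError(f"fraction {self.fraction} outside [0, 1]")


def downsample_depth(
    profile: DepthProfile, spec: DownsampleSpec,
) -> DepthProfile:
    """Thin each per-base depth with an independent binomial draw.

    Keeping each read with probability ``fraction`` is expectation-
    equivalent to re-extracting that share of reads, without needing the
    reads themselves. Reproducible for a fixed ``spec.seed``.
    """
    frac = spec.fraction
    if frac == 1.0:
        return DepthProfile(profile.sample_id, dict(profile.depths),
                            profile.source_reads)
    rng = np.random.default_rng(spec.seed)
    keys = sorted(profile.depths)
    depths = np.array([profile.depths[k] for k in keys], dtype=np.int64)
    thinned = rng.binomial(depths, frac) if frac > 0 else np.zeros_like(depths)
    new_reads = (
        int(round(profile.source_reads * frac))
        if profile.source_reads else None
    )
    return DepthProfile(
        profile.sample_id,
        dict(zip(keys, (int(d) for d in thinned))),
        new_reads,
    )


@dataclass
class CnvComparison:
    truth: GenomicInterval
    called: Optional[GenomicInterval]
    start_delta_bp: Optional[int]
    end_delta_bp: Optional[int]
    reciprocal_overlap: float
    matched: bool


def compare_cnv_calls(
    truth: GenomicInterval,
    called: Optional[GenomicInterval],
    match_threshold: float = 0.5,
) -> CnvComparison:
    """Breakpoint deltas (truth - called) and reciprocal overlap.

    Reciprocal overlap is intersection length over the longer interval;
    calls at or above ``match_threshold`` count as matched. A missing call
    gives overlap 0 and no deltas.
    """
    if called is None:
        return CnvComparison(truth, None, None, None, 0.0, False)
    if normalize_chrom(truth.chrom) != normalize_chrom(called.chrom):
        ro = 0.0
    else:
        inter = max(0, min(truth.end, called.end) - max(truth.start, called.start))
        longer = max(len(truth), len(called))
        ro = inter / longer if longer else 0.0
    return CnvComparison(
        truth=truth,
        called=called,
        start_delta_bp=truth.start - called.start,
        end_delta_bp=truth.end - called.end,
        reciprocal_overlap=ro,
        matched=ro >= match_threshold,
    )


def sensitivity_curve(
    cnv_sizes_bp: Sequence[int] = (200_000, 1_000_000, 2_000_000),
    depth_fractions: Sequence[float] = (0.1, 0.5, 1.0),
    replicates: int = 20,
    seed: int = 0,
    mean_depth: float = 300.0,
    dispersion: float = 10.0,
    n_samples: int = 4,
    target_bp: int = 150,
    target_spacing_bp: int = 60_000,
    span_bp: int = 20_000_000,
    match_threshold: float = 0.5,
) -> pd.DataFrame:
    """Recall of planted single-copy deletions across sizes and depths.

    Emulates the panel's target geometry (short targets at wide spacing,
    as exonic capture leaves over a chromosome) on one chromosome segment:
    each replicate plants one heterozygous deletion of the given size at a
    random position in one of ``n_samples`` batch samples, thins all
    depths to the given fraction, runs normalization + calling, and scores
    a match by reciprocal overlap. Rows: event size; columns: depth
    fraction; cells: recall over ``replicates`` seeded replicates.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    starts = np.arange(0, span_bp - target_bp, target_spacing_bp)
    targets = [
        GenomicInterval("chr1", int(s), int(s) + target_bp, f"t{k}")
        for k, s in enumerate(starts)
    ]
    centers = starts + target_bp / 2
    master = np.random.default_rng(seed)
    table = np.zeros((len(cnv_sizes_bp), len(depth_fractions)))
    for si, size in enumerate(cnv_sizes_bp):
        for fi, frac in enumerate(depth_fractions):
            hits = 0
            for rep in range(replicates):
                rng = np.random.default_rng(master.integers(2**31))
                ev_start = int(rng.integers(0, span_bp - size))
                truth = GenomicInterval("chr1", ev_start, ev_start + size, "del")
                copy = np.full((n_samples, len(targets)), 2.0)
                in_event = (centers >= ev_start) & (centers < ev_start + size)
                copy[0, in_event] = 1.0
                mu = mean_depth * copy / 2.0
                p = dispersion / (dispersion + mu)
                per_base = rng.negative_binomial(
                    dispersion, p[:, :, None],
                    size=(n_samples, len(targets), target_bp),
                )
                depths = per_base.mean(axis=2)
                if frac == 0.0:
                    depths[:] = 0.0
                elif frac < 1.0:
                    # thinning target totals is equivalent to per-base thinning
                    totals = (depths * target_bp).astype(np.int64)
                    depths = rng.binomial(totals, frac) / target_bp
                mat = TargetDepthMatrix(
                    targets=targets,
                    samples=[f"S{i}" for i in range(n_samples)],
                    mean_depth=depths,
                )
                if np.all(depths == 0):
                    continue
                ratios, _ = normalize_target_depths(mat)
                calls = call_depth_cnv(targets, ratios.iloc[0].to_numpy())
                if any(
                    c.kind == "del"
                    and compare_cnv_calls(truth, c.interval,
                                          match_threshold).matched
                    for c in calls
                ):
                    hits += 1
            table[si, fi] = hits / replicates
    return pd.DataFrame(
        table,
        index=[f"{s}bp" for s in cnv_sizes_bp],
        columns=[f"{f:g}x" for f in depth_fractions],
    )
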