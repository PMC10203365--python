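"""Six-rule Mendelian variant prioritization cascade.

Candidate variants arrive pre-annotated (population frequency, database
pathogenicity flags, in-silico prediction votes, phenotype match) and are
screened in order:

R1  known high-frequency pathogenic variant -> retained regardless of
    population frequency;
R2  otherwise the population frequency must be below the cutoff (default
    1%); an unknown frequency passes;
R3-R5  evidence screen: database-reported pathogenic, OR a clarified
    deleterious mechanism for the gene, OR enough damaging prediction
    votes (default 2 of 3 tools) — configurable to require all three;
R6  the surviving genotype must fit the gene's inheritance model and the
    patient's phenotype: AD needs any het/hom, AR needs a hom or two
    distinct surviving hets in the gene (compound het), X-linked needs a
    hemi/hom (a het survives only as a flagged carrier).

Separately, a predicted protein-stability change is called significant
when the folding free-energy difference ddG between mutant and wild type
exceeds 1.6 kcal/mol (strict).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

VTYPES = (
    "missense", "frameshift", "splicing", "intragenic_cnv",
    "whole_gene_del", "other",
)


@dataclass
class VariantRecord:
    gene_id: str
    variant_id: str
    vtype: str = "other"
    pop_freq: Optional[float] = None
    known_pathogenic_hf: bool = False
    db_pathogenic: bool = False
    mechanism_deleterious: bool = False
    prediction_damaging_votes: int = 0
    zygosity: str = "het"
    phenotype_match: bool = False
    reported_before: bool = False
    ddg_kcal_mol: Optional[float] = None

    def __post_init__(self):
        if self.vtype not in VTYPES:
            raise ValueError(f"unknown vtype {self.vtype!r}")
        if self.zygosity not in ("het", "hom", "hemi"):
            raise ValueError(f"unknown zygosity {self.zygosity!r}")
        if self.pop_freq is not None and not 0 <= self.pop_freq <= 1:
            raise ValueError("pop_freq outside [0, 1]")
        if not 0 <= self.prediction_damaging_votes <= 3:
            raise ValueError("prediction_damaging_votes outside 0..3")


@dataclass
class TriageConfig:
    freq_cutoff: float = 0.01
    min_damaging_votes: int = 2
    ddg_cutoff: float = 1.6           # kcal/mol
    evidence_mode: str = "or"         # combine R3-R5 as OR (default) or AND
    inheritance_map: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if not 0 < self.freq_cutoff < 1:
            raise ValueError("freq_cutoff must be in (0, 1)")
        if self.evidence_mode not in ("or", "and"):
            raise ValueError("evidence_mode must be 'or' or 'and'")
        for gene, model in self.inheritance_map.items():
            if model not in ("AD", "AR", "XL"):
                raise ValueError(
                    f"inheritance model for {gene} must be AD/AR/XL"
                )


Trace = list[tuple[str, bool]]


@dataclass
class KeptVariant:
    record: VariantRecord
    trace: Trace
    carrier: bool = False  # XL het retained as carrier finding only


@dataclass
class TriageResult:
    kept: list[KeptVariant]
    dropped: list[tuple[VariantRecord, Trace]]
    summary: dict[str, int]
    n_reported: int
    n_novel: int


def _evidence_pass(rec: VariantRecord, cfg: TriageConfig) -> bool:
    flags = (
        rec.db_pathogenic,
        rec.mechanism_deleterious,
        rec.prediction_damaging_votes >= cfg.min_damaging_votes,
    )
    return all(flags) if cfg.evidence_mode == "and" else any(flags)


def triage_variants(
    records: Sequence[VariantRecord], cfg: TriageConfig,
) -> TriageResult:
    """Run the full cascade; every record ends up kept or dropped with a
    rule trace. The inheritance map must cover every gene that reaches R6."""
    survivors: list[tuple[VariantRecord, Trace]] = []
    dropped: list[tuple[VariantRecord, Trace]] = []
    for rec in records:
        trace: Trace = []
        if rec.known_pathogenic_hf:
            # an established pathogenic variant skips the frequency and
            # evidence screens; only the phenotype/inheritance gate remains
            trace.append(("R1", True))
            survivors.append((rec, trace))
            continue
        trace.append(("R1", False))
        freq_ok = rec.pop_freq is None or rec.pop_freq < cfg.freq_cutoff
        trace.append(("R2", freq_ok))
        if not freq_ok:
            dropped.append((rec, trace))
            continue
        ev = _evidence_pass(rec, cfg)
        trace.append(("R3-R5", ev))
        if not ev:
            dropped.append((rec, trace))
            continue
        survivors.append((rec, trace))

    # R6 needs gene-level context (compound heterozygosity)
    missing = sorted(
        {r.gene_id for r, _ in survivors} - set(cfg.inheritance_map)
    )
    if missing:
        raise KeyError(
            f"no inheritance model configured for gene(s): {missing}"
        )
    het_counts: dict[str, set[str]] = {}
    for rec, _ in survivors:
        if rec.zygosity == "het" and rec.phenotype_match:
            het_counts.setdefault(rec.gene_id, set()).add(rec.variant_id)

    kept: list[KeptVariant] = []
    for rec, trace in survivors:
        model = cfg.inheritance_map[rec.gene_id]
        carrier = False
        if not rec.phenotype_match:
            genotype_ok = False
        elif model == "AD":
            genotype_ok = rec.zygosity in ("het", "hom")
        elif model == "AR":
            genotype_ok = (
                rec.zygosity == "hom"
                or (rec.zygosity == "het"
                    and len(het_counts.get(rec.gene_id, ())) >= 2)
            )
        else:  # XL
            genotype_ok = rec.zygosity in ("hemi", "hom")
            if not genotype_ok and rec.zygosity == "het":
                genotype_ok, carrier = True, True
        trace.append(("R6", genotype_ok))
        if genotype_ok:
            kept.append(KeptVariant(rec, trace, carrier=carrier))
        else:
            dropped.append((rec, trace))

    summary = summarize_variants([k.record for k in kept])
    return TriageResult(
        kept=kept,
        dropped=dropped,
        summary=summary,
        n_reported=summary["n_reported"],
        n_novel=summary["n_novel"],
    )


def classify_ddg(
    ddg_kcal_mol: Optional[float], cfg: TriageConfig | None = None,
) -> Optional[bool]:
    """Is a predicted stability change significant (ddG > cutoff, strict)?

    Returns None for a missing or non-finite value: unknown, never
    significant.
    """
    cutoff = (cfg or TriageConfig()).ddg_cutoff
    if ddg_kcal_mol is None or not math.isfinite(ddg_kcal_mol):
        return None
    return ddg_kcal_mol > cutoff


def summarize_variants(
    kept_records: Sequence[VariantRecord],
) -> dict[str, int]:
    """Counts per variant category plus total and reported/novel split."""
    out = {v: 0 for v in VTYPES}
    for rec in kept_records:
        out[rec.vtype] += 1
    out["total"] = len(kept_records)
    out["n_reported"] = sum(1 for r in kept_records if r.reported_before)
    out["n_novel"] = out["total"] - out["n_reported"]
    return out


# ---------------------------------------------------------------------------
# TSV plumbing for the CLI
# ---------------------------------------------------------------------------

_BOOL = {"1": True, "0": False, "true": True, "false": False,
         "yes": True, "no": False, "": False}


def read_variant_table(source) -> list[VariantRecord]:
    """Header-driven TSV whose columns mirror VariantRecord fields."""
    from panelsmith._util import as_text

    lines = [ln for ln in as_text(source).splitlines() if ln.strip()]
    if not lines:
        return []
    header = lines[0].split("\t")
    out = []
    for line in lines[1:]:
        row = dict(zip(header, line.split("\t")))
        out.append(VariantRecord(
            gene_id=row["gene_id"],
            variant_id=row["variant_id"],
            vtype=row.get("vtype", "other"),
            pop_freq=float(row["pop_freq"]) if row.get("pop_freq") else None,
            known_pathogenic_hf=_BOOL[row.get("known_pathogenic_hf", "0").lower()],
            db_pathogenic=_BOOL[row.get("db_pathogenic", "0").lower()],
            mechanism_deleterious=_BOOL[row.get("mechanism_deleterious", "0").lower()],
            prediction_damaging_votes=int(row.get("prediction_damaging_votes", 0)),
            zygosity=row.get("zygosity", "het"),
            phenotype_match=_BOOL[row.get("phenotype_match", "0").lower()],
            reported_before=_BOOL[row.get("reported_before", "0").lower()],
            ddg_kcal_mol=float(row["ddg_kcal_mol"]) if row.get("ddg_kcal_mol") else None,
        ))
    return out


def read_inheritance_map(source) -> dict[str, str]:
    """Two-column TSV (gene, model) into an inheritance map."""
    from panelsmith._util import as_text

    out = {}
    for line in as_text(source).splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        gene, model = line.split("\t")[:2]
        if gene.lower() in ("gene", "gene_id"):
            continue
        out[gene] = model
    return out
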