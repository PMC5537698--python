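"""Triage of candidate miRNA targets from an overexpression transcriptome.

Three-stage funnel: genes downregulated after miRNA overexpression
(per-timepoint log2FC filter, union across timepoints), intersected with
the in-silico predicted-target universe (membership in >= min_algorithms
prediction algorithms), then restricted to genes upregulated in the tumour
cohort — the direction expected for a real target of a miRNA the tumour
has lost.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

from .shortlist import ExpressionStat

logger = logging.getLogger(__name__)

N_ALGORITHMS = 12  # size of the bundled prediction-algorithm panel


@dataclass(frozen=True)
class DEGene:
    """One gene's differential expression at one overexpression timepoint."""

    gene: str
    log2fc: float
    p: float | None
    adj_p: float | None
    timepoint: str = "48h"

    def __post_init__(self) -> None:
        if self.adj_p is not None and not (0.0 <= self.adj_p <= 1.0):
            raise ValueError(f"adj_p must be in [0, 1], got {self.adj_p}")


@dataclass(frozen=True)
class PredictionRecord:
    """A gene and the set of prediction algorithms that list it as a target."""

    gene: str
    algorithms_hit: frozenset[str]

    def __post_init__(self) -> None:
        if not self.algorithms_hit:
            raise ValueError(f"prediction record for {self.gene} has no algorithms")


@dataclass
class TriageCandidate:
    gene: str
    down_lfc_48: float | None = None
    down_lfc_72: float | None = None
    n_algorithms: int = 0
    gbm_stat: ExpressionStat | None = None
    passes: set = field(default_factory=set)

    @property
    def is_final(self) -> bool:
        return {"downregulated", "predicted", "gbm_up"} <= self.passes


@dataclass
class TriageResult:
    candidates: list[TriageCandidate]
    funnel: dict  # stage -> size

    @property
    def final_genes(self) -> set[str]:
        return {c.gene for c in self.candidates if c.is_final}


def de_filter(
    genes: Sequence[DEGene],
    direction: str,
    lfc_cut: float = 0.57,
    alpha: float | None = 0.05,
) -> set[str]:
    """Deduplicated gene set passing a one-sided log2FC (+ FDR) filter.

    ``lfc_cut`` is the unsigned magnitude — sign is carried by
    ``direction`` ("down" keeps log2fc <= −lfc_cut, "up" keeps >= +lfc_cut).
    ``alpha`` applies to the BH-adjusted p; pass ``alpha=None`` to filter on
    fold change alone (the magnitude-only variant some shortlists use).
    """
    if lfc_cut < 0:
        raise ValueError("lfc_cut must be non-negative; direction carries the sign")
    if direction not in ("down", "up"):
        raise ValueError(f"direction must be 'down' or 'up', got {direction!r}")

    kept: set[str] = set()
    for g in genes:
        if direction == "down":
            fc_ok = g.log2fc <= -lfc_cut
        else:
            fc_ok = g.log2fc >= lfc_cut
        p_ok = True if alpha is None else (g.adj_p is not None and g.adj_p < alpha)
        if fc_ok and p_ok:
            kept.add(g.gene)
    return kept


def union_timepoints(sets: Sequence[set[str]]) -> set[str]:
    """Deduplicated union of per-timepoint gene sets."""
    out: set[str] = set()
    for s in sets:
        out |= s
    return out


def triage(
    down: set[str],
    predictions: Sequence[PredictionRecord],
    gbm_stats: Sequence[ExpressionStat],
    min_algorithms: int = 1,
    alpha: float = 0.05,
    de_genes: Sequence[DEGene] = (),
) -> TriageResult:
    """Run the two intersection stages and record funnel sizes.

    Stage 1 keeps downregulated genes predicted by >= min_algorithms
    algorithms; stage 2 further requires significant upregulation
    (log2fc > 0, adjusted or raw p < alpha) in >= 1 tumour cohort.
    ``de_genes``, when given, annotates candidates with their per-timepoint
    overexpression log2FCs.
    """
    if min_algorithms > N_ALGORITHMS:
        raise ValueError(
            f"min_algorithms={min_algorithms} exceeds the {N_ALGORITHMS}-algorithm panel"
        )
    pred_by_gene: dict[str, PredictionRecord] = {}
    for p in predictions:
        if p.gene in pred_by_gene:
            raise ValueError(f"duplicate prediction record for gene {p.gene}")
        pred_by_gene[p.gene] = p

    stats_by_gene: dict[str, list[ExpressionStat]] = {}
    for s in gbm_stats:
        stats_by_gene.setdefault(s.entity, []).append(s)

    lfc = {("48h", g.gene): g.log2fc for g in de_genes if g.timepoint == "48h"}
    lfc.update({("72h", g.gene): g.log2fc for g in de_genes if g.timepoint == "72h"})

    candidates: list[TriageCandidate] = []
    for gene in sorted(down):
        cand = TriageCandidate(
            gene=gene,
            down_lfc_48=lfc.get(("48h", gene)),
            down_lfc_72=lfc.get(("72h", gene)),
            n_algorithms=len(pred_by_gene[gene].algorithms_hit) if gene in pred_by_gene else 0,
            passes={"downregulated"},
        )
        if cand.n_algorithms >= min_algorithms:
            cand.passes.add("predicted")
            up_stats = [
                s for s in stats_by_gene.get(gene, [])
                if s.log2fc is not None and s.log2fc > 0 and s.significant(alpha)
            ]
            if up_stats:
                cand.passes.add("gbm_up")
                cand.gbm_stat = min(
                    up_stats, key=lambda s: (s.adj_p if s.adj_p is not None else s.p, s.cohort)
                )
        candidates.append(cand)

    n_stage1 = sum("predicted" in c.passes for c in candidates)
    n_stage2 = sum(c.is_final for c in candidates)
    funnel = {"downregulated": len(down), "predicted": n_stage1, "gbm_up": n_stage2}
    logger.info("triage funnel: %s", funnel)
    return TriageResult(candidates=candidates, funnel=funnel)


def validate_candidates(
    candidates: Sequence[TriageCandidate],
    validation_stats: Sequence[ExpressionStat],
    alpha: float = 0.05,
) -> list[dict]:
    """Per-candidate, per-cohort verdict table for validation cohorts.

    Candidates absent from the validation stats are reported "untested".
    """
    by_gene: dict[str, list[ExpressionStat]] = {}
    for s in validation_stats:
        by_gene.setdefault(s.entity, []).append(s)

    rows: list[dict] = []
    for cand in candidates:
        stats = by_gene.get(cand.gene, [])
        if not stats:
            rows.append({"gene": cand.gene, "cohort": None, "log2fc": None,
                         "verdict": "untested"})
            continue
        for s in sorted(stats, key=lambda s: s.cohort):
            if s.log2fc is None or not s.significant(alpha):
                verdict = "not_regulated"
            else:
                verdict = "upregulated" if s.log2fc > 0 else "downregulated"
            rows.append({"gene": cand.gene, "cohort": s.cohort,
                         "log2fc": s.log2fc, "verdict": verdict})
    return rows
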