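"""Host-gene assignment and expression-concordance shortlisting.

A miRNA sitting in a recurrently deleted region is a copy-number-driven
candidate only if something measurable is actually *down* — either the
mature miRNA itself or, for an intragenic miRNA whose own expression was
never assayed, its host gene. This module implements that concordance rule
(sign of the expression change must match the direction of the copy-number
event, with significance in at least one cohort), host-gene assignment by
strand-agnostic containment, and the flanking-gene focality check used to
argue a deletion is confined to one locus.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

from .intervals import GenomicInterval, contains
from .mirnome_map import MiRNARecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneRecord:
    """A gene symbol with its full genomic span."""

    symbol: str
    interval: GenomicInterval


@dataclass(frozen=True)
class ExpressionStat:
    """One entity's differential expression in one cohort contrast.

    log2fc is tumour minus control (log2 units); adj_p is
    Benjamini–Hochberg-adjusted where the cohort provides it (None for
    cohorts that publish only raw p, in which case ``significant`` falls
    back to the raw p-value).
    """

    entity: str
    log2fc: float | None
    p: float | None
    adj_p: float | None
    cohort: str

    def __post_init__(self) -> None:
        for name, v in (("p", self.p), ("adj_p", self.adj_p)):
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.log2fc is not None and not math.isfinite(self.log2fc):
            raise ValueError(f"log2fc must be finite or None, got {self.log2fc}")

    def significant(self, alpha: float) -> bool:
        if self.log2fc is None:
            return False
        pval = self.adj_p if self.adj_p is not None else self.p
        return pval is not None and pval < alpha


@dataclass(frozen=True)
class ShortlistEntry:
    mature_name: str
    direction: str  # "amplified" | "deleted"
    evidence: str  # "self" | "host" | "both"
    mirna_stat: ExpressionStat | None
    host_gene: str | None
    host_stat: ExpressionStat | None


def assign_host_gene(
    mirna: MiRNARecord, genes: Sequence[GeneRecord]
) -> str | None:
    """The gene whose span fully contains the miRNA's locus, or None.

    The precursor interval is used when available, else the mature one.
    Containment is strand-agnostic — an intragenic miRNA can sit antisense
    to its host. If several genes contain the locus, the smallest span
    wins (the most local annotation); ties break on symbol for determinism.
    """
    locus = mirna.precursor_interval or mirna.mature_interval
    hosts = [g for g in genes if contains(g.interval, locus)]
    if not hosts:
        return None
    return min(hosts, key=lambda g: (g.interval.length, g.symbol)).symbol


def _best_stat(
    stats: Sequence[ExpressionStat], sign: int, alpha: float
) -> ExpressionStat | None:
    """The most significant stat that is significant AND sign-concordant."""
    ok = [
        s for s in stats
        if s.significant(alpha) and s.log2fc is not None and sign * s.log2fc > 0
    ]
    if not ok:
        return None
    return min(ok, key=lambda s: (s.adj_p if s.adj_p is not None else s.p, s.cohort))


def concordance_shortlist(
    amplified_mirnas: set[str],
    deleted_mirnas: set[str],
    stats: Sequence[ExpressionStat],
    hosts: dict[str, str],
    alpha: float = 0.05,
) -> list[ShortlistEntry]:
    """Keep copy-number-concordant miRNAs from the amplified/deleted sets.

    A miRNA in the amplified set is retained iff its own log2fc is positive
    and significant in >= 1 cohort, OR its host gene's is; the deleted set
    mirrors this with negative sign. Evidence clauses are OR-combined
    across cohorts — a single concordant significant cohort suffices, and a
    discordant result in another cohort does not veto. miRNAs with no
    usable stats anywhere (all NA) are dropped.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")

    by_entity: dict[str, list[ExpressionStat]] = {}
    for s in stats:
        by_entity.setdefault(s.entity, []).append(s)

    entries: list[ShortlistEntry] = []
    for direction, mirna_set, sign in (
        ("amplified", amplified_mirnas, +1),
        ("deleted", deleted_mirnas, -1),
    ):
        for name in sorted(mirna_set):
            self_stat = _best_stat(by_entity.get(name, []), sign, alpha)
            host = hosts.get(name)
            host_stat = (
                _best_stat(by_entity.get(host, []), sign, alpha) if host else None
            )
            if self_stat is None and host_stat is None:
                continue
            evidence = (
                "both" if self_stat and host_stat else "self" if self_stat else "host"
            )
            entries.append(
                ShortlistEntry(
                    mature_name=name,
                    direction=direction,
                    evidence=evidence,
                    mirna_stat=self_stat,
                    host_gene=host,
                    host_stat=host_stat,
                )
            )
    return entries


@dataclass(frozen=True)
class NeighbourVerdict:
    symbol: str
    side: str  # "upstream" | "downstream" (genomic left/right of the locus gene)
    distance_bp: int  # gap between gene spans; 0 if they touch or overlap
    strand: str
    verdicts: dict  # cohort -> "upregulated" | "downregulated" | "not_regulated"
    overall: str


def flanking_check(
    locus_gene: str,
    genes: Sequence[GeneRecord],
    stats: Sequence[ExpressionStat],
    k: int = 2,
    alpha: float = 0.05,
) -> list[NeighbourVerdict]:
    """Expression verdicts for the k nearest genes on each side of a locus.

    Used to test focality of a deletion: if only the locus gene (and its
    resident miRNA) respond while the immediate neighbours are
    not_regulated, the event is confined to the locus. A neighbour's
    overall verdict is not_regulated iff no cohort is significant or
    significant cohorts disagree in sign.
    """
    target = next((g for g in genes if g.symbol == locus_gene), None)
    if target is None:
        raise ValueError(f"locus gene {locus_gene!r} not present in the annotation")

    same_chrom = [g for g in genes if g.interval.chrom == target.interval.chrom
                  and g.symbol != locus_gene]
    upstream = sorted(
        (g for g in same_chrom if g.interval.end < target.interval.start),
        key=lambda g: target.interval.start - g.interval.end,
    )[:k]
    downstream = sorted(
        (g for g in same_chrom if g.interval.start > target.interval.end),
        key=lambda g: g.interval.start - target.interval.end,
    )[:k]
    if not upstream and not downstream:
        logger.warning("locus gene %s has no neighbours on %s",
                       locus_gene, target.interval.chrom)

    by_entity: dict[str, list[ExpressionStat]] = {}
    for s in stats:
        by_entity.setdefault(s.entity, []).append(s)

    out: list[NeighbourVerdict] = []
    for side, neighbours in (("upstream", upstream), ("downstream", downstream)):
        for g in neighbours:
            if side == "upstream":
                dist = target.interval.start - g.interval.end - 1
            else:
                dist = g.interval.start - target.interval.end - 1
            verdicts = {}
            for s in by_entity.get(g.symbol, []):
                if not s.significant(alpha) or s.log2fc is None:
                    verdicts[s.cohort] = "not_regulated"
                else:
                    verdicts[s.cohort] = (
                        "upregulated" if s.log2fc > 0 else "downregulated"
                    )
            signs = {v for v in verdicts.values() if v != "not_regulated"}
            overall = signs.pop() if len(signs) == 1 else "not_regulated"
            out.append(
                NeighbourVerdict(
                    symbol=g.symbol,
                    side=side,
                    distance_bp=max(dist, 0),
                    strand=g.interval.strand,
                    verdicts=verdicts,
                    overall=overall,
                )
            )
    return out
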