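"""Intersect a miRNA annotation with an SCNA catalog.

Produces the three headline statistics of the mapping stage:

* per-source event fraction — how many catalog events carry >= 1 miRNA;
* span fraction — what share of the merged aberrant genome the
  miRNA-bearing events cover;
* miRNome fraction — how many distinct mature miRNAs fall in any event.

Plus the amplified/deleted split of mapped miRNAs that feeds the
expression-concordance shortlist.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import TYPE_CHECKING, Literal, Sequence

from .intervals import GenomicInterval, merge, overlap_bp, total_span

if TYPE_CHECKING:  # pragma: no cover
    from .scna_catalog import AberrantRegion

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MiRNARecord:
    """A mature miRNA, its precursor hairpin locus, and an optional host gene.

    The mature interval is the ~19–25 nt processed product's genomic span;
    the precursor interval, when known, contains or overlaps it. An
    intragenic miRNA's host gene is the protein-coding gene whose span
    contains its locus, irrespective of strand.
    """

    mature_name: str
    mature_interval: GenomicInterval
    precursor_name: str | None = None
    precursor_interval: GenomicInterval | None = None
    host_gene: str | None = None

    def locus(self, which: Literal["mature", "precursor"] = "mature") -> GenomicInterval | None:
        return self.mature_interval if which == "mature" else self.precursor_interval


@dataclass(frozen=True)
class Assignment:
    """One (mature miRNA, catalog event) overlap."""

    mature_name: str
    event_id: str
    source: str
    event_type: str
    overlap_bp: int


@dataclass
class MappingResult:
    assignments: list[Assignment]
    per_source_event_counts: dict[str, tuple[int, int]]  # source -> (with_mirna, total)
    span_fraction: dict[str, float | None]
    mirnome_fraction: tuple[int, int]  # (mapped distinct matures, total matures)

    @property
    def mapped_mirnas(self) -> set[str]:
        return {a.mature_name for a in self.assignments}

    def summary(self) -> dict:
        mapped, total = self.mirnome_fraction
        return {
            "per_source_event_counts": {
                s: {"events_with_mirna": w, "total_events": t}
                for s, (w, t) in sorted(self.per_source_event_counts.items())
            },
            "event_fraction": {
                s: (w / t if t else None)
                for s, (w, t) in sorted(self.per_source_event_counts.items())
            },
            "span_fraction": dict(sorted(self.span_fraction.items())),
            "mirnome_fraction": {
                "mapped_mirnas": mapped,
                "total_mirnas": total,
                "fraction": (mapped / total if total else None),
            },
        }


def map_mirnas(
    catalog: Sequence["AberrantRegion"],
    mirnas: Sequence[MiRNARecord],
    locus: Literal["mature", "precursor"] = "mature",
    min_overlap_bp: int = 1,
) -> MappingResult:
    """Map each miRNA onto every catalog event it overlaps.

    ``locus`` selects which miRNA coordinates are intersected: the mature
    product (default — the denominator the mapping statistics are quoted
    on) or the precursor hairpin (the locus copy-number qPCR assays).
    An overlap of >= ``min_overlap_bp`` shared bases counts as mapped.
    """
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")
    if locus == "precursor" and all(m.precursor_interval is None for m in mirnas) and mirnas:
        raise ValueError("locus='precursor' requested but no miRNA has a precursor interval")

    assignments: list[Assignment] = []
    for mirna in mirnas:
        iv = mirna.locus(locus)
        if iv is None:
            continue
        for event in catalog:
            bp = overlap_bp(iv, event.interval)
            if bp >= min_overlap_bp:
                assignments.append(
                    Assignment(
                        mature_name=mirna.mature_name,
                        event_id=event.event_id,
                        source=event.source,
                        event_type=event.event_type,
                        overlap_bp=bp,
                    )
                )

    events_hit = {a.event_id for a in assignments}
    per_source: dict[str, tuple[int, int]] = {}
    for source in sorted({e.source for e in catalog}):
        evs = [e for e in catalog if e.source == source]
        per_source[source] = (sum(e.event_id in events_hit for e in evs), len(evs))

    result = MappingResult(
        assignments=assignments,
        per_source_event_counts=per_source,
        span_fraction={},
        mirnome_fraction=(len({a.mature_name for a in assignments}), len(mirnas)),
    )
    result.span_fraction = span_fraction(catalog, result)
    return result


def span_fraction(
    catalog: Sequence["AberrantRegion"], mapping: MappingResult
) -> dict[str, float | None]:
    """Per source: covered-base span of miRNA-bearing events / span of all events.

    Both numerator and denominator are merged unions, so overlapping events
    are not double-counted. A source with zero total span reports None.
    """
    events_hit = {a.event_id for a in mapping.assignments}
    fractions: dict[str, float | None] = {}
    for source in sorted({e.source for e in catalog}):
        evs = [e for e in catalog if e.source == source]
        denom = total_span([e.interval for e in evs])
        if denom == 0:
            fractions[source] = None
            continue
        numer = total_span([e.interval for e in evs if e.event_id in events_hit])
        fractions[source] = numer / denom
    return fractions


def split_by_event_type(
    mapping: MappingResult, catalog: Sequence["AberrantRegion"]
) -> tuple[set[str], set[str]]:
    """Deduplicated mature-name sets in amplified vs deleted events.

    The union is taken across both catalog sources: a miRNA found by both
    GISTIC and RAE counts once. A miRNA overlapping both an amplified and
    a deleted event lands in both sets and is logged.
    """
    amplified = {a.mature_name for a in mapping.assignments if a.event_type == "amplified"}
    deleted = {a.mature_name for a in mapping.assignments if a.event_type == "deleted"}
    both = amplified & deleted
    if both:
        logger.warning(
            "%d miRNA(s) overlap both amplified and deleted events: %s",
            len(both), ", ".join(sorted(both)),
        )
    return amplified, deleted
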