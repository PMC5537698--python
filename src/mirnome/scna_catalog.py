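"""SCNA event catalog and per-region sample burden.

The catalog of recurrent amplified/deleted regions (as produced by GISTIC or
RAE on a tumour cohort) is an *input* here, not something this package
recomputes. This module types the catalog, partitions it by source algorithm
and event direction, and counts, for a given region, how many distinct
samples carry a segment whose mean crosses a copy-number threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Literal, Sequence

from .intervals import GenomicInterval, overlap_bp, overlaps

if TYPE_CHECKING:  # pragma: no cover
    from .formats_io import RegionTableRow, SegmentRecord

logger = logging.getLogger(__name__)

EVENT_TYPES = ("amplified", "deleted")
SOURCES = ("GISTIC", "RAE")


@dataclass(frozen=True)
class AberrantRegion:
    """One recurrent copy-number event from a catalog algorithm."""

    event_id: str
    interval: GenomicInterval
    event_type: str  # "amplified" | "deleted"
    source: str  # "GISTIC" | "RAE"
    segments: tuple = field(default=(), compare=False)

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"event_type must be one of {EVENT_TYPES}, got {self.event_type!r}")
        if self.source not in SOURCES:
            raise ValueError(f"source must be one of {SOURCES}, got {self.source!r}")


@dataclass(frozen=True)
class BurdenResult:
    """Distinct-sample counts beyond each threshold for one region."""

    event_id: str
    thresholds: tuple[float, ...]
    counts: tuple[int, ...]
    direction: str = "below"

    def as_dict(self) -> dict:
        return {
            "event_id": self.event_id,
            "direction": self.direction,
            **{f"n_samples_{'lt' if self.direction == 'below' else 'gt'}_{t:g}": c
               for t, c in zip(self.thresholds, self.counts)},
        }


def load_catalog(rows: Sequence["RegionTableRow"]) -> list[AberrantRegion]:
    """Build typed events from region-table rows, dropping untyped rows.

    Rows whose event_type is neither amplified nor deleted carry no sign
    information and are rejected with a log entry rather than guessed at.
    """
    catalog: list[AberrantRegion] = []
    n_rejected = 0
    for row in rows:
        if row.event_type not in EVENT_TYPES:
            n_rejected += 1
            logger.warning(
                "rejecting catalog row %s: unknown event_type %r",
                row.event_id, row.event_type,
            )
            continue
        catalog.append(
            AberrantRegion(
                event_id=row.event_id,
                interval=row.interval,
                event_type=row.event_type,
                source=row.source,
            )
        )
    counts = partition_counts(catalog)
    logger.info("loaded %d events (%d rejected): %s", len(catalog), n_rejected, counts)
    return catalog


def partition_counts(catalog: Sequence[AberrantRegion]) -> dict[tuple[str, str], int]:
    """Event counts per (source, event_type) partition."""
    counts: dict[tuple[str, str], int] = {}
    for region in catalog:
        key = (region.source, region.event_type)
        counts[key] = counts.get(key, 0) + 1
    return counts


def region_sample_burden(
    region: AberrantRegion,
    segments: Sequence["SegmentRecord"],
    thresholds: Sequence[float],
    direction: Literal["below", "above"] = "below",
    mean_mode: Literal["segment", "weighted"] = "segment",
) -> BurdenResult:
    """Count distinct samples whose copy-number signal crosses each threshold.

    With ``mean_mode="segment"`` (default) a sample qualifies at threshold t
    if ANY of its segments overlapping the region has segment_mean strictly
    beyond t (``< t`` for direction="below", ``> t`` for "above") — the
    literal reading of "samples having a segment mean of < −0.3". With
    ``mean_mode="weighted"`` the sample's overlapping segments are first
    collapsed to one overlap-length-weighted mean.

    A sample with several qualifying segments is counted once.
    """
    if not thresholds:
        raise ValueError("thresholds must be nonempty")
    if direction not in ("below", "above"):
        raise ValueError(f"direction must be 'below' or 'above', got {direction!r}")
    if not segments:
        logger.warning("region %s: no segments supplied, burden is 0", region.event_id)

    # per-sample summary values to compare against each threshold
    per_sample: dict[str, list[tuple[float, int]]] = {}
    for seg in segments:
        bp = overlap_bp(seg.interval, region.interval)
        if bp > 0:
            per_sample.setdefault(seg.sample_id, []).append((seg.segment_mean, bp))

    counts = []
    for t in thresholds:
        n = 0
        for values in per_sample.values():
            if mean_mode == "weighted":
                wsum = sum(m * bp for m, bp in values)
                wtot = sum(bp for _, bp in values)
                qualifies = _beyond(wsum / wtot, t, direction)
            else:
                qualifies = any(_beyond(m, t, direction) for m, _ in values)
            n += qualifies
        counts.append(n)
    return BurdenResult(
        event_id=region.event_id,
        thresholds=tuple(float(t) for t in thresholds),
        counts=tuple(counts),
        direction=direction,
    )


def _beyond(value: float, threshold: float, direction: str) -> bool:
    return value < threshold if direction == "below" else value > threshold


def segments_in_region(
    region: AberrantRegion, segments: Sequence["SegmentRecord"]
) -> list["SegmentRecord"]:
    """Segments with any overlap with the region's interval."""
    return [s for s in segments if overlaps(s.interval, region.interval)]
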