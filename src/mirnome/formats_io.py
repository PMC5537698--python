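"""Readers and writers for every external format the pipeline touches.

Formats: hg19-style region strings ("chr10:127622813-135506681", tolerant of
the Unicode hyphens publication tables carry), SCNA region-catalog TSV,
SEG-like segment tables, miRBase-dialect GFF3, BED gene annotation,
differential-expression TSV, prediction-membership TSV, qPCR Ct CSV, and
TSV/JSON report output.

All readers are strict: malformed rows raise with the offending row/token
named rather than being silently coerced — a reader never returns fewer
records than rows without saying so.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import gffutils
import pandas as pd

from .intervals import GenomicInterval
from .mirnome_map import MiRNARecord
from .qpcr_quant import CtTable
from .shortlist import ExpressionStat, GeneRecord
from .target_triage import PredictionRecord

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """A file's content does not match its declared format."""


class RegionParseError(FormatError):
    """A region string could not be parsed into a genomic interval."""


# ASCII hyphen plus the Unicode hyphens/dashes publication tables use
_SEPARATORS = "-‐‑‒–—−"
_REGION_RE = re.compile(
    rf"^\s*(?P<chrom>[^:\s]+)\s*:\s*(?P<start>\d+)\s*[{_SEPARATORS}]\s*(?P<end>\d+)\s*$"
)


def parse_region_string(s: str) -> GenomicInterval:
    """Parse "<chrom>:<start>-<end>" into a 1-based inclusive interval.

    The chromosome name is preserved verbatim ("chr10" stays "chr10"); the
    start–end separator may be an ASCII hyphen, en-dash or Unicode hyphen.
    """
    m = _REGION_RE.match(s)
    if m is None:
        raise RegionParseError(
            f"malformed region string {s!r}: expected '<chrom>:<start>-<end>'"
        )
    start, end = int(m["start"]), int(m["end"])
    if start > end:
        raise RegionParseError(
            f"region {s!r}: start ({start}) exceeds end ({end})"
        )
    if start < 1:
        raise RegionParseError(f"region {s!r}: start must be >= 1")
    return GenomicInterval(chrom=m["chrom"], start=start, end=end)


def format_region_string(interval: GenomicInterval) -> str:
    """Canonical ASCII form; inverse of parse_region_string on valid input."""
    return f"{interval.chrom}:{interval.start}-{interval.end}"


@dataclass(frozen=True)
class RegionTableRow:
    event_id: str
    interval: GenomicInterval
    event_type: str  # "amplified" | "deleted" | "unknown"
    source: str  # "GISTIC" | "RAE"


@dataclass(frozen=True)
class SegmentRecord:
    """One per-sample segmented copy-number row (segment mean in log2 units)."""

    sample_id: str
    interval: GenomicInterval
    segment_mean: float


def _read_tsv(path, required: Sequence[str], sep: str = "\t") -> pd.DataFrame:
    frame = pd.read_csv(path, sep=sep, dtype=str)
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise FormatError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )
    return frame


def _numeric(frame: pd.DataFrame, column: str, path, allow_na: bool = False) -> pd.Series:
    values = pd.to_numeric(frame[column].replace({"NA": None, "": None}), errors="coerce")
    bad = frame.index[values.isna() & frame[column].notna()
                      & ~frame[column].isin(["NA", ""])]
    if len(bad):
        raise FormatError(
            f"{path}: non-numeric value in column {column!r} at row(s) "
            f"{', '.join(str(i + 2) for i in bad[:10])}"  # 1-based incl. header
        )
    if not allow_na and values.isna().any():
        bad = frame.index[values.isna()]
        raise FormatError(
            f"{path}: missing value in column {column!r} at row(s) "
            f"{', '.join(str(i + 2) for i in bad[:10])}"
        )
    return values


def read_region_table(path) -> list[RegionTableRow]:
    """SCNA catalog TSV: columns event_id, region, event_type, source."""
    frame = _read_tsv(path, ["event_id", "region", "event_type", "source"])
    rows = []
    for i, rec in frame.iterrows():
        etype = str(rec["event_type"]).strip().lower()
        if etype not in ("amplified", "deleted"):
            etype = "unknown"
        rows.append(
            RegionTableRow(
                event_id=str(rec["event_id"]),
                interval=parse_region_string(str(rec["region"])),
                event_type=etype,
                source=str(rec["source"]).strip(),
            )
        )
    return rows


def read_seg(path) -> list[SegmentRecord]:
    """SEG-like TSV: columns sample, chrom, start, end, segment_mean."""
    frame = _read_tsv(path, ["sample", "chrom", "start", "end", "segment_mean"])
    starts = _numeric(frame, "start", path)
    ends = _numeric(frame, "end", path)
    means = _numeric(frame, "segment_mean", path)
    records = []
    for i in frame.index:
        records.append(
            SegmentRecord(
                sample_id=str(frame.at[i, "sample"]),
                interval=GenomicInterval(
                    chrom=str(frame.at[i, "chrom"]),
                    start=int(starts[i]),
                    end=int(ends[i]),
                ),
                segment_mean=float(means[i]),
            )
        )
    return records


def write_seg(records: Sequence[SegmentRecord], path) -> None:
    frame = pd.DataFrame(
        {
            "sample": [r.sample_id for r in records],
            "chrom": [r.interval.chrom for r in records],
            "start": [r.interval.start for r in records],
            "end": [r.interval.end for r in records],
            "segment_mean": [f"{r.segment_mean:.6g}" for r in records],
        }
    )
    frame.to_csv(path, sep="\t", index=False)


def read_mirna_gff3(path) -> list[MiRNARecord]:
    """miRBase-dialect GFF3: miRNA_primary_transcript + miRNA features.

    Each mature miRNA feature is linked to its precursor via the
    Derives_from attribute. Matures whose precursor link is missing or
    dangling are retained with a null precursor and logged. Duplicate
    mature IDs are an error (the annotation is corrupt).
    """
    precursors: dict[str, tuple[str, GenomicInterval]] = {}
    matures: list[tuple[str, str, GenomicInterval, str | None]] = []
    n_features = 0
    try:
        for feat in gffutils.DataIterator(str(path)):
            n_features += 1
            iv = GenomicInterval(
                chrom=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand if feat.strand in ("+", "-") else ".",
            )
            fid = feat.attributes.get("ID", [None])[0]
            name = feat.attributes.get("Name", [fid])[0] or fid
            if feat.featuretype == "miRNA_primary_transcript":
                precursors[fid] = (name, iv)
            elif feat.featuretype == "miRNA":
                derives = feat.attributes.get("Derives_from", [None])[0]
                matures.append((fid, name, iv, derives))
    except Exception as exc:  # noqa: BLE001 - gffutils raises various types
        raise FormatError(f"{path}: not parseable as GFF3 ({exc})") from exc
    if n_features == 0:
        raise FormatError(f"{path}: no GFF3 features found")

    seen: dict[str, int] = {}
    for fid, *_ in matures:
        seen[fid] = seen.get(fid, 0) + 1
    dupes = sorted(k for k, v in seen.items() if v > 1)
    if dupes:
        raise FormatError(f"{path}: duplicate mature miRNA ID(s): {', '.join(dupes)}")

    records: list[MiRNARecord] = []
    for fid, name, iv, derives in matures:
        if derives is None:
            logger.warning("mature miRNA %s has no Derives_from link", name)
            pname, piv = None, None
        elif derives not in precursors:
            logger.warning("mature miRNA %s links to unknown precursor %s", name, derives)
            pname, piv = None, None
        else:
            pname, piv = precursors[derives]
        records.append(
            MiRNARecord(
                mature_name=name,
                mature_interval=iv,
                precursor_name=pname,
                precursor_interval=piv,
            )
        )
    return records


def read_genes_bed(path) -> list[GeneRecord]:
    """BED (>= 4 columns; strand read from column 6 when present).

    BED starts are 0-based half-open and are converted to the package's
    1-based inclusive convention.
    """
    frame = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if frame.shape[1] < 4:
        raise FormatError(f"{path}: BED gene annotation needs >= 4 columns (name in col 4)")
    records = []
    for i, rec in frame.iterrows():
        strand = rec[5] if frame.shape[1] >= 6 and rec[5] in ("+", "-") else "."
        try:
            start, end = int(rec[1]), int(rec[2])
        except ValueError as exc:
            raise FormatError(f"{path}: non-integer BED coordinate at row {i + 1}") from exc
        records.append(
            GeneRecord(
                symbol=str(rec[3]),
                interval=GenomicInterval(chrom=str(rec[0]), start=start + 1,
                                         end=end, strand=strand),
            )
        )
    return records


def write_genes_bed(genes: Sequence[GeneRecord], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(
                f"{g.interval.chrom}\t{g.interval.start - 1}\t{g.interval.end}"
                f"\t{g.symbol}\t0\t{g.interval.strand if g.interval.strand != '.' else '+'}\n"
            )


def read_de_table(path, cohort: str, compute_bh: bool = False) -> list[ExpressionStat]:
    """Differential-expression TSV: columns gene, log2fc, p, adj_p.

    ``adj_p`` must be precomputed unless ``compute_bh=True``, in which case
    Benjamini–Hochberg adjustment is applied to the raw p column — the
    caller must ask for it explicitly so adjusted and raw significance are
    never mixed by accident.
    """
    frame = _read_tsv(path, ["gene", "log2fc", "p"])
    if "adj_p" not in frame.columns:
        if not compute_bh:
            raise FormatError(
                f"{path}: column 'adj_p' is missing; supply BH-adjusted p-values "
                "or pass compute_bh=True to adjust the raw p column"
            )
        from statsmodels.stats.multitest import multipletests

        praw = _numeric(frame, "p", path, allow_na=True)
        adj = pd.Series(index=frame.index, dtype=float)
        ok = praw.notna()
        if ok.any():
            adj[ok] = multipletests(praw[ok], method="fdr_bh")[1]
        frame["adj_p"] = adj
    log2fc = _numeric(frame, "log2fc", path, allow_na=True)
    p = _numeric(frame, "p", path, allow_na=True)
    adj_p = _numeric(frame, "adj_p", path, allow_na=True)
    return [
        ExpressionStat(
            entity=str(frame.at[i, "gene"]),
            log2fc=None if pd.isna(log2fc[i]) else float(log2fc[i]),
            p=None if pd.isna(p[i]) else float(p[i]),
            adj_p=None if pd.isna(adj_p[i]) else float(adj_p[i]),
            cohort=cohort,
        )
        for i in frame.index
    ]


def write_de_table(stats: Sequence[ExpressionStat], path) -> None:
    frame = pd.DataFrame(
        {
            "gene": [s.entity for s in stats],
            "log2fc": [("NA" if s.log2fc is None else f"{s.log2fc:.6g}") for s in stats],
            "p": [("NA" if s.p is None else f"{s.p:.6g}") for s in stats],
            "adj_p": [("NA" if s.adj_p is None else f"{s.adj_p:.6g}") for s in stats],
        }
    )
    frame.to_csv(path, sep="\t", index=False)


def read_ct_table(path) -> CtTable:
    """qPCR Ct CSV: columns sample, group, assay, replicate, ct."""
    frame = pd.read_csv(path, dtype={"sample": str, "group": str, "assay": str})
    missing = [c for c in ("sample", "group", "assay", "replicate", "ct")
               if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    try:
        return CtTable(frame)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def read_predictions(path) -> list[PredictionRecord]:
    """Prediction-membership TSV: columns gene, algorithm (one row per hit)."""
    frame = _read_tsv(path, ["gene", "algorithm"])
    hits: dict[str, set[str]] = {}
    for _, rec in frame.iterrows():
        hits.setdefault(str(rec["gene"]), set()).add(str(rec["algorithm"]))
    return [
        PredictionRecord(gene=g, algorithms_hit=frozenset(a))
        for g, a in sorted(hits.items())
    ]


def write_table(frame: pd.DataFrame, path, columns: Sequence[str] | None = None) -> None:
    """TSV writer with a fixed, explicit column order."""
    if columns is not None:
        frame = frame[list(columns)]
    frame.to_csv(path, sep="\t", index=False)


def write_report(results: dict, path) -> None:
    """JSON summary report (sorted keys, stable across runs)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(results, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")


def read_report(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def _jsonable(obj):
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, GenomicInterval):
        return format_region_string(obj)
    if hasattr(obj, "__dataclass_fields__"):
        from dataclasses import asdict

        return asdict(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")
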