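"""Synthetic inputs with planted ground truth for every pipeline stage.

The generator emulates the data classes the pipeline consumes in a real
study: a genome with non-overlapping genes and intragenic/intergenic
miRNAs (some intragenic ones antisense to their host, the configuration a
host/miRNA co-deletion analysis must handle); an SCNA catalog of planted
amplified/deleted events with per-sample segment profiles; tumour-vs-control
differential expression coupled to copy number; qPCR Ct tables derived from
planted copy states; and a miRNA-overexpression experiment with planted
true targets plus in-silico prediction membership.

Every dataset is a pure function of (parameters, seed) and the ground
truth is serialized alongside, so recovery tests never re-derive it.

Default condition choices (why these numbers):

* chromosome/gene/miRNA counts are desk-scale but large enough that
  mapping fractions, burden and shortlisting are nontrivial;
* segment-mean effects are ±0.5 so the conventional −0.3 / −0.5 deletion
  thresholds bracket the deletion mean and burden monotonicity is
  exercised on both sides;
* the copy-number qPCR plants a single-copy (heterozygous) loss, the
  analytically forced log2 ratio of −1;
* the tumour/control expression cohort is 72 vs 16, the cohort size a
  GBM tissue study of this kind typically accrues;
* the overexpression funnel defaults (33 down, 12 predicted targets,
  4 tumour-upregulated) keep every funnel stage strictly smaller than the
  previous one.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats as sps

from .formats_io import (
    SegmentRecord,
    format_region_string,
    write_de_table,
    write_genes_bed,
    write_seg,
)
from .intervals import GenomicInterval, overlaps
from .mirnome_map import MiRNARecord
from .qpcr_quant import CtTable
from .scna_catalog import AberrantRegion
from .shortlist import ExpressionStat, GeneRecord
from .target_triage import DEGene, PredictionRecord

PREDICTION_ALGORITHMS = (
    "miRWalk", "MicroT4", "miRanda", "miRBridge", "miRDB", "miRMap",
    "miRNAMap", "PICTAR2", "PITA", "RNA22", "RNAhybrid", "Targetscan",
)


@dataclass
class SyntheticTruth:
    """Everything the generator planted, reproducible from (params, seed)."""

    seed: int
    genome: list[tuple[str, int]] = field(default_factory=list)
    genes: list[GeneRecord] = field(default_factory=list)
    mirnas: list[MiRNARecord] = field(default_factory=list)
    hosts: dict[str, str] = field(default_factory=dict)  # mature -> host symbol
    events: list[AberrantRegion] = field(default_factory=list)
    carriers: dict[str, list[str]] = field(default_factory=dict)  # event_id -> samples
    event_mirnas: dict[str, list[str]] = field(default_factory=dict)
    amp_mirnas: set[str] = field(default_factory=set)
    del_mirnas: set[str] = field(default_factory=set)
    mean_amp: float = 0.5
    mean_del: float = -0.5
    planted_lfc: dict[str, float] = field(default_factory=dict)
    coupling: float | None = None
    noise_sd: float | None = None
    ct_carriers: list[str] = field(default_factory=list)
    oe: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        def enc(o):
            if isinstance(o, GenomicInterval):
                return {"chrom": o.chrom, "start": o.start, "end": o.end,
                        "strand": o.strand}
            if isinstance(o, (set, frozenset)):
                return sorted(o)
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            raise TypeError(type(o))

        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True,
                      default=enc)
            fh.write("\n")


def make_genome_and_annotation(
    n_chroms: int = 4,
    n_genes: int = 60,
    n_mirnas: int = 40,
    frac_intragenic: float = 0.5,
    chrom_length: int = 1_000_000,
    seed: int = 0,
) -> SyntheticTruth:
    """Place non-overlapping genes and intragenic/intergenic miRNAs.

    Intragenic miRNAs sit in a gene's interior (its "intron" for the
    purposes of containment), with roughly half placed on the strand
    opposite the host. Host assignments are recorded in the truth.
    """
    if not (0.0 <= frac_intragenic <= 1.0):
        raise ValueError("frac_intragenic must be in [0, 1]")
    rng = np.random.default_rng(seed)
    truth = SyntheticTruth(seed=seed)
    truth.genome = [(f"chr{i + 1}", chrom_length) for i in range(n_chroms)]

    # genes laid down left to right with random gaps; error if they spill over
    genes: list[GeneRecord] = []
    per_chrom = [n_genes // n_chroms + (i < n_genes % n_chroms) for i in range(n_chroms)]
    for (chrom, length), n_here in zip(truth.genome, per_chrom):
        cursor = 1
        for j in range(n_here):
            cursor += int(rng.integers(2_000, 15_000))
            glen = int(rng.integers(6_000, 20_000))
            if cursor + glen - 1 > length:
                raise ValueError(
                    f"requested genes exceed capacity of {chrom} ({length} bp)"
                )
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneRecord(
                symbol=f"GENE{len(genes) + 1:03d}",
                interval=GenomicInterval(chrom, cursor, cursor + glen - 1, strand),
            ))
            cursor += glen
    truth.genes = genes

    n_intra = round(n_mirnas * frac_intragenic)
    mirnas: list[MiRNARecord] = []
    host_order = rng.permutation(len(genes))
    for i in range(n_mirnas):
        name = f"syn-miR-{i + 1}"
        pre_name = f"syn-mir-{i + 1}"
        if i < n_intra:
            host = genes[int(host_order[i % len(genes)])]
            margin = 500
            lo = host.interval.start + margin
            hi = host.interval.end - margin - 100
            pstart = int(rng.integers(lo, hi))
            # half of the intragenic miRNAs sit antisense to their host
            if rng.random() < 0.5:
                strand = "+" if host.interval.strand == "-" else "-"
            else:
                strand = host.interval.strand
            host_symbol = host.symbol
        else:
            # intergenic: drop into a gap between genes on a random chromosome
            chrom, length = truth.genome[int(rng.integers(0, n_chroms))]
            occupied = sorted(
                (g.interval.start, g.interval.end)
                for g in genes if g.interval.chrom == chrom
            )
            gaps = []
            prev = 1
            for s, e in occupied:
                if s - prev > 300:
                    gaps.append((prev, s - 1))
                prev = e + 1
            if length - prev > 300:
                gaps.append((prev, length))
            if not gaps:
                raise ValueError(f"no intergenic space left on {chrom}")
            gs, ge = gaps[int(rng.integers(0, len(gaps)))]
            pstart = int(rng.integers(gs + 100, ge - 200))
            strand = "+" if rng.random() < 0.5 else "-"
            host_symbol = None
        pre_iv = GenomicInterval(
            chrom if i >= n_intra else host.interval.chrom,
            pstart, pstart + 79, strand,
        )
        mstart = pstart + int(rng.integers(5, 50))
        mat_iv = GenomicInterval(pre_iv.chrom, mstart, mstart + 21, strand)
        mirnas.append(MiRNARecord(
            mature_name=name,
            mature_interval=mat_iv,
            precursor_name=pre_name,
            precursor_interval=pre_iv,
            host_gene=host_symbol,
        ))
        if host_symbol is not None:
            truth.hosts[name] = host_symbol
    truth.mirnas = mirnas
    return truth


def make_scna_events(
    truth: SyntheticTruth,
    n_events: int = 12,
    min_len: int = 30_000,
    max_len: int = 200_000,
    seed: int | None = None,
) -> list[AberrantRegion]:
    """Plant an SCNA catalog: alternating amplified/deleted events.

    Sources alternate GISTIC/RAE so both per-source statistics are
    exercised. Planted in-event miRNAs (by mature-interval overlap) and
    the amplified/deleted miRNA split are recorded in the truth.
    """
    rng = np.random.default_rng(truth.seed + 1 if seed is None else seed)
    events: list[AberrantRegion] = []
    for i in range(n_events):
        event_type = "amplified" if i % 2 == 0 else "deleted"
        # same-type events never overlap (each sample's planted copy state at
        # a locus is then unambiguous); opposite-type events may
        for _ in range(200):
            chrom, length = truth.genome[int(rng.integers(0, len(truth.genome)))]
            elen = int(rng.integers(min_len, max_len))
            start = int(rng.integers(1, max(2, length - elen)))
            iv = GenomicInterval(chrom, start, start + elen - 1)
            if not any(overlaps(iv, e.interval) for e in events
                       if e.event_type == event_type):
                break
        else:
            raise ValueError("could not place non-overlapping events; genome too small")
        events.append(AberrantRegion(
            event_id=f"EV{i + 1:02d}",
            interval=iv,
            event_type=event_type,
            source="GISTIC" if i % 4 < 2 else "RAE",
        ))
    truth.events = events
    truth.event_mirnas = {
        e.event_id: sorted(
            m.mature_name for m in truth.mirnas
            if overlaps(m.mature_interval, e.interval)
        )
        for e in events
    }
    truth.amp_mirnas = {
        n for e in events if e.event_type == "amplified"
        for n in truth.event_mirnas[e.event_id]
    }
    truth.del_mirnas = {
        n for e in events if e.event_type == "deleted"
        for n in truth.event_mirnas[e.event_id]
    }
    return events


def make_scna_profiles(
    truth: SyntheticTruth,
    n_samples: int = 200,
    carrier_frac: float = 0.3,
    mean_amp: float = 0.5,
    mean_del: float = -0.5,
    noise_sd: float = 0.1,
    seed: int | None = None,
) -> list[SegmentRecord]:
    """Per-sample segmented profiles over the planted events.

    Each carrier sample gets a segment at the event's exact span with
    segment_mean ~ Normal(event mean, noise_sd); every sample additionally
    carries whole-chromosome background segments ~ Normal(0, noise_sd).
    Carrier lists per event are recorded in the truth.
    """
    if not (0.0 < carrier_frac <= 1.0):
        raise ValueError("carrier_frac must be in (0, 1]")
    if not truth.events:
        raise ValueError("no planted events; call make_scna_events first")
    rng = np.random.default_rng(truth.seed + 2 if seed is None else seed)
    truth.mean_amp, truth.mean_del = mean_amp, mean_del
    samples = [f"S{i + 1:03d}" for i in range(n_samples)]
    n_carriers = max(1, round(carrier_frac * n_samples))

    records: list[SegmentRecord] = []
    for sample in samples:
        for chrom, length in truth.genome:
            records.append(SegmentRecord(
                sample_id=sample,
                interval=GenomicInterval(chrom, 1, length),
                segment_mean=float(rng.normal(0.0, noise_sd)) if noise_sd > 0 else 0.0,
            ))
    for event in truth.events:
        chosen = sorted(rng.choice(len(samples), size=n_carriers, replace=False))
        carrier_ids = [samples[i] for i in chosen]
        truth.carriers[event.event_id] = carrier_ids
        mean = mean_amp if event.event_type == "amplified" else mean_del
        for sid in carrier_ids:
            records.append(SegmentRecord(
                sample_id=sid,
                interval=event.interval,
                segment_mean=float(rng.normal(mean, noise_sd)) if noise_sd > 0 else mean,
            ))
    records.sort(key=lambda r: (r.sample_id, r.interval.chrom, r.interval.start))
    return records


def _planted_lfc(truth: SyntheticTruth, coupling: float) -> dict[str, float]:
    """Copy-number-coupled planted log2FCs for every gene and miRNA."""
    lfc: dict[str, float] = {}
    entities = [(m.mature_name, m.mature_interval) for m in truth.mirnas]
    entities += [(g.symbol, g.interval) for g in truth.genes]
    for name, iv in entities:
        effect = 0.0
        for e in truth.events:
            if overlaps(iv, e.interval):
                mean = truth.mean_amp if e.event_type == "amplified" else truth.mean_del
                effect += coupling * mean
        lfc[name] = effect
    return lfc


def _simulate_de(
    planted: dict[str, float],
    n_tumour: int,
    n_control: int,
    noise_sd: float,
    rng: np.random.Generator,
    cohort: str,
) -> list[ExpressionStat]:
    """Two-group per-entity simulation -> log2FC, t-test p, BH-adjusted p.

    At noise_sd = 0 a t-test is degenerate (zero variance), so p is set to
    0 for entities with a planted effect and 1 otherwise; this is what
    makes zero-noise recovery exact.
    """
    names = sorted(planted)
    log2fc, praw = [], []
    for name in names:
        mu = planted[name]
        if noise_sd == 0:
            log2fc.append(mu)
            praw.append(0.0 if mu != 0 else 1.0)
        else:
            t_vals = rng.normal(mu, noise_sd, size=n_tumour)
            c_vals = rng.normal(0.0, noise_sd, size=n_control)
            log2fc.append(float(t_vals.mean() - c_vals.mean()))
            praw.append(float(sps.ttest_ind(t_vals, c_vals, equal_var=True).pvalue))
    if noise_sd == 0:
        adj = list(praw)
    else:
        from statsmodels.stats.multitest import multipletests

        adj = list(multipletests(praw, method="fdr_bh")[1])
    return [
        ExpressionStat(entity=n, log2fc=f, p=p, adj_p=a, cohort=cohort)
        for n, f, p, a in zip(names, log2fc, praw, adj)
    ]


def make_expression(
    truth: SyntheticTruth,
    n_tumour: int = 72,
    n_control: int = 16,
    coupling: float = 2.0,
    noise_sd: float = 0.2,
    seed: int | None = None,
    cohort: str = "synthetic-cohort",
) -> list[ExpressionStat]:
    """Tumour-vs-control DE stats with copy-number-coupled planted shifts.

    Entities inside deleted events receive planted log2FC =
    coupling x mean_del (mirrored for amplified ones); everything else 0.
    """
    rng = np.random.default_rng(truth.seed + 3 if seed is None else seed)
    truth.coupling, truth.noise_sd = coupling, noise_sd
    truth.planted_lfc = _planted_lfc(truth, coupling)
    return _simulate_de(truth.planted_lfc, n_tumour, n_control, noise_sd, rng, cohort)


def make_ct(
    truth: SyntheticTruth,
    assays: tuple[str, ...] = ("MIR-LOCUS", "HOST-LOCUS"),
    references: tuple[str, ...] = ("REF-LOCUS",),
    n_tumour: int = 50,
    n_control: int = 10,
    carrier_frac: float = 1.0,
    sd_ct: float = 0.1,
    n_replicates: int = 2,
    seed: int | None = None,
) -> CtTable:
    """Ct table from planted copy states: Ct = base − log2(copies) + noise.

    Tumour carriers hold a single-copy loss (copies = 1) at ALL target
    assays simultaneously — the co-deletion configuration — while reference
    assays are copy-neutral everywhere. Controls are diploid throughout,
    so a carrier's expected log2 ratio is exactly −1.
    """
    import pandas as pd

    rng = np.random.default_rng(truth.seed + 4 if seed is None else seed)
    base = {a: float(rng.uniform(22.0, 30.0)) for a in [*assays, *references]}
    samples = (
        [(f"T{i + 1:03d}", "tumour") for i in range(n_tumour)]
        + [(f"C{i + 1:03d}", "control") for i in range(n_control)]
    )
    carriers = [
        sid for sid, grp in samples
        if grp == "tumour" and rng.random() < carrier_frac
    ]
    truth.ct_carriers = carriers
    carrier_set = set(carriers)

    rows = []
    for sid, grp in samples:
        for assay in [*assays, *references]:
            if assay in references:
                copies = 2
            else:
                copies = 1 if sid in carrier_set else 2
            mu = base[assay] - np.log2(copies)
            for rep in range(1, n_replicates + 1):
                ct = mu + (rng.normal(0.0, sd_ct) if sd_ct > 0 else 0.0)
                rows.append((sid, grp, assay, rep, float(ct)))
    frame = pd.DataFrame(rows, columns=["sample", "group", "assay", "replicate", "ct"])
    return CtTable(frame)


def make_overexpression(
    truth: SyntheticTruth,
    n_targets: int = 12,
    n_down_extra: int = 21,
    n_up: int = 10,
    n_gbm_up: int = 4,
    target_lfc: float = -0.8,
    predicted_sensitivity: float = 1.0,
    n_decoy_predictions: int = 10,
    noise_sd: float = 0.0,
    n_reps: int = 3,
    seed: int | None = None,
) -> tuple[list[DEGene], list[DEGene], list[PredictionRecord], list[ExpressionStat]]:
    """Overexpression transcriptome + prediction membership + tumour stats.

    True targets are downregulated (planted log2FC = target_lfc) at both
    timepoints; extra down and up genes are split between the timepoints so
    the cross-timepoint union is nontrivial. The prediction table contains
    each true target with probability predicted_sensitivity, plus decoys
    drawn from non-downregulated genes; n_gbm_up of the targets are planted
    as significantly upregulated in the tumour cohort.
    """
    rng = np.random.default_rng(truth.seed + 5 if seed is None else seed)
    universe = [g.symbol for g in truth.genes]
    needed = n_targets + n_down_extra + n_up + n_decoy_predictions
    if needed > len(universe):
        raise ValueError(
            f"need {needed} distinct genes but the annotation has {len(universe)}"
        )
    order = [universe[i] for i in rng.permutation(len(universe))]
    targets = order[:n_targets]
    extra = order[n_targets:n_targets + n_down_extra]
    ups = order[n_targets + n_down_extra:n_targets + n_down_extra + n_up]
    decoy_pool = order[n_targets + n_down_extra + n_up:]

    extra_48, extra_72 = extra[: (n_down_extra + 1) // 2], extra[(n_down_extra + 1) // 2:]
    up_48, up_72 = ups[: (n_up + 1) // 2], ups[(n_up + 1) // 2:]
    down_48 = set(targets) | set(extra_48)
    down_72 = set(targets) | set(extra_72)

    def de_table(down: set[str], up: set[str], timepoint: str) -> list[DEGene]:
        planted = {
            g: (target_lfc if g in down else (-target_lfc if g in up else 0.0))
            for g in universe
        }
        stats = _simulate_de(planted, n_reps, n_reps, noise_sd, rng,
                             cohort=f"overexpression-{timepoint}")
        return [
            DEGene(gene=s.entity, log2fc=s.log2fc, p=s.p, adj_p=s.adj_p,
                   timepoint=timepoint)
            for s in stats
        ]

    de48 = de_table(down_48, set(up_48), "48h")
    de72 = de_table(down_72, set(up_72), "72h")

    predicted_targets = [
        t for t in targets if rng.random() < predicted_sensitivity
    ]
    decoys = decoy_pool[:n_decoy_predictions]
    predictions = [
        PredictionRecord(
            gene=g,
            algorithms_hit=frozenset(
                rng.choice(PREDICTION_ALGORITHMS,
                           size=int(rng.integers(2, 6)), replace=False).tolist()
            ),
        )
        for g in sorted([*predicted_targets, *decoys])
    ]

    gbm_up = sorted(predicted_targets)[:n_gbm_up]
    gbm_stats = [
        ExpressionStat(
            entity=g,
            log2fc=1.2 if g in gbm_up else 0.0,
            p=1e-5 if g in gbm_up else 0.9,
            adj_p=1e-4 if g in gbm_up else 0.95,
            cohort="synthetic-tumour",
        )
        for g in universe
    ]

    truth.oe = {
        "targets": sorted(targets),
        "down_48": sorted(down_48),
        "down_72": sorted(down_72),
        "up_48": sorted(up_48),
        "up_72": sorted(up_72),
        "union_down": sorted(down_48 | down_72),
        "predicted_targets": sorted(predicted_targets),
        "gbm_up": gbm_up,
        "target_lfc": target_lfc,
    }
    return de48, de72, predictions, gbm_stats


def write_mirna_gff3(mirnas: list[MiRNARecord], path) -> None:
    """miRBase-dialect GFF3 writer (round-trips through formats_io)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        seen_pre: set[str] = set()
        for m in mirnas:
            if m.precursor_name and m.precursor_name not in seen_pre:
                seen_pre.add(m.precursor_name)
                p = m.precursor_interval
                fh.write(
                    f"{p.chrom}\t.\tmiRNA_primary_transcript\t{p.start}\t{p.end}"
                    f"\t.\t{p.strand if p.strand != '.' else '+'}\t.\t"
                    f"ID={m.precursor_name};Name={m.precursor_name}\n"
                )
            iv = m.mature_interval
            derives = f";Derives_from={m.precursor_name}" if m.precursor_name else ""
            fh.write(
                f"{iv.chrom}\t.\tmiRNA\t{iv.start}\t{iv.end}\t.\t"
                f"{iv.strand if iv.strand != '.' else '+'}\t.\t"
                f"ID={m.mature_name};Name={m.mature_name}{derives}\n"
            )


def simulate_study(outdir, seed: int = 0, **params) -> dict[str, str]:
    """Generate and write a complete synthetic study; returns file paths.

    Files: annotation (GFF3 + BED), region catalog TSV, SEG profiles,
    tumour-vs-control DE TSV, Ct CSV, overexpression DE TSVs,
    prediction-membership TSV, tumour-cohort stats TSV and truth JSON.
    Identical (params, seed) produce byte-identical files.
    """
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    truth = make_genome_and_annotation(
        n_chroms=params.get("n_chroms", 4),
        n_genes=params.get("n_genes", 60),
        n_mirnas=params.get("n_mirnas", 40),
        frac_intragenic=params.get("frac_intragenic", 0.5),
        seed=seed,
    )
    make_scna_events(truth, n_events=params.get("n_events", 12))
    segments = make_scna_profiles(
        truth,
        n_samples=params.get("n_samples", 200),
        carrier_frac=params.get("carrier_frac", 0.3),
        noise_sd=params.get("scna_noise_sd", 0.1),
    )
    expr = make_expression(
        truth,
        n_tumour=params.get("n_tumour", 72),
        n_control=params.get("n_control", 16),
        coupling=params.get("coupling", 2.0),
        noise_sd=params.get("expr_noise_sd", 0.2),
    )
    ct = make_ct(truth, sd_ct=params.get("sd_ct", 0.1))
    de48, de72, preds, gbm_stats = make_overexpression(
        truth, noise_sd=params.get("oe_noise_sd", 0.0)
    )

    paths = {k: str(outdir / v) for k, v in {
        "gff3": "mirna_annotation.gff3",
        "bed": "genes.bed",
        "catalog": "scna_catalog.tsv",
        "seg": "segments.seg",
        "de": "expression_de.tsv",
        "ct": "ct_table.csv",
        "oe_48h": "overexpression_48h.tsv",
        "oe_72h": "overexpression_72h.tsv",
        "predictions": "predictions.tsv",
        "gbm_stats": "tumour_cohort_de.tsv",
        "truth": "truth.json",
    }.items()}

    write_mirna_gff3(truth.mirnas, paths["gff3"])
    write_genes_bed(truth.genes, paths["bed"])
    pd.DataFrame({
        "event_id": [e.event_id for e in truth.events],
        "region": [format_region_string(e.interval) for e in truth.events],
        "event_type": [e.event_type for e in truth.events],
        "source": [e.source for e in truth.events],
    }).to_csv(paths["catalog"], sep="\t", index=False)
    write_seg(segments, paths["seg"])
    write_de_table(expr, paths["de"])
    ct.frame.to_csv(paths["ct"], index=False)
    for de, key in ((de48, "oe_48h"), (de72, "oe_72h")):
        write_de_table(
            [ExpressionStat(entity=g.gene, log2fc=g.log2fc, p=g.p,
                            adj_p=g.adj_p, cohort=key) for g in de],
            paths[key],
        )
    pd.DataFrame(
        [(p.gene, a) for p in preds for a in sorted(p.algorithms_hit)],
        columns=["gene", "algorithm"],
    ).to_csv(paths["predictions"], sep="\t", index=False)
    write_de_table(gbm_stats, paths["gbm_stats"])
    truth.to_json(paths["truth"])
    return paths
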