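# Methods

## Coordinate model and interval algebra

All external coordinates are 1-based and inclusive on both ends, matching
hg19 region strings ("chr10:127622813-135506681") and GFF3. Chromosome
names are compared as exact strings — "chr10" and "10" never match — so
annotations from different naming conventions fail loudly instead of
silently mixing. Strand is carried on every interval but ignored by
`overlaps` and `contains`: copy-number events are strand-agnostic, and an
intragenic miRNA may lie antisense to its host gene.

Two deliberate edge-case conventions under closed coordinates:

* `overlaps` requires at least one shared base, so (1–100) and (101–200)
  do **not** overlap;
* `merge` fuses abutting intervals (end + 1 == next start) because they
  cover one contiguous base run; consequently
  `total_span` counts every covered base exactly once and
  `total_span(merge(X)) == total_span(X)` always holds.

The whole algebra is validated against a per-base set-arithmetic oracle
(every base enumerated explicitly) on thousands of random instances with
coordinates ≤ 10⁴; the production code never enumerates bases.

## Mapping miRNAs onto the SCNA catalog

A miRNA "maps to" an aberrant region when its chosen locus shares
≥ `min_overlap_bp` bases with the region's interval. The default locus is
the **mature** product, because the headline miRNome denominators are
counted over mature miRNAs; precursor mode exists because locus copy-number
qPCR assays the precursor-encompassing region. `min_overlap_bp` defaults
to 1 — the most permissive reading of "located in" — and is exposed.

Three statistics are derived from the assignment set, per catalog source
(GISTIC and RAE region catalogs are inputs, never recomputed):

* event fraction — events with ≥ 1 miRNA over all events;
* span fraction — merged covered span of miRNA-bearing events over merged
  covered span of all events (merging prevents double-counting overlapping
  events; a source with zero span reports null);
* miRNome fraction — distinct mapped mature names over all matures.

The amplified/deleted miRNA split deduplicates by mature name across both
sources; a miRNA overlapping events of both types lands in both sets and is
logged, since its net copy-number state is cohort-dependent.

## Sample burden

For a region and a set of per-sample segments, the burden at threshold t is
the number of distinct samples with ≥ 1 overlapping segment whose own
segment mean is strictly beyond t. This is the literal reading of "samples
having a segment mean of < −0.3": the segment's mean is compared as-is, any
overlap qualifies, and a sample with several qualifying segments counts
once. An alternative (`mean_mode="weighted"`) first collapses each sample's
overlapping segments to an overlap-length-weighted mean; it is strictly
more conservative for samples whose deletion covers only part of the
region. Thresholding is strict (<, not ≤), which the tests pin down:
a planted mean of exactly −0.5 never crosses a −0.5 threshold.

## Concordance shortlist

The biological expectation is directional: miRNAs in deleted regions should
be down, in amplified regions up — in their own measurements or, for
intragenic miRNAs that many expression platforms do not probe, in their
host gene's. The rule is an OR across evidence channels and cohorts:
significant + sign-concordant in **any one** cohort suffices, and a
discordant result elsewhere does not veto (a miRNA whose own lab
measurement disagrees can still enter on host evidence). Significance is
BH-adjusted p < α where the cohort supplies adjusted values, raw p < α for
cohorts that publish only raw p; α defaults to 0.05. Entities whose stats
are all NA are dropped rather than guessed. The shortlist is therefore
monotone in α and always a subset of the input miRNA sets.

Host assignment: the gene whose span fully contains the miRNA's precursor
(mature, when no precursor is annotated), strand-agnostic; among multiple
containing genes the smallest span wins, with a symbol tie-break for
determinism. Partial overlap is not hosting.

The flanking check takes a locus gene and reports, for the k nearest genes
on each side (gap distance between spans, k = 2 by default), a per-cohort
expression verdict; the overall verdict is `not_regulated` unless every
significant cohort agrees in sign. A focal deletion should leave all
neighbours `not_regulated`.

## ΔΔCt quantification

Replicate Cts are averaged per (sample, assay). ΔCt = mean target Ct minus
the arithmetic mean of the reference assays' means — the simplest symmetric
multi-reference rule, which on the Ct scale already corresponds to the
geometric mean of reference template quantities; a geometric mean of the Ct
values themselves is available behind `reference_average="geometric"`. ΔΔCt subtracts the calibrator group's mean ΔCt — the control group
by default, so each sample's value is relative to average control — and the
reported log2 ratio is −ΔΔCt, assuming amplification efficiency 2 (the
standard ΔΔCt assumption; no efficiency estimation from dilution series is
attempted). Consequences the tests assert exactly: adding a constant to all
Cts changes nothing (location invariance); shifting only the target by one
cycle shifts the log2 ratio by exactly one; a single-copy loss against a
diploid calibrator reads −1.

Samples missing the target or any reference assay are skipped with a
warning — their normalization is undefined — and an empty calibrator group
is an error. Group comparison is a two-sided unpaired Student's t-test
(equal variances); locus–locus and miRNA–host association is Pearson's r
with a two-sided p, pairs with any missing value dropped pairwise, and the
coefficient reported as null when either vector is constant.

## Target triage

Stage 0: per-timepoint filter at log2FC ≤ −0.57 and BH-adjusted p < 0.05,
then the deduplicated union across timepoints. The magnitude cutoff (0.57)
and the significance filter are independently configurable (`alpha=None`
disables the p filter), since fold-change-only shortlists of this kind are
common. Note 0.57 is slightly below log2(1.5) ≈ 0.585; the default follows
the printed convention and is a parameter, not a constant. Stage 1
intersects with genes predicted by ≥ `min_algorithms` of the 12-algorithm
prediction panel (default 1 — union membership; predictions are consumed as
membership tables, never computed). Stage 2 requires significant
upregulation in ≥ 1 tumour cohort — the expected direction for a genuine
target of a miRNA the tumour has lost. Funnel sizes are logged at each
stage and are monotonically non-increasing by construction.

## Synthetic data: what it emulates, what it does not

The generator produces every input class the pipeline consumes, with the
truth serialized to JSON so tests compare against stored values rather than
re-deriving them:

* **Genome/annotation** — default 4 chromosomes × 1 Mb, 60 non-overlapping
  genes (6–20 kb), 40 miRNAs (80 bp precursor containing a 22 bp mature),
  half intragenic with ~half of those antisense to the host.
* **SCNA catalog + segments** — 12 events (30–200 kb), alternating
  amplified/deleted and GISTIC/RAE; same-type events never overlap (each
  sample's planted copy state at a locus is then unambiguous), opposite-type
  events may, which produces the miRNA-in-both-sets case. Carriers
  (default 30 % of 200 samples) get a segment at the event span with mean
  ~ Normal(±0.5, σ); everyone gets whole-chromosome background segments
  ~ Normal(0, σ). Effect means of ±0.5 make the conventional −0.3/−0.5
  thresholds bracket the deletion mean.
* **Expression** — tumour/control of 72/16 (a typical single-centre GBM
  tissue cohort); each entity's planted log2FC is coupling × (sum of the
  segment-mean effects of the events covering it), default coupling 2.0 so
  a deletion plants a log2FC of −1. Observed stats come from a per-entity
  two-sample simulation with a real t-test and BH adjustment.
* **Ct tables** — Ct = base(assay) − log2(copies) + Normal(0, σ_Ct), two
  replicates; target assays share a sample's copy state (the co-deletion
  configuration), references are copy-neutral, controls diploid.
* **Overexpression** — 12 true targets planted at log2FC −0.8 at both
  timepoints, 21 extra down and 10 up genes split between timepoints so the
  cross-timepoint union is nontrivial; prediction membership contains each
  target with probability `predicted_sensitivity` plus decoys from
  non-down genes; 4 targets are planted as tumour-upregulated, giving a
  strictly shrinking default funnel 33 → 12 → 4.

At zero noise every stage recovers the planted truth exactly; a t-test is
degenerate at zero variance, so the generator then sets p to 0 for planted
effects and 1 otherwise — this convention is what makes the recovery
theorem exact rather than approximate. Noise is Gaussian on the log2/Ct
scales throughout.

What the generator does **not** emulate — and hence what passing tests do
not certify about real data: segmentation artefacts and waviness in
copy-number profiles, GC/length biases, subclonal or fractional copy
states, correlated noise across genes, platform-specific expression
distributions, multi-mapping or cross-hybridizing miRNA probes, and qPCR
efficiency drift. Real-cohort analyses should treat the pipeline's
statistics as exact arithmetic on whatever its inputs are, with input
quality out of scope.

## Numerical and design choices

* Burden thresholds are strict inequalities; merge treats abutting
  intervals as contiguous; both choices are asserted in tests.
* All tie-breaks (host gene by span then symbol, best stat by p then
  cohort) are deterministic, so outputs are byte-reproducible; reports are
  JSON with sorted keys and no timestamps, and the CLI writes a manifest of
  parameters + input SHA-256 checksums.
* BH adjustment is never recomputed across pipeline stages: adjusted
  p-values travel with their source table, and the DE reader refuses a
  table without `adj_p` unless adjustment is explicitly requested.
* Readers reject malformed rows with the offending row/token named;
  region-string parsing tolerates the Unicode hyphens and dashes that
  publication tables carry.
* The acceptance script measures statistical quantities (ΔΔCt bias,
  co-deletion r) over 20 replicate simulations at σ = 0.1 and n = 50
  samples — bias is an expectation, so it is estimated by averaging
  replicates, not from a single draw.

## Known limitations

* The catalog is consumed, not computed: no GISTIC/RAE reimplementation,
  no significance model for recurrence.
* No liftover; mixed-assembly inputs are the caller's error (and will
  usually surface as zero overlap, not an exception).
* ΔΔCt assumes 100 % efficiency; efficiency calibration from dilution
  series is out of scope.
* The flanking check's distance is span-gap distance, ignoring
  transcription start sites and orientation-specific promoter sharing.
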