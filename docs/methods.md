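# Methods

## The measurement idea

In vitro transcribed (IVT) RNAs are synthesized from fully sequenced cDNA
templates, so their sequence content is known exactly and — unlike cellular
RNA — they are untouched by splicing or post-transcriptional regulation.
Sequenced to sufficient depth, such transcripts should show near-uniform
read coverage; any reproducible structure in their coverage is technical
bias from library construction and sequencing. `covbias` quantifies that
bias at three levels:

1. **Within a transcript** — the fold change between the best- and
   worst-covered deciles of bases, the base-level coefficient of variation
   (CV), and the 3'/5' processivity ratio.
2. **Between samples** — regions of high, unpredictable coverage ("hunc"
   regions) whose depth varies extremely across a dilution series of
   IVT:background mixing ratios, reproducibly in both replicates.
3. **Against sequence features** — rank-based association of coverage
   variability with hexamer entropy, GC content, and similarity to
   ribosomal RNA.

## Coverage statistics

All statistics operate on per-base depth vectors in transcript space
(5'→3'), obtained by projecting genome-space bedGraph coverage through
BED12 exon structures. Coordinates are 0-based, half-open throughout.

**FPKM** is fragments (read pairs) per kilobase of exon per million mapped
fragments; detection means FPKM ≥ 5.

**Within-transcript fold change.** The first and last 200 bases are
trimmed (fragmentation edge artifacts); transcripts under 500 bases are
excluded. The remaining depths are sorted and the mean of the top decile
bin (highest ⌊n/10⌋ bases) is divided by the mean of the bottom decile
bin. Interpreting the 10th/90th "percentile average" as decile-bin means is
one of two defensible readings; the alternative (mean of all values at or
beyond the interpolated percentile cut) is available as
`MetricsConfig(fc_mode="cutoff")` and coincides with the default on the
worked examples. A bottom-decile mean of zero yields `inf`, which counts
in every `>k` summary bucket. Summary counts are strictly-greater-than and
nested: a transcript above 100 also counts above 10 and above 2.

**Processivity.** Mean depth over the fractional window [0.85 L, 0.95 L)
divided by mean depth over [0.05 L, 0.15 L), indices by `floor`,
half-open — a 1,000-base transcript uses bases [850, 950) and [50, 150).
A ratio near 1 indicates the polymerase reached the template end;
transcripts at FPKM ≤ 5 are excluded. The first/last 5% are avoided
because fragment ends are depleted there regardless of processivity.

**Base-level CV** uses the sample (n−1) standard deviation over the mean;
the choice of denominator is conventional and does not affect rank-based
downstream analyses.

## The hunc caller

Per replicate and transcript, the five dilution conditions (IVT-only, 1:1,
1:2, 1:10 IVT:mouse, mouse-only) are each min-max normalized to [0, 1]
(constant vectors, e.g. the mouse-only condition on a clean IVT
transcript, map to zeros). The per-base spread across the five normalized
conditions is the median absolute deviation with scale constant 1,
MAD = median(|x − median(x)|), chosen for outlier resistance. Per-base
MADs are averaged over a 100-base window centred on each base; only full
windows are scored (centres `range(50, L−50)`), and the first 300 / last
250 scored windows are trimmed. Per-base MADs below 1e−12 are zeroed: they
are floating-point residue of exactly proportional coverage vectors.

The score cutoff is the 95th percentile of all window scores pooled over
transcripts, computed per replicate with linear (type-7) quantile
interpolation. Runs of at least 20 contiguous above-cutoff windows become
candidate intervals spanning [first centre − 50, last centre + 50);
candidates are intersected across replicates (≥ 1 base overlap, abutting
does not count; the emitted interval is the intersection). Two mouse
filters then remove variability explained by background reads misaligned
to similar human sequence: transcripts with mouse-only FPKM ≥ 5 in either
replicate are dropped, as are regions whose mean mouse-only depth exceeds
10 inside the region or in the 100-base flank on either side (strict >,
following the operational text). Rejected candidates are returned with
the filter that removed them.

Replicate-divergent regions subtract replicate-2 window scores from
replicate-1 scores, threshold at the pooled 2.5th/97.5th percentiles,
apply the same mouse filters, and drop candidates within 200 bases of an
already-called hunc region (such regions are usually extensions of it).
In place of the study-final manual inspection, the pipeline emits a
window-score trace (TSV) around every surviving region for review.

### Detector response: what an anomaly must look like

With five conditions, the per-base MAD is the third-smallest absolute
deviation from the median, so a deviation confined to a *single* condition
is invisible: the other three IVT-bearing conditions still agree exactly
and the MAD stays 0. A detectable anomaly must perturb at least two
conditions. Further, an *elevation* that exceeds a condition's coverage
maximum becomes that condition's new normalization scale and shifts the
normalized values of every base in the transcript — smearing the signal
transcript-wide. Localized *suppressions* have neither problem. The
synthetic injections therefore suppress depth (multiplier 1/amplitude,
amplitude in [3, 6]) over one interval in 2–4 of the four IVT-bearing
conditions, identically in both replicates — matching the observed
phenomenology of dips that vary across dilutions but reproduce across
replicates.

## The simulator

`simulate_fragment_coverage` is a minimal paired-end fragmentation
sampler: fragments are assigned to transcripts multinomially with
probability ∝ weight × length; each fragment draws a Gaussian length
(mean 250, sd 25 by default) truncated to [read length, transcript
length] and a start uniform over the eligible positions [0, L − flen];
both 100-base read ends increment depth. Sequencing error, intronic
reads and polymorphism are deliberately absent — coverage deviates from
uniform only through fragmentation randomness. The process is symmetric
under strand reversal, so the processivity null is centred on 1, and the
expected depth at a deep-interior base has the closed form
n · 2R / (L − E[flen] + 1), which the tests check by direct summation.
Per-transcript weights default to equal (uniform expression) and may be
seeded from an FPKM table to emulate quantity-matched simulation.

`simulate_dilution_experiment` builds one fragmentation realization per
replicate and scales it by the IVT read share of each condition (1, 1/2,
1/3, 1/11, 0) — the five libraries of a replicate really are dilutions of
one IVT pool, so the fragmentation noise is shared and the five
normalized coverage shapes agree exactly at null. This makes the null
calibration sharp: with no injected anomaly the MAD is identically zero
and the caller returns no regions, at any depth and over any number of
seeds. Injected anomalies (above), homology decoys with recorded
mouse-only FPKM, and locally elevated mouse coverage exercise every
filter with known ground truth.

`simulate_library_panel` emulates the library-preparation comparison:
each library (plasmid, no selection, polyA, rRNA-depleted, plus the
bias-free "simulated" control) draws its own fragmentation realization
and multiplies depth by a smooth log-normal bias field whose roughness σ
increases from plasmid (0.15) to rRNA-depleted (0.5), reproducing the
observed ordering of base-level CV by protocol. Half of each field's
log-variance is shared across libraries (sequence-driven bias every
protocol sees). The polyA library adds an exponential 3' enrichment ramp
(scale 1,500 bases). The rRNA-depleted library suppresses 90% of the
depth over planted rRNA-homologous segments, emulating probe
co-depletion of rRNA-similar sequence.

What the generator does **not** emulate: alignment artifacts and
multi-mapping, sequencing error, GC-dependent amplification curves,
random-priming nucleotide bias at read starts, RNA secondary structure,
or real rRNA sequence. Passing tests therefore demonstrate the
correctness and calibration of the statistics and the caller under
controlled bias, not the biological completeness of the bias model.

## Sequence features and association

Hexamer entropy counts all step-1 overlapping 6-mers (those containing
non-ACGT bases are skipped), converts to frequencies, and reports Shannon
entropy in bits (≤ 12); the base of the logarithm does not affect any
rank-based analysis. GC fraction excludes ambiguous bases from the
denominator. Similarity to rRNA is the best Smith–Waterman local
alignment score of the transcript or its reverse complement against the
reference set. The generic scoring surface defaults to match +2,
mismatch −1, linear gap −2 — convenient for exhaustive verification —
but that scheme sits near the local-alignment phase transition, where
best scores between *unrelated* sequences grow with sequence length and
stop discriminating homology; similarity screening therefore uses the
stricter BLASTN-like `RRNA_SCORING` (+2/−3/−5). The shipped rRNA
references are synthetic stand-ins (`make_synthetic_rrna`, labelled as
such); full-scale users should substitute the real 45S (NR_046235.1) and
5S (X71804.1) sequences.

The coverage-drop score between the no-selection and rRNA-depleted
libraries is max(0, 1 − mean(depleted)/mean(no selection)) after scaling
each library so its pooled mean depth over all transcripts is 1. The
pooled-mean normalization is this package's reconstruction; the original
procedure is not fully specified. The drop is computed per transcript; a
windowed variant would be a natural extension.

Association analysis excludes transcripts at FPKM ≤ 5, sorts by the
metric (ties broken by transcript id), takes the 100 least and 100 most
extreme transcripts, and compares each sequence feature between the two
sets with a two-sided Mann–Whitney U test — the unpaired rank-sum test,
appropriate for two independent transcript sets (the source material is
inconsistent between "rank-sum" and "signed-rank"; the groups are
unpaired). The exact null distribution is used when n + m ≤ 12 without
ties, otherwise the normal approximation with midrank ties and
continuity correction. No multiple-testing correction is applied; all
raw p-values are emitted together. Effect sizes against the simulated
control are per-transcript CV ratios, summarized by mean and median.

## Determinism and problem sizes

All randomness flows from one integer seed through named
`numpy.random.default_rng` substreams per stage, so identical configs
reproduce byte-identical TSV/BED outputs. The validation studies run at
desk scale, chosen to finish in minutes on one CPU while keeping every
statistic in its calibrated regime: 10 seeds × 200 transcripts
(600–3,000 bases, ≥ 100× mean depth) for the null fold-change and
processivity checks; 20 seeds × 60 transcripts with 8 planted anomalies
and 2 decoys for hunc recovery; 10,000 null pairs (n = m = 100) for
rank-sum calibration; 200 transcripts (half with planted rRNA segments)
for the depletion-drop correlation, which lands at R² ≈ 0.2 — the same
order as the full-scale observation (R² ≈ 0.31).

## Reproducing the full-scale analysis (GSE50445)

The deposited sequencing data (NCBI GEO accession GSE50445) permits the
full-scale reproduction: 963 retained transcripts, 86 hunc regions over
65 transcripts, and the published fold-change and detection tables. The
workflow is not part of the test suite (it requires the ~GB-scale
download and an hg19 alignment with RUM or a comparable splice-aware
aligner producing unique-read bedGraph coverage):

1. Align each library to hg19; keep uniquely mapped reads; produce
   per-sample bedGraph coverage and transcript-level FPKM tables.
2. Obtain the IVT transcript models (MGC Genes track, BED12) and filter
   multi-locus/overlapping clones (`find_overlapping`,
   `filter_transcripts`).
3. Build a `PipelineConfig` with `simulate_first=false`, a sample
   manifest mapping each condition/replicate to its bedGraph, the BED12
   models, transcript FASTA, and real rRNA references; run
   `covbias run-all --config config.json`.

Expected agreement is to tooling tolerance: aligner version and unique-
read definitions shift FPKM values and the pooled MAD cutoffs slightly.

## Known limitations

- The caller's sensitivity is blind to single-condition anomalies and to
  elevations that redefine a condition's normalization scale (see
  detector response above); both are properties of the published
  procedure, not implementation choices.
- With fewer than ~20 transcripts the pooled 95th-percentile cutoff is
  dominated by any injected signal and loses its calibration meaning.
- BLAST e-values are not reproduced; raw local-alignment scores are used
  instead (deterministic, parameter-explicit).
- The bigWig binary format is not read; convert to bedGraph first.
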