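# Methods

This note documents the models, estimators and numerical choices behind
`adtx`, what the synthetic-data generator does and does not emulate, and
the limits of what passing tests demonstrate.

## Coordinates and annotation

All genomic coordinates are 1-based and inclusive on both ends (GTF
convention) throughout the package; BED input is converted on read and
back on write. Transcript models keep version-suffixed identifiers
verbatim. Gene biotypes collapse onto four levels (protein_coding,
lncRNA, pseudogene, other); unknown annotation biotypes map to `other`.
Single-transcript genes are retained for gene-level sums but generate no
splicing events.

## Cohort classification

Dementia is defined as MMSE < 24. The three diagnosis rules (control:
CERAD 3–4, Braak 0–3, no dementia; AsymAD: CERAD 1–3, Braak 3–6, no
dementia; AD: CERAD 1–2, Braak 3–6, dementia) overlap in exactly one
cell: CERAD 3, Braak 3, no dementia satisfies both the control and
AsymAD definitions. The classifier applies a fixed precedence
(default AD → AsymAD → control, i.e. pathology-forward, so the overlap
resolves to AsymAD), logs every multi-rule match, and exposes the
precedence as a parameter. Any cell matching no rule is `unclassified`.

The low-expression filter keeps a row when TPM > 0.1 in at least
⌈0.05 · n⌉ samples — the ceiling is the conservative reading of "no less
than 5 %" — applied once over all samples jointly, not per group. The
filter is idempotent and order-preserving.

## Differential transcript expression

Group differences use the two-sided Wilcoxon rank-sum test (exact null
distribution when the pooled sample is ≤ 25 without ties, otherwise the
normal approximation with midrank tie correction). The fold-change
estimator is the ratio of group means with a pseudocount:
FC = (mean_b + ε)/(mean_a + ε), ε = 0.01 TPM (configurable). The mean
was chosen over the median so recovery of multiplicative planted effects
is unbiased; the pseudocount makes the statistic total and exactly
reciprocal under group exchange. Multiple testing uses Benjamini–
Hochberg throughout (the field default). Direction calls require
FC > 1.5 (up) or FC < 0.67 (down) at FDR < 0.05.

Host-gene expression for the transcript–gene correlation is the sum of
member-transcript TPMs from the same matrix, which makes the analysis
self-contained and scale-consistent; an independent gene-level matrix
can be supplied instead. Pearson correlation with the standard two-sided
test classifies transcripts as positive (r > 0.3, p < 0.05), negative
(r < −0.3, p < 0.05) or irrelevant; zero-variance vectors are labelled
irrelevant and logged. Correlation is computed on TPM values, not on
log-transformed ones.

## Splicing events and PSI

Local events are inferred from all transcript pairs within a gene,
strand-aware (classification runs on genomic coordinates; A5↔A3 and
AF↔AL swap on the minus strand, so mirrored structures give identical
types):

* **SE** — an internal exon of one transcript is bridged by a single
  intron of the other whose boundaries match both flanking junctions.
* **RI** — one transcript's exon spans the other's exon–intron–exon
  block exactly.
* **A5 / A3** — two introns share one boundary and differ at the other,
  with the flanking alternative exons overlapping (the overlap
  requirement separates these from AF/AL).
* **MX** — non-overlapping internal exons with identical outer flanking
  junctions; inclusion is the form carrying the 5′-most exon.
* **AF / AL** — alternative non-overlapping terminal exons splicing
  into (out of) the same junction; overlapping terminal exon pairs are
  ambiguous and discarded (logged); inclusion is the 5′-most first exon
  (3′-most last exon).

Candidates are deduplicated by (gene, type, coordinate signature), and
inclusion/exclusion transcript sets are unioned across supporting pairs,
matching local-event semantics where many pairs support one event.

PSI(event, sample) = Σ TPM(inclusion) / Σ TPM(inclusion ∪ exclusion),
undefined (missing) when the denominator is zero. Events are kept when
PSI > 0.1 in at least ⌈0.05 · n⌉ samples. Differential splicing uses the
unpaired rank-sum test by default: the groups are independent samples,
so the signed-rank (paired) test is not the natural choice, but it
remains available (`test="signed_rank"`, pairing by rank order, equal
group sizes only). ΔPSI is the difference of group medians; significance
requires |ΔPSI| > 0.1 at FDR < 0.05. The literal alternative reading
"median PSI > 0.1" is redundant with the expression filter and cannot
define a between-group difference, so the Δ-median reading is the
default.

The frame check asks whether the variable genomic region length is
divisible by 3; it uses region lengths only (no CDS projection; CDS
records are not required inputs) and is reported only for events in
protein-coding genes.

## Isoform switching

IF(t, s) = TPM(t, s) / Σ over host-gene transcripts, undefined when the
gene is unexpressed in the sample; such samples are dropped per test
rather than imputed as zero (absence of the gene says nothing about the
isoform balance). dIF is the difference of group means of IF, tested
with the pooled-variance Student's *t*-test (Welch optional). FDR pools
across all transcripts of one comparison by default (per-gene pooling
optional). Usage calls require |dIF| > 0.1 at FDR < 0.05; a gene
switches when any member transcript does. For two-transcript genes the
dIFs of the pair are exactly opposite, and the call is antisymmetric in
group order.

## RBP networks

Candidate regulators must change mean expression by ≥ 10 % (relative to
the first group's mean; inclusive boundary). Binding windows are the
±300 bp neighbourhoods of an event's defining splice sites, merged
before overlap counting so one CLIP peak is never counted twice. Edges
require ≥ 1 in-window binding site and Spearman |ρ| > 0.5 with p < 0.05
between RBP TPM and event PSI, computed over the union of the two
compared groups' samples (matching per-comparison networks; an
all-samples option exists). Edge p-values are raw by default — no FDR
is applied at the edge level — with a BH option. Binding is a hard
deterministic filter: removing all sites empties the network regardless
of correlations.

## Statistics

BH q-values are computed on ranks with the cumulative-minimum
monotonicity enforcement and returned in input order.
Over-representation uses the exact hypergeometric upper tail,
P[X ≥ k], with gene sets intersected with the universe; the universe is
the host genes of filter-surviving transcripts (not the whole
annotation), restricted to protein-coding genes for DET enrichment, to
avoid inflation from never-expressed genes. Degenerate inputs resolve
deterministically: all-tied rank input gives p = 1; a zero-variance
*t*-test gives p = 1 when the group means agree and p = 0 otherwise,
and is logged.

## Synthetic cohorts

The generator emulates the five pipeline inputs with planted,
recoverable effects. Default study conditions: 1,000 genes with two
transcripts each, 60 samples per diagnosis group, log-normal TPM noise
(per-transcript baselines ~ Normal(1, 1) on the log scale, per-cell
noise sd 0.5), 5 % of transcripts with a planted fold-3 change, 5 % of
genes with a planted reciprocal dIF 0.3 switch, 20 RBPs, 10 % of
eligible events driven at strength 0.8 within ±300 bp binding windows.
These sizes keep every detector's planted effects comfortably above its
thresholds while leaving null features abundant for calibration, and run
in seconds on one core.

Construction choices that matter for interpretation:

* Group fold changes are additive in log-TPM (keeping TPM positive and
  the fold change interpretable) and are planted on whole host genes —
  every member transcript scaled together — so expression effects never
  leak into isoform fractions or PSI. Conversely, a reciprocal switch
  necessarily changes its two isoforms' expression (shares shift under a
  conserved gene total): switched isoforms are therefore genuine
  expression changes and are counted as such when false discoveries are
  tallied.
* Switch and driver genes draw one shared gene-level noise term for the
  transcript pair plus an antisymmetric share jitter on the logit scale,
  so the per-sample gene sum is algebraically independent of the planted
  shares — planted switches conserve gene-level expression exactly,
  which is what makes the switch-without-expression-change contrast
  testable.
* In a two-transcript gene the single local event's PSI equals the
  inclusion isoform's IF, so the planted switches are simultaneously the
  planted differentially spliced events, with |ΔPSI| equal to the
  planted dIF. There is no separate ΔPSI knob.
* Each RBP driver contributes a latent per-sample variable that tilts
  the inclusion/exclusion balance of its driven events (logit amplitude
  2 × strength) and feeds the RBP's own log-expression with weight
  `driver_strength`. Every RBP — driver or not — receives a ±25 % group
  expression shift so the 10 %-change regulator filter passes all of
  them and binding evidence, not expression filtering, is what excludes
  decoys. Decoy binding sites are placed strictly outside every window
  of their event; background sites inside windows of non-driven events
  keep a driver-free network honest (candidates exist; correlation alone
  must reject them).
* Metadata are drawn uniformly from each intended group's defining
  score ranges, never from the ambiguous CERAD 3/Braak 3 cell, so
  classification inverts the generator exactly.
* Gene sets are emitted per planted-effect category plus random sets,
  making enrichment testable with known-enriched sets.

What the simulator does **not** model: read-level sampling and
quantification uncertainty, sequencing depth and batch effects,
covariates (age, sex), realistic genome coordinates, correlated
co-regulation structure beyond single-RBP drivers, and any real-data
noise distribution — the log-normal choice is a stand-in isolated behind
`SimulationConfig`. Passing recovery tests therefore demonstrates the
correctness of the estimators and thresholds under a clean generative
model, not performance on real brain RNA-seq, where effect sizes,
dependence and confounding are harsher.

## Reproducibility

All generators are deterministic under a fixed seed (independent
numpy `SeedSequence` streams per stage, so changing one stage's
parameters never shifts another's draws). Pipeline runs are
byte-reproducible: every table embeds the effective thresholds in its
header and the manifest records seed, thresholds and per-stage row
counts, with no timestamps in any output.

## Known limitations

* Event inference compares transcript pairs; nested or graph-valued
  splicing structures (e.g. multi-exon skips combined with alternative
  sites) are represented only through the pairwise events they imply.
* The frame check uses genomic variable-region lengths, not
  CDS-projected lengths, and so approximates coding impact.
* PSI is transcript-abundance-based; junction-read PSI from alignments
  is out of scope.
* Edge-level network inference is correlational; binding co-occurrence
  filters but does not establish causality.
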