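# adtx — transcript-level analysis of Alzheimer's-disease cohorts

`adtx` is a Python library (with a thin CLI) for transcript-resolution
analysis of bulk RNA-seq brain cohorts spanning the progression of
Alzheimer's disease: non-demented controls, asymptomatic AD (AsymAD —
autopsy-confirmed pathology without cognitive impairment) and AD. It is
aimed at computational biologists who have a transcript TPM matrix, a
GENCODE-style annotation and neuropathology metadata, and want the whole
chain from cohort harmonization to splicing-regulatory networks in one
tested, reproducible package.

## What it computes

* **Cohort harmonization** — samples are classified from CERAD score
  (neuritic plaques, 1–4), Braak stage (tangles, 0–6) and MMSE
  (dementia ⇔ MMSE < 24): control (CERAD 3–4, Braak 0–3, no dementia),
  AsymAD (CERAD 1–3, Braak 3–6, no dementia), AD (CERAD 1–2, Braak 3–6,
  dementia). Transcripts are kept when TPM > 0.1 in ≥ 5 % of samples.
* **Differential transcript expression (DET)** — per-transcript Wilcoxon
  rank-sum test; a transcript is a DET when its fold change exceeds 1.5
  (or falls below 0.67) at Benjamini–Hochberg FDR < 0.05. Includes the
  ±20 %-change cross-tabulation between disease stages and
  transcript–host-gene Pearson correlation classes
  (|r| > 0.3, p < 0.05).
* **Alternative splicing** — the seven local event types (SE, A5, A3,
  MX, RI, AF, AL) are inferred from pairwise comparison of transcript
  exon structures. Percent spliced-in is transcript-based:
  PSI = Σ TPM(inclusion) / Σ TPM(inclusion ∪ exclusion). Differential
  splicing requires |ΔPSI(median)| > 0.1 at FDR < 0.05; a length-mod-3
  check flags frame-preserving variable regions.
* **Isoform switching** — isoform fractions IF_i = T_i / Σ_j E_j per
  gene and sample; dIF is the difference of group means, tested with
  Student's *t*; usage changes need |dIF| > 0.1 at FDR < 0.05. Switching
  genes are cross-checked against gene-level expression to surface
  switches invisible to gene-level analysis.
* **RBP regulatory networks** — RNA-binding proteins with ≥ 10 %
  expression change are linked to differentially spliced events when
  CLIP binding evidence lies within ±300 bp of the event's splice sites
  and Spearman |ρ| > 0.5 (p < 0.05) between RBP TPM and event PSI.
* **Over-representation analysis** — exact hypergeometric upper-tail
  test of gene sets (GMT) against a filtered-expression universe.
* **Synthetic cohorts** — `adtx.simulate` generates annotation,
  expression, metadata, binding sites and gene sets with planted fold
  changes, reciprocal isoform switches, RBP drivers and decoy binding,
  plus a machine-readable ground truth, so every stage is testable
  end to end.

## Worked example

```bash
python examples/differential_transcripts.py
```

```
direction
none    903
up       49
down     48
...
planted fold-3 transcripts recovered: 50/50
```

A 500-gene synthetic cohort (60 samples per group) carries 50
transcripts with a planted fold-3 change between control and AD. The
detector calls 97 DETs: all 50 planted ones plus the isoforms of planted
switch genes, whose expression genuinely shifts when usage is
redistributed under a conserved gene total. `examples/` contains one
script per capability (classification, DET, splicing/PSI, switches, RBP
network, full pipeline); each prints the numbers it computes and what
they mean.

The same analyses run from the shell:

```bash
adtx run --run-dir out/demo --simulate --seed 7
adtx report --run-dir out/demo
```

which writes per-stage TSVs (thresholds embedded in each header), a JSON
manifest with row counts, and summary tables (DET overlap between
stages, event-type tabulations, switch usage counts).

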