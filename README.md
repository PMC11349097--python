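# neomer

Analytics for split-module ("Neomer") aptamer library screening: from
sequencing reads of a selected library to candidate biomarker aptamers
("Aptamarkers"), their qPCR quantification in patient plasma, and a
classification stage predicting a binary clinical state — here, high vs
low brain amyloid deposition (centiloid ≥ 30) — from the resulting
abundance profiles.

## The problem and the model

A Neomer library interleaves 16 random nucleotides among fixed scaffold
segments of a 73-nt template:

```
CCAGATACAGACNNGAGGNNNGAATNNNAACCATCGGCGCCAACANNNCATTCNNNCAGANNCAGTAGACAGC
```

The 16 random nt span 4^16 ≈ 4.29×10⁹ sequences — small enough that a
physical library can contain ~1,000 copies of every possible sequence,
unlike a conventional contiguous 40-nt random region (4^40 ≈ 1.2×10²⁴).
A KasI site (GGCGCC) in the central fixed segment lets the amplicon be cut
into **module A** and **module B**, each carrying 8 random nt, so each
module spans only 4^8 = 65,536 sequences and can be counted exhaustively
from one sequencing run.

For sample *s*, with module marginal frequencies *a_s* and *b_s*, the
frequency of the full sequence with module keys (i, j) is reconstructed as
the outer product

> f_s(i, j) = a_s(i) · b_s(j).

For a contrast of n high-amyloid vs n low-amyloid samples, each of the
65,536² sequences gets a screening statistic

> z(i, j) = ( mean_high f(i,j) − mean_low f(i,j) ) / ( (sd_high + sd_low) / 2 ),

with sample SDs (ddof = 1). The top-K (default 10,000) sequences by z are
ranked, and the final candidates are the top 4 by the **separation
margin** min_high f − max_low f (positive iff the groups separate
completely). The scan is blocked over rows of the implied matrix, so the
full matrix is never materialised per sample, and is exactly equivalent to
the exhaustive computation.

Selected Aptamarkers are quantified in plasma by qPCR: baseline = mean
fluorescence of cycles 1–5; Cq = interpolated cycle where fluorescence
reaches 6× baseline; efficiency E = 10^slope of the best log-linear fit
above Cq; per-run normalisation of Cq and E by run-mean/reference factors;
duplicate wells merged under a 6% CV limit; relative template
RT = (1/E)^Cq; and per-sample proportions RTp_m = RT_m / Σ RT over the
eight-marker panel. RTp profiles plus clinical covariates (age, sex,
clinical class) feed a scikit-learn classification stage with zero-mean
scaling fit on the training split, importance-ranked sequential feature
exclusion, grid-search with stratified 4-fold CV, and held-out evaluation
at a 0.5 probability threshold.

The study's plasma/NGS/qPCR raw data are not public; a first-class
synthetic-data module generates every input with known ground truth
(planted enriched motif families, scaffold-conformant barcoded reads,
sigmoidal qPCR curves, labelled cohorts), which is what the tests and the
acceptance script run on.

## Worked example

`examples/03_zscore_screen.py` plants a 5-sequence motif family (one
module-A key, five module-B keys, 5× enriched in the high group) into a
k=4 test library, 10 vs 10 samples at 10⁶ reads/module, and screens it:

```
planted pairs: [(22, 110), (22, 111), (22, 165), (22, 195), (22, 219)] (5x in 'high')

top 5 of 10000 ranked sequences (0 zero-variance sequences excluded):
 * A=ACCG B=TAAT  z= 114.05  fold= 4.77
 * A=ACCG B=CGTT  z=  87.82  fold= 4.76
 * A=ACCG B=GGCC  z=  80.39  fold= 4.81
 * A=ACCG B=CGTG  z=  72.71  fold= 4.82
   A=ACCT B=CGTT  z=  69.28  fold= 2.16

selected by separation (min high sample - max low sample):
   ( 22,165)  separation=5.86e-05  aptamer=CCAGATACAGACACGAGGCGAATGAACCATCGGCGCCAACAGGCATTCCCAGACCAGTAGACAGC
   ( 22,110)  separation=5.83e-05  aptamer=CCAGATACAGACACGAGGCGAATGAACCATCGGCGCCAACACGCATTCTCAGAGCAGTAGACAGC
   ( 22,195)  separation=5.69e-05  aptamer=CCAGATACAGACACGAGGCGAATGAACCATCGGCGCCAACATACATTCACAGATCAGTAGACAGC
   ( 22,219)  separation=5.55e-05  aptamer=CCAGATACAGACACGAGGCGAATGAACCATCGGCGCCAACATCCATTCGCAGATCAGTAGACAGC
```

`*` marks planted ground truth: planted pairs carry the full 5× fold and
top z scores; sequences sharing only one planted module key show the
intermediate √5 ≈ 2.2 fold; all four selected candidates are planted. The
other examples cover the scaffold and published records (`01`), read
demultiplexing and counting (`02`), qPCR quantification (`04`) and the
classification stage (`05`).

A thin CLI mirrors the stages
(`neomer run|simulate|count|zscan|qpcr|model|report`), e.g.:

```
neomer run --seed 7 --out runs/demo --config cfg.yaml
neomer report --run-dir runs/demo
```

Every run writes a `manifest.json` with the full config, parameter
decisions and output digests; reruns with the same seed are byte-identical.

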