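# Methods

## Library model

The scaffold is represented as alternating fixed segments and random runs
(canonically `(2,3,3,3,3,2)` random nt inside a 73-nt template). Module
sequences are encoded as radix-4 integers with A=0, C=1, G=2, T=3
(alphabetical, the conventional 2-bit encoding), a bijection onto
[0, 4^k−1] that is lexicographic in the base order. Read matching is
substitution-only: the template (with N wildcards) is slid along the read
at every offset, and the leftmost alignment with at most
`max_fixed_mismatches` mismatches at fixed positions (default 0) and no N
at random positions wins. Reads whose length cannot accommodate the
template, or that fail the budget, are counted but not matched; no indel
handling is attempted, which keeps counting linear in read length and
reflects that substitutions dominate short-amplicon Illumina error
profiles. The module split follows the KasI cleavage position (G^GCGCC):
module A ends `...AACCATCG`, module B begins `GCGCCAACA`.

Reduced-k scaffolds (`make_scaffold(k)` for k < 8) keep the canonical
fixed segments and shrink the random runs, so brute-force oracles over
4^(2k) sequences stay exact and fast in tests; k=4 (65,536 full
sequences) is the standard test resolution, k=8 the production one.

## Counting and frequencies

Demultiplexing is an exact match of the 6-nt sample barcode at a fixed
offset (default 0: with this primer layout the sequencing primer ends
immediately before the hex code). No 1-mismatch rescue is attempted,
because a set of ~21 codes of length 6 is not guaranteed error-correcting;
reads with a corrupted barcode go to "undetermined". Frequencies default
to counts divided by the number of *matched* reads (so they sum to 1);
dividing by all reads is available but makes frequencies depend on the
junk-read rate. The choice is recorded in run manifests.

## Screening statistic

Per sequence (i, j), z = (mean_num − mean_den) / ((sd_num + sd_den)/2)
with sample SDs (ddof = 1; the convention is logged in result parameters).
The scan walks row blocks of the implied 4^k × 4^k matrix. Block means are
rank-one contractions (Aᵀ·B over samples); variances use a second,
centred pass over the samples so no cancellation occurs and the block
scan agrees with a plain-Python oracle to ≤1e−12 in z. Peak memory is
O(block_rows × 4^k), default block_rows = 256.

Sequences whose two group SDs are both zero carry no variance information
and are excluded from ranking (count reported). Ties everywhere break by
(z desc, iA asc, iB asc) for cross-platform determinism. The fold value
(mean_num + ε)/(mean_den + ε), with ε defaulting to the reciprocal
geometric mean of matched totals, is reporting-only and never ranks.
Candidate selection uses the min–max separation margin
min_num − max_den, the strictest reading of "all samples of one group
above all of the other"; ties break by z then key order.

## Synthetic selection data

Each sample's full-library frequency vector is drawn as a shared
symmetric-Dirichlet baseline (concentration 5 per cell — mild key-to-key
heterogeneity, since perfectly uniform baselines degenerate the SDs)
times i.i.d. per-cell gamma multipliers with CV
`sample_heterogeneity_cv` (default 0.05). The default makes multinomial
counting noise the dominant variance component at the module-marginal
level, the regime of a deep, well-mixed library prep; larger values model
noisier preps and proportionally weaken z scores.

Planted enrichment is **rank-one**: each planted pair multiplies its
module-A row and module-B column by √factor, so the pair itself gains the
full factor. This models selection acting on module-level motifs and is
the only kind of signal the outer-product reconstruction can observe — a
boost confined to a single full-library cell moves each 256-cell marginal
by well under 2% and is invisible to the method (verified numerically).
Consequently a planted *set* is exactly identifiable only when it is
closed under the product of its module key sets; the default plant is a
motif family (one module-A key × n module-B keys), and the effective
enriched grid is always recorded in the ground truth. Reads are then
multinomial at `depth` per module (default 10⁶), drawn at full-library
resolution for k ≤ 5 and marginalised; for k > 5 the update is applied to
the marginals directly (an approximation, flagged in the ground truth).

What this generator does not emulate: PCR amplification bias, GC effects,
chimeric reads, indels, selection chemistry, or correlations between
module A and module B beyond the planted rank-one structure. Passing
recovery tests therefore demonstrate the statistics of the screen, not
robustness to those artefacts.

## qPCR model and estimation

Simulated traces follow F(c) = B(1 + η_c) + F₀E^c / (1 + F₀E^c/Fmax),
multiplicative Gaussian noise η with σ = 1% by default, B = 100, 40
cycles, with F₀ solved so the noiseless 6×-baseline crossing lands
exactly on the true Cq. Fmax defaults to 5×10⁶ (a wide-dynamic-range
detector): because the threshold sits at 5B of signal, the exponential
window above Cq needs ≳3 decades of headroom before saturation bends the
log-linear fit; smaller Fmax values bias the efficiency estimate low.
True E is drawn in (1.75, 2.0) and Cq in (18, 28) by default.

Estimation: Cq by two-point linear interpolation between the flanking
cycles of the first threshold crossing; traces that never cross, or that
amplify already within the baseline window (cycles 1–5, detected as
max/min ≥ the threshold multiple there), fail QC with a reason.
Efficiency fits log₁₀ of baseline-subtracted fluorescence against cycle
over every contiguous window of length ≥ 4 from ceil(Cq) to the detected
plateau, keeping the window with the highest R² (ties: earlier, then
longer). The plateau ends where the per-cycle gain drops below
1 + 0.25(E_prelim − 1), with E_prelim from the first four cycles above
Cq — i.e. where saturation has eaten three quarters of the gain. Fitted E
outside (1, 3] fails QC as implausible.

Normalisation divides each run's Cq and E by (run mean / reference), with
references ref_Cq = 20 and ref_E = 1.9 exposed as configuration and
echoed to outputs (the appropriate fixed divisors are instrument- and
assay-specific). The replicate CV limit (6, read as percent) applies to
normalised Cq, because Cq drives RT exponentially while E enters only
through its normalised average; both-value QC is a configuration switch.
After QC, a sample missing any of the eight RTp features is excluded from
model building entirely (strict complete-case policy, logged), avoiding
silent imputation.

## Cohort generator and classification stage

Cohorts default to 390 samples with a stratified 291/99 train/test split
recorded at generation time; the split is an input downstream and never
recomputed. RTp features live on the 8-simplex via Dirichlet draws
(concentration 60); class effects multiply the high-class concentrations
by exp(effect). The "strong" preset uses log-effects
(0.8, 0.6, 0.5, 0.4, −0.5, −0.6, −0.4, −0.3) — a clearly separable
biomarker panel — plus a +4-year age shift and a mildly associated
clinical class; the "null" preset zeroes every effect. Sex is always
uninformative.

Scaling is fit on the training split only (fitting on all data would leak
the held-out samples). Feature importance comes from impurity for tree
ensembles, absolute coefficients for linear models on standardised
features, and permutation importance otherwise; the source is recorded
per report. The least-important feature is re-ranked and dropped each
iteration; hyperparameters are re-tuned each iteration by exhaustive grid
search under stratified 4-fold CV on accuracy. Evaluation thresholds the
positive-class probability (or the logistic of a decision score) at 0.5;
sensitivity is recall of the high-amyloid class. Centiloid exactly 30
labels as high (≥ convention; configurable).

## Problem sizes and determinism

Tests and the acceptance script run at k ≤ 4 (where the exhaustive oracle
is exact), 20 replicates for selection recovery, 200 wells for qPCR
recovery and 10 replicates per cohort regime — sizes at which every check
completes in seconds while estimating the relevant rates with binomial
error well inside the asserted margins. All randomness flows through
`numpy.random.default_rng` seeded from explicit configuration; identically
seeded runs produce byte-identical text outputs, which the run manifest
verifies by SHA-256 digest.

## Known limitations

* The separation metric and the fold definition are reconstructions of
  underspecified choices; both are recorded in output parameters so
  alternative definitions can be compared.
* Rank-one planting cannot express antagonistic module interactions;
  recovery claims are limited to marginal-visible signals (see above).
* The qPCR efficiency estimator inherits the max-R² window rule; under
  heavy saturation (low Fmax) it is biased low. The plateau detector
  bounds, but does not eliminate, this bias.
* The classification stage is deliberately thin over scikit-learn and
  makes no claim about real-cohort transferability; cohort presets are
  synthetic regimes, not calibrated to any population.
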