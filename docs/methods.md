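# Methods

## Scope and data model

The package analyses two-group (control vs treated) cell experiments at
three levels: gene-level RNA-seq counts, extracellular-flux plate traces,
and scalar bench assays. Counts live in a `CountMatrix` (genes × samples,
non-negative integers, every sample labelled control/treated); traces in a
tidy table of (well, group, phase, time, OCR, ECAR) rows; assays in tidy
(sample, group, value) tables. All readers validate their invariants
(group completeness, strictly increasing time per well, phase order,
finiteness) before any computation.

## Negative-binomial differential expression

Counts are modelled NB with mean μ and dispersion φ, variance μ + φμ².

*Normalisation.* Median-of-ratios size factors: for genes expressed in
every sample, the ratio of each sample's count to the gene's geometric
mean; the per-sample median of those ratios, rescaled so the factors'
geometric mean is 1. This estimator has a closed form on small examples
(two identical samples → (1, 1); one sample doubled → (1/√2, √2)), which
the tests exploit.

*Dispersion.* Per-gene method of moments on normalised counts,
max(0, (s² − μ)/μ²), with the group-mean difference removed before the
variance (denominator n − 2) so true expression effects do not inflate φ.
The common dispersion is a 10%-trimmed mean of the per-gene values; the
working estimate shrinks each gene 70% toward the common value. The
shrinkage weight trades the noise of a 12-sample moment estimate against
gene-specific variation; at the default the null type-I error of the exact
test stays within one point of nominal (measured in the acceptance suite).

*Exact test.* Size-factor division equalises effective library sizes
(factors have geometric mean 1); pseudo-counts are rounded to integers —
a deliberate quantile-free simplification, documented as an approximation.
For a gene with group sums (S_ctl, S_trt) and total s, the null
conditional law of S_trt given s is negative hypergeometric with sizes
n_trt/φ and n_ctl/φ: the per-replicate NB success probability cancels, so
no nuisance mean enters. It is evaluated by log-gamma weights normalised
with log-sum-exp; φ = 0 uses the exact binomial limit. Two-sided p-values
double the smaller tail (observed split included once per tail) and cap
at 1, so a perfectly balanced split returns exactly 1. An independent
brute-force oracle (explicit NB pmf products at an arbitrary mean) verifies
the law to 1e-12 in the tests.

*Fold change and FDR.* log2((m_trt + c)/(m_ctl + c)) with prior count
c = 0.5 to stabilise low counts (all-zero genes return 0 with a logged
flag); Benjamini–Hochberg adjustment via statsmodels, property-tested
against the step-up hand formula.

Deliberately out of scope: TMM, quasi-likelihood GLMs, covariate designs,
multi-group contrasts.

## Transcript-length bias correction

The observed artifact is a monotone dependence of per-gene LogFC on log2
transcript length (LogTL). The correction:

1. fit LogFC = α + β·LogTL by OLS over **all** genes with finite LogFC and
   positive length (the trend is global, so no significance filter is
   applied; genes without usable length are excluded and counted);
2. corrected = initial − (α + β·LogTL), the OLS residual — hence exactly
   orthogonal to LogTL (slope and Pearson r vanish to ~1e-15; the tests
   require 1e-10);
3. reconcile per gene: keep the smaller-magnitude of (initial, corrected)
   when both have the same strict sign; otherwise 0. "Signs differ" is
   taken to include the case where exactly one value is 0 — the
   conservative reading; both-zero also yields 0;
4. call up/down at FDR ≤ 0.05 and |final| ≥ 0.1. FDR is **not** recomputed:
   p-values derive from counts, and the correction adjusts effect size
   only.

The centred-design OLS is used for numerical conditioning; Spearman uses
average ranks for ties, and all-constant input is defined as ρ = 0 with a
warning. Whether such a length trend is artifact or biology is not a
question this module answers; it diagnoses and removes the dependence
either way.

## ATP-rate decomposition

Per well, phase summary rates follow the plate-reader convention: basal
OCR/ECAR are the **last** basal reading (fully equilibrated), post-injection
OCR is the **phase minimum** (deepest inhibition); a mean-of-phase
alternative is available (`statistic="mean"`). Then

- mitoATP = max(0, OCR_basal − OCR_oligo) · o_per_o2 · P/O, with
  o_per_o2 = 2 oxygen atoms per O₂ and P/O = 2.75 pmol ATP per pmol O;
- PER = ECAR_basal · buffer_factor · chamber_volume · K_vol converts
  acidification (mpH/min) to proton efflux (pmol H⁺/min);
- mitoPER = max(0, OCR_basal − OCR_rotAA) · CCF with CCF = 0.61 pmol H⁺
  per pmol O₂ of mitochondrial CO₂-derived acidification;
- glycoATP = max(0, PER − mitoPER); totalATP = mitoATP + glycoATP.

P/O and CCF are instrument-vendor defaults surfaced in `ATPRateConstants`
rather than hard-coded; buffer_factor, chamber volume and K_vol default to
a product of 1 so that PER equals ECAR numerically and the arithmetic is
transparent — real plates substitute their calibrated values. Clamping
events are logged, never silent. Total = mito + glyco holds identically,
and all rates scale linearly with a common rescaling of OCR and ECAR when
no clamp fires.

Group summaries report mean ± SEM (n − 1 denominator), fold over the
control mean, and a two-sided Mann–Whitney U p-value vs control: full
enumeration of all C(n₁+n₂, n₁) assignments for min(n₁, n₂) ≤ 8 (midranks
under ties; the fully separated 5v5 case gives p = 2/252), normal
approximation with tie correction above.

## Bench-assay statistics

*ΔΔCt.* Technical-replicate Ct values are averaged per (sample, gene);
ΔCt = Ct_target − Ct_reference per sample; ΔΔCt subtracts the arithmetic
mean control ΔCt per gene (the standard relative-quantification
convention); relative expression is 2^−ΔΔCt, making the control group's
geometric mean exactly 1. A uniform Ct shift across target and reference
cancels, which the tests assert. Amplification-efficiency modelling and
multi-reference normalisation are out of scope.

*Densitometry.* band/loading ratios, rescaled so the control mean is 1
(figures conventionally plot control near 1; raw ratios are available via
`rescale=False`). *Percent-of-control* divides by the control mean × 100.
Both are invariant to rescaling all inputs by a positive constant.

*Two-group tests.* `kind="auto"` selects pooled-variance Student's t when
min(n₁, n₂) ≤ 3 and Mann–Whitney when ≥ 5, mirroring the replicate
structure of the assays (t for triplicates, U for five-well plates); the
undefined n = 4 case falls back to t with a log note. Zero pooled variance
resolves to p = 1 (equal means) or p = 0 (unequal), logged. Labels:
* p < 0.05, ** p < 0.01, *** p < 0.001, else ns.

*Dose conversion.* µM = (ng/mL)/(g/mol); display rounding two decimals.

## Synthetic data

`simulate_counts` draws transcript lengths log2-uniform over 2⁹–2¹⁴ bp (a
broad, scale-free default; no canonical length distribution is assumed),
baseline means log10-uniform over 10–1000 counts, and NB counts at
dispersion 0.05 for 6 + 6 replicates. By default 6% of genes are
up-regulated and 4.5% down-regulated — an up-dominant minority — with
|true LogFC| = effect_logfc_scale × LogNormal(0, 0.25), giving a
unimodal spread of effect magnitudes around the configured scale. The
length artifact adds slope × (LogTL − mean LogTL) to every gene's
fold change (centred, so the global mean LogFC is unchanged), applied to
the treated-group mean.

When a target Spearman correlation is requested instead of a slope, the
slope is calibrated by Brent root-finding on a pilot objective: the
count-level noise of the estimated LogFC is replaced by its delta-method
normal approximation (sd² ≈ 2(1/μ + φ)/(n ln²2)), one pilot noise matrix
is reused across candidate slopes so the objective is smooth and monotone,
and the realised Spearman of three pilot replicates is matched to the
target. At 10,000 genes the realised correlation lands within ±0.05 of
targets across [−0.6, 0.6] (verified per seed in the tests). The realised
value reported in `SimTruth` is recomputed from the actual generated
counts via the package's own size factors and fold-change estimator.

`simulate_seahorse` builds three-phase traces with OCR phase means ordered
basal > post-oligomycin (fraction 0.4) > post-Rot/AA (fraction 0.1) and a
compensatory ECAR response (×1.35 post-oligomycin, ×1.25 post-Rot/AA —
only basal ECAR enters the ATP arithmetic). `noise_cv` is the
**between-well** coefficient of variation: one multiplicative log-normal
factor per well scales its entire trace (emulating seeding-density
variability, the dominant error source on replicate wells), plus
per-measurement instrument jitter at one fifth of that CV. All log-normal
noises are unit-mean. `simulate_assays` draws unit-mean log-normal
multiplicative noise around the group means.

What the generators do **not** emulate: read-level effects (3′ coverage
bias, mappability, GC), gene–gene correlation, library-composition shifts
(so median-of-ratios is exactly correct by construction), injection
transients within Seahorse phases, and plate edge effects. Passing tests
therefore demonstrate the correctness and calibration of the estimators
under their stated model, not robustness to those real-data pathologies.

## Numerical choices and degenerate inputs

- Exact-test enumeration is O(total) per gene with vectorised log-gamma;
  totals in the tens of thousands remain fast.
- Pseudo-count rounding introduces sub-ulp-of-a-count discretisation;
  at the default depths its effect on p-values is negligible, and the
  enumeration oracle is run on exact integers.
- OLS on the centred design; correlations on constant input return 0 with
  a warning rather than NaN.
- Mann–Whitney ties use midranks; tail comparisons use a 1e-9 slack on U
  to absorb floating-point rank sums.
- Report/TSV writers are timestamp-free and use deterministic float
  formatting (`%.17g` for traces), so identical configs reproduce
  byte-identical outputs; trace CSVs are re-read with round-trip float
  parsing.

## Problem sizes

Simulation-based checks use 10,000 genes for calibration/recovery
properties, 5,000 genes × 10–20 seeds for null calibration, 50 seeds for
plate-level detection rates, and enumeration oracles up to conditioned
totals of 50 and Mann–Whitney group sizes of 8 — sizes at which the
Monte-Carlo bounds quoted above are comfortably binding.

## Known limitations

- The exact test assumes a common dispersion across groups per gene and
  equalised library sizes; strongly unequal depths rely on the rounding
  approximation above.
- Moment dispersion estimates are noisy at very low counts; the shrinkage
  weight is fixed, not empirical-Bayes.
- The length correction is strictly linear in LogTL; a curved dependence
  would leave structure in the residuals (the Spearman diagnostic of the
  corrected table exposes this).
- glycoATP inherits any miscalibration of the proton-conversion constants;
  with the transparent defaults it is numerically ECAR-based.
- The auto test selection is a convention, not an inference about
  normality.
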