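# Methods

## The model

`cshdwi` implements the Consumption-and-Supply Hypoxia (CSH) approach to
imaging tumor hypoxia with diffusion-weighted MRI (DWI), as applied to
prostate cancer. The biological premise is that a voxel is hypoxic when
oxygen *consumption* is high — proxied by high cellularity, i.e. a low
apparent diffusion coefficient (ADC) — while oxygen *supply* is low,
proxied by a low fractional blood volume (fBV). On a (fBV, ADC) scatter
the hypoxic region is bounded by a line with axis intercepts ADC₀ and
fBV₀:

    voxel hypoxic  ⇔  ADC/ADC₀ + fBV/fBV₀ < 1

The intercepts shipped as defaults, ADC₀ = 0.79×10⁻³ mm²/s and
fBV₀ = 0.43, are the published values trained against pimonidazole
staining of prostatectomy specimens; this package never refits them
(no pimonidazole ground truth is in scope). Per lesion the biomarker is
the hypoxia fraction HF_DWI = (hypoxic valid voxels)/(valid voxels).

Two conventions here were genuinely open and are the package's own:

* **Boundary voxels** (score exactly 1) count as non-hypoxic (strict
  inequality). The boundary has measure zero on continuous data; the
  strict rule makes small worked examples unambiguous.
* **HF denominators** use only voxels with a valid IVIM fit; a lesion
  with zero valid voxels raises an error rather than reporting HF = 0.
* The per-voxel hypoxia level exported for visualisation is the clipped
  deficit HL = max(0, 1 − score): zero on/above the line, one at the
  origin. No statistic consumes HL.

## Segmented IVIM fit

DWI signals follow the intravoxel-incoherent-motion model
S(b) = S₀[f·exp(−b·D*) + (1−f)·exp(−b·D)]. Above a perfusion-suppression
threshold the D* term is negligible, so the estimator is segmented: an
OLS line through log S(b) for b ≥ 200 s/mm² gives slope −ADC, and the
intercept extrapolated to b = 0 gives S_int = S₀(1−f), hence
fBV = 1 − S_int/S(0). D* is never estimated — with only two or three
high-b samples per scheme a free-D* fit would be overparameterised, and
the CSH model does not use it.

Numerical choices:

* threshold 200 s/mm², inclusive, so the 3-point scheme (0, 200, 800)
  uses {200, 800} and the 4-point scheme (0, 50, 300, 800) uses
  {300, 800} — both at least the required two points;
* ADC clamped to [0, 4×10⁻³] mm²/s and fBV to [0, 1]; small negative
  noise excursions are clamped rather than rejected so lesion voxel
  counts (the HF denominator) are preserved;
* a voxel is invalid only when S(0) ≤ 0, a high-b sample is ≤ 0, or
  fewer than two high-b samples exist; invalid voxels propagate out of
  every downstream median and HF.

In biexponential data the segmented estimator carries the well-known
perfusion-leakage bias (residual D* signal at b = 200 steepens the
slope); a test pins this bias against the closed-form evaluation of the
estimator on the exact forward signal.

## Cross-cohort calibration

To transfer the model to a second center, clinical differences are
removed first, then protocol differences:

1. **Propensity matching.** Logistic regression of target-cohort
   membership on indicator-coded pGG (five levels) and pTstage (two
   levels); 1:1 *optimal* matching without replacement on the logit
   scale, solved as a rectangular assignment problem. Every reference
   patient is kept; only target patients may drop (the ATC estimand).
   Ties break deterministically in lexical patient-id order. When a
   covariate stratum exists in only one cohort the logistic fit is
   perfectly separated; the package then matches stratum-exactly
   (within-stratum pairing first, leftover references by logit
   distance) and logs a warning. Stratum-exact pairing, not merely
   propensity-equality pairing, is what makes matched covariate
   marginals identical to the reference whenever counts permit —
   distinct strata can collide on the same propensity value. Balance
   is reported as standardized mean differences (pooled-SD form,
   0/0 ≡ 0) before and after matching.
2. **Median scaling.** F_ADC = median ADC(reference)/median ADC(target)
   over the pooled lesion voxels of the matched cohorts (all voxels
   concatenated, not per-lesion medians), and likewise F_fBV; target
   voxels are multiplied by the factors, fBV re-clamped to [0, 1] with
   a logged clamp count. The reference cohort is never altered. Because
   the CSH score is invariant under jointly scaling a parameter and its
   intercept, median scaling is exactly the transformation the model
   tolerates; the medians' equivariance under positive scaling makes
   bias recovery exact on noise-free copies (a property the tests
   assert at 1e−12).

pGG is treated as categorical in the propensity model (the matched
design reproduced grade tables exactly, which indicator coding with
optimal matching achieves when feasible) and as numeric 1–5 only in the
correlation analysis.

## Statistics

Two-sample HF comparisons (pGG < 3 vs ≥ 3; pTstage 2 vs 3, one HF per
patient from the highest-grade index lesion) are assumption-gated: a
pooled-variance t-test only if both groups pass Shapiro-Wilk normality
and Levene's homogeneity at the same α (default 0.05), otherwise
Mann-Whitney U; all tests two-sided; the gate decision is logged. The
conjunction rule is the package's choice — source descriptions of such
gates rarely pin down the exact rule. Across all five grades the
analysis is per-lesion: Kruskal-Wallis with tie correction (all-equal
data returns H = 0, p = 1, not an error) and a Pearson correlation of
HF against grade codes 1–5 (Spearman available). No multiplicity
correction is applied, matching the analysis the pipeline mirrors.

## Synthetic cohorts

The generator produces the statistical structure the pipeline needs and
nothing anatomical:

| parameter | default | meaning |
|---|---|---|
| n_patients | 106 | reference-cohort size |
| pgg_probs | (8,44,26,16,12)/106 | grade-group mix (reference) |
| ptstage3_prob_by_pgg | .30,.50,.75,.85,.90 | grade→stage-3 probability (overall ≈ 0.64) |
| lesion_size_range | 50–2000 voxels | uniform lesion size |
| extra_lesion_prob | 0.10 | chance of a second lesion (319 lesions/291 patients externally) |
| adc_center_by_pgg | 0.78→0.64 ×10⁻³ mm²/s | grade-wise ADC center |
| fbv_mean_by_pgg | 0.145→0.114 | grade-wise fBV mean |
| adc_sigma_voxel / adc_sigma_lesion | 0.09 / 0.06 ×10⁻³ | voxel spread / lesion latent scale |
| fbv_concentration / fbv_logit_sigma_lesion | 50 / 0.22 | Beta concentration / latent scale |
| copula_rho | 0.35 | voxel-level ADC–fBV coupling |
| bias_adc / bias_fbv | 1.0 / 1.0 (study runs use 1.2 / 0.65) | multiplicative center effect |
| noise_sigma | 0.02 | Rician σ relative to S₀ (SNR 50 at b = 0) |
| s0, bvalues | 1000, (0,200,800) | baseline signal, acquisition scheme |
| dstar | 10×10⁻³ mm²/s | pseudo-diffusion (biexponential mode) |

Per lesion a latent severity factor u ~ N(0,1) shifts the ADC center by
0.06×10⁻³·u and the fBV mean by 0.22·u on the logit scale; within the
lesion, voxel ADC is truncated-normal on [0.1, 3.0]×10⁻³ and fBV is
Beta, coupled through a Gaussian copula (ρ = 0.35). Grade enters only
through the decreasing centers, so the true HF of a lesion is an
emergent quantity, recomputable exactly from the stored voxels — that
choice (rather than sampling HF directly) is what lets end-to-end tests
demand exact recovery. The grade-wise centers were fixed once so that
the cohort-level outputs sit at physiologic magnitudes: pooled voxel
medians near 0.70×10⁻³ mm²/s and 0.12, and lesion-median HF near 0.11
for pGG < 3 versus 0.27 for pGG ≥ 3 at large n.

Signals are generated either in `ideal` mode (perfusion contributes only
at b = 0; the segmented estimator is then exactly unbiased, which is the
configuration for exact-recovery tests and the default) or in
`biexponential` mode (residual D* signal at all b; exhibits the
segmented fit's leakage bias). Magnitude noise is Rician,
S′ = √((S+ε₁)² + ε₂²), the correct model for magnitude MRI and
positively biased at low signal (Rayleigh floor σ√(π/2) at S = 0). The
default center biases used in study-shaped runs, ADC ×1.2 and fBV ×0.65,
imply ideal recovery factors 1/1.2 ≈ 0.83 and 1/0.65 ≈ 1.54.

What the generator does *not* emulate — and hence what passing tests do
not establish about real data: anatomy and partial-volume effects,
spatial noise correlation and distortion, scanner-specific non-linear
(non-multiplicative) parameter biases, delineation variability, and any
link between lesion size and grade. Passing tests show the estimators
and the transfer machinery are correct under the stated generative
assumptions, not that the biomarker is biologically valid.

## Problem sizes and determinism

All randomness flows through one `numpy` Generator seeded from the
config; identical configs reproduce bit-identical cohorts, artifacts and
summary JSON. Default test and reproduction runs use desk-scale sizes
chosen to keep the whole suite in minutes: unit fixtures of 4–20
patients with 20–80-voxel lesions; the statistical-layer calibration
checks use 1000 null replicates at n = 106 per group and 50 power
replicates at the full study size; the reproduction script simulates
106 reference and 291 target patients at full lesion sizes.

## Known limitations

* The segmented fit assumes complete perfusion suppression at
  b ≥ 200 s/mm²; in biexponential data ADC is biased high and fBV low.
* Median scaling corrects only a global multiplicative center effect; it
  cannot correct b-value-scheme-dependent distribution *shape*
  differences (no ComBat-style harmonisation is attempted).
* With two high-b points the per-voxel ADC noise at SNR 50 is of the
  same order as the biological voxel spread, so fitted HF distributions
  are wider than the underlying truth; threshold-based fractions are
  accordingly noise-sensitive even when the parameter medians are not.
* pTstage separation of HF arises only indirectly (stage correlates with
  grade), so it is weaker in simulation than grade separation.
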