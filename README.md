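# cshdwi

Consumption-and-Supply Hypoxia (CSH) imaging from multi-b-value
diffusion-weighted MRI, for quantitative-imaging researchers who want to
compute the lesion hypoxia fraction **HF_DWI** in prostate cancer and
transfer the model between centers.

Tumor hypoxia drives radioresistance and metastasis, but routine hypoxia
assessment needs a non-invasive readout. The CSH model reads hypoxia off
two DWI-derived maps: the apparent diffusion coefficient (ADC, a proxy
for cellularity and hence oxygen *consumption*) and the fractional blood
volume (fBV, a proxy for oxygen *supply*). A voxel is classified hypoxic
when

```
ADC/ADC₀ + fBV/fBV₀ < 1,    ADC₀ = 0.79×10⁻³ mm²/s,  fBV₀ = 0.43
```

and a lesion's HF_DWI is the fraction of its (valid-fit) voxels below
that line. The package implements the full validation workflow:

* **`ivim`** — segmented intravoxel-incoherent-motion fit: OLS of
  log S(b) over b ≥ 200 s/mm² gives ADC; the b = 0 extrapolated
  intercept gives fBV = 1 − S_int/S(0). Supports the (0, 200, 800) and
  (0, 50, 300, 800) s/mm² schemes.
* **`csh`** — voxel scores, hypoxia flags, HL maps, per-lesion HF_DWI.
* **`calibration`** — cross-center transfer: propensity-score *optimal*
  1:1 matching on pGG/pTstage (every reference patient kept), balance
  diagnostics, and median scaling
  F_ADC = median ADC(ref)/median ADC(target), likewise F_fBV.
* **`cohort_stats`** — assumption-gated t / Mann-Whitney comparisons of
  HF_DWI by grade group and stage, Kruskal-Wallis across grades 1–5 and
  the HF–grade Pearson correlation.
* **`synthetic_cohort`** — a seeded two-center cohort generator
  (grade-dependent voxel distributions, IVIM forward signals with Rician
  noise, multiplicative center biases) so the whole pipeline runs and is
  tested without patient data.
* **`io_formats`** / **`cli`** — NIfTI volumes, CSV tables, and the
  `cshpipe` command line.

## Worked example

Fit one voxel acquired at b = (0, 200, 800) s/mm² and score it:

```python
from cshdwi import fit_voxel_segmented, csh_score, CSHParams

adc, fbv, ok = fit_voxel_segmented([1000.0, 782.42, 514.09], [0, 200, 800])
print(f"ADC = {adc*1e3:.3f}e-3 mm^2/s, fBV = {fbv:.3f}, valid = {ok}")
s = csh_score(adc, fbv, CSHParams())
print(f"CSH score = {s:.3f} -> {'hypoxic' if s < 1 else 'non-hypoxic'}")
```

```
ADC = 0.700e-3 mm^2/s, fBV = 0.100, valid = True
CSH score = 1.119 -> non-hypoxic
```

The voxel diffuses too freely (0.700/0.79 ≈ 0.89 of the ADC intercept)
for its moderate perfusion to matter: the score exceeds 1, so it lies on
the normoxic side of the line.

Run a small two-center study — a 40-patient reference cohort and a
100-patient imbalanced target cohort whose true ADC and fBV carry
multiplicative center biases of 1.2 and 0.65:

```python
from cshdwi import PipelineConfig, SimulationConfig, run_all
from cshdwi.synthetic_cohort import FULL_NKI_PGG_PROBS

cfg = PipelineConfig(sim=SimulationConfig(
    n_patients=40, target_n_patients=100,
    target_pgg_probs=FULL_NKI_PGG_PROBS,
    bias_adc=1.2, bias_fbv=0.65, seed=1))
result = run_all(cfg)
```

Selected `result.summary` output:

```json
{
  "n_matched_pairs": 40,
  "scaling_factors": {"f_adc": 0.8067, "f_fbv": 1.4369},
  "max_abs_smd_before": 0.4444,
  "max_abs_smd_after": 0.1021
}
```

Matching keeps all 40 reference patients and improves covariate balance
(max |SMD| 0.44 → 0.10); the estimated scaling factors sit near the
ideal inverses of the injected biases (1/1.2 ≈ 0.83, 1/0.65 ≈ 1.54),
the residual deviation reflecting sampling and Rician noise at this
cohort size. The per-lesion HF–grade correlation in the target cohort is
positive and significant (ρ = 0.50, p = 3.9×10⁻⁸ on 106 lesions),
reflecting the generator's grade-dependent hypoxia.

The same workflow is available from the shell:

```
cshpipe simulate --out-dir sim/
cshpipe ivim-fit --dwi sim/REF-001_dwi.nii.gz --bvals 0,200,800 \
        --mask sim/REF-001_mask.nii.gz --out-adc adc.nii.gz --out-fbv fbv.nii.gz
cshpipe run-all --seed 1 --out-dir run/
```

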