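# dcekinet

Pharmacokinetic response assessment for breast DCE-MRI acquired at **high
spatial but low (~1 min) temporal resolution** — the regime of routine 3D
breast protocols, where only the post-first-pass decay of the contrast bolus
is sampled and only the simplest tracer-kinetic model is identifiable.

The package is aimed at imaging scientists evaluating neoadjuvant
chemotherapy response: it turns a 4D dynamic series plus tumor/artery ROIs
into voxelwise kinetic maps, reduces them to per-patient percent changes,
and scores those changes against pathology with cutoff rules, ROC analysis
and nonparametric tests.

## The model

Signal enhancement is assumed proportional to gadolinium concentration at
the low concentrations of the decay phase, so relative concentration is the
baseline-subtracted signal (amplitude constant R = 1 for both tissue and
artery; R cancels in the fit). Tissue kinetics follow the Tofts / modified
Kety model with negligible plasma volume:

```
C_t(t) = K^trans ∫₀ᵗ C_p(u) · exp(−(K^trans/V_e)(t−u)) du
```

where `K^trans` (min⁻¹) is the plasma↔EES transfer constant, `V_e` the
fractional extravascular-extracellular (leakage) volume and
`k_ep = K^trans/V_e` the efflux rate. The plasma input `C_p` comes either
from a **measured** arterial ROI (a 9-pixel square tracking the internal
thoracic artery, with manual per-frame motion shifts) or from the
**theoretical** Weinmann population biexponential

```
C_p(t) = D·(a₁ e^(−m₁ t) + a₂ e^(−m₂ t)),
a₁ = 3.99, a₂ = 4.78 kg/L,  m₁ = 0.144, m₂ = 0.0111 min⁻¹
```

with dose `D` in mmol/kg (default 0.1). Fitting is bounded nonlinear least
squares per voxel; classification uses simple cutoff rules on pre/post
percent changes (a drop at least as large as the cutoff ⇒ responder), with
sensitivity/specificity reported against Sataloff pathology grades
(A complete, B partial, C+D non-responder) alongside exact Clopper-Pearson
confidence intervals, pair-counting AUCs and DeLong paired AUC comparisons.

A 24-patient reference cohort (kinetic and size changes with clinical and
pathologic labels) ships as a checksum-pinned fixture, and synthetic
generators provide 4D phantoms and patient cohorts with known ground truth.

## Worked example

```python
import dcekinet as dk

# a noisy digital phantom: one lesion with Ktrans=0.2 min^-1, Ve=0.3,
# a thick artery carrying the input function, 2% Rician noise
ph = dk.generate_phantom(dk.PhantomConfig(sigma=0.02, seed=7))

# measured AIF from the 9-pixel artery square, then voxelwise Tofts maps
aif, track = dk.measure_aif(ph.series, seed_center=(3, 3, 3))
pm = dk.fit_tofts_map(ph.series, ph.rois["tumor"], aif)
kt, ve = dk.summarize_roi(pm)
print(f"fitted voxels: {pm.n_fitted}")
print(f"median Ktrans = {kt:.3f} min^-1 (truth 0.200)")
print(f"median Ve     = {ve:.3f}          (truth 0.300)")
```

prints

```
fitted voxels: 81
median Ktrans = 0.200 min^-1 (truth 0.200)
median Ve     = 0.305          (truth 0.300)
```

i.e. the tumor-median kinetics are recovered from the noisy series to within
a few percent. On the clinical side, the packaged cohort reproduces the
response-assessment layer:

```python
rep = dk.reproduce_reference_analysis()
blk = rep["cutoff_analyses"]["ve_measured"]
print(blk["counts"])                       # {'tp': 8, 'fp': 1, 'tn': 12, 'fn': 3}
print(blk["rates"]["sensitivity"],         # 73
      blk["rates"]["specificity"],         # 92
      round(blk["auc"], 2))                # 0.83
```

A V_e drop smaller than 72% (measured AIF) flags 8 of the 11 pathologic
non-responders while excluding only 1 of 13 responders — sensitivity 73%,
specificity 92%, AUC 0.83.

The same operations are scriptable from the shell:

```
dcekinet reproduce --out report.json
dcekinet classify --param ve --aif measured --cutoff -72
dcekinet simulate phantom --seed 0 --out phantom/
dcekinet fit --series s.nii.gz --times times.csv --roi roi.csv --aif aif.csv --out maps/
```

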