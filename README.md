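# licseg

Automated liver segmentation on MRI liver-iron-concentration (LIC) maps.

Patients with transfusion-dependent anaemias (e.g. thalassemia major)
accumulate iron in the liver; clinical monitoring reads the **median LIC**
over a liver region of interest drawn on a quantitative MRI map. Producing
that ROI by hand on every exam is the bottleneck. `licseg` implements a fully
automated replacement for the manual tracing step on a single trans-axial
multi-echo gradient-echo slice, plus the evaluation statistics needed to
judge it, and a seeded synthetic-phantom generator to exercise the whole
pipeline with known ground truth.

## Method

1. **Relaxometry.** Each pixel's echo train is fitted with the offset model
   `S(TE) = S0·exp(−R2*·TE) + C` (bounded non-linear least squares, all
   parameters ≥ 0); R2\* (s⁻¹) converts to iron concentration by the linear
   calibration `LIC = 0.202 + 0.0254·R2*` in mg Fe/g dry weight.
2. **Body ROI.** Otsu thresholding of the first-echo image, hole filling,
   largest connected object.
3. **Landmark ROI restriction.** Fuzzy c-means (c = 6, m = 2) on first-echo
   intensities in a sub-window around the body centroid finds the brightest
   cluster — the abdominal aorta and IVC. A half-plane cut from the aorta
   through the anterior point of the assumed left midclavicular line (2/3 of
   the way from the midline to the patient-left body edge) rejects the
   patient-left region, where organs can share the liver's LIC.
4. **Liver segmentation.** FCM (c = 2, m = 2) on LIC values inside the
   restricted ROI; the higher-centroid cluster is the liver, hardened at a
   membership threshold MT = 0.5.
5. **Post-processing.** Opening + closing with a 5-pixel disk, hole filling,
   largest object; then erosion by an 8-pixel disk (the "erosion size", ES)
   for the clinical mask, which deliberately stays clear of the uncertain
   liver edge. The median LIC is read over the clinical mask.

Evaluation uses %DSC, %JC, Hausdorff distance (mm), the under-/
over-segmentation fractions %FP and %FN (type I vs the manual clinical mask,
type II vs the manual entire-liver mask — %FN-type-II = 0 is the clinical
acceptability requirement), output grades I/II/III, and paired agreement
statistics (Bland–Altman, %CV, R², paired t) for median LIC.

## Worked example

```python
from licseg import PhantomSpec, generate_phantom, run_pipeline, evaluate_clinical

stack, truth = generate_phantom(PhantomSpec(seed=42))   # 256x256, 20 echoes
result = run_pipeline(stack)
report = evaluate_clinical(result.liver_clinical, truth.clinical_liver,
                           truth.entire_liver, stack.pixel_spacing_mm)

print(f"landmarks detected : {result.landmarks.detection_ok}")
print(f"aorta (row, col)   : ({result.landmarks.aorta_rc[0]:.1f}, {result.landmarks.aorta_rc[1]:.1f})")
print(f"median LIC         : {result.median_lic:.2f} mg/g dw")
print(f"%DSC / %JC         : {report.dsc_pct:.2f} / {report.jc_pct:.2f}")
print(f"Hausdorff          : {report.hausdorff_mm:.2f} mm")
print(f"%FP / %FN-I / %FN-II: {report.fp_pct:.2f} / {report.fn_type1_pct:.2f} / {report.fn_type2_pct:.2f}")
print(f"output grade       : {report.grade}")
```

Output:

```
landmarks detected : True
aorta (row, col)   : (157.8, 145.9)
median LIC         : 10.13 mg/g dw
%DSC / %JC         : 99.63 / 99.26
Hausdorff          : 4.80 mm
%FP / %FN-I / %FN-II: 0.64 / 0.10 / 0.00
output grade       : I
```

The phantom assigns the liver 10 mg/g dw; the automated clinical mask stays
entirely inside the true liver (%FN-type-II = 0, grade I) and reads the
median LIC back to within the Rician-noise bias of the fit.

The same flow is available from the shell:

```sh
licseg simulate --n 1 --seed 42 --preset standard --out work/
licseg segment  --input work/case_000.npz --seed 42 --out work/seg/
licseg evaluate --auto work/seg/liver_clinical.png \
                --manual-entire work/case_000_entire.png \
                --manual-clinical work/case_000_clinical.png
```

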