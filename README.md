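# t2rp — T2-mapping MRI pipeline for radiation-induced pneumonitis

`t2rp` detects and localizes radiation-induced pneumonitis (RP) after lung
radiotherapy from quantitative MRI.  RP is an inflammatory lung injury that
appears weeks to months after stereotactic body radiotherapy; the
infiltration of inflammatory cells obliterates air-tissue interfaces,
reduces magnetic-field inhomogeneity and *prolongs T2 relaxation*.  A
multi-echo T2-weighted follow-up acquisition therefore carries a dose-free
signature of RP that can replace some of the repeated follow-up CT scans.
The package is aimed at medical-physics and quantitative-imaging
researchers who want a tested, fully reproducible implementation of this
workflow, including a synthetic cohort generator so every stage can be
validated without patient data.

## Method

For each patient, co-registered volumes are processed as follows:

1. **T2 mapping** — five echo volumes (TE = 18, 36, 61, 100, 131 ms) follow
   mono-exponential decay S(TE) = S₀·exp(−TE/T2); ln S is fitted
   voxel-by-voxel by ordinary least squares, T2 = −1/slope.  Echoes below a
   noise floor are dropped per voxel; non-decaying voxels are flagged
   invalid.
2. **Dose geometry** — the planned dose is converted to EQD2 under the
   linear-quadratic model, EQD2 = D·(d + α/β)/(2 + α/β) with α/β = 3 Gy,
   and V20 is the lung volume receiving more than 20 Gy (EQD2).
3. **Baseline correction** — with no pre-treatment T2 map available, the
   lung is split into six cranio-caudal sub-volumes (three per lung); the
   band farthest from the tumor, averaged over the GTV-bearing coronal
   slices, gives T̄₂,ref, and T2,corr = T2 − T̄₂,ref.
4. **Stratification** — per patient, the mean corrected T2 in the PTV
   (T̄₂,corr^PTV) and in (V20 ∩ lung) \ GTV.  Each parameter is scored
   against the endpoint RP grade ≥ 1 by ROC analysis with 5000 patient
   bootstrap resamples (median ROC + 95% CI), a two-sided Mann-Whitney U
   test (α = 0.05), and the Youden index J = sensitivity + specificity − 1
   maximized along the median ROC curve to fix a cut-off.
5. **Segmentation** — voxels of the corrected map inside V20 ∩ lung above
   the cut-off, smoothed by slice-wise 6×6 dilation and 3×3 erosion, form
   the predicted RP mask.  RP patients whose follow-up CT and MRI are more
   than four weeks apart are excluded.  Masks are scored with DSC,
   sensitivity, precision, voxel-level SegAUC and HD95 (mm).

The synthetic module generates the whole cohort — two-lung anatomy, GTV/PTV,
sigmoidal dose falloff, lung T2 background with an elevated-T2 RP region,
Rician-noise multi-echo signal, outcomes and follow-up dates — reproducibly
from one seed.

## Worked example

```bash
python examples/04_stratification.py
```

```
cohort: 15 RP / 9 non-RP patients
PTV parameter medians:  RP 10.3 ms, non-RP 5.3 ms
median bootstrap AUC:   0.75 [0.52, 0.93]
Mann-Whitney:           U = 100, p = 0.0564
Youden index:           0.52 at cut-off 10.0 ms (sens 0.60, spec 0.92)
```

The cohort's RP patients show a ~5–10 ms elevation of the mean
baseline-corrected PTV T2; the median bootstrap AUC of 0.75 quantifies how
well that parameter separates RP from non-RP patients, and the 10.0 ms
Youden cut-off is the threshold later applied voxel-wise for segmentation.
The other examples (`examples/01…06`) walk through cohort simulation, T2
fitting, baseline correction, segmentation scoring and the end-to-end run;
the same pipeline is available from the shell:

```bash
t2rp run-all --out out --seed 1        # or: simulate / fit-t2 /
                                       # extract-params / stratify / segment
```

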