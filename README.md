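# glymphkit

Multi-compartment glymphatic analysis of multi-shell diffusion MRI.

The glymphatic system clears brain metabolic waste along a three-limb route:
CSF influx through periarterial spaces (pAs), exchange with interstitial
fluid in the white-matter (WM) parenchyma, and efflux through perivenous
spaces (pVs).  `glymphkit` measures all three limbs in vivo:

* **Periarterial**: an anisotropic bi-tensor ("tissue + free water") model

      S(b, g) = S0 [ f·exp(−b gᵀD_fluid g) + (1−f)·exp(−b gᵀD_tissue g) ]

  fitted voxelwise to multi-shell DWI.  Unlike classical free-water
  elimination, the fluid tensor is anisotropic, so its axial diffusivity
  (FWAD) captures directional fluid mobility along perivascular channels;
  the mixing fraction `f` is the free-water volume fraction (FWVF).
* **Parenchymal**: WM-FWVF, the mean free-water fraction over WM after
  excluding lesion (WMH) and pAs voxels.
* **Perivenous**: the DTI-ALPS index,
  `mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc)`,
  from directional diffusivities in projection- and association-fiber ROIs.

Around the fitting core: perivascular-space morphometry (connected
components, medial-axis diameters, elongation, false-positive filtering,
WMH subtraction), cortical ROI mapping into superficial WM (Laplacian depth
≤ 5 mm + k-NN label propagation), selection of the four largest pAs per ROI
with the sensitivity procedure that justifies the four, subject-level
feature extraction, and the cohort statistics: standardized-β regressions
with Benjamini–Hochberg FDR, ANCOVA with Tukey HSD and a rank-based
fallback, stratified 10-fold cross-validated classification with pairwise
DeLong AUC tests, and serial two-mediator bootstrap mediation.  Synthetic
generators (DWI phantoms with pAs tubes and WMH blobs, Rician noise, cohort
tables with planted effects) make the whole pipeline testable without
scanner data.

Who it is for: researchers quantifying glymphatic function from multi-shell
DWI (HCP-Aging- or ADNI-style protocols), and anyone needing a tested,
scriptable implementation of the bi-tensor/ALPS/pAs metric stack with its
statistical battery.

## Worked example

Simulate a phantom, fit it, and extract subject features:

```bash
glymphkit simulate --preset hcpa --shape 10,10,10 --snr 30 --seed 7 --out sim/
glymphkit fit --dwi sim/dwi.nii --bval sim/dwi.bval --bvec sim/dwi.bvec \
              --mask sim/mask_brain.nii --out maps/
glymphkit pas --pas-mask sim/mask_pas.nii --wm-mask sim/mask_wm.nii \
              --wmh-mask sim/mask_wmh.nii --out pas/
glymphkit extract --maps maps/ --pas-mask sim/mask_pas.nii \
                  --wm-mask sim/mask_wm.nii --wmh-mask sim/mask_wmh.nii \
                  --out features.tsv
```

Or in Python:

```python
import glymphkit as gk
from glymphkit.synthetic import PhantomSpec, render_phantom
import numpy as np

scheme = gk.make_scheme("hcpa", seed=0)            # 6 b0 + 45@b1500 + 45@b3000
spec = PhantomSpec(shape=(10, 10, 10), snr=30.0, seed=7)
dwi, labels, truth, masks = render_phantom(spec, scheme)
maps = gk.fit_volume(dwi, masks["brain"], scheme, spacing=spec.spacing)

print("pAs FWVF:", np.nanmean(maps["FWVF"][masks["pas"]]))
print("WM  FWVF:", np.nanmean(maps["FWVF"][masks["wm"]]))
print("MAE vs truth:", np.nanmean(np.abs(maps["FWVF"] - truth["FWVF"])[masks["brain"]]))
```

prints

```
pAs FWVF: 0.9507744311205029
WM  FWVF: 0.09865886399233723
MAE vs truth: 0.0224155204128282
```

— the perivascular tube (true FWVF 0.9) is cleanly separated from white
matter (true 0.1) at SNR 30, with a map-level mean absolute error near 0.02.

A statistics example on a synthetic cohort with a planted mediation chain
(diastolic blood pressure → periarterial FWAD → amyloid SUVR → cognition):

```python
from glymphkit.synthetic import CohortSpec, make_cohort

pheno, features, truth = make_cohort(
    CohortSpec(n=2000, a1=0.5, a2=0.5, b=0.5, c_prime=0.0,
               mediation_noise_sd=0.2, seed=6))
res = gk.serial_mediation("med_x", "med_m1", "med_m2", "med_y",
                          pheno, n_boot=1000, seed=1)
print(res.indirect, (res.ci_low, res.ci_high), res.significant)
```

prints an indirect effect of `0.125…` (the planted a₁·a₂·b = 0.125) with a
bias-corrected 95 % CI excluding zero.

`docs/methods.md` describes the model, the noise handling (Rician floor
correction, noise-scaled priors, spatially regularised volume fits), every
default, and the limitations.

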