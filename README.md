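# octamacula

Quantification of the macular microvasculature on en-face OCT-angiography
(OCTA), for researchers studying retinal capillary damage — e.g. radiation
maculopathy after ocular plaque brachytherapy — who need reproducible,
automated image biomarkers instead of instrument-reported numbers.

From a 3×3 mm en-face angiogram (365×365 px export, one image per
capillary plexus: superficial SCP, deep DCP) the pipeline computes:

* **VAD** — vessel area density: the fraction of region area covered by
  binarized vessels, `VAD = |vessel px ∩ region| / |region|`;
* **VSD** — vessel skeleton density: the same ratio for 1-px-wide vessel
  centerlines, which removes the weight of large-vessel caliber;
* **FAZ area** — the foveal avascular zone, in mm², found as the enclosed
  avascular connected component at the image center;
* **burnout** classification — nonperfused area within the central 3-mm
  disc above a threshold (default 6 mm²), flagging end-stage eyes;
* paired-eye **cohort statistics** — treated-vs-fellow contrasts with a
  patient-clustered bootstrap (eyes are correlated within patients),
  Spearman rank correlations against radiation dose, and ROC/AUC for
  burnout prediction.

Regions follow the ETDRS convention: the 1-mm-diameter foveal disc and
the 1–3 mm parafoveal annulus, centered on the fovea.

The enhancement chain mirrors the published analysis procedure:
border crop (365 → 364 px) → homomorphic illumination correction →
normalization → subtraction of the FAZ noise floor → top-hat/bottom-hat
contrast enhancement (disc, radius 4 px) → bilateral denoising →
multiscale Hessian vesselness with a τ-regularized response → Otsu
binarization → topology-preserving skeletonization.

Because patient OCTA exports are generally not shareable, the package
ships a synthetic angiogram generator (`octamacula.synthgen`) that renders
branching capillary networks around an elliptical FAZ with programmable
density, noise, vignetting, burnout attenuation and paired-eye cohort
structure — with exact pixel-level ground truth, so every stage is
validated end to end.  See `docs/methods.md` for the models and their
limitations.

## Worked example

Generate and analyze a 10-patient synthetic cohort (each patient: one
treated and one fellow eye, two plexus each; treated eyes carry a
programmed density deficit and FAZ enlargement):

```bash
octa-macula demo --out demo_run --n-patients 10 --seed 42
```

The run writes per-eye phantom images, a ground-truth table, the measured
metrics table and the statistical report under `demo_run/`.  The summary
begins:

```
Group comparisons (clustered bootstrap):
        vad_foveal_scp treated vs fellow: diff=-0.0675 CI95=(-0.1050, -0.0254) p=0.0060
    vad_parafoveal_scp treated vs fellow: diff=-0.0310 CI95=(-0.0486, -0.0124) p=0.0020
        vad_foveal_dcp treated vs fellow: diff=-0.0792 CI95=(-0.1179, -0.0325) p=0.0030
    vsd_parafoveal_dcp treated vs fellow: diff=-0.0138 CI95=(-0.0232, -0.0047) p=0.0010
           faz_scp_mm2 treated vs fellow: diff=+0.2685 CI95=(+0.0207, +0.4899) p=0.0320
```

Read: measured from the rendered images alone, treated eyes lost ~6.8
points of foveal SCP vessel area density and ~7.9 points at the DCP
(fractions ×100 give percent), their skeleton densities dropped, and
their FAZ grew by ~0.27 mm² — the programmed injury pattern, recovered
by the imaging chain and flagged significant by the clustered bootstrap.

The same stages are available individually (`octa-macula synthgen`,
`preprocess`, `quantify`, `faz`, `cohort`) and as library functions:

```python
from octamacula import PhantomParams, generate_phantom, run_preprocess
from octamacula import binarize_otsu, make_region_masks, vad

angio, truth = generate_phantom(PhantomParams(rng_seed=7, target_vad=0.32))
vessels = binarize_otsu(run_preprocess(angio.pixels))
foveal, parafoveal = make_region_masks(364, scan_width_mm=3.0)
print(round(vad(vessels, parafoveal), 3), round(truth.true_vad_parafoveal, 3))
# 0.309 0.321
```

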