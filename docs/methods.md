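# Methods

This note describes the models and procedures implemented in `octamacula`,
the choices made where the design was genuinely open, and what the
synthetic validation does and does not demonstrate.

## Problem setting

En-face OCT-angiography (OCTA) of the macula produces, per eye and per
capillary plexus (superficial, SCP; deep, DCP), a square grayscale image
in which flow appears bright.  The exported image is 365x365 px with a
1-px border; the 364x364 core represents a 3x3 mm field, i.e.
~8.24 um/px.  The quantities of clinical interest are:

* **VAD** (vessel area density): fraction of region area covered by
  binarized vessels;
* **VSD** (vessel skeleton density): fraction covered by 1-px
  centerlines, which de-emphasizes large-vessel caliber;
* **FAZ area** (mm^2): the capillary-free zone at the fovea;
* **burnout** classification: end-stage eyes whose capillary detail is
  undetectable.

Regions follow the ETDRS convention: the foveal disc (1 mm diameter) and
the parafoveal annulus (1-3 mm), centered on the fovea.

## Enhancement chain

The raw image passes through, in fixed order: grayscale conversion and
border crop; homomorphic filtering; min-max normalization; subtraction of
the mean of a sample region inside the FAZ; top-hat/bottom-hat contrast
enhancement; bilateral denoising; multiscale Hessian vesselness.  All
stages are deterministic, and intensities are clipped to [0, 1] between
stages.

**Homomorphic filter.**  `log1p` of the image is filtered in the Fourier
domain with a geometric transfer function `H(f) = lg^w(f) * hg^(1-w(f))`,
`w(f) = exp(-f^2 / 2 f0^2)`; defaults `f0` = 10 cycles/image, `lg` = 0.5,
`hg` = 1.5.  The geometric (log-gain) form was chosen over the additive
high-boost form because it composes cleanly: applying the filter twice
equals applying it once with squared gains, which makes the operator easy
to reason about and test.

**FAZ background subtraction.**  The original procedure selects a patch
inside the FAZ manually and subtracts its mean intensity, removing the
noise floor that instruments misread as flow.  Manual selection is not
reproducible, so the default sample region is a central disc of radius
15 px (the scan protocol centers the fovea, and a normal FAZ comfortably
contains this disc); an explicit mask can be supplied instead.  The
subtracted image is clipped at zero and *not* renormalized — renormalizing
would reintroduce the scale the subtraction just removed.

**Top-hat/bottom-hat.**  `clip(img + tophat - bottomhat, 0, 1)` with a
disc element of radius 4 px, the canonical contrast-enhancement
composition of the two residues.

**Bilateral filter.**  Defaults sigma_spatial = 3 px,
sigma_intensity = 0.1 (normalized units): strong enough to flatten sensor
noise, below typical vessel contrast (~0.3-0.7).

**Vesselness.**  At each scale `s` the scale-normalized Gaussian-derivative
Hessian eigenvalues `|l1| <= |l2|` are computed (mirror boundary handling,
with the sampled kernel's DC leakage subtracted so flat areas give exactly
zero curvature).  For bright ridges, `x = -l2` drives a tau-regularized
response bounded in [0, 1] that saturates for strong elongated structures
(`tau` = 0.75).  Because a 2-D Hessian cannot separate blobs from ridges
through `l2` alone, the response is multiplied by `1 - (l1/l2)^2` where
`l1 < 0`: 1 on ideal ridges, 0 at isotropic blob centers, gentle at vessel
junctions.  This suppresses speckle while keeping the dense capillary mesh
connected.  Default scales are {0.8, 1.2, 1.8} px.  Scales were matched to
capillary ridge widths at 8.2 um/px; a set extending to 3 px inflates the
apparent width of capillaries (the saturated response halo of a thin
vessel at a coarse scale is wide), which biases VAD upward by several
points — with {0.8, 1.2, 1.8} the VAD mean absolute error on phantoms is
~0.03 in both regions.

## Binarization, skeleton, densities

A single global Otsu threshold (256-bin between-class variance) binarizes
the vesselness map; vessels are the strictly-above-threshold class.  A
constant map yields all-background with a logged warning.  Skeletons come
from topology-preserving iterative thinning, followed by (a) pruning of
side-branches shorter than 3 px that terminate at a junction — open ends
of real centerlines are not shortened — and (b) a thinness repair pass
that removes any remaining fully-set 2x2 block.  At an X-crossing no
block pixel can be removed without disconnecting a branch; there the
crossing is shifted diagonally onto an adjacent vessel-mask pixel, which
preserves connectivity, with a least-damage removal as last resort.
Skeleton pixels count as unit length each; diagonal steps are not
weighted by sqrt(2).

Densities are stored as fractions and rendered as percentages in reports.
Otsu is computed once per image, not per region.

## FAZ extraction

FAZ extraction operates on the *raw* (cropped, normalized) image, not the
vesselness map.  Vessels are marked by an adaptive rule — above the local
25-px mean by an offset of 0.20, or above 0.50 absolutely (the absolute
arm covers saturated vessel fields where the local mean itself is high);
zero-mean speckle inside avascular zones stays below the offset.  Isolated
foreground specks of <= 20 px are removed; sequential binary closings with
square/rectangular elements {3x3, 5x1, 1x5, 5x5} bridge inter-capillary
gaps so the FAZ becomes one enclosed background region.  A final opening
is configurable but off by default: it tends to sever the thin perifoveal
arcade and leak the FAZ into the peripheral background.

Among 8-connected background components that do not touch the image
border, the component containing the image-center pixel is selected (scans
are fovea-centered by protocol); if the center pixel is on a vessel, the
largest component whose centroid lies within 0.6 mm of center is taken.
Ranking purely by size within a wide centroid cap proved fragile for
small FAZs, which can be out-sized by adjacent avascular pockets.  If no
candidate exists a `FAZNotFoundError` is raised — the expected outcome for
burnout eyes, where the ischemic area merges with the background.  Area
is pixel count times `(scan_width / side)^2`, reported in mm^2.

## Burnout classification and cohort statistics

Nonperfused area is the background remaining inside the central 3-mm disc
after morphologically closing the vessel map (disc radius 3 px, so normal
inter-capillary spacing does not count).  An eye is burnout when that
area exceeds 6 mm^2 (~85 % of the 7.07 mm^2 disc).  A 9 mm^2 cutoff
cannot be expressed inside a 3-mm disc, whose area it exceeds; 6 mm^2 is
the package default and is config-exposed.

Eyes are clustered within patients, so group contrasts use a
patient-clustered bootstrap: patients are resampled with replacement and
both of a patient's eyes move together.  The CI is the 2.5-97.5
percentile interval; the two-sided p-value doubles the add-one-corrected
tail fraction of bootstrap differences beyond zero.  Under a null cohort
the empirical type-I error at the 0.05 level is ~0.04-0.06 (200
simulations).  Eyes without a measurable value for a metric (e.g. FAZ not
found) drop out of that metric's comparison.  Generalized estimating
equations and multivariate logistic regression are deliberately out of
scope; the clustered bootstrap preserves the paired-eye design that GEE
would model.

Spearman's rho is the Pearson correlation of average ranks; its p-value
is exact (full permutation enumeration) for n <= 7, a seeded permutation
test (10^4 permutations) for n < 30, and the asymptotic t reference
otherwise.  ROC/AUC is the tie-corrected normalized Mann-Whitney
statistic with a sensitivity/specificity grid over unique thresholds.
No multiple-testing correction is applied.

## Synthetic angiogram generator

Real patient OCTA is not available, so validation rests on phantoms with
exact pixel-level truth.  The scene model:

* **Network**: stochastic branching trees seeded on the frame edge,
  stepping 25 um with small smooth heading jitter (capillaries are smooth
  arcs), branching at probability 0.10, widths drawn from 2-4 px (SCP) or
  1-3 px (DCP).  Trees are added until the parafoveal VAD reaches the
  programmed target (trees shrink as the target nears; the landed density
  is within ~0.001 of target).  Unreachable targets raise an error.
* **FAZ**: a randomly oriented ellipse of programmed area (mm^2),
  encircled by a continuous terminal capillary ring; vessels never
  intrude (a 1-px moat separates the masks).
* **Rendering**: background 0.18 with spatially correlated texture
  (sigma 1.5 px, amplitude 0.08) modeling sub-resolution capillary
  decorrelation — absent inside the FAZ, which is avascular by
  definition; per-vessel brightness U(0.40, 0.90) (decorrelation varies
  between vessels); optical blur sigma 0.8 px (~15 um FWHM lateral
  resolution); multiplicative linear illumination gradient (amplitude
  0.30 by default); additive Gaussian sensor noise (sigma 0.05 default);
  extra Gaussian speckle inside the FAZ (the false flow signal of poorly
  fixating eyes); quantization to 8 bits with a 1-px export border.
* **Burnout**: random vessel patches are deleted until exactly
  `round((1-a) n)` pixels survive (the last patch is trimmed, so the
  surviving area is exact); removed pixels are repainted with
  background-matched texture plus noise, and survivors lose contrast
  proportionally.
* **Cohorts**: each patient draws a baseline parafoveal VAD
  (SCP 0.321 +- 0.041, DCP 0.366 +- 0.035 — healthy fellow-eye values),
  shared by both eyes, which induces the inter-eye correlation the
  bootstrap must respect.  The treated eye receives the programmed
  deficit (percentage points), modulated by the centered foveal dose at a
  programmed slope; a fraction of treated eyes (default 0.29, tilted
  toward high-dose eyes through a logistic link) develop burnout, with
  their densities collapsed by the burnout attenuation (0.85).  RM
  (radiation-maculopathy) and no-RM subgroups carry multipliers weighted
  so the cohort mean deficit equals the programmed effect.  FAZ areas are
  log-normal around 0.30 mm^2, multiplied by the programmed enlargement
  factor in treated eyes.  Visual acuity (logMAR) worsens with the DCP
  deficit.  Doses, intervals and flags are drawn per patient.  The
  ground-truth table is parametric; rendering the phantom pairs is
  optional (`render=True`) and the pipeline measures them end to end.

## What the validation shows — and what it does not

Phantoms reproduce the geometry and the main nuisance structure of
en-face OCTA (avascular zone, plexus-specific density, vignetting,
speckle, texture, burnout), so passing tests demonstrate that the chain
recovers known densities (VAD MAE ~0.03, rank correlation >= 0.95), FAZ
areas (mean relative error ~4-8 %, rank correlation ~1.0) and programmed
cohort effects (a 12-point DCP deficit recovered within +-2 points at
n = 50).  They do not demonstrate performance on real OCTA: real speckle
is multiplicative and spatially structured, motion and projection
artifacts are absent from the model, and vessel tortuosity/anastomosis
statistics are only qualitatively right.

Two measured limitations are worth stating plainly:

* **Scale-free hallucination on empty images.**  The chain is invariant
  to global intensity scale (normalization, tau-relative vesselness,
  Otsu).  When true vessels are deeply attenuated, background texture is
  segmented instead and measured VAD stalls near 0.3 regardless of truth
  — the same noise-as-flow failure the instrument software exhibits on
  sick eyes.  Density monotonicity under attenuation therefore holds
  exactly at the metric layer (on vessel masks) but not through the
  measured chain at extreme attenuation, and measured densities of
  burnout eyes should not be interpreted.  Cohort analyses of burnout use
  the ground-truth flags.
* **Enhancement vs raw thresholding.**  On clean high-contrast phantoms
  a single global Otsu on the raw image is already near-optimal and the
  enhancement chain cannot beat it.  The chain's advantage appears on
  attenuated, dim, noisy vasculature — the irradiated-eye case it was
  designed for — where it improves mean segmentation Dice.

## Problem sizes

Default validation sizes keep the whole suite and the acceptance script
comfortably reproducible on one CPU: 20 phantoms per recovery sweep,
50 small (128-px) phantoms for the skeleton contract, 200 simulated
cohorts of 50 patients (1000 bootstrap draws each) for the type-I check,
and a 10-patient rendered demo cohort.
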