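"""Synthetic en-face OCTA phantoms with exact pixel-level ground truth.

Real macular OCTA exports are a square grayscale grid in which perfused
vessels appear as bright curvilinear structures converging on a dark,
capillary-free foveal avascular zone (FAZ).  The generator emulates that
scene so the downstream enhancement/segmentation/density stages can be
validated against known truth:

* a stochastic branching network grown from the image edge toward the
  macular center, stopped when a target vessel area density is reached;
* an elliptical FAZ of programmable area, encircled by a terminal
  capillary ring (the perifoveal arcade the FAZ extractor relies on);
* additive Gaussian speckle inside the FAZ — emulating the false flow
  signal that poorly fixating eyes produce on real instruments — plus
  global sensor noise and a low-frequency illumination gradient;
* a burnout transform that deletes vessel segments and dims survivors,
  emulating end-stage radiation maculopathy;
* paired-eye cohorts with patient-level baselines (inter-eye correlation),
  programmable treated-eye density deficits, dose-linked effect sizes,
  FAZ enlargement and burnout prevalence.

All randomness flows from ``numpy.random.default_rng(seed)``; equal seeds
give bit-identical phantoms and tables.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.draw import line as draw_line
from skimage.morphology import dilation, disk

from octamacula.types import EnFaceAngiogram, Plexus

_BACKGROUND = 0.18  # baseline tissue decorrelation level, normalized units
_VESSEL_LEVEL = 0.80  # nominal vessel intensity before blur/illumination
_VESSEL_LEVEL_RANGE = (0.40, 0.90)  # per-vessel decorrelation heterogeneity
_TEXTURE_AMP = 0.08  # sub-resolution capillary texture amplitude
_TEXTURE_SIGMA = 1.5  # spatial correlation of the background texture, px
_PSF_SIGMA = 0.8  # lateral point-spread blur, px (~15 um FWHM optics at 8.2 um/px)


class PhantomParameterError(ValueError):
    """Raised when phantom parameters are inconsistent or unreachable."""


@dataclass
class PhantomParams:
    """Scene parameters of one synthetic angiogram.

    ``target_vad`` is the vessel area density the network is grown to
    (measured in the parafoveal annulus when the 3-mm circle fits the
    frame, else over the whole frame).  ``image_side_px`` includes the
    1-px export border that the preprocessing crop removes.
    """

    image_side_px: int = 365
    scan_width_mm: float = 3.0
    faz_area_mm2: float = 0.30
    n_seed_vessels: int = 24
    branch_probability: float = 0.10
    vessel_width_px_range: tuple[int, int] = (2, 4)
    target_vad: float = 0.32
    noise_sigma: float = 0.05
    faz_noise_level: float = 0.05
    illumination_gradient_amp: float = 0.30
    burnout_attenuation: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.image_side_px < 64:
            raise PhantomParameterError("image_side_px must be >= 64")
        if not (0 <= self.faz_area_mm2 < self.scan_width_mm**2):
            raise PhantomParameterError(
                "faz_area_mm2 must lie in [0, scan_width_mm^2)"
            )
        for name in (
            "branch_probability",
            "target_vad",
            "illumination_gradient_amp",
            "burnout_attenuation",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise PhantomParameterError(f"{name}={v} outside [0, 1]")
        wmin, wmax = self.vessel_width_px_range
        if not (1 <= wmin <= wmax):
            raise PhantomParameterError("vessel_width_px_range must satisfy 1 <= min <= max")
        if self.target_vad > 0.70:
            raise PhantomParameterError(
                f"target_vad={self.target_vad} is not reachable by a curvilinear "
                "network (practical ceiling 0.70)"
            )

    @property
    def mm_per_px(self) -> float:
        return self.scan_width_mm / self.image_side_px


@dataclass
class GroundTruth:
    """Exact scene truth of a phantom; densities are pixel counts on the masks."""

    vessel_mask: np.ndarray
    faz_mask: np.ndarray
    scan_width_mm: float
    fovea_center_px: tuple[float, float]
    true_vad_foveal: float = 0.0
    true_vad_parafoveal: float = 0.0
    true_vsd_foveal: float = 0.0
    true_vsd_parafoveal: float = 0.0
    true_faz_area_mm2: float = 0.0

    @classmethod
    def from_masks(
        cls,
        vessel_mask: np.ndarray,
        faz_mask: np.ndarray,
        scan_width_mm: float,
        fovea_center_px: tuple[float, float],
    ) -> "GroundTruth":
        """Build truth with densities recomputed by brute-force pixel counts."""
        from octamacula.vesselmetrics import make_region_masks, skeletonize_vessels
        from octamacula.types import VesselMap

        side = vessel_mask.shape[0]
        mm_per_px = scan_width_mm / side
        faz_area = float(faz_mask.sum()) * mm_per_px**2
        gt = cls(
            vessel_mask=vessel_mask.astype(bool),
            faz_mask=faz_mask.astype(bool),
            scan_width_mm=scan_width_mm,
            fovea_center_px=fovea_center_px,
            true_faz_area_mm2=faz_area,
        )
        try:
            foveal, parafoveal = make_region_masks(side, scan_width_mm, fovea_center_px)
        except ValueError:
            return gt  # frame too small for the 3-mm circle; regional truth undefined
        skel = skeletonize_vessels(VesselMap(vessel_mask, scan_width_mm)).pixels
        for region, tag in ((foveal, "foveal"), (parafoveal, "parafoveal")):
            npx = region.pixels.sum()
            setattr(gt, f"true_vad_{tag}", float((vessel_mask & region.pixels).sum() / npx))
            setattr(gt, f"true_vsd_{tag}", float((skel & region.pixels).sum() / npx))
        return gt

    def cropped(self) -> "GroundTruth":
        """Truth on the border-cropped (first row/column removed) geometry."""
        r, c = self.fovea_center_px
        return GroundTruth.from_masks(
            self.vessel_mask[1:, 1:],
            self.faz_mask[1:, 1:],
            self.scan_width_mm,
            (r - 1.0, c - 1.0),
        )


# ---------------------------------------------------------------------------
# scene construction


def _faz_ellipse(params: PhantomParams, rng: np.random.Generator) -> tuple[np.ndarray, tuple]:
    """Rasterize a randomly oriented ellipse of the requested physical area."""
    side = params.image_side_px
    center = ((side - 1) / 2.0, (side - 1) / 2.0)
    if params.faz_area_mm2 <= 0:
        return np.zeros((side, side), bool), (center, 0.0, 0.0, 0.0)
    area_px = params.faz_area_mm2 / params.mm_per_px**2
    ratio = rng.uniform(0.75, 1.0)  # minor/major axis
    a = np.sqrt(area_px / (np.pi * ratio))
    b = ratio * a
    theta = rng.uniform(0, np.pi)
    rr, cc = np.mgrid[0:side, 0:side]
    y = rr - center[0]
    x = cc - center[1]
    u = x * np.cos(theta) + y * np.sin(theta)
    v = -x * np.sin(theta) + y * np.cos(theta)
    mask = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return mask, (center, a, b, theta)


def _stamp_centers(canvas: np.ndarray, centers: np.ndarray, width: int) -> None:
    """OR a disk of diameter ``width`` onto ``canvas`` at each center pixel."""
    if len(centers) == 0:
        return
    # offsets within width/2 of the centerline: width 1 -> single pixel,
    # width 2 -> 5-px cross, width 3 -> 3x3 block, width 4 -> 13-px disk
    radius = int(np.ceil(width / 2.0))
    grid = np.mgrid[-radius:radius + 1, -radius:radius + 1]
    offs = np.argwhere(np.hypot(grid[0], grid[1]) <= width / 2.0 + 1e-9) - radius
    pts = (centers[:, None, :] + offs[None, :, :]).reshape(-1, 2)
    np.clip(pts, 0, canvas.shape[0] - 1, out=pts)
    canvas[pts[:, 0], pts[:, 1]] = True


def _grow_tree(
    params: PhantomParams,
    rng: np.random.Generator,
    canvas: np.ndarray,
    size_factor: float = 1.0,
) -> None:
    """Grow one branching vessel tree from the frame edge and stamp it."""
    side = params.image_side_px
    wmin, wmax = params.vessel_width_px_range
    # seed on a random edge, heading toward the interior with jitter
    edge = rng.integers(4)
    t = rng.uniform(0, side - 1)
    if edge == 0:
        pos, base = np.array([0.0, t]), np.pi / 2
    elif edge == 1:
        pos, base = np.array([side - 1.0, t]), -np.pi / 2
    elif edge == 2:
        pos, base = np.array([t, 0.0]), 0.0
    else:
        pos, base = np.array([t, side - 1.0]), np.pi
    heading = base + rng.normal(0, 0.4)
    stack = [(pos, heading, int(rng.integers(wmin, wmax + 1)))]
    step = 3.0
    per_width: dict[int, list] = {}
    n_steps = 0
    step_cap = max(int(800 * size_factor), 12)
    while stack and n_steps < step_cap:
        pos, heading, width = stack.pop()
        max_len = max(int(rng.integers(30, 80) * size_factor), 4)
        for _ in range(max_len):
            n_steps += 1
            heading += rng.normal(0, 0.13)  # smooth arcs: capillaries are not kinked
            new = pos + step * np.array([np.sin(heading), np.cos(heading)])
            if not (0 <= new[0] < side and 0 <= new[1] < side):
                break
            rr, cc = draw_line(
                int(round(pos[0])), int(round(pos[1])),
                int(round(new[0])), int(round(new[1])),
            )
            per_width.setdefault(width, []).extend(zip(rr.tolist(), cc.tolist()))
            pos = new
            if rng.random() < params.branch_probability and len(stack) < 12:
                child_w = max(wmin, width - 1)
                stack.append((pos.copy(), heading + rng.choice([-1, 1]) * rng.uniform(0.5, 1.0), child_w))
    for width, pts in per_width.items():
        _stamp_centers(canvas, np.asarray(pts, dtype=int), width)


def _capillary_ring(
    canvas: np.ndarray, ellipse: tuple, ring_width: int = 2
) -> None:
    """Draw the terminal capillary arcade just outside the FAZ boundary."""
    (cy, cx), a, b, theta = ellipse
    if a <= 0:
        return
    margin = 1.0 + ring_width / 2.0
    t = np.linspace(0, 2 * np.pi, 720, endpoint=False)
    u = (a + margin) * np.cos(t)
    v = (b + margin) * np.sin(t)
    y = cy + u * np.sin(theta) + v * np.cos(theta)
    x = cx + u * np.cos(theta) - v * np.sin(theta)
    pts = np.stack([np.round(y), np.round(x)], axis=1).astype(int)
    inside = (
        (pts[:, 0] >= 0) & (pts[:, 0] < canvas.shape[0])
        & (pts[:, 1] >= 0) & (pts[:, 1] < canvas.shape[1])
    )
    _stamp_centers(canvas, pts[inside], ring_width)


def _measurement_region(params: PhantomParams) -> np.ndarray:
    """Region over which target_vad is enforced: parafoveal annulus if it fits."""
    side = params.image_side_px
    center = (side - 1) / 2.0
    rr, cc = np.mgrid[0:side, 0:side]
    dist_mm = np.hypot(rr - center, cc - center) * params.mm_per_px
    if params.scan_width_mm >= 3.0:
        annulus = (dist_mm > 0.5) & (dist_mm <= 1.5)
        if annulus.any():
            return annulus
    return np.ones((side, side), bool)


def _render(
    vessel_mask: np.ndarray,
    faz_mask: np.ndarray,
    params: PhantomParams,
    rng: np.random.Generator,
    brightness: np.ndarray | None = None,
) -> np.ndarray:
    """Render the scene masks into an 8-bit angiogram.

    ``brightness`` is an optional per-pixel vessel brightness field in
    [0, 1] units (decorrelation signal varies between vessels on real
    OCTA); where absent, vessels render at the nominal level.
    """
    side = params.image_side_px
    # gray background with spatially correlated texture: decorrelation from
    # capillaries below the lateral resolution, never truly black on OCTA
    texture = ndi.gaussian_filter(rng.normal(0, 1.0, (side, side)), _TEXTURE_SIGMA)
    texture *= _TEXTURE_AMP / max(texture.std(), 1e-12)
    texture[faz_mask] = 0.0  # the avascular zone has no capillary texture
    bg = _BACKGROUND + texture
    levels = np.where(
        vessel_mask,
        brightness if brightness is not None else _VESSEL_LEVEL,
        0.0,
    )
    # optical point spread: capillaries near the resolution limit render as
    # Gaussian ridges whose peak falls with caliber (partial-volume effect)
    soft_levels = np.clip(ndi.gaussian_filter(levels, sigma=_PSF_SIGMA), 0, 1)
    soft_mask = np.clip(ndi.gaussian_filter(vessel_mask.astype(float), _PSF_SIGMA), 0, 1)
    img = bg * (1.0 - soft_mask) + soft_levels
    if params.illumination_gradient_amp > 0:
        phi = rng.uniform(0, 2 * np.pi)
        rr, cc = np.mgrid[0:side, 0:side]
        proj = (np.sin(phi) * rr + np.cos(phi) * cc) / side
        proj = (proj - proj.min()) / max(proj.max() - proj.min(), 1e-12)
        img *= 1.0 + params.illumination_gradient_amp * (proj - 0.5)
    if params.noise_sigma > 0:
        img += rng.normal(0, params.noise_sigma, img.shape)
    if params.faz_noise_level > 0 and faz_mask.any():
        img[faz_mask] += rng.normal(0, params.faz_noise_level, int(faz_mask.sum()))
    img[0, :] = 0.0  # export border removed by the crop stage
    img[:, 0] = 0.0
    return (np.clip(img, 0, 1) * 255).round().astype(np.uint8)


def generate_phantom(
    params: PhantomParams, plexus: Plexus = Plexus.SCP, eye_id: str = "synthetic"
) -> tuple[EnFaceAngiogram, GroundTruth]:
    """Generate one synthetic angiogram and its exact ground truth.

    The network is grown tree by tree until the vessel area density in the
    measurement region reaches ``params.target_vad``; a
    :class:`PhantomParameterError` is raised if the target cannot be
    reached.  Vessels never intrude into the FAZ (a 1-px moat separates
    the masks), matching the defining avascularity of the zone.
    """
    rng = np.random.default_rng(params.rng_seed)
    side = params.image_side_px
    faz_mask, ellipse = _faz_ellipse(params, rng)
    keep_out = dilation(faz_mask, disk(1)) if faz_mask.any() else faz_mask
    region = _measurement_region(params)
    region_n = int(region.sum())
    canvas = np.zeros((side, side), bool)
    brightness = np.zeros((side, side), dtype=np.float64)
    if params.target_vad > 0:
        if faz_mask.any():
            ring = np.zeros_like(canvas)
            _capillary_ring(ring, ellipse)
            ring &= ~keep_out
            canvas |= ring
            brightness[ring] = _VESSEL_LEVEL
        max_trees = 40 * max(params.n_seed_vessels, 1)
        trees = 0
        while True:
            measured = (canvas & region).sum() / region_n
            if measured >= params.target_vad:
                break
            if trees >= max_trees:
                raise PhantomParameterError(
                    f"target_vad={params.target_vad} unreachable after {max_trees} "
                    "trees; lower the target or widen vessel_width_px_range"
                )
            # shrink trees as the target nears so the final density lands close
            deficit = params.target_vad - measured
            layer = np.zeros_like(canvas)
            _grow_tree(params, rng, layer, size_factor=min(1.0, deficit / 0.10))
            layer &= ~keep_out
            new = layer & ~canvas
            # per-vessel decorrelation signal varies on real OCTA
            brightness[new] = rng.uniform(*_VESSEL_LEVEL_RANGE)
            canvas |= layer
            trees += 1
    vessel_mask = canvas
    img = _render(vessel_mask, faz_mask, params, rng, brightness)
    center = ((side - 1) / 2.0, (side - 1) / 2.0)
    truth = GroundTruth.from_masks(vessel_mask, faz_mask, params.scan_width_mm, center)
    angio = EnFaceAngiogram(img, params.scan_width_mm, plexus, eye_id)
    if params.burnout_attenuation > 0:
        angio, truth = apply_burnout(
            angio, truth, params.burnout_attenuation, int(rng.integers(2**31))
        )
    return angio, truth


def apply_burnout(
    angiogram: EnFaceAngiogram,
    truth: GroundTruth,
    attenuation: float,
    seed: int,
) -> tuple[EnFaceAngiogram, GroundTruth]:
    """Attenuate the vasculature: delete segments and dim survivors.

    Random vessel patches are removed until exactly
    ``round((1 - attenuation) * n)`` of the original ``n`` vessel pixels
    survive; removed pixels are repainted at background level and the
    surviving vessels lose contrast proportionally, emulating the
    burnout-macula pattern of end-stage radiation damage.
    """
    if not (0.0 <= attenuation <= 1.0):
        raise ValueError("attenuation must be in [0, 1]")
    if attenuation == 0.0:
        return (
            EnFaceAngiogram(
                angiogram.pixels.copy(), angiogram.scan_width_mm,
                angiogram.plexus, angiogram.eye_id,
            ),
            dataclasses.replace(
                truth, vessel_mask=truth.vessel_mask.copy(), faz_mask=truth.faz_mask.copy()
            ),
        )
    rng = np.random.default_rng(seed)
    mask = truth.vessel_mask.copy()
    n_orig = int(mask.sum())
    target = int(round((1.0 - attenuation) * n_orig))
    img = angiogram.as_float()
    non_vessel = ~mask & ~truth.faz_mask
    bg_level = float(np.median(img[non_vessel])) if non_vessel.any() else _BACKGROUND
    # split the background statistics into a spatially correlated (texture)
    # and a white (sensor noise) component so repainted patches match the
    # surviving background instead of standing out as high-frequency speckle
    smooth = ndi.gaussian_filter(img, _TEXTURE_SIGMA)
    if non_vessel.any():
        sigma_hf = float(np.std((img - smooth)[non_vessel]))
        sigma_lf = float(np.std(smooth[non_vessel]))
    else:
        sigma_hf, sigma_lf = 0.02, 0.02
    # patch radius sized so one patch is <= ~1% of the original vessel area
    radius = int(np.clip(np.sqrt(0.01 * max(n_orig, 1) / np.pi), 2, 10))
    removed = np.zeros_like(mask)
    while mask.sum() > target:
        cand = np.argwhere(mask)
        cy, cx = cand[rng.integers(len(cand))]
        rr, cc = np.mgrid[
            max(cy - radius, 0): min(cy + radius + 1, mask.shape[0]),
            max(cx - radius, 0): min(cx + radius + 1, mask.shape[1]),
        ]
        d2 = (rr - cy) ** 2 + (cc - cx) ** 2
        sel = (d2 <= radius**2) & mask[rr, cc]
        need = int(mask.sum()) - target
        if sel.sum() > need:  # trim the patch to land exactly on target
            order = np.argsort(d2[sel], kind="stable")[:need]
            pr, pc = rr[sel][order], cc[sel][order]
        else:
            pr, pc = rr[sel], cc[sel]
        mask[pr, pc] = False
        removed[pr, pc] = True
    lf = ndi.gaussian_filter(rng.normal(0, 1.0, img.shape), _TEXTURE_SIGMA)
    lf *= sigma_lf / max(lf.std(), 1e-12)
    repaint = bg_level + lf + rng.normal(0, sigma_hf, img.shape)
    img[removed] = repaint[removed]
    surv = mask
    img[surv] = bg_level + (img[surv] - bg_level) * (1.0 - 0.6 * attenuation)
    out = (np.clip(img, 0, 1) * 255).round().astype(np.uint8)
    out[0, :] = angiogram.pixels[0, :]
    out[:, 0] = angiogram.pixels[:, 0]
    new_truth = GroundTruth.from_masks(
        mask, truth.faz_mask, truth.scan_width_mm, truth.fovea_center_px
    )
    return (
        EnFaceAngiogram(out, angiogram.scan_width_mm, angiogram.plexus, angiogram.eye_id),
        new_truth,
    )


# ---------------------------------------------------------------------------
# cohort generation

# Fellow-eye (healthy) population means for the parafoveal region, fractions.
_BASELINE = {
    "scp": {"vad_para": 0.321, "vad_fov_offset": -0.027, "vsd_ratio": 0.388, "sd": 0.041},
    "dcp": {"vad_para": 0.366, "vad_fov_offset": -0.019, "vsd_ratio": 0.435, "sd": 0.035},
}
_BASELINE_FAZ_MM2 = 0.30  # normal foveal avascular zone area
_BURNOUT_ATTENUATION = 0.85


@dataclass
class CohortParams:
    """Programmable paired-eye cohort.

    ``effect_vad_scp``/``effect_vad_dcp`` are the mean treated-eye VAD
    deficits in percentage points; ``dose_slope_pp_per_gy`` modulates the
    deficit around its mean by the (centered) foveal dose, giving the
    negative dose-density correlation seen after plaque brachytherapy.
    ``effect_faz`` multiplies the treated eye's FAZ area.  A fraction
    ``fraction_burnout`` of treated eyes develop the burnout pattern
    (probability tilted toward high-dose eyes); their densities collapse
    by the burnout attenuation factor.
    """

    n_patients: int = 31
    effect_vad_scp: float = 8.6
    effect_vad_dcp: float = 12.2
    effect_faz: float = 2.0
    fraction_burnout: float = 0.29
    fraction_rm: float = 0.8
    dose_mean_gy: tuple[float, float] = (20.5, 30.0)  # foveal, optic disc
    dose_sd_gy: tuple[float, float] = (29.6, 20.0)
    dose_slope_pp_per_gy: float = 0.08
    dose_burnout_beta: float = 1.2
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        for name in ("fraction_burnout", "fraction_rm"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} outside [0, 1]")
        for e in (self.effect_vad_scp, self.effect_vad_dcp):
            if not (0.0 <= e <= 100.0):
                raise ValueError("VAD effects are percentage points in [0, 100]")
        if self.effect_faz < 0:
            raise ValueError("effect_faz must be >= 0")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate_cohort(
    params: CohortParams, render: bool = False
) -> tuple[list[dict], pd.DataFrame]:
    """Generate a paired treated/fellow-eye cohort with ground-truth metrics.

    Returns ``(eyes, table)``.  ``table`` has one row per eye with the
    programmed (ground-truth) densities, FAZ areas, doses and flags.
    ``eyes`` holds one record per eye with the :class:`PhantomParams` for
    each plexus; with ``render=True`` the phantoms are also generated and
    attached under ``"phantoms"`` as ``{plexus: (angiogram, truth)}``.

    Both eyes of a patient share a patient-level baseline density, which
    induces the inter-eye correlation that the clustered bootstrap in the
    statistics layer must respect.
    """
    rng = np.random.default_rng(params.rng_seed)
    n = params.n_patients
    # patient-level draws
    base = {
        pl: rng.normal(_BASELINE[pl]["vad_para"], _BASELINE[pl]["sd"], n)
        for pl in ("scp", "dcp")
    }
    base_faz = np.exp(rng.normal(np.log(_BASELINE_FAZ_MM2), 0.35, n))
    fov_dose = np.clip(rng.normal(params.dose_mean_gy[0], params.dose_sd_gy[0], n), 0, None)
    disc_dose = np.clip(rng.normal(params.dose_mean_gy[1], params.dose_sd_gy[1], n), 0, None)
    rm = rng.random(n) < params.fraction_rm
    # RM eyes carry a larger-than-average deficit, non-RM a smaller one,
    # weighted so the cohort mean deficit equals the programmed effect
    m_norm = 0.35
    p_rm = params.fraction_rm
    m_rm = (1.0 - (1.0 - p_rm) * m_norm) / p_rm if p_rm > 0 else 1.0
    eff_mult = np.where(rm, m_rm, m_norm)
    # burnout probability rises with foveal dose among RM eyes
    if params.fraction_burnout > 0:
        z = (fov_dose - fov_dose.mean()) / max(fov_dose.std(), 1e-9)
        logit0 = np.log(params.fraction_burnout / (1 - params.fraction_burnout))
        p_b = _sigmoid(logit0 + params.dose_burnout_beta * z)
        burnout = (rng.random(n) < p_b) & rm
    else:
        burnout = np.zeros(n, bool)
    interval = np.clip(rng.normal(28, 14, n), 6, None)

    rows: list[dict] = []
    eyes: list[dict] = []
    dose_c = fov_dose - fov_dose.mean()
    for i in range(n):
        pid = f"P{i:03d}"
        for treated in (True, False):
            eye_id = f"{pid}-{'OD' if treated else 'OS'}"
            row: dict = {
                "patient_id": pid,
                "eye_id": eye_id,
                "treated": treated,
                "rm": bool(rm[i]) if treated else False,
                "burnout": bool(burnout[i]) if treated else False,
                "foveal_dose_gy": float(fov_dose[i]) if treated else 0.0,
                "disc_dose_gy": float(disc_dose[i]) if treated else 0.0,
                "interval_months": float(interval[i]) if treated else float("nan"),
            }
            row["group"] = (
                "fellow_control" if not treated
                else ("treated_RM" if rm[i] else "treated_noRM")
            )
            faz = base_faz[i] * rng.uniform(0.9, 1.1)
            metrics = {}
            for pl in ("scp", "dcp"):
                b = _BASELINE[pl]
                vad_para = base[pl][i] + rng.normal(0, 0.010)
                if treated:
                    eff_pp = getattr(params, f"effect_vad_{pl}")
                    deficit = (
                        eff_pp * eff_mult[i] + params.dose_slope_pp_per_gy * dose_c[i]
                    ) / 100.0
                    vad_para -= max(deficit, 0.0)
                vad_fov = vad_para + b["vad_fov_offset"] + rng.normal(0, 0.006)
                if treated and burnout[i]:
                    vad_para *= 1.0 - _BURNOUT_ATTENUATION
                    vad_fov *= 1.0 - _BURNOUT_ATTENUATION
                vad_para = float(np.clip(vad_para, 0.01, 0.99))
                vad_fov = float(np.clip(vad_fov, 0.01, 0.99))
                metrics[pl] = vad_para
                row[f"vad_parafoveal_{pl}"] = vad_para
                row[f"vad_foveal_{pl}"] = vad_fov
                row[f"vsd_parafoveal_{pl}"] = vad_para * b["vsd_ratio"]
                row[f"vsd_foveal_{pl}"] = vad_fov * b["vsd_ratio"]
            faz_scale = params.effect_faz if treated else 1.0
            row["faz_scp_mm2"] = float(faz * faz_scale)
            row["faz_dcp_mm2"] = float(faz * faz_scale * rng.uniform(0.95, 1.15))
            row["bcva_logmar"] = float(
                np.clip(
                    0.05
                    + (1.5 * (0.36 - row["vad_parafoveal_dcp"]))
                    + rng.normal(0, 0.08),
                    0,
                    2.0,
                )
            )
            rows.append(row)
            eye: dict = {"patient_id": pid, "eye_id": eye_id, "params": {}}
            for pl in ("scp", "dcp"):
                eye["params"][pl] = PhantomParams(
                    faz_area_mm2=min(row[f"faz_{pl}_mm2"], 2.0),
                    target_vad=(
                        metrics[pl]
                        if not row["burnout"]
                        # grow the pre-burnout network, then attenuate
                        else min(metrics[pl] / (1.0 - _BURNOUT_ATTENUATION), 0.6)
                    ),
                    burnout_attenuation=_BURNOUT_ATTENUATION if row["burnout"] else 0.0,
                    vessel_width_px_range=(2, 4) if pl == "scp" else (1, 3),
                    rng_seed=int(rng.integers(2**31)),
                )
            eyes.append(eye)

    table = pd.DataFrame(rows)
    if render:
        for eye in eyes:
            eye["phantoms"] = {
                pl: generate_phantom(
                    p, Plexus(pl.upper()), eye_id=eye["eye_id"]
                )
                for pl, p in eye["params"].items()
            }
    return eyes, table


# ---------------------------------------------------------------------------
# disk output


def save_phantom(
    out_dir: str | Path,
    angiogram: EnFaceAngiogram,
    truth: GroundTruth,
    stem: str,
) -> None:
    """Write the angiogram and its truth masks as 8-bit grayscale PNGs."""
    from PIL import Image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    Image.fromarray(angiogram.pixels).save(out / f"{stem}.png")
    Image.fromarray((truth.vessel_mask * 255).astype(np.uint8)).save(
        out / f"{stem}_vessels.png"
    )
    Image.fromarray((truth.faz_mask * 255).astype(np.uint8)).save(
        out / f"{stem}_faz.png"
    )
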