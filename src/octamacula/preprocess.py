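"""Enhancement chain: raw en-face angiogram -> vesselness map.

Stage order (fixed):

1. grayscale conversion + border crop (365 -> 364 px),
2. homomorphic filtering (log-domain high-boost; suppresses the
   multiplicative illumination gradient of en-face exports),
3. min-max normalization to [0, 1],
4. subtraction of the mean intensity of a sample region inside the FAZ
   (removes the noise floor that instruments misread as flow),
5. grayscale top-hat / bottom-hat contrast enhancement (disc element,
   radius 4 px),
6. bilateral denoising (edge-preserving),
7. multiscale Hessian vesselness with a tau-regularized response bounded
   in [0, 1] (Jerman-type enhancement), maximum over scales.

Every stage is a pure deterministic function; outputs are clipped to
[0, 1] after each stage so the domain stays stable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import black_tophat, disk, white_tophat
from skimage.restoration import denoise_bilateral

from octamacula.types import EnFaceAngiogram, Plexus

logger = logging.getLogger(__name__)


@dataclass
class HomomorphicConfig:
    cutoff_freq: float = 10.0  # cycles per image width
    low_gain: float = 0.5  # applied to illumination (low) frequencies
    high_gain: float = 1.5  # applied to reflectance (high) frequencies


@dataclass
class BilateralConfig:
    sigma_spatial_px: float = 3.0
    sigma_intensity: float = 0.1  # normalized intensity units


@dataclass
class JermanConfig:
    # sub-capillary to arteriole ridge widths at ~8.2 um/px
    scales_px: tuple[float, ...] = (0.8, 1.2, 1.8)
    tau: float = 0.75

    def __post_init__(self) -> None:
        if len(self.scales_px) == 0 or any(s <= 0 for s in self.scales_px):
            raise ValueError("scales_px must be nonempty and positive")
        if not (0.0 < self.tau <= 1.0):
            raise ValueError("tau must be in (0, 1]")


@dataclass
class PreprocessConfig:
    """All tunables of the enhancement chain.

    ``faz_sample_radius_px`` replaces the manual selection of a
    background patch inside the FAZ with a fixed central disc; scans are
    fovea-centered by protocol, and the normal FAZ comfortably contains
    a 15-px-radius disc.  An explicit boolean mask can be supplied
    instead via ``faz_sample_mask``.
    """

    homomorphic: HomomorphicConfig = field(default_factory=HomomorphicConfig)
    tophat_radius_px: int = 4
    bilateral: BilateralConfig = field(default_factory=BilateralConfig)
    jerman: JermanConfig = field(default_factory=JermanConfig)
    faz_sample_radius_px: int = 15
    faz_sample_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.tophat_radius_px < 1:
            raise ValueError("tophat_radius_px must be >= 1")


class StageError(RuntimeError):
    """Wraps a failure with the name of the pipeline stage that raised it."""


def grayscale_and_crop(
    image: np.ndarray,
    scan_width_mm: float = 3.0,
    plexus: Plexus = Plexus.SCP,
    eye_id: str = "",
) -> EnFaceAngiogram:
    """Collapse RGB to luminance and remove the 1-px export border.

    Input must be 365x365 (grayscale or RGB); output is the 364x364 core
    obtained by dropping the first row and first column.
    """
    img = np.asarray(image)
    if img.ndim == 3:
        if img.shape[2] not in (3, 4):
            raise ValueError(f"expected RGB(A) channels, got shape {img.shape}")
        rgb = img[..., :3].astype(np.float64)
        img = (0.2125 * rgb[..., 0] + 0.7154 * rgb[..., 1] + 0.0721 * rgb[..., 2])
        img = img.round().astype(np.uint8) if image.dtype == np.uint8 else img
    if img.shape != (365, 365):
        raise ValueError(
            f"expected a 365x365 export (1-px border), got {img.shape[0]}x{img.shape[1]}"
        )
    return EnFaceAngiogram(img[1:, 1:], scan_width_mm, plexus, eye_id)


def homomorphic_filter(image: np.ndarray, config: HomomorphicConfig | None = None) -> np.ndarray:
    """Log-domain high-boost filtering for multiplicative illumination.

    ``log1p`` of the image is filtered in the Fourier domain with the
    geometric (log-gain) Gaussian transfer function
    ``H(f) = low_gain^w(f) * high_gain^(1 - w(f))`` with
    ``w(f) = exp(-f^2 / (2 f0^2))`` and mapped back with ``expm1``.
    Low frequencies (illumination) are scaled by ``low_gain``, high
    frequencies (reflectance detail) by ``high_gain``; applying the
    filter twice equals applying it once with squared gains.
    """
    config = config or HomomorphicConfig()
    img = np.asarray(image, dtype=np.float64)
    logi = np.log1p(np.clip(img, 0, None))
    fy = np.fft.fftfreq(img.shape[0])[:, None] * img.shape[0]
    fx = np.fft.fftfreq(img.shape[1])[None, :] * img.shape[1]
    f2 = fy**2 + fx**2
    w = np.exp(-f2 / (2.0 * config.cutoff_freq**2))
    h = config.low_gain**w * config.high_gain ** (1.0 - w)
    filtered = np.real(np.fft.ifft2(np.fft.fft2(logi) * h))
    return np.clip(np.expm1(filtered), 0, None)


def normalize(image: np.ndarray) -> np.ndarray:
    """Linear min-max rescale to [0, 1]; a constant image maps to zeros."""
    img = np.asarray(image, dtype=np.float64)
    lo, hi = img.min(), img.max()
    if hi == lo:
        return np.zeros_like(img)
    return (img - lo) / (hi - lo)


def central_disc_mask(side_px: int, radius_px: int) -> np.ndarray:
    rr, cc = np.mgrid[0:side_px, 0:side_px]
    c = (side_px - 1) / 2.0
    return np.hypot(rr - c, cc - c) <= radius_px


def subtract_faz_background(image: np.ndarray, sample_region: np.ndarray) -> np.ndarray:
    """Subtract the mean intensity of the FAZ sample region, clipping at zero.

    The region emulates the study's manually chosen avascular patch: its
    mean estimates the noise floor that would otherwise be segmented as
    flow signal.
    """
    img = np.asarray(image, dtype=np.float64)
    region = np.asarray(sample_region, dtype=bool)
    if region.shape != img.shape:
        raise ValueError("sample region must match image shape")
    if not region.any():
        raise ValueError("empty FAZ sample region")
    return np.clip(img - img[region].mean(), 0, None)


def tophat_bottomhat_enhance(image: np.ndarray, radius_px: int = 4) -> np.ndarray:
    """Contrast enhancement ``clip(image + tophat - bottomhat, 0, 1)``.

    Grayscale top-hat (image - opening) lifts bright structures thinner
    than the disc element; bottom-hat (closing - image) darkens the gaps
    between them.
    """
    if radius_px < 1:
        raise ValueError("radius_px must be >= 1")
    img = np.asarray(image, dtype=np.float64)
    selem = disk(radius_px)
    enhanced = img + white_tophat(img, selem) - black_tophat(img, selem)
    return np.clip(enhanced, 0, 1)


def bilateral_denoise(
    image: np.ndarray, sigma_spatial: float = 3.0, sigma_intensity: float = 0.1
) -> np.ndarray:
    """Edge-preserving smoothing (bilateral filter) on a [0, 1] image."""
    if sigma_spatial <= 0 or sigma_intensity <= 0:
        raise ValueError("bilateral sigmas must be positive")
    img = np.clip(np.asarray(image, dtype=np.float64), 0, 1)
    return denoise_bilateral(
        img, sigma_color=sigma_intensity, sigma_spatial=sigma_spatial
    )


def jerman_vesselness(
    image: np.ndarray,
    scales_px: tuple[float, ...] = (1.0, 2.0, 3.0),
    tau: float = 0.75,
) -> np.ndarray:
    """Multiscale Hessian vesselness with tau-regularized response.

    At every scale ``s`` the scale-normalized Hessian eigenvalues
    ``|l1| <= |l2|`` are computed with Gaussian derivatives.  For bright
    ridges the response is driven by ``x = -l2`` (positive on ridges).
    The regularized magnitude is

        ``rho = x``                      if ``x > tau * max(x)``
        ``rho = tau * max(x)``           if ``0 < x <= tau * max(x)``
        ``rho = 0``                      otherwise,

    and the response is ``V = x^2 (rho - x) (3 / (x + rho))^3`` for
    ``0 < x < rho / 2`` and ``V = 1`` for ``x >= rho / 2``, zero where
    ``x <= 0``.  Because a 2-D Hessian cannot distinguish a bright blob
    from a ridge through ``l2`` alone, the response is multiplied by the
    anisotropy factor ``1 - (l1/l2)^2`` when ``l1 < 0`` (1 on ideal
    ridges, 0 on isotropic blobs, gentle on junctions), which suppresses
    speckle.  The output is the
    maximum over scales and lies in [0, 1]; a constant image yields all
    zeros.
    """
    if len(scales_px) == 0 or any(s <= 0 for s in scales_px):
        raise ValueError("scales_px must be nonempty and positive")
    if not (0.0 < tau <= 1.0):
        raise ValueError("tau must be in (0, 1]")
    img = np.asarray(image, dtype=np.float64)
    out = np.zeros_like(img)
    for s in scales_px:
        # Gaussian-derivative Hessian (mirror boundaries keep the operator
        # exactly equivariant under 90-degree rotations).  The sampled
        # second-derivative kernel leaks a small DC term at sub-pixel
        # sigma; subtract its response to a constant so flat areas give
        # exactly zero curvature.
        ones = np.ones_like(img)
        hrr = ndi.gaussian_filter(img, s, order=(2, 0), mode="mirror")
        hrr -= ndi.gaussian_filter(ones, s, order=(2, 0), mode="mirror") * img
        hrc = ndi.gaussian_filter(img, s, order=(1, 1), mode="mirror")
        hrc -= ndi.gaussian_filter(ones, s, order=(1, 1), mode="mirror") * img
        hcc = ndi.gaussian_filter(img, s, order=(0, 2), mode="mirror")
        hcc -= ndi.gaussian_filter(ones, s, order=(0, 2), mode="mirror") * img
        mean = (hrr + hcc) / 2.0
        delta = np.sqrt(((hrr - hcc) / 2.0) ** 2 + hrc**2)
        ev_hi, ev_lo = mean + delta, mean - delta
        # sort by magnitude: l2 = larger magnitude
        big = np.abs(ev_hi) >= np.abs(ev_lo)
        l2 = np.where(big, ev_hi, ev_lo)
        l1 = np.where(big, ev_lo, ev_hi)
        x = -l2 * s**2  # scale-normalized; positive on bright ridges
        xmax = x.max()
        if xmax <= 1e-8:  # flat image at this scale (float-noise curvature)
            continue
        cut = tau * xmax
        rho = np.where(x > cut, x, cut)
        rho = np.where(x <= 0, 0.0, rho)
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            v = x**2 * (rho - x) * (3.0 / (x + rho)) ** 3
        v = np.where(x >= rho / 2.0, 1.0, v)
        v = np.where((x <= 0) | (rho <= 0), 0.0, v)
        with np.errstate(divide="ignore", invalid="ignore"):
            aniso = np.where(
                l1 < 0,
                1.0 - (np.abs(l1) / np.maximum(np.abs(l2), 1e-300)) ** 2,
                1.0,
            )
        v *= np.clip(aniso, 0, 1)
        out = np.maximum(out, np.clip(v, 0, 1))
    return out


def run_preprocess(
    angiogram: EnFaceAngiogram | np.ndarray,
    config: PreprocessConfig | None = None,
    save_stages: dict[str, np.ndarray] | None = None,
) -> np.ndarray:
    """Run the full enhancement chain and return the vesselness map.

    ``angiogram`` may be a raw 365x365 array (the crop stage is applied)
    or an :class:`EnFaceAngiogram` that is already cropped.  If
    ``save_stages`` is a dict, each stage's output is stored under its
    name.  Deterministic: identical inputs give bit-identical outputs.
    """
    config = config or PreprocessConfig()
    stages = save_stages if save_stages is not None else {}

    def _run(name, fn, *args):
        try:
            res = fn(*args)
        except Exception as exc:  # attach the stage name for diagnosis
            raise StageError(f"stage '{name}' failed: {exc}") from exc
        stages[name] = res
        logger.info("stage=%s done", name)
        return res

    if isinstance(angiogram, np.ndarray):
        angiogram = _run("grayscale_and_crop", grayscale_and_crop, angiogram)
    img = angiogram.as_float()
    img = _run("homomorphic", homomorphic_filter, img, config.homomorphic)
    img = _run("normalize", normalize, img)
    if config.faz_sample_mask is not None:
        region = config.faz_sample_mask
    else:
        region = central_disc_mask(img.shape[0], config.faz_sample_radius_px)
    img = _run("subtract_faz_background", subtract_faz_background, img, region)
    img = np.clip(img, 0, 1)
    img = _run("tophat_bottomhat", tophat_bottomhat_enhance, img, config.tophat_radius_px)
    img = _run(
        "bilateral",
        bilateral_denoise,
        img,
        config.bilateral.sigma_spatial_px,
        config.bilateral.sigma_intensity,
    )
    vmap = _run(
        "jerman",
        jerman_vesselness,
        img,
        tuple(config.jerman.scales_px),
        config.jerman.tau,
    )
    return vmap
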