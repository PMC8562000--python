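"""Domain containers shared across the pipeline.

All image-like containers carry their physical geometry (``side_px``,
``scan_width_mm``) so that areas and lengths can always be converted to
millimetres.  The pixel scale of a cropped 3-mm macular scan is
``3.0 / 364 ~= 8.24 um/px``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np


class Plexus(str, enum.Enum):
    """Retinal capillary plexus of an en-face slab."""

    SCP = "SCP"
    DCP = "DCP"


@dataclass
class EnFaceAngiogram:
    """A single en-face OCTA image with its scan geometry.

    Parameters
    ----------
    pixels
        2-D intensity grid.  ``uint8`` on input; float in [0, 1] after
        normalization.  Bright pixels are flow (vessels) on a dark
        background.
    scan_width_mm
        Physical width of the (square) scan field.
    plexus
        Capillary plexus the slab was projected from.
    eye_id
        Free-form identifier of the eye the image belongs to.
    """

    pixels: np.ndarray
    scan_width_mm: float = 3.0
    plexus: Plexus = Plexus.SCP
    eye_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.shape[0] != self.pixels.shape[1]:
            raise ValueError(
                f"angiogram must be a square 2-D grid, got shape {self.pixels.shape}"
            )
        if self.scan_width_mm <= 0:
            raise ValueError("scan_width_mm must be positive")

    @property
    def side_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def mm_per_px(self) -> float:
        return self.scan_width_mm / self.side_px

    @property
    def px_area_mm2(self) -> float:
        return self.mm_per_px**2

    def as_float(self) -> np.ndarray:
        """Pixels as float64 in [0, 1] (uint8 divided by 255)."""
        if self.pixels.dtype == np.uint8:
            return self.pixels.astype(np.float64) / 255.0
        return self.pixels.astype(np.float64)


@dataclass
class _BinaryGrid:
    pixels: np.ndarray
    scan_width_mm: float = 3.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels).astype(bool)
        if self.pixels.ndim != 2 or self.pixels.shape[0] != self.pixels.shape[1]:
            raise ValueError(f"expected a square 2-D grid, got {self.pixels.shape}")

    @property
    def side_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def mm_per_px(self) -> float:
        return self.scan_width_mm / self.side_px

    @property
    def px_area_mm2(self) -> float:
        return self.mm_per_px**2


@dataclass
class VesselMap(_BinaryGrid):
    """Binary map of segmented vessel pixels."""


@dataclass
class SkeletonMap(_BinaryGrid):
    """One-pixel-wide vessel centerlines (subset of a :class:`VesselMap`)."""


@dataclass
class RegionMask(_BinaryGrid):
    """Sampling region: the foveal disc or the parafoveal annulus.

    The foveal region is the central disc of 1 mm diameter; the parafoveal
    region is the annulus between the 1 mm and 3 mm diameter circles, both
    centered on the fovea.
    """

    label: str = "foveal"
    center_px: tuple[float, float] = (0.0, 0.0)
    inner_diameter_mm: float = 0.0
    outer_diameter_mm: float = 1.0


@dataclass
class DensityMetrics:
    """Regional vessel densities for one eye (fractions in [0, 1]).

    VAD (vessel area density) is the fraction of region area covered by
    binarized vessels; VSD (vessel skeleton density) the fraction covered
    by the one-pixel-wide centerlines.  Clinical reports multiply both by
    100 and quote percent.
    """

    eye_id: str = ""
    vad_foveal_scp: float = float("nan")
    vad_parafoveal_scp: float = float("nan")
    vsd_foveal_scp: float = float("nan")
    vsd_parafoveal_scp: float = float("nan")
    vad_foveal_dcp: float = float("nan")
    vad_parafoveal_dcp: float = float("nan")
    vsd_foveal_dcp: float = float("nan")
    vsd_parafoveal_dcp: float = float("nan")
    otsu_threshold_scp: float = float("nan")
    otsu_threshold_dcp: float = float("nan")

    def as_dict(self) -> dict[str, float]:
        return {
            k: v
            for k, v in self.__dict__.items()
            if k != "eye_id"
        }


@dataclass
class FAZResult:
    """The selected foveal avascular zone component.

    ``area_mm2 = pixel count * (scan_width_mm / side_px)^2``.
    """

    component_mask: np.ndarray
    scan_width_mm: float
    area_mm2: float
    centroid_px: tuple[float, float]
    boundary_polygon: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))

    @property
    def side_px(self) -> int:
        return self.component_mask.shape[0]
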