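"""Foveal avascular zone (FAZ) extraction from raw angiograms.

The FAZ is recovered as a background (avascular) connected component of
a binarized angiogram:

1. adaptive ("variable") thresholding marks vessel pixels while rejecting
   the speckle noise that accumulates inside avascular zones,
2. small residual white dots inside the FAZ are removed,
3. morphological closing with square/rectangular elements bridges the
   inter-capillary gaps of the perifoveal arcade so the FAZ becomes one
   enclosed background region,
4. among enclosed background components whose centroid lies near the
   image center, the largest is selected; its pixel count times the pixel
   area gives the FAZ area in mm^2.

The extraction runs on the *raw* image (normalized to [0, 1]), not on the
vesselness map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from skimage import measure
from skimage.filters import threshold_local
from skimage.morphology import closing as _closing, opening as _opening, remove_small_objects

from octamacula.types import EnFaceAngiogram, FAZResult

logger = logging.getLogger(__name__)


class FAZNotFoundError(RuntimeError):
    """No avascular component near the image center (e.g. burnout eyes,
    where the ischemic area merges with the peripheral background)."""


@dataclass
class FAZConfig:
    """Tunables of the FAZ extractor.

    ``adaptive_offset`` is the margin above the local mean a pixel must
    exceed to count as vessel; ``hard_threshold`` catches uniformly bright
    (vessel-saturated) areas where the local mean itself is high.  The
    candidate component must have its centroid within
    ``center_cap_mm`` of the image center.
    """

    adaptive_block_px: int = 25  # window of the local-mean threshold (odd)
    adaptive_offset: float = 0.20  # normalized intensity units
    hard_threshold: float = 0.50
    max_hole_px: int = 20
    closing_elements: tuple[tuple[int, int], ...] = ((3, 3), (5, 1), (1, 5), (5, 5))
    opening_element: tuple[int, int] | None = None
    center_cap_mm: float = 0.6


def binarize_variable_threshold(
    image: np.ndarray, config: FAZConfig | None = None
) -> np.ndarray:
    """Adaptive vessel binarization that excludes avascular-zone speckle.

    A pixel is vessel if it exceeds the local (block) mean by
    ``adaptive_offset`` — zero-mean speckle inside the FAZ stays below
    that margin — or exceeds ``hard_threshold`` absolutely.
    """
    config = config or FAZConfig()
    img = np.asarray(image, dtype=np.float64)
    block = config.adaptive_block_px | 1  # threshold_local wants odd
    local_mean = threshold_local(img, block_size=block, method="mean")
    return (img > local_mean + config.adaptive_offset) | (img > config.hard_threshold)


def remove_small_specks(binary: np.ndarray, max_hole_px: int = 20) -> np.ndarray:
    """Delete isolated foreground specks of at most ``max_hole_px`` pixels.

    These are the residual white dots inside the FAZ that would otherwise
    break the avascular region into fragments.
    """
    return remove_small_objects(
        np.asarray(binary, dtype=bool), max_size=max_hole_px, connectivity=2
    )


def morphological_open_link(
    binary: np.ndarray,
    closing_elements: tuple[tuple[int, int], ...] = ((3, 3), (5, 1), (1, 5), (5, 5)),
    opening_element: tuple[int, int] | None = None,
) -> np.ndarray:
    """Bridge inter-capillary gaps with square/rectangular elements.

    Sequential binary closings (square, then horizontal and vertical
    rectangles) link the edges of detected vessels so the FAZ background
    becomes a single enclosed region; an optional final opening removes
    protrusions the closings created.
    """
    out = np.asarray(binary, dtype=bool)
    for shape in closing_elements:
        out = _closing(out, np.ones(shape, bool))
    if opening_element is not None:
        out = _opening(out, np.ones(opening_element, bool))
    return out


def extract_faz(
    angiogram: EnFaceAngiogram, config: FAZConfig | None = None
) -> FAZResult:
    """Run the full FAZ extraction chain and return the selected component.

    Candidate avascular regions are the 8-connected background components
    that do not touch the image border (the FAZ is enclosed by the
    perifoveal arcade).  Scans are fovea-centered by protocol, so the
    component containing the image-center pixel is preferred; if the
    center pixel falls on a vessel or on an excluded component, the
    largest candidate whose centroid lies within ``center_cap_mm`` of the
    center is taken instead.  :class:`FAZNotFoundError` is raised when
    none qualifies.
    """
    config = config or FAZConfig()
    img = angiogram.as_float()
    vessels = binarize_variable_threshold(img, config)
    vessels = remove_small_specks(vessels, config.max_hole_px)
    vessels = morphological_open_link(
        vessels, config.closing_elements, config.opening_element
    )
    background = ~vessels
    labels = measure.label(background, connectivity=2)
    side = img.shape[0]
    center = np.array([(side - 1) / 2.0, (side - 1) / 2.0])
    cap_px = config.center_cap_mm / angiogram.mm_per_px
    border_labels = np.unique(
        np.concatenate([labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]])
    )
    props = {p.label: p for p in measure.regionprops(labels)}
    center_label = labels[int(round(center[0])), int(round(center[1]))]
    best = None
    if center_label != 0 and center_label not in border_labels:
        best = props[center_label]
    else:
        for prop in props.values():
            if prop.label in border_labels:
                continue
            dist = np.hypot(*(np.array(prop.centroid) - center))
            if dist > cap_px:
                continue
            if best is None or prop.area > best.area:
                best = prop
    if best is None:
        raise FAZNotFoundError(
            f"no enclosed avascular component within {config.center_cap_mm} mm "
            "of the image center"
        )
    mask = labels == best.label
    area_mm2 = float(mask.sum()) * angiogram.px_area_mm2
    contours = measure.find_contours(mask.astype(float), 0.5)
    boundary = max(contours, key=len) if contours else np.empty((0, 2))
    logger.info(
        "eye=%s plexus=%s faz_area_mm2=%.4f centroid=%s",
        angiogram.eye_id, angiogram.plexus.value, area_mm2, best.centroid,
    )
    return FAZResult(
        component_mask=mask,
        scan_width_mm=angiogram.scan_width_mm,
        area_mm2=area_mm2,
        centroid_px=tuple(float(c) for c in best.centroid),
        boundary_polygon=boundary,
    )
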