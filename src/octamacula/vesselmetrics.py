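"""Binarization, skeletonization and regional vessel densities.

The vesselness map is binarized with Otsu's method (single global
threshold over a 256-bin histogram, vessels = bright class), thinned to
one-pixel centerlines, and sampled in the two standard macular regions:
the central foveal disc (1 mm diameter) and the parafoveal annulus
(1-3 mm), both centered on the fovea.

VAD = vessel pixels / region pixels; VSD = skeleton pixels / region
pixels.  Skeleton pixels are counted as unit length each (no sqrt(2)
weighting of diagonal steps).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.morphology import skeletonize as _sk_skeletonize

from octamacula.types import (
    DensityMetrics,
    EnFaceAngiogram,
    RegionMask,
    SkeletonMap,
    VesselMap,
)

logger = logging.getLogger(__name__)

_EIGHT = np.ones((3, 3), bool)


@dataclass
class VesselMetricsConfig:
    """Tunables of the density stage."""

    prune_spurs: bool = True
    max_spur_len: int = 3  # skeleton side-branches shorter than this are removed


def otsu_threshold(image: np.ndarray, nbins: int = 256) -> float:
    """Otsu threshold maximizing between-class variance over ``nbins`` bins."""
    return float(threshold_otsu(np.asarray(image, dtype=np.float64), nbins=nbins))


def binarize_otsu(
    vesselness: np.ndarray | EnFaceAngiogram, scan_width_mm: float = 3.0
) -> VesselMap:
    """Global Otsu binarization; vessels are the strictly-above-threshold class.

    A constant map cannot be split into two classes: the result is
    all-background and a warning is logged.
    """
    if isinstance(vesselness, EnFaceAngiogram):
        scan_width_mm = vesselness.scan_width_mm
        vesselness = vesselness.as_float()
    img = np.asarray(vesselness, dtype=np.float64)
    if img.max() == img.min():
        logger.warning("constant map: Otsu undefined, returning all-background")
        return VesselMap(np.zeros_like(img, dtype=bool), scan_width_mm)
    t = otsu_threshold(img)
    return VesselMap(img > t, scan_width_mm)


def _neighbor_count(skel: np.ndarray) -> np.ndarray:
    return ndi.convolve(skel.astype(np.uint8), np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]]), mode="constant")


def _prune_spurs(skel: np.ndarray, max_len: int) -> np.ndarray:
    """Remove skeleton side-branches shorter than ``max_len`` pixels.

    From every endpoint, walk along the skeleton; if a junction (>= 3
    neighbors) is met in fewer than ``max_len`` steps, the walked pixels
    are a spur and are deleted.  Open ends of genuine centerlines are not
    shortened because their walk never reaches a junction that early.
    """
    out = skel.copy()
    nb = _neighbor_count(out)
    endpoints = np.argwhere(out & (nb == 1))
    offsets = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    for ep in endpoints:
        path = [tuple(ep)]
        prev = None
        cur = tuple(ep)
        is_spur = False
        for _ in range(max_len - 1):
            nxt = [
                (cur[0] + dr, cur[1] + dc)
                for dr, dc in offsets
                if 0 <= cur[0] + dr < out.shape[0]
                and 0 <= cur[1] + dc < out.shape[1]
                and out[cur[0] + dr, cur[1] + dc]
                and (cur[0] + dr, cur[1] + dc) != prev
            ]
            if len(nxt) != 1:
                is_spur = len(nxt) > 1  # reached a junction: the walk was a spur
                break
            prev, cur = cur, nxt[0]
            if nb[cur] >= 3:
                is_spur = True
                break
            path.append(cur)
        if is_spur:
            for r, c in path:
                out[r, c] = False
    return out


def _neighbors8(r: int, c: int, shape: tuple[int, int]):
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == dc == 0:
                continue
            rr, cc = r + dr, c + dc
            if 0 <= rr < shape[0] and 0 <= cc < shape[1]:
                yield rr, cc


def _break_2x2_blocks(skel: np.ndarray, allowed: np.ndarray | None = None) -> np.ndarray:
    """Ensure no fully-set 2x2 block remains (max local thickness 1 px).

    A block pixel is removed if it is 8-simple (removal keeps its
    neighborhood connected).  At an X-crossing no corner is simple; there
    the crossing is shifted diagonally: a corner is cleared and an empty
    pixel (inside ``allowed``, i.e. the vessel mask) is set to reconnect
    the branch the corner carried.  As a last resort the least-connected
    corner is removed, favoring thinness over connectivity.
    """
    out = skel.copy()
    allowed = np.ones_like(out) if allowed is None else allowed
    for _ in range(8):  # bounded; blocks are rare after thinning
        blocks = out[:-1, :-1] & out[1:, :-1] & out[:-1, 1:] & out[1:, 1:]
        coords = np.argwhere(blocks)
        if len(coords) == 0:
            break
        for r, c in coords:
            corners = ((r, c), (r + 1, c + 1), (r + 1, c), (r, c + 1))
            if not all(out[p] for p in corners):
                continue
            if any(out[p] and _try_remove_simple(out, p) for p in corners):
                continue
            if _shift_crossing(out, corners, allowed):
                continue
            # least-damage fallback: drop the corner with fewest outside links
            nb = [(sum(out[q] for q in _neighbors8(*p, out.shape)), p) for p in corners]
            out[min(nb)[1]] = False
    return out


def _try_remove_simple(skel: np.ndarray, p: tuple[int, int]) -> bool:
    if _is_8_simple(skel, *p):
        skel[p] = False
        return True
    return False


def _shift_crossing(
    skel: np.ndarray, corners: tuple, allowed: np.ndarray
) -> bool:
    """Clear one block corner and set a reconnecting pixel outside the block."""
    block = set(corners)
    for p in corners:
        outside = [q for q in _neighbors8(*p, skel.shape) if skel[q] and q not in block]
        if len(outside) != 1:
            continue
        n = outside[0]
        others = [q for q in block if q != p]
        for q in _neighbors8(*n, skel.shape):
            if skel[q] or not allowed[q] or q in block:
                continue
            if not any(
                abs(q[0] - o[0]) <= 1 and abs(q[1] - o[1]) <= 1 for o in others
            ):
                continue
            skel[p] = False
            skel[q] = True
            # reject the shift if it created a new fully-set 2x2 block
            r0, c0 = max(q[0] - 1, 0), max(q[1] - 1, 0)
            win = skel[r0: q[0] + 2, c0: q[1] + 2]
            if (win[:-1, :-1] & win[1:, :-1] & win[:-1, 1:] & win[1:, 1:]).any():
                skel[p] = True
                skel[q] = False
                continue
            return True
    return False


def _is_8_simple(skel: np.ndarray, r: int, c: int) -> bool:
    """True if removing (r, c) keeps its 8-neighborhood connectivity."""
    h, w = skel.shape
    patch = np.zeros((3, 3), bool)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w:
                patch[dr + 1, dc + 1] = skel[rr, cc]
    patch[1, 1] = False
    n_before, _ = ndi.label(patch, structure=_EIGHT)[1], None
    return n_before <= 1 and patch.any()


def skeletonize_vessels(
    vessel_map: VesselMap, config: VesselMetricsConfig | None = None
) -> SkeletonMap:
    """Iteratively thin the vessel map to one-pixel-wide centerlines.

    Topology-preserving thinning (8-connectivity); short spurs are pruned
    by default, and any residual fully-set 2x2 block is broken so the
    skeleton's maximum local thickness is one pixel.
    """
    config = config or VesselMetricsConfig()
    skel = _sk_skeletonize(vessel_map.pixels)
    if config.prune_spurs:
        skel = _prune_spurs(skel, config.max_spur_len)
    skel = _break_2x2_blocks(skel, allowed=vessel_map.pixels)
    skel &= vessel_map.pixels  # centerlines are a subset of the vessels
    return SkeletonMap(skel, vessel_map.scan_width_mm)


def make_region_masks(
    side_px: int,
    scan_width_mm: float,
    center_px: tuple[float, float] | None = None,
) -> tuple[RegionMask, RegionMask]:
    """Rasterize the foveal disc (1 mm diameter) and parafoveal annulus (1-3 mm).

    Pixel scale is ``scan_width_mm / side_px``; a pixel belongs to a region
    when its center does.  Raises if the 3-mm circle does not fit.
    """
    if center_px is None:
        center_px = ((side_px - 1) / 2.0, (side_px - 1) / 2.0)
    mm_per_px = scan_width_mm / side_px
    r_out_px = 1.5 / mm_per_px
    cy, cx = center_px
    if not (0 <= cy < side_px and 0 <= cx < side_px):
        raise ValueError(f"center {center_px} outside the {side_px}-px image")
    # 1-px slack tolerates the half-pixel shift of border-cropped geometry
    margin = min(cy, cx, side_px - 1 - cy, side_px - 1 - cx) + 0.5
    if r_out_px > margin + 1.0:
        raise ValueError(
            f"3-mm circle (radius {r_out_px:.1f} px) exceeds image bounds "
            f"(margin {margin:.1f} px)"
        )
    rr, cc = np.mgrid[0:side_px, 0:side_px]
    dist_mm = np.hypot(rr - cy, cc - cx) * mm_per_px
    foveal = dist_mm <= 0.5
    parafoveal = (dist_mm > 0.5) & (dist_mm <= 1.5)
    return (
        RegionMask(foveal, scan_width_mm, "foveal", center_px, 0.0, 1.0),
        RegionMask(parafoveal, scan_width_mm, "parafoveal", center_px, 1.0, 3.0),
    )


def vad(vessel_map: VesselMap, region: RegionMask) -> float:
    """Vessel area density: vessel pixels / region pixels."""
    n_region = int(region.pixels.sum())
    if n_region == 0:
        raise ValueError("empty region mask")
    return float((vessel_map.pixels & region.pixels).sum() / n_region)


def vsd(skeleton_map: SkeletonMap, region: RegionMask) -> float:
    """Vessel skeleton density: skeleton pixels / region pixels."""
    n_region = int(region.pixels.sum())
    if n_region == 0:
        raise ValueError("empty region mask")
    return float((skeleton_map.pixels & region.pixels).sum() / n_region)


def quantify_eye(
    scp_vesselness: np.ndarray,
    dcp_vesselness: np.ndarray,
    scan_width_mm: float = 3.0,
    center_px: tuple[float, float] | None = None,
    config: VesselMetricsConfig | None = None,
    eye_id: str = "",
) -> DensityMetrics:
    """Full density readout for one eye from its two plexus vesselness maps."""
    if scp_vesselness.shape != dcp_vesselness.shape:
        raise ValueError("SCP and DCP maps must share geometry")
    side = scp_vesselness.shape[0]
    foveal, parafoveal = make_region_masks(side, scan_width_mm, center_px)
    out = DensityMetrics(eye_id=eye_id)
    for name, vmap in (("scp", scp_vesselness), ("dcp", dcp_vesselness)):
        arr = np.asarray(vmap, dtype=np.float64)
        t = otsu_threshold(arr) if arr.max() > arr.min() else float("nan")
        setattr(out, f"otsu_threshold_{name}", t)
        logger.info("eye=%s plexus=%s otsu_threshold=%.4f", eye_id, name.upper(), t)
        vessels = binarize_otsu(arr, scan_width_mm)
        skeleton = skeletonize_vessels(vessels, config)
        setattr(out, f"vad_foveal_{name}", vad(vessels, foveal))
        setattr(out, f"vad_parafoveal_{name}", vad(vessels, parafoveal))
        setattr(out, f"vsd_foveal_{name}", vsd(skeleton, foveal))
        setattr(out, f"vsd_parafoveal_{name}", vsd(skeleton, parafoveal))
    return out
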