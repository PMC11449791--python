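"""Puncta densitometry, perisomatic ring analysis and optical density.

The puncta pipeline mirrors the standard FIJI/ImageJ recipe: rolling-ball
background subtraction, conversion to 8-bit, a fixed binarization threshold
(marker- and layer-specific, supplied by the caller), a blur to clean noise
and split closely apposed puncta, then connected-component counting within
the region of interest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi
from shapely.geometry import Polygon
from skimage.draw import polygon2mask
from skimage.measure import label, regionprops
from skimage.restoration import rolling_ball

__all__ = [
    "PunctaImage",
    "puncta_count",
    "ei_ratio",
    "perisomatic_density",
    "optical_density",
    "read_puncta_image",
    "write_puncta_image",
]


@dataclass
class PunctaImage:
    """Single-channel grayscale image with physical pixel size (um/px)."""

    pixels: np.ndarray
    px_um: float
    roi: np.ndarray | None = None  # (k, 2) polygon vertices in um (x, y)

    def __post_init__(self) -> None:
        if self.px_um <= 0:
            raise ValueError("px_um must be positive")
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D grayscale array")

    @property
    def field_um2(self) -> float:
        return self.pixels.size * self.px_um**2


def write_puncta_image(img: PunctaImage, path: str | Path) -> None:
    """TIFF plus a JSON sidecar holding the pixel size (and ROI)."""
    import tifffile

    path = Path(path)
    tifffile.imwrite(path, img.pixels)
    sidecar = {"px_um": img.px_um}
    if img.roi is not None:
        sidecar["roi_um"] = np.asarray(img.roi).tolist()
    path.with_suffix(".json").write_text(json.dumps(sidecar))


def read_puncta_image(path: str | Path) -> PunctaImage:
    import tifffile

    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    roi = np.asarray(meta["roi_um"]) if "roi_um" in meta else None
    return PunctaImage(tifffile.imread(path), float(meta["px_um"]), roi)


def _to_8bit(img: np.ndarray) -> np.ndarray:
    if img.dtype == np.uint8:
        return img
    lo, hi = float(img.min()), float(img.max())
    if hi <= lo:
        return np.zeros(img.shape, dtype=np.uint8)
    return np.round((img.astype(float) - lo) / (hi - lo) * 255).astype(np.uint8)


def _binarize(
    pixels: np.ndarray,
    threshold: float,
    rolling_radius_px: int,
    blur_sigma_px: float = 1.0,
) -> np.ndarray:
    """Rolling-ball background subtraction → 8-bit → threshold → blur →
    re-threshold. Returns the final boolean mask."""
    img = pixels.astype(float)
    if rolling_radius_px > 0:
        img = img - rolling_ball(img, radius=rolling_radius_px)
    img8 = _to_8bit(np.clip(img, 0, None))
    binary = img8 >= threshold
    if blur_sigma_px > 0:
        blurred = ndi.gaussian_filter(binary.astype(float), blur_sigma_px)
        binary = blurred > 0.5
    return binary


def puncta_count(
    img: PunctaImage,
    threshold: float,
    rolling_radius_px: int = 50,
    min_area_um2: float | None = None,
    max_area_um2: float | None = None,
) -> tuple[int, float]:
    """Count puncta and return (count, density per um^2 of the ROI).

    Components are 4-connected (diagonal contact does not merge puncta).
    Area filters are optional — the neuropil-square analysis uses none;
    the perisomatic analysis applies its own bounds.
    """
    if not 0 <= threshold <= 255:
        raise ValueError("threshold must lie within 8-bit range")
    binary = _binarize(img.pixels, threshold, rolling_radius_px)
    if img.roi is not None:
        roi_px = np.asarray(img.roi)[:, ::-1] / img.px_um  # (y, x)
        roi_mask = polygon2mask(binary.shape, roi_px)
        if not roi_mask.any():
            raise ValueError("empty ROI")
        area_um2 = float(roi_mask.sum()) * img.px_um**2
    else:
        roi_mask = None
        area_um2 = img.field_um2
    lab = label(binary, connectivity=1)
    count = 0
    for rp in regionprops(lab):
        a = rp.area * img.px_um**2
        if min_area_um2 is not None and a < min_area_um2:
            continue
        if max_area_um2 is not None and a > max_area_um2:
            continue
        if roi_mask is not None:
            cy, cx = rp.centroid
            if not roi_mask[int(round(cy)), int(round(cx))]:
                continue
        count += 1
    return count, count / area_um2


def ei_ratio(vglut1_density: float, vgat_density: float) -> float:
    """Excitatory/inhibitory puncta-density ratio (VGLUT1 / VGAT)."""
    if vgat_density <= 0:
        raise ValueError("VGAT density must be positive")
    return vglut1_density / vgat_density


def perisomatic_density(
    img: PunctaImage,
    soma_polygon_um: np.ndarray,
    threshold: float,
    ring_um: float = 1.25,
    area_bounds_um2: tuple[float, float] = (0.15, 2.5),
    rolling_radius_px: int = 50,
) -> tuple[float, float]:
    """Perisomatic puncta density on a ring around a drawn soma profile.

    The soma polygon is dilated by ``ring_um``; the ring (dilation minus
    soma) is binarized as in :func:`puncta_count`; components with area in
    ``area_bounds_um2`` count as puncta. Returns
    ``(puncta per um of soma perimeter, puncta area fraction of the ring)``.
    """
    poly = Polygon(np.asarray(soma_polygon_um, dtype=float))
    if not poly.is_valid or poly.area == 0:
        raise ValueError("soma polygon must be closed and non-self-intersecting")
    outer = poly.buffer(ring_um)
    h, w = img.pixels.shape
    minx, miny, maxx, maxy = outer.bounds
    if minx < 0 or miny < 0 or maxx > w * img.px_um or maxy > h * img.px_um:
        raise ValueError("perisomatic ring exits the image bounds")

    def mask_of(geom) -> np.ndarray:
        pts = np.asarray(geom.exterior.coords)[:, ::-1] / img.px_um  # (y, x)
        return polygon2mask(img.pixels.shape, pts)

    ring_mask = mask_of(outer) & ~mask_of(poly)
    binary = _binarize(img.pixels, threshold, rolling_radius_px) & ring_mask
    lab = label(binary, connectivity=1)
    lo, hi = area_bounds_um2
    count = 0
    puncta_area = 0.0
    for rp in regionprops(lab):
        a = rp.area * img.px_um**2
        if lo <= a <= hi:
            count += 1
            puncta_area += a
    ring_area = float(ring_mask.sum()) * img.px_um**2
    return count / poly.length, puncta_area / ring_area


def optical_density(
    img: np.ndarray,
    roi_mask: np.ndarray,
    white_matter_mask: np.ndarray,
) -> float:
    """White-matter-normalized optical density of a region.

    ``OD(x) = -log10(G(x) / G_max)`` with ``G_max`` the bit-depth maximum
    (255 for 8-bit, 65535 for 16-bit); zero grey levels are clamped to one
    count. The region OD is the ROI mean minus the white-matter mean.
    """
    img = np.asarray(img)
    g_max = 255.0 if img.dtype == np.uint8 else 65535.0 if img.dtype == np.uint16 \
        else float(img.max())
    g = np.clip(img.astype(float), 1.0, None)
    od = -np.log10(g / g_max)
    for m in (roi_mask, white_matter_mask):
        if np.asarray(m).shape != img.shape or not np.asarray(m).any():
            raise ValueError("masks must be non-empty and match the image")
    return float(od[np.asarray(roi_mask, bool)].mean()
                 - od[np.asarray(white_matter_mask, bool)].mean())
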