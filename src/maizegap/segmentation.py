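"""Green-plant segmentation for nadir field images.

The chain isolates green vegetation from soil with the excess-green index
(ExG = 2G - R - B), thresholds the index map with Otsu's method, fills small
holes with a morphological closing, and extracts connected plant blobs whose
area-based image moments give the stem-centroid of each seedling.

Coordinates follow raster convention: x rightward, y downward, 0-based,
pixel centers at integer coordinates. Bounding boxes are half-open
``[x_min, x_max) x [y_min, y_max)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import measure, morphology
from skimage.filters import threshold_otsu

__all__ = [
    "PlantBlob",
    "excess_green",
    "otsu_binarize",
    "close_mask",
    "extract_blobs",
    "blob_centroid",
]


def _validate_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an HxWx3 RGB array, got shape {image.shape}")
    if image.shape[0] < 1 or image.shape[1] < 1:
        raise ValueError("image must have positive height and width")
    return image


def excess_green(image: np.ndarray) -> np.ndarray:
    """Per-pixel excess-green index ``2G - R - B``.

    Parameters
    ----------
    image : ndarray, shape (H, W, 3)
        RGB intensities in [0, 255], channel order (R, G, B).

    Returns
    -------
    ndarray of int32, shape (H, W)
        Signed, unclipped index values in [-510, 510]. High on green
        vegetation, near zero on soil, shadow and dead residue.
    """
    image = _validate_rgb(image).astype(np.int32)
    r, g, b = image[..., 0], image[..., 1], image[..., 2]
    return 2 * g - r - b


def _rescale_u8(values: np.ndarray) -> np.ndarray:
    """Affine min/max rescale of a scalar map to 8-bit [0, 255]."""
    values = np.asarray(values, dtype=np.float64)
    lo, hi = values.min(), values.max()
    if hi == lo:
        raise ValueError("cannot rescale a constant map")
    scaled = (values - lo) * (255.0 / (hi - lo))
    return np.rint(scaled).astype(np.uint8)


def otsu_binarize(scalar_map: np.ndarray) -> tuple[int, np.ndarray]:
    """Threshold a scalar map with Otsu's method.

    The map is affinely rescaled to 8-bit and the threshold maximizing the
    between-class variance of the 256-bin histogram is selected; the mask is
    ``rescaled > threshold``.

    Returns ``(threshold, mask)`` where the threshold is on the rescaled
    0..255 scale.

    Raises
    ------
    ValueError
        If the map is constant (no foreground/background separation exists).
    """
    scalar_map = np.asarray(scalar_map)
    if scalar_map.size == 0:
        raise ValueError("empty scalar map")
    if np.unique(scalar_map).size < 2:
        raise ValueError("degenerate input: scalar map has fewer than 2 distinct values")
    u8 = _rescale_u8(scalar_map)
    hist = np.bincount(u8.ravel(), minlength=256).astype(np.int64)
    thr = int(threshold_otsu(hist=(hist, np.arange(256))))
    return thr, u8 > thr


def close_mask(mask: np.ndarray, kernel_px: int = 5) -> np.ndarray:
    """Morphological closing (dilation then erosion) with a square element.

    The mask is padded by ``kernel_px`` before the operation so border
    behavior matches closing on an infinite empty canvas; the result is a
    superset of the input (closing is extensive) and the operation is
    idempotent.
    """
    if kernel_px < 1 or kernel_px % 2 == 0:
        raise ValueError("kernel_px must be odd and >= 1")
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    footprint = np.ones((kernel_px, kernel_px), dtype=bool)
    padded = np.pad(mask, kernel_px, mode="constant", constant_values=False)
    closed = morphology.closing(padded, footprint)
    return closed[kernel_px:-kernel_px, kernel_px:-kernel_px]


@dataclass
class PlantBlob:
    """One filtered connected component of the plant mask.

    ``moments`` are the raw area moments over the member pixel set:
    m00 (area, pixel count), m10 = sum of x, m01 = sum of y; the centroid is
    (m10/m00, m01/m00).
    """

    pixels: np.ndarray  # (N, 2) int array of (x, y) member pixels
    contour: np.ndarray  # (M, 2) float array of (x, y) outline vertices
    area: int
    moments: dict = field(default_factory=dict)
    centroid: tuple[float, float] = (np.nan, np.nan)
    bbox: tuple[int, int, int, int] = (0, 0, 0, 0)  # half-open x_min, y_min, x_max, y_max

    @classmethod
    def from_pixels(cls, pixels_xy: np.ndarray, contour_xy: np.ndarray | None = None) -> "PlantBlob":
        pixels_xy = np.asarray(pixels_xy)
        m00 = int(pixels_xy.shape[0])
        if m00 == 0:
            raise ValueError("zero-area blob")
        m10 = int(pixels_xy[:, 0].sum())
        m01 = int(pixels_xy[:, 1].sum())
        x0, y0 = m10 / m00, m01 / m00
        xmin, ymin = pixels_xy.min(axis=0)
        xmax, ymax = pixels_xy.max(axis=0) + 1
        if contour_xy is None:
            contour_xy = np.empty((0, 2))
        return cls(
            pixels=pixels_xy,
            contour=np.asarray(contour_xy, dtype=float),
            area=m00,
            moments={"m00": m00, "m10": m10, "m01": m01},
            centroid=(x0, y0),
            bbox=(int(xmin), int(ymin), int(xmax), int(ymax)),
        )


def _component_contour(component_mask: np.ndarray, offset_rc: tuple[int, int]) -> np.ndarray:
    """Outline of one component as (x, y) vertices (longest iso-contour)."""
    padded = np.pad(component_mask.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        return np.empty((0, 2))
    longest = max(contours, key=len)
    rows = longest[:, 0] - 1 + offset_rc[0]
    cols = longest[:, 1] - 1 + offset_rc[1]
    return np.column_stack([cols, rows])


def extract_blobs(mask: np.ndarray, min_area_px: int) -> list[PlantBlob]:
    """External contours of 8-connected components, filtered by area.

    Components smaller than ``min_area_px`` pixels are discarded (weed and
    noise suppression). Blobs are returned sorted by centroid in row-major
    order (top-to-bottom, then left-to-right).
    """
    if min_area_px < 1:
        raise ValueError("min_area_px must be >= 1")
    mask = np.asarray(mask, dtype=bool)
    labels = measure.label(mask, connectivity=2)
    blobs: list[PlantBlob] = []
    for region in measure.regionprops(labels):
        if region.area < min_area_px:
            continue
        coords_rc = region.coords  # (N, 2) as (row, col)
        pixels_xy = coords_rc[:, ::-1].copy()
        r0, c0, _, _ = region.bbox
        contour = _component_contour(region.image, (r0, c0))
        blobs.append(PlantBlob.from_pixels(pixels_xy, contour))
    blobs.sort(key=lambda b: (b.centroid[1], b.centroid[0]))
    return blobs


def blob_centroid(blob: PlantBlob) -> tuple[float, float]:
    """Centroid (m10/m00, m01/m00) from the blob's area moments."""
    m00 = blob.moments.get("m00", blob.area)
    if m00 <= 0:
        raise ValueError("zero-area blob has no centroid")
    return blob.moments["m10"] / m00, blob.moments["m01"] / m00
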