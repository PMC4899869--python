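"""Automated spot/cell detection on a marker channel.

The pipeline is deliberately minimal and auditable — every stage has an
inspectable intermediate: Gaussian smoothing, in-mask thresholding (Otsu
or absolute), 8-connected component labeling, area gating, optional
watershed splitting of merged objects, intensity-weighted centroids.
Identical inputs produce identical points in identical (labeling scan)
order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops
from skimage.segmentation import watershed

from .errors import DegenerateImageError, MaskShapeError
from .io import ChannelImage, PointSet, RegionMask, nearest_pixel

__all__ = ["DetectionParams", "detect_cells"]


@dataclass
class DetectionParams:
    """Detection knobs.

    smoothing_sigma : Gaussian blur scale in pixels (>= 0; 0 disables).
    threshold_mode : "otsu" (computed on in-mask pixels only, so bright
        excluded regions such as autofluorescent epithelium cannot skew
        the threshold) or "absolute".
    threshold_value : intensity cutoff, required iff mode is "absolute".
    min_area, max_area : connected-component area gates in pixels.
    split_touching : if set, components larger than ``2 * min_area`` are
        split by watershed on the smoothed intensity, seeded at local
        maxima of a Laplacian-of-Gaussian blob response (scale
        ``split_sigma``), which separates touching spots closer than the
        plain intensity maxima can.
    split_sigma : LoG scale for split seeding, in pixels; defaults to
        ``max(1.0, 0.7 * smoothing_sigma)`` when None.
    """

    smoothing_sigma: float = 2.0
    threshold_mode: str = "otsu"
    threshold_value: float | None = None
    min_area: int = 20
    max_area: int = 2000
    split_touching: bool = False
    split_sigma: float | None = None

    def __post_init__(self):
        if self.smoothing_sigma < 0:
            raise ValueError("smoothing_sigma must be >= 0")
        if not 0 < self.min_area <= self.max_area:
            raise ValueError("need 0 < min_area <= max_area")
        if self.threshold_mode not in ("otsu", "absolute"):
            raise ValueError(f"unknown threshold mode {self.threshold_mode!r}")
        if self.threshold_mode == "absolute":
            if self.threshold_value is None or not np.isfinite(
                self.threshold_value
            ):
                raise ValueError(
                    "absolute mode requires a finite threshold_value"
                )


def detect_cells(image: ChannelImage, mask: RegionMask,
                 params: DetectionParams | None = None) -> PointSet:
    """Detect cell centroids in one channel within the valid mask region.

    Returns a PointSet (provenance="detected") whose points are the
    intensity-weighted centroids of surviving components, ordered by
    labeling scan order. No point falls outside ``mask.valid``: a centroid
    pulled out of its (non-convex) component is snapped to the nearest
    component pixel.
    """
    if params is None:
        params = DetectionParams()
    pixels = image.pixels
    if pixels.shape != mask.shape:
        raise MaskShapeError(
            f"image shape {pixels.shape} != mask shape {mask.shape}"
        )
    if params.smoothing_sigma > 0:
        smoothed = ndimage.gaussian_filter(pixels, params.smoothing_sigma)
    else:
        smoothed = pixels.astype(np.float64)
    smoothed = smoothed * mask.valid

    in_mask = smoothed[mask.valid]
    if params.threshold_mode == "otsu":
        if np.all(in_mask == in_mask.flat[0]):
            raise DegenerateImageError(
                "constant in-mask intensities; Otsu threshold undefined"
            )
        thresh = threshold_otsu(in_mask)
    else:
        thresh = float(params.threshold_value)

    binary = (smoothed > thresh) & mask.valid
    labels = label(binary, connectivity=2)

    log_response = None
    if params.split_touching:
        split_sigma = params.split_sigma
        if split_sigma is None:
            split_sigma = max(1.0, 0.7 * params.smoothing_sigma)
        log_response = -ndimage.gaussian_laplace(
            np.asarray(pixels, dtype=np.float64), split_sigma
        ) * mask.valid

    centroids = []
    for prop in regionprops(labels, intensity_image=smoothed):
        if prop.area < params.min_area or prop.area > params.max_area:
            continue
        if params.split_touching and prop.area > 2 * params.min_area:
            sub = _split_component(prop, smoothed, log_response, params)
            if sub is not None:
                centroids.extend(sub)
                continue
        centroids.append(_weighted_centroid(prop))

    points = PointSet(
        np.asarray(centroids, dtype=np.float64).reshape(-1, 2),
        cell_class=image.channel_name,
        sample_id=image.sample_id,
        provenance="detected",
    )
    return _snap_into_mask(points, binary)


def _weighted_centroid(prop):
    cy, cx = prop.centroid_weighted
    return (cx, cy)


def _split_component(prop, smoothed, log_response, params):
    """Watershed split seeded at local maxima of the LoG blob response.

    Returns centroid list for the sub-components, or None when no split is
    possible (single maximum)."""
    y0, x0, y1, x1 = prop.bbox
    region_img = smoothed[y0:y1, x0:x1]
    region_mask = prop.image
    peaks = peak_local_max(
        log_response[y0:y1, x0:x1], labels=region_mask.astype(int),
        min_distance=1, exclude_border=False,
    )
    if len(peaks) < 2:
        return None
    markers = np.zeros(region_mask.shape, dtype=int)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    ws = watershed(-region_img, markers=markers, mask=region_mask)
    out = []
    for sub in regionprops(ws, intensity_image=region_img):
        if sub.area < params.min_area or sub.area > params.max_area:
            continue
        cy, cx = sub.centroid_weighted
        out.append((cx + x0, cy + y0))
    return out or None


def _snap_into_mask(points, binary):
    if len(points) == 0:
        return points
    coords = points.coords.copy()
    xi = nearest_pixel(coords[:, 0])
    yi = nearest_pixel(coords[:, 1])
    h, w = binary.shape
    fg = np.column_stack(np.nonzero(binary))  # (row, col)
    for k in range(len(coords)):
        x, y = np.clip(xi[k], 0, w - 1), np.clip(yi[k], 0, h - 1)
        if not binary[y, x]:
            d = (fg[:, 0] - coords[k, 1]) ** 2 + (fg[:, 1] - coords[k, 0]) ** 2
            j = int(np.argmin(d))
            coords[k] = (fg[j, 1], fg[j, 0])
    points.coords = coords
    return points
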