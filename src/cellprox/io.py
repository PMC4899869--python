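"""Images, masks, point tables and result files.

Coordinate convention used throughout the package: 0-based, ``x`` is the
column index and ``y`` the row index; coordinates are continuous, with the
center of pixel ``(row i, col j)`` at ``(x=j, y=i)``. A point on a pixel
boundary belongs to the pixel whose center is nearest, ties toward the
smaller index. All distances are computed in pixels; ``pixel_size``
(microns/pixel) converts to physical units for reporting only.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
import tifffile
from shapely.geometry import Polygon

from .errors import (
    ChannelAbsentError,
    EmptyValidRegionError,
    MaskShapeError,
    MissingFileError,
    OutOfBoundsError,
    PointSchemaError,
    PolygonError,
    UnreadableImageError,
)

__all__ = [
    "ChannelImage",
    "RegionMask",
    "PointSet",
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "read_points",
    "write_points",
    "write_result",
    "read_result",
    "nearest_pixel",
]


def nearest_pixel(coord):
    """Map continuous coordinates to the index of the nearest pixel.

    Ties (coordinate exactly halfway between two centers) resolve toward
    the smaller index: ``2.5 -> 2``.
    """
    return np.ceil(np.asarray(coord, dtype=float) - 0.5).astype(np.int64)


@dataclass
class ChannelImage:
    """A single marker channel of a fluorescence micrograph.

    Parameters
    ----------
    pixels : 2D float array, finite and non-negative.
    channel_name : marker label, e.g. ``"CD45"``, ``"GFP"``, ``"p16"``.
    pixel_size : physical edge length of one pixel in microns (> 0).
    sample_id : opaque sample identifier.
    """

    pixels: np.ndarray
    channel_name: str
    pixel_size: float = 1.0
    sample_id: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("pixels must be a non-empty 2D raster")
        if not np.all(np.isfinite(self.pixels)) or np.any(self.pixels < 0):
            raise ValueError("intensities must be finite and non-negative")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self):
        return self.pixels.shape


@dataclass
class RegionMask:
    """Valid-region raster plus named excluded sub-regions.

    ``valid`` marks interstitial stroma available for analysis and for
    random placement of the Monte-Carlo null. ``excluded_regions`` maps
    region names (``"epithelium"``, ``"follicle_0"``, ``"background"`` ...)
    to boolean rasters of the same shape; no pixel is both valid and
    excluded.
    """

    valid: np.ndarray
    excluded_regions: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.valid.ndim != 2:
            raise ValueError("valid must be a 2D raster")
        if not self.valid.any():
            raise EmptyValidRegionError("mask has no valid pixel")
        cleaned = {}
        for name, reg in self.excluded_regions.items():
            reg = np.asarray(reg, dtype=bool)
            if reg.shape != self.valid.shape:
                raise MaskShapeError(
                    f"excluded region {name!r} shape {reg.shape} != valid "
                    f"shape {self.valid.shape}"
                )
            if (reg & self.valid).any():
                raise ValueError(f"excluded region {name!r} overlaps valid")
            cleaned[name] = reg
        self.excluded_regions = cleaned

    @property
    def shape(self):
        return self.valid.shape

    def valid_pixel_coords(self):
        """(n, 2) array of x, y centers of valid pixels, scan order."""
        rows, cols = np.nonzero(self.valid)
        return np.column_stack([cols, rows]).astype(np.float64)

    def contains(self, x, y):
        """Whether points fall on a valid pixel (nearest-pixel rule)."""
        xi = nearest_pixel(x)
        yi = nearest_pixel(y)
        h, w = self.valid.shape
        ok = (xi >= 0) & (xi < w) & (yi >= 0) & (yi < h)
        out = np.zeros(np.shape(xi), dtype=bool)
        out[ok] = self.valid[yi[ok], xi[ok]]
        return out


@dataclass
class PointSet:
    """Planar coordinates of one cell class in one sample.

    ``coords`` is an (n, 2) float array of (x, y) pairs; may be empty and
    may contain duplicates. ``provenance`` records how the points were
    obtained: ``manual``, ``detected`` or ``simulated``.
    """

    coords: np.ndarray
    cell_class: str = ""
    sample_id: str = ""
    provenance: str = "manual"

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=np.float64)
        if coords.size == 0:
            coords = coords.reshape(0, 2)
        if coords.ndim != 2 or coords.shape[1] != 2:
            raise ValueError("coords must be an (n, 2) array of x, y pairs")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        if self.provenance not in ("manual", "detected", "simulated"):
            raise ValueError(f"unknown provenance {self.provenance!r}")
        self.coords = coords

    def __len__(self):
        return self.coords.shape[0]

    @property
    def x(self):
        return self.coords[:, 0]

    @property
    def y(self):
        return self.coords[:, 1]

    def validate_bounds(self, shape):
        """Raise if any point falls outside the raster ``shape``.

        The raster spans ``[-0.5, ncols - 0.5] x [-0.5, nrows - 0.5]`` in
        continuous coordinates (pixel centers at integers).
        """
        h, w = shape
        ok = (
            (self.x >= -0.5)
            & (self.x <= w - 0.5)
            & (self.y >= -0.5)
            & (self.y <= h - 0.5)
        )
        if not ok.all():
            bad = self.coords[~ok][0]
            raise OutOfBoundsError(
                f"point ({bad[0]}, {bad[1]}) outside raster of shape {shape}"
            )


# ---------------------------------------------------------------------------
# images


def read_image(path, channel_name, channel_map=None, pixel_size=1.0,
               sample_id=None) -> ChannelImage:
    """Read one channel of a single- or multi-page TIFF.

    ``channel_map`` maps channel names to page indices and is required for
    multi-page files; channel identity is never inferred from TIFF metadata.
    """
    path = Path(path)
    if not path.exists():
        raise MissingFileError(str(path))
    try:
        with tifffile.TiffFile(path) as tif:
            n_pages = len(tif.pages)
            if channel_map is None:
                if n_pages != 1:
                    raise ChannelAbsentError(
                        f"{path} has {n_pages} pages; a channel_map is "
                        f"required to select {channel_name!r}"
                    )
                page = 0
            else:
                if channel_name not in channel_map:
                    raise ChannelAbsentError(
                        f"channel {channel_name!r} not in channel map "
                        f"{sorted(channel_map)}"
                    )
                page = int(channel_map[channel_name])
                if page >= n_pages:
                    raise ChannelAbsentError(
                        f"channel {channel_name!r} maps to page {page} but "
                        f"{path} has only {n_pages} pages"
                    )
            pixels = tif.pages[page].asarray()
    except (ChannelAbsentError, MissingFileError):
        raise
    except Exception as exc:  # tifffile raises several decode error types
        raise UnreadableImageError(f"{path}: {exc}") from exc
    return ChannelImage(
        pixels=np.asarray(pixels, dtype=np.float64),
        channel_name=channel_name,
        pixel_size=pixel_size,
        sample_id=sample_id if sample_id is not None else path.stem,
    )


def write_image(image: ChannelImage, path):
    tifffile.imwrite(os.fspath(path), np.asarray(image.pixels))


# ---------------------------------------------------------------------------
# masks


def _rasterize_polygon(vertices, shape):
    """Boolean raster of pixels whose centers fall inside the polygon.

    A center on the polygon boundary counts as inside.
    """
    poly = Polygon(vertices)
    if not poly.is_valid:
        raise PolygonError("self-intersecting or otherwise invalid polygon")
    h, w = shape
    xs, ys = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    return shapely.intersects_xy(poly, xs.ravel(), ys.ravel()).reshape(h, w)


def read_mask(path_or_polygons, shape=None) -> RegionMask:
    """Read a RegionMask from a raster file or a polygon JSON document.

    Raster dialect: TIFF/PNG, any integer dtype, nonzero = valid region.
    Polygon dialect: ``{"regions": [{"name": str, "vertices": [[x, y], ...]},
    ...], "tissue": [[x, y], ...]?}``; pixels are inside a polygon iff their
    center is inside (boundary inclusive); valid = tissue (or everything)
    minus the union of named regions. ``shape`` is required for polygons and
    checked for rasters when given.
    """
    if isinstance(path_or_polygons, dict):
        return _mask_from_polygons(path_or_polygons, shape)
    path = Path(path_or_polygons)
    if not path.exists():
        raise MissingFileError(str(path))
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            return _mask_from_polygons(json.load(fh), shape)
    if path.suffix.lower() in (".tif", ".tiff"):
        raster = tifffile.imread(path)
    else:
        from imageio.v3 import imread

        raster = imread(path)
        if raster.ndim == 3:  # collapse RGB(A) to a single plane
            raster = raster[..., 0]
    raster = np.asarray(raster)
    if raster.ndim != 2:
        raise UnreadableImageError(f"{path}: mask raster must be 2D")
    if shape is not None and tuple(raster.shape) != tuple(shape):
        raise MaskShapeError(
            f"mask shape {raster.shape} != expected {tuple(shape)}"
        )
    return RegionMask(valid=raster != 0)


def _mask_from_polygons(doc, shape):
    if shape is None:
        raise MaskShapeError("a raster shape is required to rasterize polygons")
    if "tissue" in doc and doc["tissue"] is not None:
        tissue = _rasterize_polygon(doc["tissue"], shape)
    else:
        tissue = np.ones(shape, dtype=bool)
    excluded = {}
    for region in doc.get("regions", []):
        excluded[region["name"]] = _rasterize_polygon(
            region["vertices"], shape
        )
    valid = tissue.copy()
    for reg in excluded.values():
        valid &= ~reg
    if not valid.any():
        raise EmptyValidRegionError("exclusions leave no valid pixel")
    # clip exclusions to the tissue so the partition invariant holds
    excluded = {name: reg & tissue for name, reg in excluded.items()}
    if "tissue" in doc and doc["tissue"] is not None:
        excluded.setdefault("background", ~tissue)
    return RegionMask(valid=valid, excluded_regions=excluded)


def write_mask(mask: RegionMask, path):
    tifffile.imwrite(
        os.fspath(path), mask.valid.astype(np.uint8) * np.uint8(255)
    )


# ---------------------------------------------------------------------------
# point tables


def read_points(path, shape=None, default_class="", default_sample="",
                provenance="manual") -> PointSet:
    """Read a point table CSV with header columns x, y[, cell_class, sample_id]."""
    path = Path(path)
    if not path.exists():
        raise MissingFileError(str(path))
    df = pd.read_csv(path, float_precision="round_trip")
    missing = {"x", "y"} - set(df.columns)
    if missing:
        raise PointSchemaError(
            f"{path}: missing required column(s) {sorted(missing)}"
        )
    try:
        coords = df[["x", "y"]].astype(np.float64).to_numpy()
    except (TypeError, ValueError) as exc:
        raise PointSchemaError(f"{path}: non-numeric coordinates") from exc
    if not np.all(np.isfinite(coords)):
        raise PointSchemaError(f"{path}: non-finite coordinates")
    cell_class = default_class
    if "cell_class" in df.columns and len(df):
        cell_class = str(df["cell_class"].iloc[0])
    sample_id = default_sample
    if "sample_id" in df.columns and len(df):
        sample_id = str(df["sample_id"].iloc[0])
    points = PointSet(coords, cell_class=cell_class, sample_id=sample_id,
                      provenance=provenance)
    if shape is not None:
        points.validate_bounds(shape)
    return points


def write_points(points: PointSet, path):
    df = pd.DataFrame({"x": points.x, "y": points.y})
    if points.cell_class:
        df["cell_class"] = points.cell_class
    if points.sample_id:
        df["sample_id"] = points.sample_id
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# results


def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        out = {"__type__": type(obj).__name__}
        for f in dataclasses.fields(obj):
            out[f.name] = _to_jsonable(getattr(obj, f.name))
        return out
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    return obj


def write_result(result, path, config_echo=None, seed=None):
    """Serialize a result object (AssociationResult, GroupSummary, ...) to JSON.

    The document carries every field at full float precision plus the config
    echo, the seed and the package version, and is re-readable losslessly
    with :func:`read_result`. The file appears atomically (write-then-rename).
    """
    from . import __version__

    doc = {
        "software": "cellprox",
        "version": __version__,
        "seed": seed,
        "config_echo": _to_jsonable(config_echo),
        "result": _to_jsonable(result),
    }
    path = Path(path)
    tmp = path.with_name(path.name + ".tmp")
    try:
        with open(tmp, "w") as fh:
            json.dump(doc, fh, indent=1)
        os.replace(tmp, path)
    finally:
        if tmp.exists():
            tmp.unlink()


def read_result(path):
    """Reconstruct the result object written by :func:`write_result`."""
    with open(path) as fh:
        doc = json.load(fh)
    return _from_jsonable(doc["result"])


def _from_jsonable(obj):
    from . import aggregate as _agg
    from . import spatial as _spatial

    registry = {
        "NNSummary": _spatial.NNSummary,
        "MonteCarloNull": _spatial.MonteCarloNull,
        "AssociationResult": _spatial.AssociationResult,
        "GroupSummary": _agg.GroupSummary,
    }
    if isinstance(obj, dict) and "__type__" in obj:
        cls = registry[obj["__type__"]]
        kwargs = {
            k: _from_jsonable(v) for k, v in obj.items() if k != "__type__"
        }
        return cls(**kwargs)
    if isinstance(obj, dict):
        return {k: _from_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_from_jsonable(v) for v in obj]
    return obj
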