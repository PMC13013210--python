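"""Raster data model and map algebra for SSI surfaces.

A :class:`Grid` is a single-band, north-up, axis-aligned raster: a 2-D
value array plus a GDAL-style 6-tuple geotransform, a CRS identifier and
a nodata sentinel. GeoTIFF I/O is implemented with :mod:`tifffile`,
reading and writing the standard GeoTIFF tags (ModelPixelScale,
ModelTiepoint, GeoKeyDirectory/GeoAsciiParams for the CRS citation, and
GDAL_NODATA), so outputs load in any GIS.

Conventions: pixel-is-area, row 0 at the top, no rotation terms; SSI
grids are stored float32 (computation is float64 internally), category
grids uint8. Float nodata defaults to -9999, categorical nodata to 255.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, replace

import numpy as np
import tifffile

from .core import (
    ClassificationScheme,
    FormulaConstants,
    DEFAULT_CONSTANTS,
    Unit,
    ValidationError,
    compute_ssi_units,
)

__all__ = [
    "Grid",
    "CategoricalGrid",
    "AlignmentError",
    "EmptyDomainError",
    "read_grid",
    "write_grid",
    "assert_aligned",
    "ssi_grid",
    "classify_grid",
    "class_area_fractions",
]

FLOAT_NODATA = -9999.0
CATEGORY_NODATA = 255

# GeoTIFF / GDAL tag codes
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GEO_KEYS = 34735
_TAG_GEO_ASCII = 34737
_TAG_GDAL_NODATA = 42113


class AlignmentError(ValueError):
    """Two rasters do not share shape, geotransform and CRS."""


class EmptyDomainError(ValueError):
    """An operation that needs valid cells found none."""


@dataclass(frozen=True)
class Grid:
    """Single-band georeferenced raster.

    ``transform`` is GDAL-ordered: (x_origin, pixel_width, row_rot,
    y_origin, col_rot, pixel_height) with pixel_height negative for
    north-up rasters. Rotation terms must be zero.
    """

    values: np.ndarray
    transform: tuple[float, float, float, float, float, float]
    crs: str = "unspecified"
    nodata: float = FLOAT_NODATA

    def __post_init__(self):
        v = np.asarray(self.values)
        if v.ndim != 2 or v.size == 0:
            raise ValueError(f"grid values must be a non-empty 2-D array, got shape {v.shape}")
        t = tuple(float(x) for x in self.transform)
        if len(t) != 6:
            raise ValueError("geotransform must have 6 components")
        if t[2] != 0.0 or t[4] != 0.0:
            raise ValueError("rotated geotransforms are not supported")
        if t[1] == 0.0 or t[5] == 0.0:
            raise ValueError("pixel sizes must be nonzero")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "transform", t)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def pixel_size(self) -> tuple[float, float]:
        return abs(self.transform[1]), abs(self.transform[5])

    @property
    def valid_mask(self) -> np.ndarray:
        vals = self.values
        mask = vals != self.nodata
        if np.issubdtype(vals.dtype, np.floating):
            mask &= np.isfinite(vals)
        return mask

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) map coordinates of every cell center, each shaped like values."""
        x0, px, _, y0, _, py = self.transform
        rows, cols = self.shape
        xs = x0 + (np.arange(cols) + 0.5) * px
        ys = y0 + (np.arange(rows) + 0.5) * py
        return np.meshgrid(xs, ys)

    def with_values(self, values: np.ndarray, nodata: float | None = None) -> "Grid":
        return replace(self, values=values, nodata=self.nodata if nodata is None else nodata)


@dataclass(frozen=True)
class CategoricalGrid:
    """Classified raster: small-integer codes tied to a ClassificationScheme."""

    codes: np.ndarray
    transform: tuple[float, float, float, float, float, float]
    scheme: ClassificationScheme
    crs: str = "unspecified"
    nodata_code: int = CATEGORY_NODATA

    def __post_init__(self):
        c = np.asarray(self.codes)
        if c.ndim != 2 or c.size == 0:
            raise ValueError("codes must be a non-empty 2-D array")
        known = {cat.code for cat in self.scheme.categories} | {self.nodata_code}
        present = set(np.unique(c).tolist())
        if not present <= known:
            raise ValueError(f"codes {sorted(present - known)} not in scheme")
        object.__setattr__(self, "codes", c)
        object.__setattr__(self, "transform", tuple(float(x) for x in self.transform))

    @property
    def shape(self) -> tuple[int, int]:
        return self.codes.shape

    @property
    def valid_mask(self) -> np.ndarray:
        return self.codes != self.nodata_code

    def as_grid(self) -> Grid:
        """View the codes as a plain Grid (for area summaries)."""
        return Grid(self.codes, self.transform, self.crs, nodata=self.nodata_code)


def _geo_extratags(transform, crs: str, nodata) -> list:
    x0, px, _, y0, _, py = transform
    ascii_params = crs + "|"
    # Minimal GeoKeyDirectory: one citation key pointing into GeoAsciiParams.
    keydir = (1, 1, 0, 1, 1026, _TAG_GEO_ASCII, len(ascii_params), 0)
    return [
        (_TAG_PIXEL_SCALE, "d", 3, (abs(px), abs(py), 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, x0, y0, 0.0)),
        (_TAG_GEO_KEYS, "H", len(keydir), keydir),
        (_TAG_GEO_ASCII, "s", len(ascii_params), ascii_params),
        (_TAG_GDAL_NODATA, "s", 0, repr(float(nodata)) if isinstance(nodata, float) else str(nodata)),
    ]


def write_grid(grid: Grid | CategoricalGrid, path: str | os.PathLike) -> str:
    """Write a grid as a single-band GeoTIFF.

    Float grids are stored float32, categorical grids uint8; the
    geotransform, CRS citation and nodata tag ride along as GeoTIFF tags.
    """
    path = os.fspath(path)
    if isinstance(grid, CategoricalGrid):
        data = np.ascontiguousarray(grid.codes, dtype=np.uint8)
        nodata: float | int = int(grid.nodata_code)
    else:
        data = np.ascontiguousarray(grid.values, dtype=np.float32)
        nodata = float(grid.nodata)
    tags = _geo_extratags(grid.transform, grid.crs, nodata)
    try:
        tifffile.imwrite(path, data, extratags=tags)
    except (OSError, PermissionError) as exc:
        raise OSError(f"cannot write raster to {path!r}: {exc}") from exc
    return path


def read_grid(path: str | os.PathLike, band: int | None = None) -> Grid:
    """Load a single-band GeoTIFF into a Grid.

    Multi-band files require an explicit ``band`` index. A missing CRS
    citation yields ``crs="unspecified"`` rather than an error.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(f"raster file not found: {path!r}")
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = page.asarray()
        if data.ndim == 3:
            if band is None:
                raise ValueError(f"{path!r} has {data.shape[-1]} bands; pass band=")
            data = data[..., band]
        tags = page.tags

        def tag(code, default=None):
            t = tags.get(code)
            return default if t is None else t.value

        scale = tag(_TAG_PIXEL_SCALE)
        tie = tag(_TAG_TIEPOINT)
        if scale is not None and tie is not None:
            px, py = float(scale[0]), float(scale[1])
            x0 = float(tie[3]) - float(tie[0]) * px
            y0 = float(tie[4]) + float(tie[1]) * py
            transform = (x0, px, 0.0, y0, 0.0, -py)
        else:
            transform = (0.0, 1.0, 0.0, 0.0, 0.0, -1.0)
        ascii_params = tag(_TAG_GEO_ASCII)
        crs = "unspecified"
        if ascii_params:
            crs = str(ascii_params).split("|")[0].strip("\x00") or "unspecified"
        nodata_str = tag(_TAG_GDAL_NODATA)
        if nodata_str is not None:
            nodata = float(str(nodata_str).strip("\x00 "))
        elif np.issubdtype(data.dtype, np.floating):
            nodata = FLOAT_NODATA
        else:
            nodata = CATEGORY_NODATA
    return Grid(data, transform, crs, nodata=nodata)


def assert_aligned(a, b, tol: float = 1e-6) -> bool:
    """True iff two grids share shape, CRS and geotransform (within ``tol``
    of a pixel in each component)."""
    if a.shape != b.shape or a.crs != b.crs:
        return False
    pa = max(abs(a.transform[1]), abs(a.transform[5]))
    return all(
        abs(x - y) <= tol * pa for x, y in zip(a.transform, b.transform)
    )


def _alignment_diff(a, b) -> str:
    parts = []
    if a.shape != b.shape:
        parts.append(f"shape {a.shape} vs {b.shape}")
    if a.crs != b.crs:
        parts.append(f"CRS {a.crs!r} vs {b.crs!r}")
    if a.transform != b.transform:
        parts.append(f"geotransform {a.transform} vs {b.transform}")
    return "; ".join(parts) or "sub-tolerance geotransform drift"


def ssi_grid(
    temp: Grid,
    rh: Grid,
    in_unit: Unit | str = Unit.CELSIUS,
    out_unit: Unit | str = Unit.FAHRENHEIT,
    clamp_rh: bool = False,
    constants: FormulaConstants = DEFAULT_CONSTANTS,
) -> Grid:
    """Elementwise SSI over co-registered temperature and humidity grids.

    Nodata in either input propagates to the output. Humidity outside
    [0, 100] on valid cells raises unless ``clamp_rh`` is set, in which
    case it is clipped. Output values are float32 (storage dtype);
    arithmetic runs in float64.
    """
    if not assert_aligned(temp, rh):
        raise AlignmentError(f"temperature and humidity grids are misaligned: {_alignment_diff(temp, rh)}")
    valid = temp.valid_mask & rh.valid_mask
    ta = np.asarray(temp.values, dtype=np.float64)
    ur = np.asarray(rh.values, dtype=np.float64)
    bad = valid & ((ur < 0.0) | (ur > 100.0))
    n_bad = int(bad.sum())
    if n_bad:
        if not clamp_rh:
            raise ValidationError(
                f"relative humidity outside [0, 100] on {n_bad} valid cells "
                "(pass clamp_rh=True to clip)"
            )
        ur = np.clip(ur, 0.0, 100.0)
    out = np.full(temp.shape, FLOAT_NODATA, dtype=np.float64)
    out[valid] = compute_ssi_units(ta[valid], in_unit, ur[valid], out_unit, constants)
    return Grid(out.astype(np.float32), temp.transform, temp.crs, nodata=FLOAT_NODATA)


def classify_grid(ssi: Grid, scheme: ClassificationScheme) -> CategoricalGrid:
    """Per-cell comfort classification of a Fahrenheit-scale SSI grid.

    Uses the scheme's interior breakpoints with left-closed/right-open
    semantics; nodata cells receive the categorical nodata code.
    """
    valid = ssi.valid_mask
    vals = np.asarray(ssi.values, dtype=np.float64)
    bounds = np.asarray(scheme.bounds)
    idx = np.digitize(vals, bounds, right=False)  # [lower, upper) intervals
    code_for_index = np.array([c.code for c in scheme.categories], dtype=np.uint8)
    codes = np.full(ssi.shape, CATEGORY_NODATA, dtype=np.uint8)
    codes[valid] = code_for_index[idx[valid]]
    return CategoricalGrid(codes, ssi.transform, scheme, ssi.crs)


def _is_geographic(crs: str) -> bool:
    c = crs.upper().replace(" ", "")
    return any(k in c for k in ("4326", "WGS84", "GEOGRAPHIC", "LONGLAT", "CRS84"))


def _cell_area_weights(cat: CategoricalGrid) -> np.ndarray:
    """Per-row cell areas; cos-latitude weighted for geographic CRS.

    City-scale approximation: within a row the area is constant; for a
    projected CRS every cell has area |px|*|py|.
    """
    x0, px, _, y0, _, py = cat.transform
    rows, _ = cat.shape
    if _is_geographic(cat.crs):
        lat = y0 + (np.arange(rows) + 0.5) * py
        return abs(px * py) * np.cos(np.radians(lat))
    return np.full(rows, abs(px * py))


def class_area_fractions(cat: CategoricalGrid, mask: np.ndarray | None = None):
    """Percent of valid-cell area in each category, as ``{code: percent}``.

    ``mask`` optionally restricts the domain (e.g. to a union of zones).
    Geographic rasters use per-row cos-latitude cell areas; projected
    rasters use the constant cell area. Percentages sum to 100 over the
    codes present.
    """
    valid = cat.valid_mask
    if mask is not None:
        valid = valid & mask
    if not valid.any():
        raise EmptyDomainError("no valid cells in the requested domain")
    row_area = _cell_area_weights(cat)
    area_img = np.broadcast_to(row_area[:, None], cat.shape)
    total = float(area_img[valid].sum())
    out: dict[int, float] = {}
    for code in np.unique(cat.codes[valid]):
        sel = valid & (cat.codes == code)
        out[int(code)] = 100.0 * float(area_img[sel].sum()) / total
    return out
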