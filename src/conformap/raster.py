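"""Pixel-wise application of calibrated conformal predictors to rasters.

A probability raster (one band per class) becomes a two-band uncertainty
product: a 32-bit *bitmask* band in which bit ``c`` is set exactly when
class ``c`` (band order) is in the pixel's prediction set, and an 8-bit
*set-length* band — the per-pixel uncertainty measure.  Regression rasters
(a point band, or lower/upper quantile bands) become lower/upper/width
interval layers.  Every per-pixel result is identical to the tabular
operation on that pixel's values; rasters are processed tile by tile so
memory stays bounded, and nodata in any input band propagates strictly to
all output bands.

GeoTIFF I/O is built on tifffile; georeferencing tags (ModelPixelScale,
ModelTiepoint, GeoKey directories, GDAL metadata) are passed through
verbatim from input to output — no reprojection is performed.

Nodata sentinels in the products: 255 in the set-length band (set lengths
never exceed 32) and all-ones in the bitmask band.  With a full 32-class
roster the all-ones bitmask is also a legitimate full set, so the length
band is the authoritative nodata indicator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import tifffile

from .classification import LacCalibration, MondrianCalibration
from .regression import RegressionCalibration

__all__ = [
    "Raster",
    "SetMaskRaster",
    "read_geotiff",
    "write_geotiff",
    "classify_raster",
    "class_inclusion_mask",
    "regress_raster",
    "encode_bitmask",
    "decode_bitmask",
    "SETMASK_NODATA",
    "LENGTH_NODATA",
]

SETMASK_NODATA = np.uint32(0xFFFFFFFF)
LENGTH_NODATA = np.uint8(255)

# GeoTIFF / GDAL tag codes passed through opaquely
_GEO_TAG_CODES = (33550, 33922, 34264, 34735, 34736, 34737, 42112)
_GDAL_NODATA_CODE = 42113


@dataclass
class Raster:
    """A band-interleaved in-memory raster: ``data`` has shape (bands, H, W).

    ``geo`` carries GeoTIFF tags as opaque tifffile extratags tuples; they
    are copied verbatim to any derived raster.
    """

    data: np.ndarray
    nodata: float | int | None = None
    band_names: tuple | None = None
    geo: tuple = field(default=())

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim == 2:
            data = data[None, :, :]
        if data.ndim != 3:
            raise ValueError("raster data must be (bands, H, W) or (H, W)")
        self.data = data
        if self.band_names is not None:
            self.band_names = tuple(self.band_names)
            if len(self.band_names) != data.shape[0]:
                raise ValueError("band_names length must equal band count")
        self.geo = tuple(self.geo)

    @property
    def n_bands(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1], self.data.shape[2]

    def valid_mask(self) -> np.ndarray:
        """(H, W) boolean: True where all bands carry valid data."""
        return _valid_block(self.data, self.nodata)

    def derive(self, data: np.ndarray, nodata, band_names=None) -> "Raster":
        """New raster sharing this raster's georeferencing."""
        return Raster(data=data, nodata=nodata, band_names=band_names, geo=self.geo)


def _valid_block(block: np.ndarray, nodata) -> np.ndarray:
    valid = np.ones(block.shape[1:], dtype=bool)
    if np.issubdtype(block.dtype, np.floating):
        valid &= np.isfinite(block).all(axis=0)
    if nodata is not None and not (
        isinstance(nodata, float) and np.isnan(nodata)
    ):
        valid &= (block != nodata).all(axis=0)
    return valid


def _tiles(height: int, width: int, tile: int) -> Iterator[tuple[slice, slice]]:
    for r in range(0, height, tile):
        for c in range(0, width, tile):
            yield slice(r, min(r + tile, height)), slice(c, min(c + tile, width))


def read_geotiff(path) -> Raster:
    """Read a (Geo)TIFF; georeferencing tags are retained opaquely."""
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        data = series.asarray()
        axes = series.axes
        page = tif.pages[0]
        geo = []
        nodata = None
        for tag in page.tags.values():
            if tag.code in _GEO_TAG_CODES:
                geo.append((tag.code, tag.dtype, tag.count, tag.value, True))
            elif tag.code == _GDAL_NODATA_CODE:
                text = str(tag.value).strip()
                nodata = float(text) if text not in ("", "None") else None
    if data.ndim == 2:
        data = data[None, :, :]
    elif data.ndim == 3 and axes.endswith("S"):
        data = np.moveaxis(data, -1, 0)  # pixel-interleaved -> band-major
    if nodata is not None and np.issubdtype(data.dtype, np.integer):
        nodata = int(nodata)
    return Raster(data=data, nodata=nodata, geo=tuple(geo))


def write_geotiff(path, raster: Raster, tile: int = 256) -> None:
    """Write a tiled GeoTIFF, copying georeferencing tags verbatim."""
    extratags = list(raster.geo)
    if raster.nodata is not None:
        extratags.append(
            (_GDAL_NODATA_CODE, "s", 0, f"{raster.nodata}", True)
        )
    data = raster.data
    tifffile.imwrite(
        path,
        data[0] if data.shape[0] == 1 else data,
        photometric="minisblack",
        planarconfig="separate" if data.shape[0] > 1 else None,
        tile=(tile, tile),
        extratags=extratags,
    )


def encode_bitmask(membership: np.ndarray) -> np.ndarray:
    """Pack a (..., C) boolean membership array into uint32 codes (bit c = class c)."""
    membership = np.asarray(membership, dtype=bool)
    C = membership.shape[-1]
    if C > 32:
        raise ValueError("bitmask encoding supports at most 32 classes")
    weights = (np.uint64(1) << np.arange(C, dtype=np.uint64)).astype(np.uint64)
    return (membership.astype(np.uint64) @ weights).astype(np.uint32)


def decode_bitmask(codes: np.ndarray, n_classes: int) -> np.ndarray:
    """Unpack uint32 codes into a (..., n_classes) boolean membership array."""
    if not (1 <= n_classes <= 32):
        raise ValueError("n_classes must lie in [1, 32]")
    codes = np.asarray(codes, dtype=np.uint32)
    bits = np.arange(n_classes, dtype=np.uint32)
    return (codes[..., None] >> bits) & np.uint32(1) > 0


@dataclass
class SetMaskRaster:
    """Prediction-set product: bitmask band + set-length band.

    Invariant: popcount(bitmask) equals the length band at every valid
    pixel; length 255 marks nodata (authoritative — see module docstring).
    """

    bitmask: Raster
    length: Raster
    classes: tuple

    def class_index(self, c) -> int:
        if c in self.classes:
            return self.classes.index(c)
        raise ValueError(f"class {c!r} not in roster {list(self.classes)!r}")


def _thresholds_for(calibration, alpha, n_bands) -> np.ndarray:
    if isinstance(calibration, MondrianCalibration):
        t = np.array(
            [calibration.thresholds[c] for c in calibration.classes], dtype=float
        )
    elif isinstance(calibration, LacCalibration):
        if alpha is None:
            if len(calibration.thresholds) != 1:
                raise ValueError("alpha is required when several were calibrated")
            alpha = next(iter(calibration.thresholds))
        t = np.full(len(calibration.classes), calibration.threshold(alpha))
    else:
        raise TypeError(f"unsupported calibration type {type(calibration).__name__}")
    if n_bands != len(calibration.classes):
        raise ValueError(
            f"raster has {n_bands} bands but the calibration roster has "
            f"{len(calibration.classes)} classes"
        )
    return t


def classify_raster(
    raster: Raster,
    calibration: LacCalibration | MondrianCalibration,
    alpha: float | None = None,
    tile: int = 256,
) -> SetMaskRaster:
    """Per-pixel prediction sets for a probability raster.

    Band ``c`` must hold the probability of roster class ``c``.  The result
    at each valid pixel is identical to the tabular set rule applied to
    that pixel's probability vector; nodata propagates strictly.
    """
    C = raster.n_bands
    if C > 32:
        raise ValueError("rosters larger than 32 classes are not supported")
    t = _thresholds_for(calibration, alpha, C)
    H, W = raster.shape
    bitmask = np.full((H, W), SETMASK_NODATA, dtype=np.uint32)
    length = np.full((H, W), LENGTH_NODATA, dtype=np.uint8)
    for rows, cols in _tiles(H, W, tile):
        block = raster.data[:, rows, cols]
        valid = _valid_block(block, raster.nodata)
        vals = block[:, valid].astype(float, copy=False)
        if vals.size and (vals.min() < 0.0 or vals.max() > 1.0):
            raise ValueError("valid pixels must have probabilities in [0, 1]")
        member = vals >= t[:, None]  # (C, n_valid)
        bm = bitmask[rows, cols]
        ln = length[rows, cols]
        bm[valid] = encode_bitmask(member.T)
        ln[valid] = member.sum(axis=0).astype(np.uint8)
        bitmask[rows, cols] = bm
        length[rows, cols] = ln
    return SetMaskRaster(
        bitmask=raster.derive(bitmask, int(SETMASK_NODATA), ("set_bitmask",)),
        length=raster.derive(length, int(LENGTH_NODATA), ("set_length",)),
        classes=tuple(calibration.classes),
    )


def class_inclusion_mask(setmask: SetMaskRaster, c, length: str = "any") -> Raster:
    """Binary raster of pixels whose prediction set contains class ``c``.

    ``length`` filters by set length: ``"any"``, ``"singleton"`` (= 1,
    confident pixels) or ``"multi"`` (> 1, pixels where ``c`` co-occurs
    with other candidate classes).  Output: 1/0 uint8, nodata 255.
    """
    if length not in ("any", "singleton", "multi"):
        raise ValueError("length must be 'any', 'singleton' or 'multi'")
    bit = setmask.class_index(c)
    codes = setmask.bitmask.data[0]
    lengths = setmask.length.data[0]
    valid = lengths != LENGTH_NODATA
    hit = ((codes >> np.uint32(bit)) & np.uint32(1)) > 0
    if length == "singleton":
        hit &= lengths == 1
    elif length == "multi":
        hit &= lengths > 1
    out = np.where(valid, hit.astype(np.uint8), LENGTH_NODATA)
    return setmask.length.derive(out, int(LENGTH_NODATA), (f"includes_{c}",))


def regress_raster(
    raster: Raster,
    calibration: RegressionCalibration,
    tile: int = 256,
) -> Raster:
    """Lower/upper/width interval bands from prediction band(s).

    Absolute-residual calibration expects one point-prediction band; CQR
    expects two bands (lower then upper fitted quantile).  Nodata pixels
    become NaN in all three output bands.
    """
    expected = 1 if calibration.method == "absolute_residual" else 2
    if raster.n_bands != expected:
        raise ValueError(
            f"{calibration.method} expects {expected} band(s), raster has "
            f"{raster.n_bands}"
        )
    H, W = raster.shape
    out = np.full((3, H, W), np.nan, dtype=np.float32)
    for rows, cols in _tiles(H, W, tile):
        block = raster.data[:, rows, cols].astype(float, copy=False)
        valid = _valid_block(block, raster.nodata)
        if calibration.method == "absolute_residual":
            lower = block[0] - calibration.qhat
            upper = block[0] + calibration.qhat
        else:
            qlo = np.minimum(block[0], block[1])
            qhi = np.maximum(block[0], block[1])
            lower = qlo - calibration.qhat
            upper = qhi + calibration.qhat
            lower, upper = np.minimum(lower, upper), np.maximum(lower, upper)
        tile_out = out[:, rows, cols]
        tile_out[0][valid] = lower[valid]
        tile_out[1][valid] = upper[valid]
        tile_out[2][valid] = (upper - lower)[valid]
        out[:, rows, cols] = tile_out
    return raster.derive(out, np.nan, ("lower", "upper", "width"))
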