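"""Raster containers, file I/O, the class scheme, and IHS pan-sharpening.

Scenes are held as ``H×W×B`` float arrays of digital numbers (DN) with an
explicit boolean nodata mask; label maps are ``H×W`` integer rasters where 0
is the "unlabeled" sentinel.  Two on-disk formats are supported: multi-page
TIFF (band-interleaved, with a GDAL-style nodata tag) and a dependency-light
whitespace text matrix for single-band data.

Convention: row-major arrays, ``(row, col)`` indexing, 0-based, origin at the
top-left corner.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

__all__ = [
    "MultibandScene",
    "LabelRaster",
    "ClassDef",
    "ClassScheme",
    "default_class_scheme",
    "read_raster",
    "write_raster",
    "read_labels",
    "write_labels",
    "rgb_to_ihs",
    "ihs_to_rgb",
    "ihs_pansharpen",
]

# GDAL's ASCII nodata tag; understood by most geospatial TIFF readers.
_GDAL_NODATA_TAG = 42113

DEFAULT_BAND_NAMES = ("blue", "green", "red", "nir")


@dataclass
class MultibandScene:
    """A multi-band raster of digital numbers.

    Parameters
    ----------
    pixels : ndarray, shape (H, W, B)
        Digital numbers, stored as float64 internally so that incremental
        segment statistics are exact regardless of the file dtype.
    band_names : sequence of str
        Ordered band labels; length must equal B.
    pixel_size_m : float
        Ground resolution of one pixel, in metres.
    nodata_mask : ndarray of bool, shape (H, W)
        True where the pixel carries no data.
    """

    pixels: np.ndarray
    band_names: Sequence[str] = DEFAULT_BAND_NAMES
    pixel_size_m: float = 1.0
    nodata_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim == 2:
            px = px[:, :, np.newaxis]
        if px.ndim != 3:
            raise ValueError(f"pixels must be H×W×B, got shape {px.shape}")
        h, w, b = px.shape
        if h < 1 or w < 1 or b < 1:
            raise ValueError(f"empty raster: shape {px.shape}")
        self.pixels = px
        names = list(self.band_names)[:b] if len(self.band_names) >= b else [
            f"band{i + 1}" for i in range(b)
        ]
        if len(names) != b:
            names = [f"band{i + 1}" for i in range(b)]
        self.band_names = tuple(names)
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros((h, w), dtype=bool)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
            if self.nodata_mask.shape != (h, w):
                raise ValueError("nodata_mask shape does not match pixels")
        valid = ~self.nodata_mask
        if not np.all(np.isfinite(self.pixels[valid])):
            raise ValueError("non-finite pixel values outside the nodata mask")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    @property
    def n_bands(self) -> int:
        return self.pixels.shape[2]

    def band(self, name: str) -> np.ndarray:
        """Return one band as an H×W view, looked up by name."""
        try:
            i = list(self.band_names).index(name)
        except ValueError:
            raise KeyError(f"no band named {name!r}; have {self.band_names}") from None
        return self.pixels[:, :, i]


@dataclass
class ClassDef:
    id: int
    abbreviation: str
    common_name: str
    group: str  # "forest" | "non-forest"


@dataclass
class ClassScheme:
    """Ordered set of thematic classes with contiguous 1-based ids."""

    classes: list[ClassDef]

    def __post_init__(self) -> None:
        ids = [c.id for c in self.classes]
        if ids != list(range(1, len(ids) + 1)):
            raise ValueError(f"class ids must be contiguous from 1, got {ids}")

    def __len__(self) -> int:
        return len(self.classes)

    @property
    def ids(self) -> list[int]:
        return [c.id for c in self.classes]

    @property
    def abbreviations(self) -> list[str]:
        return [c.abbreviation for c in self.classes]

    def __getitem__(self, class_id: int) -> ClassDef:
        return self.classes[class_id - 1]

    @classmethod
    def from_csv(cls, path: str | Path) -> "ClassScheme":
        with open(path, newline="") as fh:
            rows = list(csv.DictReader(fh))
        return cls(
            [
                ClassDef(int(r["id"]), r["abbreviation"], r["common_name"], r["group"])
                for r in rows
            ]
        )

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["id", "abbreviation", "common_name", "group"])
            for c in self.classes:
                w.writerow([c.id, c.abbreviation, c.common_name, c.group])


def default_class_scheme() -> ClassScheme:
    """The 9-class forest cover scheme: seven tree-species stands at the
    species level, grass land, and a pooled non-forest class."""
    ref = resources.files("forestseg.data").joinpath("class_scheme.csv")
    with resources.as_file(ref) as p:
        return ClassScheme.from_csv(p)


@dataclass
class LabelRaster:
    """An H×W integer class-id raster; 0 means unlabeled/nodata.

    ``class_scheme`` may be None for ad-hoc label maps (e.g. classifications
    over a bespoke signature set); label validation then only requires
    non-negative integers.
    """

    labels: np.ndarray
    class_scheme: ClassScheme | None = field(default_factory=default_class_scheme)

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim == 3 and lab.shape[2] == 1:
            lab = lab[:, :, 0]
        if lab.ndim != 2:
            raise ValueError(f"labels must be H×W, got shape {lab.shape}")
        lab = lab.astype(np.int32, copy=False)
        if lab.min() < 0:
            raise ValueError("labels must be non-negative")
        if self.class_scheme is not None:
            valid = set(self.class_scheme.ids) | {0}
            present = set(np.unique(lab).tolist())
            if not present <= valid:
                raise ValueError(
                    f"labels {sorted(present - valid)} not in the class scheme"
                )
        self.labels = lab

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("geotiff", "tiff", "matrix-text"):
            raise ValueError(f"unknown raster format {fmt!r}")
        return "tiff" if fmt in ("geotiff", "tiff") else "matrix-text"
    if path.suffix.lower() in (".tif", ".tiff"):
        return "tiff"
    return "matrix-text"


def read_raster(
    path: str | Path,
    format: str | None = None,
    band_names: Sequence[str] | None = None,
    pixel_size_m: float = 1.0,
) -> MultibandScene:
    """Read a scene from a TIFF or a whitespace text matrix.

    TIFF files may carry a nodata value in the GDAL nodata tag; matching
    cells (or NaNs) become True in the scene's ``nodata_mask``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    fmt = _infer_format(path, format)
    if fmt == "tiff":
        with tifffile.TiffFile(path) as tf:
            arr = tf.asarray()
            nodata = None
            tag = tf.pages[0].tags.get(_GDAL_NODATA_TAG)
            if tag is not None:
                nodata = str(tag.value).strip()
        if arr.ndim == 2:
            arr = arr[:, :, np.newaxis]
        elif arr.ndim == 3 and arr.shape[0] <= 16 and arr.shape[0] < arr.shape[2]:
            # band-first pages -> band-last
            arr = np.moveaxis(arr, 0, 2)
        if arr.shape[2] < 1:
            raise ValueError(f"{path}: raster has no bands")
        arr = arr.astype(np.float64)
        mask = ~np.isfinite(arr).all(axis=2)
        if nodata is not None and nodata.lower() != "nan":
            mask |= (arr == float(nodata)).any(axis=2)
        arr[mask] = 0.0
    else:
        arr = np.loadtxt(path, dtype=np.float64, ndmin=2)[:, :, np.newaxis]
        mask = ~np.isfinite(arr).all(axis=2)
        arr[mask] = 0.0
    names = band_names if band_names is not None else (
        DEFAULT_BAND_NAMES if arr.shape[2] == 4 else [f"band{i+1}" for i in range(arr.shape[2])]
    )
    return MultibandScene(arr, band_names=names, pixel_size_m=pixel_size_m, nodata_mask=mask)


def write_raster(scene: MultibandScene, path: str | Path, format: str | None = None) -> None:
    """Write a scene; NaN marks nodata in TIFF output (declared in the
    GDAL nodata tag), so read_raster(write_raster(x)) == x."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "tiff":
        data = scene.pixels.astype(np.float64).copy()
        extratags = []
        if scene.nodata_mask.any():
            data[scene.nodata_mask] = np.nan
            extratags = [(_GDAL_NODATA_TAG, "s", 0, "nan", True)]
        tifffile.imwrite(path, data, photometric="minisblack", extratags=extratags)
    else:
        if scene.n_bands != 1:
            raise ValueError("matrix-text format supports single-band scenes only")
        np.savetxt(path, scene.pixels[:, :, 0], fmt="%.10g")


def read_labels(path: str | Path, class_scheme: ClassScheme | None = None) -> LabelRaster:
    """Read a 1-band integer raster as a label map (0 = unlabeled)."""
    scene = read_raster(path)
    lab = scene.pixels[:, :, 0].astype(np.int32)
    lab[scene.nodata_mask] = 0
    scheme = class_scheme if class_scheme is not None else default_class_scheme()
    return LabelRaster(lab, scheme)


def write_labels(labels: LabelRaster, path: str | Path) -> None:
    path = Path(path)
    if _infer_format(path, None) == "tiff":
        tifffile.imwrite(path, labels.labels.astype(np.int32), photometric="minisblack")
    else:
        np.savetxt(path, labels.labels, fmt="%d")


# ---------------------------------------------------------------------------
# IHS pan-sharpening
# ---------------------------------------------------------------------------

# Linear intensity/chroma transform used for fusion.  The first row is the
# intensity I=(R+G+B)/3; the two chroma rows span the plane orthogonal to it,
# so hue (chroma angle) and saturation (chroma magnitude) are untouched when
# only I is replaced.
_IHS_FWD = np.array(
    [
        [1.0 / 3.0, 1.0 / 3.0, 1.0 / 3.0],
        [-np.sqrt(2.0) / 6.0, -np.sqrt(2.0) / 6.0, 2.0 * np.sqrt(2.0) / 6.0],
        [1.0 / np.sqrt(2.0), -1.0 / np.sqrt(2.0), 0.0],
    ]
)
_IHS_INV = np.linalg.inv(_IHS_FWD)


def rgb_to_ihs(rgb: np.ndarray) -> np.ndarray:
    """Map an ...×3 array of (R, G, B) to (I, v1, v2).

    Hue is ``atan2(v2, v1)`` and saturation ``hypot(v1, v2)``; they are kept
    as Cartesian chroma components so the inverse is a single matrix multiply.
    """
    return np.asarray(rgb, dtype=np.float64) @ _IHS_FWD.T


def ihs_to_rgb(ihs: np.ndarray) -> np.ndarray:
    """Exact inverse of :func:`rgb_to_ihs`."""
    return np.asarray(ihs, dtype=np.float64) @ _IHS_INV.T


def ihs_pansharpen(rgb: MultibandScene, pan: MultibandScene) -> MultibandScene:
    """Fuse a coarse 3-band RGB scene with a fine panchromatic band.

    The RGB scene is upsampled (nearest neighbour) to the pan grid, converted
    to IHS, its intensity channel replaced by the pan band, and converted
    back.  Hue and saturation of the upsampled RGB are preserved exactly.
    """
    if rgb.n_bands != 3:
        raise ValueError(f"rgb scene must have 3 bands, got {rgb.n_bands}")
    if pan.n_bands != 1:
        raise ValueError(f"pan scene must have 1 band, got {pan.n_bands}")
    (hr, wr), (hp, wp) = rgb.shape, pan.shape
    if hp % hr or wp % wr:
        raise ValueError(
            f"pan dimensions {hp}×{wp} are not an integer multiple of rgb {hr}×{wr}"
        )
    fy, fx = hp // hr, wp // wr
    up = np.repeat(np.repeat(rgb.pixels, fy, axis=0), fx, axis=1)
    ihs = rgb_to_ihs(up)
    ihs[:, :, 0] = pan.pixels[:, :, 0]
    out = ihs_to_rgb(ihs)
    mask = np.repeat(np.repeat(rgb.nodata_mask, fy, axis=0), fx, axis=1) | pan.nodata_mask
    out[mask] = 0.0
    return MultibandScene(
        out,
        band_names=rgb.band_names,
        pixel_size_m=pan.pixel_size_m,
        nodata_mask=mask,
    )
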