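"""Multi-band reflectance rasters.

A :class:`BandStack` is the unit every pipeline stage consumes: six named
2-D reflectance planes (blue, green, red, red_edge, nir, thermal) sharing a
single nodata mask and an affine georeferencing transform.  Reflectance is
unitless in [0, 1]; the thermal plane is in arbitrary calibrated units and
never enters a spectral index.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import tifffile

#: Canonical band order of the multispectral + thermal stack.
BAND_ORDER = ("blue", "green", "red", "red_edge", "nir", "thermal")

#: Identity affine transform (a, b, c, d, e, f):
#: x = a*col + b*row + c,  y = d*col + e*row + f.
IDENTITY_TRANSFORM = (1.0, 0.0, 0.0, 0.0, 1.0, 0.0)


class BandError(KeyError):
    """A required band is missing from a stack."""


@dataclass
class BandStack:
    """Named reflectance planes with a shared nodata mask.

    Parameters
    ----------
    bands
        Mapping band name -> 2-D float plane.  Must contain exactly the
        names in :data:`BAND_ORDER`.
    nodata_mask
        Boolean plane, ``True`` where the pixel is invalid.
    transform
        Affine transform ``(a, b, c, d, e, f)`` mapping (col, row) pixel
        coordinates to world coordinates.
    """

    bands: dict[str, np.ndarray]
    nodata_mask: np.ndarray = None
    transform: tuple[float, ...] = IDENTITY_TRANSFORM
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = set(self.bands)
        if names != set(BAND_ORDER):
            missing = set(BAND_ORDER) - names
            extra = names - set(BAND_ORDER)
            raise BandError(
                f"band names must be exactly {set(BAND_ORDER)}; "
                f"missing={sorted(missing)} unexpected={sorted(extra)}"
            )
        # enforce canonical ordering and float dtype
        self.bands = {n: np.asarray(self.bands[n], dtype=np.float64) for n in BAND_ORDER}
        shapes = {b.shape for b in self.bands.values()}
        if len(shapes) != 1:
            raise ValueError(f"band planes disagree in shape: {shapes}")
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.shape, dtype=bool)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.nodata_mask.shape != self.shape:
            raise ValueError(
                f"nodata mask shape {self.nodata_mask.shape} != band shape {self.shape}"
            )
        self.transform = tuple(float(v) for v in self.transform)

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.bands.values())).shape

    @property
    def height(self) -> int:
        return self.shape[0]

    @property
    def width(self) -> int:
        return self.shape[1]

    def band(self, name: str) -> np.ndarray:
        try:
            return self.bands[name]
        except KeyError:
            raise BandError(f"stack has no band {name!r}; bands are {list(self.bands)}")

    def as_array(self) -> np.ndarray:
        """Stack bands into a (6, H, W) array in canonical order."""
        return np.stack([self.bands[n] for n in BAND_ORDER])

    @classmethod
    def from_array(
        cls,
        arr: np.ndarray,
        nodata_mask: np.ndarray | None = None,
        transform: tuple[float, ...] = IDENTITY_TRANSFORM,
        scale: float | None = None,
    ) -> "BandStack":
        """Build a stack from a (6, H, W) array in canonical band order.

        ``scale`` divides integer digital numbers into [0, 1] reflectance
        (e.g. 65535 for uint16 imagery); reflectance bands only — the
        thermal plane is passed through unscaled.
        """
        arr = np.asarray(arr, dtype=np.float64)
        if arr.ndim != 3 or arr.shape[0] != len(BAND_ORDER):
            raise ValueError(f"expected ({len(BAND_ORDER)}, H, W) array, got {arr.shape}")
        if scale is not None:
            arr = arr.copy()
            arr[:5] /= float(scale)
        bands = {n: arr[i] for i, n in enumerate(BAND_ORDER)}
        return cls(bands=bands, nodata_mask=nodata_mask, transform=transform)


def extract_roi(stack: BandStack, window: tuple[int, int, int, int]) -> BandStack:
    """Crop a stack to a pixel window ``(row, col, height, width)``.

    All bands and the nodata mask are cropped identically and the affine
    transform is shifted so that cropped pixel (0, 0) maps to the same
    world coordinate as source pixel (row, col).
    """
    r, c, h, w = (int(v) for v in window)
    if h <= 0 or w <= 0:
        raise ValueError(f"window has non-positive size: {window}")
    if r < 0 or c < 0 or r + h > stack.height or c + w > stack.width:
        raise ValueError(
            f"window {window} exceeds raster bounds {stack.height}x{stack.width}"
        )
    a, b, c0, d, e, f = stack.transform
    new_transform = (a, b, a * c + b * r + c0, d, e, d * c + e * r + f)
    return BandStack(
        bands={n: p[r : r + h, c : c + w].copy() for n, p in stack.bands.items()},
        nodata_mask=stack.nodata_mask[r : r + h, c : c + w].copy(),
        transform=new_transform,
        meta=dict(stack.meta),
    )


# ---------------------------------------------------------------------------
# TIFF input/output.  Band names and the affine transform travel in the
# ImageDescription tag as JSON; a sidecar YAML with a band-order list is
# also accepted on read.
# ---------------------------------------------------------------------------

_NODATA_FILL = -9999.0


def write_stack(path, stack: BandStack) -> None:
    """Write a stack as a 6-band float TIFF with JSON metadata.

    Planes are stored at full float64 precision so an export -> ingest
    round trip is bit-exact.
    """
    arr = stack.as_array().astype(np.float64)
    arr[:, stack.nodata_mask] = _NODATA_FILL
    desc = json.dumps(
        {
            "bands": list(BAND_ORDER),
            "transform": list(stack.transform),
            "nodata": _NODATA_FILL,
        }
    )
    tifffile.imwrite(str(path), arr, description=desc)


def read_stack(path, band_names=None, transform=None) -> BandStack:
    """Read a multi-band TIFF written by :func:`write_stack`.

    ``band_names`` overrides the embedded band order (e.g. loaded from a
    sidecar YAML mapping) for stacks produced by other software.
    """
    with tifffile.TiffFile(str(path)) as tif:
        arr = tif.asarray().astype(np.float64)
        desc = tif.pages[0].description or ""
    meta = {}
    if desc:
        try:
            meta = json.loads(desc)
        except json.JSONDecodeError:
            meta = {}
    names = list(band_names or meta.get("bands", BAND_ORDER))
    if arr.ndim == 2:
        arr = arr[None]
    if arr.shape[0] != len(names) and arr.shape[-1] == len(names):
        arr = np.moveaxis(arr, -1, 0)
    nodata_val = meta.get("nodata", _NODATA_FILL)
    mask = np.any(arr == nodata_val, axis=0)
    arr = np.where(arr == nodata_val, 0.0, arr)
    tfm = tuple(transform or meta.get("transform", IDENTITY_TRANSFORM))
    bands = {n: arr[i] for i, n in enumerate(names)}
    return BandStack(bands=bands, nodata_mask=mask, transform=tfm)


def write_class_raster(path, labels: np.ndarray, transform=IDENTITY_TRANSFORM) -> None:
    """Write a hard-label class raster as a single-band uint8 TIFF."""
    desc = json.dumps({"transform": list(transform), "kind": "class_labels"})
    tifffile.imwrite(str(path), np.asarray(labels, dtype=np.uint8), description=desc)


def read_class_raster(path) -> np.ndarray:
    return tifffile.imread(str(path)).astype(np.int64)
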