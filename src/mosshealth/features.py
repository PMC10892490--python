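"""Per-pixel feature cubes: raw bands + spectral indices + texture planes.

A :class:`FeatureCube` is an ordered set of named 2-D feature planes
aligned to a source :class:`~mosshealth.bands.BandStack`.  The feature
order is recorded and stable between training and prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bands import BandStack, BAND_ORDER
from .spectral import compute_all_indices, INDEX_NAMES, MODEL8
from .texture import compute_window_stats, STAT_NAMES

__all__ = ["FeatureSpec", "FeatureCube", "build_feature_cube", "DEFAULT_SPEC"]


@dataclass(frozen=True)
class FeatureSpec:
    """Declarative description of which feature planes to compute.

    ``indices`` may contain the preset name ``"model8"`` or any of the 21
    index identifiers; ``stats_bands`` lists the raw bands whose windowed
    mean/variance/skewness/kurtosis enter the cube; ``stats_window`` is the
    odd window side length in pixels.
    """

    bands: tuple[str, ...] = BAND_ORDER
    indices: tuple[str, ...] = ("model8",)
    stats_bands: tuple[str, ...] = BAND_ORDER
    stats_window: int = 5
    arvi_as_printed: bool = False

    def to_dict(self) -> dict:
        return {
            "bands": list(self.bands),
            "indices": list(self.indices),
            "stats_bands": list(self.stats_bands),
            "stats_window": self.stats_window,
            "arvi_as_printed": self.arvi_as_printed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureSpec":
        return cls(
            bands=tuple(d.get("bands", BAND_ORDER)),
            indices=tuple(d.get("indices", ("model8",))),
            stats_bands=tuple(d.get("stats_bands", BAND_ORDER)),
            stats_window=int(d.get("stats_window", 5)),
            arvi_as_printed=bool(d.get("arvi_as_printed", False)),
        )


#: Default stage-1 feature set: 6 raw bands, the eight-index preset, and
#: the four windowed statistics of every raw band (38 planes).
DEFAULT_SPEC = FeatureSpec()


@dataclass
class FeatureCube:
    """Ordered named feature planes with a shared validity mask."""

    names: list[str]
    planes: np.ndarray  # (F, H, W)
    nodata_mask: np.ndarray  # (H, W); True where any feature is invalid
    spec: FeatureSpec | None = field(default=None, repr=False)

    @property
    def shape(self) -> tuple[int, int]:
        return self.planes.shape[1:]

    def plane(self, name: str) -> np.ndarray:
        try:
            return self.planes[self.names.index(name)]
        except ValueError:
            raise KeyError(f"no feature {name!r}; cube holds {self.names}")


def build_feature_cube(stack: BandStack, spec: FeatureSpec = DEFAULT_SPEC) -> FeatureCube:
    """Compute every feature plane the spec requests, in a stable order."""
    for b in spec.bands:
        if b not in BAND_ORDER:
            raise KeyError(f"unknown band {b!r} in feature spec")
    for b in spec.stats_bands:
        if b not in BAND_ORDER:
            raise KeyError(f"unknown stats band {b!r} in feature spec")
    for ix in spec.indices:
        if ix != "model8" and ix not in INDEX_NAMES:
            raise KeyError(f"unknown index {ix!r} in feature spec")

    names: list[str] = []
    planes: list[np.ndarray] = []
    mask = stack.nodata_mask.copy()

    for b in spec.bands:
        names.append(b)
        planes.append(stack.bands[b])

    if spec.indices:
        for ip in compute_all_indices(
            stack, subset=list(spec.indices), arvi_as_printed=spec.arvi_as_printed
        ):
            names.append(ip.name)
            planes.append(ip.values)
            mask |= ip.nodata_mask

    for b in spec.stats_bands:
        ws = compute_window_stats(
            stack.bands[b], spec.stats_window, nodata_mask=stack.nodata_mask, source=b
        )
        for stat in STAT_NAMES:
            names.append(f"{b}_{stat}")
            planes.append(ws.plane(stat))
        mask |= ws.nodata_mask

    return FeatureCube(
        names=names,
        planes=np.stack(planes).astype(np.float64),
        nodata_mask=mask,
        spec=spec,
    )
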