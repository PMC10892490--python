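"""Synthetic multispectral scene generation.

Emulates the statistical structure the mapping workflow assumes: a
five-class landscape (healthy moss, stressed moss, moribund moss, lichen,
non-vegetated ground) of spatially coherent patches, with class-dependent
six-band reflectance signatures and additive Gaussian noise.  Class
signatures follow the field's qualitative spectral ordering for moss
degradation: healthy moss is green with a strong NIR plateau, stressed
moss shows elevated red (carotenoids), moribund moss is grey with low,
flat reflectance, lichen carries a strong red-edge contrast, and bare
ground is spectrally flat and bright.  NDVI of the class means therefore
decreases healthy > stressed > moribund > non-vegetated by construction.

Sparse training labels emulate manually digitized polygons: axis-aligned
rectangles rejection-sampled to lie within a single ground-truth class, so
that the exported GeoJSON rasterizes exactly to the exported sparse mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml
from scipy.ndimage import gaussian_filter
from shapely.geometry import box

from .bands import BandStack, BAND_ORDER, write_stack, write_class_raster
from .labels import DEFAULT_SCHEME, write_geojson

__all__ = ["SceneSpec", "SyntheticScene", "default_spec", "generate", "export"]

# class order: healthy, stressed, moribund, lichen, non_vegetation
_SIGNATURES = np.array(
    [
        # blue   green  red    red_edge nir    thermal
        [0.040, 0.180, 0.060, 0.300, 0.550, 0.500],  # healthy moss
        [0.060, 0.120, 0.220, 0.280, 0.350, 0.500],  # stressed moss
        [0.100, 0.120, 0.130, 0.150, 0.180, 0.500],  # moribund moss
        [0.080, 0.120, 0.140, 0.380, 0.280, 0.500],  # lichen
        [0.300, 0.320, 0.340, 0.350, 0.360, 0.500],  # non-vegetated
    ]
)

_PRIORS = (0.10, 0.20, 0.25, 0.20, 0.25)

_NOISE_SD = {"easy": 0.02, "moderate": 0.05, "hard": 0.10}


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic scene."""

    height: int = 256
    width: int = 256
    class_means: tuple = tuple(map(tuple, _SIGNATURES))
    noise_sd: float = 0.02
    noise_correlation: float = 0.0  # spatial correlation length of the noise, px
    correlation_length: float = 8.0  # patch-structure smoothing scale, px
    priors: tuple = _PRIORS
    labeled_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self):
        means = np.asarray(self.class_means, dtype=float)
        if means.shape != (5, 6):
            raise ValueError(f"class_means must be 5x6; got {means.shape}")
        if np.any(means[:, :5] < 0) or np.any(means[:, :5] > 1):
            raise ValueError("reflectance class means must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if abs(sum(self.priors) - 1.0) > 1e-9:
            raise ValueError(f"priors must sum to 1; got {self.priors}")
        if not 0 < self.labeled_fraction <= 1:
            raise ValueError("labeled_fraction must be in (0, 1]")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["class_means"] = [[float(v) for v in row] for row in self.class_means]
        d["priors"] = [float(p) for p in self.priors]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SceneSpec":
        d = dict(d)
        d["class_means"] = tuple(tuple(r) for r in d["class_means"])
        d["priors"] = tuple(d["priors"])
        return cls(**d)


@dataclass
class SyntheticScene:
    stack: BandStack
    truth: np.ndarray  # dense class raster, IDs 1..5
    sparse_labels: np.ndarray  # training view, 0 = unlabeled
    polygons: list = field(default_factory=list)  # (shapely box, class name)
    spec: SceneSpec = None


def default_spec(
    difficulty: str = "easy",
    height: int = 256,
    width: int = 256,
    seed: int = 0,
    labeled_fraction: float = 0.3,
) -> SceneSpec:
    """Scene presets graded by class separability.

    ``easy`` separates class means by at least 5 noise SDs in some band,
    ``moderate`` by ~2, ``hard`` by ~1 (overlapping signatures).  All
    difficulties share identical class priors and signatures; only the
    noise level changes.
    """
    if difficulty not in _NOISE_SD:
        raise ValueError(f"difficulty must be one of {sorted(_NOISE_SD)}")
    return SceneSpec(
        height=height,
        width=width,
        noise_sd=_NOISE_SD[difficulty],
        seed=seed,
        labeled_fraction=labeled_fraction,
    )


def _class_map(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    """Spatially coherent class map: smoothed white noise thresholded at
    the quantiles of the class priors."""
    f = gaussian_filter(
        rng.standard_normal((spec.height, spec.width)), sigma=spec.correlation_length
    )
    qs = np.cumsum(spec.priors)[:-1]
    thresholds = np.quantile(f, qs)
    return (np.searchsorted(thresholds, f, side="right") + 1).astype(np.int64)


def _sparse_rectangles(
    truth: np.ndarray, target_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, list]:
    """Rejection-sample single-class rectangles until the labeled fraction
    is reached (or the attempt budget runs out)."""
    h, w = truth.shape
    labels = np.zeros_like(truth)
    polys = []
    target = int(target_fraction * truth.size)
    attempts = 0
    max_attempts = 20000
    while labels.astype(bool).sum() < target and attempts < max_attempts:
        attempts += 1
        rh = int(rng.integers(4, 13))
        rw = int(rng.integers(4, 13))
        r = int(rng.integers(0, h - rh + 1))
        c = int(rng.integers(0, w - rw + 1))
        block = truth[r : r + rh, c : c + rw]
        if not np.all(block == block.flat[0]):
            continue
        cid = int(block.flat[0])
        labels[r : r + rh, c : c + rw] = cid
        # pixel coordinates, identity transform: x = col, y = row
        polys.append((box(c, r, c + rw, r + rh), DEFAULT_SCHEME.name_of(cid)))
    return labels, polys


def generate(spec: SceneSpec) -> SyntheticScene:
    """Draw a fully seeded synthetic scene from its spec."""
    ss = np.random.SeedSequence(spec.seed)
    map_rng, noise_rng, label_rng = (np.random.default_rng(s) for s in ss.spawn(3))

    truth = _class_map(spec, map_rng)
    counts = np.bincount(truth.ravel(), minlength=6)[1:]
    if (counts == 0).any():
        empty = [i + 1 for i in range(5) if counts[i] == 0]
        raise ValueError(
            f"priors infeasible at {spec.height}x{spec.width}: classes {empty} "
            f"received no pixels"
        )

    means = np.asarray(spec.class_means)  # (5, 6)
    arr = means[truth - 1].transpose(2, 0, 1).copy()  # (6, H, W)
    if spec.noise_sd > 0:
        noise = noise_rng.standard_normal(arr.shape)
        if spec.noise_correlation > 0:
            noise = gaussian_filter(
                noise, sigma=(0, spec.noise_correlation, spec.noise_correlation)
            )
            noise /= noise.std(axis=(1, 2), keepdims=True)
        arr += spec.noise_sd * noise
    arr[:5] = np.clip(arr[:5], 0.0, 1.0)

    sparse, polys = _sparse_rectangles(truth, spec.labeled_fraction, label_rng)
    stack = BandStack.from_array(arr)
    return SyntheticScene(
        stack=stack, truth=truth, sparse_labels=sparse, polygons=polys, spec=spec
    )


def export(scene: SyntheticScene, out_dir) -> dict[str, Path]:
    """Write the on-disk contract the pipeline ingests.

    Produces ``stack.tif`` (6 bands, names in tags), ``truth.tif``,
    ``labels.tif`` (sparse training mask), ``labels.geojson`` (the
    rectangles as polygons with a ``class`` property) and ``spec.yaml``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "stack": out / "stack.tif",
        "truth": out / "truth.tif",
        "labels": out / "labels.tif",
        "polygons": out / "labels.geojson",
        "spec": out / "spec.yaml",
    }
    try:
        write_stack(paths["stack"], scene.stack)
        write_class_raster(paths["truth"], scene.truth, transform=scene.stack.transform)
        write_class_raster(paths["labels"], scene.sparse_labels, transform=scene.stack.transform)
        write_geojson(paths["polygons"], scene.polygons)
        with open(paths["spec"], "w") as fh:
            yaml.safe_dump(scene.spec.to_dict(), fh)
    except OSError as e:
        raise OSError(f"failed to export scene to {out}: {e}") from e
    return paths
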