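"""mosshealth: drone-multispectral moss and lichen health mapping.

A reusable implementation of a two-stage vegetation-health segmentation
workflow for multispectral UAV imagery: spectral-index and texture
feature extraction, a gradient-boosted-tree pixel classifier, an
encoder-decoder CNN segmenter, and the stacked ensemble in which stage-1
class probabilities become extra CNN input channels.
"""

from .bands import BandStack, BAND_ORDER, extract_roi, read_stack, write_stack
from .spectral import (
    INDEX_NAMES,
    MODEL8,
    IndexPlane,
    compute_index,
    compute_all_indices,
)
from .texture import WindowStats, compute_window_stats
from .features import FeatureSpec, FeatureCube, build_feature_cube
from .correlation import CorrelationReport, correlate_with_health
from .tiling import TileGrid, make_grid, stitch
from .labels import ClassScheme, DEFAULT_SCHEME, rasterize_labels
from .gbm import GbmConfig, GbmModel, build_feature_table, train_gbm, predict_gbm
from .unet import CnnConfig, UNet, build_network, make_patches, train_cnn, run_method
from .evaluation import confusion, metrics, evaluate, kfold, area_report
from .synthetic import SceneSpec, default_spec, generate
from .pipeline import RunConfig, run_pipeline

__version__ = "0.1.0"
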