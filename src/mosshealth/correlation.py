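"""Correlation screening of features against the moss-health gradient.

Moss health is a categorical state (Healthy, Stressed, Moribund) observed
along a degradation sequence; for correlation screening it is encoded
ordinally along that gradient (Healthy=1, Stressed=2, Moribund=3) and each
feature plane is correlated (Pearson) against the encoding over moss pixels
only.  The report records the encoding used, the feature-vs-health vector
and the feature-pair correlation matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import FeatureCube

__all__ = ["CorrelationReport", "correlate_with_health", "HEALTH_ENCODING"]

#: Ordinal encoding of moss health along the degradation gradient.
HEALTH_ENCODING = {"healthy_moss": 1, "stressed_moss": 2, "moribund_moss": 3}

_MOSS_IDS = (1, 2, 3)


@dataclass
class CorrelationReport:
    feature_names: list[str]
    health_correlation: np.ndarray  # (F,) Pearson r vs ordinal health
    feature_matrix: np.ndarray  # (F, F) pairwise Pearson
    encoding: dict = field(default_factory=lambda: dict(HEALTH_ENCODING))
    degenerate: np.ndarray = None  # (F,) True where the feature had zero variance
    n_pixels: int = 0


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def correlate_with_health(features: FeatureCube, labels: np.ndarray) -> CorrelationReport:
    """Pearson correlation of each feature against ordinal moss health.

    ``labels`` is a hard class raster; only moss pixels (IDs 1-3) enter the
    analysis.  Zero-variance features are reported with r = 0 and flagged
    degenerate rather than NaN.
    """
    labels = np.asarray(labels)
    if labels.shape != features.shape:
        raise ValueError(f"labels {labels.shape} misaligned with features {features.shape}")
    moss = np.isin(labels, _MOSS_IDS) & ~features.nodata_mask
    if not moss.any():
        raise ValueError("no valid moss pixels (classes 1-3) to correlate against")

    health = labels[moss].astype(np.float64)
    rows = features.planes[:, moss]  # (F, n)
    f = rows.shape[0]

    degenerate = rows.std(axis=1) == 0
    r_health = np.zeros(f)
    for i in range(f):
        if not degenerate[i]:
            r_health[i] = _pearson(rows[i], health)

    matrix = np.eye(f)
    for i in range(f):
        for j in range(i + 1, f):
            if degenerate[i] or degenerate[j]:
                r = 0.0
            else:
                r = _pearson(rows[i], rows[j])
            matrix[i, j] = matrix[j, i] = r

    return CorrelationReport(
        feature_names=list(features.names),
        health_correlation=r_health,
        feature_matrix=matrix,
        degenerate=degenerate,
        n_pixels=int(moss.sum()),
    )
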