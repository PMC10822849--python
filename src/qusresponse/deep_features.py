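"""Frozen convolutional feature extraction from parametric-map images.

One 224 x 224 map image goes through a frozen convolutional backbone whose
final feature-extraction layer emits a 7 x 7 x 2048 activation map, flattened
row-major (row, column, channel) to a length-100,352 vector.  Vectors from
all image planes of a tumour are averaged element-wise into one feature
vector per patient and parameter.

The backbone is injected behind a small interface so any network with the
7 x 7 x 2048 output contract can be used.  The default,
:class:`RandomConvBackbone`, is a two-stage strided convolutional network
with fixed, seeded He-initialised weights and ReLU activations — a frozen
random-projection CNN.  Untrained random convolutional features are a
well-studied, surprisingly strong representation; here they additionally
keep the whole pipeline deterministic and dependency-light.  Weights are
frozen at construction and never updated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol

import numpy as np

from .errors import ValidationError
from .parametric_maps import MapImage

__all__ = [
    "FEATURE_LENGTH",
    "FeatureVector",
    "Backbone",
    "RandomConvBackbone",
    "extract_features",
    "extract_features_batch",
    "average_tumor_features",
]

#: 7 * 7 * 2048 — the backbone output contract.
FEATURE_LENGTH = 7 * 7 * 2048


@dataclass
class FeatureVector:
    values: np.ndarray  # (100352,) float32
    provenance: dict = field(default_factory=dict)
    n_slices_averaged: int = 1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != (FEATURE_LENGTH,):
            raise ValidationError(
                f"feature vector must have length {FEATURE_LENGTH}, got {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("feature vector must be finite")


class Backbone(Protocol):
    """Anything that maps a (224, 224, 3) array to a (7, 7, 2048) array."""

    def forward(self, image: np.ndarray) -> np.ndarray: ...


def _patches(x: np.ndarray, size: int) -> np.ndarray:
    """Non-overlapping ``size x size`` patches -> (n, n, size*size*channels)."""
    h, w, c = x.shape
    n = h // size
    x = x.reshape(n, size, n, size, c).transpose(0, 2, 1, 3, 4)
    return x.reshape(n, n, size * size * c)


class RandomConvBackbone:
    """Frozen two-stage strided CNN with seeded random weights.

    Stage 1: 8x8/stride-8 convolution, 3 -> 64 channels, ReLU (224 -> 28).
    Stage 2: 4x4/stride-4 convolution, 64 -> 2048 channels, ReLU (28 -> 7).
    Non-overlapping strides make each stage an exact patch-wise linear map.
    Weights are He-initialised from ``numpy.random.default_rng(seed)`` at
    construction, stored in float32 and never modified, so inference is
    bit-reproducible across processes.
    """

    output_shape = (7, 7, 2048)

    def __init__(self, seed: int = 20240129):
        rng = np.random.default_rng(seed)
        fan1 = 8 * 8 * 3
        fan2 = 4 * 4 * 64
        self.w1 = (rng.standard_normal((fan1, 64)) * np.sqrt(2.0 / fan1)).astype(np.float32)
        self.b1 = np.zeros(64, dtype=np.float32)
        self.w2 = (rng.standard_normal((fan2, 2048)) * np.sqrt(2.0 / fan2)).astype(np.float32)
        self.b2 = np.zeros(2048, dtype=np.float32)

    def forward(self, image: np.ndarray) -> np.ndarray:
        if image.shape != (224, 224, 3):
            raise ValidationError(f"backbone expects (224, 224, 3), got {image.shape}")
        x = image.astype(np.float32)
        h1 = np.maximum(_patches(x, 8) @ self.w1 + self.b1, 0.0)  # (28, 28, 64)
        h2 = np.maximum(_patches(h1, 4) @ self.w2 + self.b2, 0.0)  # (7, 7, 2048)
        return h2


def _preprocess(image: MapImage | np.ndarray) -> np.ndarray:
    """Replicate to 3 channels if needed and scale [0, 1] -> [-1, 1]."""
    if isinstance(image, MapImage):
        arr = image.to_3channel()
    else:
        arr = np.asarray(image, dtype=float)
        if arr.shape == (224, 224):
            arr = np.repeat(arr[:, :, None], 3, axis=2)
    if arr.shape != (224, 224, 3):
        raise ValidationError(f"expected a 224x224(x3) image, got {arr.shape}")
    return arr * 2.0 - 1.0


def extract_features(image: MapImage | np.ndarray, backbone: Backbone) -> FeatureVector:
    """Forward pass through the frozen backbone, flattened to 100,352 values.

    The canonical [-1, 1] input scaling is applied here; flattening is C-order
    over (row, column, channel), which downstream feature indices rely on.
    """
    activ = backbone.forward(_preprocess(image))
    if activ.shape != (7, 7, 2048):
        raise ValidationError(f"backbone returned {activ.shape}, expected (7, 7, 2048)")
    prov = dict(image.provenance) if isinstance(image, MapImage) else {}
    return FeatureVector(values=np.ascontiguousarray(activ, dtype=np.float32).reshape(-1), provenance=prov)


def extract_features_batch(images: list, backbone: Backbone) -> np.ndarray:
    """Vectorised extraction for many images -> (n, 100352) float32 matrix."""
    if isinstance(backbone, RandomConvBackbone) and images:
        batch = np.stack([_preprocess(im) for im in images]).astype(np.float32)
        n = batch.shape[0]
        p1 = batch.reshape(n, 28, 8, 28, 8, 3).transpose(0, 1, 3, 2, 4, 5).reshape(n, 28, 28, 192)
        h1 = np.maximum(p1 @ backbone.w1 + backbone.b1, 0.0)
        p2 = h1.reshape(n, 7, 4, 7, 4, 64).transpose(0, 1, 3, 2, 4, 5).reshape(n, 7, 7, 1024)
        h2 = np.maximum(p2 @ backbone.w2 + backbone.b2, 0.0)
        return np.ascontiguousarray(h2).reshape(n, FEATURE_LENGTH)
    return np.stack([extract_features(im, backbone).values for im in images])


def average_tumor_features(vectors: list[FeatureVector]) -> FeatureVector:
    """Element-wise mean of the per-slice vectors of one tumour."""
    if not vectors:
        raise ValidationError("cannot average an empty list of feature vectors")
    mat = np.stack([v.values for v in vectors])
    prov = dict(vectors[0].provenance)
    return FeatureVector(
        values=mat.mean(axis=0, dtype=np.float64).astype(mat.dtype),
        provenance=prov,
        n_slices_averaged=len(vectors),
    )
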