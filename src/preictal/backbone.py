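"""Image-backbone feature extraction for normalized epoch features.

The two per-epoch feature matrices (band profile, correlation map) are
composed into a single 3-channel image — band profile resampled into the
top block, correlation map into the bottom block — and pushed through a
registered image backbone; the backbone's pooled penultimate activations
are the epoch's fixed-length deep feature vector.

Backbones are pluggable via a string-keyed registry:

* ``"mini-cnn"`` (default) — a deterministic, seeded 4-layer convolutional
  network with global average pooling and a 128-d read-out, implemented in
  NumPy.  Weights are random but fixed, in the spirit of random-projection
  features: they are untrained and serve as a reproducible, dependency-free
  extractor for testing and synthetic experiments.
* ``"tiny-cnn"`` — a deliberately weaker 2-layer/32-d variant, used as the
  backbone-swap ablation arm.
* ``"efficientnet-b0"`` — the pretrained EfficientNet-B0 penultimate pooled
  layer (1280-d), available when ``torch`` and ``timm`` plus the pretrained
  weights are installed; used frozen, never fine-tuned by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from skimage.transform import resize

from .features import BandProfile, CorrelationMap

__all__ = [
    "FeatureImage",
    "DeepFeatureVector",
    "compose_image",
    "extract_features",
    "register_backbone",
    "get_backbone",
    "list_backbones",
]


@dataclass
class FeatureImage:
    """An H x W x 3 image in [0, 1] assembled from one epoch's features."""

    pixels: np.ndarray
    provenance: dict = field(default_factory=dict)


@dataclass
class DeepFeatureVector:
    values: np.ndarray
    backbone_id: str
    layer_id: str


def compose_image(
    band: BandProfile,
    corr: CorrelationMap,
    size: tuple[int, int] = (224, 224),
) -> FeatureImage:
    """Assemble the two normalized feature matrices into one image.

    Deterministic layout: the band profile is bilinearly resampled into the
    top half, the correlation map into the bottom half; the stack is
    min-max scaled to [0, 1] per image and replicated across 3 channels.
    A constant stack (e.g. a perfectly baseline-like epoch where both
    inputs are all ones) maps to an all-zero image.
    """
    h, w = size
    for name, arr in (("band profile", band.values), ("correlation map", corr.values)):
        bad = np.argwhere(~np.isfinite(arr))
        if len(bad):
            cells = ", ".join(str(tuple(int(i) for i in cell)) for cell in bad[:5])
            raise ValueError(f"non-finite values in {name} at cells {cells}")
    top = resize(
        band.values.astype(np.float64), (h // 2, w),
        order=1, mode="edge", anti_aliasing=False, preserve_range=True,
    )
    bottom = resize(
        corr.values.astype(np.float64), (h - h // 2, w),
        order=1, mode="edge", anti_aliasing=False, preserve_range=True,
    )
    stack = np.vstack([top, bottom])
    lo, hi = stack.min(), stack.max()
    if hi - lo < 1e-12:
        stack = np.zeros_like(stack)
    else:
        stack = (stack - lo) / (hi - lo)
    pixels = np.repeat(stack[:, :, None], 3, axis=2).astype(np.float32)
    return FeatureImage(
        pixels=pixels,
        provenance={
            "layout": "band-top/corr-bottom",
            "band_shape": tuple(band.values.shape),
            "corr_shape": tuple(corr.values.shape),
        },
    )


# --------------------------------------------------------------------------
# Backbone registry


class _NumpyConvBackbone:
    """Seeded random-weight CNN: stride-2 3x3 convs, ReLU, pooled read-out.

    Untrained random convolutional features; deterministic for a fixed seed
    and fully reproducible offline.  The final activations are averaged over
    a ``pool_grid`` x ``pool_grid`` spatial grid (1 = global average
    pooling) before a random linear read-out, so regional structure in the
    feature image survives pooling.
    """

    layer_id = "grid-pool-dense"

    def __init__(
        self,
        backbone_id: str,
        channel_plan: tuple[int, ...],
        n_features: int,
        seed: int,
        input_hw: tuple[int, int] = (224, 224),
        pool_grid: int = 4,
    ):
        self.backbone_id = backbone_id
        self.n_features = n_features
        self.input_hw = input_hw
        self.pool_grid = pool_grid
        rng = np.random.default_rng(seed)
        self.kernels = []
        c_in = 3
        for c_out in channel_plan:
            fan_in = 9 * c_in
            w = rng.standard_normal((3, 3, c_in, c_out)) * np.sqrt(2.0 / fan_in)
            b = np.zeros(c_out)
            self.kernels.append((w.astype(np.float32), b.astype(np.float32)))
            c_in = c_out
        pooled_dim = c_in * pool_grid * pool_grid
        self.readout_w = (
            rng.standard_normal((pooled_dim, n_features)) * np.sqrt(1.0 / pooled_dim)
        ).astype(np.float32)
        self.readout_b = np.zeros(n_features, dtype=np.float32)

    @staticmethod
    def _conv_s2(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
        xp = np.pad(x, ((1, 1), (1, 1), (0, 0)))
        win = sliding_window_view(xp, (3, 3, x.shape[2]))[::2, ::2, 0]
        out = np.tensordot(win, w, axes=([2, 3, 4], [0, 1, 2])) + b
        return np.maximum(out, 0.0)

    def forward(self, pixels: np.ndarray) -> np.ndarray:
        if pixels.shape[:2] != self.input_hw:
            raise ValueError(
                f"{self.backbone_id} expects {self.input_hw} input, "
                f"got {pixels.shape[:2]}"
            )
        x = pixels.astype(np.float32)
        for w, b in self.kernels:
            x = self._conv_s2(x, w, b)
        g = self.pool_grid
        hs = np.array_split(np.arange(x.shape[0]), g)
        ws = np.array_split(np.arange(x.shape[1]), g)
        pooled = np.concatenate(
            [x[np.ix_(hi, wi)].mean(axis=(0, 1)) for hi in hs for wi in ws]
        )
        return pooled @ self.readout_w + self.readout_b


def _efficientnet_factory():
    try:
        import timm  # type: ignore
        import torch  # type: ignore
    except ImportError as err:
        raise ImportError(
            "backbone 'efficientnet-b0' requires the optional torch + timm "
            "dependencies (pip install 'preictal[torch]')"
        ) from err

    class _EfficientNetB0:
        backbone_id = "efficientnet-b0"
        layer_id = "penultimate-pooled-1280"
        n_features = 1280
        input_hw = (224, 224)

        def __init__(self):
            self.model = timm.create_model(
                "efficientnet_b0", pretrained=True, num_classes=0
            ).eval()
            cfg = self.model.default_cfg
            self.mean = np.array(cfg["mean"], dtype=np.float32)
            self.std = np.array(cfg["std"], dtype=np.float32)

        def forward(self, pixels: np.ndarray) -> np.ndarray:
            x = (pixels - self.mean) / self.std
            t = torch.from_numpy(x.transpose(2, 0, 1)[None])
            with torch.no_grad():
                return self.model(t).numpy()[0]

    return _EfficientNetB0()


_FACTORIES: dict[str, Callable[[], object]] = {
    "mini-cnn": lambda: _NumpyConvBackbone("mini-cnn", (8, 16, 32, 64), 128, seed=7),
    "tiny-cnn": lambda: _NumpyConvBackbone("tiny-cnn", (4, 8), 32, seed=7, pool_grid=1),
    "efficientnet-b0": _efficientnet_factory,
}
_INSTANCES: dict[str, object] = {}


def register_backbone(backbone_id: str, factory: Callable[[], object]) -> None:
    """Register a backbone factory under a string id."""
    _FACTORIES[backbone_id] = factory
    _INSTANCES.pop(backbone_id, None)


def list_backbones() -> list[str]:
    return sorted(_FACTORIES)


def get_backbone(backbone_id: str):
    if backbone_id not in _FACTORIES:
        raise KeyError(
            f"unknown backbone {backbone_id!r}; registered: {list_backbones()}"
        )
    if backbone_id not in _INSTANCES:
        _INSTANCES[backbone_id] = _FACTORIES[backbone_id]()
    return _INSTANCES[backbone_id]


def extract_features(img: FeatureImage, backbone_id: str = "mini-cnn") -> DeepFeatureVector:
    """Forward an image through a registered backbone's feature layer.

    Inference is deterministic: the same image always yields the same
    vector, and the vector length is constant for a given backbone.
    """
    bb = get_backbone(backbone_id)
    values = np.asarray(bb.forward(img.pixels))
    return DeepFeatureVector(
        values=values, backbone_id=backbone_id, layer_id=bb.layer_id
    )
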