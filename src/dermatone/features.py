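"""Convolutional feature extraction for image synthesis and classification.

A VGG-19-style stack of 3x3 convolutions with ReLU and *average* pooling
(no fully connected layers), implemented directly in NumPy with explicit
forward and backward passes so that any scalar loss on the feature maps can
be differentiated with respect to the input image (the contract both style
transfer and deep blending rely on) or with respect to the weights of a
trainable stage (the transfer-learning classifier head).

Weights come either from a user-supplied HDF5 file (e.g. converted
ImageNet-trained VGG-19 weights) or from a seeded He-normal initialization;
the small seeded "fixture" network keeps every test runnable on one CPU in
seconds. Features are deterministic functions of (weights, input).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Conv3x3",
    "AvgPool2",
    "FeatureExtractor",
    "FeatureSet",
    "fixture_extractor",
    "vgg19_descriptor",
]


class Conv3x3:
    """Same-padded 3x3 convolution + optional ReLU, with manual gradients."""

    def __init__(self, name: str, weight: np.ndarray, bias: np.ndarray, relu: bool = True):
        weight = np.asarray(weight, dtype=float)
        if weight.ndim != 4 or weight.shape[2:] != (3, 3):
            raise ValueError("conv weight must have shape (out, in, 3, 3)")
        self.name = name
        self.weight = weight
        self.bias = np.asarray(bias, dtype=float)
        self.relu = relu

    @property
    def in_channels(self) -> int:
        return self.weight.shape[1]

    @property
    def out_channels(self) -> int:
        return self.weight.shape[0]

    def forward(self, x: np.ndarray):
        c, h, w = x.shape
        if c != self.in_channels:
            raise ValueError(f"{self.name}: expected {self.in_channels} channels, got {c}")
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1)))
        y = np.zeros((self.out_channels, h, w))
        for ki in range(3):
            for kj in range(3):
                y += np.tensordot(
                    self.weight[:, :, ki, kj], xp[:, ki : ki + h, kj : kj + w], axes=(1, 0)
                )
        y += self.bias[:, None, None]
        if self.relu:
            mask = y > 0
            return np.where(mask, y, 0.0), (xp, mask)
        return y, (xp, None)

    def backward(self, dy: np.ndarray, cache, weight_grads: bool = False):
        xp, mask = cache
        if mask is not None:
            dy = np.where(mask, dy, 0.0)
        h, w = dy.shape[1:]
        dxp = np.zeros_like(xp)
        dW = np.zeros_like(self.weight) if weight_grads else None
        for ki in range(3):
            for kj in range(3):
                dxp[:, ki : ki + h, kj : kj + w] += np.tensordot(
                    self.weight[:, :, ki, kj], dy, axes=(0, 0)
                )
                if weight_grads:
                    dW[:, :, ki, kj] = np.tensordot(
                        dy, xp[:, ki : ki + h, kj : kj + w], axes=([1, 2], [1, 2])
                    )
        dx = dxp[:, 1:-1, 1:-1]
        if weight_grads:
            return dx, dW, dy.sum(axis=(1, 2))
        return dx


class AvgPool2:
    """2x2 average pooling, stride 2 (odd trailing rows/columns dropped)."""

    def __init__(self, name: str):
        self.name = name

    def forward(self, x: np.ndarray):
        c, h, w = x.shape
        h2, w2 = h // 2, w // 2
        if h2 == 0 or w2 == 0:
            raise ValueError(f"{self.name}: input {h}x{w} too small to pool")
        xt = x[:, : 2 * h2, : 2 * w2]
        y = xt.reshape(c, h2, 2, w2, 2).mean(axis=(2, 4))
        return y, (h, w)

    def backward(self, dy: np.ndarray, cache, weight_grads: bool = False):
        h, w = cache
        c, h2, w2 = dy.shape
        dx = np.zeros((c, h, w))
        up = np.repeat(np.repeat(dy, 2, axis=1), 2, axis=2) / 4.0
        dx[:, : 2 * h2, : 2 * w2] = up
        if weight_grads:
            return dx, None, None
        return dx


@dataclass
class FeatureSet:
    """Feature tensors keyed by layer name, plus the source image reference."""

    features: dict[str, np.ndarray]
    image: np.ndarray | None = None

    def __getitem__(self, layer: str) -> np.ndarray:
        return self.features[layer]

    @property
    def layers(self) -> list[str]:
        return list(self.features)


def vgg19_descriptor() -> list[dict]:
    """Architecture descriptor of the 16-conv / 5-average-pool VGG-19 trunk."""
    plan = [(1, 2, 64), (2, 2, 128), (3, 4, 256), (4, 4, 512), (5, 4, 512)]
    layers: list[dict] = []
    in_ch = 3
    for block, n_convs, ch in plan:
        for i in range(1, n_convs + 1):
            layers.append({"type": "conv", "name": f"conv{block}_{i}", "in": in_ch, "out": ch})
            in_ch = ch
        layers.append({"type": "avgpool", "name": f"pool{block}"})
    return layers


def fixture_descriptor(channels: tuple[int, int, int] = (8, 16, 16)) -> list[dict]:
    """Tiny 3-conv / 2-average-pool descriptor used throughout the tests."""
    c1, c2, c3 = channels
    return [
        {"type": "conv", "name": "conv1_1", "in": 3, "out": c1},
        {"type": "avgpool", "name": "pool1"},
        {"type": "conv", "name": "conv2_1", "in": c1, "out": c2},
        {"type": "avgpool", "name": "pool2"},
        {"type": "conv", "name": "conv3_1", "in": c2, "out": c3},
    ]


class FeatureExtractor:
    """Ordered stack of conv/pool layers with seeded or file-based weights.

    Parameters
    ----------
    descriptor : list of layer dicts ({"type": "conv"|"avgpool", "name", ...})
    weights : "random_seeded" or path to an HDF5 file with datasets
        ``<layer>/weight`` (out, in, 3, 3) and ``<layer>/bias`` (out,)
    seed : RNG seed for the seeded initialization
    mean : per-channel input offset subtracted before the first layer
        (depends on the weights' training convention; zero by default)
    zero_bias : force all conv biases to zero (seeded init only)
    """

    def __init__(
        self,
        descriptor: list[dict] | None = None,
        weights: str = "random_seeded",
        seed: int = 0,
        mean: np.ndarray | None = None,
        zero_bias: bool = True,
    ):
        descriptor = descriptor if descriptor is not None else fixture_descriptor()
        names = [d["name"] for d in descriptor]
        if len(set(names)) != len(names):
            raise ValueError("layer names must be unique")
        self.descriptor = descriptor
        self.mean = np.zeros(3) if mean is None else np.asarray(mean, dtype=float)

        h5 = None
        if weights != "random_seeded":
            import h5py

            h5 = h5py.File(weights, "r")
        rng = np.random.default_rng(seed)
        self.layers: list = []
        try:
            for d in descriptor:
                if d["type"] == "conv":
                    if h5 is not None:
                        W = np.asarray(h5[f"{d['name']}/weight"])
                        b = np.asarray(h5[f"{d['name']}/bias"])
                    else:
                        fan_in = d["in"] * 9
                        W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(d["out"], d["in"], 3, 3))
                        b = np.zeros(d["out"]) if zero_bias else rng.normal(0, 0.01, d["out"])
                    self.layers.append(Conv3x3(d["name"], W, b))
                elif d["type"] == "avgpool":
                    self.layers.append(AvgPool2(d["name"]))
                else:
                    raise ValueError(f"unknown layer type {d['type']!r}")
        finally:
            if h5 is not None:
                h5.close()

    # -- introspection ------------------------------------------------------

    @property
    def layer_names(self) -> list[str]:
        return [l.name for l in self.layers]

    def save_descriptor(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.descriptor, fh, indent=2)

    # -- forward / backward -------------------------------------------------

    def _to_chw(self, image: np.ndarray) -> np.ndarray:
        image = np.asarray(image, dtype=float)
        if image.ndim == 3 and image.shape[-1] == 3:
            image = np.transpose(image, (2, 0, 1))
        if image.ndim != 3:
            raise ValueError(f"expected (H, W, 3) or (C, H, W) image, got {image.shape}")
        if image.shape[1] == 0 or image.shape[2] == 0:
            raise ValueError("zero-sized image")
        return image - self.mean[:, None, None]

    def forward_all(self, image: np.ndarray, upto: str | None = None):
        """Run the stack, returning ({layer: activation}, caches)."""
        x = self._to_chw(image)
        acts: dict[str, np.ndarray] = {}
        caches: list = []
        for layer in self.layers:
            x, cache = layer.forward(x)
            acts[layer.name] = x
            caches.append(cache)
            if upto is not None and layer.name == upto:
                break
        return acts, caches

    def extract_features(self, image: np.ndarray, layers: list[str]) -> FeatureSet:
        """Feature tensors at the requested layers for one image."""
        unknown = [l for l in layers if l not in self.layer_names]
        if unknown:
            raise ValueError(f"unknown layer name(s): {unknown}")
        deepest = max(layers, key=self.layer_names.index)
        acts, _ = self.forward_all(image, upto=deepest)
        return FeatureSet({l: acts[l] for l in layers}, image=image)

    def backward(self, caches: list, grads: dict[str, np.ndarray]) -> np.ndarray:
        """Gradient of sum_l <grads[l], activation_l> w.r.t. the input image.

        ``caches`` must come from ``forward_all`` on the same input; ``grads``
        maps layer names to gradients of the loss w.r.t. those activations.
        Returns an (H, W, 3) gradient.
        """
        n = len(caches)
        layer_slice = self.layers[:n]
        d = None
        for layer, cache in zip(reversed(layer_slice), reversed(caches)):
            if d is None:
                d = np.zeros_like(_output_like(layer, cache, grads))
            if layer.name in grads:
                d = d + grads[layer.name]
            d = layer.backward(d, cache)
        return np.transpose(d, (1, 2, 0))


def _output_like(layer, cache, grads):
    if layer.name in grads:
        return grads[layer.name]
    raise ValueError("backward requires a gradient at the deepest forwarded layer")


def fixture_extractor(seed: int = 0, channels: tuple[int, int, int] = (8, 16, 16)) -> FeatureExtractor:
    """The small deterministic extractor used in tests and demos."""
    return FeatureExtractor(fixture_descriptor(channels), seed=seed)
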