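"""Heterogeneous backbone zoo with stage-wise pooled feature extraction.

The federation pairs a ResNet-18-style global model with VGG-16-style local
models; this module builds both at full scale and as tiny (1/16-width,
3-stage) desk-scale variants that keep the same topological contrast
(residual trunk vs plain convolutional trunk).  Each backbone exposes
activations at declared "tap" stages; pooled per-channel features from the
taps are concatenated into a fixed-dimension vector:

* full-scale global (ResNet-18-like): stages 3 and 4 (256 and 512 channels),
  each pooled by average AND maximum -> 2 x (256 + 512) = 1536 dims;
* full-scale local (VGG-16-like): all five convolutional blocks
  (64 + 128 + 256 + 512 + 512 = 1472 dims), average pooling only.

Grad-CAM heatmaps are computed at the last tapped stage from gradients of a
chosen class logit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import nn

__all__ = [
    "BackboneSpec", "FeatureBundle", "Heatmap", "Backbone",
    "default_spec", "build_backbone", "preprocess_roi", "extract_features",
    "gradcam",
]

ARCH_IDS = ("global_resnet18", "local_vgg16", "tiny_global", "tiny_local")


@dataclass(frozen=True)
class BackboneSpec:
    """Architecture + feature-tap contract for one backbone."""

    arch_id: str
    stage_channels: tuple[int, ...]
    tap_stages: tuple[int, ...]          # indices into stage_channels
    pooling_modes: tuple[str, ...]       # applied to every tap, avg before max
    input_size: tuple[int, int, int]     # (H, W, C)
    seed: int = 0

    @property
    def expected_feature_dim(self) -> int:
        return sum(self.stage_channels[s] for s in self.tap_stages) \
            * len(self.pooling_modes)

    def validate(self) -> None:
        if self.arch_id not in ARCH_IDS:
            raise ValueError(f"unknown arch_id {self.arch_id!r}")
        if list(self.tap_stages) != sorted(set(self.tap_stages)):
            raise ValueError("tap_stages must be strictly increasing")
        if any(s < 0 or s >= len(self.stage_channels) for s in self.tap_stages):
            raise ValueError("tap stage index out of range")
        if not self.pooling_modes or \
                not set(self.pooling_modes) <= {"average", "maximum"}:
            raise ValueError("pooling_modes must be a non-empty subset of "
                             "{'average', 'maximum'}")


def default_spec(arch_id: str, seed: int = 0) -> BackboneSpec:
    """The shipped spec for each architecture id."""
    if arch_id == "global_resnet18":
        return BackboneSpec(arch_id, (64, 128, 256, 512), (2, 3),
                            ("average", "maximum"), (224, 224, 3), seed)
    if arch_id == "local_vgg16":
        return BackboneSpec(arch_id, (64, 128, 256, 512, 512),
                            (0, 1, 2, 3, 4), ("average",), (224, 224, 3), seed)
    if arch_id == "tiny_global":
        return BackboneSpec(arch_id, (8, 16, 32), (0, 1, 2),
                            ("average",), (64, 64, 1), seed)
    if arch_id == "tiny_local":
        return BackboneSpec(arch_id, (8, 16, 32), (0, 1, 2),
                            ("average",), (64, 64, 1), seed)
    raise ValueError(f"unknown arch_id {arch_id!r}")


@dataclass
class FeatureBundle:
    """Per-stage pooled features of one image plus their concatenation."""

    per_stage: dict[int, dict[str, np.ndarray]]
    concatenated: np.ndarray


@dataclass
class Heatmap:
    """A [0, 1] class-activation map at input resolution."""

    values: np.ndarray


# ---------------------------------------------------------------------------
# network building blocks
# ---------------------------------------------------------------------------

class _BasicBlock(nn.Module):
    """Conv-BN x2 with an additive shortcut (ResNet basic block)."""

    def __init__(self, rng, cin: int, cout: int, stride: int):
        self.conv1 = nn.Conv2d(rng, cin, cout, 3, stride=stride, pad=1)
        self.bn1 = nn.BatchNorm2d(cout)
        self.conv2 = nn.Conv2d(rng, cout, cout, 3, stride=1, pad=1)
        self.bn2 = nn.BatchNorm2d(cout)
        if stride != 1 or cin != cout:
            self.short = nn.Conv2d(rng, cin, cout, 1, stride=stride, pad=0)
            self.short_bn = nn.BatchNorm2d(cout)
        else:
            self.short = None
            self.short_bn = None

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        h = self.bn2(self.conv2(nn.relu(self.bn1(self.conv1(x)))))
        s = self.short_bn(self.short(x)) if self.short is not None else x
        return nn.relu(nn.add(h, s))


class _VGGBlock(nn.Module):
    """n_conv conv-BN-ReLU layers followed by 2x2 max pooling."""

    def __init__(self, rng, cin: int, cout: int, n_conv: int):
        self.convs = [nn.Conv2d(rng, cin if i == 0 else cout, cout, 3, pad=1)
                      for i in range(n_conv)]
        self.bns = [nn.BatchNorm2d(cout) for _ in range(n_conv)]

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        for conv, bn in zip(self.convs, self.bns):
            x = nn.relu(bn(conv(x)))
        return nn.maxpool2(x)


class Backbone(nn.Module):
    """A stage-tapped image classifier with 2 output logits."""

    def __init__(self, spec: BackboneSpec):
        spec.validate()
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        h, w, cin = spec.input_size
        ch = spec.stage_channels
        self.stages: list[list] = []
        if spec.arch_id == "global_resnet18":
            if h < 32 or w < 32:
                raise ValueError("global_resnet18 needs input >= 32 px")
            self.stem = nn.Conv2d(rng, cin, ch[0], 7, stride=2, pad=3)
            self.stem_bn = nn.BatchNorm2d(ch[0])
            self.stem_pool = True
            for i, c in enumerate(ch):
                prev = ch[0] if i == 0 else ch[i - 1]
                stride = 1 if i == 0 else 2
                self.stages.append([_BasicBlock(rng, prev, c, stride),
                                    _BasicBlock(rng, c, c, 1)])
        elif spec.arch_id == "tiny_global":
            if h < 16 or w < 16:
                raise ValueError("tiny_global needs input >= 16 px")
            self.stem = nn.Conv2d(rng, cin, ch[0], 3, stride=2, pad=1)
            self.stem_bn = nn.BatchNorm2d(ch[0])
            self.stem_pool = False
            for i, c in enumerate(ch):
                prev = ch[0] if i == 0 else ch[i - 1]
                stride = 1 if i == 0 else 2
                self.stages.append([_BasicBlock(rng, prev, c, stride)])
        elif spec.arch_id == "local_vgg16":
            if h < 32 or w < 32:
                raise ValueError("local_vgg16 needs input >= 32 px")
            self.stem = None
            self.stem_bn = None
            n_convs = (2, 2, 3, 3, 3)
            for i, (c, k) in enumerate(zip(ch, n_convs)):
                prev = cin if i == 0 else ch[i - 1]
                self.stages.append([_VGGBlock(rng, prev, c, k)])
        elif spec.arch_id == "tiny_local":
            if h < 16 or w < 16:
                raise ValueError("tiny_local needs input >= 16 px")
            self.stem = nn.Conv2d(rng, cin, ch[0], 3, stride=2, pad=1)
            self.stem_bn = nn.BatchNorm2d(ch[0])
            self.stem_pool = False
            for i, c in enumerate(ch):
                prev = ch[0] if i == 0 else ch[i - 1]
                self.stages.append([_VGGBlock(rng, prev, c, 1)])
        else:  # pragma: no cover - guarded by validate()
            raise ValueError(spec.arch_id)
        self.head = nn.Linear(rng, ch[-1], 2)

    def forward(self, x: nn.Tensor) -> tuple[nn.Tensor, list[nn.Tensor]]:
        """Return (logits, per-stage activation maps, one per stage)."""
        if self.stem is not None:
            x = nn.relu(self.stem_bn(self.stem(x)))
            if self.stem_pool:
                x = nn.maxpool2(x)
        maps = []
        for stage in self.stages:
            for block in stage:
                x = block(x)
            maps.append(x)
        logits = self.head(nn.global_avg_pool(x))
        return logits, maps

    def __call__(self, x: nn.Tensor) -> tuple[nn.Tensor, list[nn.Tensor]]:
        return self.forward(x)

    # -- inference helpers (values only, no training) -----------------------

    def predict_proba(self, images: np.ndarray, batch: int = 32) -> np.ndarray:
        """Class probabilities for NHWC images (inference mode)."""
        self.set_training(False)
        out = []
        with nn.no_grad():
            for lo in range(0, len(images), batch):
                x = nn.Tensor(_nhwc_to_nchw(images[lo:lo + batch]))
                logits, _ = self.forward(x)
                out.append(nn.softmax_probs(logits.data))
        return np.concatenate(out, axis=0)

    def stage_features(self, images: np.ndarray, batch: int = 32
                       ) -> dict[int, np.ndarray]:
        """Average-pooled per-channel features at every tap stage (values)."""
        self.set_training(False)
        feats: dict[int, list[np.ndarray]] = {s: [] for s in self.spec.tap_stages}
        with nn.no_grad():
            for lo in range(0, len(images), batch):
                x = nn.Tensor(_nhwc_to_nchw(images[lo:lo + batch]))
                _, maps = self.forward(x)
                for s in self.spec.tap_stages:
                    feats[s].append(maps[s].data.mean(axis=(2, 3)))
        return {s: np.concatenate(v, axis=0) for s, v in feats.items()}


def _nhwc_to_nchw(images: np.ndarray) -> np.ndarray:
    images = np.asarray(images, dtype=nn.DTYPE)
    if images.ndim == 3:
        images = images[..., None]
    return images.transpose(0, 3, 1, 2)


def build_backbone(spec: BackboneSpec) -> Backbone:
    """Construct a backbone with deterministic seeded initialization."""
    return Backbone(spec)


# ---------------------------------------------------------------------------
# preprocessing and feature extraction
# ---------------------------------------------------------------------------

def preprocess_roi(image: np.ndarray, size: int = 224,
                   channels: int = 3) -> np.ndarray:
    """Resize an ROI to a square and min-max normalize it to [0, 1].

    Grayscale inputs are channel-replicated when ``channels`` is 3; a
    constant image maps to all zeros.
    """
    from skimage.transform import resize

    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise ValueError("empty ROI")
    if not np.isfinite(image).all():
        raise ValueError("non-finite pixel values")
    if image.ndim == 2:
        image = image[..., None]
    if image.ndim != 3 or image.shape[2] not in (1, 3):
        raise ValueError("ROI must be HxW or HxWxC with C in {1, 3}")
    out = resize(image, (size, size, image.shape[2]), order=1,
                 preserve_range=True, anti_aliasing=False)
    lo, hi = out.min(), out.max()
    out = np.zeros_like(out) if hi == lo else (out - lo) / (hi - lo)
    if channels == 3 and out.shape[2] == 1:
        out = np.repeat(out, 3, axis=2)
    return out


def extract_features(backbone: Backbone, images: np.ndarray,
                     batch: int = 8) -> list[FeatureBundle]:
    """Pool tapped stage maps into fixed-dimension feature vectors.

    Concatenation order is ascending stage; within a stage, average-pooled
    channels precede max-pooled ones.
    """
    spec = backbone.spec
    images = np.asarray(images, dtype=float)
    if images.ndim == 3:
        images = images[..., None]
    h, w, c = spec.input_size
    if images.shape[1:] != (h, w, c):
        raise ValueError(f"images {images.shape[1:]} do not match "
                         f"spec input_size {(h, w, c)}")
    backbone.set_training(False)
    bundles: list[FeatureBundle] = []
    for lo in range(0, len(images), batch):
        with nn.no_grad():
            x = nn.Tensor(_nhwc_to_nchw(images[lo:lo + batch]))
            _, maps = backbone.forward(x)
        n = x.shape[0]
        for i in range(n):
            per_stage: dict[int, dict[str, np.ndarray]] = {}
            parts = []
            for s in spec.tap_stages:
                m = maps[s].data[i]
                pooled = {}
                for mode in ("average", "maximum"):
                    if mode in spec.pooling_modes:
                        pooled[mode] = (m.mean(axis=(1, 2)) if mode == "average"
                                        else m.max(axis=(1, 2)))
                        parts.append(pooled[mode])
                per_stage[s] = pooled
            vec = np.concatenate(parts)
            assert len(vec) == spec.expected_feature_dim
            bundles.append(FeatureBundle(per_stage=per_stage, concatenated=vec))
    return bundles


def gradcam(backbone: Backbone, image: np.ndarray,
            target_class: int) -> Heatmap:
    """Grad-CAM at the last tapped stage for one image.

    Channel weights are the spatial means of the target-logit gradient;
    the heatmap is the rectified weighted sum of channel maps, bilinearly
    upsampled to input size and max-normalized (all-zero maps stay zero).
    """
    from skimage.transform import resize

    if target_class not in (0, 1):
        raise ValueError("target_class must be 0 or 1")
    image = np.asarray(image, dtype=float)
    if image.ndim == 2:
        image = image[..., None]
    backbone.set_training(False)
    x = nn.Tensor(_nhwc_to_nchw(image[None]))
    logits, maps = backbone.forward(x)
    onehot = np.zeros((2, 1))
    onehot[target_class, 0] = 1.0
    score = nn.matmul(logits, nn.Tensor(onehot))
    score.backward()
    last = maps[backbone.spec.tap_stages[-1]]
    grads = last.grad[0]                      # C x h x w
    acts = last.data[0]
    weights = grads.mean(axis=(1, 2))
    cam = np.maximum((weights[:, None, None] * acts).sum(axis=0), 0.0)
    h, w, _ = backbone.spec.input_size
    cam = resize(cam, (h, w), order=1, preserve_range=True,
                 anti_aliasing=False)
    cam = np.maximum(cam, 0.0)
    m = cam.max()
    if m > 0:
        cam = cam / m
    return Heatmap(values=cam)


# ---------------------------------------------------------------------------
# persistence / export
# ---------------------------------------------------------------------------

def save_checkpoint(backbone: Backbone, path) -> None:
    """Write spec + parameters to a single .npz archive."""
    import json
    from dataclasses import asdict

    meta = json.dumps(asdict(backbone.spec))
    np.savez(path, _spec=np.frombuffer(meta.encode(), dtype=np.uint8),
             **{f"p{i:03d}": p for i, p in enumerate(backbone.state())})


def load_checkpoint(path) -> Backbone:
    import json

    with np.load(path) as z:
        meta = json.loads(bytes(z["_spec"]).decode())
        params = [z[k] for k in sorted(z.files) if k.startswith("p")]
    for key in ("stage_channels", "tap_stages", "pooling_modes", "input_size"):
        meta[key] = tuple(meta[key])
    bb = Backbone(BackboneSpec(**meta))
    bb.load_state(params)
    return bb


def export_feature_csv(bundles: Sequence[FeatureBundle],
                       labels: Sequence[int], center_id: str, path) -> None:
    """One row per patient: f0001..fNNNN columns + label + center_id."""
    import pandas as pd

    mat = np.stack([b.concatenated for b in bundles])
    cols = [f"f{i + 1:04d}" for i in range(mat.shape[1])]
    df = pd.DataFrame(mat, columns=cols)
    df["label"] = list(labels)
    df["center_id"] = center_id
    df.to_csv(path, index=False)
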