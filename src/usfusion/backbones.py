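"""CNN branch construction, training, and tap-layer feature extraction.

Each backbone exposes two things: a 2-class forward pass and a *tap* —
the flattened output of the named layer preceding the classification
layers, used as the branch feature vector for classifier-level fusion.
The tap dimensions are part of the module contract:

=============  ============  ====================  ========
name           native input  tap layer             tap dim
=============  ============  ====================  ========
squeezenet     224           relu_conv10           392
squeezenet     224           pool10                2
googlenet      224           pool5-drop_7x7_s1     1024
googlenet_v1   224           pool_4d (+shortcut)   528
resnet18       224           pool5                 512
vgg16          224           drop7                 4096
densenet201    224           avg_pool              1920
tiny           51            fc1                   64
=============  ============  ====================  ========

The large architectures are randomly-initialized, forward-only
shape-contract builds (pretrained weights are deliberately out of
scope); the ``tiny`` branch (3 conv/pool blocks + fully connected) is
fully trainable with SGD-momentum and is the workhorse for simulation
experiments.  Grayscale patches are bilinearly resized to the native
input side and replicated to three channels where needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import maximum_filter, zoom

from . import nn
from .annotations import HCC, PAR, PairedPatch, translate_reflect

LABEL_INDEX = {HCC: 0, PAR: 1}


@dataclass
class BackboneSpec:
    name: str
    native_input: int
    tap_layer: str
    tap_dim: int
    n_outputs: int = 2


REGISTRY: dict[str, BackboneSpec] = {
    "tiny": BackboneSpec("tiny", 51, "fc1", 64),
    "squeezenet": BackboneSpec("squeezenet", 224, "relu_conv10", 392),
    "googlenet": BackboneSpec("googlenet", 224, "pool5-drop_7x7_s1", 1024),
    "googlenet_v1": BackboneSpec("googlenet_v1", 224, "pool_4d", 528),
    "resnet18": BackboneSpec("resnet18", 224, "pool5", 512),
    "vgg16": BackboneSpec("vgg16", 224, "drop7", 4096),
    "densenet201": BackboneSpec("densenet201", 224, "avg_pool", 1920),
}

#: Secondary tap of SqueezeNet (global pool over the 2 class maps).
SQUEEZENET_POOL10_DIM = 2


@dataclass
class TrainConfig:
    """SGD-momentum training hyperparameters for a branch."""

    learning_rate: float = 2e-4
    momentum: float = 0.1
    minibatch: int = 25
    epochs: int = 70
    seed: int = 0
    augmentation: bool = True
    pretrained: bool = False

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.momentum, self.minibatch,
               self.epochs) <= 0 and self.momentum != 0:
            raise ValueError("training hyperparameters must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


def scratch_train_config(seed: int = 0, epochs: int = 40) -> TrainConfig:
    """Training schedule for branches trained from random initialization.

    The default ``TrainConfig`` values suit fine-tuning of pretrained
    weights; a randomly initialized branch needs a larger step and
    heavier momentum to converge within a short schedule.
    """
    return TrainConfig(learning_rate=2e-3, momentum=0.9, epochs=epochs,
                       seed=seed)


# ---------------------------------------------------------------------------
# Input preparation

def _resize_channel(img: np.ndarray, side: int) -> np.ndarray:
    img = np.asarray(img, dtype=np.float32)
    if img.shape == (side, side):
        return img
    factors = (side / img.shape[0], side / img.shape[1])
    out = zoom(img, factors, order=1, grid_mode=True, mode="nearest")
    return out[:side, :side]


def prepare_batch(images, side: int, n_channels: int) -> np.ndarray:
    """Stack grayscale images into an NCHW batch.

    Fixed affine normalization (x - 128)/64 keeps the mid-gray working
    range near unit scale so gradients are well-conditioned at the small
    branch learning rate, while preserving absolute brightness (the CEUS
    enhancement signal) across patches.
    """
    batch = np.stack([_resize_channel(im, side) for im in images])
    batch = (batch - 128.0) / 64.0
    batch = batch[:, None, :, :]
    if n_channels > 1:
        batch = np.repeat(batch, n_channels, axis=1)
    return batch.astype(np.float32)


# ---------------------------------------------------------------------------
# Tiny trainable branch

class TinyBackbone:
    """3 conv/pool blocks + fully connected head, native input 51."""

    n_channels = 1

    def __init__(self, seed: int = 0):
        self.spec = REGISTRY["tiny"]
        rng = np.random.default_rng(seed)
        s = 51
        self.net = nn.Sequential([
            ("conv1", nn.Conv2D(1, 8, 3, rng)), ("relu1", nn.ReLU()),
            ("pool1", nn.MaxPool2()),
            ("conv2", nn.Conv2D(8, 16, 3, rng)), ("relu2", nn.ReLU()),
            ("pool2", nn.MaxPool2()),
            ("conv3", nn.Conv2D(16, 16, 3, rng)), ("relu3", nn.ReLU()),
            ("pool3", nn.MaxPool2()),
            ("flatten", nn.Flatten()),
            ("fc1", nn.Dense(16 * (s // 8) * (s // 8), 64, rng)),
            ("relu4", nn.ReLU()),
            ("fc2", nn.Dense(64, 2, rng)),
        ])
        self.history: list[dict] = []

    def forward_logits(self, x: np.ndarray) -> np.ndarray:
        return self.net.forward(x)

    def tap_features(self, x: np.ndarray) -> np.ndarray:
        _, tap = self.net.forward(x, tap=self.spec.tap_layer)
        return tap


# ---------------------------------------------------------------------------
# Frozen shape-contract architectures

def _fire(c_in, squeeze, expand, rng):
    sq = nn.FrozenConv(c_in, squeeze, 1, rng, pad=0)
    e1 = nn.FrozenConv(squeeze, expand // 2, 1, rng, pad=0)
    e3 = nn.FrozenConv(squeeze, expand // 2, 3, rng)

    def f(x):
        s = nn.relu(sq(x))
        return np.concatenate([nn.relu(e1(s)), nn.relu(e3(s))], axis=1)
    return f


class SqueezeNet:
    n_channels = 3

    def __init__(self, seed: int = 0):
        self.spec = REGISTRY["squeezenet"]
        rng = np.random.default_rng(seed)
        self.conv1 = nn.FrozenConv(3, 64, 3, rng, stride=2, pad=1)
        self.fire2 = _fire(64, 16, 128, rng)
        self.fire3 = _fire(128, 16, 128, rng)
        self.fire4 = _fire(128, 32, 256, rng)
        self.fire5 = _fire(256, 32, 256, rng)
        self.fire6 = _fire(256, 48, 384, rng)
        self.fire7 = _fire(384, 48, 384, rng)
        self.fire8 = _fire(384, 64, 512, rng)
        self.fire9 = _fire(512, 64, 512, rng)
        self.conv10 = nn.FrozenConv(512, 2, 1, rng, pad=0)

    def _taps(self, x):
        x = nn.relu(self.conv1(x))          # 112
        x = nn.maxpool2(x)                  # 56
        x = self.fire3(self.fire2(x))
        x = nn.maxpool2(x)                  # 28
        x = self.fire5(self.fire4(x))
        x = nn.maxpool2(x)                  # 14
        x = self.fire9(self.fire8(self.fire7(self.fire6(x))))
        x = nn.channel_norm(x)
        relu_conv10 = nn.relu(self.conv10(x))            # 2 x 14 x 14
        pool10 = nn.global_avgpool(relu_conv10)          # 2
        return {"relu_conv10": relu_conv10.reshape(len(x), -1),
                "pool10": pool10}, pool10

    def forward_logits(self, x):
        return self._taps(x)[1]

    def tap_features(self, x, dual_tap: bool = False):
        taps, _ = self._taps(x)
        if dual_tap:
            return np.concatenate([taps["pool10"], taps["relu_conv10"]], axis=1)
        return taps[self.spec.tap_layer]


def _pool3_same(x):
    return maximum_filter(x, size=(1, 1, 3, 3), mode="nearest")


def _inception(c_in, c1, c3r, c3, c5r, c5, pp, rng):
    b1 = nn.FrozenConv(c_in, c1, 1, rng, pad=0)
    b3a = nn.FrozenConv(c_in, c3r, 1, rng, pad=0)
    b3b = nn.FrozenConv(c3r, c3, 3, rng)
    b5a = nn.FrozenConv(c_in, c5r, 1, rng, pad=0)
    b5b = nn.FrozenConv(c5r, c5, 5, rng)
    bp = nn.FrozenConv(c_in, pp, 1, rng, pad=0)

    def f(x):
        x = nn.channel_norm(x)
        return np.concatenate([
            nn.relu(b1(x)),
            nn.relu(b3b(nn.relu(b3a(x)))),
            nn.relu(b5b(nn.relu(b5a(x)))),
            nn.relu(bp(_pool3_same(x))),
        ], axis=1)
    return f


#: (c1, c3r, c3, c5r, c5, pool-proj) per inception module, standard widths.
_INCEPTION_CFG = {
    "3a": (64, 96, 128, 16, 32, 32),     # -> 256
    "3b": (128, 128, 192, 32, 96, 64),   # -> 480
    "4a": (192, 96, 208, 16, 48, 64),    # -> 512
    "4b": (160, 112, 224, 24, 64, 64),   # -> 512
    "4c": (128, 128, 256, 24, 64, 64),   # -> 512
    "4d": (112, 144, 288, 32, 64, 64),   # -> 528
    "4e": (256, 160, 320, 32, 128, 128),  # -> 832
    "5a": (256, 160, 320, 32, 128, 128),  # -> 832
    "5b": (384, 192, 384, 48, 128, 128),  # -> 1024
}


class GoogLeNet:
    n_channels = 3

    def __init__(self, seed: int = 0, variant_v1: bool = False):
        self.variant_v1 = variant_v1
        self.spec = REGISTRY["googlenet_v1" if variant_v1 else "googlenet"]
        rng = np.random.default_rng(seed)
        self.conv1 = nn.FrozenConv(3, 64, 7, rng, stride=2, pad=3)
        self.conv2 = nn.FrozenConv(64, 64, 1, rng, pad=0)
        self.conv3 = nn.FrozenConv(64, 192, 3, rng)
        cin = 192
        self.modules = {}
        for name, cfg in _INCEPTION_CFG.items():
            self.modules[name] = _inception(cin, *cfg, rng)
            cin = cfg[0] + cfg[2] + cfg[4] + cfg[5]
        if variant_v1:
            # residual shortcut replacing the skipped 4e/5a/5b modules
            self.shortcut = nn.FrozenConv(512, 528, 1, rng, pad=0)
            self.fc = nn.Dense(528, 2, np.random.default_rng(seed + 1))
        else:
            self.fc = nn.Dense(1024, 2, np.random.default_rng(seed + 1))

    def _stem(self, x):
        x = nn.relu(self.conv1(x))   # 112
        x = nn.maxpool2(x)           # 56
        x = nn.relu(self.conv3(nn.relu(self.conv2(x))))
        x = nn.maxpool2(x)           # 28
        x = self.modules["3b"](self.modules["3a"](x))
        x = nn.maxpool2(x)           # 14
        return x

    def _taps(self, x):
        x = self._stem(x)
        x4a = self.modules["4a"](x)
        x4c = self.modules["4c"](self.modules["4b"](x4a))
        x4d = self.modules["4d"](x4c)
        if self.variant_v1:
            main = nn.global_avgpool(x4d)
            short = nn.global_avgpool(self.shortcut(nn.avgpool2(x4c)))
            tap = main + short
            return {"pool_4d": tap}, self.fc.forward(tap.astype(np.float32))
        x = nn.maxpool2(self.modules["4e"](x4d))   # 7
        x = self.modules["5b"](self.modules["5a"](x))
        tap = nn.global_avgpool(x)                 # 1024
        return ({"pool5-drop_7x7_s1": tap},
                self.fc.forward(tap.astype(np.float32)))

    def forward_logits(self, x):
        return self._taps(x)[1]

    def tap_features(self, x):
        return self._taps(x)[0][self.spec.tap_layer]


class ResNet18:
    n_channels = 3

    def __init__(self, seed: int = 0):
        self.spec = REGISTRY["resnet18"]
        rng = np.random.default_rng(seed)
        self.conv1 = nn.FrozenConv(3, 64, 7, rng, stride=2, pad=3)
        self.blocks = []
        cin = 64
        for cout, stride in ((64, 1), (64, 1), (128, 2), (128, 1),
                             (256, 2), (256, 1), (512, 2), (512, 1)):
            self.blocks.append(self._basic_block(cin, cout, stride, rng))
            cin = cout
        self.fc = nn.Dense(512, 2, np.random.default_rng(seed + 1))

    @staticmethod
    def _basic_block(cin, cout, stride, rng):
        c1 = nn.FrozenConv(cin, cout, 3, rng, stride=stride)
        c2 = nn.FrozenConv(cout, cout, 3, rng)
        proj = nn.FrozenConv(cin, cout, 1, rng, stride=stride, pad=0) \
            if (stride != 1 or cin != cout) else None

        def f(x):
            idn = proj(x) if proj is not None else x
            out = c2(nn.relu(nn.channel_norm(c1(x))))
            return nn.relu(nn.channel_norm(out) + idn)
        return f

    def _taps(self, x):
        x = nn.relu(self.conv1(x))  # 112
        x = nn.maxpool2(x)          # 56
        for block in self.blocks:
            x = block(x)            # ... 7
        tap = nn.global_avgpool(x)  # 512
        return {"pool5": tap}, self.fc.forward(tap.astype(np.float32))

    def forward_logits(self, x):
        return self._taps(x)[1]

    def tap_features(self, x):
        return self._taps(x)[0]["pool5"]


class VGG16:
    n_channels = 3

    def __init__(self, seed: int = 0):
        self.spec = REGISTRY["vgg16"]
        rng = np.random.default_rng(seed)
        cfg = [64, 64, "P", 128, 128, "P", 256, 256, 256, "P",
               512, 512, 512, "P", 512, 512, 512, "P"]
        self.layers = []
        cin = 3
        for item in cfg:
            if item == "P":
                self.layers.append("P")
            else:
                self.layers.append(nn.FrozenConv(cin, item, 3, rng))
                cin = item
        rng2 = np.random.default_rng(seed + 1)
        self.fc6 = nn.Dense(512 * 7 * 7, 4096, rng2)
        self.fc7 = nn.Dense(4096, 4096, rng2)
        self.fc8 = nn.Dense(4096, 2, rng2)

    def _taps(self, x):
        for layer in self.layers:
            x = nn.maxpool2(x) if layer == "P" else nn.relu(layer(x))
        x = nn.channel_norm(x).reshape(len(x), -1).astype(np.float32)
        h = np.maximum(self.fc6.forward(x), 0.0)
        h = np.maximum(self.fc7.forward(h), 0.0)
        drop7 = h  # dropout is identity at inference
        return {"drop7": drop7}, self.fc8.forward(drop7)

    def forward_logits(self, x):
        return self._taps(x)[1]

    def tap_features(self, x):
        return self._taps(x)[0]["drop7"]


class DenseNet201:
    n_channels = 3

    def __init__(self, seed: int = 0):
        self.spec = REGISTRY["densenet201"]
        rng = np.random.default_rng(seed)
        self.conv1 = nn.FrozenConv(3, 64, 7, rng, stride=2, pad=3)
        self.blocks = []
        self.transitions = []
        cin = 64
        growth = 32
        for i, n_layers in enumerate((6, 12, 48, 32)):
            layers = []
            for _ in range(n_layers):
                bottleneck = nn.FrozenConv(cin, 4 * growth, 1, rng, pad=0)
                grow = nn.FrozenConv(4 * growth, growth, 3, rng)
                layers.append((bottleneck, grow))
                cin += growth
            self.blocks.append(layers)
            if i < 3:
                self.transitions.append(nn.FrozenConv(cin, cin // 2, 1, rng,
                                                      pad=0))
                cin //= 2
        self.out_channels = cin  # 1920
        self.fc = nn.Dense(cin, 2, np.random.default_rng(seed + 1))

    def _taps(self, x):
        x = nn.relu(self.conv1(x))  # 112
        x = nn.maxpool2(x)          # 56
        for i, layers in enumerate(self.blocks):
            for bottleneck, grow in layers:
                h = nn.relu(bottleneck(nn.channel_norm(x)))
                x = np.concatenate([x, grow(h)], axis=1)
            if i < len(self.transitions):
                x = nn.avgpool2(self.transitions[i](nn.channel_norm(x)))
        tap = nn.global_avgpool(nn.relu(nn.channel_norm(x)))  # 1920
        return {"avg_pool": tap}, self.fc.forward(tap.astype(np.float32))

    def forward_logits(self, x):
        return self._taps(x)[1]

    def tap_features(self, x):
        return self._taps(x)[0]["avg_pool"]


_BUILDERS = {
    "tiny": TinyBackbone,
    "squeezenet": SqueezeNet,
    "googlenet": lambda seed=0: GoogLeNet(seed, variant_v1=False),
    "googlenet_v1": lambda seed=0: GoogLeNet(seed, variant_v1=True),
    "resnet18": ResNet18,
    "vgg16": VGG16,
    "densenet201": DenseNet201,
}


def build_backbone(name: str, seed: int = 0):
    """Construct a backbone by registry name (seeded initialization)."""
    if name not in _BUILDERS:
        raise ValueError(f"unknown backbone {name!r}; "
                         f"known: {sorted(_BUILDERS)}")
    return _BUILDERS[name](seed)


# ---------------------------------------------------------------------------
# Training and inference

def _channel_arrays(patches, channel: str):
    if channel not in ("bmode", "ceus"):
        raise ValueError("channel must be 'bmode' or 'ceus'")
    return [getattr(p, channel) for p in patches]


def _label_indices(patches):
    return np.array([LABEL_INDEX[p.label] for p in patches])


def _augment_array(img: np.ndarray, rng: np.random.Generator,
                   max_shift: int = 5) -> np.ndarray:
    out = img
    if rng.integers(0, 2):
        out = out[:, ::-1]
    if rng.integers(0, 2):
        out = out[::-1, :]
    dr, dc = (int(v) for v in rng.integers(-max_shift, max_shift + 1, size=2))
    return translate_reflect(np.ascontiguousarray(out), dr, dc)


def train_branch(model: TinyBackbone, patches, channel: str,
                 config: TrainConfig | None = None) -> TinyBackbone:
    """Train a single-modality branch with SGD momentum + cross-entropy.

    Requires both classes in the training set.  Per-epoch loss and
    training accuracy are appended to ``model.history``.  Deterministic
    given ``config.seed``.
    """
    config = config or TrainConfig()
    y = _label_indices(patches)
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    arrays = _channel_arrays(patches, channel)
    rng = np.random.default_rng(config.seed)
    opt = nn.SGDMomentum(model.net.params_grads(),
                         learning_rate=config.learning_rate,
                         momentum=config.momentum)
    n = len(arrays)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses, correct = [], 0
        for start in range(0, n, config.minibatch):
            idx = order[start:start + config.minibatch]
            imgs = [arrays[i] for i in idx]
            if config.augmentation:
                imgs = [_augment_array(im, rng) for im in imgs]
            xb = prepare_batch(imgs, model.spec.native_input, 1)
            yb = y[idx]
            logits = model.forward_logits(xb)
            loss, dlogits = nn.softmax_cross_entropy(logits, yb)
            model.net.backward(dlogits)
            opt.step()
            losses.append(loss)
            correct += int((logits.argmax(axis=1) == yb).sum())
        model.history.append({"epoch": epoch, "loss": float(np.mean(losses)),
                              "accuracy": correct / n})
    return model


def extract_features(model, patches, channel: str, **kwargs) -> np.ndarray:
    """Tap-layer feature vectors, one row per patch (order preserved)."""
    x = prepare_batch(_channel_arrays(patches, channel),
                      model.spec.native_input, model.n_channels)
    feats = []
    for start in range(0, len(x), 32):
        feats.append(np.asarray(model.tap_features(x[start:start + 32],
                                                   **kwargs), dtype=float))
    return np.concatenate(feats, axis=0)


def predict_probabilities(model, patches, channel: str) -> np.ndarray:
    """Softmax class probabilities, columns ordered [HCC, PAR]."""
    x = prepare_batch(_channel_arrays(patches, channel),
                      model.spec.native_input, model.n_channels)
    probs = []
    for start in range(0, len(x), 32):
        logits = model.forward_logits(x[start:start + 32])
        probs.append(nn.softmax(np.asarray(logits, dtype=float)))
    return np.concatenate(probs, axis=0)


def activation_map(feature_vector: np.ndarray,
                   target_shape: tuple[int, int]) -> np.ndarray:
    """Reshape a tap vector row-major into a min-max scaled 8-bit image.

    A constant vector (degenerate min-max) maps to all zeros.
    """
    v = np.asarray(feature_vector, dtype=float).ravel()
    h, w = target_shape
    if h * w != v.size:
        raise ValueError(f"cannot reshape length {v.size} to {h}x{w}")
    lo, hi = v.min(), v.max()
    if hi - lo < 1e-12:
        return np.zeros((h, w), dtype=np.uint8)
    scaled = (v - lo) / (hi - lo) * 255.0
    return np.rint(scaled).reshape(h, w).astype(np.uint8)
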