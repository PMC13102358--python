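"""Residual window classifier.

The default ``paper`` preset follows the ResNet-34 layout: a 7x7
convolution with batch normalization, ReLU and 3x3 max pooling, then 16
basic residual blocks (two 3x3 convolutions each) in four stages of
(3, 4, 6, 3) blocks at widths (64, 128, 256, 512) with identity or
1x1-projection skip connections, finishing with global average pooling and a
fully connected four-unit head.  The ``desk`` preset keeps the identical
structure at one block per stage and reduced widths so CPU-scale training
exercises the same code path.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .layers import (
    BatchNorm2d,
    Conv2d,
    GlobalAvgPool,
    Linear,
    MaxPool2d,
    ReLU,
    softmax,
)

PRESETS = {
    "paper": {"blocks": (3, 4, 6, 3), "widths": (64, 128, 256, 512)},
    "desk": {"blocks": (1, 1, 1, 1), "widths": (8, 16, 32, 64)},
}


class BasicBlock:
    """conv3x3-BN-ReLU-conv3x3-BN plus identity/projection skip, ReLU."""

    def __init__(self, cin, cout, stride, rng):
        self.conv1 = Conv2d(cin, cout, 3, stride=stride, pad=1, rng=rng)
        self.bn1 = BatchNorm2d(cout)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(cout, cout, 3, stride=1, pad=1, rng=rng)
        self.bn2 = BatchNorm2d(cout)
        self.relu2 = ReLU()
        if stride != 1 or cin != cout:
            self.proj: Conv2d | None = Conv2d(cin, cout, 1, stride=stride, rng=rng)
            self.proj_bn: BatchNorm2d | None = BatchNorm2d(cout)
        else:
            self.proj = None
            self.proj_bn = None

    def layers(self):
        out = [self.conv1, self.bn1, self.relu1, self.conv2, self.bn2, self.relu2]
        if self.proj is not None:
            out += [self.proj, self.proj_bn]
        return out

    def forward(self, x, train=False):
        out = self.relu1.forward(self.bn1.forward(self.conv1.forward(x, train), train))
        out = self.bn2.forward(self.conv2.forward(out, train), train)
        if self.proj is not None:
            skip = self.proj_bn.forward(self.proj.forward(x, train), train)
        else:
            skip = x
        return self.relu2.forward(out + skip, train)

    def backward(self, dout):
        d = self.relu2.backward(dout)
        dmain = self.bn2.backward(d)
        dmain = self.conv2.backward(dmain)
        dmain = self.conv1.backward(self.bn1.backward(self.relu1.backward(dmain)))
        if self.proj is not None:
            dskip = self.proj.backward(self.proj_bn.backward(d))
        else:
            dskip = d
        return dmain + dskip


class ResNetClassifier:
    """Four-class residual network over (2, H, W) binary window tensors."""

    MIN_SPATIAL = 4

    def __init__(self, input_shape, blocks=(3, 4, 6, 3), widths=(64, 128, 256, 512),
                 n_classes=4, seed=0):
        c, h, w = input_shape
        if h < self.MIN_SPATIAL or w < self.MIN_SPATIAL:
            raise ValueError(
                f"input spatial dimensions {h}x{w} too small for the pooling "
                f"stack; minimum is {self.MIN_SPATIAL}x{self.MIN_SPATIAL}"
            )
        if len(blocks) != len(widths):
            raise ValueError("blocks and widths must have equal length")
        self.input_shape = tuple(input_shape)
        self.config = {
            "input_shape": list(input_shape),
            "blocks": list(blocks),
            "widths": list(widths),
            "n_classes": n_classes,
            "seed": seed,
        }
        rng = np.random.default_rng(seed)
        self.conv1 = Conv2d(c, widths[0], 7, stride=2, pad=3, rng=rng)
        self.bn1 = BatchNorm2d(widths[0])
        self.relu1 = ReLU()
        self.pool = MaxPool2d(3, stride=2, pad=1)
        self.stages: list[list[BasicBlock]] = []
        cin = widths[0]
        for stage_idx, (n_blocks, width) in enumerate(zip(blocks, widths)):
            stage = []
            for b in range(n_blocks):
                stride = 2 if (stage_idx > 0 and b == 0) else 1
                stage.append(BasicBlock(cin, width, stride, rng))
                cin = width
            self.stages.append(stage)
        self.gap = GlobalAvgPool()
        self.fc = Linear(cin, n_classes, rng=rng)

    # ------------------------------------------------------------------
    @property
    def n_residual_blocks(self) -> int:
        return sum(len(s) for s in self.stages)

    def _layers(self):
        out = [self.conv1, self.bn1, self.relu1, self.pool]
        for stage in self.stages:
            for block in stage:
                out.extend(block.layers())
        out += [self.gap, self.fc]
        return out

    def named_parameters(self):
        for i, layer in enumerate(self._layers()):
            for key, p in layer.params.items():
                yield f"layer{i}.{key}", p, layer.grads.get(key)

    def forward(self, x, train=False):
        if x.shape[1:] != self.input_shape:
            raise ValueError(
                f"input shape {x.shape[1:]} does not match network input "
                f"{self.input_shape}"
            )
        x = np.ascontiguousarray(x, dtype=np.float32)
        out = self.pool.forward(
            self.relu1.forward(self.bn1.forward(self.conv1.forward(x, train), train)),
            train,
        )
        for stage in self.stages:
            for block in stage:
                out = block.forward(out, train)
        return self.fc.forward(self.gap.forward(out, train), train)

    def backward(self, dlogits):
        d = self.gap.backward(self.fc.backward(dlogits))
        for stage in reversed(self.stages):
            for block in reversed(stage):
                d = block.backward(d)
        d = self.pool.backward(d)
        return self.conv1.backward(self.bn1.backward(self.relu1.backward(d)))

    def predict_proba(self, x, batch_size=64) -> np.ndarray:
        """Softmax class probabilities, batch order preserved."""
        out = []
        for i in range(0, len(x), batch_size):
            out.append(softmax(self.forward(x[i : i + batch_size], train=False)))
        return np.concatenate(out, axis=0) if out else np.empty((0, self.config["n_classes"]))

    # ------------------------------------------------------------------
    # (de)serialization
    # ------------------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for i, layer in enumerate(self._layers()):
            for key, p in layer.params.items():
                state[f"layer{i}.{key}"] = p.copy()
            for key, b in layer.buffers.items():
                state[f"layer{i}.buf.{key}"] = b.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self._layers()):
            for key in layer.params:
                layer.params[key] = state[f"layer{i}.{key}"].copy()
            for key in layer.buffers:
                layer.buffers[key] = state[f"layer{i}.buf.{key}"].copy()

    def save(self, path: str | Path, class_labels=None, extra=None) -> None:
        from .. import CLASS_LABELS

        meta = {
            "schema_version": 1,
            "config": self.config,
            "class_labels": list(class_labels or CLASS_LABELS),
            "extra": extra or {},
        }
        arrays = {k.replace(".", "__"): v for k, v in self.state_dict().items()}
        arrays["__meta__"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> tuple["ResNetClassifier", dict]:
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            state = {
                k.replace("__", "."): data[k] for k in data.files if k != "__meta__"
            }
        cfg = meta["config"]
        net = cls(
            tuple(cfg["input_shape"]),
            blocks=tuple(cfg["blocks"]),
            widths=tuple(cfg["widths"]),
            n_classes=cfg["n_classes"],
            seed=cfg["seed"],
        )
        net.load_state_dict(state)
        return net, meta


def build_network(input_shape, preset: str = "paper", seed: int = 0) -> ResNetClassifier:
    """Construct the residual classifier for ``input_shape`` = (2, H, W)."""
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    spec = PRESETS[preset]
    return ResNetClassifier(
        input_shape, blocks=spec["blocks"], widths=spec["widths"], seed=seed
    )
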