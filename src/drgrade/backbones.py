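"""Backbone contract and the two tiny reference members.

The ensemble is agnostic to its members: anything exposing the contract
(5-way logits plus named convolutional target maps with class-score
gradients) can join. Two small reference backbones ship for desk-scale
work: a plain four-block net with a single explanation layer, and a
dual-stage net whose class scores are the *sum* of two heads attached at
different depths, so its explanation is the average of two Grad-CAMs.
"""

from __future__ import annotations

import json
from abc import ABC, abstractmethod
from pathlib import Path

import numpy as np

from drgrade.nn import AvgMaxPool, Conv2d, Dense, MaxPool2, ReLU


class BackboneContract(ABC):
    """What the ensemble and the explainer need from a member network."""

    name: str
    input_side: int
    target_layers: list[str]

    @abstractmethod
    def forward(self, x: np.ndarray) -> tuple[dict[str, np.ndarray], np.ndarray]:
        """Return ({target_layer: feature maps (N, K, h, w)}, logits (N, 5))."""

    @abstractmethod
    def class_gradients(self, x: np.ndarray, class_idx: int) -> dict[str, np.ndarray]:
        """d(class score)/d(feature maps) for each target layer."""

    def preprocess(self, pixels: np.ndarray) -> np.ndarray:
        """uint8 HxWx3 (already at input_side) -> float32 CHW in [0, 1]."""
        return (pixels.astype(np.float32) / 255.0).transpose(2, 0, 1)


class TinyConvNet(BackboneContract):
    """Four conv blocks, GAP, 5-way head; one explanation layer."""

    ARCH = "tiny_conv"

    def __init__(self, name: str = "member_A", input_side: int = 96, seed: int = 0,
                 width: int = 8):
        rng = np.random.default_rng(seed)
        self.name = name
        self.input_side = input_side
        self.width = width
        w = width
        self.conv1, self.relu1, self.pool1 = Conv2d(3, w, rng=rng), ReLU(), MaxPool2()
        self.conv2, self.relu2, self.pool2 = Conv2d(w, 2 * w, rng=rng), ReLU(), MaxPool2()
        self.conv3, self.relu3, self.pool3 = Conv2d(2 * w, 4 * w, rng=rng), ReLU(), MaxPool2()
        self.conv4, self.relu4 = Conv2d(4 * w, 4 * w, rng=rng), ReLU()
        self.gap = AvgMaxPool()
        self.head = Dense(8 * w, 5, rng=rng)
        self.target_layers = ["features"]
        self._blocks = [self.conv1, self.relu1, self.pool1, self.conv2, self.relu2,
                        self.pool2, self.conv3, self.relu3, self.pool3,
                        self.conv4, self.relu4]

    # -- contract ----------------------------------------------------------
    def forward(self, x):
        a = x
        for layer in self._blocks:
            a = layer.forward(a)
        feats = a
        logits = self.head.forward(self.gap.forward(feats))
        return {"features": feats}, logits

    def class_gradients(self, x, class_idx):
        maps, logits = self.forward(x)
        donehot = np.zeros_like(logits)
        donehot[:, class_idx] = 1.0
        dgap = self.head.backward(donehot)
        dfeats = self.gap.backward(dgap)
        return {"features": dfeats}

    # -- training ----------------------------------------------------------
    def parameters(self):
        out = []
        for layer in self._blocks + [self.head]:
            out.extend(getattr(layer, "params", []))
        return out

    def backward_from_logits(self, dlogits):
        da = self.gap.backward(self.head.backward(dlogits))
        for layer in reversed(self._blocks):
            da = layer.backward(da)
        return da

    # -- persistence -------------------------------------------------------
    def state_arrays(self):
        arrays = {}
        for i, (value, _) in enumerate(self.parameters()):
            arrays[f"p{i}"] = value
        return arrays

    def load_state_arrays(self, arrays):
        for i, (value, _) in enumerate(self.parameters()):
            value[...] = arrays[f"p{i}"]

    def config(self):
        return {"arch": self.ARCH, "name": self.name, "input_side": self.input_side,
                "width": self.width}


class DualStageNet(BackboneContract):
    """Member whose logits sum two heads attached at different stages.

    The class score is ``head_1(GAP(stage1)) + head_2(GAP(stage2))`` where
    stage2 deepens stage1; the member therefore exposes two target layers
    and its Grad-CAM explanation averages both stage heatmaps.
    """

    ARCH = "dual_stage"

    def __init__(self, name: str = "member_B", input_side: int = 96, seed: int = 1,
                 width: int = 8):
        rng = np.random.default_rng(seed)
        self.name = name
        self.input_side = input_side
        self.width = width
        w = width
        self.conv1, self.relu1, self.pool1 = Conv2d(3, w, rng=rng), ReLU(), MaxPool2()
        self.conv2, self.relu2, self.pool2 = Conv2d(w, 2 * w, rng=rng), ReLU(), MaxPool2()
        self.conv3, self.relu3 = Conv2d(2 * w, 4 * w, rng=rng), ReLU()  # -> stage1
        self.pool3 = MaxPool2()
        self.conv4, self.relu4 = Conv2d(4 * w, 4 * w, rng=rng), ReLU()  # -> stage2
        self.gap1, self.gap2 = AvgMaxPool(), AvgMaxPool()
        self.head1 = Dense(8 * w, 5, rng=rng)
        self.head2 = Dense(8 * w, 5, rng=rng)
        self.target_layers = ["stage1", "stage2"]
        self._trunk1 = [self.conv1, self.relu1, self.pool1, self.conv2, self.relu2,
                        self.pool2, self.conv3, self.relu3]
        self._trunk2 = [self.pool3, self.conv4, self.relu4]

    def forward(self, x):
        a = x
        for layer in self._trunk1:
            a = layer.forward(a)
        stage1 = a
        for layer in self._trunk2:
            a = layer.forward(a)
        stage2 = a
        logits = self.head1.forward(self.gap1.forward(stage1)) + self.head2.forward(
            self.gap2.forward(stage2)
        )
        return {"stage1": stage1, "stage2": stage2}, logits

    def _stage_gradients(self, dlogits):
        """Gradients w.r.t. stage activations; stage1 gets both the direct
        head path and the path through the deeper trunk."""
        dstage2 = self.gap2.backward(self.head2.backward(dlogits))
        da = dstage2
        for layer in reversed(self._trunk2):
            da = layer.backward(da)
        dstage1 = da + self.gap1.backward(self.head1.backward(dlogits))
        return dstage1, dstage2

    def class_gradients(self, x, class_idx):
        maps, logits = self.forward(x)
        donehot = np.zeros_like(logits)
        donehot[:, class_idx] = 1.0
        dstage1, dstage2 = self._stage_gradients(donehot)
        return {"stage1": dstage1, "stage2": dstage2}

    def parameters(self):
        out = []
        for layer in self._trunk1 + self._trunk2 + [self.head1, self.head2]:
            out.extend(getattr(layer, "params", []))
        return out

    def backward_from_logits(self, dlogits):
        dstage1, _ = self._stage_gradients(dlogits)
        da = dstage1
        for layer in reversed(self._trunk1):
            da = layer.backward(da)
        return da

    def state_arrays(self):
        return {f"p{i}": value for i, (value, _) in enumerate(self.parameters())}

    def load_state_arrays(self, arrays):
        for i, (value, _) in enumerate(self.parameters()):
            value[...] = arrays[f"p{i}"]

    def config(self):
        return {"arch": self.ARCH, "name": self.name, "input_side": self.input_side,
                "width": self.width}


_ARCHS = {TinyConvNet.ARCH: TinyConvNet, DualStageNet.ARCH: DualStageNet}


def default_members(input_side: int = 96, seed: int = 0, width: int = 8):
    """The standard desk-scale two-member ensemble."""
    return [
        TinyConvNet(name="member_A", input_side=input_side, seed=seed, width=width),
        DualStageNet(name="member_B", input_side=input_side, seed=seed + 1, width=width),
    ]


def save_members(members, out_dir: str | Path) -> Path:
    """Serialize member weights plus an index naming members/target layers."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    index = {"members": []}
    for m in members:
        weights_file = f"{m.name}.npz"
        np.savez(out_dir / weights_file, **m.state_arrays())
        entry = dict(m.config())
        entry.update({"weights": weights_file, "target_layers": m.target_layers})
        index["members"].append(entry)
    (out_dir / "index.json").write_text(json.dumps(index, indent=2))
    return out_dir


def load_members(model_dir: str | Path):
    model_dir = Path(model_dir)
    index = json.loads((model_dir / "index.json").read_text())
    members = []
    for entry in index["members"]:
        cls = _ARCHS[entry["arch"]]
        m = cls(name=entry["name"], input_side=entry["input_side"], width=entry["width"])
        with np.load(model_dir / entry["weights"]) as data:
            m.load_state_arrays(dict(data))
        members.append(m)
    return members
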