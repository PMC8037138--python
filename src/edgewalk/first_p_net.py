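"""First-edge-point predictor.

A reduced bottleneck-residual encoder whose four stage outputs are
projected, resized to a common half-resolution grid and concatenated;
a small convolutional head then produces a 1/8-resolution edge-point
score map. The argmax cell of that map, mapped back through the cell
centre, is the initial point handed to the tracing agent.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .metrics import Contour, normalize_symmetric, sobel_edge_map
from .nn import (
    Adam,
    BatchNorm2d,
    BilinearResize,
    Bottleneck,
    Conv2d,
    MaxPool2d,
    Module,
    ReLU,
    Sequential,
    bce_with_logits,
    conv_bn_relu,
)


@dataclass
class FirstPNetConfig:
    input_size: int = 368
    stage_blocks: tuple[int, int, int, int] = (2, 2, 2, 2)
    stem_channels: int = 64
    stage_planes: tuple[int, int, int, int] = (64, 128, 256, 512)
    fusion_channels: int = 64
    head_channels: int = 16
    scale: int = 8
    learning_rate: float = 1e-5
    batch_size: int = 1
    epochs: int = 10
    pos_weight: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.input_size % self.scale != 0:
            raise ValueError(f"input_size must be divisible by {self.scale}")

    @property
    def prob_map_size(self) -> int:
        return self.input_size // self.scale


def desk_first_p_config(**overrides) -> FirstPNetConfig:
    """Small-width profile that trains in minutes on one CPU core."""
    defaults = dict(
        input_size=96,
        stem_channels=8,
        stage_planes=(4, 8, 8, 8),
        fusion_channels=8,
        head_channels=8,
        learning_rate=3e-3,
        epochs=10,
        pos_weight=8.0,
    )
    defaults.update(overrides)
    return FirstPNetConfig(**defaults)


class FirstPNet(Module):
    def __init__(self, cfg: FirstPNetConfig, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(cfg.seed)
        self.cfg = cfg
        c = cfg.stem_channels
        self.stem = Sequential(
            Conv2d(3, c, 7, stride=2, padding=3, bias=False, rng=rng),
            BatchNorm2d(c),
            ReLU(),
            MaxPool2d(3, 2, padding=1),
        )
        self.stages: list[Sequential] = []
        cin = c
        for i, (planes, blocks) in enumerate(zip(cfg.stage_planes, cfg.stage_blocks)):
            stride = 1 if i == 0 else 2
            mods = [Bottleneck(cin, planes, stride=stride, rng=rng)]
            cin = planes * Bottleneck.expansion
            for _ in range(blocks - 1):
                mods.append(Bottleneck(cin, planes, stride=1, rng=rng))
            self.stages.append(Sequential(*mods))
        fuse_size = cfg.input_size // 2
        self.projections = [
            conv_bn_relu(cfg.stage_planes[i] * Bottleneck.expansion, cfg.fusion_channels, 3, rng=rng)
            for i in range(4)
        ]
        self.resizers = [BilinearResize(fuse_size, fuse_size) for _ in range(4)]
        hc = cfg.head_channels
        self.head = Sequential(
            *conv_bn_relu(4 * cfg.fusion_channels, hc, 3, stride=2, rng=rng).items,
            *conv_bn_relu(hc, hc, 3, stride=1, rng=rng).items,
            *conv_bn_relu(hc, hc, 3, stride=2, rng=rng).items,
            *conv_bn_relu(hc, hc, 3, stride=1, rng=rng).items,
            Conv2d(hc, 1, 1, rng=rng),
        )

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """(N, 3, S, S) in [-1, 1] -> (N, S/8, S/8) score map."""
        s = self.cfg.input_size
        if x.ndim != 4 or x.shape[1] != 3 or x.shape[2] != s or x.shape[3] != s:
            raise ValueError(f"expected (N, 3, {s}, {s}) input, got {x.shape}")
        t = self.stem.forward(x, train)
        taps = []
        for stage in self.stages:
            t = stage.forward(t, train)
            taps.append(t)
        branches = [
            rz.forward(proj.forward(tap, train), train)
            for rz, proj, tap in zip(self.resizers, self.projections, taps)
        ]
        self._split = [b.shape[1] for b in branches]
        cat = np.concatenate(branches, axis=1)
        out = self.head.forward(cat, train)
        return out[:, 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dcat = self.head.backward(dy[:, None])
        edges = np.cumsum([0] + self._split)
        dtaps = [
            proj.backward(rz.backward(dcat[:, e0:e1]))
            for rz, proj, (e0, e1) in zip(
                self.resizers, self.projections, zip(edges[:-1], edges[1:])
            )
        ]
        d = dtaps[3]
        for i in (3, 2, 1):
            d = self.stages[i].backward(d) + dtaps[i - 1]
        d = self.stages[0].backward(d)
        return self.stem.backward(d)


def build_first_p_input(gray: np.ndarray) -> np.ndarray:
    """3-channel input [gray, Sobel(gray), gray], each mapped to [-1, 1].

    The score map does not exist yet at first-point time, so the third
    channel duplicates the grayscale layer.
    """
    g = normalize_symmetric(gray)
    s = normalize_symmetric(sobel_edge_map(gray))
    return np.stack([g, s, g], axis=0)


def first_p_forward(net: FirstPNet, gray: np.ndarray) -> np.ndarray:
    """Inference: grayscale image -> (S/8, S/8) score map."""
    return net.forward(build_first_p_input(gray)[None], train=False)[0]


def select_first_point(prob_map: np.ndarray, scale: int = 8) -> tuple[int, int]:
    """Argmax cell mapped to full resolution at the cell centre.

    Ties break at the smallest flattened index.
    """
    pm = np.asarray(prob_map)
    if not np.all(np.isfinite(pm)):
        raise ValueError("probability map contains non-finite values")
    idx = int(pm.argmax())
    r, c = divmod(idx, pm.shape[1])
    return (scale * r + scale // 2, scale * c + scale // 2)


def make_first_p_target(gt: Contour, input_size: int, scale: int = 8) -> np.ndarray:
    """Binary (S/8, S/8) map: 1 in every cell containing a gt contour point."""
    if len(gt) == 0:
        raise ValueError("ground-truth contour is empty")
    size = input_size // scale
    target = np.zeros((size, size), dtype=np.float64)
    target[gt.points[:, 0] // scale, gt.points[:, 1] // scale] = 1.0
    return target


def train_first_p(
    dataset: list[tuple[np.ndarray, Contour]],
    cfg: FirstPNetConfig,
    progress: bool = False,
) -> tuple[FirstPNet, list[float]]:
    """Fit the predictor with per-pixel binary cross-entropy and Adam.

    Returns the trained network and the per-epoch mean loss curve.
    """
    if not dataset:
        raise ValueError("dataset is empty")
    rng = np.random.default_rng(cfg.seed)
    net = FirstPNet(cfg, rng=rng)
    opt = Adam(net.parameters(), lr=cfg.learning_rate)
    inputs = [build_first_p_input(g)[None] for g, _ in dataset]
    targets = [make_first_p_target(c, cfg.input_size, cfg.scale)[None] for _, c in dataset]
    curve: list[float] = []
    order = np.arange(len(dataset))
    iterator = range(cfg.epochs)
    if progress:
        from tqdm import tqdm

        iterator = tqdm(iterator, desc="train-first")
    for _ in iterator:
        rng.shuffle(order)
        losses = []
        for i in order:
            scores = net.forward(inputs[i], train=True)
            loss, dscores = bce_with_logits(scores, targets[i], pos_weight=cfg.pos_weight)
            opt.zero_grad()
            net.backward(dscores)
            opt.step()
            losses.append(loss)
        curve.append(float(np.mean(losses)))
    return net, curve


# -- oracle stubs (perfectly informed first-point provider) ----------------

def oracle_prob_map(gt: Contour, input_size: int, scale: int = 8, blur: float = 1.0) -> np.ndarray:
    """A stand-in score map built from the gt contour itself.

    Emulates a converged first-point predictor so the tracing agent can
    be trained and evaluated in isolation.
    """
    target = make_first_p_target(gt, input_size, scale)
    if blur > 0:
        target = ndimage.gaussian_filter(target, blur)
    return target


def oracle_first_point(gt: Contour, rng: np.random.Generator | None = None) -> tuple[int, int]:
    """A gt contour point (the first, or a random one when rng is given)."""
    if rng is None:
        return tuple(int(v) for v in gt.points[0])
    return tuple(int(v) for v in gt.points[rng.integers(len(gt.points))])


# -- checkpoints -----------------------------------------------------------

def save_first_p(net: FirstPNet, path: str | Path) -> None:
    state = net.state_dict()
    state["config_json"] = np.frombuffer(
        json.dumps(asdict(net.cfg)).encode(), dtype=np.uint8
    )
    np.savez(Path(path), **state)


def load_first_p(path: str | Path) -> FirstPNet:
    with np.load(Path(path)) as data:
        raw = {k: data[k] for k in data.files}
    cfg_dict = json.loads(bytes(raw.pop("config_json")).decode())
    cfg_dict["stage_blocks"] = tuple(cfg_dict["stage_blocks"])
    cfg_dict["stage_planes"] = tuple(cfg_dict["stage_planes"])
    cfg = FirstPNetConfig(**cfg_dict)
    net = FirstPNet(cfg)
    net.load_state_dict(raw)
    return net
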