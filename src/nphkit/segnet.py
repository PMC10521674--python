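"""Probability-map-augmented 3-D UNet for 6-class CT brain segmentation.

The encoder halves the grid four times (so input shapes must be
divisible by 16) while doubling feature channels; the decoder mirrors it
with skip concatenations, two auxiliary 1x1x1-conv taps that are summed
and fed forward, and a separate two-convolution branch that ingests the
two spatial probability maps (ventricle, subarachnoid) and joins the
main stream at the last upsampling level.  Every 3x3x3 convolution is
followed by group normalisation.  The head produces a 6-channel softmax:
background, ventricle, subarachnoid, gray-white, cerebellar CSF,
cerebellar gray-white (skull voxels train as background).

Input CT intensities are clipped to the annotation viewing window
[-980, 80] HU and min-max scaled; the bounds are configurable because
relative density information is deliberately preserved.

Training uses Adam (default lr 1e-3, weight decay 1e-4, dropout 0.5) and
voxelwise cross-entropy, either plain or restricted to the hardest
fraction of voxels per image ("hard per-image" mode, default fraction
0.7).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
from sklearn.base import BaseEstimator

from . import _nn
from ._nn import Tensor
from .errors import InvariantError
from .types import (
    N_SEG_CLASSES,
    SEG_CLASS_NAMES,
    SKULL_LABEL,
    LabelVolume,
    ProbabilityMapSet,
    VolumeGrid,
)


@dataclass
class SegNetConfig:
    input_shape: tuple[int, int, int] = (64, 64, 32)
    base_channels: int = 8
    n_classes: int = N_SEG_CLASSES
    n_probmaps: int = 2
    groups: int = 4
    use_probmaps: bool = True
    clip_window: tuple[float, float] = (-980.0, 80.0)

    def validate(self):
        if len(self.input_shape) != 3 or any(s % 16 != 0 or s <= 0 for s in self.input_shape):
            raise InvariantError(f"input shape must be divisible by 16, got {self.input_shape}")
        if self.n_classes != N_SEG_CLASSES:
            raise InvariantError(f"the segmentation head has {N_SEG_CLASSES} classes")
        if self.n_probmaps != 2:
            raise InvariantError("exactly 2 probability maps (ventricle, subarachnoid)")
        if self.base_channels < 1 or self.groups < 1:
            raise InvariantError("base_channels and groups must be >= 1")
        if self.clip_window[0] >= self.clip_window[1]:
            raise InvariantError("clip window must satisfy lo < hi")


@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    weight_decay: float = 1e-4
    dropout: float = 0.5
    epochs: int = 300
    loss_mode: str = "hard"   # "plain" | "hard"
    hard_fraction: float = 0.7
    seed: int = 0

    def validate(self):
        if self.learning_rate <= 0:
            raise InvariantError("learning rate must be > 0")
        if self.epochs < 1:
            raise InvariantError("epochs must be >= 1")
        if not 0 <= self.dropout < 1:
            raise InvariantError("dropout must be in [0, 1)")
        if self.loss_mode not in ("plain", "hard"):
            raise InvariantError("loss_mode must be 'plain' or 'hard'")
        if not 0 < self.hard_fraction <= 1:
            raise InvariantError("hard_fraction must be in (0, 1]")


def _he(rng, co, ci, k):
    fan_in = ci * k ** 3
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(co, ci, k, k, k))


class SegModel:
    """Parameter container + forward graph of the modified 3-D UNet."""

    n_levels = 4  # resolution levels below the input

    def __init__(self, cfg: SegNetConfig, seed: int = 0):
        cfg.validate()
        self.cfg = cfg
        B = cfg.base_channels
        rng = np.random.default_rng(seed)
        P = {}

        def conv(name, co, ci, k):
            P[f"{name}.w"] = _nn.parameter(_he(rng, co, ci, k))
            P[f"{name}.b"] = _nn.parameter(np.zeros(co))

        def gn(name, c):
            P[f"{name}.g"] = _nn.parameter(np.ones(c))
            P[f"{name}.beta"] = _nn.parameter(np.zeros(c))

        enc_ch = [B, 2 * B, 4 * B, 8 * B]
        ci = 1
        for i, co in enumerate(enc_ch, start=1):
            conv(f"enc{i}a", co, ci, 3); gn(f"enc{i}a.gn", co)
            conv(f"enc{i}b", co, co, 3); gn(f"enc{i}b.gn", co)
            ci = co
        # decoder blocks: (input ch, conv-out ch)
        self._dec_plan = [
            (8 * B, 4 * B),          # dec1 at S/16
            (4 * B + 4 * B, 2 * B),  # dec2 (concat enc3 skip)
            (2 * B + 2 * B, B),      # dec3 (concat enc2 skip)
            (B + B + B, B),          # dec4 (concat enc1 skip + aux sum)
        ]
        for j, (cin, cout) in enumerate(self._dec_plan, start=1):
            conv(f"dec{j}a", cout, cin, 3); gn(f"dec{j}a.gn", cout)
            conv(f"dec{j}b", cout, cout, 3); gn(f"dec{j}b.gn", cout)
            conv(f"dec{j}u", cout, cout, 1); gn(f"dec{j}u.gn", cout)
        conv("aux2", B, 2 * B, 1)
        conv("aux3", B, B, 1)
        if cfg.use_probmaps:
            conv("pm1", B, cfg.n_probmaps, 3); gn("pm1.gn", B)
            conv("pm2", B, B, 3); gn("pm2.gn", B)
        head_in = 2 * B if cfg.use_probmaps else B
        conv("head", B, head_in, 3); gn("head.gn", B)
        conv("out", cfg.n_classes, B, 1)
        self.params = P

    # ---------------------------------------------------------- forward
    def _block(self, name, x, stride_first=1):
        P = self.params
        g = self.cfg.groups
        h = _nn.conv3d(x, P[f"{name}a.w"], P[f"{name}a.b"], stride=stride_first)
        h = _nn.group_norm(h, P[f"{name}a.gn.g"], P[f"{name}a.gn.beta"], g)
        h = _nn.conv3d(h, P[f"{name}b.w"], P[f"{name}b.b"])
        h = _nn.group_norm(h, P[f"{name}b.gn.g"], P[f"{name}b.gn.beta"], g)
        return _nn.relu(h)

    def _dec_block(self, j, x, tap_sink=None):
        P = self.params
        g = self.cfg.groups
        h = _nn.conv3d(x, P[f"dec{j}a.w"], P[f"dec{j}a.b"])
        h = _nn.group_norm(h, P[f"dec{j}a.gn.g"], P[f"dec{j}a.gn.beta"], g)
        h = _nn.relu(h)
        if tap_sink is not None:
            tap_sink.append(h)  # aux branch taps the first rectifier output
        h = _nn.conv3d(h, P[f"dec{j}b.w"], P[f"dec{j}b.b"])
        h = _nn.group_norm(h, P[f"dec{j}b.gn.g"], P[f"dec{j}b.gn.beta"], g)
        h = _nn.relu(h)
        h = _nn.upsample2(h)
        h = _nn.conv3d(h, P[f"dec{j}u.w"], P[f"dec{j}u.b"])
        h = _nn.group_norm(h, P[f"dec{j}u.gn.g"], P[f"dec{j}u.gn.beta"], g)
        return _nn.relu(h)

    def forward_graph(self, x_np, pm_np=None, dropout_p=0.0, rng=None) -> Tensor:
        cfg = self.cfg
        P = self.params
        if tuple(x_np.shape) != tuple(cfg.input_shape):
            raise InvariantError(
                f"volume shape {x_np.shape} != model input shape {cfg.input_shape}"
            )
        if cfg.use_probmaps:
            if pm_np is None or pm_np.shape[0] != cfg.n_probmaps:
                raise InvariantError("this model needs exactly 2 probability-map channels")
            if tuple(pm_np.shape[1:]) != tuple(cfg.input_shape):
                raise InvariantError("probability maps must share the model input grid")
        x = Tensor(x_np[None])  # (1, D, H, W)

        def drop(t):
            return _nn.dropout(t, dropout_p, rng) if dropout_p > 0 else t

        e1 = self._block("enc1", x, stride_first=2)
        e2 = self._block("enc2", e1, stride_first=2)
        e3 = self._block("enc3", e2, stride_first=2)
        e4 = self._block("enc4", _nn.max_pool2(e3))
        e4 = drop(e4)

        taps: list[Tensor] = []
        d1 = drop(self._dec_block(1, e4))
        d2 = drop(self._dec_block(2, _nn.concat([d1, e3]), tap_sink=taps))
        d3 = drop(self._dec_block(3, _nn.concat([d2, e2]), tap_sink=taps))
        a2 = _nn.upsample2(_nn.conv3d(taps[0], P["aux2.w"], P["aux2.b"]))
        a3 = _nn.conv3d(taps[1], P["aux3.w"], P["aux3.b"])
        aux = _nn.upsample2(_nn.add(a2, a3))
        d4 = self._dec_block(4, _nn.concat([d3, e1, aux]))

        if cfg.use_probmaps:
            pm = Tensor(pm_np)
            pm = _nn.conv3d(pm, P["pm1.w"], P["pm1.b"])
            pm = _nn.group_norm(pm, P["pm1.gn.g"], P["pm1.gn.beta"], cfg.groups)
            pm = _nn.conv3d(pm, P["pm2.w"], P["pm2.b"])
            pm = _nn.group_norm(pm, P["pm2.gn.g"], P["pm2.gn.beta"], cfg.groups)
            pm = _nn.relu(pm)
            h = _nn.concat([d4, pm])
        else:
            h = d4
        h = _nn.conv3d(h, P["head.w"], P["head.b"])
        h = _nn.group_norm(h, P["head.gn.g"], P["head.gn.beta"], cfg.groups)
        h = _nn.relu(h)
        return _nn.conv3d(h, P["out.w"], P["out.b"])

    def bottleneck_shape(self):
        return tuple(s // 2 ** self.n_levels for s in self.cfg.input_shape)


def build_model(cfg: SegNetConfig, seed: int = 0) -> SegModel:
    """Construct the modified UNet with seeded He-normal initialisation."""
    return SegModel(cfg, seed=seed)


def preprocess_intensity(vol: VolumeGrid, clip_window=(-980.0, 80.0)) -> np.ndarray:
    """Clip to the annotation viewing window, then min-max scale to [0, 1]."""
    lo, hi = clip_window
    return (np.clip(np.asarray(vol.data, dtype=float), lo, hi) - lo) / (hi - lo)


def collapse_training_labels(lab: LabelVolume) -> np.ndarray:
    """Map the phantom legend onto the 6 softmax classes (skull -> background)."""
    t = lab.labels.astype(np.intp)
    return np.where(t >= SKULL_LABEL, 0, t)


def forward(model: SegModel, volume: VolumeGrid, probmaps: ProbabilityMapSet | None) -> np.ndarray:
    """Class-probability volume: (6, *input_shape), channels summing to 1."""
    x = preprocess_intensity(volume, model.cfg.clip_window)
    pm = probmaps.maps if (probmaps is not None and model.cfg.use_probmaps) else None
    logits = model.forward_graph(x, pm)
    return _nn.softmax(logits.data)


def predict_labels(model: SegModel, volume: VolumeGrid,
                   probmaps: ProbabilityMapSet | None) -> LabelVolume:
    """Per-voxel argmax segmentation (ties break to the lowest class index)."""
    probs = forward(model, volume, probmaps)
    legend = {i: SEG_CLASS_NAMES[i] for i in range(1, N_SEG_CLASSES)}
    return LabelVolume(
        labels=probs.argmax(axis=0).astype(np.uint8),
        legend=legend, spacing=volume.spacing, affine=volume.affine,
    )


def train(model: SegModel, pairs, tc: TrainConfig):
    """Fit on (volume, probmaps, labels) triples; returns (model, loss trace).

    One Adam step per volume per epoch; the loss trace holds the mean
    per-voxel cross-entropy of each epoch and has length ``tc.epochs``.
    Fully deterministic for a fixed seed.
    """
    tc.validate()
    if not pairs:
        raise InvariantError("training requires at least one (volume, probmaps, labels) triple")
    prepped = []
    for vol, pm, lab in pairs:
        x = preprocess_intensity(vol, model.cfg.clip_window)
        pm_np = pm.maps if (pm is not None and model.cfg.use_probmaps) else None
        prepped.append((x, pm_np, collapse_training_labels(lab)))
    opt = _nn.Adam(model.params, lr=tc.learning_rate, weight_decay=tc.weight_decay)
    rng = np.random.default_rng(tc.seed)
    hard = tc.hard_fraction if tc.loss_mode == "hard" else None
    trace = []
    for _ in range(tc.epochs):
        losses = []
        order = rng.permutation(len(prepped))
        for i in order:
            x, pm_np, tgt = prepped[i]
            opt.zero_grad()
            logits = model.forward_graph(x, pm_np, dropout_p=tc.dropout, rng=rng)
            loss = _nn.softmax_cross_entropy(logits, tgt, hard_fraction=hard)
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        trace.append(float(np.mean(losses)))
    return model, trace


# ------------------------------------------------------------ checkpoint

def save_checkpoint(model: SegModel, path) -> None:
    """Single-file .npz checkpoint with the config embedded as JSON."""
    arrays = {k: p.data for k, p in model.params.items()}
    cfg = asdict(model.cfg)
    np.savez(path, __config__=np.frombuffer(json.dumps(cfg).encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path) -> SegModel:
    with np.load(path) as z:
        cfg_raw = json.loads(bytes(z["__config__"]).decode())
        cfg_raw["input_shape"] = tuple(cfg_raw["input_shape"])
        cfg_raw["clip_window"] = tuple(cfg_raw["clip_window"])
        cfg = SegNetConfig(**cfg_raw)
        model = SegModel(cfg)
        for k in model.params:
            model.params[k].data = z[k].astype(np.float32)
    return model


# ------------------------------------------------------------- estimator

class UNetSegmenter3D(BaseEstimator):
    """scikit-learn style wrapper around the modified 3-D UNet.

    Parameters mirror SegNetConfig + TrainConfig; ``fit`` takes a list of
    VolumeGrid, a list of LabelVolume, and (optionally) per-subject
    ProbabilityMapSet priors.  Fitted attributes: ``model_``,
    ``loss_trace_``.
    """

    def __init__(self, base_channels=8, groups=4, use_probmaps=True,
                 clip_window=(-980.0, 80.0), learning_rate=1e-3,
                 weight_decay=1e-4, dropout=0.5, epochs=300,
                 loss_mode="hard", hard_fraction=0.7, seed=0):
        self.base_channels = base_channels
        self.groups = groups
        self.use_probmaps = use_probmaps
        self.clip_window = clip_window
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.dropout = dropout
        self.epochs = epochs
        self.loss_mode = loss_mode
        self.hard_fraction = hard_fraction
        self.seed = seed

    def fit(self, volumes, labels, probmaps=None):
        if not volumes or len(volumes) != len(labels):
            raise InvariantError("need equal, nonzero numbers of volumes and labels")
        if probmaps is None:
            probmaps = [None] * len(volumes)
        cfg = SegNetConfig(
            input_shape=tuple(volumes[0].shape),
            base_channels=self.base_channels, groups=self.groups,
            use_probmaps=self.use_probmaps, clip_window=tuple(self.clip_window),
        )
        model = build_model(cfg, seed=self.seed)
        tc = TrainConfig(
            learning_rate=self.learning_rate, weight_decay=self.weight_decay,
            dropout=self.dropout, epochs=self.epochs, loss_mode=self.loss_mode,
            hard_fraction=self.hard_fraction, seed=self.seed,
        )
        self.model_, self.loss_trace_ = train(
            model, list(zip(volumes, probmaps, labels)), tc
        )
        return self

    def predict(self, volumes, probmaps=None):
        if not hasattr(self, "model_"):
            raise InvariantError("estimator is not fitted")
        if probmaps is None:
            probmaps = [None] * len(volumes)
        return [predict_labels(self.model_, v, p) for v, p in zip(volumes, probmaps)]

    def predict_proba(self, volumes, probmaps=None):
        if not hasattr(self, "model_"):
            raise InvariantError("estimator is not fitted")
        if probmaps is None:
            probmaps = [None] * len(volumes)
        return [forward(self.model_, v, p) for v, p in zip(volumes, probmaps)]
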