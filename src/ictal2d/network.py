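"""The compound-scalable MBConv classification network.

The baseline architecture is the familiar 9-stage design: a 3x3 stem
convolution, seven MBConv stages, and a 1x1 convolution + global pooling +
fully-connected head. Larger variants are produced by compound scaling:
width (channel counts) multiplied by a width coefficient and rounded to
multiples of 8, depth (per-stage repeats) multiplied by a depth
coefficient and rounded up, and input resolution raised per level. Levels
0..7 reproduce the published scaling table; a ``tiny`` preset (64 px,
width 0.35, depth 0.5) exists solely so end-to-end tests and examples run
on one CPU in minutes and is not one of the published variants.

The "depth features" consumed by downstream classifiers are the pooled
penultimate representation — the layer before the classification head.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .nn import autograd as ag
from .nn.layers import ConvBNAct, Linear, MBConvBlock, Module
from .nn.optim import Adam

#: Per-level (input resolution, width coefficient, depth coefficient).
SCALING_TABLE: dict[int, tuple[int, float, float]] = {
    0: (224, 1.0, 1.0),
    1: (240, 1.0, 1.1),
    2: (260, 1.1, 1.2),
    3: (300, 1.2, 1.4),
    4: (380, 1.4, 1.8),
    5: (456, 1.6, 2.2),
    6: (528, 1.8, 2.6),
    7: (600, 2.0, 3.1),
}

BASE_FEATURE_DIM = 1280


@dataclass(frozen=True)
class StageSpec:
    """One stage of the architecture table."""

    operator: str  # "plain_conv" or "mbconv"
    expansion: int  # 1 or 6 (1 for plain conv stages)
    kernel: int  # 1, 3 or 5
    in_resolution: int
    out_channels: int
    layers: int
    stride_first: int  # 1 or 2

    def __post_init__(self) -> None:
        if self.operator not in ("plain_conv", "mbconv"):
            raise ValueError(f"unknown operator {self.operator!r}")
        if self.layers < 1:
            raise ValueError("layers must be >= 1")
        if self.operator == "mbconv" and self.expansion not in (1, 6):
            raise ValueError("mbconv expansion must be 1 or 6")
        if self.operator == "mbconv" and self.kernel not in (3, 5):
            raise ValueError("mbconv kernel must be 3 or 5")
        if self.stride_first not in (1, 2):
            raise ValueError("stride_first must be 1 or 2")


@dataclass(frozen=True)
class ScalingConfig:
    """Compound-scaling coefficients for one network level."""

    level: int | None
    input_resolution: int
    width_coefficient: float
    depth_coefficient: float
    allow_reduction: bool = False

    def __post_init__(self) -> None:
        if self.level is not None:
            expected = SCALING_TABLE.get(self.level)
            if expected is None:
                raise ValueError(f"level must be in 0..7, got {self.level}")
            got = (self.input_resolution, self.width_coefficient,
                   self.depth_coefficient)
            if got != expected:
                raise ValueError(
                    f"level {self.level} settings {got} do not match the "
                    f"scaling table {expected}"
                )

    @classmethod
    def from_level(cls, level: int) -> "ScalingConfig":
        res, w, d = SCALING_TABLE[level]
        return cls(level=level, input_resolution=res, width_coefficient=w,
                   depth_coefficient=d)

    @classmethod
    def tiny(cls) -> "ScalingConfig":
        """Desk-scale preset for CPU tests; not a published variant."""
        return cls(level=None, input_resolution=64, width_coefficient=0.35,
                   depth_coefficient=0.5, allow_reduction=True)


@dataclass(frozen=True)
class NetworkSpec:
    """The architecture induced by scaling the baseline."""

    stages: tuple[StageSpec, ...]
    input_resolution: int
    feature_dim: int
    num_classes: int = 2
    width_coefficient: float = 1.0
    depth_coefficient: float = 1.0


def baseline_spec() -> list[StageSpec]:
    """The 9-stage baseline architecture table (level 0).

    First strides are inferred from the resolution column: stride 2
    wherever the next stage's input resolution halves.
    """
    rows = [
        # operator, expansion, kernel, in_res, channels, layers
        ("plain_conv", 1, 3, 224, 32, 1),
        ("mbconv", 1, 3, 112, 16, 1),
        ("mbconv", 6, 3, 112, 24, 2),
        ("mbconv", 6, 5, 56, 40, 2),
        ("mbconv", 6, 3, 28, 80, 3),
        ("mbconv", 6, 5, 14, 112, 3),
        ("mbconv", 6, 5, 14, 192, 4),
        ("mbconv", 6, 3, 7, 320, 1),
        ("plain_conv", 1, 1, 7, 1280, 1),
    ]
    stages = []
    for i, (op, exp, k, res, ch, layers) in enumerate(rows):
        next_res = rows[i + 1][3] if i + 1 < len(rows) else res
        stride = 2 if next_res * 2 == res else 1
        stages.append(
            StageSpec(operator=op, expansion=exp, kernel=k, in_resolution=res,
                      out_channels=ch, layers=layers, stride_first=stride)
        )
    return stages


def round_filters(channels: float, width_coefficient: float = 1.0,
                  divisor: int = 8) -> int:
    """Scale a channel count and round to the nearest multiple of
    ``divisor``, never dropping below 90% of the unrounded value."""
    scaled = channels * width_coefficient
    new = max(divisor, int(scaled + divisor / 2) // divisor * divisor)
    if new < 0.9 * scaled:
        new += divisor
    return int(new)


def round_repeats(layers: int, depth_coefficient: float) -> int:
    return int(math.ceil(layers * depth_coefficient))


def scale_spec(baseline: list[StageSpec], cfg: ScalingConfig,
               num_classes: int = 2) -> NetworkSpec:
    """Apply compound scaling to the baseline architecture.

    Channel counts are width-scaled in every stage; repeats are
    depth-scaled in the MBConv stages only (stem and head always have one
    layer); input resolutions follow from the configured resolution and
    the stage strides. Coefficients below 1 are rejected unless the config
    opts in (the tiny test preset).
    """
    w, d = cfg.width_coefficient, cfg.depth_coefficient
    if (w < 1 or d < 1) and not cfg.allow_reduction:
        raise ValueError(
            f"scaling coefficients must be >= 1 (got width {w}, depth {d}); "
            "use the tiny preset for reduced test-scale networks"
        )
    stages = []
    res = cfg.input_resolution
    for st in baseline:
        layers = (round_repeats(st.layers, d) if st.operator == "mbconv"
                  else st.layers)
        stages.append(
            replace(
                st,
                in_resolution=res,
                out_channels=round_filters(st.out_channels, w),
                layers=layers,
            )
        )
        if st.stride_first == 2:
            res = math.ceil(res / 2)
    return NetworkSpec(
        stages=tuple(stages),
        input_resolution=cfg.input_resolution,
        feature_dim=round_filters(BASE_FEATURE_DIM, w),
        num_classes=num_classes,
        width_coefficient=w,
        depth_coefficient=d,
    )


def spec_for_level(level: int, num_classes: int = 2) -> NetworkSpec:
    return scale_spec(baseline_spec(), ScalingConfig.from_level(level),
                      num_classes)


def tiny_spec(num_classes: int = 2) -> NetworkSpec:
    return scale_spec(baseline_spec(), ScalingConfig.tiny(), num_classes)


class Network(Module):
    """The built network: stem -> MBConv stages -> head conv -> pool -> FC."""

    def __init__(self, spec: NetworkSpec, seed: int = 0,
                 se_ratio: float = 0.25, use_se: bool = True):
        rng = np.random.default_rng(seed)
        self.spec = spec
        self._seed = seed
        stem, *mb_stages, head = spec.stages
        self.stem = ConvBNAct(3, stem.out_channels, stem.kernel,
                              stem.stride_first, rng)
        blocks: list[MBConvBlock] = []
        self._stage_slices: list[tuple[int, int]] = []
        in_ch = stem.out_channels
        for st in mb_stages:
            first = len(blocks)
            for layer in range(st.layers):
                blocks.append(
                    MBConvBlock(
                        in_ch=in_ch,
                        out_ch=st.out_channels,
                        expansion=st.expansion,
                        kernel=st.kernel,
                        stride=st.stride_first if layer == 0 else 1,
                        rng=rng,
                        se_ratio=se_ratio,
                        use_se=use_se,
                    )
                )
                in_ch = st.out_channels
            self._stage_slices.append((first, len(blocks)))
        self.blocks = blocks
        self.head = ConvBNAct(in_ch, head.out_channels, head.kernel,
                              head.stride_first, rng)
        self.fc = Linear(spec.feature_dim, spec.num_classes, rng)

    # -- forward passes -----------------------------------------------------

    def forward_features(self, x: ag.Tensor, training: bool = False
                         ) -> ag.Tensor:
        """Pooled penultimate representation (the depth features)."""
        h = self.stem(x, training)
        for block in self.blocks:
            h = block(h, training)
        h = self.head(h, training)
        return ag.global_avg_pool(h)

    def forward(self, x: ag.Tensor, training: bool = False) -> ag.Tensor:
        return self.fc(self.forward_features(x, training), training)

    __call__ = forward

    def stage_output_sizes(self, resolution: int | None = None) -> list[int]:
        """Spatial size after the stem and after each MBConv stage, computed
        by a forward pass of a single input."""
        res = resolution or self.spec.input_resolution
        x = ag.Tensor(np.zeros((1, 3, res, res), dtype=np.float32))
        sizes = []
        h = self.stem(x)
        sizes.append(h.shape[2])
        for first, last in self._stage_slices:
            for block in self.blocks[first:last]:
                h = block(h)
            sizes.append(h.shape[2])
        return sizes

    def reinit_head(self, seed: int | None = None) -> None:
        rng = np.random.default_rng(self._seed if seed is None else seed)
        self.fc = Linear(self.spec.feature_dim, self.spec.num_classes, rng)

    def head_param_names(self) -> set[str]:
        return {f"fc.{name}" for name, _ in self.fc.named_parameters()}

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update(
            {name: b.copy() for name, b in self.named_buffers()}
        )
        return state

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        for name, value in state.items():
            if name in params:
                params[name].data = value.astype(np.float32).copy()
            elif name in buffers:
                buffers[name][...] = value
            else:
                raise KeyError(f"unknown parameter {name!r}")


def build_network(spec: NetworkSpec, seed: int = 0, **kwargs) -> Network:
    """Construct a network with deterministic weight initialization."""
    return Network(spec, seed=seed, **kwargs)


def _as_batch(batch) -> np.ndarray:
    from .representation import NetInput

    if isinstance(batch, np.ndarray):
        arr = batch
    else:
        arr = np.stack([
            b.tensor if isinstance(b, NetInput) else np.asarray(b)
            for b in batch
        ])
    if arr.ndim == 3:
        arr = arr[None]
    return arr.astype(np.float32)


def extract_depth_features(net: Network, batch, batch_size: int = 32
                           ) -> np.ndarray:
    """Pooled pre-head representation, one row of ``feature_dim`` per item."""
    arr = _as_batch(batch)
    res = net.spec.input_resolution
    if arr.shape[1:] != (3, res, res):
        raise ValueError(
            f"batch shape {arr.shape[1:]} does not match the network input "
            f"(3, {res}, {res}); expected resolution {res}"
        )
    out = []
    for i in range(0, arr.shape[0], batch_size):
        feats = net.forward_features(ag.Tensor(arr[i:i + batch_size]))
        out.append(feats.data)
    return np.concatenate(out, axis=0)


def predict_logits(net: Network, batch, batch_size: int = 32) -> np.ndarray:
    arr = _as_batch(batch)
    out = []
    for i in range(0, arr.shape[0], batch_size):
        out.append(net.forward(ag.Tensor(arr[i:i + batch_size])).data)
    return np.concatenate(out, axis=0)


# ---------------------------------------------------------------------------
# Pretrained weights
# ---------------------------------------------------------------------------

def save_weights(net: Network, path) -> None:
    """Write all parameters and running statistics to a ``.npz`` archive."""
    np.savez(path, **net.state_dict())


def load_pretrained(net: Network, weights, strict: bool = False
                    ) -> tuple[Network, list[str]]:
    """Load every archive entry whose name and shape match the network.

    ``weights`` is a path to a ``.npz`` archive or a name -> array mapping.
    If any classification-head parameter is skipped (e.g. the archive head
    was trained for a different number of classes), the head is
    reinitialized. Returns the network and the list of skipped names;
    ``strict=True`` raises on any mismatch instead.
    """
    if isinstance(weights, (str, bytes)) or hasattr(weights, "__fspath__"):
        with np.load(weights) as npz:
            archive = {k: npz[k] for k in npz.files}
    else:
        archive = dict(weights)

    params = dict(net.named_parameters())
    buffers = dict(net.named_buffers())
    skipped: list[str] = []
    for name, value in archive.items():
        target = params.get(name)
        if target is not None:
            if target.data.shape == value.shape:
                target.data = value.astype(np.float32).copy()
            else:
                skipped.append(name)
            continue
        buf = buffers.get(name)
        if buf is not None and buf.shape == value.shape:
            buf[...] = value
        else:
            skipped.append(name)
    missing = sorted(set(params) - set(archive))
    if strict and (skipped or missing):
        raise ValueError(
            "pretrained archive does not match the network; "
            f"skipped={sorted(skipped)} missing={missing}"
        )
    if any(name in net.head_param_names() for name in skipped):
        net.reinit_head()
    return net, sorted(skipped)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    epochs: int = 30
    batch_size: int = 32
    lr: float = 1e-3
    weight_decay: float = 0.0
    patience: int = 10  # early stop on validation accuracy
    seed: int = 0
    freeze_backbone: bool = False


@dataclass
class EpochStats:
    epoch: int
    train_loss: float
    val_accuracy: float


def train(
    net: Network,
    train_set: tuple[np.ndarray, np.ndarray],
    val_set: tuple[np.ndarray, np.ndarray],
    hyper: TrainConfig | None = None,
) -> tuple[Network, list[EpochStats]]:
    """Minimize cross-entropy with Adam; keep the best-validation weights.

    ``train_set``/``val_set`` are (inputs (N,3,R,R), integer labels (N,))
    pairs. Fully seeded: two runs with the same config produce identical
    weights and history.
    """
    hyper = hyper or TrainConfig()
    x_train, y_train = _as_batch(train_set[0]), np.asarray(train_set[1])
    x_val, y_val = _as_batch(val_set[0]), np.asarray(val_set[1])
    if x_train.shape[0] == 0:
        raise ValueError("training set is empty")
    rng = np.random.default_rng(hyper.seed)
    if hyper.freeze_backbone:
        params = [p for name, p in net.named_parameters()
                  if name in net.head_param_names()]
    else:
        params = net.parameters()
    opt = Adam(params, lr=hyper.lr, weight_decay=hyper.weight_decay)

    history: list[EpochStats] = []
    best_acc, best_state, since_best = -np.inf, net.state_dict(), 0
    n = x_train.shape[0]
    for epoch in range(hyper.epochs):
        order = rng.permutation(n)
        losses = []
        for i in range(0, n, hyper.batch_size):
            idx = order[i:i + hyper.batch_size]
            if idx.size < 2:  # batch norm needs > 1 sample
                continue
            net.zero_grad()
            logits = net.forward(ag.Tensor(x_train[idx]), training=True)
            loss = ag.softmax_cross_entropy(logits, y_train[idx])
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        preds = predict_logits(net, x_val, hyper.batch_size).argmax(axis=1)
        val_acc = float(np.mean(preds == y_val)) if y_val.size else float("nan")
        history.append(EpochStats(epoch, float(np.mean(losses)), val_acc))
        if val_acc > best_acc:
            best_acc, best_state, since_best = val_acc, net.state_dict(), 0
        else:
            since_best += 1
            if since_best >= hyper.patience:
                break
    net.load_state(best_state)
    return net, history
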