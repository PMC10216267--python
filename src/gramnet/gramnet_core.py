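"""Modular CNN building blocks and their series/parallel composition.

A *SubNet* is a short stack of conv -> (batch-norm) -> ReLU -> (max-pool)
layer groups.  Networks grow incrementally: a new SubNet is attached to a
frozen existing network either in **series** (it consumes the network's
final feature maps) or in **parallel** (it reads the raw input; the final
feature maps of both branches are spatially aligned and concatenated along
the channel axis).  A single classification head — global average pooling
followed by one fully connected layer and softmax — always sits at the
output and is rebuilt when the network grows.

Freezing is absolute: a frozen SubNet's parameters and batch-norm
statistics never change during any subsequent training, which is what makes
each growth stage cheap — only the newest SubNet and the head backpropagate.

Five SubNet presets, "A" through "E", ship with the package:

======  =========================================
A       3x3 kernels, 8 / 16 / 32 filters
B, D    3x3 kernels, 64 / 128 / 256 filters
C       1x1 kernels, 8 / 16 / 32 filters
E       1x3 / 3x1 / 1x3 kernels, 64 / 128 / 256
======  =========================================

Max pooling halves the spatial dimensions after every group (ceil mode,
saturating at 1x1).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np

from . import nn

__all__ = [
    "SubNetSpec",
    "SubNetModule",
    "ClassificationHead",
    "GraMNetGraph",
    "Minibatch",
    "SUBNET_PRESETS",
    "build_subnet",
    "graph_from_subnet",
    "combine_series",
    "combine_parallel",
    "forward_with_head",
    "count_parameters",
    "count_madd",
    "frozen_state_hash",
    "save_graph",
    "load_graph",
    "one_hot",
]


@dataclasses.dataclass(frozen=True)
class SubNetSpec:
    """Layer-group stack: an ordered list of (kernel_h, kernel_w, n_filters)."""

    name: str
    layer_groups: tuple[tuple[int, int, int], ...]
    use_batchnorm: bool = True
    use_maxpool: tuple[bool, ...] | None = None  # per group; None = all pooled

    def __post_init__(self):
        if not self.layer_groups:
            raise ValueError("need at least one layer group")
        for kh, kw, nf in self.layer_groups:
            if kh < 1 or kw < 1 or nf < 1:
                raise ValueError("kernel dims and filter counts must be >= 1")
        if self.use_maxpool is not None and \
                len(self.use_maxpool) != len(self.layer_groups):
            raise ValueError("use_maxpool must have one flag per layer group")

    @property
    def pool_flags(self) -> tuple[bool, ...]:
        return self.use_maxpool or (True,) * len(self.layer_groups)

    @property
    def out_channels(self) -> int:
        return self.layer_groups[-1][2]


SUBNET_PRESETS: dict[str, SubNetSpec] = {
    "A": SubNetSpec("A", ((3, 3, 8), (3, 3, 16), (3, 3, 32))),
    "B": SubNetSpec("B", ((3, 3, 64), (3, 3, 128), (3, 3, 256))),
    "C": SubNetSpec("C", ((1, 1, 8), (1, 1, 16), (1, 1, 32))),
    "D": SubNetSpec("D", ((3, 3, 64), (3, 3, 128), (3, 3, 256))),
    "E": SubNetSpec("E", ((1, 3, 64), (3, 1, 128), (1, 3, 256))),
}


class SubNetModule:
    """A built SubNet: layers plus parameters, with a freeze flag."""

    def __init__(self, spec: SubNetSpec, in_channels: int, seed: int = 0):
        self.spec = spec
        self.in_channels = in_channels
        self.seed = seed
        rng = np.random.default_rng(seed)
        layers: list[nn.Layer] = []
        cin = in_channels
        for g, ((kh, kw, nf), pool) in enumerate(
                zip(spec.layer_groups, spec.pool_flags)):
            layers.append(nn.Conv2d(cin, nf, kh, kw, rng,
                                    name=f"{spec.name}.conv{g}"))
            if spec.use_batchnorm:
                layers.append(nn.BatchNorm2d(nf, name=f"{spec.name}.bn{g}"))
            layers.append(nn.ReLU())
            if pool:
                layers.append(nn.MaxPool2())
            cin = nf
        self.layers = nn.Sequential(layers)

    @property
    def out_channels(self) -> int:
        return self.spec.out_channels

    @property
    def n_conv_layers(self) -> int:
        return len(self.spec.layer_groups)

    @property
    def frozen(self) -> bool:
        return self.layers.frozen

    @frozen.setter
    def frozen(self, value: bool):
        self.layers.frozen = value

    def parameters(self):
        return self.layers.parameters()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.layers.forward(x, train=train and not self.frozen)

    def backward(self, dy: np.ndarray, need_dx: bool = False):
        return self.layers.backward(dy, need_dx=need_dx)

    def out_shape(self, in_shape):
        return self.layers.out_shape(in_shape)

    def state(self) -> dict[str, np.ndarray]:
        """All parameters plus batch-norm running statistics."""
        d: dict[str, np.ndarray] = {}
        for i, layer in enumerate(self.layers.layers):
            for p in layer.parameters():
                d[f"l{i}.{p.name}"] = p.data
            if isinstance(layer, nn.BatchNorm2d):
                d[f"l{i}.running_mean"] = layer.running_mean
                d[f"l{i}.running_var"] = layer.running_var
        return d

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers.layers):
            for p in layer.parameters():
                p.data = np.ascontiguousarray(state[f"l{i}.{p.name}"], dtype=np.float32)
                p.grad = np.zeros_like(p.data)
            if isinstance(layer, nn.BatchNorm2d):
                layer.running_mean = state[f"l{i}.running_mean"].astype(np.float32)
                layer.running_var = state[f"l{i}.running_var"].astype(np.float32)


def build_subnet(spec: SubNetSpec, in_channels: int, seed: int = 0) -> SubNetModule:
    """Construct a SubNet with seed-deterministic initialization."""
    return SubNetModule(spec, in_channels, seed=seed)


class ClassificationHead:
    """Global average pooling + one fully connected layer over M classes."""

    def __init__(self, in_channels: int, n_classes: int, seed: int = 0):
        self.in_channels = in_channels
        self.n_classes = n_classes
        rng = np.random.default_rng(seed)
        self.gap = nn.GlobalAvgPool()
        self.fc = nn.Linear(in_channels, n_classes, rng, name="head")

    def parameters(self):
        return self.fc.parameters()

    def forward(self, feats: np.ndarray, train: bool = False) -> np.ndarray:
        return self.fc.forward(self.gap.forward(feats, train=train), train=train)

    def backward(self, dlogits: np.ndarray, need_dx: bool = True):
        dx = self.fc.backward(dlogits, need_dx=need_dx)
        if not need_dx:
            return None
        return self.gap.backward(dx)


# ----------------------------------------------------------------- graph ---


def _align_shapes(sa, sb):
    """Common spatial target: the elementwise minimum of the two maps."""
    th, tw = min(sa[0], sb[0]), min(sa[1], sb[1])
    if sa[0] % th or sa[1] % tw or sb[0] % th or sb[1] % tw:
        raise ValueError(f"cannot align feature maps {sa} and {sb}")
    return th, tw


class _Leaf:
    def __init__(self, subnet: SubNetModule):
        self.subnet = subnet

    kind = "leaf"

    @property
    def out_channels(self):
        return self.subnet.out_channels

    @property
    def depth(self):
        return self.subnet.n_conv_layers

    def subnets(self):
        return [self.subnet]

    def forward(self, x, train=False):
        return self.subnet.forward(x, train=train)

    def out_shape(self, in_shape):
        return self.subnet.out_shape(in_shape)

    def madd(self, in_shape):
        return self.subnet.layers.madd(in_shape)


class _Series:
    """New SubNet consumes the final feature maps of the (frozen) base."""

    def __init__(self, left, subnet: SubNetModule):
        self.left = left
        self.subnet = subnet

    kind = "series"

    @property
    def out_channels(self):
        return self.subnet.out_channels

    @property
    def depth(self):
        return self.left.depth + self.subnet.n_conv_layers

    def subnets(self):
        return self.left.subnets() + [self.subnet]

    def forward(self, x, train=False):
        return self.subnet.forward(self.left.forward(x, train=train), train=train)

    def out_shape(self, in_shape):
        return self.subnet.out_shape(self.left.out_shape(in_shape))

    def madd(self, in_shape):
        return self.left.madd(in_shape) + \
            self.subnet.layers.madd(self.left.out_shape(in_shape))


class _Parallel:
    """Both branches read the same raw input; outputs are spatially aligned
    (larger map average-pooled to the smaller) and depth-concatenated."""

    def __init__(self, left, subnet: SubNetModule):
        self.left = left
        self.subnet = subnet
        self._pool_right = None  # align op for the new branch, set per forward

    kind = "parallel"

    @property
    def out_channels(self):
        return self.left.out_channels + self.subnet.out_channels

    @property
    def depth(self):
        return max(self.left.depth, self.subnet.n_conv_layers)

    def subnets(self):
        return self.left.subnets() + [self.subnet]

    def forward(self, x, train=False):
        fl = self.left.forward(x, train=train)
        fr = self.subnet.forward(x, train=train)
        return self.join(fl, fr, train=train)

    def join(self, fl, fr, train=False):
        if fl.shape[2] * fl.shape[3] == 0 or fr.shape[2] * fr.shape[3] == 0:
            raise ValueError("cannot align a zero-size feature map")
        th, tw = _align_shapes(fl.shape[2:], fr.shape[2:])
        if fl.shape[2:] != (th, tw):
            fl = nn.AvgPoolTo(th, tw).forward(fl, train=False)
        self._pool_right = None
        if fr.shape[2:] != (th, tw):
            self._pool_right = nn.AvgPoolTo(th, tw)
            fr = self._pool_right.forward(fr, train=train)
        return np.concatenate([fl, fr], axis=1)

    def split_grad_right(self, dcat):
        """Gradient slice for the new branch, un-aligned back to its size."""
        d = dcat[:, self.left.out_channels:]
        if self._pool_right is not None:
            d = self._pool_right.backward(d)
        return d

    def out_shape(self, in_shape):
        cl, hl, wl = self.left.out_shape(in_shape)
        cr, hr, wr = self.subnet.out_shape(in_shape)
        th, tw = _align_shapes((hl, wl), (hr, wr))
        return (cl + cr, th, tw)

    def madd(self, in_shape):
        return self.left.madd(in_shape) + self.subnet.layers.madd(in_shape)


@dataclasses.dataclass
class Minibatch:
    """Inputs as (N, H, W, D) with one-hot (N, M) truths."""

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=np.float32)
        if self.x.ndim == 3:
            self.x = self.x[..., None]
        if self.x.ndim != 4 or len(self.x) < 1:
            raise ValueError("inputs must be (N, H, W, D) with N >= 1")
        self.y = np.asarray(self.y, dtype=np.float32)
        if not np.array_equal(self.y.sum(axis=1), np.ones(len(self.y))) or \
                not np.isin(self.y, (0.0, 1.0)).all():
            raise ValueError("truths must be one-hot")

    @property
    def nchw(self) -> np.ndarray:
        return np.ascontiguousarray(self.x.transpose(0, 3, 1, 2))


def one_hot(labels, classes) -> np.ndarray:
    classes = list(classes)
    y = np.zeros((len(labels), len(classes)), dtype=np.float32)
    for i, lab in enumerate(labels):
        y[i, classes.index(lab)] = 1.0
    return y


class GraMNetGraph:
    """Composition tree of SubNets with one classification head."""

    def __init__(self, root, head: ClassificationHead, input_channels: int,
                 stage_name: str = ""):
        self.root = root
        self.head = head
        self.input_channels = input_channels
        self.stage_name = stage_name

    def subnets(self) -> list[SubNetModule]:
        return self.root.subnets()

    def trainable_subnets(self) -> list[SubNetModule]:
        return [s for s in self.subnets() if not s.frozen]

    def frozen_subnets(self) -> list[SubNetModule]:
        return [s for s in self.subnets() if s.frozen]

    @property
    def conv_layer_count(self) -> int:
        """Effective convolution depth (parallel branches count as their max)."""
        return self.root.depth

    @property
    def total_layers(self) -> int:
        """Convolution depth plus the single fully connected layer."""
        return self.conv_layer_count + 1

    def forward_features(self, x_nchw: np.ndarray, train: bool = False) -> np.ndarray:
        return self.root.forward(x_nchw, train=train)

    def forward_logits(self, x_nchw: np.ndarray, train: bool = False) -> np.ndarray:
        return self.head.forward(self.forward_features(x_nchw, train=train),
                                 train=train)

    def parameters(self):
        ps = []
        for s in self.subnets():
            ps.extend(s.parameters())
        ps.extend(self.head.parameters())
        return ps


def graph_from_subnet(subnet: SubNetModule, n_classes: int,
                      seed: int = 0) -> GraMNetGraph:
    """Stage-1 graph: a single SubNet plus a fresh head."""
    head = ClassificationHead(subnet.out_channels, n_classes, seed=seed)
    return GraMNetGraph(_Leaf(subnet), head, subnet.in_channels,
                        stage_name=subnet.spec.name)


def _freeze_base(base: GraMNetGraph) -> None:
    for s in base.subnets():
        s.frozen = True


def combine_series(base: GraMNetGraph, new: SubNetModule,
                   seed: int = 0) -> GraMNetGraph:
    """Grow the network in series: ``new`` consumes the frozen base's final
    feature maps; a fresh head follows.  Total layer count becomes
    L_base + L_new + 1 (the head being the one fully connected layer)."""
    if new.in_channels != base.root.out_channels:
        raise ValueError(
            f"channel mismatch: SubNet expects {new.in_channels}, "
            f"base provides {base.root.out_channels}")
    _freeze_base(base)
    root = _Series(base.root, new)
    head = ClassificationHead(root.out_channels, base.head.n_classes, seed=seed)
    return GraMNetGraph(root, head, base.input_channels,
                        stage_name=f"{base.stage_name}+{new.spec.name}")


def combine_parallel(base: GraMNetGraph, new: SubNetModule,
                     seed: int = 0) -> GraMNetGraph:
    """Grow the network in parallel: ``new`` reads the raw input; branch
    outputs are aligned and depth-concatenated before a fresh joint head."""
    if new.in_channels != base.input_channels:
        raise ValueError(
            f"parallel SubNet must accept the raw input "
            f"({base.input_channels} channels), got {new.in_channels}")
    _freeze_base(base)
    root = _Parallel(base.root, new)
    head = ClassificationHead(root.out_channels, base.head.n_classes, seed=seed)
    return GraMNetGraph(root, head, base.input_channels,
                        stage_name=f"({base.stage_name})||{new.spec.name}")


def forward_with_head(net: GraMNetGraph, batch: Minibatch) -> np.ndarray:
    """Class probabilities (rows sum to 1) for a minibatch."""
    return nn.softmax(net.forward_logits(batch.nchw, train=False))


# ------------------------------------------------------------ accounting ---


def count_parameters(obj) -> int:
    """Number of learnable scalars in a module, head, graph, or list thereof."""
    if isinstance(obj, (list, tuple)):
        return sum(count_parameters(o) for o in obj)
    if hasattr(obj, "parameters"):
        return sum(p.size for p in obj.parameters())
    raise TypeError(f"cannot count parameters of {type(obj)!r}")


def count_madd(obj, input_shape) -> int:
    """Forward multiply-add count at ``input_shape`` = (C, H, W).

    Covers convolution and fully connected layers; for a graph the head's
    FC layer is included.
    """
    c, h, w = input_shape
    if c < 1 or h < 1 or w < 1:
        return 0
    if isinstance(obj, GraMNetGraph):
        return obj.root.madd(input_shape) + \
            obj.head.fc.madd(obj.root.out_shape(input_shape))
    if isinstance(obj, SubNetModule):
        return obj.layers.madd(input_shape)
    if isinstance(obj, nn.Layer):
        return obj.madd(input_shape)
    raise TypeError(f"cannot count MAdds of {type(obj)!r}")


def frozen_state_hash(net: GraMNetGraph) -> str:
    """SHA-256 over every frozen SubNet's parameters and BN statistics."""
    h = hashlib.sha256()
    for s in net.frozen_subnets():
        state = s.state()
        for key in sorted(state):
            h.update(key.encode())
            h.update(np.ascontiguousarray(state[key]).tobytes())
    return h.hexdigest()


# ---------------------------------------------------------- serialization ---


def _spec_to_dict(spec: SubNetSpec) -> dict:
    return {"name": spec.name,
            "layer_groups": [list(g) for g in spec.layer_groups],
            "use_batchnorm": spec.use_batchnorm,
            "use_maxpool": list(spec.use_maxpool) if spec.use_maxpool else None}


def _spec_from_dict(d: dict) -> SubNetSpec:
    return SubNetSpec(d["name"], tuple(tuple(g) for g in d["layer_groups"]),
                      d["use_batchnorm"],
                      tuple(d["use_maxpool"]) if d["use_maxpool"] else None)


def _node_to_dict(node, subnet_index: dict) -> dict:
    i = len(subnet_index)
    if node.kind == "leaf":
        subnet_index[i] = node.subnet
        return {"kind": "leaf", "subnet": i}
    left = _node_to_dict(node.left, subnet_index)
    i = len(subnet_index)
    subnet_index[i] = node.subnet
    return {"kind": node.kind, "left": left, "subnet": i}


def save_graph(net: GraMNetGraph, directory: str | Path) -> None:
    """Write topology (JSON text) plus parameter blobs (npz)."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    subnet_index: dict[int, SubNetModule] = {}
    topo = {
        "root": _node_to_dict(net.root, subnet_index),
        "input_channels": net.input_channels,
        "n_classes": net.head.n_classes,
        "stage_name": net.stage_name,
        "subnets": [{"spec": _spec_to_dict(s.spec), "in_channels": s.in_channels,
                     "frozen": bool(s.frozen)}
                    for _, s in sorted(subnet_index.items())],
    }
    (d / "topology.json").write_text(json.dumps(topo, indent=2))
    arrays = {}
    for i, s in sorted(subnet_index.items()):
        for k, v in s.state().items():
            arrays[f"subnet{i}/{k}"] = v
    arrays["head/weight"] = net.head.fc.weight.data
    arrays["head/bias"] = net.head.fc.bias.data
    np.savez(d / "params.npz", **arrays)


def load_graph(directory: str | Path) -> GraMNetGraph:
    d = Path(directory)
    topo = json.loads((d / "topology.json").read_text())
    blobs = np.load(d / "params.npz")
    subnets = []
    for i, sd in enumerate(topo["subnets"]):
        s = SubNetModule(_spec_from_dict(sd["spec"]), sd["in_channels"])
        prefix = f"subnet{i}/"
        s.load_state({k[len(prefix):]: blobs[k] for k in blobs.files
                      if k.startswith(prefix)})
        s.frozen = sd["frozen"]
        subnets.append(s)

    def build(nd):
        if nd["kind"] == "leaf":
            return _Leaf(subnets[nd["subnet"]])
        left = build(nd["left"])
        cls = _Series if nd["kind"] == "series" else _Parallel
        return cls(left, subnets[nd["subnet"]])

    root = build(topo["root"])
    head = ClassificationHead(root.out_channels, topo["n_classes"])
    head.fc.weight.data = blobs["head/weight"].astype(np.float32)
    head.fc.bias.data = blobs["head/bias"].astype(np.float32)
    return GraMNetGraph(root, head, topo["input_channels"],
                        stage_name=topo.get("stage_name", ""))
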