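"""The binocular multi-task encoder-decoder network and its variants.

The model family is U-net-shaped: per-eye convolutional encoders join at a
binocular concatenation stage; from a shared bottleneck, separate decoder
branches produce a segmentation map for each camera (25-way softmax per
pixel) and a linear-activation depth map referenced to the left camera.
Lateral connections feed intermediate segmentation-branch features into the
depth branch at matched resolutions; there are no connections in the other
direction, so segmentation never depends on depth-branch weights.

Everything here — layers, automatic differentiation, the Adam-ready
parameter containers — is implemented directly on NumPy arrays (NHWC
layout, float32).  The layer set is exactly what the architecture needs:
3x3/1x1 convolution, batch normalization, ReLU, 2x2 max pooling, nearest
up-sampling, and channel concatenation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

# --------------------------------------------------------------------------
# Parameters and layers
# --------------------------------------------------------------------------


class Param:
    """A weight array with accumulated gradient.

    ``trainable=False`` marks state updated by forward passes (batch-norm
    running statistics) rather than by the optimizer.
    """

    __slots__ = ("value", "grad", "trainable", "name")

    def __init__(self, value: np.ndarray, trainable: bool = True, name: str = ""):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.trainable = trainable
        self.name = name

    @property
    def size(self) -> int:
        return self.value.size


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, xs: list[np.ndarray], training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> list[np.ndarray]:
        raise NotImplementedError


class Input(Layer):
    def forward(self, xs, training):
        raise RuntimeError("input nodes are fed, not computed")


def _glorot(rng: np.random.Generator, shape, fan_in, fan_out):
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class Conv2D(Layer):
    """k x k convolution, stride 1, 'same' padding, optional shared weights."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 bias: bool = True, name: str = "", share_with: "Conv2D" = None):
        self.cin, self.cout, self.k = cin, cout, k
        if share_with is not None:
            self.w = share_with.w
            self.b = share_with.b
        else:
            self.w = Param(_glorot(rng, (k * k * cin, cout), k * k * cin, cout),
                           name=f"{name}.w")
            self.b = Param(np.zeros(cout, np.float32), name=f"{name}.b") if bias else None
        self._cache = None

    def params(self):
        return [self.w] + ([self.b] if self.b is not None else [])

    # The k*k kernel is applied as k*k shifted (N*H*W, cin) @ (cin, cout)
    # matmuls on views of the padded input — no im2col buffer is built.

    def forward(self, xs, training):
        (x,) = xs
        n, h, w, c = x.shape
        k = self.k
        wm = self.w.value.reshape(k * k, c, self.cout)
        if k == 1:
            y = x.reshape(-1, c) @ wm[0]
        else:
            p = k // 2
            xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
            y = None
            for i in range(k):
                for j in range(k):
                    part = xp[:, i:i + h, j:j + w, :].reshape(-1, c) @ wm[i * k + j]
                    y = part if y is None else y + part
            self._xp = xp
        if self.b is not None:
            y += self.b.value
        self._xshape = x.shape
        if k == 1:
            self._x = x
        return y.reshape(n, h, w, self.cout)

    def backward(self, gy):
        n, h, w, c = self._xshape
        k = self.k
        g = gy.reshape(-1, self.cout)
        wm = self.w.value.reshape(k * k, c, self.cout)
        gw = self.w.grad.reshape(k * k, c, self.cout)
        if self.b is not None:
            self.b.grad += g.sum(axis=0)
        if k == 1:
            gw[0] += self._x.reshape(-1, c).T @ g
            return [(g @ wm[0].T).reshape(n, h, w, c)]
        p = k // 2
        xp = self._xp
        gxp = np.zeros_like(xp)
        for i in range(k):
            for j in range(k):
                view = xp[:, i:i + h, j:j + w, :].reshape(-1, c)
                gw[i * k + j] += view.T @ g
                gxp[:, i:i + h, j:j + w, :] += (g @ wm[i * k + j].T
                                                ).reshape(n, h, w, c)
        return [gxp[:, p:p + h, p:p + w, :]]


class BatchNorm(Layer):
    """Per-channel batch normalization (momentum 0.99, eps 1e-3)."""

    def __init__(self, c: int, name: str = "", momentum: float = 0.99,
                 eps: float = 1e-3):
        self.gamma = Param(np.ones(c, np.float32), name=f"{name}.gamma")
        self.beta = Param(np.zeros(c, np.float32), name=f"{name}.beta")
        self.moving_mean = Param(np.zeros(c, np.float32), trainable=False,
                                 name=f"{name}.moving_mean")
        self.moving_var = Param(np.ones(c, np.float32), trainable=False,
                                name=f"{name}.moving_var")
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def params(self):
        return [self.gamma, self.beta, self.moving_mean, self.moving_var]

    def forward(self, xs, training):
        (x,) = xs
        if training:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            m = self.momentum
            self.moving_mean.value = m * self.moving_mean.value + (1 - m) * mean
            self.moving_var.value = m * self.moving_var.value + (1 - m) * var
        else:
            mean = self.moving_mean.value
            var = np.maximum(self.moving_var.value, 0.0)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        self._cache = (xhat, inv, x.shape, training)
        return (self.gamma.value * xhat + self.beta.value).astype(np.float32)

    def backward(self, gy):
        xhat, inv, xshape, training = self._cache
        self.gamma.grad += (gy * xhat).sum(axis=(0, 1, 2))
        self.beta.grad += gy.sum(axis=(0, 1, 2))
        g = gy * self.gamma.value
        if not training:
            return [(g * inv).astype(np.float32)]
        m = xshape[0] * xshape[1] * xshape[2]
        gx = (g - g.mean(axis=(0, 1, 2))
              - xhat * (g * xhat).mean(axis=(0, 1, 2))) * inv
        return [gx.astype(np.float32)]


class ReLU(Layer):
    def forward(self, xs, training):
        (x,) = xs
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, gy):
        return [np.where(self._mask, gy, 0.0).astype(np.float32)]


class MaxPool2(Layer):
    def forward(self, xs, training):
        (x,) = xs
        n, h, w, c = x.shape
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c)
        y = xr.max(axis=(2, 4))
        self._cache = (xr, y, x.shape)
        return y

    def backward(self, gy):
        xr, y, xshape = self._cache
        n, h, w, c = xshape
        mask = xr == y[:, :, None, :, None, :]
        # split gradient equally across tied maxima
        counts = mask.sum(axis=(2, 4), keepdims=True)
        g = mask * (gy[:, :, None, :, None, :] / counts)
        return [g.reshape(n, h, w, c).astype(np.float32)]


class Upsample2(Layer):
    """Nearest-neighbour x2 up-sampling."""

    def forward(self, xs, training):
        (x,) = xs
        return x.repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, gy):
        n, h, w, c = gy.shape
        return [gy.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))]


class Concat(Layer):
    def forward(self, xs, training):
        self._sizes = [x.shape[-1] for x in xs]
        return np.concatenate(xs, axis=-1)

    def backward(self, gy):
        out = []
        start = 0
        for s in self._sizes:
            out.append(gy[..., start:start + s])
            start += s
        return out


# --------------------------------------------------------------------------
# Computation graph
# --------------------------------------------------------------------------


@dataclass
class Node:
    name: str
    layer: Layer
    inputs: list[str]


class Graph:
    """A static DAG of layers evaluated in insertion (topological) order."""

    def __init__(self):
        self.nodes: list[Node] = []
        self.by_name: dict[str, Node] = {}

    def add(self, name: str, layer: Layer, inputs: Sequence[str]) -> str:
        for i in inputs:
            if i not in self.by_name:
                raise KeyError(f"unknown input node {i!r} for {name!r}")
        node = Node(name, layer, list(inputs))
        self.nodes.append(node)
        self.by_name[name] = node
        return name

    def forward(self, feeds: dict[str, np.ndarray], outputs: Sequence[str],
                training: bool) -> dict[str, np.ndarray]:
        values = dict(feeds)
        for node in self.nodes:
            if isinstance(node.layer, Input):
                if node.name not in values:
                    raise ValueError(f"missing feed for input {node.name!r}")
                continue
            values[node.name] = node.layer.forward(
                [values[i] for i in node.inputs], training)
        return {o: values[o] for o in outputs}

    def backward(self, out_grads: dict[str, np.ndarray]) -> None:
        grads: dict[str, np.ndarray] = dict(out_grads)
        for node in reversed(self.nodes):
            g = grads.pop(node.name, None)
            if g is None or isinstance(node.layer, Input):
                continue
            gins = node.layer.backward(g)
            for iname, gi in zip(node.inputs, gins):
                if iname in grads:
                    grads[iname] = grads[iname] + gi
                else:
                    grads[iname] = gi


# --------------------------------------------------------------------------
# Network configuration
# --------------------------------------------------------------------------

Variant = Literal["binocular_full", "binocular_no_lateral",
                  "binocular_seg_only", "monocular_unet"]

# Full-size per-stage channel widths.  Stage k operates at input_size / 2**k;
# the last seg entry is the shared bottleneck, the last depth entry the width
# of the depth branch's stem block at bottleneck resolution.  The exact
# values are pinned so the full-size models land on their reference totals:
# 10,901,923 parameters (binocular; 10,889,955 trainable + 11,968 batch-norm
# running statistics) and 3,120,921 (monocular U-net).
SEG_WIDTHS_FULL = (6, 22, 76, 200, 208)
DEPTH_WIDTHS_FULL = (192, 127, 108, 79, 1010)


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture description.

    ``seg_widths`` are the encoder / segmentation-decoder channel widths
    per resolution stage (length ``encoder_depth + 1``, bottleneck last);
    ``depth_widths`` are the depth-decoder widths (length
    ``encoder_depth + 1``, the depth branch's bottleneck-resolution stem
    width last).  When left at None they default to the full-size tables
    scaled by ``base_channels / SEG_WIDTHS_FULL[0]``.
    """

    input_height: int = 224
    input_width: int = 224
    class_count: int = 25
    conv_kernel: int = 3
    conv_stride: int = 1
    encoder_depth: int = 4
    base_channels: int = SEG_WIDTHS_FULL[0]
    seg_widths: tuple[int, ...] | None = None
    depth_widths: tuple[int, ...] | None = None
    lateral_resolutions: tuple[int, ...] | None = None
    variant: Variant = "binocular_full"
    eye_weight_sharing: bool = False

    def resolved_seg_widths(self) -> tuple[int, ...]:
        if self.seg_widths is not None:
            w = tuple(self.seg_widths)
        else:
            scale = self.base_channels / SEG_WIDTHS_FULL[0]
            w = tuple(max(2, round(v * scale)) for v in SEG_WIDTHS_FULL)
        if len(w) < self.encoder_depth + 1:
            raise ValueError("seg_widths shorter than encoder_depth + 1")
        return w[: self.encoder_depth + 1]

    def resolved_depth_widths(self) -> tuple[int, ...]:
        """Depth-branch widths (d_0 .. d_{depth-1}, stem)."""
        if self.depth_widths is not None:
            d = tuple(self.depth_widths)
        else:
            scale = self.base_channels / SEG_WIDTHS_FULL[0]
            d = tuple(max(2, round(v * scale)) for v in DEPTH_WIDTHS_FULL)
        if len(d) < self.encoder_depth + 1:
            raise ValueError("depth_widths shorter than encoder_depth + 1")
        return d[: self.encoder_depth] + (d[-1],)

    def resolved_laterals(self) -> tuple[int, ...]:
        """Decoder resolutions receiving segmentation->depth laterals.

        Default: every decoder resolution below full image resolution
        (28, 56 and 112 for a 224 input at depth 4)."""
        stages = [self.input_width // 2 ** k
                  for k in range(1, self.encoder_depth)]
        if self.lateral_resolutions is None:
            return tuple(sorted(stages))
        lat = tuple(sorted(self.lateral_resolutions))
        for res in lat:
            if res not in stages:
                raise ValueError(
                    f"lateral resolution {res} not present in the decoder "
                    f"(available: {sorted(stages)})")
        return lat

    def validate(self) -> None:
        if self.conv_kernel != 3 or self.conv_stride != 1:
            raise ValueError("the architecture uses 3x3 convolutions at stride 1")
        div = 2 ** self.encoder_depth
        if self.input_height % div or self.input_width % div:
            raise ValueError(
                f"input size {self.input_height}x{self.input_width} is not "
                f"divisible by 2**encoder_depth = {div}")
        if self.class_count < 2:
            raise ValueError("class_count must be >= 2")
        self.resolved_seg_widths()
        self.resolved_depth_widths()
        self.resolved_laterals()


@dataclass
class Predictions:
    left_seg_probs: np.ndarray                 # (H, W, classes) or batch
    right_seg_probs: np.ndarray | None
    depth_map: np.ndarray | None               # (H, W, 1), linear activation


class ModelHandle:
    def __init__(self, graph: Graph, config: NetworkConfig,
                 input_names: list[str], output_names: dict[str, str]):
        self.graph = graph
        self.config = config
        self.input_names = input_names
        self.output_names = output_names  # role -> node name

    # -- parameters --------------------------------------------------------
    def parameters(self) -> list[Param]:
        seen: dict[int, Param] = {}
        for node in self.graph.nodes:
            for p in node.layer.params():
                seen.setdefault(id(p), p)
        return list(seen.values())

    @property
    def param_counts(self) -> tuple[int, int, int]:
        return count_parameters(self)


# --------------------------------------------------------------------------
# Builders
# --------------------------------------------------------------------------


def _conv_block(g: Graph, rng, x: str, cin: int, cout: int, name: str,
                n_convs: int = 2, share: dict | None = None,
                share_key: str | None = None) -> str:
    """(conv 3x3 -> batch-norm -> ReLU) x n_convs.

    When ``share``/``share_key`` are given, convolution weights are aliased
    across blocks with the same key (weight-tied monocular pathways)."""
    for i in range(n_convs):
        ci = cin if i == 0 else cout
        cname = f"{name}.conv{i}"
        skey = f"{share_key}.conv{i}" if share_key else cname
        shared_src = share.get(skey) if share is not None else None
        conv = Conv2D(ci, cout, 3, rng, name=cname, share_with=shared_src)
        if share is not None and shared_src is None:
            share[skey] = conv
        x = g.add(cname, conv, [x])
        x = g.add(f"{name}.bn{i}", BatchNorm(cout, name=f"{name}.bn{i}"), [x])
        x = g.add(f"{name}.relu{i}", ReLU(), [x])
    return x


def build_network(config: NetworkConfig, seed: int = 0) -> ModelHandle:
    """Instantiate a network variant as a computation graph.

    Deterministic for fixed ``config`` and ``seed`` (Glorot-uniform
    initialization from a seeded generator).
    """
    config.validate()
    rng = np.random.default_rng(seed)
    g = Graph()
    w = config.resolved_seg_widths()
    dwid = config.resolved_depth_widths()
    depth_stages = config.encoder_depth
    variant = config.variant
    binocular = variant != "monocular_unet"
    want_depth = variant in ("binocular_full", "binocular_no_lateral")
    laterals = config.resolved_laterals() if variant == "binocular_full" else ()

    inputs = ["left_rgb", "right_rgb"] if binocular else ["left_rgb"]
    for name in inputs:
        g.add(name, Input(), [])

    merge_stage = depth_stages  # eyes join right before the bottleneck

    def encoder(eye: str, share: dict | None):
        """Monocular encoder for one eye; returns (skips, pooled output)."""
        x = f"{eye}_rgb"
        skips = []
        cin = 3
        for k in range(merge_stage):
            x = _conv_block(g, rng, x, cin, w[k], f"enc_{eye}.s{k}",
                            share=share, share_key=f"enc.s{k}")
            skips.append(x)
            x = g.add(f"enc_{eye}.pool{k}", MaxPool2(), [x])
            cin = w[k]
        return skips, x

    share = {} if (binocular and config.eye_weight_sharing) else None
    skips_l, enc_l = encoder("left", share)
    if binocular:
        skips_r, enc_r = encoder("right", share)
        trunk = g.add("binocular_concat", Concat(), [enc_l, enc_r])
        cin_b = 2 * w[merge_stage - 1]
    else:
        skips_r = skips_l
        trunk = enc_l
        cin_b = w[merge_stage - 1]

    bott = _conv_block(g, rng, trunk, cin_b, w[depth_stages], "bottleneck")

    def seg_decoder(tag: str, skips: list[str]) -> tuple[str, list[str]]:
        x = bott
        feats = [None] * depth_stages          # per-stage decoder features
        for k in range(depth_stages - 1, -1, -1):
            prev = w[depth_stages] if k == depth_stages - 1 else w[k + 1]
            x = g.add(f"dec_{tag}.up{k}", Upsample2(), [x])
            x = _conv_block(g, rng, x, prev, w[k], f"dec_{tag}.upconv{k}",
                            n_convs=1)
            x = g.add(f"dec_{tag}.skip{k}", Concat(), [x, skips[k]])
            x = _conv_block(g, rng, x, 2 * w[k], w[k], f"dec_{tag}.s{k}")
            feats[k] = x
        logits = g.add(f"seg_{tag}_logits",
                       Conv2D(w[0], config.class_count, 1, rng,
                              name=f"seg_{tag}_logits"), [x])
        return logits, feats

    out_names: dict[str, str] = {}
    left_logits, feats_l = seg_decoder("left", skips_l)
    out_names["left_seg"] = left_logits
    if binocular:
        right_logits, feats_r = seg_decoder("right", skips_r)
        out_names["right_seg"] = right_logits

    if want_depth:
        # stem: a wide fusion block at bottleneck resolution feeding the
        # depth decoder (the seg decoders read the bottleneck directly)
        stem_w = dwid[depth_stages]
        x = _conv_block(g, rng, bott, w[depth_stages], stem_w, "depth_stem",
                        n_convs=1)
        for k in range(depth_stages - 1, -1, -1):
            prev = stem_w if k == depth_stages - 1 else dwid[k + 1]
            x = g.add(f"dec_depth.up{k}", Upsample2(), [x])
            x = _conv_block(g, rng, x, prev, dwid[k], f"dec_depth.upconv{k}",
                            n_convs=1)
            cat = [x, skips_l[k]]
            cin = dwid[k] + w[k]
            res = config.input_width // 2 ** k
            if res in laterals:
                cat += [feats_l[k], feats_r[k]]
                cin += 2 * w[k]
            x = g.add(f"dec_depth.cat{k}", Concat(), cat)
            x = _conv_block(g, rng, x, cin, dwid[k], f"dec_depth.s{k}")
        out_names["depth"] = g.add(
            "depth_out", Conv2D(dwid[0], 1, 1, rng, name="depth_out"), [x])

    return ModelHandle(g, config, inputs, out_names)


# --------------------------------------------------------------------------
# Inference and parameter accounting
# --------------------------------------------------------------------------


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def forward_pass(model: ModelHandle, left_rgb: np.ndarray,
                 right_rgb: np.ndarray | None = None,
                 training: bool = False) -> Predictions:
    """Run the network on one image pair or a batch.

    Accepts (H, W, 3) or (N, H, W, 3) inputs; single images come back
    unbatched.  ``right_rgb`` is forbidden for the monocular variant and
    required for binocular ones.  Deterministic in inference mode.
    """
    cfg = model.config
    binocular = cfg.variant != "monocular_unet"
    if binocular and right_rgb is None:
        raise ValueError("binocular variants require right_rgb")
    if not binocular and right_rgb is not None:
        raise ValueError("monocular_unet takes a single (left) image")
    squeeze = left_rgb.ndim == 3
    feeds = {"left_rgb": _as_batch(left_rgb, cfg, "left_rgb")}
    if binocular:
        feeds["right_rgb"] = _as_batch(right_rgb, cfg, "right_rgb")
    outs = model.graph.forward(feeds, list(model.output_names.values()),
                               training=training)
    by_role = {role: outs[nm] for role, nm in model.output_names.items()}
    left = softmax(by_role["left_seg"])
    right = softmax(by_role["right_seg"]) if "right_seg" in by_role else None
    depth = by_role.get("depth")
    if squeeze:
        left = left[0]
        right = None if right is None else right[0]
        depth = None if depth is None else depth[0]
    return Predictions(left_seg_probs=left, right_seg_probs=right,
                       depth_map=depth)


def _as_batch(x: np.ndarray, cfg: NetworkConfig, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=np.float32)
    if x.ndim == 3:
        x = x[None]
    if x.ndim != 4 or x.shape[1:] != (cfg.input_height, cfg.input_width, 3):
        raise ValueError(
            f"{name}: expected shape (N, {cfg.input_height}, "
            f"{cfg.input_width}, 3), got {x.shape}")
    return x


def count_parameters(model: ModelHandle) -> tuple[int, int, int]:
    """(total, trainable, non_trainable) parameter counts.

    Non-trainable parameters are exactly the batch-normalization running
    mean/variance entries."""
    trainable = sum(p.size for p in model.parameters() if p.trainable)
    non_trainable = sum(p.size for p in model.parameters() if not p.trainable)
    return trainable + non_trainable, trainable, non_trainable


def summarize(model: ModelHandle) -> dict:
    """JSON-ready architecture summary."""
    total, tr, nt = count_parameters(model)
    layers = []
    for node in model.graph.nodes:
        layers.append({
            "name": node.name,
            "type": type(node.layer).__name__,
            "inputs": node.inputs,
            "params": int(sum(p.size for p in node.layer.params())),
        })
    return {"variant": model.config.variant, "total_params": total,
            "trainable_params": tr, "non_trainable_params": nt,
            "layers": layers}


def save_weights(model: ModelHandle, path) -> None:
    arrays = {}
    for i, p in enumerate(model.parameters()):
        arrays[f"{i:04d}:{p.name}:{int(p.trainable)}"] = p.value
    np.savez(path, **arrays)


def load_weights(model: ModelHandle, path) -> None:
    data = np.load(path)
    params = model.parameters()
    if len(data.files) != len(params):
        raise ValueError(f"checkpoint has {len(data.files)} arrays, model "
                         f"has {len(params)} parameters")
    for key in data.files:
        idx = int(key.split(":")[0])
        if params[idx].value.shape != data[key].shape:
            raise ValueError(f"shape mismatch for {key}")
        params[idx].value = data[key].astype(np.float32)


def get_weight_state(model: ModelHandle) -> list[np.ndarray]:
    return [p.value.copy() for p in model.parameters()]


def set_weight_state(model: ModelHandle, state: list[np.ndarray]) -> None:
    for p, v in zip(model.parameters(), state):
        p.value = v.copy()
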