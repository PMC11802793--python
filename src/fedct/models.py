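"""Network definitions, the CE+Dice deep-supervision loss, and task routing.

Two architectures are defined, both size-parameterized so tests run tiny
configurations while full-scale counterparts remain constructible:

* **Teacher** — a residual 3D U-Net: per-task convolutional network taking a
  2-channel input (normalized CT + heart mask) and emitting its task's
  channels at full resolution plus deep-supervision outputs at each coarser
  decoder level.
* **Student** — a patch-attention encoder over the same 2-channel input
  (window-partitioned self-attention by default, global attention in the
  "plain" variant) with a convolutional decoder and **three output heads**,
  one 1x1x1 convolution per task (HCO: 5 channels, MS: 2, CALC: 1), all
  sharing the backbone.

Training loss per supervision level is binary cross-entropy plus soft-Dice
(eps = 1e-5 smoothing); heatmap channels are treated as independent soft
foregrounds, since landmark Gaussians overlap spatially and a cross-channel
softmax would be wrong.  Level weights are proportional to 2^-l, normalized
to sum to one.  Optimization uses AdamW (decoupled weight decay).
"""

from __future__ import annotations

import hashlib
import json
from collections import OrderedDict
from dataclasses import asdict, dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .core import TASK_CHANNELS, TASKS
from .labelcodec import downsample_target


# ---------------------------------------------------------------------------
# configs


@dataclass(frozen=True)
class TeacherConfig:
    task: str = "HCO"
    base_filters: int = 8          # full-scale configuration uses 32
    depth: int = 2                 # resolution levels
    in_channels: int = 2
    deep_supervision: bool = True
    lr: float = 0.01
    weight_decay: float = 1e-4

    def __post_init__(self) -> None:
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.task not in TASK_CHANNELS:
            raise ValueError(f"unknown task {self.task!r}")

    @property
    def out_channels(self) -> int:
        return TASK_CHANNELS[self.task]


@dataclass(frozen=True)
class StudentConfig:
    variant: str = "windowed"      # "windowed" | "plain"
    input_shape: tuple[int, int, int] = (32, 32, 32)
    patch_size: int = 8
    embed_dim: int = 24            # feature size of the full-scale configuration
    n_blocks: int = 2
    n_heads: int = 2
    window_tokens: int = 2         # window edge length in tokens (windowed variant)
    decoder_filters: int = 8
    in_channels: int = 2
    lr: float = 1e-4
    weight_decay: float = 1e-4

    def __post_init__(self) -> None:
        if self.variant not in ("windowed", "plain"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.embed_dim % self.n_heads:
            raise ValueError("embed_dim must be divisible by n_heads")
        if any(s % self.patch_size for s in self.input_shape):
            raise ValueError("input_shape must be divisible by patch_size")


def _config_hash(config) -> str:
    payload = json.dumps(asdict(config), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


# ---------------------------------------------------------------------------
# model state


@dataclass
class ModelState:
    """Named, shaped parameter collection exchanged between clients/server."""

    params: "OrderedDict[str, np.ndarray]"
    partitions: dict[str, str]
    config_hash: str

    def copy(self) -> "ModelState":
        return ModelState(
            OrderedDict((k, v.copy()) for k, v in self.params.items()),
            dict(self.partitions),
            self.config_hash,
        )

    def checksum(self, partition_prefix: str | None = None) -> str:
        h = hashlib.sha256()
        for name, arr in self.params.items():
            if partition_prefix and not self.partitions[name].startswith(partition_prefix):
                continue
            h.update(name.encode())
            h.update(np.ascontiguousarray(arr).tobytes())
        return h.hexdigest()

    def allclose(self, other: "ModelState", rtol: float = 0.0, atol: float = 0.0) -> bool:
        if self.params.keys() != other.params.keys():
            return False
        return all(
            np.allclose(self.params[k], other.params[k], rtol=rtol, atol=atol)
            for k in self.params
        )


def save_checkpoint(state: ModelState, path) -> None:
    meta = json.dumps({"config_hash": state.config_hash, "partitions": state.partitions})
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **state.params)


def load_checkpoint(path, expect_config=None) -> ModelState:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        params = OrderedDict((k, data[k]) for k in data.files if k != "__meta__")
    state = ModelState(params, meta["partitions"], meta["config_hash"])
    if expect_config is not None and _config_hash(expect_config) != state.config_hash:
        raise ValueError(
            f"checkpoint config hash {state.config_hash} does not match "
            f"expected {_config_hash(expect_config)}"
        )
    return state


# ---------------------------------------------------------------------------
# parameter container


class _Net:
    """Base: ordered named parameters with partition labels."""

    def __init__(self, config) -> None:
        self.config = config
        self.params: "OrderedDict[str, Tensor]" = OrderedDict()
        self.partitions: dict[str, str] = {}

    def _param(self, name: str, array: np.ndarray, partition: str = "backbone") -> Tensor:
        t = Tensor(array, requires_grad=True, name=name)
        self.params[name] = t
        self.partitions[name] = partition
        return t

    def state(self) -> ModelState:
        return ModelState(
            OrderedDict((k, v.data.copy()) for k, v in self.params.items()),
            dict(self.partitions),
            _config_hash(self.config),
        )

    def load_state(self, state: ModelState) -> None:
        if state.config_hash != _config_hash(self.config):
            raise ValueError("refusing to load state into a mismatched config")
        if set(state.params) != set(self.params):
            raise ValueError("parameter name sets differ between state and model")
        for name, tensor in self.params.items():
            arr = state.params[name]
            if arr.shape != tensor.data.shape:
                raise ValueError(f"shape mismatch for parameter {name}")
            tensor.data = arr.astype(float).copy()

    def zero_grad(self) -> None:
        for t in self.params.values():
            t.grad = None


def _he(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


# Output-layer bias init: targets are sparse (small Gaussian blobs / thin
# calcifications), so heads start at a low foreground prior, sigmoid(-4) ~ 2%.
OUT_BIAS_INIT = -4.0


# ---------------------------------------------------------------------------
# teacher: residual 3D U-Net


class TeacherNet(_Net):
    def __init__(self, config: TeacherConfig, seed: int = 0) -> None:
        super().__init__(config)
        rng = np.random.default_rng(seed)
        f = config.base_filters
        self.channels = [f * 2**l for l in range(config.depth)]
        cin = config.in_channels
        for l, cout in enumerate(self.channels):
            self._res_block(rng, f"enc{l}", cin, cout)
            cin = cout
        for l in range(config.depth - 2, -1, -1):
            cup = self.channels[l + 1]
            self._conv(rng, f"up{l}", cup, self.channels[l], k=1)
            self._res_block(rng, f"dec{l}", self.channels[l], self.channels[l])
        levels = range(config.depth) if config.deep_supervision else [0]
        for l in levels:
            c = self.channels[l]
            self._conv(rng, f"out{l}", c, config.out_channels, k=1,
                       partition=f"head:{config.task}", bias_init=OUT_BIAS_INIT)

    def _conv(self, rng, name, cin, cout, k=3, partition="backbone", bias_init=0.0):
        self._param(f"{name}.w", _he(rng, (cout, cin, k, k, k), cin * k**3), partition)
        self._param(f"{name}.b", np.full(cout, bias_init, dtype=float), partition)

    def _res_block(self, rng, name, cin, cout):
        self._conv(rng, f"{name}.c1", cin, cout)
        self._conv(rng, f"{name}.c2", cout, cout)
        for sub in ("n1", "n2"):
            self._param(f"{name}.{sub}.g", np.ones(cout))
            self._param(f"{name}.{sub}.b", np.zeros(cout))
        if cin != cout:
            self._conv(rng, f"{name}.proj", cin, cout, k=1)

    def _apply_conv(self, name, x):
        return ad.conv3d(x, self.params[f"{name}.w"], self.params[f"{name}.b"])

    def _apply_block(self, name, x, cin, cout):
        h = ad.instance_norm(self._apply_conv(f"{name}.c1", x),
                             self.params[f"{name}.n1.g"], self.params[f"{name}.n1.b"])
        h = ad.instance_norm(self._apply_conv(f"{name}.c2", ad.relu(h)),
                             self.params[f"{name}.n2.g"], self.params[f"{name}.n2.b"])
        skip = self._apply_conv(f"{name}.proj", x) if cin != cout else x
        return ad.relu(ad.add(h, skip))

    def forward(self, x_np: np.ndarray) -> list[Tensor]:
        """Input (2, D, H, W) -> [full-res logits, half-res logits, ...]."""
        cfg: TeacherConfig = self.config
        if x_np.shape[0] != cfg.in_channels:
            raise ValueError(f"expected {cfg.in_channels} input channels, got {x_np.shape[0]}")
        div = 2 ** (cfg.depth - 1)
        if any(s % div for s in x_np.shape[1:]):
            raise ValueError(f"spatial dims {x_np.shape[1:]} must be divisible by {div}")
        x = Tensor(x_np)
        encs = []
        cin = cfg.in_channels
        for l, cout in enumerate(self.channels):
            if l > 0:
                x = ad.avg_pool2(x)
            x = self._apply_block(f"enc{l}", x, cin, cout)
            encs.append(x)
            cin = cout
        feats = {cfg.depth - 1: encs[-1]}
        x = encs[-1]
        for l in range(cfg.depth - 2, -1, -1):
            x = self._apply_conv(f"up{l}", ad.upsample2(x))
            x = ad.add(x, encs[l])
            x = self._apply_block(f"dec{l}", x, self.channels[l], self.channels[l])
            feats[l] = x
        levels = range(cfg.depth) if cfg.deep_supervision else [0]
        return [self._apply_conv(f"out{l}", feats[l]) for l in levels]


def build_teacher(config: TeacherConfig, seed: int = 0) -> tuple[TeacherNet, ModelState]:
    net = TeacherNet(config, seed)
    return net, net.state()


# ---------------------------------------------------------------------------
# student: patch attention encoder + conv decoder + three heads


class StudentNet(_Net):
    def __init__(self, config: StudentConfig, seed: int = 0) -> None:
        super().__init__(config)
        rng = np.random.default_rng(seed)
        e = config.embed_dim
        ps = config.patch_size
        pdim = config.in_channels * ps**3
        self._param("embed.w", _he(rng, (pdim, e), pdim))
        self._param("embed.b", np.zeros(e))
        for i in range(config.n_blocks):
            for nm, shape, fan in (
                ("qkv.w", (e, 3 * e), e), ("qkv.b", (3 * e,), 0),
                ("proj.w", (e, e), e), ("proj.b", (e,), 0),
                ("mlp1.w", (e, 2 * e), e), ("mlp1.b", (2 * e,), 0),
                ("mlp2.w", (2 * e, e), 2 * e), ("mlp2.b", (e,), 0),
            ):
                arr = np.zeros(shape) if nm.endswith(".b") else _he(rng, shape, fan)
                self._param(f"blk{i}.{nm}", arr)
            self._param(f"blk{i}.ln1.g", np.ones(e))
            self._param(f"blk{i}.ln1.b", np.zeros(e))
            self._param(f"blk{i}.ln2.g", np.ones(e))
            self._param(f"blk{i}.ln2.b", np.zeros(e))
        # decoder: token grid channels e -> upsample to full res
        df = config.decoder_filters
        n_up = int(np.log2(ps))
        if 2**n_up != ps:
            raise ValueError("patch_size must be a power of two")
        cin = e
        for i in range(n_up):
            cout = max(df, cin // 2) if i < n_up - 1 else df
            self._param(f"dec{i}.w", _he(rng, (cout, cin, 3, 3, 3), cin * 27))
            self._param(f"dec{i}.b", np.zeros(cout))
            self._param(f"dec{i}.n.g", np.ones(cout))
            self._param(f"dec{i}.n.b", np.zeros(cout))
            cin = cout
        # full-resolution stem fused before the final feature conv
        self._param("stem.w", _he(rng, (df, config.in_channels, 3, 3, 3), config.in_channels * 27))
        self._param("stem.b", np.zeros(df))
        self._param("stem.n.g", np.ones(df))
        self._param("stem.n.b", np.zeros(df))
        self._param("fuse.w", _he(rng, (df, 2 * df, 3, 3, 3), 2 * df * 27))
        self._param("fuse.b", np.zeros(df))
        self._param("fuse.n.g", np.ones(df))
        self._param("fuse.n.b", np.zeros(df))
        for task in TASKS:
            c = TASK_CHANNELS[task]
            self._param(f"head_{task}.w", _he(rng, (c, df, 1, 1, 1), df), f"head:{task}")
            self._param(f"head_{task}.b", np.full(c, OUT_BIAS_INIT), f"head:{task}")
        tgrid = tuple(s // ps for s in config.input_shape)
        self._param("pos", rng.normal(0.0, 0.02, size=(int(np.prod(tgrid)), e)))

    def _attention(self, i: int, x: Tensor, nw: int, wt: int) -> Tensor:
        """x: (nw, wt, E) window-grouped tokens."""
        cfg: StudentConfig = self.config
        e, nh = cfg.embed_dim, cfg.n_heads
        hd = e // nh
        qkv = ad.linear(x, self.params[f"blk{i}.qkv.w"], self.params[f"blk{i}.qkv.b"])
        qkv = ad.reshape(qkv, (nw, wt, 3, nh, hd))
        qkv = ad.transpose(qkv, (2, 0, 3, 1, 4))  # (3, nw, nh, wt, hd)
        q = ad.reshape(qkv, (3, nw * nh, wt, hd))
        qm = _slice0(q, 0)
        km = _slice0(q, 1)
        vm = _slice0(q, 2)
        att = ad.scale(ad.matmul(qm, ad.transpose(km, (0, 2, 1))), 1.0 / np.sqrt(hd))
        att = ad.softmax(att)
        out = ad.matmul(att, vm)  # (nw*nh, wt, hd)
        out = ad.reshape(out, (nw, nh, wt, hd))
        out = ad.transpose(out, (0, 2, 1, 3))
        out = ad.reshape(out, (nw, wt, e))
        return ad.linear(out, self.params[f"blk{i}.proj.w"], self.params[f"blk{i}.proj.b"])

    def forward(self, x_np: np.ndarray) -> dict[str, Tensor]:
        cfg: StudentConfig = self.config
        if x_np.shape[0] != cfg.in_channels:
            raise ValueError(f"expected {cfg.in_channels} input channels, got {x_np.shape[0]}")
        ps = cfg.patch_size
        spatial = x_np.shape[1:]
        if spatial != tuple(cfg.input_shape):
            raise ValueError(f"spatial dims {spatial} do not match configured {cfg.input_shape}")
        tgrid = tuple(s // ps for s in spatial)
        t = int(np.prod(tgrid))
        c = cfg.in_channels

        x = Tensor(x_np)
        # patchify: (C, td*ps, th*ps, tw*ps) -> (T, C*ps^3)
        xp = ad.reshape(x, (c, tgrid[0], ps, tgrid[1], ps, tgrid[2], ps))
        xp = ad.transpose(xp, (1, 3, 5, 0, 2, 4, 6))
        tokens = ad.reshape(xp, (t, c * ps**3))
        h = ad.linear(tokens, self.params["embed.w"], self.params["embed.b"])
        h = ad.add(h, self.params["pos"])

        wt_edge = cfg.window_tokens if cfg.variant == "windowed" else None
        if wt_edge and all(g % wt_edge == 0 for g in tgrid) and any(g > wt_edge for g in tgrid):
            nwin = tuple(g // wt_edge for g in tgrid)
            nw = int(np.prod(nwin))
            wt = wt_edge**3
            def group(z):
                z = ad.reshape(z, (nwin[0], wt_edge, nwin[1], wt_edge, nwin[2], wt_edge, -1))
                z = ad.transpose(z, (0, 2, 4, 1, 3, 5, 6))
                return ad.reshape(z, (nw, wt, cfg.embed_dim))
            def ungroup(z):
                z = ad.reshape(z, (nwin[0], nwin[1], nwin[2], wt_edge, wt_edge, wt_edge, -1))
                z = ad.transpose(z, (0, 3, 1, 4, 2, 5, 6))
                return ad.reshape(z, (t, cfg.embed_dim))
        else:
            nw, wt = 1, t
            group = lambda z: ad.reshape(z, (1, t, cfg.embed_dim))  # noqa: E731
            ungroup = lambda z: ad.reshape(z, (t, cfg.embed_dim))  # noqa: E731

        for i in range(cfg.n_blocks):
            ln = ad.layer_norm(h, self.params[f"blk{i}.ln1.g"], self.params[f"blk{i}.ln1.b"])
            h = ad.add(h, ungroup(self._attention(i, group(ln), nw, wt)))
            ln = ad.layer_norm(h, self.params[f"blk{i}.ln2.g"], self.params[f"blk{i}.ln2.b"])
            m = ad.relu(ad.linear(ln, self.params[f"blk{i}.mlp1.w"], self.params[f"blk{i}.mlp1.b"]))
            m = ad.linear(m, self.params[f"blk{i}.mlp2.w"], self.params[f"blk{i}.mlp2.b"])
            h = ad.add(h, m)

        # tokens -> (E, td, th, tw) feature grid
        g = ad.transpose(ad.reshape(h, tgrid + (cfg.embed_dim,)), (3, 0, 1, 2))
        n_up = int(np.log2(ps))
        for i in range(n_up):
            g = ad.conv3d(ad.upsample2(g), self.params[f"dec{i}.w"], self.params[f"dec{i}.b"])
            g = ad.relu(ad.instance_norm(g, self.params[f"dec{i}.n.g"], self.params[f"dec{i}.n.b"]))
        stem = ad.conv3d(x, self.params["stem.w"], self.params["stem.b"])
        stem = ad.relu(ad.instance_norm(stem, self.params["stem.n.g"], self.params["stem.n.b"]))
        feat = ad.conv3d(ad.concat([g, stem], axis=0),
                         self.params["fuse.w"], self.params["fuse.b"])
        feat = ad.relu(ad.instance_norm(feat, self.params["fuse.n.g"], self.params["fuse.n.b"]))
        self.last_features = feat
        return {
            task: ad.conv3d(feat, self.params[f"head_{task}.w"], self.params[f"head_{task}.b"])
            for task in TASKS
        }

    def head_param_names(self, task: str | None = None) -> set[str]:
        if task is None:
            return {n for n, p in self.partitions.items() if p.startswith("head:")}
        return {n for n, p in self.partitions.items() if p == f"head:{task}"}


def _slice0(t: Tensor, i: int) -> Tensor:
    """Select index i along axis 0 (differentiable)."""
    def bw(g):
        if t.grad is None:
            t.grad = np.zeros_like(t.data)
        t.grad[i] += g
    out = Tensor(t.data[i])
    out._parents = (t,)
    out._backward = bw
    out.requires_grad = True
    return out


def build_student(config: StudentConfig, seed: int = 0) -> tuple[StudentNet, ModelState]:
    net = StudentNet(config, seed)
    return net, net.state()


# ---------------------------------------------------------------------------
# losses


def ds_loss(predictions: list[Tensor], target: np.ndarray, soft: bool,
            weights: list[float] | None = None) -> Tensor:
    """Deep-supervision loss: sum_l w_l (CE_l + DiceLoss_l).

    ``predictions[l]`` is the logit map at 1/2**l resolution; the target is
    downsampled per level (block mean for soft heatmaps, nearest for hard
    masks).  Weights default to 2^-l and are always normalized to sum 1.
    """
    L = len(predictions)
    w = np.array([2.0 ** (-l) for l in range(L)] if weights is None else weights, dtype=float)
    if len(w) != L:
        raise ValueError("one weight per supervision level required")
    w = w / w.sum()
    total: Tensor | None = None
    for l, pred in enumerate(predictions):
        tgt = downsample_target(np.asarray(target, dtype=float), l, soft=soft)
        if pred.data.shape != tgt.shape:
            raise ValueError(
                f"level {l}: prediction shape {pred.data.shape} vs target {tgt.shape}"
            )
        lvl = ad.add(ad.bce_with_logits(pred, tgt), ad.soft_dice_loss(pred, tgt))
        term = ad.scale(lvl, float(w[l]))
        total = term if total is None else ad.add(total, term)
    return total


def sample_targets(sample, enc, include_pseudo: bool = True) -> dict[str, tuple[np.ndarray, bool]]:
    """Build per-task voxel targets from a sample's labels.

    Returns task -> (target array (C, D, H, W), soft flag).
    """
    from .core import TASK_CALC
    from .labelcodec import encode_points
    out = {}
    for task in TASKS:
        if not sample.has_label(task, include_pseudo=include_pseudo):
            continue
        lab = sample.labels[task]
        if task == TASK_CALC:
            out[task] = (np.asarray(lab.payload.values, dtype=float)[None], False)
        else:
            try:
                out[task] = (encode_points(lab.payload, sample.volume, enc, task), True)
            except ValueError:
                continue  # partial or out-of-grid annotation: skip this task
    return out


def routed_loss(outputs: dict[str, "Tensor | list[Tensor]"],
                targets: dict[str, tuple[np.ndarray, bool]]) -> Tensor:
    """Mean of per-task losses over the tasks present in ``targets``.

    Heads of absent tasks are never touched by the graph, so their gradient
    is exactly zero.
    """
    present = [t for t in TASKS if t in targets]
    if not present:
        raise ValueError("sample carries no usable task labels")
    total: Tensor | None = None
    for task in present:
        preds = outputs[task]
        if isinstance(preds, Tensor):
            preds = [preds]
        tgt, soft = targets[task]
        term = ad.scale(ds_loss(preds, tgt, soft=soft), 1.0 / len(present))
        total = term if total is None else ad.add(total, term)
    return total


# ---------------------------------------------------------------------------
# optimizer


class AdamW:
    """AdamW with decoupled weight decay; state keyed by parameter name."""

    def __init__(self, params: "OrderedDict[str, Tensor]", lr: float,
                 betas=(0.9, 0.999), eps: float = 1e-8, weight_decay: float = 0.0,
                 trainable: set[str] | None = None):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.trainable = trainable  # None = all
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for name, p in self.params.items():
            if self.trainable is not None and name not in self.trainable:
                continue
            if p.grad is None:
                continue
            g = p.grad
            self.m[name] = self.b1 * self.m[name] + (1 - self.b1) * g
            self.v[name] = self.b2 * self.v[name] + (1 - self.b2) * g * g
            mhat = self.m[name] / (1 - self.b1**self.t)
            vhat = self.v[name] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * (mhat / (np.sqrt(vhat) + self.eps)
                                         + self.weight_decay * p.data)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None


__all__ = [
    "TeacherConfig", "StudentConfig", "ModelState", "TeacherNet", "StudentNet",
    "build_teacher", "build_student", "ds_loss", "routed_loss", "sample_targets",
    "AdamW", "save_checkpoint", "load_checkpoint",
]
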