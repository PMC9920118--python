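"""Attention-gated multitask encoder-decoder for respiration estimation.

The teacher network maps a (3, 128) window of derived respiration channels
(RR-interval, R-peak-amplitude and accelerometer surrogates at 4 Hz) to a
fused 128-sample respiration waveform (decoder head) and a scalar average
respiration rate (inception-residual regression head).  A compact student
variant with three encoder-decoder levels supports attention-transfer
knowledge distillation.

Architecture summary (teacher, ``ned=5``):

* encoder: five levels of strided conv (k=3, s=2) + batch norm + leaky ReLU
  (slope 0.2) + MC dropout + inception-residual block; filters double from
  32 to 512;
* bottleneck: conv to 1024 filters + inception-residual block;
* decoder: five transposed-conv levels (k=3, s=2) mirroring the encoder,
  each skip connection gated by an attention block whose gating vector
  comes from the layer below;
* rate head: cascade of conv (k=4, s=2) stages with self-attention gates,
  filters 128 -> 64 -> 32 -> 2, ending in a unit dense layer.

The student keeps the 1024-filter bottleneck but uses stride-1 convs with
2x average pooling (encoder) and linear 2x upsampling (decoder); several
inception-residual blocks are removed (``removed_incres``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import core
from .nn.core import Tensor
from .nn.layers import BatchNorm1d, Conv1d, ConvTranspose1d, Dense, Module

__all__ = ["ArchConfig", "ModelOutput", "AttentionGate", "IncResBlock",
           "TeacherNet", "StudentNet", "build_teacher", "build_student",
           "teacher_config", "student_config", "parameter_count", "forward",
           "model_summary", "save_checkpoint", "load_checkpoint"]

# Inception-residual blocks removed when deriving the default student from
# the teacher: every encoder/decoder level block and all head blocks are
# pruned; the compact variant keeps only the bottleneck block.
DEFAULT_STUDENT_REMOVED = ("enc1", "enc2", "enc3", "dec1", "dec2", "dec3",
                           "head1", "head2", "head3")


@dataclass(frozen=True)
class ArchConfig:
    """Architecture hyperparameters.

    ``width_scale`` multiplies every channel count (minimum 1) and exists for
    CPU-scale experiments; the published sizes correspond to
    ``width_scale=1``.
    """

    ned: int = 5
    base_filters: int = 32
    bottleneck_filters: int = 1024
    incres_kernels: tuple[int, ...] = (15, 17, 19, 21)
    incres_branch_frac: float = 0.125
    head_filters: tuple[int, ...] = (128, 64, 32, 2)
    head_strides: tuple[int, ...] = (2, 2, 2, 2)
    tail_filters: tuple[int, ...] = ()          # student-only extra decoder convs
    dropout_p: float = 0.1
    enc_kernel: int = 3
    enc_stride: int = 2
    attention_on: bool = True
    input_len: int = 128
    in_channels: int = 3
    width_scale: float = 1.0
    removed_incres: tuple[str, ...] = ()
    leaky_slope: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if not 1 <= self.ned <= 5:
            raise ValueError("ned must be in 1..5")
        if not 0.0 <= self.dropout_p < 1.0:
            raise ValueError("dropout_p must be in [0, 1)")
        if self.base_filters < 1 or self.bottleneck_filters < 1:
            raise ValueError("filter counts must be positive")

    def ch(self, c: int) -> int:
        return max(int(round(c * self.width_scale)), 1)

    @property
    def enc_filters(self) -> tuple[int, ...]:
        return tuple(self.ch(self.base_filters * 2 ** i) for i in range(self.ned))


def teacher_config(width_scale: float = 1.0, seed: int = 0, ned: int = 5,
                   **kw) -> ArchConfig:
    """Default five-level teacher."""
    return ArchConfig(ned=ned, enc_stride=2, head_filters=(128, 64, 32, 2),
                      head_strides=(2, 2, 2, 2), width_scale=width_scale,
                      seed=seed, **kw)


def student_config(ned: int = 3, width_scale: float = 1.0, seed: int = 0,
                   removed_incres: tuple[str, ...] | None = None,
                   **kw) -> ArchConfig:
    """Compact student: stride-1 encoder, pooled levels, pruned blocks."""
    if removed_incres is None:
        removed = ["head1", "head2", "head3"]
        removed += [f"enc{i}" for i in range(1, ned + 1)]
        removed += [f"dec{i}" for i in range(1, ned + 1)]
        removed_incres = tuple(removed)
    return ArchConfig(ned=ned, enc_stride=1, head_filters=(128, 32, 4),
                      head_strides=(4, 2, 2), tail_filters=(8, 4),
                      width_scale=width_scale, removed_incres=removed_incres,
                      seed=seed, **kw)


@dataclass
class ModelOutput:
    """One forward pass: fused respiration series and average-rate estimate."""

    resp: np.ndarray                 # (N, input_len) or (input_len,)
    rr: np.ndarray                   # (N,) or scalar
    attention: dict = field(default_factory=dict)   # name -> coefficients


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

class IncResBlock(Module):
    """Inception-style residual block.

    Four parallel convolutions with kernel sizes 15/17/19/21 (each with
    batch norm and leaky ReLU) run on the input; their concatenation is
    recombined by a 1x1 convolution and added to a 1x1-projected residual
    of the block input.  'Same' padding preserves length.
    """

    def __init__(self, c: int, cfg: ArchConfig, rng: np.random.Generator):
        f = max(int(round(c * cfg.incres_branch_frac)), 1)
        self.slope = cfg.leaky_slope
        self.branches = [Conv1d(c, f, k, rng=rng) for k in cfg.incres_kernels]
        self.branch_bns = [BatchNorm1d(f) for _ in cfg.incres_kernels]
        self.recombine = Conv1d(len(self.branches) * f, c, 1, rng=rng)
        self.recombine_bn = BatchNorm1d(c)
        self.proj = Conv1d(c, c, 1, rng=rng)

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        outs = []
        for conv, bnorm in zip(self.branches, self.branch_bns):
            outs.append(core.leaky_relu(bnorm(conv(x), training), self.slope))
        y = self.recombine_bn(self.recombine(core.concat(outs)), training)
        return core.leaky_relu(y + self.proj(x), self.slope)


class AttentionGate(Module):
    """Additive attention gate.

    The skip feature map x and the gating vector g (from the layer below)
    are projected by 1x1 convolutions, summed, passed through ReLU, a
    second 1x1 convolution (psi) and a sigmoid; the resulting coefficients
    in (0, 1) rescale x elementwise.  When g is at half the temporal
    resolution of x its projection is linearly upsampled before the sum.
    """

    def __init__(self, cx: int, cg: int, rng: np.random.Generator):
        self.ix = Conv1d(cx, cx, 1, bias=False, rng=rng)
        self.ig = Conv1d(cg, cx, 1, bias=True, rng=rng)
        self.psi = Conv1d(cx, 1, 1, bias=True, rng=rng)

    def __call__(self, x: Tensor, g: Tensor) -> tuple[Tensor, Tensor]:
        gx = self.ix(x)
        gg = self.ig(g)
        if gg.shape[-1] * 2 == gx.shape[-1]:
            gg = core.upsample2(gg)
        elif gg.shape[-1] != gx.shape[-1]:
            raise ValueError(
                f"gating length {gg.shape[-1]} not alignable to {gx.shape[-1]}")
        alpha = core.sigmoid(self.psi(core.relu(gx + gg)))
        return x * alpha, alpha


class _Level(Module):
    """conv/conv-transpose + BN + leaky ReLU + dropout + optional IncRes."""

    def __init__(self, cin: int, cout: int, cfg: ArchConfig,
                 rng: np.random.Generator, *, transposed: bool = False,
                 kernel: int | None = None, stride: int | None = None,
                 incres: bool = True):
        k = kernel if kernel is not None else cfg.enc_kernel
        s = stride if stride is not None else cfg.enc_stride
        cls = ConvTranspose1d if transposed else Conv1d
        self.conv = cls(cin, cout, k, stride=s, rng=rng)
        self.bn = BatchNorm1d(cout)
        self.incres = IncResBlock(cout, cfg, rng) if incres else None
        self.slope = cfg.leaky_slope
        self.p = cfg.dropout_p

    def __call__(self, x: Tensor, training: bool, drop: bool,
                 rng: np.random.Generator) -> Tensor:
        y = core.leaky_relu(self.bn(self.conv(x), training), self.slope)
        y = core.dropout(y, self.p, rng, drop)
        if self.incres is not None:
            y = self.incres(y, training)
        return y


class _RateHead(Module):
    """Cascaded conv stages with self-attention, ending in a unit dense."""

    def __init__(self, cin: int, length: int, cfg: ArchConfig,
                 rng: np.random.Generator):
        self.stages = []
        self.gates = []
        L = length
        for i, (c, s) in enumerate(zip(cfg.head_filters, cfg.head_strides), 1):
            cc = cfg.ch(c)
            self.stages.append(_Level(cin, cc, cfg, rng, kernel=4, stride=s,
                                      incres=f"head{i}" not in cfg.removed_incres))
            self.gates.append(AttentionGate(cc, cc, rng)
                              if cfg.attention_on else None)
            cin = cc
            L = -(-L // s)
        self.dense = Dense(cin * L, 1, rng=rng)
        self._flat = cin * L

    def __call__(self, z: Tensor, training: bool, drop: bool,
                 rng: np.random.Generator, attention: dict,
                 feats: dict | None = None) -> Tensor:
        h = z
        for i, (stage, gate) in enumerate(zip(self.stages, self.gates), 1):
            h = stage(h, training, drop, rng)
            if gate is not None:
                h, alpha = gate(h, h)
                attention[f"head{i}"] = alpha
            if feats is not None:
                feats[f"head{i}"] = h
        n = h.shape[0]
        return self.dense(h.reshape(n, self._flat))


# ---------------------------------------------------------------------------
# teacher
# ---------------------------------------------------------------------------

class TeacherNet(Module):
    """Five-level strided encoder-decoder with gated skips and a rate head."""

    def __init__(self, cfg: ArchConfig):
        if cfg.enc_stride != 2:
            raise ValueError("teacher uses stride-2 encoder convs")
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        enc = cfg.enc_filters                      # e.g. (32,...,512)
        cbot = cfg.ch(cfg.bottleneck_filters)
        self.enc_levels = []
        cin = cfg.in_channels
        for i, c in enumerate(enc, 1):
            self.enc_levels.append(_Level(cin, c, cfg, rng,
                                          incres=f"enc{i}" not in cfg.removed_incres))
            cin = c
        self.bottleneck = _Level(cin, cbot, cfg, rng, stride=1,
                                 incres="bneck" not in cfg.removed_incres)
        dec = tuple(reversed(enc))                 # (512,...,32)
        gate_src = (cbot,) + dec[:-1]              # gating channels per skip
        self.gates = [AttentionGate(cx, cg, rng) if cfg.attention_on else None
                      for cx, cg in zip(dec, gate_src)]
        self.dec_levels = []
        cin = cbot
        for j, c in enumerate(dec, 1):
            self.dec_levels.append(_Level(cin, c, cfg, rng, transposed=True,
                                          stride=2,
                                          incres=f"dec{j}" not in cfg.removed_incres))
            cin = 2 * c                            # concat with gated skip
        self.out_conv = Conv1d(cin, 1, 3, rng=rng)
        self.head = _RateHead(cbot, cfg.input_len // 2 ** cfg.ned, cfg, rng)
        # affine de-standardisation of the rate output, set by the trainer
        self.rr_norm = {"offset": np.zeros(()), "scale": np.ones(())}

    def __call__(self, x: Tensor, training: bool = False,
                 mc_dropout: bool = False,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        drop = training or mc_dropout
        attention: dict = {}
        feats: dict = {}
        skips = []
        h = x
        for i, level in enumerate(self.enc_levels, 1):
            h = level(h, training, drop, rng)
            skips.append(h)
            feats[f"enc{i}"] = h
        z = self.bottleneck(h, training, drop, rng)
        feats["bneck"] = z
        h = z
        below = z
        for j, (level, gate) in enumerate(zip(self.dec_levels, self.gates), 1):
            h = level(h, training, drop, rng)
            feats[f"dec{j}"] = h
            skip = skips[-j]
            if gate is not None:
                skip, alpha = gate(skip, below)
                attention[f"dec{j}"] = alpha
            below = h
            h = core.concat([h, core.upsample2(skip)])
        resp = self.out_conv(h)
        rr = self.head(z, training, drop, rng, attention, feats)
        return resp, rr, attention, feats


# ---------------------------------------------------------------------------
# student
# ---------------------------------------------------------------------------

class StudentNet(Module):
    """Compact variant: stride-1 convs, pooled encoder, pruned IncRes blocks."""

    def __init__(self, cfg: ArchConfig):
        if cfg.enc_stride != 1:
            raise ValueError("student uses stride-1 convs")
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        enc = cfg.enc_filters                      # e.g. (32, 64, 128)
        cbot = cfg.ch(cfg.bottleneck_filters)
        self.enc_levels = []
        cin = cfg.in_channels
        for i, c in enumerate(enc, 1):
            self.enc_levels.append(_Level(cin, c, cfg, rng, stride=1,
                                          incres=f"enc{i}" not in cfg.removed_incres))
            cin = c
        self.bottleneck = _Level(cin, cbot, cfg, rng, stride=1,
                                 incres="bneck" not in cfg.removed_incres)
        dec = tuple(reversed(enc))
        gate_src = (cbot,) + dec[:-1]
        self.gates = [AttentionGate(cx, cg, rng) if cfg.attention_on else None
                      for cx, cg in zip(dec, gate_src)]
        self.dec_levels = []
        cin = cbot
        for j, c in enumerate(dec, 1):
            self.dec_levels.append(_Level(cin, c, cfg, rng, transposed=True,
                                          stride=1,
                                          incres=f"dec{j}" not in cfg.removed_incres))
            cin = 2 * c
        self.tail = []
        for c in cfg.tail_filters:
            cc = cfg.ch(c)
            self.tail.append(_Level(cin, cc, cfg, rng, transposed=True,
                                    stride=1, incres=False))
            cin = cc
        self.out_conv = Conv1d(cin, 1, 3, rng=rng)
        self.head = _RateHead(cbot, cfg.input_len // 2 ** cfg.ned, cfg, rng)
        # affine de-standardisation of the rate output, set by the trainer
        self.rr_norm = {"offset": np.zeros(()), "scale": np.ones(())}

    def __call__(self, x: Tensor, training: bool = False,
                 mc_dropout: bool = False,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        drop = training or mc_dropout
        attention: dict = {}
        feats: dict = {}
        skips = []
        h = x
        for i, level in enumerate(self.enc_levels, 1):
            h = level(h, training, drop, rng)
            skips.append(h)
            feats[f"enc{i}"] = h
            h = core.avgpool2(h)
        z = self.bottleneck(h, training, drop, rng)
        feats["bneck"] = z
        h = z
        below = z
        for j, (level, gate) in enumerate(zip(self.dec_levels, self.gates), 1):
            h = level(core.upsample2(h), training, drop, rng)
            feats[f"dec{j}"] = h
            skip = skips[-j]
            if gate is not None:
                skip, alpha = gate(skip, below)  # gate upsamples g internally
                attention[f"dec{j}"] = alpha
            below = h
            h = core.concat([h, skip])
        for t in self.tail:
            h = t(h, training, drop, rng)
        resp = self.out_conv(h)
        rr = self.head(z, training, drop, rng, attention, feats)
        return resp, rr, attention, feats


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def build_teacher(cfg: ArchConfig | None = None) -> TeacherNet:
    return TeacherNet(cfg or teacher_config())


def build_student(cfg: ArchConfig | None = None) -> StudentNet:
    if cfg is None:
        cfg = student_config(removed_incres=DEFAULT_STUDENT_REMOVED)
    return StudentNet(cfg)


def parameter_count(model: Module) -> int:
    """Total number of trainable scalar parameters."""
    return model.n_parameters()


def forward(model, window: np.ndarray, train_mode: bool = False,
            mc_dropout: bool = False, rng_seed: int | None = None,
            with_attention: bool = True) -> ModelOutput:
    """Run one window (3, L) or a batch (N, 3, L) through the model.

    Deterministic when dropout is disabled; seeded-reproducible otherwise.
    """
    arr = np.asarray(window, dtype=np.float64)
    single = arr.ndim == 2
    if single:
        arr = arr[None]
    if arr.ndim != 3 or arr.shape[1] != model.cfg.in_channels \
            or arr.shape[2] != model.cfg.input_len:
        raise ValueError(
            f"expected (N, {model.cfg.in_channels}, {model.cfg.input_len}) "
            f"input, got {arr.shape}")
    rng = np.random.default_rng(rng_seed)
    resp, rr, attention, _ = model(Tensor(arr), training=train_mode,
                                   mc_dropout=mc_dropout, rng=rng)
    resp_np = resp.data[:, 0, :]
    rr_np = rr.data[:, 0] * float(model.rr_norm["scale"]) \
        + float(model.rr_norm["offset"])
    att = {k: v.data[:, 0, :] for k, v in attention.items()} if with_attention else {}
    if single:
        resp_np, rr_np = resp_np[0], float(rr_np[0])
        att = {k: v[0] for k, v in att.items()}
    return ModelOutput(resp=resp_np, rr=rr_np, attention=att)


def model_summary(model: Module) -> str:
    """Per-parameter shape/size dump plus the total count."""
    lines = [f"{'parameter':60s} {'shape':>18s} {'size':>12s}"]
    total = 0
    for name, p in model.parameters():
        lines.append(f"{name:60s} {str(p.data.shape):>18s} {p.data.size:>12d}")
        total += p.data.size
    lines.append(f"{'TOTAL':60s} {'':>18s} {total:>12d}  "
                 f"({total / 1e6:.2f} M)")
    return "\n".join(lines)


def iter_dropout_layers(module):
    """Yield every sub-module carrying a dropout probability attribute."""
    stack = [module]
    while stack:
        m = stack.pop()
        if isinstance(m, _Level):
            yield m
        for val in vars(m).values():
            if isinstance(val, Module):
                stack.append(val)
            elif isinstance(val, (list, tuple)):
                stack.extend(v for v in val if isinstance(v, Module))


def set_dropout_p(model: Module, p: float) -> dict:
    """Override the dropout probability of every layer; returns the previous
    values keyed by layer id for :func:`restore_dropout_p`."""
    old = {}
    for layer in iter_dropout_layers(model):
        old[id(layer)] = layer.p
        layer.p = p
    return old


def restore_dropout_p(model: Module, old: dict) -> None:
    for layer in iter_dropout_layers(model):
        if id(layer) in old:
            layer.p = old[id(layer)]


def save_checkpoint(model: Module, path) -> None:
    """Parameters + BN statistics + architecture config in one npz file."""
    import dataclasses
    import json
    cfg_json = json.dumps(dataclasses.asdict(model.cfg))
    np.savez_compressed(path, __config__=np.bytes_(cfg_json.encode()),
                        **model.state_arrays())


def load_checkpoint(model: Module, path) -> None:
    with np.load(path) as data:
        model.load_state_arrays({k: v for k, v in data.items()
                                 if k != "__config__"})


def load_model(path):
    """Rebuild the right architecture from a checkpoint and load its state."""
    import json
    with np.load(path) as data:
        cfg_dict = json.loads(bytes(data["__config__"]).decode())
        for key in ("incres_kernels", "head_filters", "head_strides",
                    "tail_filters", "removed_incres"):
            cfg_dict[key] = tuple(cfg_dict[key])
        cfg = ArchConfig(**cfg_dict)
        model = TeacherNet(cfg) if cfg.enc_stride == 2 else StudentNet(cfg)
        model.load_state_arrays({k: v for k, v in data.items()
                                 if k != "__config__"})
    return model
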