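"""Architecture zoo: recurrent and parameter-matched feedforward CNNs.

Fifteen variants across three families, unrolled over discrete timesteps
(one timestep = one full input-to-output pass; block states and top-down
signals always come from the previous pass):

* **C family** (CORnet-style, 4 areas V1/V2/V4/IT + linear decoder, 224 px):
  ``C`` (plain feedforward), ``CL`` (additive lateral state), ``CS``
  (bottleneck-residual blocks with internal weight-shared passes), ``CT``
  (top-down from *all* higher areas via the pool->channel-mean->conv scheme),
  ``CLT`` (CT plus a 1x1 lateral state conv), ``C-V1V1`` / ``C-ITIT``
  (lateral in a single named area), and ``CD``, a deeper feedforward control
  whose appended conv blocks bring its parameter count up to CS.
* **B family** (4 layers v1/v2/v4/it, 128 px): ``B``, ``BL`` (lateral conv),
  ``BT`` (top-down transposed conv from the adjacent higher layer), ``BLT``
  (both; all recurrent terms combine additively before the nonlinearity),
  and ``BD``, a deeper feedforward control parameter-matched to BLT.
* **VGG**: ``VGG16`` and a custom single-head ``VGG11`` feedforward control.

The top-down scheme of CT/CLT follows the block equations
``FF(x) = R(N(x * th_ff))``, ``TD(M) = R(N(M * th_td))``,
``M = Concat_i(ChannelMean(AdaptiveAvgPool(m_i, H_x)))``,
``y = R(N(Concat(FF, [rr,] TD) * th_out))`` with
``rr = R(N(s_{t-1} * th_rr))`` (1x1, stride 1); ``M`` is zero on the first
pass, when no higher-level output exists.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import nn
from .nn import (
    BatchNorm2d,
    Conv2d,
    ConvTranspose2d,
    GroupNorm,
    Linear,
    Module,
    Tensor,
    adaptive_avg_pool2d,
    channel_mean,
    concat,
    conv2d,
    max_pool2d,
    relu,
    reshape,
)

VARIANTS = ("B", "BL", "BT", "BLT", "BD",
            "C", "CL", "CS", "CT", "CLT", "C-V1V1", "C-ITIT", "CD",
            "VGG11", "VGG16")

RECURRENT = {"BL", "BT", "BLT", "CL", "CS", "CT", "CLT", "C-V1V1", "C-ITIT"}

_C_PLAN = (64, 128, 256, 512)
_B_PLAN = (64, 64, 128, 128)
_CD_EXPANSION = 3.5  # appended-block width as a multiple of the area's width


class ModelError(ValueError):
    pass


def canonical_variant(name: str) -> str:
    key = name.replace(" ", "").replace("-", "").replace("_", "").upper()
    for v in VARIANTS:
        if v.replace("-", "") == key:
            return v
    raise ModelError(f"unknown variant {name!r}")


@dataclass(frozen=True)
class ModelSpec:
    """Architecture description; ``width_scale`` shrinks every channel plan
    proportionally for desk-scale runs."""

    variant: str
    timesteps: int = 5
    n_classes: int = 1000
    input_size: int | None = None
    width_scale: float = 1.0
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "variant", canonical_variant(self.variant))
        if self.timesteps < 1:
            raise ModelError("timesteps must be >= 1")

    @property
    def family(self) -> str:
        if self.variant.startswith("VGG"):
            return "VGG"
        return "B" if self.variant[0] == "B" else "C"

    @property
    def recurrent(self) -> bool:
        return self.variant in RECURRENT

    @property
    def default_input_size(self) -> int:
        return 128 if self.family == "B" else 224

    @property
    def resolved_input_size(self) -> int:
        return self.input_size or self.default_input_size


def _scale_plan(plan, ws: float) -> tuple[int, ...]:
    return tuple(max(4, int(round(c * ws))) for c in plan)


@dataclass
class UnrollTrace:
    """Per-timestep logits of one unrolled run; the final row is the
    model's decision output."""

    logits: np.ndarray  # (T, N, n_classes)

    @property
    def final(self) -> np.ndarray:
        return self.logits[-1]


# ---------------------------------------------------------------------------
# Functional pieces of the top-down scheme
# ---------------------------------------------------------------------------


def conv_norm_relu(x: Tensor, weight: Tensor, norm: Module,
                   stride: int = 1, pad: int | None = None) -> Tensor:
    """R(N(x * theta)): convolution, normalisation, ReLU."""
    k = weight.shape[2]
    return relu(norm(conv2d(x, weight, stride=stride,
                            pad=k // 2 if pad is None else pad)))


def process_top_down(m_i: Tensor, x: Tensor) -> Tensor:
    """Adaptive-average-pool a higher block's output to x's spatial size,
    then average over channels, yielding one channel at x's resolution."""
    pooled = adaptive_avg_pool2d(m_i, x.shape[2])
    return channel_mean(pooled)


def aggregate_top_down(higher_outputs, x: Tensor) -> Tensor:
    """Concatenate processed top-down maps, nearest higher block first.

    An empty list yields an all-zero single-channel map (first pass)."""
    if not higher_outputs:
        n = x.shape[0]
        return Tensor(np.zeros((n, 1, x.shape[2], x.shape[3])))
    return concat([process_top_down(m, x) for m in higher_outputs], axis=1)


# ---------------------------------------------------------------------------
# Blocks.  Uniform call contract: block(x, state, higher) -> (y, state, td_src)
#   state   -- same-layer output carried to the next timestep (or None)
#   higher  -- list of higher-layer outputs from the previous timestep
#   td_src  -- what lower layers should see as this layer's top-down source
# ---------------------------------------------------------------------------


class ZBlock(Module):
    """CORnet-Z style feedforward block: conv -> ReLU -> maxpool."""

    def __init__(self, c_in, c_out, kernel=3, stride=1, pool=True, rng=None):
        super().__init__()
        self.add_module("conv", Conv2d(c_in, c_out, kernel, stride, rng=rng))
        self.pool = pool
        self.final_conv = "conv"

    def __call__(self, x, state=None, higher=None):
        y = relu(self.conv(x))
        if self.pool:
            y = max_pool2d(y, 3, 2)
        return y, None, y


class ConvBNBlock(Module):
    """conv -> batch norm -> ReLU, optional 2x2 pooling; the appended block
    of the deeper feedforward controls (CD, BD) and the B-family skeleton."""

    def __init__(self, c_in, c_out, kernel=3, stride=1, pool=False, rng=None):
        super().__init__()
        self.add_module("conv", Conv2d(c_in, c_out, kernel, stride, rng=rng))
        self.add_module("norm", BatchNorm2d(c_out))
        self.pool = pool
        self.final_conv = "conv"

    def __call__(self, x, state=None, higher=None):
        y = relu(self.norm(self.conv(x)))
        if self.pool:
            y = max_pool2d(y, 2, 2)
        return y, None, y


class RTBlock(Module):
    """Additive lateral block (CORblock-RT scheme): the previous-timestep
    output re-enters through its own convolution before norm + ReLU."""

    def __init__(self, c_in, c_out, kernel=3, stride=2, rng=None):
        super().__init__()
        self.add_module("conv_ff", Conv2d(c_in, c_out, kernel, stride, rng=rng))
        self.add_module("conv_lat", Conv2d(c_out, c_out, 3, 1, rng=rng))
        self.add_module("norm", GroupNorm(c_out))
        self.final_conv = "conv_ff"

    def __call__(self, x, state=None, higher=None):
        z = self.conv_ff(x)
        if state is not None:
            z = z + self.conv_lat(state)
        y = relu(self.norm(z))
        return y, y, y


class CTBlock(Module):
    """Top-down block of the CT/CLT scheme (optionally with lateral state).

    ``n_higher`` fixes the channel count of the aggregated top-down map M;
    blocks with no higher area (the top of the hierarchy) drop the TD branch.
    """

    def __init__(self, c_in, c_out, n_higher, kernel=3, stride=2,
                 lateral=False, rng=None):
        super().__init__()
        self.n_higher = n_higher
        self.lateral = lateral
        self.add_module("conv_ff", Conv2d(c_in, c_out, kernel, stride, rng=rng))
        self.add_module("norm_ff", GroupNorm(c_out))
        branches = 1
        if n_higher > 0:
            self.add_module("conv_td",
                            Conv2d(n_higher, c_out, kernel, stride, rng=rng))
            self.add_module("norm_td", GroupNorm(c_out))
            branches += 1
        if lateral:
            self.add_module("conv_rr", Conv2d(c_out, c_out, 1, 1, pad=0, rng=rng))
            self.add_module("norm_rr", GroupNorm(c_out))
            branches += 1
        self.add_module("conv_out", Conv2d(branches * c_out, c_out, 3, 1, rng=rng))
        self.add_module("norm_out", GroupNorm(c_out))
        self.final_conv = "conv_out"

    def __call__(self, x, state=None, higher=None):
        ff = conv_norm_relu(x, self.conv_ff.w, self.norm_ff,
                            stride=self.conv_ff.stride)
        branches = [ff]
        if self.lateral:
            if state is None:
                state = Tensor(np.zeros(ff.shape))
            rr = conv_norm_relu(state, self.conv_rr.w, self.norm_rr, pad=0)
            branches.append(rr)
        if self.n_higher > 0:
            if higher:
                M = aggregate_top_down(higher, x)
            else:  # first pass: no higher-level information, M = 0
                M = Tensor(np.zeros((x.shape[0], self.n_higher,
                                     x.shape[2], x.shape[3])))
            td = conv_norm_relu(M, self.conv_td.w, self.norm_td,
                                stride=self.conv_td.stride)
            branches.append(td)
        xp = concat(branches, axis=1) if len(branches) > 1 else branches[0]
        y = conv_norm_relu(xp, self.conv_out.w, self.norm_out)
        return y, y, y


class BBlock(Module):
    """B-family block: bottom-up conv, plus (optionally) a lateral conv of
    the previous state and a transposed conv of the adjacent higher layer's
    previous output, combined additively before norm + ReLU, then pooled."""

    def __init__(self, c_in, c_out, higher_c=None, lateral=False, rng=None):
        super().__init__()
        self.add_module("conv_ff", Conv2d(c_in, c_out, 3, 1, rng=rng))
        if lateral:
            self.add_module("conv_lat", Conv2d(c_out, c_out, 3, 1, rng=rng))
        if higher_c:
            self.add_module("conv_td",
                            ConvTranspose2d(higher_c, c_out, 4, 2, 1, rng=rng))
        self.lateral = lateral
        self.higher_c = higher_c
        self.add_module("norm", BatchNorm2d(c_out))
        self.final_conv = "conv_ff"

    def __call__(self, x, state=None, higher=None):
        z = self.conv_ff(x)
        if self.lateral and state is not None:
            z = z + self.conv_lat(state)
        if self.higher_c and higher:
            z = z + self.conv_td(higher[0])
        y = relu(self.norm(z))
        return max_pool2d(y, 2, 2), y, y


class CORblockS(Module):
    """Bottleneck-residual block with ``times`` weight-shared internal passes
    and per-pass normalisation (the CORnet-S recipe)."""

    expansion = 4

    def __init__(self, c_in, c_out, times, rng=None):
        super().__init__()
        self.times = times
        mid = c_out * self.expansion
        self.add_module("conv_input", Conv2d(c_in, c_out, 1, 1, pad=0, rng=rng))
        self.add_module("skip", Conv2d(c_out, c_out, 1, 2, pad=0, rng=rng))
        self.add_module("norm_skip", BatchNorm2d(c_out))
        self.add_module("conv1", Conv2d(c_out, mid, 1, 1, pad=0, rng=rng))
        self.add_module("conv2", Conv2d(mid, mid, 3, 1, rng=rng))
        self.add_module("conv3", Conv2d(mid, c_out, 1, 1, pad=0, rng=rng))
        for t in range(times):
            self.add_module(f"norm1_{t}", BatchNorm2d(mid))
            self.add_module(f"norm2_{t}", BatchNorm2d(mid))
            self.add_module(f"norm3_{t}", BatchNorm2d(c_out))
        self.final_conv = "conv3"

    def __call__(self, x, state=None, higher=None):
        h = self.conv_input(x)
        for t in range(self.times):
            if t == 0:
                skip = self.norm_skip(self.skip(h))
                stride = 2
            else:
                skip = h
                stride = 1
            y = relu(self._children[f"norm1_{t}"](self.conv1(h)))
            y = conv2d(y, self.conv2.w, stride=stride, pad=1)
            y = relu(self._children[f"norm2_{t}"](y))
            y = self._children[f"norm3_{t}"](self.conv3(y))
            h = relu(y + skip)
        return h, None, h


class Sequential(Module):
    def __init__(self, blocks):
        super().__init__()
        self.blocks = blocks
        for i, b in enumerate(blocks):
            self.add_module(str(i), b)

    def __call__(self, x, state=None, higher=None):
        for b in self.blocks:
            x, _, _ = b(x)
        return x, None, x

    @property
    def final_conv_block(self):
        for b in reversed(self.blocks):
            if hasattr(b, "final_conv"):
                return b
        raise ModelError("no convolutional block in this stack")


class GAPDecoder(Module):
    """Global average pool + single linear readout."""

    def __init__(self, c_in, n_classes, rng=None):
        super().__init__()
        self.c_in = c_in
        self.add_module("fc", Linear(c_in, n_classes, rng=rng))

    def __call__(self, x):
        h = adaptive_avg_pool2d(x, 1)
        h = reshape(h, (x.shape[0], x.shape[1]))
        return self.fc(h)

    @property
    def head(self):
        return self.fc

    def swap(self, n_classes, rng):
        self.add_module("fc", Linear(self.c_in, n_classes, rng=rng))


class VGGHead(Module):
    """Two 4096-unit hidden layers + readout (the VGG16 classifier)."""

    def __init__(self, n_in, n_classes, hidden=4096, rng=None):
        super().__init__()
        self.hidden = hidden
        self.add_module("fc1", Linear(n_in, hidden, rng=rng))
        self.add_module("fc2", Linear(hidden, hidden, rng=rng))
        self.add_module("fc3", Linear(hidden, n_classes, rng=rng))

    def __call__(self, x):
        n = x.shape[0]
        h = reshape(x, (n, int(np.prod(x.shape[1:]))))
        h = relu(self.fc1(h))
        h = relu(self.fc2(h))
        return self.fc3(h)

    @property
    def head(self):
        return self.fc3

    def swap(self, n_classes, rng):
        self.add_module("fc3", Linear(self.hidden, n_classes, rng=rng))


class FlatDecoder(Module):
    """Flatten + single linear readout (the custom VGG11 head)."""

    def __init__(self, n_in, n_classes, rng=None):
        super().__init__()
        self.n_in = n_in
        self.add_module("fc", Linear(n_in, n_classes, rng=rng))

    def __call__(self, x):
        h = reshape(x, (x.shape[0], int(np.prod(x.shape[1:]))))
        return self.fc(h)

    @property
    def head(self):
        return self.fc

    def swap(self, n_classes, rng):
        self.add_module("fc", Linear(self.n_in, n_classes, rng=rng))


# ---------------------------------------------------------------------------
# The model container and unrolling
# ---------------------------------------------------------------------------


class Model(Module):
    """An ordered stack of blocks plus a decoder, unrolled over timesteps.

    At pass t each block consumes the current bottom-up input, its own
    state from pass t-1, and (per its top-down scope) higher-block outputs
    from pass t-1; feedforward variants ignore both and therefore produce
    identical logits at every timestep.
    """

    def __init__(self, spec: ModelSpec, layer_names, blocks, decoder,
                 td_scope: str):
        super().__init__()
        self.spec = spec
        self.layer_names = list(layer_names)
        self.blocks = list(blocks)
        self.td_scope = td_scope  # 'none' | 'adjacent' | 'all_higher'
        for name, block in zip(self.layer_names, self.blocks):
            self.add_module(name, block)
        self.add_module("decoder", decoder)

    # -- single end-to-end pass ------------------------------------------
    def forward_pass(self, x: Tensor, states, prev_srcs, grad_from: int = 0):
        """One end-to-end pass.  Blocks below index ``grad_from`` run
        without graph taping (used when only the head and last conv train)."""
        n_layers = len(self.blocks)
        new_states = [None] * n_layers
        new_srcs = [None] * n_layers
        h = x
        for i, block in enumerate(self.blocks):
            if self.td_scope == "all_higher":
                higher = [prev_srcs[j] for j in range(i + 1, n_layers)
                          if prev_srcs[j] is not None]
            elif self.td_scope == "adjacent" and i + 1 < n_layers:
                higher = ([prev_srcs[i + 1]]
                          if prev_srcs[i + 1] is not None else [])
            else:
                higher = []
            if i < grad_from:
                with nn.no_grad():
                    h, new_states[i], new_srcs[i] = block(h, states[i], higher)
            else:
                h, new_states[i], new_srcs[i] = block(h, states[i], higher)
        return self.decoder(h), new_states, new_srcs

    def unroll(self, images: np.ndarray, timesteps: int | None = None,
               ) -> UnrollTrace:
        """Run T full input->output passes and record per-pass logits."""
        T = timesteps or self.spec.timesteps
        if T < 1:
            raise ModelError("timesteps must be >= 1")
        x = Tensor(np.asarray(images, dtype=float))
        if x.data.ndim == 3:
            x = Tensor(x.data[None])
        states = [None] * len(self.blocks)
        srcs = [None] * len(self.blocks)
        logits = []
        for _ in range(T):
            out, states, srcs = self.forward_pass(x, states, srcs)
            logits.append(out.data.copy())
        return UnrollTrace(logits=np.stack(logits))

    # -- bookkeeping ------------------------------------------------------
    def last_conv_parameter_names(self) -> list[str]:
        """Parameters of the final block's final convolution (the layer
        unfrozen together with the head in the first fine-tuning phase)."""
        name = self.layer_names[-1]
        block = self.blocks[-1]
        if isinstance(block, Sequential):
            sub = block.final_conv_block
            inner = block.blocks.index(sub)
            prefix = f"{name}.{inner}.{sub.final_conv}."
        else:
            prefix = f"{name}.{block.final_conv}."
        return [n for n, _ in self.named_parameters() if n.startswith(prefix)]

    def head_parameter_names(self) -> list[str]:
        prefix = "decoder."
        return [n for n, _ in self.named_parameters() if n.startswith(prefix)]


def unroll(model: Model, images: np.ndarray,
           timesteps: int | None = None) -> UnrollTrace:
    with nn.no_grad():
        return model.unroll(images, timesteps)


def count_parameters(model: Model) -> int:
    """Total number of trainable parameters."""
    return model.n_parameters()


def swap_head(model: Model, n_classes: int, seed: int = 0) -> Model:
    """Replace the decoder's readout with a fresh ``n_classes``-way linear
    map, preserving every other parameter bit-exactly (in place)."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 9151]))
    model.decoder.swap(n_classes, rng)
    model.spec = replace(model.spec, n_classes=n_classes)
    return model


# ---------------------------------------------------------------------------
# Builders
# ---------------------------------------------------------------------------


def _rng_stream(seed: int):
    ss = np.random.SeedSequence([seed, 20251])
    children = iter(ss.spawn(512))

    def next_rng():
        return np.random.default_rng(next(children))

    return next_rng


def _build_c_family(spec: ModelSpec, rngs) -> Model:
    plan = _scale_plan(_C_PLAN, spec.width_scale)
    names = ["V1", "V2", "V4", "IT"]
    v = spec.variant
    cd_width = [max(4, int(round(_CD_EXPANSION * c))) for c in plan]
    blocks = []
    td_scope = "all_higher" if v in ("CT", "CLT") else "none"
    c_in = 3
    for i, c_out in enumerate(plan):
        kernel, stride = (7, 2) if i == 0 else (3, 1)
        if v in ("CT", "CLT"):
            n_higher = len(plan) - 1 - i
            blocks.append(CTBlock(c_in, c_out, n_higher,
                                  kernel=kernel, stride=2,
                                  lateral=(v == "CLT"), rng=rngs()))
        elif v == "CL" or (v == "C-V1V1" and i == 0) or (v == "C-ITIT" and i == 3):
            blocks.append(RTBlock(c_in, c_out, kernel=kernel, stride=2,
                                  rng=rngs()))
        elif v == "CS":
            if i == 0:
                blocks.append(Sequential([
                    ConvBNBlock(c_in, c_out, 7, 2, rng=rngs()),
                    ZBlock(c_out, c_out, 3, 1, pool=True, rng=rngs()),
                ]))
            else:
                times = {1: 2, 2: 4, 3: 2}[i]
                blocks.append(CORblockS(c_in, c_out, times, rng=rngs()))
        elif v == "CD":
            w = cd_width[i]
            blocks.append(Sequential([
                ConvBNBlock(c_in, w, 3, 1, rng=rngs()),
                ConvBNBlock(w, w, 3, 1, rng=rngs()),
                ConvBNBlock(w, c_in, 3, 1, rng=rngs()),
                ZBlock(c_in, c_out, kernel, stride, pool=True, rng=rngs()),
            ]))
        else:  # C, and the non-lateral areas of C-V1V1 / C-ITIT
            blocks.append(ZBlock(c_in, c_out, kernel, stride, pool=True,
                                 rng=rngs()))
        c_in = c_out
    decoder = GAPDecoder(plan[-1], spec.n_classes, rng=rngs())
    return Model(spec, names, blocks, decoder, td_scope)


def _build_b_family(spec: ModelSpec, rngs) -> Model:
    plan = _scale_plan(_B_PLAN, spec.width_scale)
    names = ["v1", "v2", "v4", "it"]
    v = spec.variant
    lateral = v in ("BL", "BLT")
    topdown = v in ("BT", "BLT")
    blocks = []
    c_in = 3
    for i, c_out in enumerate(plan):
        higher_c = plan[i + 1] if (topdown and i + 1 < len(plan)) else None
        if v == "BD":
            blocks.append(Sequential([
                ConvBNBlock(c_in, c_out, 3, 1, pool=True, rng=rngs()),
                ConvBNBlock(c_out, c_out, 3, 1, rng=rngs()),
                ConvBNBlock(c_out, c_out, 3, 1, rng=rngs()),
            ]))
        else:
            blocks.append(BBlock(c_in, c_out, higher_c=higher_c,
                                 lateral=lateral, rng=rngs()))
        c_in = c_out
    decoder = GAPDecoder(plan[-1], spec.n_classes, rng=rngs())
    return Model(spec, names, blocks, decoder,
                 "adjacent" if topdown else "none")


_VGG16_CFG = (64, 64, "M", 128, 128, "M", 256, 256, 256, "M",
              512, 512, 512, "M", 512, 512, 512, "M")
_VGG11_CFG = (64, 64, "M", 128, "M", 256, 256, "M",
              512, 512, "M", 512, 512, "M")


def _build_vgg(spec: ModelSpec, rngs) -> Model:
    cfg = _VGG16_CFG if spec.variant == "VGG16" else _VGG11_CFG
    ws = spec.width_scale
    blocks = []
    c_in = 3
    size = spec.resolved_input_size
    for item in cfg:
        if item == "M":
            blocks.append(_VGGPool())
            size //= 2
        else:
            c_out = max(4, int(round(item * ws)))
            blocks.append(_VGGConv(c_in, c_out, rng=rngs()))
            c_in = c_out
    if spec.variant == "VGG16":
        target = min(7, size)
        features = Sequential(blocks + [_VGGAdaptive(target)])
        decoder = VGGHead(c_in * target * target, spec.n_classes,
                          hidden=max(16, int(round(4096 * ws))), rng=rngs())
    else:
        target = min(4, size)
        features = Sequential(blocks + [_VGGAdaptive(target)])
        decoder = FlatDecoder(c_in * target * target, spec.n_classes,
                              rng=rngs())
    return Model(spec, ["features"], [features], decoder, "none")


class _VGGConv(Module):
    def __init__(self, c_in, c_out, rng=None):
        super().__init__()
        self.add_module("conv", Conv2d(c_in, c_out, 3, 1, rng=rng))
        self.final_conv = "conv"

    def __call__(self, x, state=None, higher=None):
        return relu(self.conv(x)), None, None


class _VGGPool(Module):
    def __call__(self, x, state=None, higher=None):
        return max_pool2d(x, 2, 2), None, None


class _VGGAdaptive(Module):
    def __init__(self, target):
        super().__init__()
        self.target = target

    def __call__(self, x, state=None, higher=None):
        return adaptive_avg_pool2d(x, self.target), None, None


def build_model(spec: ModelSpec | str, **overrides) -> Model:
    """Construct a zoo architecture from its spec (or variant name)."""
    if isinstance(spec, str):
        spec = ModelSpec(variant=spec, **overrides)
    rngs = _rng_stream(spec.seed)
    if spec.family == "C":
        return _build_c_family(spec, rngs)
    if spec.family == "B":
        return _build_b_family(spec, rngs)
    return _build_vgg(spec, rngs)


def save_checkpoint(model: Model, path) -> None:
    """Serialised weights (.npz) plus a JSON sidecar manifest."""
    import json
    from pathlib import Path

    path = Path(path)
    np.savez(path, **model.state_dict())
    manifest = {
        "variant": model.spec.variant,
        "timesteps": model.spec.timesteps,
        "n_classes": model.spec.n_classes,
        "input_size": model.spec.input_size,
        "width_scale": model.spec.width_scale,
        "seed": model.spec.seed,
    }
    path.with_suffix(".json").write_text(json.dumps(manifest, indent=2))


def load_checkpoint(path) -> Model:
    import json
    from pathlib import Path

    path = Path(path)
    manifest = json.loads(path.with_suffix(".json").read_text())
    model = build_model(ModelSpec(**manifest))
    with np.load(path if path.suffix == ".npz"
                 else path.with_suffix(".npz")) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model


def tiny_spec(variant: str, n_classes: int = 8, timesteps: int = 2,
              seed: int = 0) -> ModelSpec:
    """A reduced-width, reduced-resolution spec for desk-scale runs."""
    variant = canonical_variant(variant)
    size = 32 if canonical_variant(variant)[0] == "B" else 64
    if variant.startswith("VGG"):
        size = 64
    return ModelSpec(variant=variant, timesteps=timesteps, n_classes=n_classes,
                     input_size=size, width_scale=0.125, seed=seed)
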