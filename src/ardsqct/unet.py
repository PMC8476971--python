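"""A modified 2-D U-Net for lung segmentation, implemented in numpy.

The network follows the classic encoder-decoder layout with skip
connections, scaled down from the original U-Net: the first contraction
level filters the input twice with ``base_channels`` (default 32) 3x3
kernels; each downsampling step is a 3x3 convolution with stride 2 that
halves the spatial size and doubles the channel count, until the bottleneck
(e.g. 512 px input, depth 5 -> 16x16 feature maps with 1024 channels).  The
expansion path upsamples by value duplication (nearest neighbour, factor 2),
applies an "up-convolution" halving the channels, concatenates the skip
feature map from the contraction path, and filters twice again.  Every
convolution uses SAME padding and is followed by batch normalization and a
leaky ReLU (alpha = 0.1), except the final 1x1 output convolution, which has
a single filter and no activation.  A dropout layer (p = 0.4) sits between
the two bottleneck convolutions.  All weights use Xavier (Glorot) uniform
initialization.

Convolution follows the discrete-convolution orientation
``O[i,j] = sum_{p,q} I[i-p, j-q] * K[p,q]`` (flipped kernel); since kernels
are learned this is equivalent to cross-correlation up to a relabeling.

Everything — forward pass, backpropagation, parameter storage — is plain
numpy so the network trains on a CPU without any deep-learning framework.
Arrays are NCHW float32.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, asdict

import numpy as np

XAVIER_VARIANT = "glorot-uniform-fan-avg"


@dataclass
class UNetConfig:
    """Architecture parameterization; the full-scale network is (512, 32, 5)."""

    input_size_px: int = 512
    base_channels: int = 32
    depth: int = 5
    kernel_size: int = 3  # fixed
    lrelu_alpha: float = 0.1
    dropout_p: float = 0.4
    padding: str = "SAME"  # fixed

    def validate(self) -> None:
        n = self.input_size_px
        if n < 1 or (n & (n - 1)) != 0:
            raise ValueError("input_size_px must be a power of two")
        if self.base_channels < 1:
            raise ValueError("base_channels must be >= 1")
        if self.depth < 1 or n // (2**self.depth) < 4:
            raise ValueError("input_size_px / 2**depth must be >= 4")
        if self.kernel_size != 3:
            raise ValueError("kernel size is fixed at 3")
        if self.padding != "SAME":
            raise ValueError("padding is fixed at SAME")


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


def leaky_relu(x, alpha: float = 0.1):
    """f(x) = x for x >= 0, alpha*x otherwise."""
    x = np.asarray(x)
    return np.where(x >= 0, x, alpha * x)


def _xavier_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> np.ndarray:
    a = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-a, a, size=shape).astype(np.float32)


class Conv2d:
    """3x3 (or 1x1) convolution, SAME padding, stride 1 or 2, with backprop.

    Implements the flipped-kernel (true convolution) orientation.  For
    stride 2 the output size is H/2 for even H.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int, rng: np.random.Generator):
        if stride not in (1, 2):
            raise ValueError("stride must be 1 or 2")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.k = kernel_size
        self.stride = stride
        fan_in = in_channels * kernel_size * kernel_size
        fan_out = out_channels * kernel_size * kernel_size
        self.W = Param(_xavier_uniform(rng, (out_channels, in_channels, kernel_size, kernel_size),
                                       fan_in, fan_out))
        self.b = Param(np.zeros(out_channels, dtype=np.float32))
        self._xpad = None

    def params(self):
        return [("W", self.W), ("b", self.b)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.in_channels:
            raise ValueError(f"expected {self.in_channels} input channels, got {c}")
        k, s = self.k, self.stride
        if k == 1:
            out = np.tensordot(x, self.W.value[:, :, 0, 0], axes=([1], [1]))
            out = out.transpose(0, 3, 1, 2)
            self._xpad = x
        else:
            if s == 1:
                xpad = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
                ho, wo = h, w
            else:
                if h % 2 or w % 2:
                    raise ValueError("stride-2 convolution requires even spatial size")
                xpad = np.pad(x, ((0, 0), (0, 0), (1, 0), (1, 0)))
                ho, wo = h // 2, w // 2
            out = np.zeros((n, ho, wo, self.out_channels), dtype=np.float32)
            for a in range(k):
                for bq in range(k):
                    sl = xpad[:, :, 2 - a : 2 - a + s * ho : s, 2 - bq : 2 - bq + s * wo : s]
                    out += np.tensordot(sl, self.W.value[:, :, a, bq], axes=([1], [1]))
            out = out.transpose(0, 3, 1, 2)
            self._xpad = xpad
            self._outshape = (ho, wo)
        out += self.b.value[None, :, None, None]
        if train:
            self._train_cache = True
        return np.ascontiguousarray(out)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        k, s = self.k, self.stride
        xpad = self._xpad
        if k == 1:
            gW = np.tensordot(gout, xpad, axes=([0, 2, 3], [0, 2, 3]))
            self.W.grad += gW[:, :, None, None]
            self.b.grad += gout.sum(axis=(0, 2, 3))
            gx = np.tensordot(gout, self.W.value[:, :, 0, 0], axes=([1], [0]))
            return np.ascontiguousarray(gx.transpose(0, 3, 1, 2))
        ho, wo = self._outshape
        gxpad = np.zeros_like(xpad)
        for a in range(k):
            for bq in range(k):
                sl = xpad[:, :, 2 - a : 2 - a + s * ho : s, 2 - bq : 2 - bq + s * wo : s]
                self.W.grad[:, :, a, bq] += np.tensordot(gout, sl, axes=([0, 2, 3], [0, 2, 3]))
                g = np.tensordot(gout, self.W.value[:, :, a, bq], axes=([1], [0]))
                gxpad[:, :, 2 - a : 2 - a + s * ho : s, 2 - bq : 2 - bq + s * wo : s] += (
                    g.transpose(0, 3, 1, 2)
                )
        self.b.grad += gout.sum(axis=(0, 2, 3))
        if s == 1:
            return np.ascontiguousarray(gxpad[:, :, 1:-1, 1:-1])
        return np.ascontiguousarray(gxpad[:, :, 1:, 1:])


class BatchNorm2d:
    """Per-channel batch normalization with running statistics for inference."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        self.channels = channels
        self.eps = eps
        self.momentum = momentum
        self.gamma = Param(np.ones(channels, dtype=np.float32))
        self.beta = Param(np.zeros(channels, dtype=np.float32))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def params(self):
        return [("gamma", self.gamma), ("beta", self.beta)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        ivar = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * ivar[None, :, None, None]
        if train:
            self._xhat = xhat
            self._ivar = ivar
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, gout: np.ndarray) -> np.ndarray:
        xhat, ivar = self._xhat, self._ivar
        n, c, h, w = gout.shape
        m = n * h * w
        gsum = gout.sum(axis=(0, 2, 3))
        gxhat_sum = (gout * xhat).sum(axis=(0, 2, 3))
        self.gamma.grad += gxhat_sum
        self.beta.grad += gsum
        coef = (self.gamma.value * ivar / m)[None, :, None, None]
        gx = coef * (m * gout - gsum[None, :, None, None] - xhat * gxhat_sum[None, :, None, None])
        return gx.astype(np.float32)


class LeakyReLU:
    def __init__(self, alpha: float):
        self.alpha = alpha

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._neg = x < 0
        out = np.where(x < 0, self.alpha * x, x)
        return out.astype(np.float32)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        return np.where(self._neg, self.alpha * gout, gout).astype(np.float32)


class Dropout:
    """Inverted dropout; identity at inference."""

    def __init__(self, p: float, rng: np.random.Generator):
        self.p = p
        self.rng = rng

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.p <= 0:
            return x
        mask = (self.rng.random(x.shape) >= self.p).astype(np.float32) / (1.0 - self.p)
        self._mask = mask
        return x * mask

    def backward(self, gout: np.ndarray) -> np.ndarray:
        return gout * self._mask


class Upsample2x:
    """Nearest-neighbour upsampling by value duplication (factor 2)."""

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        n, c, h, w = gout.shape
        return gout.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class ConvBNAct:
    """conv -> batch norm -> LReLU block."""

    def __init__(self, in_ch, out_ch, kernel, stride, alpha, rng):
        self.conv = Conv2d(in_ch, out_ch, kernel, stride, rng)
        self.bn = BatchNorm2d(out_ch)
        self.act = LeakyReLU(alpha)

    def params(self):
        out = [("conv." + n, p) for n, p in self.conv.params()]
        out += [("bn." + n, p) for n, p in self.bn.params()]
        return out

    def forward(self, x, train):
        return self.act.forward(self.bn.forward(self.conv.forward(x, train), train), train)

    def backward(self, g):
        return self.conv.backward(self.bn.backward(self.act.backward(g)))


class UNetModel:
    """The constructed network: layer graph plus weights.

    Use :func:`build_unet` to create one.  ``forward``/``backward`` operate
    on NCHW float32 batches; ``train=True`` enables batch statistics and
    dropout and caches intermediates for backprop.
    """

    def __init__(self, config: UNetConfig, seed: int):
        config.validate()
        self.config = config
        self.seed = int(seed)
        self.metadata = {"xavier_variant": XAVIER_VARIANT}
        rng = np.random.default_rng(seed)
        self.rng = rng
        c0, d, k, alpha = config.base_channels, config.depth, config.kernel_size, config.lrelu_alpha
        ch = [c0 * 2**i for i in range(d + 1)]

        self.enc: list[tuple[ConvBNAct, ConvBNAct]] = []
        self.down: list[ConvBNAct] = []
        in_ch = 1
        for lvl in range(d):
            a = ConvBNAct(in_ch, ch[lvl], k, 1, alpha, rng)
            b = ConvBNAct(ch[lvl], ch[lvl], k, 1, alpha, rng)
            self.enc.append((a, b))
            self.down.append(ConvBNAct(ch[lvl], ch[lvl + 1], k, 2, alpha, rng))
            in_ch = ch[lvl + 1]
        self.bott_a = ConvBNAct(ch[d], ch[d], k, 1, alpha, rng)
        self.bott_drop = Dropout(config.dropout_p, rng)
        self.bott_b = ConvBNAct(ch[d], ch[d], k, 1, alpha, rng)
        self.dec: list[tuple[Upsample2x, ConvBNAct, ConvBNAct, ConvBNAct]] = []
        for lvl in range(d - 1, -1, -1):
            up = Upsample2x()
            upconv = ConvBNAct(ch[lvl + 1], ch[lvl], k, 1, alpha, rng)
            a = ConvBNAct(2 * ch[lvl], ch[lvl], k, 1, alpha, rng)
            b = ConvBNAct(ch[lvl], ch[lvl], k, 1, alpha, rng)
            self.dec.append((up, upconv, a, b))
        self.final = Conv2d(c0, 1, 1, 1, rng)

    # -- layer/parameter registry ------------------------------------------

    def named_blocks(self):
        for i, (a, b) in enumerate(self.enc):
            yield f"enc{i}.a", a
            yield f"enc{i}.b", b
        for i, dn in enumerate(self.down):
            yield f"down{i}", dn
        yield "bott.a", self.bott_a
        yield "bott.b", self.bott_b
        for i, (_, upconv, a, b) in enumerate(self.dec):
            yield f"dec{i}.up", upconv
            yield f"dec{i}.a", a
            yield f"dec{i}.b", b
        yield "final", self.final

    def named_params(self):
        for bname, block in self.named_blocks():
            for pname, p in block.params():
                yield f"{bname}.{pname}", p

    def conv_layers(self) -> list[Conv2d]:
        convs = []
        for _, block in self.named_blocks():
            if isinstance(block, Conv2d):
                convs.append(block)
            elif isinstance(block, ConvBNAct):
                convs.append(block.conv)
        return convs

    def batchnorms(self) -> list[BatchNorm2d]:
        return [b.bn for _, b in self.named_blocks() if isinstance(b, ConvBNAct)]

    def zero_grad(self) -> None:
        for _, p in self.named_params():
            p.grad[...] = 0.0

    # -- computation --------------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[:, None]
        n, c, h, w = x.shape
        if h != self.config.input_size_px or w != self.config.input_size_px:
            raise ValueError(
                f"batch spatial size {h}x{w} does not match configured "
                f"{self.config.input_size_px}"
            )
        skips = []
        for (a, b), dn in zip(self.enc, self.down):
            x = b.forward(a.forward(x, train), train)
            skips.append(x)
            x = dn.forward(x, train)
        x = self.bott_b.forward(self.bott_drop.forward(self.bott_a.forward(x, train), train), train)
        self._skip_channels = []
        for (up, upconv, a, b), skip in zip(self.dec, reversed(skips)):
            x = upconv.forward(up.forward(x, train), train)
            self._skip_channels.append(x.shape[1])
            x = np.concatenate([skip, x], axis=1)
            x = b.forward(a.forward(x, train), train)
        out = self.final.forward(x, train)
        return out

    def backward(self, gout: np.ndarray) -> None:
        """Backpropagate d(loss)/d(output); accumulates parameter gradients."""
        g = self.final.backward(np.asarray(gout, dtype=np.float32))
        gskips = []
        for (up, upconv, a, b), nch in zip(reversed(self.dec), reversed(self._skip_channels)):
            g = a.backward(b.backward(g))
            gskip, g = g[:, :-nch], g[:, -nch:]
            gskips.append(gskip)
            g = up.backward(upconv.backward(g))
        g = self.bott_a.backward(self.bott_drop.backward(self.bott_b.backward(g)))
        for (aenc, benc), dn, gskip in zip(
            reversed(self.enc), reversed(self.down), reversed(gskips)
        ):
            g = dn.backward(g) + gskip
            g = aenc.backward(benc.backward(g))


def build_unet(config: UNetConfig, seed: int = 0) -> UNetModel:
    """Construct the network for a configuration; deterministic per seed."""
    return UNetModel(config, seed)


def forward(model: UNetModel, batch: np.ndarray) -> np.ndarray:
    """Inference forward pass: (N, H, W) or (N, 1, H, W) -> (N, H, W)."""
    out = model.forward(batch, train=False)
    return out[:, 0]


def predict_mask(model: UNetModel, image: np.ndarray, threshold: float = 0.0) -> np.ndarray:
    """Binary lung mask for one preprocessed slice (or a stack of slices).

    The network regresses onto targets in {-1, +1}; 0 is the symmetric
    decision boundary on the raw output.
    """
    image = np.asarray(image, dtype=np.float32)
    single = image.ndim == 2
    batch = image[None] if single else image
    out = forward(model, batch)
    mask = (out > threshold).astype(np.uint8)
    return mask[0] if single else mask


def level_shapes(config: UNetConfig) -> list[tuple[int, int]]:
    """(spatial size, channels) at each contraction level 0..depth.

    Level k lives at input/2**k pixels with base*2**k channels; the last
    entry is the bottleneck.
    """
    return [
        (config.input_size_px // 2**k, config.base_channels * 2**k)
        for k in range(config.depth + 1)
    ]


def count_kernels(model: UNetModel) -> int:
    """Total number of convolution filters (sum of output channels)."""
    return int(sum(c.out_channels for c in model.conv_layers()))


# -- checkpointing -----------------------------------------------------------

CHECKPOINT_VERSION = 1


def save_checkpoint(model: UNetModel, path, training_state: dict | None = None) -> None:
    """Persist config, seed, weights, BN statistics and training state."""
    arrays = {f"param/{n}": p.value for n, p in model.named_params()}
    for i, bn in enumerate(model.batchnorms()):
        arrays[f"bnstat/{i}/mean"] = bn.running_mean
        arrays[f"bnstat/{i}/var"] = bn.running_var
    header = {
        "version": CHECKPOINT_VERSION,
        "config": asdict(model.config),
        "seed": model.seed,
        "metadata": model.metadata,
        "training_state": training_state or {},
    }
    np.savez_compressed(path, __header__=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8),
                        **arrays)


def load_checkpoint(path) -> tuple[UNetModel, dict]:
    """Rebuild a model from a checkpoint; returns (model, training_state)."""
    with np.load(path) as data:
        header = json.loads(bytes(data["__header__"]).decode())
        if header["version"] != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {header['version']}")
        cfg = UNetConfig(**header["config"])
        model = build_unet(cfg, header["seed"])
        for n, p in model.named_params():
            p.value[...] = data[f"param/{n}"]
        for i, bn in enumerate(model.batchnorms()):
            bn.running_mean[...] = data[f"bnstat/{i}/mean"]
            bn.running_var[...] = data[f"bnstat/{i}/var"]
    model.metadata.update(header.get("metadata", {}))
    return model, header.get("training_state", {})
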