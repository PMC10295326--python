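"""Network building blocks and the translation architecture.

The generator follows the few-shot unpaired translation design: a content
encoder (stride-2 convolution stack with instance normalization, three
downsampling stages, so a 64x64 slice yields an 8x8 spatial content code), a
class encoder (convolution stack without normalization, globally pooled to a
class latent vector, averaged over the K target images), and a decoder whose
residual blocks are conditioned on the class code through AdaIN: two fully
connected heads map the class code to a scale (kept positive via softplus)
and a bias per channel, applied uniformly at every spatial location.
Upsampling is nearest-neighbour by a factor of 2 per stage.

The discriminator is a patch discriminator: one convolution, ten residual
blocks without normalization activated by Leaky ReLU, four 2x2 average
poolings, and a final convolution with one output channel per class (two
classes here), giving a 4x4 score map for a 64x64 input.

Channel widths default to a quarter-scale desk configuration; the layer
topology (counts of blocks, strides, poolings) is fixed.
"""

from __future__ import annotations

import numpy as np

from ._autograd import Tensor

__all__ = [
    "Module",
    "Conv2d",
    "Linear",
    "InstanceNorm2d",
    "ResBlock",
    "ContentEncoder",
    "ClassEncoder",
    "Decoder",
    "Generator",
    "Discriminator",
    "RMSProp",
]


class Module:
    """Base class: parameter discovery by attribute walk."""

    def parameters(self) -> list[Tensor]:
        out = []
        for v in vars(self).values():
            if isinstance(v, Tensor) and v.requires_grad:
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for u in v:
                    if isinstance(u, Module):
                        out.extend(u.parameters())
                    elif isinstance(u, Tensor) and u.requires_grad:
                        out.append(u)
        return out

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_arrays(self, arrays) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(f"expected {len(params)} arrays, got {len(arrays)}")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {a.shape}")
            p.data = np.asarray(a, dtype=np.float32)


def _he(rng, *shape) -> np.ndarray:
    fan_in = int(np.prod(shape[1:])) or 1
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Conv2d(Module):
    def __init__(self, rng, cin, cout, k, stride=1, pad=None):
        self.stride = stride
        self.pad = (k - 1) // 2 if pad is None else pad
        self.w = Tensor(_he(rng, cout, cin, k, k), requires_grad=True)
        self.b = Tensor(np.zeros(cout, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x.conv2d(self.w, self.b, stride=self.stride, pad=self.pad)


class Linear(Module):
    def __init__(self, rng, nin, nout):
        self.w = Tensor(_he(rng, nout, nin), requires_grad=True)
        self.b = Tensor(np.zeros(nout, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w.transpose(1, 0) + self.b


class InstanceNorm2d(Module):
    """Per-sample, per-channel normalization over spatial dims."""

    def __init__(self, ch, affine=True, eps=1e-5):
        self.eps = eps
        self.affine = affine
        if affine:
            self.gamma = Tensor(np.ones((1, ch, 1, 1), dtype=np.float32), requires_grad=True)
            self.beta = Tensor(np.zeros((1, ch, 1, 1), dtype=np.float32), requires_grad=True)

    def normalize(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=(2, 3), keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=(2, 3), keepdims=True)
        return xc * (var + self.eps).pow(-0.5)

    def __call__(self, x: Tensor) -> Tensor:
        y = self.normalize(x)
        if self.affine:
            y = y * self.gamma + self.beta
        return y


class ResBlock(Module):
    """Pre-activation residual block; optional instance norm (generator) or
    none (discriminator); 1x1 skip projection on channel change."""

    def __init__(self, rng, cin, cout, norm=True, activation="relu"):
        self.c1 = Conv2d(rng, cin, cout, 3)
        self.c2 = Conv2d(rng, cout, cout, 3)
        self.n1 = InstanceNorm2d(cin) if norm else None
        self.n2 = InstanceNorm2d(cout) if norm else None
        self.skip = Conv2d(rng, cin, cout, 1, pad=0) if cin != cout else None
        self.activation = activation

    def _act(self, x: Tensor) -> Tensor:
        return x.relu() if self.activation == "relu" else x.leaky_relu(0.2)

    def __call__(self, x: Tensor) -> Tensor:
        h = self.n1(x) if self.n1 else x
        h = self.c1(self._act(h))
        h = self.n2(h) if self.n2 else h
        h = self.c2(self._act(h))
        s = self.skip(x) if self.skip else x
        return h + s


class AdaINResBlock(Module):
    """Residual block whose normalizations are conditioned on the class
    code: features are instance-normalized, then scaled by sigma2 (softplus
    of the head output, hence positive) and shifted by mu, identically at
    every spatial location."""

    def __init__(self, rng, ch):
        self.c1 = Conv2d(rng, ch, ch, 3)
        self.c2 = Conv2d(rng, ch, ch, 3)
        self.norm = InstanceNorm2d(ch, affine=False)
        self.ch = ch

    def adain(self, x: Tensor, mu: Tensor, sigma2: Tensor) -> Tensor:
        # class codes broadcast over the content batch when K images share one code
        m = mu.shape[0]
        return self.norm.normalize(x) * sigma2.reshape(m, self.ch, 1, 1) + mu.reshape(
            m, self.ch, 1, 1
        )

    def __call__(self, x: Tensor, mu: Tensor, sigma2: Tensor) -> Tensor:
        h = self.adain(self.c1(x), mu, sigma2).relu()
        h = self.adain(self.c2(h), mu, sigma2)
        return h + x


class ContentEncoder(Module):
    """Convolution stack with instance norm + ReLU and three stride-2
    downsamples, followed by residual blocks: input HxW -> code H/8 x W/8."""

    def __init__(self, rng, base=8, in_ch=1, n_res=2):
        self.head = Conv2d(rng, in_ch, base, 7)
        self.norm0 = InstanceNorm2d(base)
        self.down = []
        ch = base
        for _ in range(3):
            self.down.append(Conv2d(rng, ch, ch * 2, 4, stride=2, pad=1))
            self.down.append(InstanceNorm2d(ch * 2))
            ch *= 2
        self.res = [ResBlock(rng, ch, ch, norm=True) for _ in range(n_res)]
        self.out_channels = ch

    def __call__(self, x: Tensor) -> Tensor:
        h, w = x.shape[2], x.shape[3]
        if h % 8 or w % 8:
            raise ValueError(f"input spatial dims ({h}x{w}) must be divisible by 8")
        z = self.norm0(self.head(x)).relu()
        for i in range(0, len(self.down), 2):
            z = self.down[i + 1](self.down[i](z)).relu()
        for r in self.res:
            z = r(z)
        return z


class ClassEncoder(Module):
    """Convolution stack (no normalization) pooled to a class latent vector;
    codes of the K target images are averaged."""

    def __init__(self, rng, base=8, in_ch=1, code_dim=64):
        chs = [base, base * 2, base * 4, base * 8]
        self.head = Conv2d(rng, in_ch, base, 7)
        self.convs = [
            Conv2d(rng, chs[i], chs[i + 1], 4, stride=2, pad=1) for i in range(3)
        ]
        self.proj = Linear(rng, chs[-1], code_dim)
        self.code_dim = code_dim

    def encode_one(self, y: Tensor) -> Tensor:
        z = self.head(y).relu()
        for c in self.convs:
            z = c(z).relu()
        z = z.mean(axis=(2, 3))  # global average pool -> (n, ch)
        return self.proj(z)

    def __call__(self, ys: list[Tensor]) -> Tensor:
        if not ys:
            raise ValueError("class encoder needs at least one target image (K >= 1)")
        code = self.encode_one(ys[0])
        for y in ys[1:]:
            code = code + self.encode_one(y)
        return code * np.float32(1.0 / len(ys))


class Decoder(Module):
    """AdaIN residual blocks conditioned on the class code, then three
    nearest-neighbour x2 upsampling stages back to input resolution."""

    def __init__(self, rng, ch, code_dim=64, n_adain=2, out_ch=1):
        self.blocks = [AdaINResBlock(rng, ch) for _ in range(n_adain)]
        # two fully connected networks: class code -> (mu_i, sigma2_i), i=1..n
        self.fc1 = Linear(rng, code_dim, 2 * code_dim)
        self.fc2 = Linear(rng, 2 * code_dim, n_adain * 2 * ch)
        self.up = []
        c = ch
        for _ in range(3):
            self.up.append(Conv2d(rng, c, c // 2, 5))
            self.up.append(InstanceNorm2d(c // 2))
            c //= 2
        self.tail = Conv2d(rng, c, out_ch, 7)
        self.ch = ch
        self.n_adain = n_adain

    def adain_params(self, zy: Tensor) -> list[tuple[Tensor, Tensor]]:
        h = self.fc1(zy).relu()
        p = self.fc2(h)  # (n, n_adain * 2 * ch)
        out = []
        for i in range(self.n_adain):
            mu = p[:, 2 * i * self.ch : (2 * i + 1) * self.ch]
            raw = p[:, (2 * i + 1) * self.ch : (2 * i + 2) * self.ch]
            out.append((mu, raw.softplus() + np.float32(1e-4)))
        return out

    def __call__(self, zx: Tensor, zy: Tensor) -> Tensor:
        params = self.adain_params(zy)
        h = zx
        for blk, (mu, s2) in zip(self.blocks, params):
            h = blk(h, mu, s2)
        for i in range(0, len(self.up), 2):
            h = h.upsample_nearest(2)
            h = self.up[i + 1](self.up[i](h)).relu()
        return self.tail(h).tanh()


class Generator(Module):
    """x-bar = F(E_x(x), E_y(y_1..y_K)): content encoding of the source,
    class encoding of the target(s), AdaIN-conditioned decoding."""

    def __init__(self, rng, base=8, code_dim=64):
        self.content = ContentEncoder(rng, base=base)
        self.klass = ClassEncoder(rng, base=base, code_dim=code_dim)
        self.decoder = Decoder(rng, self.content.out_channels, code_dim=code_dim)

    def __call__(self, x: Tensor, ys) -> Tensor:
        if isinstance(ys, Tensor):
            ys = [ys]
        return self.decoder(self.content(x), self.klass(ys))


class Discriminator(Module):
    """Patch discriminator: Conv -> 10 ResBlks (no normalization, Leaky
    ReLU) with 4 average poolings -> Conv with S=2 output channels."""

    def __init__(self, rng, base=8, in_ch=1, n_classes=2):
        self.head = Conv2d(rng, in_ch, base, 3)
        widths = [base * m for m in (2, 2, 4, 4, 8, 8, 16, 16, 16, 16)]
        self.blocks = []
        ch = base
        for w in widths:
            self.blocks.append(ResBlock(rng, ch, w, norm=False, activation="leaky"))
            ch = w
        self.pool_after = {1, 3, 5, 7}  # pool after the 2nd, 4th, 6th, 8th block
        self.tail = Conv2d(rng, ch, n_classes, 1, pad=0)
        self.n_classes = n_classes

    def features(self, x: Tensor) -> Tensor:
        """The feature extractor D_f: everything but the final conv."""
        if min(x.shape[2], x.shape[3]) < 16:
            raise ValueError("input must be at least 16x16 to survive 4 poolings")
        h = self.head(x)
        for i, b in enumerate(self.blocks):
            h = b(h)
            if i in self.pool_after:
                h = h.avg_pool2d(2)
        return h

    def __call__(self, x: Tensor, class_index: int) -> Tensor:
        """Per-patch logit map for the given class channel."""
        return self.tail(self.features(x))[:, class_index]


class RMSProp:
    """Adaptive-step optimizer (RMSProp)."""

    def __init__(self, params, lr=1e-4, decay=0.99, eps=1e-8):
        self.params = list(params)
        self.lr, self.decay, self.eps = lr, decay, eps
        self.ms = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        for p, m in zip(self.params, self.ms):
            if p.grad is None:
                continue
            m *= self.decay
            m += (1.0 - self.decay) * (p.grad * p.grad)
            p.data -= (self.lr * p.grad / (np.sqrt(m) + self.eps)).astype(p.data.dtype)

    def state(self):
        return self.ms

    def load(self, ms):
        self.ms = [np.asarray(m, dtype=np.float32) for m in ms]
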