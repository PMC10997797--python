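"""Network building blocks on top of the in-repo autodiff engine.

Provides the encoder-decoder reconstruction network (U-Net style, residual
output head), the residual-block image-translation generator, the
patch-based discriminator, instance normalization, and an Adam optimizer.
Architectures come in a "paper" profile matching the published description
and a "toy" profile sized for CPU-scale tests.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concat, conv2d, no_grad, upsample2

__all__ = ["Module", "Conv2d", "InstanceNorm2d", "UNet", "ResnetGenerator",
           "PatchDiscriminator", "Adam", "no_grad"]


class Module:
    """Tiny module base: parameter collection and state (de)serialization."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []

        def visit(v):
            if isinstance(v, Tensor):
                if v.requires_grad:
                    params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    visit(item)

        for v in vars(self).values():
            visit(v)
        return params

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("state array count mismatch")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("state array shape mismatch")
            p.data = np.asarray(a, dtype=np.float64).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 1,
                 pad: int | None = None, rng: np.random.Generator | None = None,
                 zero_init: bool = False, bias: bool = True):
        rng = rng or np.random.default_rng()
        self.stride = stride
        self.pad = k // 2 if pad is None else pad
        if zero_init:
            w = np.zeros((cout, cin, k, k))
        else:
            # He initialization
            w = rng.normal(0.0, np.sqrt(2.0 / (cin * k * k)), size=(cout, cin, k, k))
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(cout), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride, pad=self.pad)


class InstanceNorm2d(Module):
    """Per-sample, per-channel normalization over the spatial axes."""

    def __init__(self, c: int, eps: float = 1e-5, affine: bool = True):
        self.eps = eps
        self.gamma = Tensor(np.ones((1, c, 1, 1)), requires_grad=True) if affine else None
        self.beta = Tensor(np.zeros((1, c, 1, 1)), requires_grad=True) if affine else None

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=(2, 3), keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=(2, 3), keepdims=True)
        out = xc * ((var + self.eps) ** -0.5)
        if self.gamma is not None:
            out = out * self.gamma + self.beta
        return out


# --------------------------------------------------------------------------- #
# reconstruction network
# --------------------------------------------------------------------------- #

class UNet(Module):
    """Encoder-decoder with skip connections and a residual output head.

    The final convolution is zero-initialized, so an untrained network is
    the identity map; training learns a correction on top of the blurred
    input.  Output is left unclipped during training (losses see the raw
    values); inference clips to [0,1].
    """

    def __init__(self, channels: int = 1, levels: int = 4, base: int = 32,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.levels = levels
        widths = [base * 2**i for i in range(levels)]
        self.enc = []
        cin = channels
        for i, w in enumerate(widths):
            stride = 1 if i == 0 else 2
            self.enc.append([Conv2d(cin, w, 3, stride=stride, rng=rng),
                             Conv2d(w, w, 3, rng=rng)])
            cin = w
        self.dec = []
        for i in range(levels - 2, -1, -1):
            w = widths[i]
            self.dec.append([Conv2d(cin, w, 3, rng=rng),       # after upsample
                             Conv2d(2 * w, w, 3, rng=rng)])    # after skip concat
            cin = w
        self.head = Conv2d(cin, channels, 3, rng=rng, zero_init=True)

    def forward(self, x: Tensor) -> Tensor:
        skips = []
        h = x
        for c1, c2 in self.enc:
            h = c2(c1(h).relu()).relu()
            skips.append(h)
        for (c1, c2), skip in zip(self.dec, reversed(skips[:-1])):
            h = c1(upsample2(h)).relu()
            h = c2(concat([h, skip], axis=1)).relu()
        return x + self.head(h)


# --------------------------------------------------------------------------- #
# image translation networks
# --------------------------------------------------------------------------- #

class _ResBlock(Module):
    def __init__(self, c: int, rng):
        self.c1 = Conv2d(c, c, 3, rng=rng)
        self.n1 = InstanceNorm2d(c)
        self.c2 = Conv2d(c, c, 3, rng=rng)
        self.n2 = InstanceNorm2d(c)

    def forward(self, x: Tensor) -> Tensor:
        h = self.n1(self.c1(x)).relu()
        return x + self.n2(self.c2(h))


class ResnetGenerator(Module):
    """Residual-block generator: downsample x2, N residual blocks, upsample x2.

    The published profile uses 9 residual blocks; the toy profile uses 3
    with a narrower base width.  Output passes through a sigmoid so both
    image domains live in [0,1].
    """

    def __init__(self, cin: int, cout: int, n_blocks: int = 9, base: int = 64,
                 n_down: int = 2, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.inc = Conv2d(cin, base, 7, rng=rng)
        self.inn = InstanceNorm2d(base)
        self.down = []
        c = base
        for _ in range(n_down):
            self.down.append([Conv2d(c, c * 2, 3, stride=2, rng=rng),
                              InstanceNorm2d(c * 2)])
            c *= 2
        self.blocks = [_ResBlock(c, rng) for _ in range(n_blocks)]
        self.up = []
        for _ in range(n_down):
            self.up.append([Conv2d(c, c // 2, 3, rng=rng),
                            InstanceNorm2d(c // 2)])
            c //= 2
        self.out = Conv2d(c, cout, 7, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        h = self.inn(self.inc(x)).relu()
        for conv, norm in self.down:
            h = norm(conv(h)).relu()
        for b in self.blocks:
            h = b(h)
        for conv, norm in self.up:
            h = norm(conv(upsample2(h))).relu()
        return self.out(h).sigmoid()


class PatchDiscriminator(Module):
    """Patch-based discriminator: stacked stride-2 convolutions scoring
    overlapping receptive fields; returns a score map, not a single scalar.

    ``n_layers=3`` with 4x4 kernels gives the published 70x70 receptive
    field; the toy profile uses ``n_layers=2`` (34x34).
    """

    def __init__(self, cin: int, base: int = 64, n_layers: int = 3,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.first = Conv2d(cin, base, 4, stride=2, pad=1, rng=rng)
        self.mids = []
        c = base
        for _ in range(n_layers - 1):
            self.mids.append([Conv2d(c, c * 2, 4, stride=2, pad=1, rng=rng),
                              InstanceNorm2d(c * 2)])
            c *= 2
        self.pre = Conv2d(c, c, 4, stride=1, pad=1, rng=rng)
        self.pren = InstanceNorm2d(c)
        self.out = Conv2d(c, 1, 4, stride=1, pad=1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        h = self.first(x).leaky_relu(0.2)
        for conv, norm in self.mids:
            h = norm(conv(h)).leaky_relu(0.2)
        h = self.pren(self.pre(h)).leaky_relu(0.2)
        return self.out(h)


# --------------------------------------------------------------------------- #
# optimizer
# --------------------------------------------------------------------------- #

class Adam:
    """Adam with the common default moment coefficients (0.9, 0.999)."""

    def __init__(self, params: list[Tensor], lr: float,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        if lr <= 0:
            raise ValueError("learning rate must be > 0")
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            step = self.lr * mhat / (np.sqrt(vhat) + self.eps)
            p.data = (p.data - step).astype(p.data.dtype, copy=False)

    def state(self) -> dict:
        return {"t": self.t, "m": [a.copy() for a in self.m],
                "v": [a.copy() for a in self.v]}

    def load_state(self, state: dict) -> None:
        self.t = int(state["t"])
        self.m = [np.asarray(a, dtype=np.float64) for a in state["m"]]
        self.v = [np.asarray(a, dtype=np.float64) for a in state["v"]]
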