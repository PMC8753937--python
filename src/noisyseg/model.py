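"""A small U-Net-style encoder-decoder in plain NumPy with hand-written
backprop, sized for CPU training on desk-scale images.

Layout for depth d and width w: encoder levels of w, 2w, ..., a bottleneck
of ``2**(d-1) * w`` channels, nearest-neighbour upsampling with skip
concatenation on the way back up, and a 1x1 sigmoid head.  Input height and
width must be divisible by ``2**(d-1)``.

The forward pass caches im2col matrices; the backward pass accumulates
parameter gradients (call :meth:`zero_grad` between steps).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["UNet", "Adam", "sigmoid", "get_weights", "set_weights"]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


class _Conv:
    """k x k convolution, stride 1, same padding (k in {1, 3})."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator, dtype=np.float32):
        fan_in = cin * k * k
        self.W = Param(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout, cin, k, k)).astype(dtype))
        # small nonzero bias keeps preactivations off the exact ReLU kink
        self.b = Param(rng.uniform(-0.01, 0.01, size=cout).astype(dtype))
        self.k, self.cin, self.cout = k, cin, cout
        self._cols = None
        self._xshape = None

    def params(self):
        return [self.W, self.b]

    @staticmethod
    def _im2col(x: np.ndarray, k: int) -> np.ndarray:
        n, c, h, w = x.shape
        p = k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        cols = sliding_window_view(xp, (k, k), axis=(2, 3))
        return np.ascontiguousarray(cols.transpose(0, 2, 3, 1, 4, 5)).reshape(n * h * w, c * k * k)

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        cols = self._im2col(x, self.k)
        self._cols, self._xshape = cols, x.shape
        out = cols @ self.W.value.reshape(self.cout, -1).T + self.b.value
        return out.reshape(n, h, w, self.cout).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._xshape
        dmat = np.ascontiguousarray(dout.transpose(0, 2, 3, 1)).reshape(n * h * w, self.cout)
        self.W.grad += (dmat.T @ self._cols).reshape(self.W.value.shape)
        self.b.grad += dmat.sum(axis=0)
        # dx = same-padded conv of dout with the rotated, channel-swapped kernel
        w_rot = self.W.value[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
        cols = self._im2col(dout, self.k)
        dx = cols @ w_rot.reshape(self.cin, -1).T
        self._cols = None
        return dx.reshape(n, h, w, self.cin).transpose(0, 3, 1, 2)


class _ReLU:
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class _Block:
    """conv3-relu-conv3-relu."""

    def __init__(self, cin, cout, rng, dtype=np.float32):
        self.c1 = _Conv(cin, cout, 3, rng, dtype)
        self.r1 = _ReLU()
        self.c2 = _Conv(cout, cout, 3, rng, dtype)
        self.r2 = _ReLU()

    def params(self):
        return self.c1.params() + self.c2.params()

    def forward(self, x):
        return self.r2.forward(self.c2.forward(self.r1.forward(self.c1.forward(x))))

    def backward(self, dout):
        return self.c1.backward(self.r1.backward(self.c2.backward(self.r2.backward(dout))))


def _pool2(x):
    n, c, h, w = x.shape
    xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
    idx = xr.argmax(axis=-1)
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
    return out, (idx, x.shape)


def _pool2_back(dout, cache):
    idx, (n, c, h, w) = cache
    dxr = np.zeros((n, c, h // 2, w // 2, 4), dtype=dout.dtype)
    np.put_along_axis(dxr, idx[..., None], dout[..., None], axis=-1)
    return dxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)


def _up2(x):
    return x.repeat(2, axis=2).repeat(2, axis=3)


def _up2_back(dout):
    n, c, h, w = dout.shape
    return dout.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class UNet:
    def __init__(self, in_channels: int = 1, width: int = 8, depth: int = 4, seed: int = 0,
                 dtype=np.float32):
        if depth < 2:
            raise ValueError("depth must be >= 2")
        if width < 1:
            raise ValueError("width must be >= 1")
        rng = np.random.default_rng(seed)
        widths = [width * (2 ** i) for i in range(depth)]
        self.depth = depth
        self.dtype = np.dtype(dtype)
        self.enc = []
        cin = in_channels
        for wd in widths[:-1]:
            self.enc.append(_Block(cin, wd, rng, self.dtype))
            cin = wd
        self.bottleneck = _Block(cin, widths[-1], rng, self.dtype)
        self.dec = []
        cin = widths[-1]
        for wd in reversed(widths[:-1]):
            self.dec.append(_Block(cin + wd, wd, rng, self.dtype))
            cin = wd
        self.head = _Conv(widths[0], 1, 1, rng, self.dtype)

    def parameters(self) -> list[Param]:
        ps = []
        for blk in self.enc:
            ps += blk.params()
        ps += self.bottleneck.params()
        for blk in self.dec:
            ps += blk.params()
        ps += self.head.params()
        return ps

    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (N, C, H, W) -> logits (N, 1, H, W)."""
        x = np.asarray(x, dtype=self.dtype)
        div = 2 ** (self.depth - 1)
        if x.shape[2] % div or x.shape[3] % div:
            raise ValueError(f"input H and W must be divisible by {div}")
        skips, pools = [], []
        for blk in self.enc:
            x = blk.forward(x)
            skips.append(x)
            x, cache = _pool2(x)
            pools.append(cache)
        x = self.bottleneck.forward(x)
        self._pools = pools
        self._nskip = [s.shape[1] for s in skips]
        for blk, skip in zip(self.dec, reversed(skips)):
            x = np.concatenate([_up2(x), skip], axis=1)
            x = blk.forward(x)
        return self.head.forward(x)

    def backward(self, dlogits: np.ndarray) -> None:
        dx = self.head.backward(np.asarray(dlogits, dtype=self.dtype))
        dskips = []
        for blk, nch in zip(reversed(self.dec), self._nskip):
            d = blk.backward(dx)
            dup, dskip = d[:, :-nch], d[:, -nch:]
            dskips.append(dskip)
            dx = _up2_back(dup)
        dx = self.bottleneck.backward(dx)
        for blk, cache, dskip in zip(reversed(self.enc), reversed(self._pools), reversed(dskips)):
            dx = _pool2_back(dx, cache)
            dx = blk.backward(dx + dskip)

    def predict(self, image: np.ndarray) -> np.ndarray:
        """Probability map for a single 2-D image (canonical orientation)."""
        x = np.asarray(image, dtype=np.float64)[None, None]
        return sigmoid(self.forward(x))[0, 0]

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0


class Adam:
    def __init__(self, params: list[Param], lr: float, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * p.grad
            v *= self.b2
            v += (1.0 - self.b2) * p.grad ** 2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def get_weights(model: UNet) -> list[np.ndarray]:
    return [p.value.copy() for p in model.parameters()]


def set_weights(model: UNet, weights: list[np.ndarray]) -> None:
    for p, w in zip(model.parameters(), weights):
        p.value[...] = w
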