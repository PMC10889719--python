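"""Minimal CPU conv-net framework used by the tissue segmenter.

Implements exactly the pieces the encoder–decoder needs — 3x3 "same"
convolutions with batch normalization, ReLU, 2x2 max pooling, 2x2
stride-2 transposed convolutions, channel concatenation with dropout, a
1x1 projection head, softmax with class-weighted categorical cross-entropy,
and Adam — with hand-written backward passes (verified against numerical
gradients in the test suite).  Arrays are NCHW float32.

Not a general autodiff system; layers cache what their backward pass needs
and must be called forward-then-backward per step.
"""

from __future__ import annotations

import numpy as np


class Layer:
    params: list  # list of [value, grad] pairs

    def __init__(self):
        self.params = []

    def forward(self, x, train=True):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - interface
        raise NotImplementedError


def _im2col(x, k):
    """(N, C, H, W) -> (N, C*k*k, H*W) with reflect-free zero 'same' padding."""
    n, c, h, w = x.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    cols = np.empty((n, c * k * k, h * w), dtype=x.dtype)
    idx = 0
    for di in range(k):
        for dj in range(k):
            cols[:, idx * c : (idx + 1) * c, :] = xp[
                :, :, di : di + h, dj : dj + w
            ].reshape(n, c, h * w)
            idx += 1
    return cols


def _col2im(cols, shape, k):
    """Adjoint of :func:`_im2col`."""
    n, c, h, w = shape
    p = k // 2
    xp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=cols.dtype)
    idx = 0
    for di in range(k):
        for dj in range(k):
            xp[:, :, di : di + h, dj : dj + w] += cols[
                :, idx * c : (idx + 1) * c, :
            ].reshape(n, c, h, w)
            idx += 1
    return xp[:, :, p : p + h, p : p + w]


class Conv2D(Layer):
    """k x k convolution, stride 1, zero 'same' padding."""

    def __init__(self, cin, cout, k=3, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / (cin * k * k))  # He init
        self.W = (rng.standard_normal((cout, cin * k * k)) * scale).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.k = k
        self.cin = cin
        self.params = [[self.W, self.dW], [self.b, self.db]]

    def forward(self, x, train=True):
        n, c, h, w = x.shape
        self._shape = x.shape
        self._cols = _im2col(x, self.k)
        out = np.einsum("oc,ncp->nop", self.W, self._cols, optimize=True)
        out += self.b[None, :, None]
        return out.reshape(n, -1, h, w)

    def backward(self, grad):
        n, _, h, w = grad.shape
        g = grad.reshape(n, -1, h * w)
        self.dW += np.einsum("nop,ncp->oc", g, self._cols, optimize=True)
        self.db += g.sum(axis=(0, 2))
        dcols = np.einsum("oc,nop->ncp", self.W, g, optimize=True)
        self._cols = None
        return _col2im(dcols, self._shape, self.k)


class BatchNorm2D(Layer):
    def __init__(self, c, momentum=0.9, eps=1e-5):
        super().__init__()
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps
        self.params = [[self.gamma, self.dgamma], [self.beta, self.dbeta]]

    def forward(self, x, train=True):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps).astype(np.float32)
        self._xhat = (x - mean[None, :, None, None]) / self._std[None, :, None, None]
        self._train = train
        return self.gamma[None, :, None, None] * self._xhat + self.beta[None, :, None, None]

    def backward(self, grad):
        self.dgamma += (grad * self._xhat).sum(axis=(0, 2, 3))
        self.dbeta += grad.sum(axis=(0, 2, 3))
        g = grad * self.gamma[None, :, None, None]
        if not self._train:
            return g / self._std[None, :, None, None]
        m = grad.shape[0] * grad.shape[2] * grad.shape[3]
        dxhat = g
        dx = (
            dxhat
            - dxhat.mean(axis=(0, 2, 3), keepdims=True)
            - self._xhat * (dxhat * self._xhat).mean(axis=(0, 2, 3), keepdims=True)
        ) / self._std[None, :, None, None]
        self._xhat = None
        return dx


class ReLU(Layer):
    def forward(self, x, train=True):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class MaxPool2(Layer):
    """2x2 max pooling, stride 2 (spatial dims must be even)."""

    def forward(self, x, train=True):
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        xv = xr.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
        self._arg = xv.argmax(axis=-1)
        self._shape = x.shape
        return xv.max(axis=-1)

    def backward(self, grad):
        n, c, h, w = self._shape
        out = np.zeros((n, c, h // 2, w // 2, 4), dtype=grad.dtype)
        np.put_along_axis(out, self._arg[..., None], grad[..., None], axis=-1)
        out = out.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return out.reshape(n, c, h, w)


class ConvTranspose2(Layer):
    """2x2, stride-2 transposed convolution (doubles the spatial size)."""

    def __init__(self, cin, cout, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / cin)
        self.W = (rng.standard_normal((cin, cout, 2, 2)) * scale).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.params = [[self.W, self.dW], [self.b, self.db]]

    def forward(self, x, train=True):
        self._x = x
        n, c, h, w = x.shape
        out = np.einsum("nchw,codi->nohdwi", x, self.W, optimize=True)
        out = out.reshape(n, -1, h, 2, w, 2).reshape(n, out.shape[1], 2 * h, 2 * w)
        return out + self.b[None, :, None, None]

    def backward(self, grad):
        n, co, H, W_ = grad.shape
        g = grad.reshape(n, co, H // 2, 2, W_ // 2, 2)  # n,o,h,d,w,i
        self.dW += np.einsum("nchw,nohdwi->codi", self._x, g, optimize=True)
        self.db += grad.sum(axis=(0, 2, 3))
        dx = np.einsum("codi,nohdwi->nchw", self.W, g, optimize=True)
        self._x = None
        return dx


class Dropout(Layer):
    def __init__(self, rate, rng=None):
        super().__init__()
        self.rate = rate
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x, train=True):
        if not train or self.rate <= 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask.astype(np.float32)

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask


def softmax(logits):
    """Channel softmax of (N, C, H, W) logits."""
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def weighted_cross_entropy(logits, labels, class_weights):
    """Class-weighted categorical cross-entropy and its logits gradient.

    ``labels`` is (N, H, W) integer classes; pixel weights are the class
    weights of the true class, and the loss is the weighted mean of pixel
    cross-entropies.
    """
    p = softmax(logits)
    n, c, h, w = logits.shape
    onehot = np.zeros_like(p)
    idx = np.indices((n, h, w))
    onehot[idx[0], labels, idx[1], idx[2]] = 1.0
    wpix = np.asarray(class_weights, dtype=np.float32)[labels]  # (N,H,W)
    wsum = wpix.sum()
    logp = np.log(np.clip(p, 1e-12, None))
    loss = -(wpix * (onehot * logp).sum(axis=1)).sum() / wsum
    dlogits = (p - onehot) * wpix[:, None] / wsum
    return float(loss), dlogits.astype(np.float32)


class Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p[0]) for p in params]
        self.v = [np.zeros_like(p[0]) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1c = 1 - self.beta1**self.t
        b2c = 1 - self.beta2**self.t
        for i, (p, g) in enumerate(self.params):
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            p -= self.lr * (self.m[i] / b1c) / (np.sqrt(self.v[i] / b2c) + self.eps)

    def zero_grad(self):
        for _, g in self.params:
            g[...] = 0.0


class UNet:
    """Encoder–decoder with skip concatenations for per-pixel classification.

    ``depth`` pooling levels halve the resolution each; with a 512-pixel
    input and depth 4 the bottleneck feature map is 32 x 32.  Batch
    normalization follows every 3x3 convolution; dropout follows each skip
    concatenation.  ``base_channels`` doubles per level.
    """

    def __init__(self, in_channels=3, n_classes=3, depth=4, base_channels=16,
                 dropout_rate=0.05, seed=0):
        self.depth = depth
        self.base_channels = base_channels
        self.n_classes = n_classes
        rng = np.random.default_rng(seed)

        def conv_block(cin, cout):
            return [
                Conv2D(cin, cout, 3, rng), BatchNorm2D(cout), ReLU(),
                Conv2D(cout, cout, 3, rng), BatchNorm2D(cout), ReLU(),
            ]

        self.enc_blocks = []
        cin = in_channels
        for lvl in range(depth):
            cout = base_channels * 2**lvl
            self.enc_blocks.append(conv_block(cin, cout))
            cin = cout
        self.pools = [MaxPool2() for _ in range(depth)]
        cbott = base_channels * 2**depth
        self.bottleneck = conv_block(cin, cbott)
        self.ups = []
        self.dec_dropouts = []
        self.dec_blocks = []
        cin = cbott
        for lvl in reversed(range(depth)):
            cskip = base_channels * 2**lvl
            self.ups.append(ConvTranspose2(cin, cskip, rng))
            self.dec_dropouts.append(Dropout(dropout_rate, rng))
            self.dec_blocks.append(conv_block(2 * cskip, cskip))
            cin = cskip
        self.head = Conv2D(cin, n_classes, 1, rng)

        self.layers = [l for blk in self.enc_blocks for l in blk]
        self.layers += self.pools + self.bottleneck + self.ups
        self.layers += self.dec_dropouts + [l for blk in self.dec_blocks for l in blk]
        self.layers += [self.head]
        self.params = [p for l in self.layers for p in l.params]

    # -------------------------------------------------------------- geometry
    def bottleneck_resolution(self, input_size: int) -> int:
        if input_size % 2**self.depth:
            raise ValueError(
                f"input size {input_size} not divisible by {2 ** self.depth}"
            )
        return input_size // 2**self.depth

    # --------------------------------------------------------------- compute
    def forward(self, x, train=True):
        x = np.ascontiguousarray(x, dtype=np.float32)
        skips = []
        for blk, pool in zip(self.enc_blocks, self.pools):
            for l in blk:
                x = l.forward(x, train)
            skips.append(x)
            x = pool.forward(x, train)
        for l in self.bottleneck:
            x = l.forward(x, train)
        self._concat_splits = []
        for up, drop, blk, skip in zip(
            self.ups, self.dec_dropouts, self.dec_blocks, reversed(skips)
        ):
            x = up.forward(x, train)
            x = np.concatenate([skip, x], axis=1)
            self._concat_splits.append(skip.shape[1])
            x = drop.forward(x, train)
            for l in blk:
                x = l.forward(x, train)
        return self.head.forward(x, train)

    def backward(self, dlogits):
        g = self.head.backward(dlogits)
        dskips = []
        for up, drop, blk, csplit in zip(
            reversed(self.ups),
            reversed(self.dec_dropouts),
            reversed(self.dec_blocks),
            reversed(self._concat_splits),
        ):
            for l in reversed(blk):
                g = l.backward(g)
            g = drop.backward(g)
            dskips.append(g[:, :csplit])
            g = up.backward(g[:, csplit:])
        for l in reversed(self.bottleneck):
            g = l.backward(g)
        # dskips were collected shallow-to-deep; the encoder unwinds deep-first
        for blk, pool, dskip in zip(
            reversed(self.enc_blocks), reversed(self.pools), reversed(dskips)
        ):
            g = pool.backward(g) + dskip
            for l in reversed(blk):
                g = l.backward(g)
        return g

    def predict_proba(self, x):
        return softmax(self.forward(x, train=False))

    # ------------------------------------------------------------------- i/o
    def state(self):
        return [p[0].copy() for p in self.params]

    def load_state(self, state):
        for (p, _), s in zip(self.params, state):
            p[...] = s
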