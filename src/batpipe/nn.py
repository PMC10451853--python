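"""Minimal CPU neural-network building blocks with manual backpropagation.

Implements exactly the pieces the two model architectures need: 2-D
convolution (stride 1, arbitrary zero padding), 2x2/stride-2 transposed
convolution, 2x2/stride-2 max pooling (floor or ceil mode), batch
normalization, ReLU, linear layers, the ADAM optimizer and the two losses
(mean squared error, per-class binary cross-entropy on logits).

All image tensors are channels-last, ``(batch, height, width, channels)``.
The heavy element-wise and convolution work is done by single-pass Numba
kernels (:mod:`batpipe._kernels`); on a memory-bandwidth-limited CPU the
number of passes over the full-resolution spectrogram activations, not the
arithmetic, is what determines the training speed. All state is NumPy, so a
fixed seed gives bit-identical training runs.
"""

from __future__ import annotations

import numpy as np

from . import _kernels as K

__all__ = [
    "Conv2d",
    "ConvTranspose2d",
    "MaxPool2d",
    "BatchNorm2d",
    "ReLU",
    "Flatten",
    "Linear",
    "CenterCrop2d",
    "Sequential",
    "Adam",
    "mse_loss",
    "bce_with_logits",
    "sigmoid",
    "warmup_kernels",
]

warmup_kernels = K.warmup


def sigmoid(z: np.ndarray) -> np.ndarray:
    z = np.asarray(z)
    out = np.empty(z.shape, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out.astype(z.dtype) if z.dtype.kind == "f" else out


class Param:
    """A trainable tensor and its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


class Module:
    training: bool = True

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


def _he_init(rng: np.random.Generator, shape, fan_in: int, dtype) -> np.ndarray:
    std = np.sqrt(2.0 / fan_in)
    return (rng.standard_normal(shape) * std).astype(dtype)


def _reuse(buf, shape, dtype):
    """Reuse a previously allocated scratch array when shape/dtype match."""
    if buf is None or buf.shape != shape or buf.dtype != dtype:
        return np.empty(shape, dtype)
    return buf


def _as4d(pad) -> tuple[int, int, int, int]:
    if isinstance(pad, int):
        return (pad, pad, pad, pad)
    pad = tuple(pad)
    if len(pad) == 2:  # (vertical, horizontal)
        return (pad[0], pad[0], pad[1], pad[1])
    if len(pad) == 4:  # (top, bottom, left, right)
        return pad
    raise ValueError("padding must be int, 2-tuple or 4-tuple")


class Conv2d(Module):
    """Stride-1 2-D convolution (cross-correlation) with zero padding.

    Weights are ``(kh, kw, c_in, c_out)``. ``input_grad=False`` skips the
    gradient with respect to the input (useful for a network's first layer).
    """

    def __init__(self, c_in: int, c_out: int, kernel, padding,
                 rng: np.random.Generator, dtype=np.float32,
                 input_grad: bool = True):
        kh, kw = (kernel, kernel) if isinstance(kernel, int) else kernel
        self.kh, self.kw = kh, kw
        self.c_in, self.c_out = c_in, c_out
        self.pad = _as4d(padding)
        self.input_grad = input_grad
        self.w = Param(_he_init(rng, (kh, kw, c_in, c_out), c_in * kh * kw, dtype))
        self.b = Param(np.zeros(c_out, dtype=dtype))
        self._xp: np.ndarray | None = None

    def params(self):
        return [self.w, self.b]

    def out_shape(self, h: int, w: int) -> tuple[int, int]:
        pt, pb, pl, pr = self.pad
        return h + pt + pb - self.kh + 1, w + pl + pr - self.kw + 1

    def _pad_input(self, x):
        pt, pb, pl, pr = self.pad
        if pt == pb == pl == pr == 0:
            return x
        return np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))

    def forward(self, x):
        x = np.ascontiguousarray(x, dtype=self.w.value.dtype)
        _, h, w, _ = x.shape
        xp = self._pad_input(x)
        ho, wo = self.out_shape(h, w)
        out = self._out_buf = _reuse(
            getattr(self, "_out_buf", None),
            (x.shape[0], ho, wo, self.c_out), x.dtype)
        if self.c_out >= 4:
            K.conv2d_fwd_ovec(xp, self.w.value, self.b.value, out)
        else:
            wt = np.ascontiguousarray(self.w.value.transpose(0, 1, 3, 2))
            K.conv2d_fwd_cvec(xp, wt, self.b.value, out)
        self._xp = xp
        self._hw = (h, w)
        return out

    def backward(self, grad):
        xp = self._xp
        h, w = self._hw
        grad = np.ascontiguousarray(grad, dtype=xp.dtype)
        dxp = np.zeros_like(xp)
        if self.c_out >= 4:
            K.conv2d_bwd_ovec(xp, self.w.value, grad, self.w.grad,
                              self.b.grad, dxp, self.input_grad)
        else:
            wt = np.ascontiguousarray(self.w.value.transpose(0, 1, 3, 2))
            dwt = np.zeros_like(wt)
            K.conv2d_bwd_cvec(xp, wt, grad, dwt, self.b.grad, dxp,
                              self.input_grad)
            self.w.grad += dwt.transpose(0, 1, 3, 2)
        pt, _, pl, _ = self.pad
        self._xp = None
        return dxp[:, pt:pt + h, pl:pl + w, :]


class ConvTranspose2d(Module):
    """2x2 transposed convolution with stride 2 (exact 2x upsampling)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 dtype=np.float32):
        self.c_in, self.c_out = c_in, c_out
        self.w = Param(_he_init(rng, (2, 2, c_in, c_out), c_in, dtype))
        self.b = Param(np.zeros(c_out, dtype=dtype))
        self._x: np.ndarray | None = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x):
        x = np.ascontiguousarray(x, dtype=self.w.value.dtype)
        b_, h, w, _ = x.shape
        out = self._out_buf = _reuse(
            getattr(self, "_out_buf", None),
            (b_, 2 * h, 2 * w, self.c_out), x.dtype)
        K.deconv2_fwd(x, self.w.value, self.b.value, out)
        self._x = x
        return out

    def backward(self, grad):
        x = self._x
        grad = np.ascontiguousarray(grad, dtype=x.dtype)
        dx = np.zeros_like(x)
        K.deconv2_bwd(x, self.w.value, grad, self.w.grad, self.b.grad, dx)
        self._x = None
        return dx


class MaxPool2d(Module):
    """2x2 max pooling with stride 2.

    ``ceil_mode=True`` keeps partial windows at the bottom/right edge (odd
    sizes round up); otherwise trailing odd rows/columns are dropped.
    """

    def __init__(self, ceil_mode: bool = False):
        self.ceil_mode = ceil_mode

    def out_shape(self, h: int, w: int) -> tuple[int, int]:
        if self.ceil_mode:
            return -(-h // 2), -(-w // 2)
        return h // 2, w // 2

    def forward(self, x):
        x = np.ascontiguousarray(x)
        b_, h, w, c = x.shape
        ho, wo = self.out_shape(h, w)
        out = self._out_buf = _reuse(
            getattr(self, "_out_buf", None), (b_, ho, wo, c), x.dtype)
        idx = _reuse(getattr(self, "_idx", None), (b_, ho, wo, c), np.uint8)
        K.maxpool2_fwd(x, out, idx)
        self._idx = idx
        self._in_shape = x.shape
        return out

    def backward(self, grad):
        dx = np.zeros(self._in_shape, dtype=grad.dtype)
        K.maxpool2_bwd(np.ascontiguousarray(grad), self._idx, dx)
        return dx


class BatchNorm2d(Module):
    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.1,
                 dtype=np.float32):
        self.c = c
        self.eps = eps
        self.momentum = momentum
        self.gamma = Param(np.ones(c, dtype=dtype))
        self.beta = Param(np.zeros(c, dtype=dtype))
        self.running_mean = np.zeros(c, dtype=dtype)
        self.running_var = np.ones(c, dtype=dtype)

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x):
        dtype = self.gamma.value.dtype
        x = np.ascontiguousarray(x, dtype=dtype)
        xf = x.reshape(-1, self.c)
        n = xf.shape[0]
        if self.training:
            sums = np.zeros(self.c, dtype=np.float64)
            sumsq = np.zeros(self.c, dtype=np.float64)
            K.bn_stats(xf, sums, sumsq)
            mean = sums / n
            var = np.maximum(sumsq / n - mean ** 2, 0.0)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean
                                 + m * mean).astype(dtype)
            self.running_var = ((1 - m) * self.running_var
                                + m * var).astype(dtype)
            mean = mean.astype(dtype)
            inv_std = (1.0 / np.sqrt(var + self.eps)).astype(dtype)
            xhat = self._xhat_buf = _reuse(
                getattr(self, "_xhat_buf", None), xf.shape, xf.dtype)
            out = self._out_buf = _reuse(
                getattr(self, "_out_buf", None), xf.shape, xf.dtype)
            K.bn_fwd(xf, mean, inv_std, self.gamma.value, self.beta.value,
                     xhat, out)
            self._xhat, self._inv_std, self._n = xhat, inv_std, n
            return out.reshape(x.shape)
        inv_std = 1.0 / np.sqrt(self.running_var.astype(np.float64) + self.eps)
        a = (self.gamma.value * inv_std).astype(dtype)
        b = (self.beta.value - self.running_mean * a).astype(dtype)
        return x * a + b

    def backward(self, grad):
        xhat, inv_std, n = self._xhat, self._inv_std, self._n
        gf = np.ascontiguousarray(grad, dtype=xhat.dtype).reshape(-1, self.c)
        sg = np.zeros(self.c, dtype=np.float64)
        sgx = np.zeros(self.c, dtype=np.float64)
        K.bn_bwd_stats(gf, xhat, sg, sgx)
        self.gamma.grad += sgx.astype(xhat.dtype)
        self.beta.grad += sg.astype(xhat.dtype)
        scale = (self.gamma.value * inv_std).astype(xhat.dtype)
        m1 = (sg / n).astype(xhat.dtype)
        m2 = (sgx / n).astype(xhat.dtype)
        dx = np.empty_like(gf)
        K.bn_bwd(gf, xhat, scale, m1, m2, dx)
        self._xhat = None
        return dx.reshape(grad.shape)


class ReLU(Module):
    """Rectified linear unit, applied in place on the incoming array."""

    def forward(self, x):
        np.maximum(x, 0, out=x)
        self._out = x
        return x

    def backward(self, grad):
        grad = np.ascontiguousarray(grad)
        if grad.dtype == self._out.dtype:
            K.relu_bwd_inplace(grad, self._out)
        else:
            grad = grad * (self._out > 0)
        self._out = None
        return grad


class Flatten(Module):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 dtype=np.float32):
        self.w = Param(_he_init(rng, (n_out, n_in), n_in, dtype))
        self.b = Param(np.zeros(n_out, dtype=dtype))

    def params(self):
        return [self.w, self.b]

    def forward(self, x):
        x = np.asarray(x, dtype=self.w.value.dtype)
        self._x = x
        return x @ self.w.value.T + self.b.value

    def backward(self, grad):
        grad = np.asarray(grad, dtype=self._x.dtype)
        self.w.grad += grad.T @ self._x
        self.b.grad += grad.sum(0)
        dx = grad @ self.w.value
        self._x = None
        return dx


class CenterCrop2d(Module):
    """Crop the height/width axes to a target size."""

    def __init__(self, height: int, width: int):
        self.h, self.w = height, width

    def forward(self, x):
        b_, h, w, c = x.shape
        if h < self.h or w < self.w:
            raise ValueError(f"cannot crop {(h, w)} to {(self.h, self.w)}")
        self._in_shape = x.shape
        self._off = ((h - self.h) // 2, (w - self.w) // 2)
        i, j = self._off
        return x[:, i:i + self.h, j:j + self.w, :]

    def backward(self, grad):
        dx = np.zeros(self._in_shape, dtype=grad.dtype)
        i, j = self._off
        dx[:, i:i + self.h, j:j + self.w, :] = grad
        return dx


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def train(self, mode: bool = True):
        for layer in self.layers:
            layer.training = mode
        self.training = mode
        return self

    def eval(self):
        return self.train(False)

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


class Adam:
    """ADAM optimizer with the standard bias-corrected moment estimates."""

    def __init__(self, params: list[Param], lr: float = 1e-4,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0

    def step(self):
        self.t += 1
        c1 = 1 - self.b1 ** self.t
        c2 = 1 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m += (1 - self.b1) * (g - m)
            v += (1 - self.b2) * (g * g - v)
            p.value -= self.lr * (m / c1) / (np.sqrt(v / c2) + self.eps)


def mse_loss(pred: np.ndarray, target: np.ndarray):
    """Mean squared error and its gradient with respect to ``pred``."""
    diff = pred - np.asarray(target, dtype=pred.dtype)
    loss = float(np.mean(diff.astype(np.float64) ** 2))
    return loss, (2.0 / diff.size) * diff


def bce_with_logits(logits: np.ndarray, target: np.ndarray):
    """Per-class binary cross-entropy on raw scores (numerically stable).

    ``target`` is a one-hot (or multi-hot) array of the same shape. Returns
    the mean loss over all elements and the gradient w.r.t. the logits.
    """
    z = logits.astype(np.float64)
    t = np.asarray(target, dtype=np.float64)
    loss = float(np.mean(np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))))
    grad = (sigmoid(z) - t) / z.size
    return loss, grad.astype(logits.dtype)
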