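"""Neural-network building blocks: dense, 3D convolutional and recurrent.

Convolutions exploit the regular stride arithmetic directly: a strided
convolution (and its transpose) is evaluated as one slice-matmul per
kernel offset, accumulated in place on the zero-padded dense grid. This
keeps every intermediate a view or a small product — no im2col buffers —
and the same decomposition serves forward, input-gradient and
weight-gradient passes.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, parameter, matmul, sigmoid, tanh

_DTYPE = np.float32


def glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(_DTYPE)


def _pad3(x: np.ndarray, p: int) -> np.ndarray:
    """Zero-pad the three spatial axes of a channels-last (B,X,Y,Z,C) array."""
    if p == 0:
        return x
    return np.pad(x, ((0, 0), (p, p), (p, p), (p, p), (0, 0)))


def _unpad3(x: np.ndarray, p: int) -> np.ndarray:
    if p == 0:
        return x
    return x[:, p:-p, p:-p, p:-p, :]


class Module:
    """Base class: parameter registry shared by all layers."""

    def parameters(self) -> list[Tensor]:
        out = []
        for v in vars(self).values():
            if isinstance(v, Tensor) and v.requires_grad:
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
        return out

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))


class Linear(Module):
    def __init__(self, rng: np.random.Generator, d_in: int, d_out: int):
        self.weight = parameter(glorot_uniform(rng, (d_in, d_out), d_in, d_out))
        self.bias = parameter(np.zeros(d_out, dtype=_DTYPE))

    def __call__(self, x: Tensor) -> Tensor:
        return matmul(x, self.weight) + self.bias


def _offset_slice(kf: int, stride: int, n_out: int) -> slice:
    """Strided slice selecting the padded-grid sites stride*i + kf."""
    return slice(kf, kf + stride * (n_out - 1) + 1, stride)


class Conv3d(Module):
    """Strided 3D convolution (cross-correlation), channels-last.

    Activations are (B, X, Y, Z, C); the weight is (K*C_in, C_out) rows
    grouped by kernel offset (x-major), so the per-offset blocks used by
    the slice-matmul evaluation are contiguous row ranges.
    """

    def __init__(self, rng, c_in: int, c_out: int, kernel: int = 4, stride: int = 2,
                 padding: int = 1):
        self.k, self.s, self.p = kernel, stride, padding
        self.c_in, self.c_out = c_in, c_out
        fan_in = c_in * kernel ** 3
        self.weight = parameter(glorot_uniform(rng, (fan_in, c_out), fan_in, c_out))
        self.bias = parameter(np.zeros(c_out, dtype=_DTYPE))

    def _offsets(self, out_spatial):
        k = self.k
        for kfx in range(k):
            for kfy in range(k):
                for kfz in range(k):
                    kf = (kfx * k + kfy) * k + kfz
                    yield kf, tuple(_offset_slice(f, self.s, n)
                                    for f, n in zip((kfx, kfy, kfz), out_spatial))

    def __call__(self, x: Tensor) -> Tensor:
        B, X, Y, Z, C = x.shape
        out_spatial = self.out_shape((X, Y, Z))
        xpad = _pad3(x.data, self.p)
        out_data = np.empty((B, *out_spatial, self.c_out), dtype=_DTYPE)
        out_data[:] = self.bias.data
        for kf, (sx, sy, sz) in self._offsets(out_spatial):
            blk = self.weight.data[kf * C:(kf + 1) * C, :]
            out_data += xpad[:, sx, sy, sz, :] @ blk
        w, b = self.weight, self.bias

        def bwd(g, x=x, w=w, b=b, xpad=xpad, out_spatial=out_spatial, C=C):
            if b.requires_grad:
                b._accum(g.sum(axis=(0, 1, 2, 3)))
            if w.requires_grad:
                dw = np.empty_like(w.data)
                for kf, (sx, sy, sz) in self._offsets(out_spatial):
                    dw[kf * C:(kf + 1) * C, :] = np.tensordot(
                        xpad[:, sx, sy, sz, :], g,
                        axes=([0, 1, 2, 3], [0, 1, 2, 3]))
                w._accum(dw)
            if x.requires_grad:
                dxpad = np.zeros_like(xpad)
                for kf, (sx, sy, sz) in self._offsets(out_spatial):
                    blk = self.weight.data[kf * C:(kf + 1) * C, :]
                    dxpad[:, sx, sy, sz, :] += g @ blk.T
                x._accum(_unpad3(dxpad, self.p))

        return Tensor(out_data, parents=(x, w, b), backward=bwd)

    def out_shape(self, spatial):
        return tuple((d + 2 * self.p - self.k) // self.s + 1 for d in spatial)


class ConvTranspose3d(Module):
    """Transposed strided 3D convolution (adjoint of :class:`Conv3d`),
    channels-last; the weight is (C_in, K*C_out), kernel-offset major."""

    def __init__(self, rng, c_in: int, c_out: int, kernel: int = 4, stride: int = 2,
                 padding: int = 1):
        self.k, self.s, self.p = kernel, stride, padding
        self.c_in, self.c_out = c_in, c_out
        K = kernel ** 3
        self.weight = parameter(glorot_uniform(rng, (c_in, c_out * K), c_in, c_out * K))
        self.bias = parameter(np.zeros(c_out, dtype=_DTYPE))

    def _offsets(self, in_spatial):
        k = self.k
        for kfx in range(k):
            for kfy in range(k):
                for kfz in range(k):
                    kf = (kfx * k + kfy) * k + kfz
                    yield kf, tuple(_offset_slice(f, self.s, n)
                                    for f, n in zip((kfx, kfy, kfz), in_spatial))

    def __call__(self, x: Tensor, out_spatial: tuple[int, int, int]) -> Tensor:
        B, Ox, Oy, Oz, C = x.shape
        expected = tuple((d + 2 * self.p - self.k) // self.s + 1 for d in out_spatial)
        if expected != (Ox, Oy, Oz):
            raise ValueError(f"input spatial {(Ox, Oy, Oz)} inconsistent with "
                             f"requested output {out_spatial}")
        co = self.c_out
        padded = tuple(d + 2 * self.p for d in out_spatial)
        out_pad = np.zeros((B, *padded, co), dtype=_DTYPE)
        for kf, (sx, sy, sz) in self._offsets((Ox, Oy, Oz)):
            blk = self.weight.data[:, kf * co:(kf + 1) * co]
            out_pad[:, sx, sy, sz, :] += x.data @ blk
        out_data = _unpad3(out_pad, self.p) + self.bias.data
        w, b = self.weight, self.bias

        def bwd(g, x=x, w=w, b=b, in_spatial=(Ox, Oy, Oz)):
            co = self.c_out
            if b.requires_grad:
                b._accum(g.sum(axis=(0, 1, 2, 3)))
            gpad = _pad3(g, self.p)
            dw = np.empty_like(w.data) if w.requires_grad else None
            dx = np.zeros_like(x.data) if x.requires_grad else None
            for kf, (sx, sy, sz) in self._offsets(in_spatial):
                gsl = np.ascontiguousarray(gpad[:, sx, sy, sz, :])
                if dw is not None:
                    dw[:, kf * co:(kf + 1) * co] = np.tensordot(
                        x.data, gsl, axes=([0, 1, 2, 3], [0, 1, 2, 3]))
                if dx is not None:
                    blk = self.weight.data[:, kf * co:(kf + 1) * co]
                    dx += gsl @ blk.T
            if dw is not None:
                w._accum(dw)
            if dx is not None:
                x._accum(dx)

        return Tensor(out_data, parents=(x, w, b), backward=bwd)


class LSTMCell(Module):
    """Single LSTM cell with shared weights across time steps.

    Gate order (i, f, g, o); the forget-gate bias is initialised to +1,
    a standard stabilisation for short rollouts.
    """

    def __init__(self, rng, d_in: int, d_hidden: int):
        self.d_in, self.d_hidden = d_in, d_hidden
        lim = 1.0 / np.sqrt(d_hidden)
        self.w_x = parameter(rng.uniform(-lim, lim, (d_in, 4 * d_hidden)).astype(_DTYPE))
        self.w_h = parameter(rng.uniform(-lim, lim, (d_hidden, 4 * d_hidden)).astype(_DTYPE))
        bias = np.zeros(4 * d_hidden, dtype=_DTYPE)
        bias[d_hidden:2 * d_hidden] = 1.0
        self.bias = parameter(bias)

    def __call__(self, x: Tensor, h: Tensor, c: Tensor) -> tuple[Tensor, Tensor]:
        H = self.d_hidden
        gates = matmul(x, self.w_x) + matmul(h, self.w_h) + self.bias
        i = sigmoid(gates[:, 0:H])
        f = sigmoid(gates[:, H:2 * H])
        g = tanh(gates[:, 2 * H:3 * H])
        o = sigmoid(gates[:, 3 * H:4 * H])
        c_next = f * c + i * g
        h_next = o * tanh(c_next)
        return h_next, c_next


class MLP(Module):
    """Fully connected stack with ReLU between layers, linear output."""

    def __init__(self, rng, widths: list[int]):
        self.layers = [Linear(rng, a, b) for a, b in zip(widths[:-1], widths[1:])]

    def __call__(self, x: Tensor) -> Tensor:
        from .autograd import relu
        for layer in self.layers[:-1]:
            x = relu(layer(x))
        return self.layers[-1](x)
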