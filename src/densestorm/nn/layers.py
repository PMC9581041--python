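"""Convolutional layers for NCHW image tensors, im2col-based.

Conventions match the common deep-learning ones: activations are
``(batch, channels, height, width)``; convolution weights are
``(out_channels, in_channels, kh, kw)``; transposed-convolution weights are
``(in_channels, out_channels, kh, kw)``. A transposed convolution is
implemented exactly as the adjoint of the corresponding strided
convolution, which makes the two layers' gradients mirror images of each
other.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from densestorm.nn.tensor import Tensor

__all__ = [
    "Module",
    "Conv2d",
    "ConvTranspose2d",
    "BatchNorm2d",
    "Sequential",
    "avg_pool2d",
    "gaussian_window",
    "conv2d",
    "conv_transpose2d",
]


# ---------------------------------------------------------------------------
# raw numpy kernels: forward conv, adjoint w.r.t. data, adjoint w.r.t. weight
# ---------------------------------------------------------------------------

def _conv_out_size(size: int, k: int, stride: int, pad: int) -> int:
    return (size + 2 * pad - k) // stride + 1


def _im2col(x: np.ndarray, k: int, stride: int, pad: int) -> np.ndarray:
    """(N, C, H, W) -> (N, Ho*Wo, C*k*k) patch matrix."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    windows = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    n, c, ho, wo = windows.shape[:4]
    return windows.transpose(0, 2, 3, 1, 4, 5).reshape(n, ho * wo, c * k * k)


def _col2im(
    cols: np.ndarray,
    x_shape: tuple[int, ...],
    k: int,
    stride: int,
    pad: int,
    ho: int,
    wo: int,
) -> np.ndarray:
    """Adjoint of :func:`_im2col`: scatter-add patches back to the image."""
    n, c, h, w = x_shape
    out = np.zeros((n, c, h + 2 * pad, w + 2 * pad))
    cols = cols.reshape(n, ho, wo, c, k, k).transpose(0, 3, 1, 2, 4, 5)
    for i in range(k):
        for j in range(k):
            out[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += (
                cols[:, :, :, :, i, j]
            )
    return out[:, :, pad : pad + h, pad : pad + w]


def _conv_fwd(x: np.ndarray, w: np.ndarray, stride: int, pad: int) -> np.ndarray:
    n, c, h, width = x.shape
    o, _, k, _ = w.shape
    ho, wo = _conv_out_size(h, k, stride, pad), _conv_out_size(width, k, stride, pad)
    cols = _im2col(x, k, stride, pad)
    out = cols @ w.reshape(o, -1).T  # (N, Ho*Wo, O)
    return out.transpose(0, 2, 1).reshape(n, o, ho, wo)


def _conv_bwd_data(
    dy: np.ndarray, w: np.ndarray, stride: int, pad: int, x_shape: tuple[int, ...]
) -> np.ndarray:
    n, o, ho, wo = dy.shape
    k = w.shape[2]
    dcols = dy.reshape(n, o, ho * wo).transpose(0, 2, 1) @ w.reshape(o, -1)
    return _col2im(dcols, x_shape, k, stride, pad, ho, wo)


def _conv_bwd_weight(
    x: np.ndarray, dy: np.ndarray, stride: int, pad: int, w_shape: tuple[int, ...]
) -> np.ndarray:
    o, c, k, _ = w_shape
    n, _, ho, wo = dy.shape
    cols = _im2col(x, k, stride, pad)  # (N, Ho*Wo, C*k*k)
    dy_mat = dy.reshape(n, o, ho * wo)
    dw = np.einsum("nol,nlc->oc", dy_mat, cols)
    return dw.reshape(w_shape)


# ---------------------------------------------------------------------------
# differentiable ops
# ---------------------------------------------------------------------------

def conv2d(x: Tensor, w: Tensor, stride: int = 1, pad: int = 0) -> Tensor:
    out = _conv_fwd(x.data, w.data, stride, pad)

    def backward(g: np.ndarray):
        return (
            _conv_bwd_data(g, w.data, stride, pad, x.shape),
            _conv_bwd_weight(x.data, g, stride, pad, w.shape),
        )

    return Tensor.from_op(out, (x, w), backward)


def conv_transpose2d(x: Tensor, w: Tensor, stride: int = 1, pad: int = 0) -> Tensor:
    """Transposed convolution; ``w`` has shape (C_in, C_out, k, k).

    Output size is ``(H - 1) * stride - 2 * pad + k`` per spatial dim.
    """
    c_in, c_out, k, _ = w.shape
    n, _, h, width = x.shape
    out_shape = (
        n,
        c_out,
        (h - 1) * stride - 2 * pad + k,
        (width - 1) * stride - 2 * pad + k,
    )
    out = _conv_bwd_data(x.data, w.data, stride, pad, out_shape)

    def backward(g: np.ndarray):
        return (
            _conv_fwd(g, w.data, stride, pad),
            _conv_bwd_weight(g, x.data, stride, pad, w.shape),
        )

    return Tensor.from_op(out, (x, w), backward)


def avg_pool2d(x: Tensor, k: int = 2) -> Tensor:
    """Non-overlapping k x k average pooling (trailing remainder cropped)."""
    n, c, h, w = x.shape
    ho, wo = h // k, w // k
    cropped = x.data[:, :, : ho * k, : wo * k]
    out = cropped.reshape(n, c, ho, k, wo, k).mean(axis=(3, 5))

    def backward(g: np.ndarray):
        gx = np.zeros(x.shape)
        spread = np.repeat(np.repeat(g, k, axis=2), k, axis=3) / (k * k)
        gx[:, :, : ho * k, : wo * k] = spread
        return (gx,)

    return Tensor.from_op(out, (x,), backward)


def gaussian_window(size: int = 11, sigma: float = 1.5) -> np.ndarray:
    """Unit-sum 2-D Gaussian window (the SSIM weighting window)."""
    ax = np.arange(size) - (size - 1) / 2.0
    g = np.exp(-(ax**2) / (2 * sigma**2))
    window = np.outer(g, g)
    return window / window.sum()


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------

class Module:
    """Base class: parameter/submodule discovery via attributes, recursive.

    Modules with non-trainable state (e.g. normalization running statistics)
    list the attribute names in ``buffer_names``; buffers travel with
    ``state_dict`` alongside the parameters.
    """

    buffer_names: tuple[str, ...] = ()
    training: bool = True

    def _children(self) -> list["Module"]:
        children: list[Module] = []
        for value in self.__dict__.values():
            if isinstance(value, Module):
                children.append(value)
            elif isinstance(value, (list, tuple)):
                children.extend(v for v in value if isinstance(v, Module))
        return children

    def parameters(self) -> list[Tensor]:
        params = [v for v in self.__dict__.values()
                  if isinstance(v, Tensor) and v.requires_grad]
        for child in self._children():
            params.extend(child.parameters())
        return params

    def _buffer_holders(self) -> list["Module"]:
        holders = [self] if self.buffer_names else []
        for child in self._children():
            holders.extend(child._buffer_holders())
        return holders

    def set_training(self, flag: bool) -> None:
        self.training = flag
        for child in self._children():
            child.set_training(flag)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> list[np.ndarray]:
        state = [p.data.copy() for p in self.parameters()]
        for holder in self._buffer_holders():
            state.extend(np.copy(getattr(holder, name)) for name in holder.buffer_names)
        return state

    def load_state_dict(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        holders = [(h, name) for h in self._buffer_holders() for name in h.buffer_names]
        if len(params) + len(holders) != len(state):
            raise ValueError("state does not match parameter/buffer count")
        for p, s in zip(params, state):
            if p.data.shape != s.shape:
                raise ValueError("parameter shape mismatch")
            p.data = s.copy()
        for (holder, name), s in zip(holders, state[len(params) :]):
            setattr(holder, name, np.copy(s))

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)


class Conv2d(Module):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int = 1,
        pad: int = 0,
        rng: np.random.Generator | None = None,
        init_std: float = 0.02,
    ):
        rng = rng or np.random.default_rng()
        self.stride, self.pad = stride, pad
        self.weight = Tensor(
            rng.normal(0.0, init_std, (out_channels, in_channels, kernel_size, kernel_size)),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros((1, out_channels, 1, 1)), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.stride, self.pad) + self.bias


class ConvTranspose2d(Module):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int = 1,
        pad: int = 0,
        rng: np.random.Generator | None = None,
        init_std: float = 0.02,
    ):
        rng = rng or np.random.default_rng()
        self.stride, self.pad = stride, pad
        self.weight = Tensor(
            rng.normal(0.0, init_std, (in_channels, out_channels, kernel_size, kernel_size)),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros((1, out_channels, 1, 1)), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return conv_transpose2d(x, self.weight, self.stride, self.pad) + self.bias


class BatchNorm2d(Module):
    """Per-channel normalization over (N, H, W), composed from primitive ops.

    Training uses batch statistics and updates exponential running averages
    (momentum 0.1); evaluation uses the running averages, which makes
    inference deterministic and independent of how an image is tiled.
    """

    buffer_names = ("running_mean", "running_var")

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        self.eps = eps
        self.momentum = momentum
        self.gamma = Tensor(np.ones((1, channels, 1, 1)), requires_grad=True)
        self.beta = Tensor(np.zeros((1, channels, 1, 1)), requires_grad=True)
        self.running_mean = np.zeros((1, channels, 1, 1))
        self.running_var = np.ones((1, channels, 1, 1))

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            centered = x - mu
            var = (centered * centered).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data
            self.running_var = (1 - m) * self.running_var + m * var.data
        else:
            mu, var = Tensor(self.running_mean), Tensor(self.running_var)
            centered = x - mu
        return self.gamma * centered / (var + self.eps).sqrt() + self.beta


class Sequential(Module):
    def __init__(self, *modules: Module):
        self.modules = list(modules)

    def forward(self, x: Tensor) -> Tensor:
        for module in self.modules:
            x = module(x)
        return x
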