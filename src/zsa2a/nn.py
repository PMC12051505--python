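"""A minimal CNN engine (forward, hand-derived backward, Adam) in NumPy.

The artifact predictor is deliberately tiny — two 3x3 convolutions and a 1x1
projection, ~21k parameters — so an im2col + GEMM implementation with
explicit gradients is both fast enough on a CPU and bitwise reproducible for
a fixed seed.  Arithmetic is float32 throughout; convolutions use zero
("same") padding and LeakyReLU activations.
"""

from __future__ import annotations

import numpy as np

__all__ = ["TinyConvNet", "Adam", "step_lr"]

_KS = 3  # spatial kernel size of the two convolution layers


def _pad_hw(x: np.ndarray) -> np.ndarray:
    """Zero-pad (B, H, W, C) by one pixel on each spatial side."""
    B, H, W, C = x.shape
    out = np.zeros((B, H + 2, W + 2, C), dtype=x.dtype)
    out[:, 1:-1, 1:-1, :] = x
    return out


def _im2col(x: np.ndarray) -> np.ndarray:
    """(B, H, W, C) -> (B*H*W, 9*C) patch matrix for a 3x3 same convolution.

    Column blocks are ordered tap-major: block ``t = 3*dy + dx`` holds channel
    values of the input shifted by (dy-1, dx-1).  Built as a strided view of
    the padded input materialised in one contiguous copy.
    """
    B, H, W, C = x.shape
    xp = _pad_hw(x)
    win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(1, 2))
    col = np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3))
    return col.reshape(B * H * W, 9 * C)


def _rot180_swap(W2: np.ndarray, C: int) -> np.ndarray:
    """Kernel for the transposed 3x3 convolution: taps rotated 180 degrees and
    in/out channels swapped.  W2 is (9*C_in, C_out) tap-major."""
    k = W2.reshape(3, 3, C, C)[::-1, ::-1]  # rotate taps
    return np.ascontiguousarray(k.transpose(0, 1, 3, 2)).reshape(9 * C, C)


class TinyConvNet:
    """3x3 conv -> LeakyReLU -> 3x3 conv -> LeakyReLU -> 1x1 conv.

    Parameters
    ----------
    hidden_channels : int
        Width C of the two hidden layers (default 48, ~21.3k parameters).
    negative_slope : float
        LeakyReLU slope for negative inputs.
    seed : int
        Seeds the He-uniform weight initialisation; biases start at zero.
    """

    def __init__(self, hidden_channels: int = 48, negative_slope: float = 0.1,
                 seed: int = 0):
        if hidden_channels < 1:
            raise ValueError("hidden_channels must be >= 1")
        self.C = int(hidden_channels)
        self.slope = float(negative_slope)
        rng = np.random.default_rng(seed)
        gain = np.sqrt(2.0 / (1.0 + self.slope ** 2))

        def he_uniform(shape, fan_in):
            limit = gain * np.sqrt(3.0 / fan_in)
            return rng.uniform(-limit, limit, shape).astype(np.float32)

        C = self.C
        self.params = {
            "W1": he_uniform((9, C), 9),
            "b1": np.zeros(C, dtype=np.float32),
            "W2": he_uniform((9 * C, C), 9 * C),
            "b2": np.zeros(C, dtype=np.float32),
            "W3": he_uniform((C, 1), C),
            "b3": np.zeros(1, dtype=np.float32),
        }

    # -- introspection ------------------------------------------------------

    @property
    def parameter_count(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    @property
    def architecture(self) -> tuple:
        return (self.C, ((_KS, _KS), (_KS, _KS), (1, 1)), f"leaky_relu({self.slope})")

    def state_dict(self) -> dict:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict):
        for k in self.params:
            self.params[k] = np.asarray(state[k], dtype=np.float32).reshape(
                self.params[k].shape)

    def zero_(self):
        """Set every parameter to zero (the network then maps any input to 0)."""
        for v in self.params.values():
            v[...] = 0
        return self

    # -- forward / backward -------------------------------------------------

    def _lrelu(self, z):
        return np.where(z > 0, z, self.slope * z)

    def forward(self, x: np.ndarray, cache: dict | None = None,
                static: dict | None = None) -> np.ndarray:
        """Map images (B, H, W) or (H, W) to same-shape outputs.

        Pass a dict as ``cache`` to retain intermediates for :meth:`backward`.
        ``static`` may hold input-dependent precomputations (the first-layer
        patch matrix) reused across iterations when ``x`` does not change.
        """
        squeeze = x.ndim == 2
        if squeeze:
            x = x[None]
        if x.ndim != 3:
            raise ValueError("input must be (H, W) or (B, H, W)")
        B, H, W = x.shape
        if H < _KS or W < _KS:
            raise ValueError(f"image must be at least {_KS}x{_KS} for same padding")
        p = self.params
        if static is not None and "col1" in static:
            col1 = static["col1"]
        else:
            x32 = np.ascontiguousarray(x, dtype=np.float32)
            col1 = _im2col(x32[..., None])                # (BHW, 9)
            if static is not None:
                static["col1"] = col1
        slope = np.float32(self.slope)
        one_minus = np.float32(1.0 - self.slope)
        z1 = col1 @ p["W1"]
        z1 += p["b1"]
        s1 = (z1 > 0).astype(np.float32)
        s1 *= one_minus
        s1 += slope
        a1 = z1 * s1
        col2 = _im2col(a1.reshape(B, H, W, self.C))       # (BHW, 9C)
        z2 = col2 @ p["W2"]
        z2 += p["b2"]
        s2 = (z2 > 0).astype(np.float32)
        s2 *= one_minus
        s2 += slope
        a2 = z2 * s2
        y = a2 @ p["W3"] + p["b3"]
        if cache is not None:
            cache.update(B=B, H=H, W=W, col1=col1, s1=s1, col2=col2, s2=s2,
                         a2=a2)
        out = y.reshape(B, H, W)
        return out[0] if squeeze else out

    def backward(self, cache: dict, dy: np.ndarray) -> dict:
        """Gradients of a scalar loss given d(loss)/d(output); uses the cache
        of the immediately preceding :meth:`forward` call."""
        p = self.params
        B, H, W = cache["B"], cache["H"], cache["W"]
        dyf = np.ascontiguousarray(dy, dtype=np.float32).reshape(B * H * W, 1)
        grads = {}
        grads["W3"] = cache["a2"].T @ dyf
        grads["b3"] = dyf.sum(axis=0)
        dz2 = dyf @ p["W3"].T
        dz2 *= cache["s2"]
        grads["W2"] = (dz2.T @ cache["col2"]).T
        grads["b2"] = dz2.sum(axis=0)
        # grad wrt a1 = transposed convolution of dz2
        dz1 = _im2col(dz2.reshape(B, H, W, self.C)) @ _rot180_swap(p["W2"], self.C)
        dz1 *= cache["s1"]
        grads["W1"] = (dz1.T @ cache["col1"]).T
        grads["b1"] = dz1.sum(axis=0)
        return grads


class Adam:
    """Adam optimiser over a dict of float32 parameter arrays."""

    def __init__(self, params: dict, lr: float = 0.01, betas=(0.9, 0.999),
                 eps: float = 1e-8):
        self.params = params
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = float(eps)
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict):
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for k, p in self.params.items():
            g = grads[k].reshape(p.shape).astype(np.float32)
            m = self.m[k]
            v = self.v[k]
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def step_lr(base_lr: float, iteration: int, step_size: int, gamma: float) -> float:
    """Step-decay schedule: lr = base * gamma ** floor(iteration / step_size)."""
    return base_lr * gamma ** (iteration // step_size)
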