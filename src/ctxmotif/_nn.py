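"""Minimal numpy neural-net layers with explicit forward/backward passes.

Sized for the small encoder/decoder networks in this package (a few dense
layers, short 1-D convolutions over 30-timestep windows); everything runs in
float64 on one CPU.  Each layer caches what its backward pass needs, so a
layer instance handles one forward/backward pair at a time.  Gradients
accumulate into ``layer.grads`` until ``zero_grad``.  All parameter
initialisation draws from a caller-supplied Generator, which is the single
source of randomness for a model.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Dense", "Relu", "Tanh", "Sequential", "Conv1d", "ConvTranspose1d", "Adam",
]


class Layer:
    """Base: parameter-free layers override forward/backward only."""

    params: dict[str, np.ndarray]
    grads: dict[str, np.ndarray]

    def __init__(self) -> None:
        self.params = {}
        self.grads = {}

    def zero_grad(self) -> None:
        for k in self.grads:
            self.grads[k][...] = 0.0

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, v in state.items():
            self.params[k] = np.array(v, dtype=float)
            self.grads[k] = np.zeros_like(self.params[k])


class Dense(Layer):
    """Affine map; Glorot-uniform init."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.params = {
            "W": rng.uniform(-limit, limit, size=(n_in, n_out)),
            "b": np.zeros(n_out),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads["W"] += self._x.T @ dout
        self.grads["b"] += dout.sum(axis=0)
        return dout @ self.params["W"].T


class Relu(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, 0.0)


class Tanh(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._y = np.tanh(x)
        return self._y

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * (1.0 - self._y**2)


class Sequential(Layer):
    def __init__(self, *layers: Layer) -> None:
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.zero_grad()

    def parameter_layers(self) -> list[Layer]:
        out = []
        for layer in self.layers:
            if isinstance(layer, Sequential):
                out.extend(layer.parameter_layers())
            elif layer.params:
                out.append(layer)
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for i, layer in enumerate(self.layers):
            for k, v in layer.state_dict().items():
                state[f"{i}.{k}"] = v
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        per_layer: dict[int, dict[str, np.ndarray]] = {}
        for key, v in state.items():
            i, sub = key.split(".", 1)
            per_layer.setdefault(int(i), {})[sub] = v
        for i, sub in per_layer.items():
            self.layers[i].load_state_dict(sub)


# -- 1-D convolutions (channels-first: [batch, channels, length]) -----------

def _col_index(k: int, n_out: int, stride: int) -> np.ndarray:
    return stride * np.arange(n_out)[None, :] + np.arange(k)[:, None]  # [k, n_out]


def _im2col(xp: np.ndarray, k: int, stride: int) -> np.ndarray:
    n_out = (xp.shape[2] - k) // stride + 1
    return xp[:, :, _col_index(k, n_out, stride)]  # [B, C, k, n_out]


def _col2im(cols: np.ndarray, length: int, stride: int) -> np.ndarray:
    b, c, k, n_out = cols.shape
    out = np.zeros((b, c, length))
    np.add.at(out, (slice(None), slice(None), _col_index(k, n_out, stride)), cols)
    return out


class Conv1d(Layer):
    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int,
                 padding: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.kernel, self.stride, self.padding = kernel, stride, padding
        limit = np.sqrt(6.0 / (c_in * kernel + c_out * kernel))
        self.params = {
            "K": rng.uniform(-limit, limit, size=(c_out, c_in, kernel)),
            "b": np.zeros(c_out),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    @staticmethod
    def out_length(length: int, kernel: int, stride: int, padding: int) -> int:
        return (length + 2 * padding - kernel) // stride + 1

    def forward(self, x: np.ndarray) -> np.ndarray:
        p = self.padding
        xp = np.pad(x, ((0, 0), (0, 0), (p, p)))
        self._cols = _im2col(xp, self.kernel, self.stride)
        self._in_length = x.shape[2]
        out = np.einsum("ocj,bcjl->bol", self.params["K"], self._cols)
        return out + self.params["b"][None, :, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads["K"] += np.einsum("bol,bcjl->ocj", dout, self._cols)
        self.grads["b"] += dout.sum(axis=(0, 2))
        dcols = np.einsum("ocj,bol->bcjl", self.params["K"], dout)
        p = self.padding
        dxp = _col2im(dcols, self._in_length + 2 * p, self.stride)
        return dxp[:, :, p : p + self._in_length] if p else dxp


class ConvTranspose1d(Layer):
    """Adjoint of Conv1d; ``out_length`` fixes the crop (output padding)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int,
                 padding: int, out_length: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.kernel, self.stride, self.padding = kernel, stride, padding
        self.out_length = out_length
        limit = np.sqrt(6.0 / (c_in * kernel + c_out * kernel))
        self.params = {
            "K": rng.uniform(-limit, limit, size=(c_in, c_out, kernel)),
            "b": np.zeros(c_out),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def _full_length(self, in_length: int) -> int:
        return self.stride * (in_length - 1) + self.kernel

    def forward(self, z: np.ndarray) -> np.ndarray:
        self._z = z
        cols = np.einsum("ioj,bil->bojl", self.params["K"], z)
        full = _col2im(cols, self._full_length(z.shape[2]), self.stride)
        p = self.padding
        if p + self.out_length > full.shape[2]:
            raise ValueError("out_length too large for this transposed convolution")
        return full[:, :, p : p + self.out_length] + self.params["b"][None, :, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        full = np.zeros((dout.shape[0], dout.shape[1], self._full_length(self._z.shape[2])))
        p = self.padding
        full[:, :, p : p + self.out_length] = dout
        dcols = _im2col(full, self.kernel, self.stride)  # [B, c_out, k, Lin]
        self.grads["K"] += np.einsum("bojl,bil->ioj", dcols, self._z)
        self.grads["b"] += dout.sum(axis=(0, 2))
        return np.einsum("ioj,bojl->bil", self.params["K"], dcols)


class Adam:
    """Adam over the parameter layers of one or more Sequential stacks."""

    def __init__(self, layers: list[Layer], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.layers = layers
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in layers]
        self._v = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in layers]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for layer, m, v in zip(self.layers, self._m, self._v):
            for k, p in layer.params.items():
                g = layer.grads[k]
                m[k] = b1 * m[k] + (1 - b1) * g
                v[k] = b2 * v[k] + (1 - b2) * g * g
                mhat = m[k] / (1 - b1**self.t)
                vhat = v[k] / (1 - b2**self.t)
                p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.zero_grad()
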