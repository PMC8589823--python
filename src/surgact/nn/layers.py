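"""Layers with explicit forward/backward passes.

Conventions: `forward(x)` caches whatever `backward(grad)` needs;
`backward` returns the gradient with respect to the input and accumulates
parameter gradients in `self.grads` (call `zero_grad` between steps).
Shapes: convolutions take (N, C, H, W); recurrent cells take a whole
sequence (T, input_size) and return (T, hidden_size).
"""

from __future__ import annotations

import numpy as np


class Module:
    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def add_param(self, name: str, value: np.ndarray) -> np.ndarray:
        self.params[name] = value
        self.grads[name] = np.zeros_like(value)
        return value

    def zero_grad(self) -> None:
        for g in self.grads.values():
            g[...] = 0.0

    def named_parameters(self, prefix: str = ""):
        for k in self.params:
            yield f"{prefix}{k}", self.params[k], self.grads[k]


def _uniform_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(max(fan_in, 1))
    return rng.uniform(-bound, bound, size=shape)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        self.W = self.add_param("W", _uniform_init(rng, (out_features, in_features), in_features))
        self.b = self.add_param("b", _uniform_init(rng, (out_features,), in_features))

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.grads["W"] += grad.T @ self._x
        self.grads["b"] += grad.sum(axis=0)
        return grad @ self.W


class PReLU(Module):
    """Parametric ReLU with a single learnable negative slope."""

    def __init__(self, init: float = 0.25):
        super().__init__()
        self.a = self.add_param("a", np.array([init], dtype=float))

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return np.where(x > 0, x, self.a[0] * x)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        neg = self._x <= 0
        self.grads["a"][0] += np.sum(grad * self._x * neg)
        return grad * np.where(neg, self.a[0], 1.0)


class Sigmoid(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._y * (1.0 - self._y)


class Flatten(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Conv2d(Module):
    """Stride-s same-ish convolution via im2col."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int, padding: int, rng: np.random.Generator):
        super().__init__()
        self.cin, self.cout = in_channels, out_channels
        self.k, self.stride, self.pad = kernel_size, stride, padding
        fan_in = in_channels * kernel_size * kernel_size
        self.W = self.add_param("W", _uniform_init(rng, (out_channels, fan_in), fan_in))
        self.b = self.add_param("b", _uniform_init(rng, (out_channels,), fan_in))

    def _im2col(self, x: np.ndarray):
        N, C, H, W = x.shape
        k, s, p = self.k, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        oh = (H + 2 * p - k) // s + 1
        ow = (W + 2 * p - k) // s + 1
        cols = np.empty((N, C, k, k, oh, ow), dtype=x.dtype)
        for i in range(k):
            for j in range(k):
                cols[:, :, i, j] = xp[:, :, i : i + s * oh : s, j : j + s * ow : s]
        return cols.reshape(N, C * k * k, oh * ow), (N, C, H, W, oh, ow)

    def forward(self, x: np.ndarray) -> np.ndarray:
        cols, meta = self._im2col(x)
        self._cols, self._meta = cols, meta
        N, C, H, W, oh, ow = meta
        y = np.einsum("of,nft->not", self.W, cols) + self.b[None, :, None]
        return y.reshape(N, self.cout, oh, ow)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        N, C, H, W, oh, ow = self._meta
        g = grad.reshape(N, self.cout, oh * ow)
        self.grads["W"] += np.einsum("not,nft->of", g, self._cols)
        self.grads["b"] += g.sum(axis=(0, 2))
        dcols = np.einsum("of,not->nft", self.W, g).reshape(N, C, self.k, self.k, oh, ow)
        k, s, p = self.k, self.stride, self.pad
        dxp = np.zeros((N, C, H + 2 * p, W + 2 * p))
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + s * oh : s, j : j + s * ow : s] += dcols[:, :, i, j]
        return dxp[:, :, p : p + H, p : p + W]


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def zero_grad(self):
        for layer in self.layers:
            layer.zero_grad()

    def named_parameters(self, prefix: str = ""):
        for i, layer in enumerate(self.layers):
            yield from layer.named_parameters(f"{prefix}{i}.")


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


class GRU(Module):
    """Single-layer gated recurrent unit over a full sequence.

    h_t = (1 - z_t) * n_t + z_t * h_{t-1} with update gate z, reset gate r
    and candidate n = tanh(Wn x + b_in + r * (Un h + b_hn)).  Gate
    activations of the last forward pass are kept in `gate_traces` under
    the names "update", "reset" and "candidate".
    """

    GATES = ("update", "reset", "candidate")

    def __init__(self, input_size: int, hidden_size: int, rng: np.random.Generator):
        super().__init__()
        self.input_size, self.hidden_size = input_size, hidden_size
        I, H = input_size, hidden_size
        for g in ("z", "r", "n"):
            self.add_param(f"W{g}", _uniform_init(rng, (H, I), H))
            self.add_param(f"U{g}", _uniform_init(rng, (H, H), H))
            self.add_param(f"b{g}", _uniform_init(rng, (H,), H))
        self.add_param("bhn", _uniform_init(rng, (H,), H))
        self.gate_traces: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray) -> np.ndarray:
        T = x.shape[0]
        H = self.hidden_size
        P = self.params
        h = np.zeros(H)
        hs = np.zeros((T + 1, H))
        zs, rs, ns, hhs = (np.zeros((T, H)) for _ in range(4))
        for t in range(T):
            z = _sigmoid(P["Wz"] @ x[t] + P["Uz"] @ h + P["bz"])
            r = _sigmoid(P["Wr"] @ x[t] + P["Ur"] @ h + P["br"])
            hh = P["Un"] @ h + P["bhn"]
            n = np.tanh(P["Wn"] @ x[t] + P["bn"] + r * hh)
            h = (1.0 - z) * n + z * h
            zs[t], rs[t], ns[t], hhs[t], hs[t + 1] = z, r, n, hh, h
        self._cache = (x, hs, zs, rs, ns, hhs)
        self.gate_traces = {"update": zs, "reset": rs, "candidate": ns}
        return hs[1:]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x, hs, zs, rs, ns, hhs = self._cache
        T = x.shape[0]
        P, G = self.params, self.grads
        dx = np.zeros_like(x)
        dh_next = np.zeros(self.hidden_size)
        for t in range(T - 1, -1, -1):
            dh = grad[t] + dh_next
            z, r, n, hh, h_prev = zs[t], rs[t], ns[t], hhs[t], hs[t]
            dn = dh * (1.0 - z)
            daz = dh * (h_prev - n) * z * (1.0 - z)
            dn_pre = dn * (1.0 - n * n)
            dar = dn_pre * hh * r * (1.0 - r)
            dhh = dn_pre * r
            G["Wz"] += np.outer(daz, x[t]); G["Uz"] += np.outer(daz, h_prev); G["bz"] += daz
            G["Wr"] += np.outer(dar, x[t]); G["Ur"] += np.outer(dar, h_prev); G["br"] += dar
            G["Wn"] += np.outer(dn_pre, x[t]); G["bn"] += dn_pre
            G["Un"] += np.outer(dhh, h_prev); G["bhn"] += dhh
            dx[t] = P["Wz"].T @ daz + P["Wr"].T @ dar + P["Wn"].T @ dn_pre
            dh_next = dh * z + P["Uz"].T @ daz + P["Ur"].T @ dar + P["Un"].T @ dhh
        return dx


class LSTM(Module):
    """Single-layer LSTM over a full sequence.

    Gate activations of the last forward pass are kept in `gate_traces`
    under "input", "forget", "output" and "candidate".
    """

    GATES = ("input", "forget", "output", "candidate")

    def __init__(self, input_size: int, hidden_size: int, rng: np.random.Generator):
        super().__init__()
        self.input_size, self.hidden_size = input_size, hidden_size
        I, H = input_size, hidden_size
        for g in ("i", "f", "o", "g"):
            self.add_param(f"W{g}", _uniform_init(rng, (H, I), H))
            self.add_param(f"U{g}", _uniform_init(rng, (H, H), H))
            self.add_param(f"b{g}", _uniform_init(rng, (H,), H))
        self.gate_traces: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray) -> np.ndarray:
        T = x.shape[0]
        H = self.hidden_size
        P = self.params
        h = np.zeros(H)
        c = np.zeros(H)
        hs = np.zeros((T + 1, H))
        cs = np.zeros((T + 1, H))
        is_, fs, os_, gs = (np.zeros((T, H)) for _ in range(4))
        for t in range(T):
            i = _sigmoid(P["Wi"] @ x[t] + P["Ui"] @ h + P["bi"])
            f = _sigmoid(P["Wf"] @ x[t] + P["Uf"] @ h + P["bf"])
            o = _sigmoid(P["Wo"] @ x[t] + P["Uo"] @ h + P["bo"])
            g = np.tanh(P["Wg"] @ x[t] + P["Ug"] @ h + P["bg"])
            c = f * c + i * g
            h = o * np.tanh(c)
            is_[t], fs[t], os_[t], gs[t] = i, f, o, g
            hs[t + 1], cs[t + 1] = h, c
        self._cache = (x, hs, cs, is_, fs, os_, gs)
        self.gate_traces = {"input": is_, "forget": fs, "output": os_, "candidate": gs}
        return hs[1:]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x, hs, cs, is_, fs, os_, gs = self._cache
        T = x.shape[0]
        P, G = self.params, self.grads
        dx = np.zeros_like(x)
        dh_next = np.zeros(self.hidden_size)
        dc_next = np.zeros(self.hidden_size)
        for t in range(T - 1, -1, -1):
            dh = grad[t] + dh_next
            i, f, o, g = is_[t], fs[t], os_[t], gs[t]
            c, c_prev, h_prev = cs[t + 1], cs[t], hs[t]
            tc = np.tanh(c)
            do = dh * tc
            dc = dh * o * (1.0 - tc * tc) + dc_next
            di, df, dg = dc * g, dc * c_prev, dc * i
            dai = di * i * (1.0 - i)
            daf = df * f * (1.0 - f)
            dao = do * o * (1.0 - o)
            dag = dg * (1.0 - g * g)
            for name, da in (("i", dai), ("f", daf), ("o", dao), ("g", dag)):
                G[f"W{name}"] += np.outer(da, x[t])
                G[f"U{name}"] += np.outer(da, h_prev)
                G[f"b{name}"] += da
            dx[t] = (P["Wi"].T @ dai + P["Wf"].T @ daf + P["Wo"].T @ dao + P["Wg"].T @ dag)
            dh_next = (P["Ui"].T @ dai + P["Uf"].T @ daf + P["Uo"].T @ dao + P["Ug"].T @ dag)
            dc_next = dc * f
        return dx
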