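"""A compact NumPy network engine for the gesture decoders.

The decoders operate on small descriptor tensors
(``[batch, time_steps, channels, features]``, e.g. ``[B, 60, 21, 6]``), so
the whole network — causal dilated temporal convolutions, circular spatial
convolutions across the electrode ring, batch normalisation, dropout and a
softmax head — is implemented directly with explicit forward and backward
passes.  The backward pass propagates gradients all the way to the input
tensor, which is exactly the quantity gradient saliency needs.

Conventions: tensors are ``[B, T, C, F]``; every layer mixes only the last
(feature-map) axis plus its declared receptive field along T (causal,
dilated) or C (circular).
"""

from __future__ import annotations

import numpy as np

from .recording import ConfigError


class Layer:
    """Base layer: stateless unless it declares params/grads dicts."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grads(self) -> None:
        for k, v in self.params.items():
            self.grads[k] = np.zeros_like(v)

    def n_params(self) -> int:
        return sum(int(v.size) for v in self.params.values())


def _he_init(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    return rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)


class CausalTemporalConv(Layer):
    """Dilated causal 1-D convolution along time, shared across channels.

    ``y[b, t, c] = b + sum_j x[b, t - j*dilation, c] @ W[j]`` with left zero
    padding, so activations at time t never depend on inputs after t.
    """

    def __init__(self, f_in: int, f_out: int, kernel: int = 3, dilation: int = 1,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        if dilation < 1 or kernel < 1:
            raise ConfigError("kernel and dilation must be >= 1")
        rng = rng or np.random.default_rng(0)
        self.kernel, self.dilation = kernel, dilation
        self.params = {"W": _he_init(rng, (kernel, f_in, f_out), kernel * f_in),
                       "b": np.zeros(f_out)}
        self.zero_grads()

    def forward(self, x, train=False, rng=None):
        k, d = self.kernel, self.dilation
        pad = (k - 1) * d
        T = x.shape[1]
        xp = np.pad(x, ((0, 0), (pad, 0), (0, 0), (0, 0)))
        # taps stacked into one [B,T,C,k*f_in] matrix -> single GEMM
        xs = np.stack([xp[:, pad - j * d: pad - j * d + T] for j in range(k)], axis=3)
        self._flat = xs.reshape(*xs.shape[:3], -1)
        self._T = T
        W = self.params["W"].reshape(-1, self.params["W"].shape[-1])
        return self._flat @ W + self.params["b"]

    def backward(self, g):
        k, d, T = self.kernel, self.dilation, self._T
        pad = (k - 1) * d
        f_out = g.shape[-1]
        Wf = self.params["W"].reshape(-1, f_out)
        gf = g.reshape(-1, f_out)
        self.grads["W"] += (self._flat.reshape(-1, Wf.shape[0]).T @ gf).reshape(self.params["W"].shape)
        self.grads["b"] += gf.sum(axis=0)
        dxs = (gf @ Wf.T).reshape(*g.shape[:3], k, -1)
        B, C, f_in = g.shape[0], g.shape[2], dxs.shape[-1]
        dxp = np.zeros((B, T + pad, C, f_in))
        for j in range(k):
            dxp[:, pad - j * d: pad - j * d + T] += dxs[:, :, :, j]
        return dxp[:, pad:]


class CircularSpatialConv(Layer):
    """Convolution across the channel axis at each time step, circular wrap.

    The electrode nodes form a closed ring around the forearm, so the
    channel axis is treated as periodic: ``y[..., c, :] = b + sum_j
    x[..., (c + j - k//2) mod C, :] @ W[j]``.
    """

    def __init__(self, f_in: int, f_out: int, kernel: int = 3,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.kernel = kernel
        self.params = {"W": _he_init(rng, (kernel, f_in, f_out), kernel * f_in),
                       "b": np.zeros(f_out)}
        self.zero_grads()

    def forward(self, x, train=False, rng=None):
        if self.kernel > x.shape[2]:
            raise ConfigError(f"spatial kernel {self.kernel} exceeds channel count {x.shape[2]}")
        k = self.kernel
        xs = np.stack([np.roll(x, -(j - k // 2), axis=2) for j in range(k)], axis=3)
        self._flat = xs.reshape(*xs.shape[:3], -1)
        W = self.params["W"].reshape(-1, self.params["W"].shape[-1])
        return self._flat @ W + self.params["b"]

    def backward(self, g):
        k = self.kernel
        f_out = g.shape[-1]
        Wf = self.params["W"].reshape(-1, f_out)
        gf = g.reshape(-1, f_out)
        self.grads["W"] += (self._flat.reshape(-1, Wf.shape[0]).T @ gf).reshape(self.params["W"].shape)
        self.grads["b"] += gf.sum(axis=0)
        dxs = (gf @ Wf.T).reshape(*g.shape[:3], k, -1)
        dx = np.zeros(g.shape[:3] + (dxs.shape[-1],))
        for j in range(k):
            dx += np.roll(dxs[:, :, :, j], j - k // 2, axis=2)
        return dx


class ParallelConvBlock(Layer):
    """Simultaneous temporal + spatial convolution of the same input.

    The two branches see the same input and are merged per feature map
    (``concat`` stacks branch outputs along the feature axis; ``sum`` adds
    them), so every output map carries both backward-in-time and
    across-channel context of its input.  A temporal-only block (vanilla
    TCN) is the degenerate case ``spatial=None``.
    """

    def __init__(self, temporal: CausalTemporalConv,
                 spatial: CircularSpatialConv | None, merge: str = "concat") -> None:
        super().__init__()
        if merge not in ("concat", "sum"):
            raise ConfigError(f"merge must be 'concat' or 'sum', got '{merge}'")
        self.temporal, self.spatial, self.merge = temporal, spatial, merge

    @property
    def children(self):
        return [l for l in (self.temporal, self.spatial) if l is not None]

    def forward(self, x, train=False, rng=None):
        yt = self.temporal.forward(x, train, rng)
        if self.spatial is None:
            return yt
        ys = self.spatial.forward(x, train, rng)
        if self.merge == "concat":
            self._split = yt.shape[-1]
            return np.concatenate([yt, ys], axis=-1)
        return yt + ys

    def backward(self, g):
        if self.spatial is None:
            return self.temporal.backward(g)
        if self.merge == "concat":
            gt, gs = g[..., : self._split], g[..., self._split:]
        else:
            gt = gs = g
        return self.temporal.backward(gt) + self.spatial.backward(gs)

    def zero_grads(self):
        for c in self.children:
            c.zero_grads()

    def n_params(self):
        return sum(c.n_params() for c in self.children)


class BatchNorm(Layer):
    """Per-feature-map normalisation over the (batch, time, channel) axes."""

    def __init__(self, f: int, momentum: float = 0.9, eps: float = 1e-5) -> None:
        super().__init__()
        self.params = {"gamma": np.ones(f), "beta": np.zeros(f)}
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(f)
        self.running_var = np.ones(f)
        self.zero_grads()

    def forward(self, x, train=False, rng=None):
        if train:
            mu = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mu
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv, train)
        return self.params["gamma"] * xhat + self.params["beta"]

    def backward(self, g):
        xhat, inv, train = self._cache
        self.grads["gamma"] += (g * xhat).sum(axis=(0, 1, 2))
        self.grads["beta"] += g.sum(axis=(0, 1, 2))
        gx = g * self.params["gamma"]
        if not train:
            return gx * inv
        n = xhat.shape[0] * xhat.shape[1] * xhat.shape[2]
        return (inv / n) * (n * gx - gx.sum(axis=(0, 1, 2))
                            - xhat * (gx * xhat).sum(axis=(0, 1, 2)))


class ReLU(Layer):
    def forward(self, x, train=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, g):
        return g * self._mask


class Dropout(Layer):
    def __init__(self, p: float) -> None:
        super().__init__()
        if not 0 <= p < 1:
            raise ConfigError("dropout_p must be in [0, 1)")
        self.p = p

    def forward(self, x, train=False, rng=None):
        if not train or self.p == 0:
            self._mask = None
            return x
        rng = rng or np.random.default_rng(0)
        self._mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, g):
        return g if self._mask is None else g * self._mask


class FlattenChannels(Layer):
    """[B, T, C, F] -> [B, T, 1, C*F]: stack channel features for a vanilla TCN."""

    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], x.shape[1], 1, -1)

    def backward(self, g):
        return g.reshape(self._shape)


class TimePoolDense(Layer):
    """Average pool over time, flatten channels x maps, dense class head.

    Pooling collapses only the (causal) time axis; the channel axis stays
    distinct so the head can weight absolute electrode positions — the
    spatial convolutions alone are rotation-equivariant around the ring
    and could not otherwise anchor a pattern to specific channels.
    """

    def __init__(self, n_channels: int, f_in: int, n_classes: int,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        d = n_channels * f_in
        self.params = {"W": _he_init(rng, (d, n_classes), d), "b": np.zeros(n_classes)}
        self.zero_grads()

    def forward(self, x, train=False, rng=None):
        self._x_shape = x.shape
        self._pooled = x.mean(axis=1).reshape(x.shape[0], -1)
        return self._pooled @ self.params["W"] + self.params["b"]

    def backward(self, g):
        self.grads["W"] += self._pooled.T @ g
        self.grads["b"] += g.sum(axis=0)
        B, T, C, F = self._x_shape
        dpool = (g @ self.params["W"].T).reshape(B, C, F)
        return np.broadcast_to(dpool[:, None] / T, self._x_shape).copy()


class FlattenDense(Layer):
    """Dense class head over the fully flattened input (linear surrogate)."""

    def __init__(self, in_shape: tuple[int, int, int], n_classes: int,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        f_in = int(np.prod(in_shape))
        self.in_shape = in_shape
        self.params = {"W": _he_init(rng, (f_in, n_classes), f_in), "b": np.zeros(n_classes)}
        self.zero_grads()

    def forward(self, x, train=False, rng=None):
        self._x_shape = x.shape
        self._flat = x.reshape(x.shape[0], -1)
        return self._flat @ self.params["W"] + self.params["b"]

    def backward(self, g):
        self.grads["W"] += self._flat.T @ g
        self.grads["b"] += g.sum(axis=0)
        return (g @ self.params["W"].T).reshape(self._x_shape)


class SequenceNet:
    """A feed-forward stack of layers ending in a logits head."""

    def __init__(self, layers: list[Layer], head: Layer) -> None:
        self.layers = layers
        self.head = head

    def _all_layers(self):
        flat = []
        for l in self.layers + [self.head]:
            if isinstance(l, ParallelConvBlock):
                flat.extend(l.children)
            else:
                flat.append(l)
        return flat

    def forward(self, x, train: bool = False, rng: np.random.Generator | None = None):
        for layer in self.layers:
            x = layer.forward(x, train, rng)
        return self.head.forward(x, train, rng)

    def blocks_forward(self, x):
        """Eval-mode activations just before the head (for causality checks)."""
        for layer in self.layers:
            x = layer.forward(x, train=False)
        return x

    def backward(self, dlogits):
        g = self.head.backward(dlogits)
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def zero_grads(self):
        for layer in self.layers + [self.head]:
            layer.zero_grads()

    def n_params(self) -> int:
        return sum(l.n_params() for l in self.layers + [self.head])

    def param_arrays(self):
        out = []
        for layer in self._all_layers():
            for name in sorted(layer.params):
                out.append((layer, name))
        return out

    def get_state(self) -> list[np.ndarray]:
        return [layer.params[name].copy() for layer, name in self.param_arrays()]

    def set_state(self, state: list[np.ndarray]) -> None:
        for (layer, name), arr in zip(self.param_arrays(), state):
            layer.params[name] = arr.copy()

    def input_gradient(self, x: np.ndarray, class_idx: int) -> np.ndarray:
        """d(logit of class)/d(input), eval mode, per sample in the batch."""
        logits = self.forward(x, train=False)
        self.zero_grads()
        d = np.zeros_like(logits)
        d[:, class_idx] = 1.0
        return self.backward(d)


class Adam:
    def __init__(self, net: SequenceNet, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.net, self.lr, self.b1, self.b2, self.eps = net, lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(l.params[n]) for l, n in net.param_arrays()]
        self.v = [np.zeros_like(l.params[n]) for l, n in net.param_arrays()]

    def step(self) -> None:
        self.t += 1
        for i, (layer, name) in enumerate(self.net.param_arrays()):
            g = layer.grads[name]
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            layer.params[name] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy_grad(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = -np.mean(np.log(p[np.arange(n), y] + 1e-12))
    g = p.copy()
    g[np.arange(n), y] -= 1.0
    return float(loss), g / n
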