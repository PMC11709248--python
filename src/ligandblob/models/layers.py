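"""Neural-network building blocks shared by the two classifier architectures."""

from __future__ import annotations

import numpy as np

from .autodiff import Parameter, Tensor

__all__ = ["Module", "Linear", "BatchNorm", "ECA", "NetVLAD", "Adam"]


class Module:
    """Base class: parameter discovery by attribute walk, train/eval modes."""

    def parameters(self) -> list[Parameter]:
        params = []
        for value in vars(self).values():
            if isinstance(value, Parameter):
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        params.append(item)
        return params

    def set_training(self, flag: bool) -> None:
        for value in vars(self).values():
            if isinstance(value, Module):
                value.set_training(flag)
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        item.set_training(flag)
        if hasattr(self, "training"):
            self.training = flag

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("state size mismatch")
        for p, a in zip(params, arrays):
            p.data = np.asarray(a, dtype=np.float64).reshape(p.data.shape)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, zero_init: bool = False):
        if zero_init:
            w = np.zeros((n_in, n_out))
        else:
            w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.w = Parameter(w)
        self.b = Parameter(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class BatchNorm(Module):
    """Normalization over the point axis (axis 0) of an (N, C) feature matrix.

    A "batch" here is the set of points/voxels of one cloud, so this is
    instance-style normalization: statistics come from the current forward
    pass in training *and* evaluation.  That keeps train and inference
    behavior identical, makes predictions deterministic, and is invariant to
    point order and cloud rotation (statistics are per-channel moments over
    an unordered set).
    """

    def __init__(self, n_features: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(n_features))
        self.beta = Parameter(np.zeros(n_features))
        self.eps = eps
        self.training = True

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=0, keepdims=True)
        centered = x - mu
        var = centered.pow(2).mean(axis=0, keepdims=True)
        inv = (var + self.eps).pow(-0.5)
        return centered * inv * self.gamma + self.beta


class ECA(Module):
    """Efficient Channel Attention: per-channel sigmoid gate from a 1D
    convolution (odd kernel) over the channel descriptor (mean over points)."""

    def __init__(self, kernel: int = 3):
        if kernel % 2 != 1:
            raise ValueError("ECA kernel must be odd")
        self.kernel = kernel
        self.w = Parameter(np.zeros(kernel))  # zero init -> gate starts at 0.5

    def __call__(self, x: Tensor) -> Tensor:
        n_ch = x.data.shape[1]
        desc = x.mean(axis=0)  # (C,)
        half = self.kernel // 2
        conv = None
        for j in range(self.kernel):
            # shifted channel indices with edge clamping
            idx = np.clip(np.arange(n_ch) + j - half, 0, n_ch - 1)
            term = desc.take(idx) * self.w.take([j])
            conv = term if conv is None else conv + term
        gate = conv.sigmoid() * 2.0  # gate in (0, 2), identity at init
        return x * gate.reshape(1, n_ch)


class NetVLAD(Module):
    """Soft-assignment aggregation of local features into a global descriptor.

    Each point feature is soft-assigned to K learnable cluster centers; the
    descriptor concatenates, per cluster, the soft-weighted sum of residuals
    to the center, intra-normalized and then globally L2-normalized.
    """

    def __init__(self, n_features: int, n_clusters: int, rng: np.random.Generator):
        self.centers = Parameter(rng.normal(0.0, 1.0, size=(n_clusters, n_features)))
        self.assign = Linear(n_features, n_clusters, rng)
        self.n_clusters = n_clusters
        self.n_features = n_features

    def __call__(self, x: Tensor) -> Tensor:
        # x: (N, C) -> descriptor (K*C,)
        logits = self.assign(x)  # (N, K)
        soft = logits.log_softmax().exp()
        weighted = soft.T @ x  # (K, C)
        colsum = soft.sum(axis=0)  # (K,)
        vlad = weighted - self.centers * colsum.reshape(self.n_clusters, 1)
        # intra-normalization per cluster, then global L2
        norms = (vlad.pow(2).sum(axis=1, keepdims=True) + 1e-12).sqrt()
        vlad = vlad / norms
        flat = vlad.reshape(self.n_clusters * self.n_features)
        total = (flat.pow(2).sum() + 1e-12).sqrt()
        return flat / total


class Adam:
    """Adam optimizer over a fixed parameter list."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

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
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
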