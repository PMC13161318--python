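"""Clustering networks and optimizer built on the autodiff engine.

Two architectures are provided, matching the tool's two input modalities:

* :class:`MLP` for tabular cohorts — rectified-linear hidden stack ending in
  a softmax over the k clusters.  The default (10 -> 5 x 256 -> 3) is the
  configuration used for laboratory-parameter cohorts.
* :class:`CNN` for 2D grayscale image cohorts — convolution-and-pooling
  blocks with zero padding, reducing the feature map to 1x1, followed by a
  single linear layer and softmax.  :func:`full_scale_blocks` is the
  six-block reference profile (requires 1024x1024 inputs);
  :func:`desk_scale_blocks` is a reduced four-block profile for 64x64
  images.

Both emit per-subject probability rows that feed directly into
:func:`survclust.logrank.partial_logrank_loss`.  :class:`AdamW` implements
adaptive moment estimation with decoupled weight decay.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad

__all__ = [
    "Linear",
    "MLP",
    "CNN",
    "AdamW",
    "full_scale_blocks",
    "desk_scale_blocks",
]


class Linear:
    """Affine layer; He-style init scaled for the rectifier stack."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.W = ad.Tensor(rng.normal(0.0, scale, (n_in, n_out)), requires_grad=True)
        self.b = ad.Tensor(np.zeros(n_out), requires_grad=True)

    @property
    def params(self):
        return [self.W, self.b]

    def __call__(self, x):
        return x @ self.W + self.b


class MLP:
    """Fully-connected clustering network with a softmax head."""

    def __init__(
        self,
        input_dim: int = 10,
        hidden: tuple[int, ...] = (256, 256, 256, 256, 256),
        k: int = 3,
        seed: int = 0,
    ):
        rng = np.random.default_rng(seed)
        dims = (input_dim, *hidden)
        self.layers = [Linear(dims[i], dims[i + 1], rng) for i in range(len(hidden))]
        self.head = Linear(dims[-1], k, rng)
        self.k = k
        self.input_dim = input_dim

    @property
    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params)
        out.extend(self.head.params)
        return out

    def __call__(self, x) -> ad.Tensor:
        h = ad.astensor(x)
        for layer in self.layers:
            h = ad.relu(layer(h))
        return ad.softmax(self.head(h), axis=-1)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return self(x).data


def full_scale_blocks():
    """Six convolution-and-pooling blocks; pools 4*4*4*2*2*2 = 1024."""
    return [
        (32, 16, 4),
        (8, 8, 4),
        (8, 8, 4),
        (8, 8, 2),
        (4, 3, 2),
        (4, 2, 2),
    ]


def desk_scale_blocks():
    """Reduced four-block profile for 64x64 images; pools 4*4*2*2 = 64.

    The first-layer kernel is deliberately large relative to the image
    (9x9 on 64px), echoing the full-scale profile's 16x16-on-512px opening
    layer: a receptive field on the order of the structures of interest
    lets shape-selective features emerge within the first epochs, which the
    survival-guided objective needs before its cluster assignments harden.
    """
    return [
        (8, 9, 4),
        (8, 5, 4),
        (8, 3, 2),
        (4, 2, 2),
    ]


class CNN:
    """Convolutional clustering network for single-channel 2D images.

    ``blocks`` is a list of ``(channels, kernel, pool)`` tuples; all
    convolutions are zero-padded so pooling alone shrinks the map.  The
    product of pool sizes must equal the input resolution so that the final
    activation map is 1x1 and can be passed straight to the linear head.
    """

    def __init__(
        self,
        input_size: tuple[int, int] = (64, 64),
        blocks: list[tuple[int, int, int]] | None = None,
        k: int = 3,
        seed: int = 0,
    ):
        if blocks is None:
            blocks = desk_scale_blocks()
        h, w = input_size
        reduction = int(np.prod([p for (_, _, p) in blocks]))
        if h != reduction or w != reduction:
            raise ValueError(
                f"input size {h}x{w} incompatible with pooling stages: this "
                f"block profile requires {reduction}x{reduction} images so the "
                "final feature map is 1x1"
            )
        rng = np.random.default_rng(seed)
        self.blocks = blocks
        self.conv_w = []
        self.conv_b = []
        c_in = 1
        for c_out, kern, _pool in blocks:
            scale = np.sqrt(2.0 / (c_in * kern * kern))
            self.conv_w.append(
                ad.Tensor(
                    rng.normal(0.0, scale, (c_out, c_in, kern, kern)),
                    requires_grad=True,
                )
            )
            self.conv_b.append(ad.Tensor(np.zeros(c_out), requires_grad=True))
            c_in = c_out
        self.head = Linear(c_in, k, rng)
        # near-uniform initial assignments: early cluster preferences should
        # come from emerging features, not from the random head
        self.head.W.data *= 0.1
        self.k = k
        self.input_size = tuple(input_size)

    @property
    def params(self):
        out = []
        for w, b in zip(self.conv_w, self.conv_b):
            out.extend([w, b])
        out.extend(self.head.params)
        return out

    def __call__(self, x) -> ad.Tensor:
        h = ad.astensor(x)
        if h.ndim == 3:  # (N, H, W) -> (N, 1, H, W)
            h = h.reshape(h.shape[0], 1, *h.shape[1:])
        for (c_out, _kern, pool), w, b in zip(self.blocks, self.conv_w, self.conv_b):
            h = ad.relu(ad.conv2d(h, w, b))
            h = ad.maxpool2d(h, pool)
        h = h.reshape(h.shape[0], h.shape[1])  # final map is 1x1
        return ad.softmax(self.head(h), axis=-1)

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        out = [self(x[i : i + batch_size]).data for i in range(0, len(x), batch_size)]
        return np.concatenate(out, axis=0)


class AdamW:
    """Adaptive moment estimation with decoupled weight decay."""

    def __init__(
        self,
        params: list[ad.Tensor],
        lr: float = 1e-3,
        weight_decay: float = 0.0,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr = lr
        self.weight_decay = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            # decoupled decay: shrink the parameter, not the gradient
            if self.weight_decay:
                p.data -= self.lr * self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
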