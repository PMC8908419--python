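"""BMNet: a shallow convolutional network over regional PET features.

The architecture mirrors the published design for regional FDG-PET
classification: a vector of per-region mean intensities is treated as a
1-channel 1-D sequence and passed through two convolution blocks
(Conv -> BatchNorm -> ReLU).  The flattened first-order feature map Y is
then fused into a second-order, inter-region representation by factorized
bilinear pooling,

    B = Y^T W Y = Y^T U V^T Y = P^T (U^T Y ∘ V^T Y),

where U, V (d x r) are the low-rank dictionary factors, P (r x o) controls
the output length and ∘ is the Hadamard product.  An average-pooling stage
reduces B, and a small fully connected head produces a metric-learning
embedding (penultimate layer) and a positive-class probability.  Setting
``use_bp=False`` replaces the bilinear stage with a single fully connected
layer of matched output size, yielding the Baseline ablation variant.

No deep-learning framework is used: every layer carries an analytic
backward pass (verified against finite differences in the test suite) so
that training is exactly reproducible from a seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

__all__ = [
    "BMNetConfig",
    "BMNet",
    "ForwardOutput",
    "ShapeError",
    "NumericError",
    "factorized_bilinear_pool",
    "conv_block_forward",
    "count_parameters",
    "save_checkpoint",
    "load_checkpoint",
]

CHECKPOINT_VERSION = 1
_BN_EPS = 1e-5


class ShapeError(ValueError):
    """Input dimensions incompatible with the layer or configuration."""


class NumericError(FloatingPointError):
    """Non-finite values encountered in a forward pass."""


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BMNetConfig:
    """Architecture hyper-parameters.

    Parameters
    ----------
    n_regions:
        Length of the input region vector (90 for an AAL-style atlas,
        400 for a Schaefer-style atlas; arbitrary here).
    conv_channels:
        Output channels of the two convolution blocks.
    conv_kernel:
        Odd kernel size of both 1-D convolutions ("same" padding).
    bp_rank:
        Rank r of the bilinear dictionary factors U, V.
    bp_out:
        Output length o of the bilinear stage (columns of P); must be
        divisible by ``avgpool_window``.
    avgpool_window:
        Window of the average pooling applied after the bilinear stage.
    fc_dims:
        Extra hidden widths of the fully connected head before the
        embedding layer.  The default () gives a two-FC head
        (embedding -> output) after the bilinear stage; the Baseline
        variant's replacement FC then makes three FC layers in total.
    embedding_dim:
        Width of the penultimate layer; its ReLU output is the embedding
        used by the metric losses.
    use_bp:
        If False, the bilinear stage is replaced by one FC layer of
        matched output size (the Baseline variant).
    """

    n_regions: int
    conv_channels: tuple[int, int] = (16, 32)
    conv_kernel: int = 3
    bp_rank: int = 32
    bp_out: int = 64
    avgpool_window: int = 2
    fc_dims: tuple[int, ...] = ()
    embedding_dim: int = 32
    use_bp: bool = True
    n_classes: int = 2

    def __post_init__(self) -> None:
        dims = (self.n_regions, *self.conv_channels, self.conv_kernel,
                self.bp_rank, self.bp_out, self.avgpool_window,
                *self.fc_dims, self.embedding_dim)
        if any(int(d) <= 0 for d in dims):
            raise ShapeError(f"all architecture dimensions must be positive, got {self}")
        if self.conv_kernel % 2 == 0:
            raise ShapeError(f"conv_kernel must be odd, got {self.conv_kernel}")
        if self.bp_out % self.avgpool_window != 0:
            raise ShapeError(
                f"bp_out={self.bp_out} must be divisible by avgpool_window={self.avgpool_window}"
            )
        if self.n_regions < self.conv_kernel:
            raise ShapeError(
                f"input length {self.n_regions} shorter than kernel {self.conv_kernel}"
            )

    @property
    def flat_dim(self) -> int:
        """d: flattened conv-trunk output length fed to the bilinear stage."""
        return self.conv_channels[1] * self.n_regions

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["conv_channels"] = list(self.conv_channels)
        d["fc_dims"] = list(self.fc_dims)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "BMNetConfig":
        d = dict(d)
        d["conv_channels"] = tuple(d["conv_channels"])
        d["fc_dims"] = tuple(d["fc_dims"])
        return cls(**d)


@dataclass
class ForwardOutput:
    """Per-sample network outputs: embedding, logit and positive-class probability."""

    embedding: np.ndarray
    logit: np.ndarray
    probability: np.ndarray


# ---------------------------------------------------------------------------
# Layers (each caches what its backward pass needs)
# ---------------------------------------------------------------------------


def _kaiming_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    bound = np.sqrt(6.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape)


class Conv1d:
    """1-D convolution with 'same' zero padding, stride 1."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        self.kernel = kernel
        self.pad = kernel // 2
        fan_in = c_in * kernel
        self.W = _kaiming_uniform(rng, (c_out, c_in, kernel), fan_in)
        self.b = np.zeros(c_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cols: np.ndarray | None = None

    def params(self):
        return [("W", self.W, self.dW), ("b", self.b, self.db)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c_in, length = x.shape
        if length < self.kernel:
            raise ShapeError(f"input length {length} shorter than kernel {self.kernel}")
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad)))
        # (n, c_in, L, k) sliding windows
        cols = np.lib.stride_tricks.sliding_window_view(xp, self.kernel, axis=2)
        self._cols = cols
        out = np.tensordot(cols, self.W, axes=([1, 3], [1, 2]))  # (n, L, c_out)
        out = out.transpose(0, 2, 1) + self.b[None, :, None]
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols = self._cols
        n, c_in, length, k = cols.shape
        self.db += dout.sum(axis=(0, 2))
        # dW[o,c,k] = sum_{n,L} dout[n,o,L] * cols[n,c,L,k]
        self.dW += np.tensordot(dout, cols, axes=([0, 2], [0, 2]))
        # dcols[n,c,L,k] = sum_o dout[n,o,L] W[o,c,k]
        dcols = np.einsum("nol,ock->nclk", dout, self.W)
        dxp = np.zeros((n, c_in, length + 2 * self.pad))
        for j in range(k):
            dxp[:, :, j:j + length] += dcols[:, :, :, j]
        return dxp[:, :, self.pad:self.pad + length]


class BatchNorm1d:
    """Per-channel batch normalization over (batch, length); momentum 0.1."""

    def __init__(self, channels: int, momentum: float = 0.1):
        self.gamma = np.ones(channels)
        self.beta = np.zeros(channels)
        self.dgamma = np.zeros(channels)
        self.dbeta = np.zeros(channels)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self._cache = None

    def params(self):
        return [("gamma", self.gamma, self.dgamma), ("beta", self.beta, self.dbeta)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            m = x.shape[0] * x.shape[2]
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            unbiased = var * m / max(m - 1, 1)
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * unbiased
        else:
            mean, var = self.running_mean, self.running_var
        ivar = 1.0 / np.sqrt(var + _BN_EPS)
        xhat = (x - mean[None, :, None]) * ivar[None, :, None]
        self._cache = (xhat, ivar, train)
        return self.gamma[None, :, None] * xhat + self.beta[None, :, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, ivar, train = self._cache
        self.dgamma += (dout * xhat).sum(axis=(0, 2))
        self.dbeta += dout.sum(axis=(0, 2))
        dxhat = dout * self.gamma[None, :, None]
        if not train:
            return dxhat * ivar[None, :, None]
        m = dout.shape[0] * dout.shape[2]
        s1 = dxhat.sum(axis=(0, 2), keepdims=True)
        s2 = (dxhat * xhat).sum(axis=(0, 2), keepdims=True)
        return (ivar[None, :, None] / m) * (m * dxhat - s1 - xhat * s2)


class ReLU:
    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class Linear:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.W = _kaiming_uniform(rng, (d_in, d_out), d_in)
        self.b = np.zeros(d_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x = None

    def params(self):
        return [("W", self.W, self.dW), ("b", self.b, self.db)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dW += self._x.T @ dout
        self.db += dout.sum(axis=0)
        return dout @ self.W.T


class BilinearPool:
    """Factorized bilinear pooling: z = P^T (U^T y ∘ V^T y) per sample."""

    def __init__(self, d: int, rank: int, out: int, rng: np.random.Generator):
        self.U = _kaiming_uniform(rng, (d, rank), d)
        self.V = _kaiming_uniform(rng, (d, rank), d)
        self.P = _kaiming_uniform(rng, (rank, out), rank)
        self.dU = np.zeros_like(self.U)
        self.dV = np.zeros_like(self.V)
        self.dP = np.zeros_like(self.P)
        self._cache = None

    def params(self):
        return [("U", self.U, self.dU), ("V", self.V, self.dV), ("P", self.P, self.dP)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        a = x @ self.U
        b = x @ self.V
        h = a * b
        self._cache = (x, a, b, h)
        return h @ self.P

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x, a, b, h = self._cache
        self.dP += h.T @ dout
        dh = dout @ self.P.T
        da = dh * b
        db = dh * a
        self.dU += x.T @ da
        self.dV += x.T @ db
        return da @ self.U.T + db @ self.V.T


class AvgPoolVec:
    """Non-overlapping average pooling on a flat feature vector."""

    def __init__(self, window: int):
        self.window = window

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, d = x.shape
        if d % self.window:
            raise ShapeError(f"feature length {d} not divisible by pool window {self.window}")
        return x.reshape(n, d // self.window, self.window).mean(axis=2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, d = dout.shape
        return np.repeat(dout, self.window, axis=1) / self.window


class ConvBlock:
    """Conv -> BatchNorm -> ReLU, the repeated unit of the trunk."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        self.conv = Conv1d(c_in, c_out, kernel, rng)
        self.bn = BatchNorm1d(c_out)
        self.relu = ReLU()

    def params(self):
        return self.conv.params() + self.bn.params()

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        return self.relu.forward(self.bn.forward(self.conv.forward(x), train))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return self.conv.backward(self.bn.backward(self.relu.backward(dout)))


def conv_block_forward(x: np.ndarray, block: ConvBlock, train: bool = False) -> np.ndarray:
    """Functional form of one convolution block: ReLU(BatchNorm(Conv(x)))."""
    return block.forward(x, train)


# ---------------------------------------------------------------------------
# The standalone bilinear pooling operation
# ---------------------------------------------------------------------------


def factorized_bilinear_pool(y: np.ndarray, U: np.ndarray, V: np.ndarray,
                             P: np.ndarray) -> np.ndarray:
    """Compute B = P^T (U^T y ∘ V^T y), the factorized bilinear feature.

    With ``o = 1`` and a unit ``P`` this equals the dense quadratic form
    y^T (U V^T) y, the low-rank factorization of the bilinear feature
    y^T W y.  Accepts a single vector (d,) or a batch (n, d).

    Parameters
    ----------
    y : (d,) or (n, d) input feature vector(s)
    U, V : (d, r) dictionary factors
    P : (r, o) output projection
    """
    y = np.asarray(y, dtype=float)
    U, V, P = (np.asarray(m, dtype=float) for m in (U, V, P))
    single = y.ndim == 1
    yb = y[None, :] if single else y
    d = yb.shape[1]
    if U.shape[0] != d or V.shape[0] != d:
        raise ShapeError(f"U/V first dimension must equal d={d}, got {U.shape}, {V.shape}")
    if U.shape[1] != V.shape[1] or P.shape[0] != U.shape[1]:
        raise ShapeError(f"rank mismatch: U {U.shape}, V {V.shape}, P {P.shape}")
    out = ((yb @ U) * (yb @ V)) @ P
    return out[0] if single else out


# ---------------------------------------------------------------------------
# The full network
# ---------------------------------------------------------------------------


class BMNet:
    """The full classifier; see the module docstring for the architecture."""

    def __init__(self, config: BMNetConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        c1, c2 = config.conv_channels
        self.block1 = ConvBlock(1, c1, config.conv_kernel, rng)
        self.block2 = ConvBlock(c1, c2, config.conv_kernel, rng)
        d = config.flat_dim
        if config.use_bp:
            self.interaction: BilinearPool | Linear = BilinearPool(
                d, config.bp_rank, config.bp_out, rng)
        else:
            # Baseline ablation: one FC layer of matched output size.
            self.interaction = Linear(d, config.bp_out, rng)
        self.pool = AvgPoolVec(config.avgpool_window)
        head_in = config.bp_out // config.avgpool_window
        self.fc_hidden: list[Linear] = []
        self.fc_relu: list[ReLU] = []
        for width in config.fc_dims:
            self.fc_hidden.append(Linear(head_in, width, rng))
            self.fc_relu.append(ReLU())
            head_in = width
        self.fc_embed = Linear(head_in, config.embedding_dim, rng)
        self.embed_relu = ReLU()
        self.fc_out = Linear(config.embedding_dim, 1, rng)

    # -- parameter plumbing -------------------------------------------------

    def _layers_with_params(self):
        layers = [("block1", self.block1), ("block2", self.block2),
                  ("interaction", self.interaction)]
        layers += [(f"fc_hidden{i}", l) for i, l in enumerate(self.fc_hidden)]
        layers += [("fc_embed", self.fc_embed), ("fc_out", self.fc_out)]
        return layers

    def named_parameters(self):
        """Yield (name, value_array, grad_array) triples; arrays are live views."""
        for lname, layer in self._layers_with_params():
            for pname, value, grad in layer.params():
                yield f"{lname}.{pname}", value, grad

    def zero_grad(self) -> None:
        for _, _, grad in self.named_parameters():
            grad[...] = 0.0

    def state_arrays(self) -> dict[str, np.ndarray]:
        """All arrays needed to restore the model: parameters + BN running stats."""
        out = {name: value for name, value, _ in self.named_parameters()}
        for bname, block in (("block1", self.block1), ("block2", self.block2)):
            out[f"{bname}.bn.running_mean"] = block.bn.running_mean
            out[f"{bname}.bn.running_var"] = block.bn.running_var
        return out

    # -- forward / backward -------------------------------------------------

    def forward(self, features: np.ndarray, train: bool = False) -> ForwardOutput:
        """Run the network on a batch (n, n_regions) or one vector (n_regions,)."""
        x = np.asarray(features, dtype=float)
        single = x.ndim == 1
        if single:
            x = x[None, :]
        if x.shape[1] != self.config.n_regions:
            raise ShapeError(
                f"expected {self.config.n_regions} regions, got {x.shape[1]}")
        h = x[:, None, :]  # (n, 1, R): one channel per subject
        h = self.block1.forward(h, train)
        h = self.block2.forward(h, train)
        n = h.shape[0]
        flat = h.reshape(n, -1)
        z = self.interaction.forward(flat)
        pooled = self.pool.forward(z)
        h = pooled
        for lin, relu in zip(self.fc_hidden, self.fc_relu):
            h = relu.forward(lin.forward(h))
        emb = self.embed_relu.forward(self.fc_embed.forward(h))
        logit = self.fc_out.forward(emb)[:, 0]
        if not np.all(np.isfinite(logit)):
            raise NumericError("non-finite activations in forward pass")
        prob = expit(logit)
        if single:
            return ForwardOutput(emb[0], logit[0], prob[0])
        return ForwardOutput(emb, logit, prob)

    def backward(self, dlogit: np.ndarray, dembedding: np.ndarray | None = None) -> None:
        """Accumulate parameter gradients.

        ``dlogit`` is dL/dlogit (n,); ``dembedding`` (n, embedding_dim) is an
        extra gradient injected at the embedding node (the metric-loss path).
        """
        demb = self.fc_out.backward(np.asarray(dlogit, dtype=float)[:, None])
        if dembedding is not None:
            demb = demb + dembedding
        dh = self.fc_embed.backward(self.embed_relu.backward(demb))
        for lin, relu in zip(reversed(self.fc_hidden), reversed(self.fc_relu)):
            dh = lin.backward(relu.backward(dh))
        dz = self.pool.backward(dh)
        dflat = self.interaction.backward(dz)
        n = dflat.shape[0]
        dconv = dflat.reshape(n, self.config.conv_channels[1], self.config.n_regions)
        dconv = self.block2.backward(dconv)
        self.block1.backward(dconv)


def count_parameters(model: BMNet) -> int:
    """Total number of learnable scalars (BN running stats excluded)."""
    return sum(int(v.size) for _, v, _ in model.named_parameters())


# ---------------------------------------------------------------------------
# Checkpoints: one versioned file holding config + parameters
# ---------------------------------------------------------------------------


def save_checkpoint(model: BMNet, path) -> None:
    arrays = model.state_arrays()
    meta = json.dumps({"version": CHECKPOINT_VERSION, "config": model.config.to_dict()})
    np.savez(path, __meta__=np.array(meta), **arrays)


def load_checkpoint(path) -> BMNet:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        if meta.get("version") != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version: {meta.get('version')}")
        model = BMNet(BMNetConfig.from_dict(meta["config"]))
        arrays = model.state_arrays()
        for name, target in arrays.items():
            target[...] = data[name]
    return model
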