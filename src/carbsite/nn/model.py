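"""The two-branch residual-convolution + dense network for per-residue
binding prediction.

One branch (convolutional) reads the 31-long window of residue-alphabet
indices: a trainable 21-dimensional embedding, then three residual blocks.
Each block applies two conv1d layers (kernel 3, padding 1, stride 1, 10
filters, batch-norm + ReLU after each) and *concatenates* the block input
with the second conv's output along the channel axis instead of adding them,
so channels grow by 10 per block (21 → 31 → 41 → 51) while kernel-2 max
pooling halves the temporal length (31 → 15 → 7 → 3).  The flattened
51×3 = 153 tensor maps to a 32-wide summary.

The dense branch reads the 2340-wide per-residue feature vector
(1024 ProtT5 ‖ 36 structural ‖ 1280 ESM-2) through 2340→512→256 linear
layers, each followed by batch normalization, dropout and ReLU.  The two
branch outputs concatenate to 288 and pass through a final hidden linear
layer and a 1-unit sigmoid output.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .layers import (
    BatchNorm1d, Conv1d, Dropout, Embedding, Layer, Linear, MaxPool1d, Param,
    ReLU, sigmoid,
)


@dataclass(frozen=True)
class NetConfig:
    """Architecture constants; defaults reproduce the published configuration."""

    window_len: int = 31
    alphabet_size: int = 21
    embed_dim: int = 21
    conv_filters: int = 10
    conv_kernel: int = 3
    conv_padding: int = 1
    conv_stride: int = 1
    conv_dilation: int = 1
    pool_kernel: int = 2
    n_blocks: int = 3
    resnet_out: int = 32
    fnn_in: int = 2340
    fnn_hidden1: int = 512
    fnn_hidden2: int = 256
    head_hidden: int = 128
    dropout: float = 0.5

    def __post_init__(self) -> None:
        for name, v in asdict(self).items():
            if name != "dropout" and v <= 0:
                raise ValueError(f"config field {name} must be positive")
        if self.conv_stride != 1 or self.conv_dilation != 1:
            raise ValueError("only stride 1 / dilation 1 convolutions are supported")

    def resnet_flat_width(self) -> int:
        """Flattened width after the last block+pool (channels × positions)."""
        channels, t = self.embed_dim, self.window_len
        for _ in range(self.n_blocks):
            channels += self.conv_filters
            t //= self.pool_kernel
        return channels * t


class ResidualBlock(Layer):
    """conv→BN→ReLU ×2, then channel-concatenation of input and output."""

    def __init__(self, in_channels: int, cfg: NetConfig, rng: np.random.Generator):
        f = cfg.conv_filters
        self.conv1 = Conv1d(in_channels, f, cfg.conv_kernel, cfg.conv_padding, rng)
        self.bn1 = BatchNorm1d(f)
        self.conv2 = Conv1d(f, f, cfg.conv_kernel, cfg.conv_padding, rng)
        self.bn2 = BatchNorm1d(f)
        self.relu1, self.relu2 = ReLU(), ReLU()
        self.in_channels = in_channels

    def params(self):
        return (self.conv1.params() + self.bn1.params()
                + self.conv2.params() + self.bn2.params())

    def forward(self, x, training=False):
        h = self.relu1.forward(self.bn1.forward(self.conv1.forward(x, training),
                                                training), training)
        h = self.relu2.forward(self.bn2.forward(self.conv2.forward(h, training),
                                                training), training)
        return np.concatenate([x, h], axis=1)

    def backward(self, grad):
        dx_skip = grad[:, : self.in_channels]
        dh = grad[:, self.in_channels:]
        dh = self.conv1.backward(
            self.bn1.backward(
                self.relu1.backward(
                    self.conv2.backward(
                        self.bn2.backward(self.relu2.backward(dh))
                    )
                )
            )
        )
        return dx_skip + dh


class ResNetFNN:
    """The full two-branch network.  ``seed`` fixes initialization and dropout."""

    def __init__(self, config: NetConfig | None = None, seed: int = 0):
        self.config = cfg = config or NetConfig()
        rng = np.random.default_rng(seed)

        self.embedding = Embedding(cfg.alphabet_size, cfg.embed_dim, rng)
        self.blocks: list[ResidualBlock] = []
        self.pools: list[MaxPool1d] = []
        channels = cfg.embed_dim
        for _ in range(cfg.n_blocks):
            self.blocks.append(ResidualBlock(channels, cfg, rng))
            self.pools.append(MaxPool1d(cfg.pool_kernel))
            channels += cfg.conv_filters
        self.resnet_linear = Linear(cfg.resnet_flat_width(), cfg.resnet_out, rng)

        self.fnn1 = Linear(cfg.fnn_in, cfg.fnn_hidden1, rng)
        self.fnn_bn1 = BatchNorm1d(cfg.fnn_hidden1)
        self.fnn_drop1 = Dropout(cfg.dropout, rng)
        self.fnn_relu1 = ReLU()
        self.fnn2 = Linear(cfg.fnn_hidden1, cfg.fnn_hidden2, rng)
        self.fnn_bn2 = BatchNorm1d(cfg.fnn_hidden2)
        self.fnn_drop2 = Dropout(cfg.dropout, rng)
        self.fnn_relu2 = ReLU()

        fused = cfg.resnet_out + cfg.fnn_hidden2
        self.head1 = Linear(fused, cfg.head_hidden, rng)
        self.head_bn = BatchNorm1d(cfg.head_hidden)
        self.head_drop = Dropout(cfg.dropout, rng)
        self.head_relu = ReLU()
        self.head2 = Linear(cfg.head_hidden, 1, rng)

    # ------------------------------------------------------------------
    def params(self) -> list[Param]:
        out = self.embedding.params()
        for block in self.blocks:
            out += block.params()
        out += self.resnet_linear.params()
        for layer in (self.fnn1, self.fnn_bn1, self.fnn2, self.fnn_bn2,
                      self.head1, self.head_bn, self.head2):
            out += layer.params()
        return out

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    def zero_grad(self) -> None:
        for p in self.params():
            p.zero_grad()

    # ------------------------------------------------------------------
    def resnet_branch_forward(
        self, windows: np.ndarray, training: bool = False,
        trace: dict | None = None,
    ) -> np.ndarray:
        windows = np.asarray(windows)
        if windows.ndim != 2 or windows.shape[1] != self.config.window_len:
            raise ValueError(
                f"windows must be B×{self.config.window_len}, got {windows.shape}"
            )
        h = self.embedding.forward(windows, training)        # B×31×21
        if trace is not None:
            trace["embedded"] = h.shape
        h = np.transpose(h, (0, 2, 1))                       # B×21×31
        if trace is not None:
            trace["permuted"] = h.shape
        for k, (block, pool) in enumerate(zip(self.blocks, self.pools), 1):
            h = block.forward(h, training)
            if trace is not None:
                trace[f"block{k}"] = h.shape
            h = pool.forward(h, training)
            if trace is not None:
                trace[f"pool{k}"] = h.shape
        self._resnet_pre_flat_shape = h.shape
        h = h.reshape(h.shape[0], -1)
        out = self.resnet_linear.forward(h, training)
        if trace is not None:
            trace["resnet_out"] = out.shape
        return out

    def _resnet_branch_backward(self, grad: np.ndarray) -> None:
        grad = self.resnet_linear.backward(grad)
        grad = grad.reshape(self._resnet_pre_flat_shape)
        for block, pool in zip(reversed(self.blocks), reversed(self.pools)):
            grad = block.backward(pool.backward(grad))
        self.embedding.backward(np.transpose(grad, (0, 2, 1)))

    def fnn_branch_forward(
        self, features: np.ndarray, training: bool = False
    ) -> np.ndarray:
        features = np.asarray(features, dtype=float)
        if features.ndim != 2 or features.shape[1] != self.config.fnn_in:
            raise ValueError(
                f"features must be B×{self.config.fnn_in}, got {features.shape}"
            )
        h = self.fnn_relu1.forward(
            self.fnn_drop1.forward(
                self.fnn_bn1.forward(self.fnn1.forward(features, training), training),
                training,
            ),
            training,
        )
        return self.fnn_relu2.forward(
            self.fnn_drop2.forward(
                self.fnn_bn2.forward(self.fnn2.forward(h, training), training),
                training,
            ),
            training,
        )

    def _fnn_branch_backward(self, grad: np.ndarray) -> None:
        grad = self.fnn2.backward(
            self.fnn_bn2.backward(
                self.fnn_drop2.backward(self.fnn_relu2.backward(grad))
            )
        )
        self.fnn1.backward(
            self.fnn_bn1.backward(
                self.fnn_drop1.backward(self.fnn_relu1.backward(grad))
            )
        )

    def forward(
        self, windows: np.ndarray, features: np.ndarray, training: bool = False,
        trace: dict | None = None,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Returns (probabilities, logits), each of shape (B,)."""
        if len(windows) != len(features):
            raise ValueError(
                f"batch mismatch: {len(windows)} windows vs {len(features)} features"
            )
        a = self.resnet_branch_forward(windows, training, trace)
        b = self.fnn_branch_forward(features, training)
        fused = np.concatenate([a, b], axis=1)
        if trace is not None:
            trace["fused"] = fused.shape
        h = self.head_relu.forward(
            self.head_drop.forward(
                self.head_bn.forward(self.head1.forward(fused, training), training),
                training,
            ),
            training,
        )
        logits = self.head2.forward(h, training)[:, 0]
        return sigmoid(logits), logits

    def backward(self, dlogits: np.ndarray) -> None:
        grad = self.head2.backward(dlogits[:, None])
        grad = self.head1.backward(
            self.head_bn.backward(
                self.head_drop.backward(self.head_relu.backward(grad))
            )
        )
        split = self.config.resnet_out
        self._resnet_branch_backward(grad[:, :split])
        self._fnn_branch_backward(grad[:, split:])

    def predict(self, windows: np.ndarray, features: np.ndarray,
                batch_size: int = 4096) -> np.ndarray:
        """Eval-mode probabilities (deterministic: dropout off, running BN)."""
        out = []
        for k in range(0, len(windows), batch_size):
            probs, _ = self.forward(windows[k:k + batch_size],
                                    features[k:k + batch_size], training=False)
            out.append(probs)
        return np.concatenate(out) if out else np.empty(0)

    def shape_trace(self, windows: np.ndarray, features: np.ndarray) -> dict:
        """Record the tensor shape at every stage of an eval-mode forward."""
        trace: dict = {}
        self.forward(windows, features, training=False, trace=trace)
        return trace

    # ------------------------------------------------------------------
    def state_dict(self) -> dict:
        state = {f"param_{i}": p.value for i, p in enumerate(self.params())}
        bns = [self.fnn_bn1, self.fnn_bn2, self.head_bn] + [
            bn for blk in self.blocks for bn in (blk.bn1, blk.bn2)
        ]
        for i, bn in enumerate(bns):
            state[f"bn_{i}_mean"] = bn.running_mean
            state[f"bn_{i}_var"] = bn.running_var
        return state

    def load_state_dict(self, state: dict) -> None:
        for i, p in enumerate(self.params()):
            value = np.asarray(state[f"param_{i}"])
            if value.shape != p.value.shape:
                raise ValueError(
                    f"checkpoint shape {value.shape} != model {p.value.shape}"
                )
            p.value[...] = value
        bns = [self.fnn_bn1, self.fnn_bn2, self.head_bn] + [
            bn for blk in self.blocks for bn in (blk.bn1, blk.bn2)
        ]
        for i, bn in enumerate(bns):
            bn.running_mean = np.asarray(state[f"bn_{i}_mean"]).copy()
            bn.running_var = np.asarray(state[f"bn_{i}_var"]).copy()

    def save(self, path) -> None:
        import json

        cfg = json.dumps(asdict(self.config))
        np.savez(path, __config__=np.frombuffer(cfg.encode(), dtype=np.uint8),
                 **self.state_dict())

    @classmethod
    def load(cls, path) -> "ResNetFNN":
        import json

        with np.load(path, allow_pickle=False) as data:
            cfg = NetConfig(**json.loads(bytes(data["__config__"]).decode()))
            net = cls(cfg)
            net.load_state_dict({k: data[k] for k in data.files if k != "__config__"})
        return net
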