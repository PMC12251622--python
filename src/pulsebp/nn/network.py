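"""The two-branch network: residual Conv1D stack over the selected features,
bidirectional LSTM stack over the 80-sample cycle waveform, concatenation,
and a linear two-output head ([SBP, DBP]).
"""

from __future__ import annotations

import numpy as np

from .layers import (
    Adam,
    BatchNorm,
    BiLSTM,
    Conv1D,
    Dense,
    GlobalAvgPool1D,
    Layer,
    Param,
    ReLU,
)


class ResBlock(Layer):
    """Conv1D(64, k=3, s=1) -> BatchNorm, plus a shortcut, then ReLU.

    The shortcut is the identity when channel counts match and a 1x1
    projection convolution otherwise.  With zero conv weights and an
    identity-compatible shortcut the block reduces to ReLU(x), i.e. the
    identity map on non-negative inputs.
    """

    def __init__(self, c_in, c_out, kernel_size, rng, dtype=np.float32, name="res"):
        self.conv = Conv1D(c_in, c_out, kernel_size, rng, dtype, name=f"{name}.conv")
        self.bn = BatchNorm(c_out, dtype=dtype, name=f"{name}.bn")
        self.proj = (
            None if c_in == c_out else Conv1D(c_in, c_out, 1, rng, dtype, name=f"{name}.proj")
        )
        self.relu = ReLU()

    def params(self):
        p = self.conv.params() + self.bn.params()
        if self.proj is not None:
            p += self.proj.params()
        return p

    def forward(self, x, training=False):
        h = self.bn.forward(self.conv.forward(x, training), training)
        s = x if self.proj is None else self.proj.forward(x, training)
        return self.relu.forward(h + s, training)

    def backward(self, dout):
        d = self.relu.backward(dout)
        dh = self.bn.backward(d)
        dx = self.conv.backward(dh)
        if self.proj is None:
            dx = dx + d
        else:
            dx = dx + self.proj.backward(d)
        return dx


class TwoBranchNet:
    """Feature branch (dense front + residual conv stack + global average
    pooling) and waveform branch (two BiLSTM layers + batch norm), fused by
    concatenation into a linear head.
    """

    def __init__(
        self,
        n_features: int = 60,
        seq_len: int = 80,
        resnet_blocks: int = 2,
        conv_filters: int = 64,
        kernel_size: int = 3,
        lstm_units: int = 100,
        lstm_layers: int = 2,
        dense_front: int = 64,
        seed: int = 0,
        dtype=np.float32,
    ):
        rng = np.random.default_rng(seed)
        self.dtype = dtype
        self.n_features = n_features
        self.seq_len = seq_len

        # feature branch
        self.front = Dense(n_features, dense_front, rng, dtype, name="front")
        self.front_bn = BatchNorm(dense_front, dtype=dtype, name="front_bn")
        self.blocks = []
        c_in = 1  # the dense output is treated as a 1-channel sequence
        for i in range(resnet_blocks):
            self.blocks.append(
                ResBlock(c_in, conv_filters, kernel_size, rng, dtype, name=f"res{i + 1}")
            )
            c_in = conv_filters
        self.gap = GlobalAvgPool1D()

        # waveform branch
        self.lstms = []
        n_in = 1
        for i in range(lstm_layers):
            last = i == lstm_layers - 1
            self.lstms.append(
                BiLSTM(n_in, lstm_units, rng, return_sequences=not last, dtype=dtype,
                       name=f"bilstm{i + 1}")
            )
            n_in = 2 * lstm_units
        self.seq_bn = BatchNorm(2 * lstm_units, dtype=dtype, name="seq_bn")

        self.head = Dense(conv_filters + 2 * lstm_units, 2, rng, dtype, name="head")

    # ------------------------------------------------------------------
    def params(self) -> list[Param]:
        p = self.front.params() + self.front_bn.params()
        for b in self.blocks:
            p += b.params()
        for l in self.lstms:
            p += l.params()
        p += self.seq_bn.params() + self.head.params()
        return p

    @property
    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params()))

    # ------------------------------------------------------------------
    def forward(self, feats: np.ndarray, seqs: np.ndarray, training: bool = False) -> np.ndarray:
        feats = feats.astype(self.dtype, copy=False)
        seqs = seqs.astype(self.dtype, copy=False)

        f = self.front_bn.forward(self.front.forward(feats, training), training)
        f = f[:, None, :]  # (B, 1, dense_front) as a 1-channel sequence
        for b in self.blocks:
            f = b.forward(f, training)
        f = self.gap.forward(f, training)

        s = seqs[:, :, None]  # (B, T, 1)
        for l in self.lstms:
            s = l.forward(s, training)
        s = self.seq_bn.forward(s, training)

        self._split = f.shape[1]
        z = np.concatenate([f, s], axis=1)
        return self.head.forward(z, training)

    def backward(self, dout: np.ndarray) -> None:
        dz = self.head.backward(dout.astype(self.dtype, copy=False))
        k = self._split
        df, ds = dz[:, :k], dz[:, k:]

        ds = self.seq_bn.backward(ds)
        for l in reversed(self.lstms):
            ds = l.backward(ds)

        df = self.gap.backward(df)
        for b in reversed(self.blocks):
            df = b.backward(df)
        df = self.front_bn.backward(df[:, 0, :])
        self.front.backward(df)

    # ------------------------------------------------------------------
    def get_weights(self) -> list[np.ndarray]:
        ws = [p.value.copy() for p in self.params()]
        for bn in self._batchnorms():
            ws.append(bn.running_mean.copy())
            ws.append(bn.running_var.copy())
        return ws

    def set_weights(self, ws: list[np.ndarray]) -> None:
        params = self.params()
        for p, w in zip(params, ws[: len(params)]):
            p.value[...] = w
        rest = ws[len(params) :]
        for i, bn in enumerate(self._batchnorms()):
            bn.running_mean[...] = rest[2 * i]
            bn.running_var[...] = rest[2 * i + 1]

    def _batchnorms(self):
        bns = [self.front_bn]
        for b in self.blocks:
            bns.append(b.bn)
        bns.append(self.seq_bn)
        return bns
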