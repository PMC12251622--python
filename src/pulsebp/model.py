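"""The two-branch ResNet-BiLSTM regressor and its training protocol.

The estimator follows the scikit-learn idiom: the design matrix ``X`` holds
the 60 selected features and the 80-sample cycle waveform side by side
(``n_features + seq_len`` columns), ``y`` is ``(n, 2)`` mmHg ``[SBP, DBP]``.
Training minimizes the joint mean squared error with Adam (initial learning
rate 0.001) for up to 150 epochs with early stopping on a held-out
validation fraction of the training data, restoring the best weights.
Features and targets are standardized internally; predictions are returned
in mmHg.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .nn import Adam, TwoBranchNet


@dataclass
class ModelConfig:
    """Architecture hyperparameters (defaults mirror the published model)."""

    n_features: int = 60
    seq_len: int = 80
    resnet_blocks: int = 2
    conv_filters: int = 64
    kernel_size: int = 3
    stride: int = 1
    lstm_units: int = 100
    lstm_layers: int = 2
    dense_front: int = 64
    seed: int = 0


@dataclass
class TrainConfig:
    """Optimization protocol."""

    lr: float = 0.001
    max_epochs: int = 150
    batch_size: int = 64
    patience: int = 10
    val_frac: float = 0.15
    scale_targets: bool = True
    seed: int = 0


def build_two_branch(cfg: ModelConfig | None = None) -> TwoBranchNet:
    """Instantiate the two-branch network from an architecture config."""
    cfg = cfg or ModelConfig()
    if cfg.stride != 1:
        raise ValueError("only stride 1 is supported")
    return TwoBranchNet(
        n_features=cfg.n_features,
        seq_len=cfg.seq_len,
        resnet_blocks=cfg.resnet_blocks,
        conv_filters=cfg.conv_filters,
        kernel_size=cfg.kernel_size,
        lstm_units=cfg.lstm_units,
        lstm_layers=cfg.lstm_layers,
        dense_front=cfg.dense_front,
        seed=cfg.seed,
    )


def count_parameters(cfg: ModelConfig | None = None) -> int:
    """Trainable parameter count of the architecture."""
    return build_two_branch(cfg).n_parameters


class ResNetBiLSTMRegressor(RegressorMixin, BaseEstimator):
    """Two-branch regressor mapping (features, cycle waveform) -> (SBP, DBP).

    Parameters
    ----------
    n_features, seq_len : input split of the design matrix columns.
    resnet_blocks, conv_filters, kernel_size, lstm_units, lstm_layers,
    dense_front : architecture; defaults are the published configuration
        (2 residual blocks of 64 filters, kernel 3, stride 1; two BiLSTM
        layers of 100 cells).
    lr, max_epochs, batch_size, patience, val_frac : training protocol
        (MSE loss, Adam at 0.001, up to 150 epochs, early stopping with
        best-weight restore on a 15% validation split of the training data).
    random_state : seeds weight initialization, shuffling and the split.

    Attributes
    ----------
    net_ : the underlying network
    history_ : dict with per-epoch train/validation loss
    n_parameters_ : trainable parameter count
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
        lr: float = 0.001,
        max_epochs: int = 150,
        batch_size: int = 64,
        patience: int = 10,
        val_frac: float = 0.15,
        scale_targets: bool = True,
        random_state: int = 0,
        verbose: int = 0,
    ):
        self.n_features = n_features
        self.seq_len = seq_len
        self.resnet_blocks = resnet_blocks
        self.conv_filters = conv_filters
        self.kernel_size = kernel_size
        self.lstm_units = lstm_units
        self.lstm_layers = lstm_layers
        self.dense_front = dense_front
        self.lr = lr
        self.max_epochs = max_epochs
        self.batch_size = batch_size
        self.patience = patience
        self.val_frac = val_frac
        self.scale_targets = scale_targets
        self.random_state = random_state
        self.verbose = verbose

    # ------------------------------------------------------------------
    def _split_columns(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        expect = self.n_features + self.seq_len
        if X.shape[1] != expect:
            raise ValueError(
                f"X must have n_features + seq_len = {expect} columns, got {X.shape[1]}"
            )
        return X[:, : self.n_features], X[:, self.n_features :]

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if y.ndim == 1:
            y = y[:, None]
        if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
            raise ValueError("X and y must be finite (impute upstream)")
        F, S = self._split_columns(X)
        n = X.shape[0]
        if n < 2:
            raise ValueError("need at least 2 training rows")

        rng = np.random.default_rng(self.random_state)

        self._f_mean = F.mean(axis=0)
        f_sd = F.std(axis=0)
        self._f_sd = np.where(f_sd > 0, f_sd, 1.0)
        Fs = (F - self._f_mean) / self._f_sd

        if self.scale_targets:
            self._y_mean = y.mean(axis=0)
            y_sd = y.std(axis=0)
            self._y_sd = np.where(y_sd > 0, y_sd, 1.0)
        else:
            self._y_mean = np.zeros(y.shape[1])
            self._y_sd = np.ones(y.shape[1])
        ys = (y - self._y_mean) / self._y_sd

        cfg = ModelConfig(
            n_features=self.n_features,
            seq_len=self.seq_len,
            resnet_blocks=self.resnet_blocks,
            conv_filters=self.conv_filters,
            kernel_size=self.kernel_size,
            lstm_units=self.lstm_units,
            lstm_layers=self.lstm_layers,
            dense_front=self.dense_front,
            seed=self.random_state,
        )
        self.net_ = build_two_branch(cfg)
        self.n_parameters_ = self.net_.n_parameters

        # validation split for early stopping
        order = rng.permutation(n)
        n_val = int(round(self.val_frac * n)) if n >= 10 else 0
        val_idx, tr_idx = order[:n_val], order[n_val:]
        opt = Adam(self.net_.params(), lr=self.lr)

        history = {"train_loss": [], "val_loss": []}
        best_val = np.inf
        best_weights = self.net_.get_weights()
        best_epoch = 0
        wait = 0

        for epoch in range(1, self.max_epochs + 1):
            perm = rng.permutation(tr_idx.size)
            idx = tr_idx[perm]
            losses = []
            for b0 in range(0, idx.size, self.batch_size):
                bi = idx[b0 : b0 + self.batch_size]
                pred = self.net_.forward(Fs[bi], S[bi], training=True)
                err = pred - ys[bi]
                loss = float(np.mean(err**2))
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite training loss at epoch {epoch}; "
                        "check input scaling and learning rate"
                    )
                losses.append(loss)
                opt.zero_grad()
                self.net_.backward(2.0 * err / err.size)
                opt.step()
            train_loss = float(np.mean(losses))
            if n_val > 0:
                val_pred = self.net_.forward(Fs[val_idx], S[val_idx], training=False)
                val_loss = float(np.mean((val_pred - ys[val_idx]) ** 2))
            else:
                val_loss = train_loss
            history["train_loss"].append(train_loss)
            history["val_loss"].append(val_loss)
            if self.verbose:
                print(f"epoch {epoch:3d}  train {train_loss:.5f}  val {val_loss:.5f}")
            if val_loss < best_val - 1e-7:
                best_val = val_loss
                best_weights = self.net_.get_weights()
                best_epoch = epoch
                wait = 0
            else:
                wait += 1
                if wait >= self.patience:
                    break

        self.net_.set_weights(best_weights)
        self.history_ = history
        self.best_epoch_ = best_epoch
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "net_")
        X = np.asarray(X, dtype=float)
        F, S = self._split_columns(X)
        Fs = (F - self._f_mean) / self._f_sd
        out = np.empty((X.shape[0], 2))
        # bounded batches keep the LSTM working set small
        for b0 in range(0, X.shape[0], 512):
            sl = slice(b0, b0 + 512)
            out[sl] = self.net_.forward(Fs[sl], S[sl], training=False)
        return out * self._y_sd + self._y_mean

    # ------------------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Persist weights (npz) and config (json sidecar)."""
        check_is_fitted(self, "net_")
        path = Path(path)
        ws = self.net_.get_weights()
        np.savez_compressed(
            path.with_suffix(".npz"),
            *ws,
            f_mean=self._f_mean,
            f_sd=self._f_sd,
            y_mean=self._y_mean,
            y_sd=self._y_sd,
        )
        meta = {"params": self.get_params(), "n_weight_arrays": len(ws)}
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "ResNetBiLSTMRegressor":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        est = cls(**meta["params"])
        data = np.load(path.with_suffix(".npz"))
        n_ws = meta["n_weight_arrays"]
        ws = [data[f"arr_{i}"] for i in range(n_ws)]
        est.net_ = build_two_branch(
            ModelConfig(
                n_features=est.n_features,
                seq_len=est.seq_len,
                resnet_blocks=est.resnet_blocks,
                conv_filters=est.conv_filters,
                kernel_size=est.kernel_size,
                lstm_units=est.lstm_units,
                lstm_layers=est.lstm_layers,
                dense_front=est.dense_front,
                seed=est.random_state,
            )
        )
        est.net_.set_weights(ws)
        est.n_parameters_ = est.net_.n_parameters
        est._f_mean = data["f_mean"]
        est._f_sd = data["f_sd"]
        est._y_mean = data["y_mean"]
        est._y_sd = data["y_sd"]
        est.n_features_in_ = est.n_features + est.seq_len
        est.history_ = {}
        return est
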