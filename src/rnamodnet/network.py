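"""Convolutional-recurrent attention network for modification-site scoring.

Architecture (default config, 41-nt one-hot input): valid 1-D convolution
with 256 filters of width 10 + ReLU (length 41-10+1 = 32), max pooling
(window 3, stride 3, remainder dropped -> length 10), bidirectional LSTM
with 128 units per direction, softmax attention pooling over the 10
positions, a 256-unit ReLU fully connected layer with dropout, and a single
sigmoid output giving the probability that the center nucleotide is
modified.

The whole stack — forward pass, backpropagation (including BPTT through the
BiLSTM), Adam, binary cross-entropy, early stopping on validation accuracy
with best-weight restoration — is implemented directly in NumPy; training
is deterministic for a given seed.

The printed recurrences this cell is sometimes described with contain a
sign error that would make the cell state non-functional; the standard LSTM
cell state C_p = F_p * C_{p-1} + I_p * tanh(W_C [x_p, H_{p-1}] + b_C) is
used.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np

from .encodings import one_hot
from .seqio import SequenceWindow

LAYER_NAMES = ("input", "conv", "blstm", "attention", "fc", "output")


@dataclass
class NetworkConfig:
    seq_len: int = 41
    conv_filters: int = 256
    kernel_size: int = 10
    pool_size: int = 3
    pool_stride: int = 3
    lstm_units: int = 128          # per direction
    fc_units: int = 256
    dropout: float = 0.3
    learning_rate: float = 1e-3
    batch_size: int = 64
    patience: int = 20
    max_epochs: int = 100
    seed: int = 0
    early_stop_metric: str = "accuracy"   # or "auc"

    def __post_init__(self):
        if self.kernel_size > self.seq_len:
            raise ValueError("kernel_size exceeds seq_len")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")

    @property
    def conv_len(self) -> int:
        return self.seq_len - self.kernel_size + 1

    @property
    def pooled_len(self) -> int:
        return self.conv_len // self.pool_stride

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "NetworkConfig":
        return cls(**json.loads(text))


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def encode_windows(windows) -> np.ndarray:
    """One-hot encode a sequence of windows/strings to (n, L, 4) float32."""
    if isinstance(windows, np.ndarray) and windows.ndim == 3:
        return windows.astype(np.float32)
    return np.stack([one_hot(w).values for w in windows]).astype(np.float32)


def window_labels(windows) -> np.ndarray:
    return np.array(
        [w.label if isinstance(w, SequenceWindow) else int(w) for w in windows]
    )


class Network:
    """The untrained/trained model object; parameters live in ``params``."""

    def __init__(self, config: NetworkConfig):
        self.config = config
        self.params: dict[str, np.ndarray] = {}
        self.training_log: list[dict] = []
        self.trained = False
        self.layer_names = LAYER_NAMES
        self._init_params(np.random.default_rng(config.seed))

    # -- initialization ----------------------------------------------------

    def _glorot(self, rng, shape):
        fan_in, fan_out = shape[0], shape[-1]
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-limit, limit, size=shape).astype(np.float32)

    def _init_params(self, rng):
        c = self.config
        H, F = c.lstm_units, c.conv_filters
        p = self.params
        p["Wc"] = self._glorot(rng, (c.kernel_size * 4, F))
        p["bc"] = np.zeros(F, dtype=np.float32)
        for d in ("f", "b"):  # forward / backward direction
            p[f"Wx_{d}"] = self._glorot(rng, (F, 4 * H))
            p[f"Wh_{d}"] = self._glorot(rng, (H, 4 * H))
            b = np.zeros(4 * H, dtype=np.float32)
            b[H : 2 * H] = 1.0  # forget-gate bias: remember by default
            p[f"b_{d}"] = b
        p["wa"] = self._glorot(rng, (2 * H, 1))[:, 0]
        p["ba"] = np.zeros(1, dtype=np.float32)
        p["Wf"] = self._glorot(rng, (2 * H, c.fc_units))
        p["bf"] = np.zeros(c.fc_units, dtype=np.float32)
        p["wo"] = self._glorot(rng, (c.fc_units, 1))[:, 0]
        p["bo"] = np.zeros(1, dtype=np.float32)

    # -- forward -----------------------------------------------------------

    def _im2col(self, X):
        c = self.config
        B = X.shape[0]
        win = np.lib.stride_tricks.sliding_window_view(X, c.kernel_size, axis=1)
        # win: (B, conv_len, 4, kernel); reorder to (B, conv_len, kernel*4)
        return np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(
            B, c.conv_len, c.kernel_size * 4
        )

    def _lstm_direction(self, P, d: str):
        """Run one LSTM direction over P (B, T, F); returns hidden states in
        input order plus the per-step cache for BPTT."""
        c = self.config
        H = c.lstm_units
        B, T, _ = P.shape
        Wx, Wh, b = self.params[f"Wx_{d}"], self.params[f"Wh_{d}"], self.params[f"b_{d}"]
        order = range(T) if d == "f" else range(T - 1, -1, -1)
        dt = np.result_type(P.dtype, Wx.dtype)
        h = np.zeros((B, H), dtype=dt)
        cstate = np.zeros((B, H), dtype=dt)
        Hs = np.zeros((B, T, H), dtype=dt)
        cache = {}
        for t in order:
            a = P[:, t, :] @ Wx + h @ Wh + b
            i = _sigmoid(a[:, :H])
            f = _sigmoid(a[:, H : 2 * H])
            g = np.tanh(a[:, 2 * H : 3 * H])
            o = _sigmoid(a[:, 3 * H :])
            c_prev, h_prev = cstate, h
            cstate = f * c_prev + i * g
            tc = np.tanh(cstate)
            h = o * tc
            Hs[:, t, :] = h
            cache[t] = (i, f, g, o, c_prev, h_prev, tc)
        return Hs, cache

    def forward(self, X, train: bool = False, rng=None):
        """Full forward pass; returns (scores, cache)."""
        c = self.config
        p = self.params
        Xc = self._im2col(X)                              # (B, N, k4)
        Z1 = Xc @ p["Wc"] + p["bc"]
        A1 = np.maximum(Z1, 0.0)                          # conv + ReLU
        T = c.pooled_len
        s = c.pool_stride
        A1t = A1[:, : T * s, :].reshape(X.shape[0], T, s, -1)
        pool_arg = A1t.argmax(axis=2)
        P = np.take_along_axis(A1t, pool_arg[:, :, None, :], axis=2)[:, :, 0, :]
        Hf, cache_f = self._lstm_direction(P, "f")
        Hb, cache_b = self._lstm_direction(P, "b")
        Hcat = np.concatenate([Hf, Hb], axis=2)           # (B, T, 2H)
        scores_att = Hcat @ p["wa"] + p["ba"]             # (B, T)
        scores_att -= scores_att.max(axis=1, keepdims=True)
        alpha = np.exp(scores_att)
        alpha /= alpha.sum(axis=1, keepdims=True)
        A = np.einsum("bt,btd->bd", alpha, Hcat)          # (B, 2H)
        Zf = A @ p["Wf"] + p["bf"]
        F1 = np.maximum(Zf, 0.0)
        if train and c.dropout > 0:
            if rng is None:
                rng = np.random.default_rng(c.seed)
            mask = (rng.random(F1.shape) >= c.dropout) / (1.0 - c.dropout)
            F1d = F1 * mask
        else:
            mask = None
            F1d = F1
        z = F1d @ p["wo"] + p["bo"]
        y = _sigmoid(z.reshape(-1))
        cache = dict(X=X, Xc=Xc, Z1=Z1, A1=A1, pool_arg=pool_arg, P=P,
                     Hf=Hf, Hb=Hb, cache_f=cache_f, cache_b=cache_b,
                     Hcat=Hcat, alpha=alpha, A=A, Zf=Zf, F1=F1, mask=mask,
                     F1d=F1d, y=y)
        return y, cache

    # -- backward ----------------------------------------------------------

    def _lstm_backward(self, dH, P, cache, d: str):
        c = self.config
        H = c.lstm_units
        B, T, _ = P.shape
        Wx, Wh = self.params[f"Wx_{d}"], self.params[f"Wh_{d}"]
        dt = np.result_type(P.dtype, Wx.dtype)
        dWx = np.zeros(Wx.shape, dtype=dt)
        dWh = np.zeros(Wh.shape, dtype=dt)
        db = np.zeros(4 * H, dtype=dt)
        dP = np.zeros_like(P)
        dh_next = np.zeros((B, H), dtype=dt)
        dc_next = np.zeros((B, H), dtype=dt)
        order = range(T) if d == "f" else range(T - 1, -1, -1)
        for t in reversed(list(order)):
            i, f, g, o, c_prev, h_prev, tc = cache[t]
            dh = dH[:, t, :] + dh_next
            do = dh * tc
            dc = dh * o * (1.0 - tc * tc) + dc_next
            di, dg, df = dc * g, dc * i, dc * c_prev
            dc_next = dc * f
            da = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g * g),
                 do * o * (1 - o)], axis=1)
            dWx += P[:, t, :].T @ da
            dWh += h_prev.T @ da
            db += da.sum(axis=0)
            dh_next = da @ Wh.T
            dP[:, t, :] = da @ Wx.T
        return dWx, dWh, db, dP

    def backward(self, cache, targets):
        """Gradients of mean BCE w.r.t. every parameter."""
        c = self.config
        p = self.params
        B = cache["X"].shape[0]
        grads = {}
        dz = (cache["y"] - targets) / B                          # (B,)
        grads["wo"] = cache["F1d"].T @ dz
        grads["bo"] = np.array([dz.sum()])
        dF1d = np.outer(dz, p["wo"])
        dF1 = dF1d * cache["mask"] if cache["mask"] is not None else dF1d
        dZf = dF1 * (cache["Zf"] > 0)
        grads["Wf"] = cache["A"].T @ dZf
        grads["bf"] = dZf.sum(axis=0)
        dA = dZf @ p["Wf"].T                                     # (B, 2H)
        Hcat, alpha = cache["Hcat"], cache["alpha"]
        dalpha = np.einsum("bd,btd->bt", dA, Hcat)
        dH = alpha[:, :, None] * dA[:, None, :]
        ds = alpha * (dalpha - (alpha * dalpha).sum(axis=1, keepdims=True))
        grads["wa"] = np.einsum("bt,btd->d", ds, Hcat)
        grads["ba"] = np.array([ds.sum()])
        dH += ds[:, :, None] * p["wa"][None, None, :]
        H = c.lstm_units
        dWx_f, dWh_f, db_f, dP_f = self._lstm_backward(
            dH[:, :, :H], cache["P"], cache["cache_f"], "f")
        dWx_b, dWh_b, db_b, dP_b = self._lstm_backward(
            dH[:, :, H:], cache["P"], cache["cache_b"], "b")
        grads.update(Wx_f=dWx_f, Wh_f=dWh_f, b_f=db_f,
                     Wx_b=dWx_b, Wh_b=dWh_b, b_b=db_b)
        dP = dP_f + dP_b
        T, s = c.pooled_len, c.pool_stride
        dA1 = np.zeros_like(cache["A1"])
        dA1t = dA1[:, : T * s, :].reshape(B, T, s, -1)
        np.put_along_axis(dA1t, cache["pool_arg"][:, :, None, :],
                          dP[:, :, None, :], axis=2)
        dZ1 = dA1 * (cache["Z1"] > 0)
        grads["Wc"] = np.einsum("bnk,bnf->kf", cache["Xc"], dZ1)
        grads["bc"] = dZ1.sum(axis=(0, 1))
        return grads

    # -- prediction & embeddings ------------------------------------------

    def predict(self, windows, batch_size: int = 512) -> np.ndarray:
        """Scores in (0, 1), one per window, order preserved, deterministic."""
        X = encode_windows(windows)
        if X.shape[1] != self.config.seq_len:
            raise ValueError(
                f"window length {X.shape[1]} != configured seq_len "
                f"{self.config.seq_len}")
        out = []
        for i in range(0, X.shape[0], batch_size):
            y, _ = self.forward(X[i : i + batch_size], train=False)
            out.append(y)
        return np.concatenate(out).astype(float)

    def layer_embeddings(self, windows, layer_name: str,
                         batch_size: int = 512) -> np.ndarray:
        """Per-window embedding at a named stage (sequence-shaped stages
        are flattened)."""
        if layer_name not in LAYER_NAMES:
            raise KeyError(f"unknown layer {layer_name!r}; layers: {LAYER_NAMES}")
        X = encode_windows(windows)
        out = []
        for i in range(0, X.shape[0], batch_size):
            xb = X[i : i + batch_size]
            if layer_name == "input":
                out.append(xb.reshape(xb.shape[0], -1))
                continue
            y, cache = self.forward(xb, train=False)
            if layer_name == "conv":
                out.append(cache["P"].reshape(xb.shape[0], -1))
            elif layer_name == "blstm":
                out.append(cache["Hcat"].reshape(xb.shape[0], -1))
            elif layer_name == "attention":
                out.append(cache["A"])
            elif layer_name == "fc":
                out.append(cache["F1"])
            else:
                out.append(y[:, None])
        return np.concatenate(out).astype(float)

    def conv_activations(self, windows, batch_size: int = 512) -> np.ndarray:
        """Pre-pooling ReLU conv activations, shape (n, conv_len, filters)."""
        X = encode_windows(windows)
        out = []
        p = self.params
        for i in range(0, X.shape[0], batch_size):
            Xc = self._im2col(X[i : i + batch_size])
            out.append(np.maximum(Xc @ p["Wc"] + p["bc"], 0.0))
        return np.concatenate(out)

    # -- persistence -------------------------------------------------------

    def save(self, directory):
        import pathlib

        d = pathlib.Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        (d / "config.json").write_text(self.config.to_json())
        np.savez(d / "weights.npz", **self.params)
        (d / "training_log.json").write_text(json.dumps(self.training_log))

    @classmethod
    def load(cls, directory) -> "Network":
        import pathlib

        d = pathlib.Path(directory)
        net = cls(NetworkConfig.from_json((d / "config.json").read_text()))
        with np.load(d / "weights.npz") as z:
            net.params = {k: z[k] for k in z.files}
        log = d / "training_log.json"
        if log.exists():
            net.training_log = json.loads(log.read_text())
        net.trained = True
        return net


def build_network(config: NetworkConfig | None = None) -> Network:
    return Network(config or NetworkConfig())


class _Adam:
    def __init__(self, params, lr):
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params, grads):
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            params[k] -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(
                params[k].dtype)


def _bce(y, t):
    eps = 1e-7
    y = np.clip(y, eps, 1 - eps)
    return float(-np.mean(t * np.log(y) + (1 - t) * np.log(1 - y)))


def train(network: Network, train_windows, val_windows,
          train_labels=None, val_labels=None, verbose: bool = False) -> Network:
    """Train with Adam on binary cross-entropy; early stopping restores the
    best validation-metric weights after ``patience`` epochs without
    improvement.  Returns the same (now trained) network."""
    c = network.config
    Xtr = encode_windows(train_windows)
    ytr = window_labels(train_windows) if train_labels is None else np.asarray(train_labels)
    Xva = encode_windows(val_windows)
    yva = window_labels(val_windows) if val_labels is None else np.asarray(val_labels)
    if len(np.unique(ytr)) < 2:
        raise ValueError("training set contains a single class")
    rng = np.random.default_rng(c.seed)
    opt = _Adam(network.params, c.learning_rate)
    best_metric, best_params, best_epoch = -np.inf, None, -1
    n = Xtr.shape[0]
    for epoch in range(c.max_epochs):
        order = rng.permutation(n)
        losses = []
        for i in range(0, n, c.batch_size):
            idx = order[i : i + c.batch_size]
            y, cache = network.forward(Xtr[idx], train=True, rng=rng)
            losses.append(_bce(y, ytr[idx]))
            grads = network.backward(cache, ytr[idx].astype(np.float32))
            opt.step(network.params, grads)
        val_scores = network.predict(Xva)
        val_acc = float(np.mean((val_scores >= 0.5) == yva))
        if c.early_stop_metric == "auc":
            from sklearn.metrics import roc_auc_score

            metric = float(roc_auc_score(yva, val_scores))
        else:
            metric = val_acc
        network.training_log.append(
            dict(epoch=epoch, train_loss=float(np.mean(losses)),
                 val_loss=_bce(val_scores, yva), val_accuracy=val_acc,
                 val_metric=metric))
        if verbose:
            print(f"epoch {epoch}: loss {np.mean(losses):.4f} "
                  f"val_acc {val_acc:.4f}")
        if metric > best_metric:
            best_metric, best_epoch = metric, epoch
            best_params = {k: v.copy() for k, v in network.params.items()}
        elif epoch - best_epoch >= c.patience:
            break
    if best_params is not None:
        network.params = best_params
    network.trained = True
    network.best_epoch = best_epoch
    return network


def predict(trained: Network, windows) -> np.ndarray:
    return trained.predict(windows)


def layer_embeddings(trained: Network, windows, layer_name: str) -> np.ndarray:
    return trained.layer_embeddings(windows, layer_name)


DEFAULT_SEARCH_SPACE = {
    "kernel_size": [6, 8, 10, 12],
    "conv_filters": [32, 64, 128, 256],
    "batch_size": [32, 64, 128],
    "learning_rate": ("log", 1e-4, 3e-3),
    "dropout": (0.0, 0.5),
}


def tune_hyperparameters(search_space=None, budget: int = 10, data=None,
                         seed: int = 0, base_config: NetworkConfig | None = None,
                         val_fraction: float = 0.2, max_epochs: int | None = None):
    """Seeded random search over the five tunable hyperparameters (kernel
    size, filter count, batch size, learning rate, dropout), each trial
    scored by inner-validation AUC; returns (best_config, trials).

    ``data`` is (windows, labels).  ``trials`` is a list of dicts with the
    sampled values and the achieved AUC, best first in ``best_config``.
    """
    from sklearn.metrics import roc_auc_score
    from sklearn.model_selection import train_test_split

    space = dict(DEFAULT_SEARCH_SPACE if search_space is None else search_space)
    if not space:
        raise ValueError("empty search space")
    if budget < 1:
        raise ValueError("budget must be >= 1")
    windows, labels = data
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    base = base_config or NetworkConfig()
    if max_epochs is not None:
        base = replace(base, max_epochs=max_epochs)
    idx = np.arange(len(labels))
    tr, va = train_test_split(idx, test_size=val_fraction, stratify=labels,
                              random_state=seed)
    Wtr = [windows[i] for i in tr]
    Wva = [windows[i] for i in va]
    trials = []
    best = (-np.inf, None)
    for trial in range(budget):
        sample = {}
        for name, spec in space.items():
            if isinstance(spec, list):
                sample[name] = spec[rng.integers(len(spec))]
            elif isinstance(spec, tuple) and spec[0] == "log":
                lo, hi = np.log(spec[1]), np.log(spec[2])
                sample[name] = float(np.exp(rng.uniform(lo, hi)))
            else:
                sample[name] = float(rng.uniform(spec[0], spec[1]))
        cfg = replace(base, seed=int(rng.integers(2**31 - 1)), **sample)
        net = train(build_network(cfg), Wtr, Wva,
                    train_labels=labels[tr], val_labels=labels[va])
        auc = float(roc_auc_score(labels[va], net.predict(Wva)))
        trials.append(dict(trial=trial, auc=auc, **sample))
        if auc > best[0]:
            best = (auc, cfg)
    return best[1], trials
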