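"""Recurrent sequence classifiers with time span-guided attention.

Three architectures share one encoder/head contract and training loop:

* ``baseline`` — a bidirectional LSTM over the embedded item sequence; the
  concatenated final forward/backward hidden states feed the MLP head.
* ``attention`` — the standard attention mechanism on the item stream:
  u_t = tanh(h_t W + b), scalar weights alpha_t by softmax over time, and a
  context c = sum_t alpha_t h_t.
* ``tangle`` — a two-input network. The item sequence is embedded
  (x_t = w_t W_e) and encoded by a BiLSTM (H_x); the day-span sequence is
  encoded by a second BiLSTM (H_tau). Per-stream hidden projections
  u_x,t = tanh(h_x,t W_x + b_x) and u_tau,t = tanh(h_tau,t W_tau + b_tau)
  are mixed convexly, v_t = lambda u_x,t + (1 - lambda) u_tau,t, with the
  scalar lambda = sigmoid(lambda_raw) learned jointly. Attention weights
  alpha_t = softmax_t(v_t W_alpha) are per hidden unit (a 2H-vector per
  step, normalized over time independently for each unit), the attention
  contribution is omega_t = h_x,t (.) alpha_t, and the context vector
  c_bar = (1/2H) sum_j (Omega^T X)_j averages the 2H rows of Omega^T X.
  When lambda = 1 the span stream has no influence and the model reduces
  to a (per-unit) standard bidirectional attention model.

All heads are y_hat = sigmoid(relu(c W0 + b0) W1 + b1) trained with mean
binary cross-entropy; sequences are right-aligned and masked, and the
LSTMs gate their state updates with the mask so left-padding does not
affect the prediction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from . import _autograd as ag
from ._autograd import Tensor
from .claims_io import EncodedBatch

__all__ = [
    "ModelConfig",
    "AttentionTrace",
    "init_lstm_params",
    "embed_items",
    "bilstm_encode",
    "tangle_attention",
    "context_vector",
    "standard_attention",
    "predict_head",
    "bce_loss",
    "build_model",
    "train",
    "TangleModel",
    "AttentionModel",
    "BaselineModel",
]

EPS = 1e-7  # probability clip in the cross-entropy


@dataclass
class ModelConfig:
    E: int = 50
    H: int = 32
    U: int = 32
    D: Optional[int] = None  # head hidden width; defaults to E
    dropout: float = 0.5
    max_epochs: int = 100
    patience: int = 5
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0
    tau_transform: str = "raw"  # or "log1p"

    def __post_init__(self):
        if min(self.E, self.H, self.U) < 1:
            raise ValueError("E, H and U must be >= 1")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must lie in [0, 1)")
        if self.tau_transform not in ("raw", "log1p"):
            raise ValueError("tau_transform must be 'raw' or 'log1p'")
        if self.D is None:
            self.D = self.E


@dataclass
class AttentionTrace:
    """Per-sequence attention diagnostics from a fitted tangle model."""

    alpha: np.ndarray  # (T, 2H)
    omega: np.ndarray  # (T, 2H)
    lam: float
    context: np.ndarray  # (E,)
    mask: np.ndarray  # (T,)
    subject_id: str = ""
    label: Optional[int] = None


# ---------------------------------------------------------------------------
# parameter initialization
# ---------------------------------------------------------------------------

def _glorot(rng, shape):
    limit = np.sqrt(6.0 / (shape[0] + shape[-1]))
    return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)


def init_lstm_params(d: int, H: int, rng) -> dict:
    """One LSTM direction: fused gate weights (i, f, g, o) and forget bias 1."""
    b = np.zeros(4 * H)
    b[H:2 * H] = 1.0
    return {
        "W": _glorot(rng, (d, 4 * H)),
        "R": _glorot(rng, (H, 4 * H)),
        "b": Tensor(b, requires_grad=True),
    }


def init_bilstm_params(d: int, H: int, rng) -> dict:
    return {"fw": init_lstm_params(d, H, rng), "bw": init_lstm_params(d, H, rng)}


# ---------------------------------------------------------------------------
# graph-building blocks (Tensor in, Tensor out)
# ---------------------------------------------------------------------------

def _lstm_direction(x: Tensor, mask: np.ndarray, p: dict, H: int, reverse: bool):
    """Run one LSTM direction over (N, T, d) with per-step mask gating.

    Masked steps leave the hidden and cell state unchanged (and the state
    starts at zero), so fully padded prefixes contribute nothing.
    Returns hidden states in original time order, list of (N, H) Tensors.
    """
    N, T = mask.shape
    h = Tensor(np.zeros((N, H)))
    c = Tensor(np.zeros((N, H)))
    order = range(T - 1, -1, -1) if reverse else range(T)
    states: list[Optional[Tensor]] = [None] * T
    for t in order:
        xt = x[:, t, :]
        z = ag.matmul(xt, p["W"]) + ag.matmul(h, p["R"]) + p["b"]
        i = ag.sigmoid(z[:, :H])
        f = ag.sigmoid(z[:, H:2 * H])
        g = ag.tanh(z[:, 2 * H:3 * H])
        o = ag.sigmoid(z[:, 3 * H:])
        c_new = f * c + i * g
        h_new = o * ag.tanh(c_new)
        m = Tensor(mask[:, t:t + 1].astype(float))
        keep = Tensor(1.0 - mask[:, t:t + 1].astype(float))
        c = m * c_new + keep * c
        h = m * h_new + keep * h
        states[t] = h
    return states


def _bilstm(x: Tensor, mask: np.ndarray, params: dict, H: int) -> Tensor:
    fw = _lstm_direction(x, mask, params["fw"], H, reverse=False)
    bw = _lstm_direction(x, mask, params["bw"], H, reverse=True)
    steps = [ag.concat([f, b], axis=-1) for f, b in zip(fw, bw)]
    return ag.stack(steps, axis=1)  # (N, T, 2H)


def _tangle_attention_graph(Hx: Tensor, Htau: Tensor, mask: np.ndarray, p: dict):
    ux = ag.tanh(ag.matmul(Hx, p["W_x"]) + p["b_x"])
    utau = ag.tanh(ag.matmul(Htau, p["W_tau"]) + p["b_tau"])
    lam = ag.sigmoid(p["lam_raw"])
    v = lam * ux + (1.0 - lam) * utau
    logits = ag.matmul(v, p["W_alpha"])  # (N, T, 2H)
    alpha = ag.masked_softmax(logits, mask[:, :, None], axis=1)
    omega = Hx * alpha
    return alpha, omega, lam


def _context_graph(omega: Tensor, X: Tensor) -> Tensor:
    prod = ag.matmul(omega.swapaxes(-1, -2), X)  # (N, 2H, E)
    return prod.mean(axis=-2)


def _standard_attention_graph(H: Tensor, mask: np.ndarray, p: dict):
    u = ag.tanh(ag.matmul(H, p["W_t"]) + p["b"])
    scores = ag.matmul(u, p["w_alpha"].reshape(-1, 1))  # (N, T, 1)
    alpha = ag.masked_softmax(scores, mask[:, :, None], axis=1)
    c = (alpha * H).sum(axis=-2)
    return alpha, c


def _head_graph(c: Tensor, p: dict, dropout: float, training: bool, rng) -> Tensor:
    hidden = ag.relu(ag.matmul(c, p["W_0"]) + p["b_0"])
    if training and dropout > 0.0:
        hidden = ag.dropout(hidden, dropout, rng)
    logit = ag.matmul(hidden, p["W_1"]) + p["b_1"]
    out = ag.sigmoid(logit)
    return out.reshape(-1) if out.ndim > 1 else out


def _bce_graph(y: np.ndarray, p: Tensor) -> Tensor:
    p = ag.clip(p, EPS, 1.0 - EPS)
    yt = Tensor(np.asarray(y, dtype=float))
    return -(yt * ag.log(p) + (1.0 - yt) * ag.log(1.0 - p)).mean()


# ---------------------------------------------------------------------------
# functional surface (numpy in, numpy out)
# ---------------------------------------------------------------------------

def embed_items(item_indices: np.ndarray, W_e) -> np.ndarray:
    """Row lookup x_t = w_t W_e; the padding index 0 maps to the zero row."""
    W = W_e.data if isinstance(W_e, Tensor) else np.asarray(W_e)
    return ag.embedding(Tensor(W), np.asarray(item_indices)).data


def bilstm_encode(inputs: np.ndarray, mask: np.ndarray, params: dict) -> np.ndarray:
    """Bidirectional LSTM encoding of (N, T, d) -> (N, T, 2H)."""
    inputs = np.asarray(inputs, dtype=float)
    if inputs.ndim != 3:
        raise ValueError(f"inputs must be (N, T, d), got shape {inputs.shape}")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != inputs.shape[:2]:
        raise ValueError("mask shape must match (N, T)")
    H = params["fw"]["R"].shape[0]
    return _bilstm(Tensor(inputs), mask, params, H).data


def _batchify(arr, width):
    arr = np.asarray(arr, dtype=float)
    squeeze = arr.ndim == 2
    if squeeze:
        arr = arr[None]
    return arr, squeeze


def tangle_attention(Hx, Htau, mask, params):
    """Time span-guided attention weights and contributions.

    Accepts a single sequence (T, 2H) or a batch (N, T, 2H); returns
    (alpha, omega) of the same leading shape. Masked steps get 0.
    """
    Hx, squeeze = _batchify(Hx, None)
    Htau, _ = _batchify(Htau, None)
    if Hx.shape != Htau.shape:
        raise ValueError("Hx and Htau must have the same shape")
    mask = np.atleast_2d(np.asarray(mask, dtype=bool))
    alpha, omega, _ = _tangle_attention_graph(Tensor(Hx), Tensor(Htau), mask, params)
    a, w = alpha.data, omega.data
    return (a[0], w[0]) if squeeze else (a, w)


def context_vector(omega, X):
    """c_bar = (1/2H) * sum_j (Omega^T X)_j for one sequence or a batch."""
    omega, squeeze = _batchify(omega, None)
    X, _ = _batchify(X, None)
    if omega.shape[-2] != X.shape[-2]:
        raise ValueError("omega and X must share the time dimension")
    c = _context_graph(Tensor(omega), Tensor(X)).data
    return c[0] if squeeze else c


def standard_attention(H, mask, params):
    """Scalar-weight attention: returns (alpha (T,), context (H',))."""
    H, squeeze = _batchify(H, None)
    mask = np.atleast_2d(np.asarray(mask, dtype=bool))
    alpha, c = _standard_attention_graph(Tensor(H), mask, params)
    a = alpha.data[..., 0]
    return (a[0], c.data[0]) if squeeze else (a, c.data)


def predict_head(c, params, training: bool = False, dropout: float = 0.0,
                 rng=None) -> np.ndarray:
    c = np.atleast_2d(np.asarray(c, dtype=float))
    out = _head_graph(Tensor(c), params, dropout, training,
                      rng or np.random.default_rng(0)).data
    return out[0] if out.shape[0] == 1 and c.shape[0] == 1 else out


def bce_loss(y, y_hat) -> float:
    y = np.asarray(y, dtype=float).reshape(-1)
    y_hat = np.asarray(y_hat, dtype=float).reshape(-1)
    if y.shape != y_hat.shape:
        raise ValueError("y and y_hat must have the same length")
    return float(_bce_graph(y, Tensor(y_hat)).data)


# ---------------------------------------------------------------------------
# model classes
# ---------------------------------------------------------------------------

def _flatten_params(tree, out=None, prefix=""):
    out = out if out is not None else {}
    for k, v in tree.items():
        key = f"{prefix}{k}"
        if isinstance(v, dict):
            _flatten_params(v, out, key + ".")
        else:
            out[key] = v
    return out


class _RecurrentModel:
    kind = "base"

    def __init__(self, config: ModelConfig, vocab_size: int, W_e: Optional[np.ndarray] = None):
        self.config = config
        self.vocab_size = vocab_size
        rng = np.random.default_rng(config.seed)
        if W_e is None:
            W_e = rng.uniform(-0.05, 0.05, size=(vocab_size + 1, config.E))
            W_e[0] = 0.0
        if W_e.shape != (vocab_size + 1, config.E):
            raise ValueError(
                f"embedding matrix shape {W_e.shape} != {(vocab_size + 1, config.E)}")
        self.params: dict = {"W_e": Tensor(np.array(W_e, dtype=float), requires_grad=True)}
        self._init_params(rng)
        self._dropout_rng = np.random.default_rng(config.seed + 7)

    def _init_params(self, rng):
        raise NotImplementedError

    def _head_params(self, rng, in_dim):
        cfg = self.config
        return {
            "W_0": _glorot(rng, (in_dim, cfg.D)),
            "b_0": Tensor(np.zeros(cfg.D), requires_grad=True),
            "W_1": _glorot(rng, (cfg.D, 1)),
            "b_1": Tensor(np.zeros(1), requires_grad=True),
        }

    def parameters(self) -> list[Tensor]:
        return list(_flatten_params(self.params).values())

    def _tau_input(self, spans: np.ndarray) -> np.ndarray:
        s = np.asarray(spans, dtype=float)
        if self.config.tau_transform == "log1p":
            s = np.log1p(s)
        return s[..., None]

    def forward(self, items, spans, mask, training=False) -> Tensor:
        raise NotImplementedError

    def predict_proba(self, batch: EncodedBatch) -> np.ndarray:
        return self.forward(batch.item_indices, batch.spans, batch.mask,
                            training=False).data

    # -- persistence -------------------------------------------------------
    def save(self, path):
        flat = {k: v.data for k, v in _flatten_params(self.params).items()}
        manifest = {
            "kind": self.kind,
            "vocab_size": self.vocab_size,
            "config": asdict(self.config),
            "shapes": {k: list(v.shape) for k, v in flat.items()},
        }
        np.savez(path, __manifest__=np.array(json.dumps(manifest)), **flat)

    @classmethod
    def load(cls, path):
        with np.load(path, allow_pickle=False) as z:
            manifest = json.loads(str(z["__manifest__"]))
            model = build_model(manifest["kind"], ModelConfig(**manifest["config"]),
                                manifest["vocab_size"])
            flat = _flatten_params(model.params)
            for k, t in flat.items():
                t.data = np.array(z[k])
        return model


class BaselineModel(_RecurrentModel):
    """Attentionless BiLSTM: final fwd/bwd states -> MLP head."""

    kind = "baseline"

    def _init_params(self, rng):
        cfg = self.config
        self.params["lstm_x"] = init_bilstm_params(cfg.E, cfg.H, rng)
        self.params["head"] = self._head_params(rng, 2 * cfg.H)

    def forward(self, items, spans, mask, training=False):
        cfg = self.config
        mask = np.asarray(mask, dtype=bool)
        x = ag.embedding(self.params["W_e"], np.asarray(items))
        Hx = _bilstm(x, mask, self.params["lstm_x"], cfg.H)
        # right-aligned + gated states: forward final at t=T-1, backward at t=0
        pooled = ag.concat([Hx[:, -1, :cfg.H], Hx[:, 0, cfg.H:]], axis=-1)
        return _head_graph(pooled, self.params["head"], cfg.dropout, training,
                           self._dropout_rng)


class AttentionModel(_RecurrentModel):
    """BiLSTM with standard (scalar-weight) attention on the item stream."""

    kind = "attention"

    def _init_params(self, rng):
        cfg = self.config
        self.params["lstm_x"] = init_bilstm_params(cfg.E, cfg.H, rng)
        self.params["attn"] = {
            "W_t": _glorot(rng, (2 * cfg.H, cfg.U)),
            "b": Tensor(np.zeros(cfg.U), requires_grad=True),
            "w_alpha": _glorot(rng, (cfg.U,)),
        }
        self.params["head"] = self._head_params(rng, 2 * cfg.H)

    def forward(self, items, spans, mask, training=False):
        cfg = self.config
        mask = np.asarray(mask, dtype=bool)
        x = ag.embedding(self.params["W_e"], np.asarray(items))
        Hx = _bilstm(x, mask, self.params["lstm_x"], cfg.H)
        _, c = _standard_attention_graph(Hx, mask, self.params["attn"])
        return _head_graph(c, self.params["head"], cfg.dropout, training,
                           self._dropout_rng)


class TangleModel(_RecurrentModel):
    """Two-input BiLSTM with time span-guided per-unit attention."""

    kind = "tangle"

    def _init_params(self, rng):
        cfg = self.config
        self.params["lstm_x"] = init_bilstm_params(cfg.E, cfg.H, rng)
        self.params["lstm_tau"] = init_bilstm_params(1, cfg.H, rng)
        self.params["attn"] = {
            "W_x": _glorot(rng, (2 * cfg.H, cfg.U)),
            "b_x": Tensor(np.zeros(cfg.U), requires_grad=True),
            "W_tau": _glorot(rng, (2 * cfg.H, cfg.U)),
            "b_tau": Tensor(np.zeros(cfg.U), requires_grad=True),
            "lam_raw": Tensor(0.0, requires_grad=True),  # lambda = sigmoid(0) = 0.5
            "W_alpha": _glorot(rng, (cfg.U, 2 * cfg.H)),
        }
        self.params["head"] = self._head_params(rng, cfg.E)

    @property
    def lam(self) -> float:
        return float(1.0 / (1.0 + np.exp(-self.params["attn"]["lam_raw"].data)))

    def _encode(self, items, spans, mask):
        cfg = self.config
        x = ag.embedding(self.params["W_e"], np.asarray(items))
        Hx = _bilstm(x, mask, self.params["lstm_x"], cfg.H)
        tau = Tensor(self._tau_input(spans))
        Htau = _bilstm(tau, mask, self.params["lstm_tau"], cfg.H)
        return x, Hx, Htau

    def forward(self, items, spans, mask, training=False):
        cfg = self.config
        mask = np.asarray(mask, dtype=bool)
        x, Hx, Htau = self._encode(items, spans, mask)
        _, omega, _ = _tangle_attention_graph(Hx, Htau, mask, self.params["attn"])
        c = _context_graph(omega, x)
        return _head_graph(c, self.params["head"], cfg.dropout, training,
                           self._dropout_rng)

    def attention_traces(self, batch: EncodedBatch) -> list[AttentionTrace]:
        mask = np.asarray(batch.mask, dtype=bool)
        x, Hx, Htau = self._encode(batch.item_indices, batch.spans, mask)
        alpha, omega, lam = _tangle_attention_graph(Hx, Htau, mask, self.params["attn"])
        c = _context_graph(omega, x)
        out = []
        for i in range(len(batch)):
            out.append(AttentionTrace(
                alpha=alpha.data[i], omega=omega.data[i], lam=float(lam.data),
                context=c.data[i], mask=mask[i],
                subject_id=batch.subject_ids[i] if batch.subject_ids else str(i),
                label=None if batch.labels is None else int(batch.labels[i]),
            ))
        return out


_MODEL_KINDS = {"baseline": BaselineModel, "attention": AttentionModel,
                "tangle": TangleModel}


def build_model(kind: str, config: ModelConfig, vocab_size: int,
                W_e: Optional[np.ndarray] = None) -> _RecurrentModel:
    if kind not in _MODEL_KINDS:
        raise ValueError(f"unknown model kind {kind!r}; choose from {sorted(_MODEL_KINDS)}")
    return _MODEL_KINDS[kind](config, vocab_size, W_e)


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def _epoch_loss(model, batch: EncodedBatch) -> float:
    p = model.forward(batch.item_indices, batch.spans, batch.mask, training=False)
    return float(_bce_graph(batch.labels, p).data)


def train(model_kind: str, train_batch: EncodedBatch, val_batch: EncodedBatch,
          config: ModelConfig, vocab_size: Optional[int] = None,
          W_e: Optional[np.ndarray] = None):
    """Fit a model by Adam on mean cross-entropy with early stopping.

    Stops when the validation loss has not improved for ``config.patience``
    consecutive epochs and restores the best weights. Deterministic for a
    fixed config seed. Returns ``(model, history)`` where history is a
    DataFrame with columns epoch, train_loss, val_loss.
    """
    if train_batch.labels is None or val_batch.labels is None:
        raise ValueError("training requires labeled batches")
    if vocab_size is None:
        vocab_size = int(max(train_batch.item_indices.max(),
                             val_batch.item_indices.max()))
    model = build_model(model_kind, config, vocab_size, W_e)
    opt = ag.Adam(model.parameters(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 13)
    N = len(train_batch)
    best_val = np.inf
    best_state = None
    stale = 0
    history = []
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(N)
        losses = []
        for start in range(0, N, config.batch_size):
            rows = order[start:start + config.batch_size]
            mb = train_batch.subset(rows)
            p = model.forward(mb.item_indices, mb.spans, mb.mask, training=True)
            loss = _bce_graph(mb.labels, p)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch} "
                    f"(lr={config.learning_rate}); aborting")
            opt.zero_grad()
            loss.backward()
            opt.step()
            model.params["W_e"].data[0] = 0.0  # padding row stays frozen
            losses.append(float(loss.data))
        val_loss = _epoch_loss(model, val_batch)
        history.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                        "val_loss": val_loss})
        if val_loss < best_val - 1e-9:
            best_val = val_loss
            best_state = {k: v.data.copy()
                          for k, v in _flatten_params(model.params).items()}
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                break
    if best_state is not None:
        for k, t in _flatten_params(model.params).items():
            t.data = best_state[k]
    return model, pd.DataFrame(history)
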