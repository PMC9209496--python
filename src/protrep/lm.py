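"""Bidirectional recurrent protein language model.

Two independent LSTM stacks read each sequence, one left-to-right
predicting the *next* residue and one right-to-left predicting the
*previous* residue. Training minimizes the sum of the two directions'
cross-entropies with AdamW under a linear learning-rate warmup. The
model is evaluated by Exponential Cross-Entropy (ECE) — the exponential
of the mean per-target natural-log cross-entropy pooled over both
directions, i.e. perplexity, minimum 1, exactly the alphabet size for a
uniform predictor. A protein's embedding is the arithmetic mean over
residue positions of the concatenated final-layer forward and backward
hidden states, hence ``2 × hidden_units`` dimensions (2,048 at the
default 1,024 units per direction).

Everything is implemented in numpy: forward passes, backpropagation
through time, and the optimizer. At the corpus sizes and model widths
this package trains (tens of hidden units, hundreds of sequences) a CPU
handles the arithmetic comfortably, and the closed-form gradients are
verified against finite differences in the test suite.

Notes on the objective:

* the first residue has no "previous" target and the last no "next";
  those positions are simply absent from the respective direction's loss;
* ambiguity letters (B, Z, X, U, O, J) are valid *inputs* with their own
  tokens but are never prediction *targets* — they carry no single
  ground-truth residue — so the output head covers the 20 canonical
  residues only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import TokenizationError
from .io import AMBIGUOUS_AA, CANONICAL_AA, ProteinRecord

PAD, START, STOP = "<pad>", "<start>", "<stop>"
#: default vocabulary: 3 specials, 20 canonical residues, 6 ambiguity letters
DEFAULT_VOCABULARY: tuple[str, ...] = (PAD, START, STOP, *CANONICAL_AA, *AMBIGUOUS_AA)
_N_SPECIALS = 3
_N_CLASSES = 20  # output head: canonical residues only
_DIRECTIONS = ("fwd", "bwd")


@dataclass(frozen=True)
class LanguageModelConfig:
    """Architecture and optimization hyper-parameters.

    Defaults follow the full-scale setup (3 layers × 1024 units, clip at
    1500 residues, AdamW at 1e-3 with 8000 warmup steps, batches of
    1024); benchmark-scale runs shrink layers/units/batch via replace().
    """

    num_layers: int = 3
    hidden_units: int = 1024
    max_sequence_length: int = 1500
    learning_rate: float = 1e-3
    warmup_steps: int = 8000
    batch_size: int = 1024
    vocabulary: tuple[str, ...] = DEFAULT_VOCABULARY
    seed: int = 0

    def __post_init__(self) -> None:
        if self.num_layers < 1 or self.hidden_units < 1 or self.batch_size < 1:
            raise ValueError("num_layers, hidden_units and batch_size must be positive")
        if self.max_sequence_length < 1:
            raise ValueError("max_sequence_length must be >= 1")
        if self.learning_rate <= 0 or self.warmup_steps < 0:
            raise ValueError("learning_rate must be positive, warmup_steps nonnegative")
        if len(set(self.vocabulary)) != len(self.vocabulary):
            raise ValueError("vocabulary tokens must be unique")
        for tok in (*CANONICAL_AA,):
            if tok not in self.vocabulary:
                raise ValueError(f"vocabulary must contain canonical residue {tok}")

    @property
    def embedding_dim(self) -> int:
        """Dimension of the pooled protein embedding (2 × hidden_units)."""
        return 2 * self.hidden_units

    @property
    def vocab_size(self) -> int:
        return len(self.vocabulary)


def tokenize(r: ProteinRecord, c: LanguageModelConfig) -> np.ndarray:
    """Map a sequence to vocabulary indices, truncating at the length cap.

    Raises :class:`TokenizationError` naming the first character outside
    the vocabulary and its (1-based) position.
    """
    lookup = {tok: i for i, tok in enumerate(c.vocabulary)}
    seq = r.sequence[: c.max_sequence_length]
    out = np.empty(len(seq), dtype=np.int64)
    for pos, ch in enumerate(seq):
        idx = lookup.get(ch)
        if idx is None:
            raise TokenizationError(
                f"sequence {r.id}: character {ch!r} at position {pos + 1} "
                "is not in the model vocabulary"
            )
        out[pos] = idx
    return out


def _target_class(c: LanguageModelConfig) -> np.ndarray:
    """Token index -> output class (0..19) or -1 for non-canonical tokens."""
    classes = np.full(c.vocab_size, -1, dtype=np.int64)
    for j, aa in enumerate(CANONICAL_AA):
        classes[c.vocabulary.index(aa)] = j
    return classes


@dataclass
class TrainedLM:
    """A (possibly untrained) model: config plus its weight arrays.

    ``parameters`` maps names to numpy arrays; ``training_log`` records
    the per-step training loss. All outputs are deterministic given the
    weights and the input.
    """

    config: LanguageModelConfig
    parameters: dict[str, np.ndarray]
    training_log: list[float] = field(default_factory=list)


# ---------------------------------------------------------------------------
# parameter initialization


def _init_parameters(c: LanguageModelConfig, rng: np.random.Generator,
                     zero: bool = False) -> dict[str, np.ndarray]:
    h = c.hidden_units
    v = c.vocab_size

    def w(shape):
        if zero:
            return np.zeros(shape)
        bound = 1.0 / np.sqrt(shape[0])
        return rng.uniform(-bound, bound, size=shape)

    params: dict[str, np.ndarray] = {"embed": w((v, h))}
    for d in _DIRECTIONS:
        for l in range(c.num_layers):
            params[f"{d}_Wx{l}"] = w((h, 4 * h))
            params[f"{d}_Wh{l}"] = w((h, 4 * h))
            b = np.zeros(4 * h)
            if not zero:
                b[h: 2 * h] = 1.0  # forget-gate bias: remember by default
            params[f"{d}_b{l}"] = b
        params[f"{d}_Wout"] = w((h, _N_CLASSES))
        params[f"{d}_bout"] = np.zeros(_N_CLASSES)
    return params


def untrained_lm(c: LanguageModelConfig) -> TrainedLM:
    """Randomly initialized model (seeded from the config)."""
    return TrainedLM(c, _init_parameters(c, np.random.default_rng(c.seed)))


def uniform_lm(c: LanguageModelConfig) -> TrainedLM:
    """All-zero weights: emits the uniform distribution over the 20
    canonical residues at every position (ECE exactly 20)."""
    return TrainedLM(c, _init_parameters(c, np.random.default_rng(c.seed), zero=True))


# ---------------------------------------------------------------------------
# LSTM forward / backward (batch-first, right-padded)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _lstm_forward(X: np.ndarray, Wx: np.ndarray, Wh: np.ndarray, b: np.ndarray):
    """One LSTM layer over a (B, T, in_dim) input; returns H and caches."""
    B, T, _ = X.shape
    h = Wh.shape[0]
    H = np.zeros((B, T, h))
    C = np.zeros((B, T, h))
    gates = np.zeros((B, T, 4 * h))
    h_prev = np.zeros((B, h))
    c_prev = np.zeros((B, h))
    XW = X @ Wx + b  # precompute input contributions for all t
    for t in range(T):
        z = XW[:, t] + h_prev @ Wh
        i = _sigmoid(z[:, :h])
        f = _sigmoid(z[:, h:2 * h])
        g = np.tanh(z[:, 2 * h:3 * h])
        o = _sigmoid(z[:, 3 * h:])
        c = f * c_prev + i * g
        gates[:, t, :h], gates[:, t, h:2 * h] = i, f
        gates[:, t, 2 * h:3 * h], gates[:, t, 3 * h:] = g, o
        C[:, t] = c
        H[:, t] = o * np.tanh(c)
        h_prev, c_prev = H[:, t], c
    return H, (X, H, C, gates)


def _lstm_backward(dH: np.ndarray, cache, Wx: np.ndarray, Wh: np.ndarray):
    """Backprop one LSTM layer; returns (dX, dWx, dWh, db)."""
    X, H, C, gates = cache
    B, T, h = H.shape
    dWx = np.zeros_like(Wx)
    dWh = np.zeros_like(Wh)
    db = np.zeros(4 * h)
    dX = np.zeros_like(X)
    dh_next = np.zeros((B, h))
    dc_next = np.zeros((B, h))
    dA = np.zeros((B, T, 4 * h))
    for t in range(T - 1, -1, -1):
        i, f = gates[:, t, :h], gates[:, t, h:2 * h]
        g, o = gates[:, t, 2 * h:3 * h], gates[:, t, 3 * h:]
        c_prev = C[:, t - 1] if t > 0 else np.zeros((B, h))
        tanh_c = np.tanh(C[:, t])
        dh = dH[:, t] + dh_next
        dc = dh * o * (1.0 - tanh_c ** 2) + dc_next
        da = dA[:, t]
        da[:, :h] = dc * g * i * (1.0 - i)
        da[:, h:2 * h] = dc * c_prev * f * (1.0 - f)
        da[:, 2 * h:3 * h] = dc * i * (1.0 - g ** 2)
        da[:, 3 * h:] = dh * tanh_c * o * (1.0 - o)
        h_prev = H[:, t - 1] if t > 0 else np.zeros((B, h))
        dWh += h_prev.T @ da
        dh_next = da @ Wh.T
        dc_next = dc * f
    flatA = dA.reshape(B * T, 4 * h)
    dWx += X.reshape(B * T, -1).T @ flatA
    db += flatA.sum(axis=0)
    dX = dA @ Wx.T
    return dX, dWx, dWh, db


def _direction_forward(params: dict, d: str, num_layers: int, X_idx: np.ndarray):
    """Run one direction's stack; returns final-layer H and all caches."""
    X = params["embed"][X_idx]
    caches = []
    H = X
    for l in range(num_layers):
        H, cache = _lstm_forward(H, params[f"{d}_Wx{l}"], params[f"{d}_Wh{l}"],
                                 params[f"{d}_b{l}"])
        caches.append(cache)
    return H, caches


def _log_softmax(logits: np.ndarray) -> np.ndarray:
    m = logits.max(axis=-1, keepdims=True)
    z = logits - m
    return z - np.log(np.exp(z).sum(axis=-1, keepdims=True))


def _loss_and_grads(params: dict, num_layers: int, batches: dict[str, tuple]
                    ) -> tuple[float, dict[str, np.ndarray]]:
    """Summed two-direction mean cross-entropy and its parameter gradients.

    ``batches`` maps direction -> (X_idx right-padded (B, T), Y targets
    (B, T) with class indices or -1 for no-target positions).
    """
    grads = {k: np.zeros_like(v) for k, v in params.items()}
    total_loss = 0.0
    for d in _DIRECTIONS:
        X_idx, Y = batches[d]
        H, caches = _direction_forward(params, d, num_layers, X_idx)
        Wout, bout = params[f"{d}_Wout"], params[f"{d}_bout"]
        logits = H @ Wout + bout
        logp = _log_softmax(logits)
        valid = Y >= 0
        n_targets = int(valid.sum())
        if n_targets == 0:
            continue
        rows = np.where(valid)
        picked = logp[rows[0], rows[1], Y[valid]]
        total_loss += -picked.sum() / n_targets

        dlogits = np.exp(logp)
        dlogits[rows[0], rows[1], Y[valid]] -= 1.0
        dlogits[~valid] = 0.0
        dlogits /= n_targets
        B, T, h = H.shape
        grads[f"{d}_Wout"] += H.reshape(B * T, h).T @ dlogits.reshape(B * T, -1)
        grads[f"{d}_bout"] += dlogits.sum(axis=(0, 1))
        dH = dlogits @ Wout.T
        for l in range(num_layers - 1, -1, -1):
            dH, dWx, dWh, db = _lstm_backward(dH, caches[l], params[f"{d}_Wx{l}"],
                                              params[f"{d}_Wh{l}"])
            grads[f"{d}_Wx{l}"] += dWx
            grads[f"{d}_Wh{l}"] += dWh
            grads[f"{d}_b{l}"] += db
        np.add.at(grads["embed"], X_idx, dH)
    return total_loss, grads


# ---------------------------------------------------------------------------
# batching


def _make_batch(token_lists: Sequence[np.ndarray], classes: np.ndarray,
                pad_index: int) -> dict[str, tuple]:
    """Right-padded forward and per-sequence-reversed backward batches
    with next-token targets (-1 where no valid canonical target)."""
    B = len(token_lists)
    T = max(len(t) for t in token_lists)
    Xf = np.full((B, T), pad_index, dtype=np.int64)
    Xb = np.full((B, T), pad_index, dtype=np.int64)
    Yf = np.full((B, T), -1, dtype=np.int64)
    Yb = np.full((B, T), -1, dtype=np.int64)
    for i, toks in enumerate(token_lists):
        L = len(toks)
        Xf[i, :L] = toks
        Xb[i, :L] = toks[::-1]
        if L >= 2:
            Yf[i, :L - 1] = classes[toks[1:]]
            Yb[i, :L - 1] = classes[toks[::-1][1:]]
    return {"fwd": (Xf, Yf), "bwd": (Xb, Yb)}


# ---------------------------------------------------------------------------
# training


def train_lm(corpus: Sequence[ProteinRecord], c: LanguageModelConfig,
             steps: int, weight_decay: float = 0.01) -> TrainedLM:
    """Train from random init with AdamW and a linear warmup.

    The learning rate ramps linearly from 0 to ``c.learning_rate`` over
    ``c.warmup_steps`` updates and stays constant afterwards. Identical
    seed, config and corpus give a bit-identical ``training_log``.
    """
    if len(corpus) == 0:
        raise ValueError("training corpus is empty")
    if steps < 1:
        raise ValueError("steps must be >= 1")
    tokens = [tokenize(r, c) for r in corpus]
    if all(len(t) < 2 for t in tokens):
        raise ValueError("no sequence of length >= 2: nothing to predict")
    classes = _target_class(c)
    pad_index = c.vocabulary.index(PAD)

    rng = np.random.default_rng(c.seed)
    params = _init_parameters(c, rng)
    m_state = {k: np.zeros_like(v) for k, v in params.items()}
    v_state = {k: np.zeros_like(v) for k, v in params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    log: list[float] = []
    n = len(tokens)
    batch_rng = np.random.default_rng(c.seed + 1)
    for step in range(1, steps + 1):
        size = min(c.batch_size, n)
        idx = batch_rng.choice(n, size=size, replace=False)
        batch = _make_batch([tokens[i] for i in idx], classes, pad_index)
        loss, grads = _loss_and_grads(params, c.num_layers, batch)
        lr = c.learning_rate * (min(1.0, step / c.warmup_steps)
                                if c.warmup_steps > 0 else 1.0)
        for k in params:
            g = grads[k]
            m_state[k] = beta1 * m_state[k] + (1 - beta1) * g
            v_state[k] = beta2 * v_state[k] + (1 - beta2) * g * g
            m_hat = m_state[k] / (1 - beta1 ** step)
            v_hat = v_state[k] / (1 - beta2 ** step)
            params[k] -= lr * (m_hat / (np.sqrt(v_hat) + eps) + weight_decay * params[k])
        log.append(float(loss))
    return TrainedLM(c, params, log)


# ---------------------------------------------------------------------------
# evaluation & embedding


def ece(m: TrainedLM, eval_set: Sequence[ProteinRecord],
        batch_size: int = 64) -> float:
    """Exponential Cross-Entropy: exp of the mean per-target natural-log
    cross-entropy pooled over both directions and all positions.

    ≥ 1 always; exactly the class count (20) for a uniform predictor.
    """
    if len(eval_set) == 0:
        raise ValueError("evaluation set is empty")
    c = m.config
    tokens = [tokenize(r, c) for r in eval_set]
    if all(len(t) < 2 for t in tokens):
        raise ValueError("no sequence of length >= 2: no prediction targets")
    classes = _target_class(c)
    pad_index = c.vocabulary.index(PAD)
    total_nll = 0.0
    total_targets = 0
    order = np.argsort([len(t) for t in tokens], kind="stable")  # limit padding
    for start in range(0, len(tokens), batch_size):
        chunk = [tokens[i] for i in order[start:start + batch_size]]
        batch = _make_batch(chunk, classes, pad_index)
        for d in _DIRECTIONS:
            X_idx, Y = batch[d]
            H, _ = _direction_forward(m.parameters, d, c.num_layers, X_idx)
            logp = _log_softmax(H @ m.parameters[f"{d}_Wout"] + m.parameters[f"{d}_bout"])
            valid = Y >= 0
            rows = np.where(valid)
            total_nll += float(-logp[rows[0], rows[1], Y[valid]].sum())
            total_targets += int(valid.sum())
    if total_targets == 0:
        raise ValueError("no valid prediction targets in the evaluation set")
    return float(np.exp(total_nll / total_targets))


def embed(m: TrainedLM, r: ProteinRecord) -> np.ndarray:
    """Mean over positions of [forward hidden; backward hidden] at the
    final layer — a ``2 × hidden_units`` vector."""
    return embed_many(m, [r])[0]


def embed_many(m: TrainedLM, records: Sequence[ProteinRecord],
               batch_size: int = 64) -> np.ndarray:
    """Batch embedding; identical to per-record calls (right padding
    cannot leak into the mean because pooling is masked by length)."""
    c = m.config
    tokens = [tokenize(r, c) for r in records]
    pad_index = c.vocabulary.index(PAD)
    out = np.empty((len(records), c.embedding_dim))
    order = np.argsort([len(t) for t in tokens], kind="stable")
    for start in range(0, len(tokens), batch_size):
        sel = order[start:start + batch_size]
        chunk = [tokens[i] for i in sel]
        B = len(chunk)
        T = max(len(t) for t in chunk)
        Xf = np.full((B, T), pad_index, dtype=np.int64)
        Xb = np.full((B, T), pad_index, dtype=np.int64)
        for i, toks in enumerate(chunk):
            Xf[i, :len(toks)] = toks
            Xb[i, :len(toks)] = toks[::-1]
        Hf, _ = _direction_forward(m.parameters, "fwd", c.num_layers, Xf)
        Hb, _ = _direction_forward(m.parameters, "bwd", c.num_layers, Xb)
        for i, toks in enumerate(chunk):
            L = len(toks)
            fwd = Hf[i, :L]
            bwd = Hb[i, :L][::-1]  # backward states re-aligned to sequence order
            out[sel[i]] = np.concatenate([fwd, bwd], axis=1).mean(axis=0)
    return out


def embedding_matrix(m: TrainedLM, records: Sequence[ProteinRecord],
                     batch_size: int = 64):
    from .io import RepresentationMatrix

    return RepresentationMatrix([r.id for r in records],
                                embed_many(m, records, batch_size), "lm-mean")


# ---------------------------------------------------------------------------
# persistence


def save_lm(m: TrainedLM, directory: str | Path) -> None:
    """Checkpoint: weights.npz + config.json + vocabulary.txt (+ log)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savez(directory / "weights.npz", **m.parameters)
    cfg = {k: getattr(m.config, k) for k in
           ("num_layers", "hidden_units", "max_sequence_length", "learning_rate",
            "warmup_steps", "batch_size", "seed")}
    cfg["loss_units"] = "nat"  # ECE uses natural-log cross-entropy
    (directory / "config.json").write_text(json.dumps(cfg, indent=1))
    (directory / "vocabulary.txt").write_text("\n".join(m.config.vocabulary) + "\n")
    (directory / "training_log.json").write_text(json.dumps(m.training_log))


def load_lm(directory: str | Path) -> TrainedLM:
    directory = Path(directory)
    cfg = json.loads((directory / "config.json").read_text())
    cfg.pop("loss_units", None)
    vocab = tuple((directory / "vocabulary.txt").read_text().splitlines())
    config = LanguageModelConfig(vocabulary=vocab, **cfg)
    with np.load(directory / "weights.npz") as npz:
        params = {k: npz[k] for k in npz.files}
    log_path = directory / "training_log.json"
    log = json.loads(log_path.read_text()) if log_path.exists() else []
    return TrainedLM(config, params, log)


# ---------------------------------------------------------------------------
# estimator facade


class BiLSTMEmbedder(BaseEstimator, TransformerMixin):
    """sklearn-style facade: fit() trains the language model on a record
    collection, transform() returns mean-pooled embeddings.

    Attributes
    ----------
    model_ : TrainedLM
    training_log_ : list of per-step losses
    """

    def __init__(self, num_layers: int = 2, hidden_units: int = 64,
                 steps: int = 300, batch_size: int = 16,
                 learning_rate: float = 1e-3, warmup_steps: int = 30,
                 max_sequence_length: int = 1500, seed: int = 0):
        self.num_layers = num_layers
        self.hidden_units = hidden_units
        self.steps = steps
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.warmup_steps = warmup_steps
        self.max_sequence_length = max_sequence_length
        self.seed = seed

    def _config(self) -> LanguageModelConfig:
        return LanguageModelConfig(
            num_layers=self.num_layers, hidden_units=self.hidden_units,
            max_sequence_length=self.max_sequence_length,
            learning_rate=self.learning_rate, warmup_steps=self.warmup_steps,
            batch_size=self.batch_size, seed=self.seed)

    def fit(self, X: Sequence[ProteinRecord], y=None) -> "BiLSTMEmbedder":
        self.model_ = train_lm(X, self._config(), self.steps)
        self.training_log_ = self.model_.training_log
        return self

    def transform(self, X: Sequence[ProteinRecord]) -> np.ndarray:
        if not hasattr(self, "model_"):
            raise RuntimeError("BiLSTMEmbedder must be fitted before transform")
        return embed_many(self.model_, X)

    def score(self, X: Sequence[ProteinRecord], y=None) -> float:
        """Negative ECE (higher is better, sklearn convention)."""
        return -ece(self.model_, X)
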