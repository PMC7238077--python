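"""The de-identification tagger network.

Architecture (two layers over a token sequence t_1..t_n):

1. *Character-enhanced token embedding layer.*  Each token is represented by
   the concatenation e_i = [x_i, h^for, h^back] of its pretrained word vector
   x_i and the final hidden states of a bidirectional LSTM run over the
   token's one-hot-encoded characters.  All per-token character LSTMs share
   weights.  The character half is reproducible for any string, including
   vocabulary the word table has never seen.
2. *Label prediction layer.*  A second bidirectional LSTM runs over
   (e_1..e_n) in "full" mode, giving d_i = [h_i^for, h_i^back]; a two-layer
   feedforward head l_i = tanh(W_1 d_i + b_1), a_i = softmax(W_2 l_i + b_2)
   yields posterior probabilities over the 29 labels, and the predicted label
   is the argmax (lowest index on ties).

The recurrent cell is a coupled-gate LSTM variant: the forget gate equals
one minus the input gate, and a constant +1 is added inside the input-gate
sigmoid (a unit forget-bias analogue)::

    i_t = sigma(W_i [z_t, h_{t-1}] + b_i + 1)
    c_t = i_t * c_{t-1} + (1 - i_t) * tanh(W_c [z_t, h_{t-1}] + b_c)
    o_t = sigma(W_o [z_t, h_{t-1}] + b_o)
    h_t = o_t * tanh(c_t)

with h_0 = c_0 = 0.  Training minimises the cross-entropy
E(p) = -sum_i log a_i[class(t_i)]; all weights live in one flat parameter
vector p with a named index map, which is what collaborative training
protocols exchange.  Gradients are computed by backpropagation written out
by hand (and validated against finite differences in the test suite).
Inverted dropout with rate ``dropout_rate`` is applied to the embedding
sequence (e_1..e_n) during training only, with a fresh seeded mask per
sequence.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import expit

from .corpus import LabeledDocument
from .encoders import CHAR_ONEHOT_DIM, EmbeddingTable, token_char_indices
from .labels import LabelScheme, build_label_scheme

__all__ = [
    "NetworkConfig",
    "LstmParams",
    "ParameterVector",
    "TaggerOutput",
    "lstm_step",
    "bilstm",
    "token_embedding",
    "forward",
    "predict_labels",
    "loss",
    "gradient",
    "loss_and_gradient",
    "init_parameters",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class NetworkConfig:
    """Network dimensions.  Defaults are the full-scale study values."""

    word_dim: int = 300
    char_onehot_dim: int = CHAR_ONEHOT_DIM
    char_hidden: int = 128
    label_hidden: int = 100
    ff_hidden: int = 100
    n_labels: int = 29
    dropout_rate: float = 0.5

    @property
    def e_dim(self) -> int:
        """Token embedding length: word vector + both character LSTM states."""
        return self.word_dim + 2 * self.char_hidden

    @property
    def d_dim(self) -> int:
        """Label-LSTM output length per position (both directions)."""
        return 2 * self.label_hidden


@dataclass(frozen=True)
class LstmParams:
    """Weights of one unidirectional coupled-gate LSTM."""

    W_i: np.ndarray
    W_c: np.ndarray
    W_o: np.ndarray
    b_i: np.ndarray
    b_c: np.ndarray
    b_o: np.ndarray

    def __post_init__(self) -> None:
        shape = self.W_i.shape
        if self.W_c.shape != shape or self.W_o.shape != shape:
            raise ValueError("W_i, W_c, W_o must share one shape")
        hidden = shape[0]
        for b in (self.b_i, self.b_c, self.b_o):
            if b.shape != (hidden,):
                raise ValueError("biases must have length hidden")
        if shape[1] <= hidden:
            raise ValueError("weight width must exceed hidden size")

    @property
    def hidden(self) -> int:
        return self.W_i.shape[0]

    @property
    def input_dim(self) -> int:
        return self.W_i.shape[1] - self.hidden


_LSTM_BLOCKS = ("char_fwd", "char_bwd", "label_fwd", "label_bwd")
_LSTM_FIELDS = ("W_i", "W_c", "W_o", "b_i", "b_c", "b_o")


@lru_cache(maxsize=None)
def _component_shapes(config: NetworkConfig) -> list[tuple[str, tuple[int, ...]]]:
    """Names and shapes of every parameter block, in flat-vector order."""
    out: list[tuple[str, tuple[int, ...]]] = []
    dims = {
        "char": (config.char_hidden, config.char_onehot_dim + config.char_hidden),
        "label": (config.label_hidden, config.e_dim + config.label_hidden),
    }
    for block in _LSTM_BLOCKS:
        h, d = dims[block.split("_")[0]]
        for w in ("W_i", "W_c", "W_o"):
            out.append((f"{block}.{w}", (h, d)))
        for b in ("b_i", "b_c", "b_o"):
            out.append((f"{block}.{b}", (h,)))
    out.append(("W_1", (config.ff_hidden, config.d_dim)))
    out.append(("b_1", (config.ff_hidden,)))
    out.append(("W_2", (config.n_labels, config.ff_hidden)))
    out.append(("b_2", (config.n_labels,)))
    return out


@lru_cache(maxsize=None)
def _shape_dict(config: NetworkConfig) -> dict[str, tuple[int, ...]]:
    return dict(_component_shapes(config))


@lru_cache(maxsize=None)
def _build_index_map_cached(config: NetworkConfig):
    index_map: dict[str, tuple[int, int]] = {}
    offset = 0
    for name, shape in _component_shapes(config):
        size = int(np.prod(shape))
        index_map[name] = (offset, offset + size)
        offset += size
    return index_map, offset


def _build_index_map(config: NetworkConfig) -> dict[str, tuple[int, int]]:
    return dict(_build_index_map_cached(config)[0])


def parameter_length(config: NetworkConfig) -> int:
    return _build_index_map_cached(config)[1]


@dataclass
class ParameterVector:
    """Flat parameter vector with a named index map into every block.

    The three gate matrices (and the three biases) of each LSTM are stored
    contiguously, so the hot path can view them as one stacked (3h, d)
    matrix and do a single matmul per step.
    """

    values: np.ndarray
    config: NetworkConfig
    index_map: dict[str, tuple[int, int]] = field(repr=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.index_map is None:
            self.index_map = _build_index_map(self.config)
        expected = parameter_length(self.config)
        if self.values.shape != (expected,):
            raise ValueError(
                f"parameter vector has length {self.values.shape}, "
                f"config requires {expected}"
            )

    def __len__(self) -> int:
        return self.values.size

    def view(self, name: str) -> np.ndarray:
        """Writable view of one named block, in its natural shape."""
        start, stop = self.index_map[name]
        return self.values[start:stop].reshape(_shape_dict(self.config)[name])

    def lstm_params(self, block: str) -> LstmParams:
        if block not in _LSTM_BLOCKS:
            raise KeyError(f"unknown LSTM block {block!r}")
        return LstmParams(*(self.view(f"{block}.{f}") for f in _LSTM_FIELDS))

    def _stacked(self, array: np.ndarray, block: str) -> tuple[np.ndarray, np.ndarray]:
        """(3h, d) gate-stacked weight view and (3h,) bias view into `array`."""
        w_start, _ = self.index_map[f"{block}.W_i"]
        _, w_stop = self.index_map[f"{block}.W_o"]
        b_start, _ = self.index_map[f"{block}.b_i"]
        _, b_stop = self.index_map[f"{block}.b_o"]
        h, d = _shape_dict(self.config)[f"{block}.W_i"]
        return array[w_start:w_stop].reshape(3 * h, d), array[b_start:b_stop]

    def copy(self) -> "ParameterVector":
        return ParameterVector(self.values.copy(), self.config, self.index_map)


def init_parameters(config: NetworkConfig, seed: int) -> ParameterVector:
    """Seeded Glorot-uniform weight matrices; zero biases."""
    rng = np.random.default_rng(seed)
    values = np.zeros(parameter_length(config))
    p = ParameterVector(values, config)
    for name, shape in _component_shapes(config):
        if len(shape) == 2:
            fan_out, fan_in = shape
            r = np.sqrt(6.0 / (fan_in + fan_out))
            p.view(name)[...] = rng.uniform(-r, r, size=shape)
    return p


# ---------------------------------------------------------------------------
# Cell primitives


_sigmoid = expit


def lstm_step(
    z_t: np.ndarray, h_prev: np.ndarray, c_prev: np.ndarray, params: LstmParams
) -> tuple[np.ndarray, np.ndarray]:
    """One step of the coupled-gate cell; returns (h_t, c_t)."""
    if z_t.shape != (params.input_dim,):
        raise ValueError(
            f"input has shape {z_t.shape}, expected ({params.input_dim},)"
        )
    if h_prev.shape != (params.hidden,) or c_prev.shape != (params.hidden,):
        raise ValueError("state vectors must have length hidden")
    g = np.concatenate([z_t, h_prev])
    i = _sigmoid(params.W_i @ g + params.b_i + 1.0)
    c_t = i * c_prev + (1.0 - i) * np.tanh(params.W_c @ g + params.b_c)
    o = _sigmoid(params.W_o @ g + params.b_o)
    return o * np.tanh(c_t), c_t


def bilstm(
    inputs: Sequence[np.ndarray],
    forward_params: LstmParams,
    backward_params: LstmParams,
    mode: str = "last",
) -> np.ndarray:
    """Bidirectional LSTM over a sequence of input vectors, h_0 = c_0 = 0.

    mode "last": concatenation of the final forward and final backward hidden
    states (length 2*hidden).  mode "full": per-position concatenation of the
    forward state at i and the backward state at i (shape (n, 2*hidden)).
    """
    if len(inputs) == 0:
        raise ValueError("bilstm requires a nonempty sequence")
    if mode not in ("last", "full"):
        raise ValueError(f"unknown mode {mode!r}")

    def run(params: LstmParams, seq) -> list[np.ndarray]:
        h = np.zeros(params.hidden)
        c = np.zeros(params.hidden)
        states = []
        for z in seq:
            h, c = lstm_step(np.asarray(z, dtype=float), h, c, params)
            states.append(h)
        return states

    fwd = run(forward_params, inputs)
    bwd = run(backward_params, list(inputs)[::-1])
    if mode == "last":
        return np.concatenate([fwd[-1], bwd[-1]])
    bwd = bwd[::-1]
    return np.stack([np.concatenate([f, b]) for f, b in zip(fwd, bwd)])


def token_embedding(
    token: str,
    table: EmbeddingTable,
    char_fwd: LstmParams,
    char_bwd: LstmParams,
) -> np.ndarray:
    """Character-enhanced token embedding e = [x, h^for, h^back]."""
    idx = token_char_indices(token)
    onehots = np.zeros((len(idx), CHAR_ONEHOT_DIM))
    onehots[np.arange(len(idx)), idx] = 1.0
    char_vec = bilstm(list(onehots), char_fwd, char_bwd, mode="last")
    return np.concatenate([table.lookup(token), char_vec])


# ---------------------------------------------------------------------------
# Fast sequence kernels (stacked-gate form).  These compute exactly the same
# arithmetic as lstm_step; equivalence is asserted in the test suite.


def _seq_forward(W: np.ndarray, b: np.ndarray, X: np.ndarray) -> dict:
    """Unidirectional pass over X (T, d_in); returns hidden sequence + cache."""
    T, d_in = X.shape
    h3 = W.shape[0]
    hidden = h3 // 3
    h = np.zeros(hidden)
    c = np.zeros(hidden)
    g_all = np.empty((T, W.shape[1]))
    g_all[:, :d_in] = X
    gates = np.empty((T, h3))  # i | cbar | o, post-nonlinearity
    cprev_all = np.empty((T, hidden))
    tanh_c_all = np.empty((T, hidden))
    h_all = np.empty((T, hidden))
    Wt = W.T
    for t in range(T):
        g_all[t, d_in:] = h
        pre = g_all[t] @ Wt + b
        i = _sigmoid(pre[:hidden] + 1.0)
        cbar = np.tanh(pre[hidden : 2 * hidden])
        o = _sigmoid(pre[2 * hidden :])
        cprev_all[t] = c
        c = i * c + (1.0 - i) * cbar
        tc = np.tanh(c)
        h = o * tc
        gates[t, :hidden] = i
        gates[t, hidden : 2 * hidden] = cbar
        gates[t, 2 * hidden :] = o
        tanh_c_all[t] = tc
        h_all[t] = h
    return {
        "g": g_all,
        "gates": gates,
        "c_prev": cprev_all,
        "tanh_c": tanh_c_all,
        "h": h_all,
        "d_in": d_in,
    }


def _seq_backward(
    W: np.ndarray,
    cache: dict,
    dh_seq: np.ndarray,
    dW: np.ndarray,
    db: np.ndarray,
) -> np.ndarray:
    """Backprop through _seq_forward; dh_seq (T, hidden) is the per-position
    gradient injected into the hidden states.  Accumulates into dW, db and
    returns dX (T, d_in)."""
    T, hidden = dh_seq.shape
    d_in = cache["d_in"]
    gates, tanh_c, c_prev = cache["gates"], cache["tanh_c"], cache["c_prev"]
    da_all = np.empty((T, 3 * hidden))
    dX = np.empty((T, d_in))
    dh = np.zeros(hidden)
    dc = np.zeros(hidden)
    for t in range(T - 1, -1, -1):
        dh = dh + dh_seq[t]
        i = gates[t, :hidden]
        cbar = gates[t, hidden : 2 * hidden]
        o = gates[t, 2 * hidden :]
        tc = tanh_c[t]
        dc = dc + dh * o * (1.0 - tc * tc)
        da = da_all[t]
        da[2 * hidden :] = dh * tc * o * (1.0 - o)
        da[:hidden] = dc * (c_prev[t] - cbar) * i * (1.0 - i)
        da[hidden : 2 * hidden] = dc * (1.0 - i) * (1.0 - cbar * cbar)
        dc = dc * i
        dg = da @ W
        dX[t] = dg[:d_in]
        dh = dg[d_in:]
    dW += da_all.T @ cache["g"]
    db += da_all.sum(axis=0)
    return dX


def _char_forward(
    W: np.ndarray, b: np.ndarray, idx: np.ndarray, mask: np.ndarray
) -> dict:
    """Shared-weight character LSTM over a batch of tokens.

    idx (B, L) holds padded character one-hot indices, mask (B, L) marks real
    positions.  Finished rows carry their state unchanged, so the final h is
    each token's last valid hidden state.  Returns final h (B, hidden) + cache.
    """
    B, L = idx.shape
    h3, width = W.shape
    hidden = h3 // 3
    n_chars = width - hidden
    Wh = W[:, n_chars:]
    Wht = Wh.T
    x_pre = W[:, :n_chars].T[idx]  # (B, L, 3h): per-position one-hot lookups
    h = np.zeros((B, hidden))
    c = np.zeros((B, hidden))
    store = {
        k: np.empty((L, B, hidden))
        for k in ("i", "cbar", "o", "c_prev", "tanh_c", "h_prev")
    }
    for t in range(L):
        pre = x_pre[:, t] + h @ Wht + b
        i = _sigmoid(pre[:, :hidden] + 1.0)
        cbar = np.tanh(pre[:, hidden : 2 * hidden])
        o = _sigmoid(pre[:, 2 * hidden :])
        c_new = i * c + (1.0 - i) * cbar
        tc = np.tanh(c_new)
        h_new = o * tc
        m = mask[:, t : t + 1]
        store["i"][t], store["cbar"][t], store["o"][t] = i, cbar, o
        store["c_prev"][t], store["tanh_c"][t], store["h_prev"][t] = c, tc, h
        h = np.where(m, h_new, h)
        c = np.where(m, c_new, c)
    store["h_final"] = h
    store["Wx_width"] = n_chars
    return store


def _char_backward(
    W: np.ndarray,
    cache: dict,
    idx: np.ndarray,
    mask: np.ndarray,
    dh_final: np.ndarray,
    dW: np.ndarray,
    db: np.ndarray,
) -> None:
    """Backprop through _char_forward, accumulating into dW and db."""
    B, L = idx.shape
    hidden = dh_final.shape[1]
    n_chars = cache["Wx_width"]
    Wh = W[:, n_chars:]
    da_all = np.empty((L, B, 3 * hidden))
    dh = dh_final.copy()
    dc = np.zeros_like(dh)
    for t in range(L - 1, -1, -1):
        m = mask[:, t : t + 1]
        i, cbar, o = cache["i"][t], cache["cbar"][t], cache["o"][t]
        tc = cache["tanh_c"][t]
        dc_tot = dc + dh * o * (1.0 - tc * tc)
        da = da_all[t]
        da[:, 2 * hidden :] = dh * tc * o * (1.0 - o)
        da[:, :hidden] = dc_tot * (cache["c_prev"][t] - cbar) * i * (1.0 - i)
        da[:, hidden : 2 * hidden] = dc_tot * (1.0 - i) * (1.0 - cbar * cbar)
        da *= m
        dg_h = da @ Wh
        dh = np.where(m, dg_h, dh)
        dc = np.where(m, dc_tot * i, dc)
    # accumulate weight gradients in bulk
    da_flat = da_all.reshape(L * B, 3 * hidden)
    np.add.at(dW[:, :n_chars].T, idx.T.reshape(-1), da_flat)
    h_prev_flat = cache["h_prev"].reshape(L * B, hidden)
    dW[:, n_chars:] += da_flat.T @ h_prev_flat
    db += da_flat.sum(axis=0)


# ---------------------------------------------------------------------------
# Document-level forward / loss / gradient

_WORD_MATRIX_CACHE: "weakref.WeakKeyDictionary" = None  # type: ignore[assignment]


def _word_matrix(table: EmbeddingTable, tokens: tuple[str, ...]) -> np.ndarray:
    """Stacked word vectors for a token tuple, memoized per table."""
    global _WORD_MATRIX_CACHE
    if _WORD_MATRIX_CACHE is None:
        import weakref

        _WORD_MATRIX_CACHE = weakref.WeakKeyDictionary()
    per_table = _WORD_MATRIX_CACHE.setdefault(table, {})
    X = per_table.get(tokens)
    if X is None:
        X = np.stack([table.lookup(t) for t in tokens])
        per_table[tokens] = X
    return X


@dataclass
class TaggerOutput:
    """Per-token posterior label probabilities plus optional diagnostics."""

    probabilities: np.ndarray  # (n_tokens, n_labels)
    embeddings: np.ndarray | None = None  # e sequence (n_tokens, e_dim)
    states: np.ndarray | None = None  # d sequence (n_tokens, d_dim)


@lru_cache(maxsize=65536)
def _char_index_batch(tokens: tuple[str, ...]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Padded (fwd, rev) character index matrices and validity mask.

    Memoized on the token tuple: documents are revisited every epoch and
    their character encodings never change.
    """
    seqs = [token_char_indices(t) for t in tokens]
    B = len(seqs)
    L = max(len(s) for s in seqs)
    idx = np.zeros((B, L), dtype=np.intp)
    idx_rev = np.zeros((B, L), dtype=np.intp)
    mask = np.zeros((B, L), dtype=bool)
    for r, s in enumerate(seqs):
        idx[r, : len(s)] = s
        idx_rev[r, : len(s)] = s[::-1]
        mask[r, : len(s)] = True
    return idx, idx_rev, mask


def _forward_pass(
    doc: LabeledDocument,
    p: ParameterVector,
    table: EmbeddingTable,
    dropout_seed: int | None,
    need_cache: bool,
) -> dict:
    config = p.config
    if table.dim != config.word_dim:
        raise ValueError(
            f"embedding table dim {table.dim} != config word_dim {config.word_dim}"
        )
    n = len(doc)
    X = _word_matrix(table, doc.tokens)
    idx, idx_rev, mask = _char_index_batch(doc.tokens)

    Wcf, bcf = p._stacked(p.values, "char_fwd")
    Wcb, bcb = p._stacked(p.values, "char_bwd")
    cache_cf = _char_forward(Wcf, bcf, idx, mask)
    cache_cb = _char_forward(Wcb, bcb, idx_rev, mask)
    e = np.concatenate([X, cache_cf["h_final"], cache_cb["h_final"]], axis=1)

    drop_keep = None
    e_in = e
    if dropout_seed is not None and config.dropout_rate > 0.0:
        rng = np.random.default_rng(dropout_seed)
        drop_keep = (rng.random(e.shape) >= config.dropout_rate) / (
            1.0 - config.dropout_rate
        )
        e_in = e * drop_keep

    Wlf, blf = p._stacked(p.values, "label_fwd")
    Wlb, blb = p._stacked(p.values, "label_bwd")
    cache_lf = _seq_forward(Wlf, blf, e_in)
    cache_lb = _seq_forward(Wlb, blb, e_in[::-1])
    d = np.concatenate([cache_lf["h"], cache_lb["h"][::-1]], axis=1)

    W1, b1 = p.view("W_1"), p.view("b_1")
    W2, b2 = p.view("W_2"), p.view("b_2")
    l = np.tanh(d @ W1.T + b1)
    logits = l @ W2.T + b2
    logits -= logits.max(axis=1, keepdims=True)
    exp = np.exp(logits)
    a = exp / exp.sum(axis=1, keepdims=True)

    out = {"a": a, "e": e, "d": d, "l": l, "n": n}
    if need_cache:
        out.update(
            cache_cf=cache_cf,
            cache_cb=cache_cb,
            cache_lf=cache_lf,
            cache_lb=cache_lb,
            idx=idx,
            idx_rev=idx_rev,
            mask=mask,
            drop_keep=drop_keep,
            e_in=e_in,
        )
    return out


def forward(
    doc: LabeledDocument,
    p: ParameterVector,
    table: EmbeddingTable,
    dropout_seed: int | None = None,
    return_diagnostics: bool = False,
) -> TaggerOutput:
    """Posterior label probabilities for every token of a document.

    Passing ``dropout_seed`` switches to training mode: inverted dropout with
    the configured rate is applied to the embedding sequence with a mask
    drawn from that seed.  ``dropout_seed=None`` is inference mode.
    """
    res = _forward_pass(doc, p, table, dropout_seed, need_cache=False)
    return TaggerOutput(
        probabilities=res["a"],
        embeddings=res["e"] if return_diagnostics else None,
        states=res["d"] if return_diagnostics else None,
    )


def predict_labels(
    doc: LabeledDocument,
    p: ParameterVector,
    table: EmbeddingTable,
    scheme: LabelScheme | None = None,
) -> list[str]:
    """Most probable label per token (inference mode; lowest index on ties)."""
    scheme = scheme or build_label_scheme()
    a = _forward_pass(doc, p, table, None, need_cache=False)["a"]
    return [scheme.labels[j] for j in a.argmax(axis=1)]


def _label_indices(doc: LabeledDocument, scheme: LabelScheme) -> np.ndarray:
    return np.array([scheme.index_of(lab) for lab in doc.labels], dtype=np.intp)


def loss(
    p: ParameterVector,
    doc: LabeledDocument,
    table: EmbeddingTable,
    dropout_seed: int | None = None,
    scheme: LabelScheme | None = None,
) -> float:
    """Cross-entropy E(p) = -sum_i log a_i[class(t_i)] for one document."""
    scheme = scheme or build_label_scheme()
    res = _forward_pass(doc, p, table, dropout_seed, need_cache=False)
    y = _label_indices(doc, scheme)
    probs = res["a"][np.arange(len(y)), y]
    return float(-np.log(np.maximum(probs, 1e-300)).sum())


def loss_and_gradient(
    p: ParameterVector,
    doc: LabeledDocument,
    table: EmbeddingTable,
    dropout_seed: int | None = None,
    scheme: LabelScheme | None = None,
) -> tuple[float, np.ndarray]:
    """Cross-entropy and its gradient w.r.t. every entry of the flat vector."""
    scheme = scheme or build_label_scheme()
    config = p.config
    res = _forward_pass(doc, p, table, dropout_seed, need_cache=True)
    n = res["n"]
    y = _label_indices(doc, scheme)
    a, d, l = res["a"], res["d"], res["l"]
    value = float(-np.log(np.maximum(a[np.arange(n), y], 1e-300)).sum())

    grad = np.zeros_like(p.values)
    gview = ParameterVector(grad, config, p.index_map)

    # feedforward head
    dlogits = a.copy()
    dlogits[np.arange(n), y] -= 1.0
    W2 = p.view("W_2")
    gview.view("W_2")[...] = dlogits.T @ l
    gview.view("b_2")[...] = dlogits.sum(axis=0)
    dl = dlogits @ W2
    dpre1 = dl * (1.0 - l * l)
    W1 = p.view("W_1")
    gview.view("W_1")[...] = dpre1.T @ d
    gview.view("b_1")[...] = dpre1.sum(axis=0)
    dd = dpre1 @ W1

    # label bi-LSTM
    H = config.label_hidden
    Wlf, _ = p._stacked(p.values, "label_fwd")
    Wlb, _ = p._stacked(p.values, "label_bwd")
    dWlf, dblf = gview._stacked(grad, "label_fwd")
    dWlb, dblb = gview._stacked(grad, "label_bwd")
    de_in = _seq_backward(Wlf, res["cache_lf"], dd[:, :H], dWlf, dblf)
    de_rev = _seq_backward(Wlb, res["cache_lb"], dd[:, H:][::-1], dWlb, dblb)
    de_in = de_in + de_rev[::-1]

    if res["drop_keep"] is not None:
        de = de_in * res["drop_keep"]
    else:
        de = de_in

    # character bi-LSTMs (only the char halves of e carry parameters)
    wd, Hc = config.word_dim, config.char_hidden
    Wcf, _ = p._stacked(p.values, "char_fwd")
    Wcb, _ = p._stacked(p.values, "char_bwd")
    dWcf, dbcf = gview._stacked(grad, "char_fwd")
    dWcb, dbcb = gview._stacked(grad, "char_bwd")
    _char_backward(
        Wcf, res["cache_cf"], res["idx"], res["mask"], de[:, wd : wd + Hc], dWcf, dbcf
    )
    _char_backward(
        Wcb, res["cache_cb"], res["idx_rev"], res["mask"], de[:, wd + Hc :], dWcb, dbcb
    )
    return value, grad


def gradient(
    p: ParameterVector,
    doc: LabeledDocument,
    table: EmbeddingTable,
    dropout_seed: int | None = None,
    scheme: LabelScheme | None = None,
) -> np.ndarray:
    """Backpropagated gradient of the cross-entropy loss (flat vector)."""
    return loss_and_gradient(p, doc, table, dropout_seed, scheme)[1]


# ---------------------------------------------------------------------------
# Checkpoints


def save_checkpoint(path, p: ParameterVector, scheme: LabelScheme | None = None) -> None:
    """Write config, label scheme, index map and values as JSON.

    Values round-trip exactly (float hex encoding), so save→load reproduces
    predictions bitwise.
    """
    scheme = scheme or build_label_scheme()
    payload = {
        "config": asdict(p.config),
        "labels": list(scheme.labels),
        "index_map": {k: list(v) for k, v in p.index_map.items()},
        "values_hex": [v.hex() for v in p.values.tolist()],
    }
    Path(path).write_text(json.dumps(payload), encoding="utf-8")


def load_checkpoint(path) -> tuple[ParameterVector, LabelScheme]:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    config = NetworkConfig(**payload["config"])
    values = np.array([float.fromhex(h) for h in payload["values_hex"]])
    labels = tuple(payload["labels"])
    scheme = LabelScheme(labels=labels, index={lab: i for i, lab in enumerate(labels)})
    p = ParameterVector(values, config)
    saved_map = {k: tuple(v) for k, v in payload["index_map"].items()}
    if saved_map != p.index_map:
        raise ValueError("checkpoint index map does not match its config")
    return p, scheme
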