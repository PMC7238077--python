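"""The four training regimes for the tagger.

* **Centralized** — plain per-sample SGD over the pooled corpus; the
  non-protective baseline (all data at one site).
* **Round robin** — K workers hold private subsets; per global epoch the
  current weights pass through workers 1..K in fixed order, each running one
  local SGD epoch (cyclic weight transfer; data stay local, weights do not).
* **DSSGD** — distributed selective stochastic gradient descent.  Workers
  train locally and exchange only *selected* parameter updates through a
  server that keeps the global vector p_glo plus a per-parameter update
  counter.  One local epoch: download the floor(theta_d * len(p)) global
  values with the highest update counts (overwriting the local copies), run
  one SGD epoch, form delta = p_after - p_at_epoch_start, keep entries with
  |delta| > tau, clamp to [-gamma, +gamma], uniformly subsample down to
  floor(theta_u * len(p)) entries, and upload them as additive deltas.
* **Local-only** — K workers train independently with no communication.

Asynchrony is simulated in-process: each round the workers run in a seeded
random order, each seeing the server state exactly as the previous worker
left it.  All randomness (epoch shuffles, dropout masks, upload sampling,
the schedule) derives from explicit seeds, so every regime is bitwise
reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .corpus import CorpusPartition, LabeledDocument
from .encoders import EmbeddingTable
from .labels import LabelScheme, build_label_scheme
from .network import ParameterVector, loss_and_gradient

__all__ = [
    "WorkerConfig",
    "ServerState",
    "SparseUpdate",
    "sgd_epoch",
    "train_centralized",
    "train_round_robin",
    "select_updates",
    "server_download",
    "server_upload",
    "dssgd_worker_epoch",
    "train_dssgd",
    "train_local_only",
]

EvalHook = Callable[[int, int, ParameterVector], None]  # (worker, epoch, params)


def _epoch_rng(seed: int, epoch: int, worker: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, epoch, worker]))


@dataclass(frozen=True)
class WorkerConfig:
    """Per-worker DSSGD hyperparameters.

    theta_d / theta_u: download / upload rates as fractions of the full
    parameter vector.  gamma: clamp bound on shared update magnitudes
    (``math.inf`` disables clamping).  tau: strict minimum magnitude below
    which updates are withheld.  eta: local SGD learning rate.
    """

    theta_d: float
    theta_u: float
    gamma: float
    tau: float
    eta: float
    seed: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta_d <= 1.0:
            raise ValueError("theta_d must be in [0, 1]")
        if not 0.0 <= self.theta_u <= 1.0:
            raise ValueError("theta_u must be in [0, 1]")
        if not self.gamma > 0.0:
            raise ValueError("gamma must be positive")
        if self.tau < 0.0:
            raise ValueError("tau must be nonnegative")
        if self.eta <= 0.0:
            raise ValueError("eta must be positive")


@dataclass
class ServerState:
    """Global weights plus per-parameter update statistics."""

    p_glo: np.ndarray
    update_counts: np.ndarray
    n_uploads: int = 0
    n_clamped: int = 0  # diagnostic: uploaded values that hit the gamma bound

    @classmethod
    def initialize(cls, p0: ParameterVector) -> "ServerState":
        return cls(
            p_glo=p0.values.copy(),
            update_counts=np.zeros(len(p0), dtype=np.int64),
        )


@dataclass(frozen=True)
class SparseUpdate:
    """(parameter index, value) pairs with strictly increasing indices."""

    indices: np.ndarray
    values: np.ndarray
    n_clamped: int = 0

    def __post_init__(self) -> None:
        if self.indices.shape != self.values.shape:
            raise ValueError("indices and values must have equal length")
        if len(self.indices) and np.any(np.diff(self.indices) <= 0):
            raise ValueError("indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.indices)


# ---------------------------------------------------------------------------
# SGD


def sgd_epoch(
    p: ParameterVector,
    docs: Sequence[LabeledDocument],
    eta: float,
    seed: int,
    table: EmbeddingTable,
    scheme: LabelScheme | None = None,
    dropout: bool = True,
    normalize: bool = True,
) -> ParameterVector:
    """One epoch of per-sample SGD over a seeded shuffle of the documents.

    Each document gets its own dropout mask, seeded from the epoch seed, so
    the whole epoch is a pure function of (p, docs, eta, seed).

    With ``normalize`` (the default) the step for a document is
    ``eta * grad / n_tokens`` — gradient descent on the *mean* per-token
    cross-entropy.  The documented loss sums over a fragment's tokens, so an
    unnormalized step at the study's learning rate of 0.9 scales with the
    fragment length and overshoots for any realistic fragment; normalizing
    makes the step size length-invariant (for a 1-token document the two
    coincide).  ``normalize=False`` gives the literal update
    ``p - eta * grad(E)``.
    """
    if len(docs) == 0:
        raise ValueError("sgd_epoch requires at least one document")
    scheme = scheme or build_label_scheme()
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(docs))
    drop_seeds = rng.integers(0, 2**31, size=len(docs))
    p = p.copy()
    for pos, k in enumerate(order):
        doc = docs[k]
        ds = int(drop_seeds[pos]) if dropout else None
        _, g = loss_and_gradient(p, doc, table, dropout_seed=ds, scheme=scheme)
        step = eta / len(doc) if normalize else eta
        p.values -= step * g
    return p


def train_centralized(
    corpus: Sequence[LabeledDocument],
    p0: ParameterVector,
    table: EmbeddingTable,
    epochs: int,
    eta: float,
    seed: int,
    eval_hook: EvalHook | None = None,
    scheme: LabelScheme | None = None,
    dropout: bool = True,
) -> list[ParameterVector]:
    """Pooled-data SGD; returns the parameter trajectory (one entry per epoch)."""
    scheme = scheme or build_label_scheme()
    p = p0.copy()
    trajectory: list[ParameterVector] = []
    for epoch in range(epochs):
        p = sgd_epoch(
            p, corpus, eta, _epoch_seed(seed, epoch, 0), table, scheme, dropout
        )
        trajectory.append(p.copy())
        if eval_hook is not None:
            eval_hook(0, epoch, p)
    return trajectory


def _epoch_seed(seed: int, epoch: int, worker: int) -> int:
    return int(_epoch_rng(seed, epoch, worker).integers(0, 2**31))


def train_round_robin(
    partition: CorpusPartition,
    p0: ParameterVector,
    table: EmbeddingTable,
    epochs: int,
    eta: float,
    seed: int,
    eval_hook: EvalHook | None = None,
    scheme: LabelScheme | None = None,
    dropout: bool = True,
) -> list[ParameterVector]:
    """Cyclic weight transfer: worker k trains one local epoch, in fixed order.

    One *global* epoch = K local epochs.  The evaluation hook fires once per
    global epoch.  With K = 1 this reduces exactly to centralized training.
    """
    scheme = scheme or build_label_scheme()
    p = p0.copy()
    trajectory: list[ParameterVector] = []
    for epoch in range(epochs):
        for k, subset in enumerate(partition.subsets):
            p = sgd_epoch(
                p, subset, eta, _epoch_seed(seed, epoch, k), table, scheme, dropout
            )
        trajectory.append(p.copy())
        if eval_hook is not None:
            eval_hook(0, epoch, p)
    return trajectory


# ---------------------------------------------------------------------------
# DSSGD primitives


def select_updates(
    delta: np.ndarray,
    cfg: WorkerConfig,
    rng: np.random.Generator | None = None,
) -> SparseUpdate:
    """Select the parameter updates a worker shares after one local epoch.

    In order: strict threshold |delta| > tau, clamp to [-gamma, +gamma],
    uniform subsample down to floor(theta_u * len(delta)) entries (survivors
    below the cap are all kept).
    """
    rng = rng or np.random.default_rng(cfg.seed)
    survivors = np.flatnonzero(np.abs(delta) > cfg.tau)
    values = delta[survivors]
    if math.isfinite(cfg.gamma):
        clamped = np.clip(values, -cfg.gamma, cfg.gamma)
        n_clamped = int(np.count_nonzero(clamped != values))
        values = clamped
    else:
        n_clamped = 0
    cap = math.floor(cfg.theta_u * len(delta))
    if len(survivors) > cap:
        keep = rng.choice(len(survivors), size=cap, replace=False)
        keep.sort()
        survivors, values = survivors[keep], values[keep]
    return SparseUpdate(indices=survivors, values=values, n_clamped=n_clamped)


def server_download(state: ServerState, theta_d: float) -> SparseUpdate:
    """Global values of the floor(theta_d * len(p_glo)) most-updated parameters.

    Ties in the update counts break toward the lowest parameter index.
    """
    if not 0.0 <= theta_d <= 1.0:
        raise ValueError("theta_d must be in [0, 1]")
    k = math.floor(theta_d * len(state.p_glo))
    order = np.argsort(-state.update_counts, kind="stable")[:k]
    order.sort()
    return SparseUpdate(indices=order, values=state.p_glo[order].copy())


def server_upload(state: ServerState, update: SparseUpdate) -> ServerState:
    """Apply an uploaded sparse update (additive deltas) to the global state."""
    if len(update) and (
        update.indices.min() < 0 or update.indices.max() >= len(state.p_glo)
    ):
        raise IndexError("update index out of range")
    state.p_glo[update.indices] += update.values
    state.update_counts[update.indices] += 1
    state.n_uploads += 1
    state.n_clamped += update.n_clamped
    return state


AuditHook = Callable[[dict], None]


def dssgd_worker_epoch(
    local_p: ParameterVector,
    state: ServerState,
    docs: Sequence[LabeledDocument],
    cfg: WorkerConfig,
    table: EmbeddingTable,
    epoch: int = 0,
    worker: int = 0,
    scheme: LabelScheme | None = None,
    dropout: bool = True,
    audit: AuditHook | None = None,
) -> tuple[ParameterVector, SparseUpdate]:
    """One DSSGD local epoch: download, train, select, upload."""
    download = server_download(state, cfg.theta_d)
    local_p = local_p.copy()
    local_p.values[download.indices] = download.values
    p_start = local_p.values.copy()
    local_p = sgd_epoch(
        local_p, docs, cfg.eta, _epoch_seed(cfg.seed, epoch, worker),
        table, scheme, dropout,
    )
    delta = local_p.values - p_start
    update = select_updates(
        delta, cfg, rng=np.random.default_rng(
            np.random.SeedSequence([cfg.seed, epoch, worker, 1])
        ),
    )
    server_upload(state, update)
    if audit is not None:
        audit(
            {
                "worker": worker,
                "epoch": epoch,
                "delta": delta,
                "update": update,
                "download": download,
                "cfg": cfg,
            }
        )
    return local_p, update


def train_dssgd(
    partition: CorpusPartition,
    worker_cfgs: Sequence[WorkerConfig],
    p0: ParameterVector,
    table: EmbeddingTable,
    epochs: int,
    schedule_seed: int,
    eval_hook: EvalHook | None = None,
    scheme: LabelScheme | None = None,
    dropout: bool = True,
    audit: AuditHook | None = None,
) -> tuple[list[list[ParameterVector]], ServerState]:
    """Collaborative DSSGD over a patient-disjoint partition.

    Per round, every worker runs one local epoch; the order within a round is
    a seeded random permutation and the server is accessed serially, which
    simulates asynchronous exchanges reproducibly.  The evaluation hook fires
    once per worker per local epoch.  Returns per-worker parameter
    trajectories and the final server state.
    """
    K = len(partition.subsets)
    if len(worker_cfgs) != K:
        raise ValueError("need one WorkerConfig per subset")
    scheme = scheme or build_label_scheme()
    state = ServerState.initialize(p0)
    locals_: list[ParameterVector] = [p0.copy() for _ in range(K)]
    trajectories: list[list[ParameterVector]] = [[] for _ in range(K)]
    for epoch in range(epochs):
        order = np.random.default_rng(
            np.random.SeedSequence([schedule_seed, epoch])
        ).permutation(K)
        for k in order:
            locals_[k], _ = dssgd_worker_epoch(
                locals_[k], state, partition.subsets[k], worker_cfgs[k],
                table, epoch=epoch, worker=int(k), scheme=scheme,
                dropout=dropout, audit=audit,
            )
            trajectories[k].append(locals_[k].copy())
            if eval_hook is not None:
                eval_hook(int(k), epoch, locals_[k])
    return trajectories, state


def train_local_only(
    partition: CorpusPartition,
    p0: ParameterVector,
    table: EmbeddingTable,
    epochs: int,
    eta: float,
    seed: int,
    eval_hook: EvalHook | None = None,
    scheme: LabelScheme | None = None,
    dropout: bool = True,
) -> list[list[ParameterVector]]:
    """Isolated training: each worker runs SGD on its subset, no communication."""
    scheme = scheme or build_label_scheme()
    trajectories: list[list[ParameterVector]] = []
    for k, subset in enumerate(partition.subsets):
        p = p0.copy()
        traj: list[ParameterVector] = []
        for epoch in range(epochs):
            p = sgd_epoch(
                p, subset, eta, _epoch_seed(seed, epoch, k), table, scheme, dropout
            )
            traj.append(p.copy())
            if eval_hook is not None:
                eval_hook(k, epoch, p)
        trajectories.append(traj)
    return trajectories
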