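"""Experiment configuration, presets and the end-to-end runner.

The five bundled presets mirror the study design:

====== ===========================================================
A      centralized SGD over the pooled corpus (non-protective)
B      round robin over 5 workers (cyclic weight transfer)
C_0.1  DSSGD, 5 workers, theta_d=0.1, theta_u=0.5, gamma=10, tau=1e-4
C_0.5  DSSGD, 5 workers, theta_d=0.5, theta_u=0.5, gamma=10, tau=1e-4
D      isolated local training, 5 workers, no communication
====== ===========================================================

All presets use learning rate 0.9.  Epoch counts and network dimensions
default to desk scale (20 epochs, a reduced network) so a full comparison
runs on one CPU in minutes; both are plain config knobs for larger runs
(the full-scale study trained 200 epochs with char_hidden=128,
label_hidden=100, ff_hidden=100 over 300-dim word vectors).

The runner is deterministic: a single global seed derives the corpus,
embedding table, weight initialization, partition, epoch shuffles, dropout
masks, upload sampling and the DSSGD schedule, so identical configs produce
identical run logs.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path
import yaml

from .corpus import (
    LabeledDocument,
    partition_by_patient,
    read_token_label_file,
)
from .encoders import EmbeddingTable, load_embedding_table, make_random_table
from .evaluation import evaluate_tagger
from .labels import build_label_scheme
from .network import (
    NetworkConfig,
    ParameterVector,
    init_parameters,
    parameter_length,
)
from .synthetic import CorpusSpec, generate_corpus, split_train_test
from .training import (
    WorkerConfig,
    train_centralized,
    train_dssgd,
    train_local_only,
    train_round_robin,
)

__all__ = ["ExperimentConfig", "PRESETS", "run_experiment", "load_config"]

STRATEGIES = ("centralized", "round_robin", "dssgd", "local")


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to reproduce one training run."""

    preset: str = "custom"
    strategy: str = "centralized"
    n_workers: int = 1
    epochs: int = 20
    eta: float = 0.9
    theta_d: float = 0.1
    theta_u: float = 0.5
    gamma: float = 10.0
    tau: float = 1e-4
    seed: int = 0
    eval_every: int = 1  # evaluate every this many epochs (always incl. last)
    # network scale (desk defaults; full-scale study: 300/128/100/100)
    word_dim: int = 50
    char_hidden: int = 16
    label_hidden: int = 32
    ff_hidden: int = 32
    dropout_rate: float = 0.5
    # data: either a corpus file + test fraction, or a generated corpus
    corpus_path: str | None = None
    embeddings_path: str | None = None
    test_fraction: float = 0.39
    corpus_spec: CorpusSpec | None = None

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.strategy == "centralized" and self.n_workers != 1:
            raise ValueError("centralized training uses a single worker")
        if self.epochs < 0:
            raise ValueError("epochs must be nonnegative")

    def network_config(self) -> NetworkConfig:
        return NetworkConfig(
            word_dim=self.word_dim,
            char_hidden=self.char_hidden,
            label_hidden=self.label_hidden,
            ff_hidden=self.ff_hidden,
            dropout_rate=self.dropout_rate,
        )

    def worker_configs(self) -> list[WorkerConfig]:
        return [
            WorkerConfig(
                theta_d=self.theta_d,
                theta_u=self.theta_u,
                gamma=self.gamma,
                tau=self.tau,
                eta=self.eta,
                seed=self.seed,
            )
            for _ in range(self.n_workers)
        ]


def _preset(name: str, **kw) -> ExperimentConfig:
    return ExperimentConfig(preset=name, **kw)


PRESETS: dict[str, ExperimentConfig] = {
    "A": _preset("A", strategy="centralized", n_workers=1, eta=0.9),
    "B": _preset("B", strategy="round_robin", n_workers=5, eta=0.9),
    "C_0.1": _preset(
        "C_0.1", strategy="dssgd", n_workers=5,
        theta_d=0.1, theta_u=0.5, gamma=10.0, tau=1e-4, eta=0.9,
    ),
    "C_0.5": _preset(
        "C_0.5", strategy="dssgd", n_workers=5,
        theta_d=0.5, theta_u=0.5, gamma=10.0, tau=1e-4, eta=0.9,
    ),
    "D": _preset("D", strategy="local", n_workers=5, eta=0.9),
}


def load_config(path) -> ExperimentConfig:
    """Read an experiment config from YAML; a ``preset`` key supplies defaults."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    preset = raw.pop("preset", "custom")
    if preset != "custom":
        if preset not in PRESETS:
            raise ValueError(f"unknown preset {preset!r}")
        base = dataclasses.asdict(PRESETS[preset])
        base.pop("corpus_spec")
    else:
        base = {}
    spec_raw = raw.pop("corpus_spec", None)
    base.update(raw)
    base["preset"] = preset
    if spec_raw is not None:
        for key in ("records_per_patient", "tokens_per_record"):
            if key in spec_raw:
                spec_raw[key] = tuple(spec_raw[key])
        base["corpus_spec"] = CorpusSpec(**spec_raw)
    return ExperimentConfig(**base)


@dataclass
class ExperimentResult:
    """Run log records, final per-worker parameters, and the data context."""

    config: ExperimentConfig
    records: list[dict]
    final_params: list[ParameterVector]
    train_docs: list[LabeledDocument]
    test_docs: list[LabeledDocument]
    table: EmbeddingTable
    server_state: object | None = None


def _prepare_data(
    config: ExperimentConfig,
) -> tuple[list[LabeledDocument], list[LabeledDocument], EmbeddingTable]:
    if config.corpus_path is not None:
        corpus = read_token_label_file(config.corpus_path)
    else:
        spec = config.corpus_spec or CorpusSpec(seed=config.seed)
        corpus = generate_corpus(spec)
    train, test = split_train_test(corpus, config.test_fraction, config.seed)
    if config.embeddings_path is not None:
        table = load_embedding_table(config.embeddings_path)
    else:
        vocab = {t for d in train for t in d.tokens}
        table = make_random_table(vocab, dim=config.word_dim, seed=config.seed)
    if table.dim != config.word_dim:
        raise ValueError(
            f"embedding dim {table.dim} does not match word_dim {config.word_dim}"
        )
    return list(train), list(test), table


def run_experiment(
    config: ExperimentConfig,
    audit=None,
) -> ExperimentResult:
    """Run one training regime end to end and score it on the test split."""
    scheme = build_label_scheme()
    train, test, table = _prepare_data(config)
    p0 = init_parameters(config.network_config(), config.seed)
    records: list[dict] = []
    strategy = config.strategy

    def hook(worker: int, epoch: int, p: ParameterVector) -> None:
        last = epoch == config.epochs - 1
        if not last and (epoch + 1) % config.eval_every != 0:
            return
        m = evaluate_tagger(test, p, table, scheme)
        records.append(
            {
                "strategy": strategy,
                "worker": worker,
                "epoch": epoch,
                "precision": m.precision,
                "recall": m.recall,
                "f1": m.f1,
            }
        )

    server_state = None
    if strategy == "centralized":
        traj = train_centralized(
            train, p0, table, config.epochs, config.eta, config.seed,
            eval_hook=hook, scheme=scheme,
        )
        finals = [traj[-1] if traj else p0]
    elif strategy == "round_robin":
        part = partition_by_patient(train, config.n_workers, config.seed)
        traj = train_round_robin(
            part, p0, table, config.epochs, config.eta, config.seed,
            eval_hook=hook, scheme=scheme,
        )
        finals = [traj[-1] if traj else p0]
    elif strategy == "dssgd":
        part = partition_by_patient(train, config.n_workers, config.seed)
        trajs, server_state = train_dssgd(
            part, config.worker_configs(), p0, table, config.epochs,
            config.seed, eval_hook=hook, scheme=scheme, audit=audit,
        )
        finals = [tr[-1] if tr else p0 for tr in trajs]
    else:  # local
        part = partition_by_patient(train, config.n_workers, config.seed)
        trajs = train_local_only(
            part, p0, table, config.epochs, config.eta, config.seed,
            eval_hook=hook, scheme=scheme,
        )
        finals = [tr[-1] if tr else p0 for tr in trajs]

    return ExperimentResult(
        config=config,
        records=records,
        final_params=finals,
        train_docs=train,
        test_docs=test,
        table=table,
        server_state=server_state,
    )


def write_manifest(path, config: ExperimentConfig) -> None:
    """Snapshot the exact configuration next to a run's outputs."""
    payload = dataclasses.asdict(config)
    if config.corpus_spec is not None:
        payload["corpus_spec"] = dataclasses.asdict(config.corpus_spec)
    payload["parameter_count"] = parameter_length(config.network_config())
    payload["upload_cap"] = math.floor(config.theta_u * payload["parameter_count"])
    Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")
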