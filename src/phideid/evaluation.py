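"""Binary PHI-vs-non-PHI token scoring and learning-curve aggregation.

Scoring follows the de-identification convention: a token counts as a true
positive iff both the prediction and the gold label are *some* PHI class —
the specific class is ignored.  Counts are micro-aggregated over all scored
tokens (the whole test set), and F1 = 2PR/(P+R) is the headline number
because PHI tokens are rare (class imbalance makes accuracy uninformative).

Degenerate case: a score over tokens with no gold PHI and no predicted PHI
is defined as precision = recall = F1 = 1.0 (vacuously perfect).  Corpus
level scores are unaffected in practice; this only matters for per-fragment
diagnostics on PHI-free fragments.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .corpus import LabeledDocument
from .labels import LabelScheme, build_label_scheme

__all__ = [
    "PhiMetrics",
    "binary_phi_scores",
    "evaluate_tagger",
    "write_run_log",
    "read_run_log",
    "aggregate_curves",
]

RUN_LOG_COLUMNS = ["strategy", "worker", "epoch", "precision", "recall", "f1"]


@dataclass(frozen=True)
class PhiMetrics:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def precision(self) -> float:
        if self.tp == 0:
            return 1.0 if self.fp == 0 and self.fn == 0 else 0.0
        return self.tp / (self.tp + self.fp)

    @property
    def recall(self) -> float:
        if self.tp == 0:
            return 1.0 if self.fp == 0 and self.fn == 0 else 0.0
        return self.tp / (self.tp + self.fn)

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 0.0 if p + r == 0.0 else 2.0 * p * r / (p + r)

    def __add__(self, other: "PhiMetrics") -> "PhiMetrics":
        return PhiMetrics(
            self.tp + other.tp, self.fp + other.fp,
            self.fn + other.fn, self.tn + other.tn,
        )


def binary_phi_scores(
    pred_labels: Sequence[str],
    gold_labels: Sequence[str],
    scheme: LabelScheme | None = None,
) -> PhiMetrics:
    """Token-level PHI-vs-non-PHI counts; PHI class identity is ignored."""
    scheme = scheme or build_label_scheme()
    if len(pred_labels) != len(gold_labels):
        raise ValueError(
            f"{len(pred_labels)} predictions vs {len(gold_labels)} gold labels"
        )
    tp = fp = fn = tn = 0
    for pred, gold in zip(pred_labels, gold_labels):
        p_phi = scheme.is_phi(pred)
        g_phi = scheme.is_phi(gold)
        if p_phi and g_phi:
            tp += 1
        elif p_phi:
            fp += 1
        elif g_phi:
            fn += 1
        else:
            tn += 1
    return PhiMetrics(tp, fp, fn, tn)


def evaluate_tagger(
    docs: Iterable[LabeledDocument],
    p,
    table,
    scheme: LabelScheme | None = None,
) -> PhiMetrics:
    """Micro-aggregated binary PHI score of a tagger over a document set."""
    from .network import predict_labels

    scheme = scheme or build_label_scheme()
    total = PhiMetrics(0, 0, 0, 0)
    for doc in docs:
        pred = predict_labels(doc, p, table, scheme)
        total = total + binary_phi_scores(pred, doc.labels, scheme)
    return total


def write_run_log(path, records: Sequence[dict]) -> None:
    """Write evaluation records as tab-separated text (one row per evaluation)."""
    frame = pd.DataFrame(list(records), columns=RUN_LOG_COLUMNS)
    frame.to_csv(path, sep="\t", index=False)


def read_run_log(path) -> pd.DataFrame:
    frame = pd.read_csv(Path(path), sep="\t")
    missing = set(RUN_LOG_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"run log is missing columns: {sorted(missing)}")
    return frame


def aggregate_curves(run_log) -> pd.DataFrame:
    """Per-strategy mean/min/max F1 per epoch across workers.

    Multi-worker strategies report the spread across workers; single-worker
    strategies pass through (mean = min = max).  Record order is irrelevant.
    """
    if isinstance(run_log, (str, Path)):
        run_log = read_run_log(run_log)
    else:
        run_log = pd.DataFrame(list(run_log), columns=RUN_LOG_COLUMNS)
    if len(run_log) == 0:
        raise ValueError("empty run log")
    grouped = (
        run_log.groupby(["strategy", "epoch"])["f1"]
        .agg(mean="mean", min="min", max="max")
        .reset_index()
        .sort_values(["strategy", "epoch"], kind="stable")
        .reset_index(drop=True)
    )
    return grouped
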