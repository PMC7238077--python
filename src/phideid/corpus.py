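"""Corpus containers, tokenization, file I/O and patient-disjoint partitioning.

A :class:`LabeledDocument` is one training/testing sequence — a fragment of a
clinical note (by convention one line of the source note) with one label per
token and the identifier of the patient the note belongs to.  Patient
identifiers matter because evaluation and multi-worker training must be
patient-disjoint: all records of one patient stay on one side of any split.

File format (UTF-8 text)::

    #doc <doc_id> <patient_id>
    <token>\\t<label>
    ...
    <blank line>            # separates fragments of the same note
    <token>\\t<label>
    ...
    #doc <next_doc_id> <patient_id>
    ...

Each fragment is read as its own :class:`LabeledDocument`; consecutive
documents sharing ``(doc_id, patient_id)`` are written back under a single
header, so write∘read is the identity on well-formed files.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .labels import LabelScheme, build_label_scheme

_TOKEN_RE = re.compile(r"\w+(?:[-.]\w+)*|[^\w\s]", re.UNICODE)


def tokenize(text: str) -> list[str]:
    """Deterministic regex tokenization into words and punctuation.

    Words keep internal hyphens and periods (``123-4567``, ``dr.smith`` stay
    single tokens); every other non-space character becomes its own token.
    No non-whitespace character of the input is lost.
    """
    return _TOKEN_RE.findall(text)


@dataclass(frozen=True)
class LabeledDocument:
    """One token sequence with per-token labels and a patient identifier."""

    doc_id: str
    patient_id: str
    tokens: tuple[str, ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.tokens) != len(self.labels):
            raise ValueError(
                f"{self.doc_id}: {len(self.tokens)} tokens but "
                f"{len(self.labels)} labels"
            )
        if len(self.tokens) == 0:
            raise ValueError(f"{self.doc_id}: empty document")
        if any(t == "" for t in self.tokens):
            raise ValueError(f"{self.doc_id}: empty token")

    def __len__(self) -> int:
        return len(self.tokens)


class CorpusFormatError(ValueError):
    """Raised for malformed token/label files; carries the line number."""

    def __init__(self, path, line_no: int, message: str):
        super().__init__(f"{path}:{line_no}: {message}")
        self.line_no = line_no


def read_token_label_file(
    path, scheme: LabelScheme | None = None
) -> list[LabeledDocument]:
    """Read a token/label corpus file, validating labels against the scheme."""
    scheme = scheme or build_label_scheme()
    path = Path(path)
    docs: list[LabeledDocument] = []
    doc_id: str | None = None
    patient_id: str | None = None
    tokens: list[str] = []
    labels: list[str] = []
    frag_start_line = 0

    def flush(line_no: int) -> None:
        nonlocal tokens, labels
        if not tokens:
            return
        if doc_id is None or patient_id is None:
            raise CorpusFormatError(path, frag_start_line, "tokens before #doc header")
        docs.append(
            LabeledDocument(doc_id, patient_id, tuple(tokens), tuple(labels))
        )
        tokens, labels = [], []

    with path.open(encoding="utf-8") as fh:
        line_no = 0
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if line.startswith("#doc"):
                flush(line_no)
                parts = line.split()
                if len(parts) != 3:
                    raise CorpusFormatError(
                        path, line_no, f"malformed header: {line!r}"
                    )
                _, doc_id, patient_id = parts
            elif line == "":
                flush(line_no)
            else:
                if "\t" not in line:
                    raise CorpusFormatError(
                        path, line_no, f"expected '<token>\\t<label>', got {line!r}"
                    )
                token, _, label = line.partition("\t")
                if token == "":
                    raise CorpusFormatError(path, line_no, "empty token")
                if label not in scheme:
                    raise CorpusFormatError(path, line_no, f"unknown label {label!r}")
                if not tokens:
                    frag_start_line = line_no
                tokens.append(token)
                labels.append(label)
        flush(line_no + 1)
    return docs


def write_token_label_file(path, docs: Sequence[LabeledDocument]) -> None:
    """Write documents in file order, grouping consecutive fragments of one note."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        prev_key = None
        for doc in docs:
            key = (doc.doc_id, doc.patient_id)
            if key != prev_key:
                fh.write(f"#doc {doc.doc_id} {doc.patient_id}\n")
                prev_key = key
            else:
                fh.write("\n")
            for token, label in zip(doc.tokens, doc.labels):
                fh.write(f"{token}\t{label}\n")


def read_i2b2_xml(path):  # pragma: no cover - declared interface, restricted data
    """Convert an i2b2 2014 challenge XML record to labeled documents.

    The challenge corpus is access-restricted and not redistributed here;
    this converter is declared for users who hold a data-use agreement.
    """
    raise NotImplementedError(
        "i2b2 2014 XML conversion is not bundled; convert records to the "
        "token/label text format documented in phideid.corpus instead"
    )


def split_long_documents(
    docs: Iterable[LabeledDocument], max_tokens: int = 100
) -> list[LabeledDocument]:
    """Split fragments longer than ``max_tokens`` into consecutive chunks."""
    if max_tokens < 1:
        raise ValueError("max_tokens must be >= 1")
    out: list[LabeledDocument] = []
    for doc in docs:
        if len(doc) <= max_tokens:
            out.append(doc)
            continue
        for start in range(0, len(doc), max_tokens):
            out.append(
                LabeledDocument(
                    doc.doc_id,
                    doc.patient_id,
                    doc.tokens[start : start + max_tokens],
                    doc.labels[start : start + max_tokens],
                )
            )
    return out


@dataclass(frozen=True)
class CorpusPartition:
    """K disjoint document subsets; all documents of a patient share a subset."""

    subsets: tuple[tuple[LabeledDocument, ...], ...]
    seed: int

    def __len__(self) -> int:
        return len(self.subsets)


def partition_by_patient(
    corpus: Sequence[LabeledDocument], K: int, seed: int
) -> CorpusPartition:
    """Partition a corpus into K patient-disjoint subsets of similar token size.

    Patients are shuffled with the given seed, sorted largest-first by total
    token count (stable, so equal-size patients keep their shuffled order),
    and greedily assigned to the currently smallest subset.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    by_patient: dict[str, list[LabeledDocument]] = {}
    for doc in corpus:
        by_patient.setdefault(doc.patient_id, []).append(doc)
    patients = list(by_patient)
    if len(patients) < K:
        raise ValueError(f"cannot split {len(patients)} patients into {K} subsets")

    rng = np.random.default_rng(seed)
    rng.shuffle(patients)
    patients.sort(key=lambda p: -sum(len(d) for d in by_patient[p]))

    owner: dict[str, int] = {}
    sizes = [0] * K
    for p in patients:
        k = min(range(K), key=lambda i: (sizes[i], i))
        owner[p] = k
        sizes[k] += sum(len(d) for d in by_patient[p])
    # subsets keep the original corpus order (so K=1 is the identity)
    subsets: list[list[LabeledDocument]] = [[] for _ in range(K)]
    for doc in corpus:
        subsets[owner[doc.patient_id]].append(doc)
    return CorpusPartition(
        subsets=tuple(tuple(s) for s in subsets), seed=seed
    )
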