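"""Abstract-corpus containers and text-format I/O.

A corpus holds three document populations used throughout the active
learning workflows: manually labeled positives, manually labeled
negatives, and a "random" pool drawn without review that is presumed
negative. Formats are plain text: an escaped TSV (lossless round trip)
and MEDLINE tagged records.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

from Bio import Medline

logger = logging.getLogger(__name__)


class Label(str, Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    UNLABELED = "unlabeled"


class PoolKind(str, Enum):
    LABELED = "labeled"
    RANDOM = "random"


@dataclass
class Document:
    """One abstract record.

    ``pool=RANDOM`` marks documents drawn without manual review; such a
    document stays UNLABELED until an oracle labels it.
    """

    doc_id: str
    title: str
    abstract: str
    label: Label = Label.UNLABELED
    pool: PoolKind = PoolKind.LABELED

    @property
    def text(self) -> str:
        return f"{self.title} {self.abstract}"


@dataclass
class Corpus:
    documents: list[Document]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for doc in self.documents:
            if doc.doc_id in seen:
                raise ValueError(f"duplicate doc_id: {doc.doc_id!r}")
            seen.add(doc.doc_id)

    def __len__(self) -> int:
        return len(self.documents)

    def __iter__(self):
        return iter(self.documents)

    def by_id(self, doc_id: str) -> Document:
        return self._index()[doc_id]

    def _index(self) -> dict[str, Document]:
        if not hasattr(self, "_idx") or len(self._idx) != len(self.documents):
            self._idx = {d.doc_id: d for d in self.documents}
        return self._idx

    def ids(self) -> list[str]:
        return [d.doc_id for d in self.documents]

    def subset(self, doc_ids: Iterable[str]) -> "Corpus":
        idx = self._index()
        return Corpus([idx[i] for i in doc_ids], provenance=dict(self.provenance))

    def pool_ids(self, pool: PoolKind) -> list[str]:
        return [d.doc_id for d in self.documents if d.pool is pool]

    def label_ids(self, label: Label) -> list[str]:
        return [d.doc_id for d in self.documents if d.label is label]


# ---------------------------------------------------------------------------
# TSV dialect: UTF-8, required header, backslash escaping of the three
# characters that would break the table (tab, newline, backslash), so the
# round trip is bit-exact for arbitrary printable text.

_COLUMNS = ("doc_id", "title", "abstract", "label", "pool")


def _escape(text: str) -> str:
    return (
        text.replace("\\", "\\\\")
        .replace("\t", "\\t")
        .replace("\r", "\\r")
        .replace("\n", "\\n")
    )


def _unescape(text: str) -> str:
    out: list[str] = []
    it = iter(range(len(text)))
    i = 0
    while i < len(text):
        ch = text[i]
        if ch == "\\" and i + 1 < len(text):
            nxt = text[i + 1]
            mapped = {"\\": "\\", "t": "\t", "n": "\n", "r": "\r"}.get(nxt)
            if mapped is not None:
                out.append(mapped)
                i += 2
                continue
        out.append(ch)
        i += 1
    return "".join(out)


def read_corpus_tsv(path: str | Path) -> Corpus:
    """Read a corpus from an escaped TSV file.

    Requires at least ``doc_id``, ``title`` and ``abstract`` columns.
    Missing/blank label means UNLABELED; missing pool defaults to LABELED
    for labeled documents and RANDOM for unlabeled ones.
    """
    path = Path(path)
    raw = path.read_text(encoding="utf-8")
    lines = raw.split("\n")
    if lines and lines[-1] == "":
        lines.pop()
    if not lines:
        raise ValueError(f"{path}: empty file, header row required")
    header = lines[0].split("\t")
    for required in ("doc_id", "title", "abstract"):
        if required not in header:
            raise ValueError(f"{path}: missing required column {required!r}")
    col = {name: j for j, name in enumerate(header)}
    docs: list[Document] = []
    seen: set[str] = set()
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != len(header):
            raise ValueError(
                f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}"
            )
        get = lambda name: _unescape(fields[col[name]]) if name in col else ""
        doc_id = get("doc_id")
        if doc_id in seen:
            raise ValueError(f"{path}:{lineno}: duplicate doc_id {doc_id!r}")
        seen.add(doc_id)
        label_raw = get("label").strip().lower()
        label = Label(label_raw) if label_raw else Label.UNLABELED
        pool_raw = get("pool").strip().lower()
        if pool_raw:
            pool = PoolKind(pool_raw)
        else:
            pool = PoolKind.LABELED if label is not Label.UNLABELED else PoolKind.RANDOM
        docs.append(Document(doc_id, get("title"), get("abstract"), label, pool))
    return Corpus(docs, provenance={"source": str(path)})


def write_corpus_tsv(corpus: Corpus, path: str | Path) -> None:
    path = Path(path)
    rows = ["\t".join(_COLUMNS)]
    for d in corpus:
        rows.append(
            "\t".join(
                (
                    _escape(d.doc_id),
                    _escape(d.title),
                    _escape(d.abstract),
                    d.label.value,
                    d.pool.value,
                )
            )
        )
    path.write_text("\n".join(rows) + "\n", encoding="utf-8")


def read_medline(path: str | Path, pool: PoolKind = PoolKind.RANDOM) -> Corpus:
    """Read MEDLINE tagged records (PMID-, TI-, AB- with continuations).

    Records without an abstract are kept with an empty abstract and
    logged; a record without a PMID is an error.
    """
    path = Path(path)
    docs: list[Document] = []
    with open(path, encoding="utf-8") as handle:
        for i, rec in enumerate(Medline.parse(handle)):
            pmid = rec.get("PMID")
            if not pmid:
                raise ValueError(f"{path}: record {i} has no PMID field")
            abstract = rec.get("AB", "")
            if not abstract:
                logger.info("record %s (PMID %s) has no abstract", i, pmid)
            docs.append(
                Document(
                    doc_id=pmid,
                    title=rec.get("TI", ""),
                    abstract=abstract,
                    label=Label.UNLABELED,
                    pool=pool,
                )
            )
    return Corpus(docs, provenance={"source": str(path), "format": "medline"})
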