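"""Reading and writing the triage file conventions.

Training corpora follow the ``Positive_<i>.json`` / ``Negative_<i>.json``
convention: each file holds a JSON array of paragraph strings and the filename
prefix is the gold label.  Keyword files are plain UTF-8 text with one keyword
per line.  Trained models and their tokenizer vocabulary persist as two JSON
artifacts with an embedded schema version and a SHA-256 payload checksum so
that a load either reproduces the training-time classifier bit for bit or
fails loudly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

from .errors import (
    ArtifactCorruptError,
    ArtifactNotFoundError,
    ArtifactVersionError,
    CorpusError,
    KeywordError,
)

logger = logging.getLogger(__name__)

RELEVANT = "relevant"
IRRELEVANT = "irrelevant"

ARTIFACT_SCHEMA_VERSION = 1
MODEL_FILE = "model.json"
VOCAB_FILE = "vocabulary.json"

_TRAINING_FILE_RE = re.compile(r"^(Positive|Negative)_(\d+)\.json$")


@dataclass
class Article:
    """One publication: an ordered list of paragraph strings.

    ``label`` is the gold annotation (``relevant`` / ``irrelevant``) and is
    present for every training article; ``source_quality`` records whether the
    text came from a publisher API (clean) or from PDF extraction (noisy).
    """

    id: str
    paragraphs: list[str]
    label: str | None = None
    source_quality: str = "api"


@dataclass
class Corpus:
    articles: list[Article] = field(default_factory=list)

    @property
    def class_counts(self) -> dict[str, int]:
        counts = {RELEVANT: 0, IRRELEVANT: 0}
        for a in self.articles:
            if a.label is not None:
                counts[a.label] = counts.get(a.label, 0) + 1
        return counts

    def __len__(self) -> int:
        return len(self.articles)


@dataclass
class KeywordSet:
    """Ordered, lowercased, deduplicated query keywords (may be phrases)."""

    keywords: list[str]

    def __post_init__(self) -> None:
        cleaned: list[str] = []
        seen: set[str] = set()
        for kw in self.keywords:
            k = kw.strip().lower()
            if not k:
                raise KeywordError("empty keyword not allowed")
            if k not in seen:
                seen.add(k)
                cleaned.append(k)
        if not cleaned:
            raise KeywordError("keyword set is empty")
        self.keywords = cleaned

    def __iter__(self):
        return iter(self.keywords)

    def __len__(self) -> int:
        return len(self.keywords)


def read_training_dir(path: str | Path) -> Corpus:
    """Read a training corpus from ``Positive_<i>.json`` / ``Negative_<i>.json`` files.

    The label is a pure function of the filename prefix; paragraph order is
    preserved.  Files matching neither prefix are skipped with a warning;
    malformed JSON or non-list content is a :class:`CorpusError` naming the
    file.
    """
    directory = Path(path)
    if not directory.is_dir():
        raise CorpusError(f"training directory not found: {directory}")
    articles: list[Article] = []
    entries = []
    for f in directory.iterdir():
        if not f.is_file():
            continue
        m = _TRAINING_FILE_RE.match(f.name)
        if m is None:
            logger.warning("skipping non-training file: %s", f.name)
            continue
        entries.append((m.group(1), int(m.group(2)), f))
    # deterministic order: label prefix, then numeric index
    entries.sort(key=lambda e: (e[0], e[1]))
    for prefix, _idx, f in entries:
        try:
            content = json.loads(f.read_text(encoding="utf-8"))
        except json.JSONDecodeError as exc:
            raise CorpusError(f"malformed JSON in {f.name}: {exc}") from exc
        if not isinstance(content, list) or not all(isinstance(p, str) for p in content):
            raise CorpusError(f"{f.name}: expected a JSON array of paragraph strings")
        label = RELEVANT if prefix == "Positive" else IRRELEVANT
        articles.append(Article(id=f.stem, paragraphs=content, label=label))
    if not articles:
        raise CorpusError(f"no training files found in {directory}")
    return Corpus(articles)


def write_training_dir(corpus: Corpus, path: str | Path) -> None:
    """Write a labeled corpus back out in the training file convention."""
    directory = Path(path)
    directory.mkdir(parents=True, exist_ok=True)
    counters = {RELEVANT: 0, IRRELEVANT: 0}
    for article in corpus.articles:
        if article.label not in counters:
            raise CorpusError(f"article {article.id} has no training label")
        counters[article.label] += 1
        prefix = "Positive" if article.label == RELEVANT else "Negative"
        name = f"{prefix}_{counters[article.label]}.json"
        (directory / name).write_text(
            json.dumps(article.paragraphs, ensure_ascii=False), encoding="utf-8"
        )


def read_keywords(path: str | Path) -> KeywordSet:
    """Read a keyword file: one keyword per non-blank line, order kept."""
    f = Path(path)
    if not f.is_file():
        raise KeywordError(f"keyword file not found: {f}")
    lines = [ln.strip() for ln in f.read_text(encoding="utf-8").splitlines()]
    keywords = [ln for ln in lines if ln]
    if not keywords:
        raise KeywordError(f"keyword file is empty: {f} (filtering would discard all text)")
    return KeywordSet(keywords)


def write_keywords(keywords: KeywordSet, path: str | Path) -> None:
    Path(path).write_text("\n".join(keywords.keywords) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Model + vocabulary artifacts
# ---------------------------------------------------------------------------

def _canonical(payload: dict) -> str:
    return json.dumps(payload, sort_keys=True, ensure_ascii=False)


def _checksum(payload: dict) -> str:
    return hashlib.sha256(_canonical(payload).encode("utf-8")).hexdigest()


def _write_artifact(path: Path, payload: dict) -> None:
    doc = {
        "schema_version": ARTIFACT_SCHEMA_VERSION,
        "sha256": _checksum(payload),
        "payload": payload,
    }
    path.write_text(json.dumps(doc, sort_keys=True, ensure_ascii=False), encoding="utf-8")


def _read_artifact(path: Path) -> dict:
    if not path.is_file():
        raise ArtifactNotFoundError(f"artifact not found: {path}")
    try:
        doc = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise ArtifactCorruptError(f"artifact {path.name} is not valid JSON: {exc}") from exc
    if not isinstance(doc, dict) or "schema_version" not in doc:
        raise ArtifactCorruptError(f"artifact {path.name} missing schema_version")
    if doc["schema_version"] != ARTIFACT_SCHEMA_VERSION:
        raise ArtifactVersionError(
            f"artifact {path.name} has incompatible schema version "
            f"{doc['schema_version']} (expected {ARTIFACT_SCHEMA_VERSION})"
        )
    if _checksum(doc.get("payload", {})) != doc.get("sha256"):
        raise ArtifactCorruptError(f"artifact {path.name} failed its checksum")
    return doc["payload"]


def save_artifacts(model, vocab, path: str | Path) -> None:
    """Persist a trained model and its vocabulary under ``path``.

    JSON floats round-trip exactly (shortest-repr encoding), so
    ``load_artifacts(save_artifacts(...))`` reproduces every weight bit for
    bit and classification output is identical.
    """
    directory = Path(path)
    directory.mkdir(parents=True, exist_ok=True)
    _write_artifact(directory / MODEL_FILE, model.to_payload())
    _write_artifact(directory / VOCAB_FILE, vocab.to_payload())


def load_artifacts(path: str | Path):
    """Load (model, vocabulary) saved by :func:`save_artifacts`."""
    from .model import MLPModel
    from .preprocess import Vocabulary

    directory = Path(path)
    model = MLPModel.from_payload(_read_artifact(directory / MODEL_FILE))
    vocab = Vocabulary.from_payload(_read_artifact(directory / VOCAB_FILE))
    return model, vocab
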