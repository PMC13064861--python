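"""Reading, normalizing, segmenting and filtering free-text experience reports.

A *report* is one participant's open-ended reflection, tagged with an
experimental condition label.  Because a single reflection typically touches
several distinct experiential facets, the unit of analysis downstream is the
*sentence*: reports are segmented, then cleaned of fragments shorter than two
words and of exact duplicate sentences.
"""

from __future__ import annotations

import csv
import io
import json
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Sequence

logger = logging.getLogger(__name__)

#: A cleaner is any text -> text callable (spelling normalization, artefact
#: removal...).  The default is the identity: no cleaning.
CleanerBackend = Callable[[str], str]


@dataclass(frozen=True)
class RawReport:
    """One participant's free-text reflection."""

    report_id: str
    condition: str
    text: str


@dataclass(frozen=True)
class SentenceRecord:
    """A single sentence extracted from a report.

    ``position`` is the 0-based order of the sentence within its report;
    ``token_count`` counts whitespace-delimited word tokens (punctuation-only
    tokens excluded).
    """

    sentence_id: str
    report_id: str
    position: int
    text: str
    token_count: int


@dataclass
class Corpus:
    """The filtered sentence collection for one condition."""

    condition: str
    sentences: list[SentenceRecord] = field(default_factory=list)
    n_reports: int = 0

    @property
    def n_sentences(self) -> int:
        return len(self.sentences)

    def texts(self) -> list[str]:
        return [s.text for s in self.sentences]

    def sentence_ids(self) -> list[str]:
        return [s.sentence_id for s in self.sentences]


def identity_cleaner(text: str) -> str:
    return text


def count_word_tokens(text: str) -> int:
    """Number of whitespace-delimited tokens that contain at least one
    alphanumeric character (pure punctuation does not count as a word)."""
    return sum(1 for tok in text.split() if re.search(r"[^\W_]", tok, re.UNICODE))


def normalize_reports(
    reports: Sequence[RawReport], cleaner: CleanerBackend = identity_cleaner
) -> list[RawReport]:
    """Apply ``cleaner`` to every report's text, report-wise.

    Identifiers and condition labels are never touched.  A cleaner failure is
    re-raised with the offending report id attached.
    """
    out: list[RawReport] = []
    for rep in reports:
        try:
            cleaned = cleaner(rep.text)
        except Exception as exc:  # noqa: BLE001 - context then re-raise
            raise RuntimeError(f"cleaner failed on report {rep.report_id!r}") from exc
        out.append(replace(rep, text=cleaned))
    return out


# Sentence boundaries: one or more terminators (. ! ? and the ellipsis
# character) optionally followed by closing quotes/brackets, then whitespace.
_BOUNDARY = re.compile(r"(?<=[.!?…])[\"'”’)\]]*\s+")

# Common abbreviations whose trailing period must not end a sentence.
_ABBREVIATIONS = {
    "e.g", "i.e", "etc", "vs", "cf", "dr", "mr", "mrs", "ms", "prof",
    "st", "no", "approx", "fig", "al",
}


def _is_abbreviation_break(left: str) -> bool:
    last = left.rstrip().rsplit(maxsplit=1)
    if not last:
        return False
    token = last[-1].rstrip(".").lstrip("(\"'").lower()
    return token in _ABBREVIATIONS


def split_sentences(text: str) -> list[str]:
    """Split ``text`` into sentences on punctuation boundaries.

    Runs of terminators (``?!``, ``...``) end a single sentence; periods that
    belong to a known abbreviation do not break.  Text without any boundary is
    returned whole.
    """
    pieces: list[str] = []
    start = 0
    for m in _BOUNDARY.finditer(text):
        left = text[start : m.start() + 1]
        if _is_abbreviation_break(text[: m.start() + 1]):
            continue
        pieces.append(left)
        start = m.end()
    tail = text[start:]
    if tail.strip():
        pieces.append(tail)
    return [p.strip() for p in pieces if p.strip()]


def segment_sentences(report: RawReport) -> list[SentenceRecord]:
    """Segment one report into ordered :class:`SentenceRecord` items.

    Sentence ids are ``<report_id>:<position>``.  Token counts are attached
    here but no filtering happens yet: that is :func:`filter_corpus`'s job.
    """
    records = []
    for pos, sent in enumerate(split_sentences(report.text)):
        records.append(
            SentenceRecord(
                sentence_id=f"{report.report_id}:{pos}",
                report_id=report.report_id,
                position=pos,
                text=sent,
                token_count=count_word_tokens(sent),
            )
        )
    return records


def _dedupe_key(text: str) -> str:
    return " ".join(text.casefold().split())


def filter_corpus(
    sentences: Iterable[SentenceRecord], condition: str = ""
) -> Corpus:
    """Drop sentences with fewer than two words and exact duplicates.

    Duplicate detection is exact string match after casefolding and whitespace
    collapse; the first occurrence wins.  An empty result is a valid (warned)
    corpus.
    """
    kept: list[SentenceRecord] = []
    seen: set[str] = set()
    for rec in sentences:
        if rec.token_count < 2:
            continue
        key = _dedupe_key(rec.text)
        if key in seen:
            continue
        seen.add(key)
        kept.append(rec)
    if not kept:
        logger.warning("filter_corpus produced an empty corpus (condition=%r)", condition)
    corpus = Corpus(condition=condition, sentences=kept)
    corpus.n_reports = len({r.report_id for r in kept})
    return corpus


def build_corpus(
    reports: Sequence[RawReport],
    condition: str | None = None,
    cleaner: CleanerBackend = identity_cleaner,
) -> Corpus:
    """normalize -> segment -> filter, restricted to ``condition`` if given."""
    if condition is not None:
        reports = [r for r in reports if r.condition == condition]
    cleaned = normalize_reports(reports, cleaner)
    records: list[SentenceRecord] = []
    for rep in cleaned:
        records.extend(segment_sentences(rep))
    return filter_corpus(records, condition=condition or "")


# ---------------------------------------------------------------------------
# File formats: CSV / JSON-lines with columns report_id, condition, text.

def read_reports_csv(path: str | Path) -> list[RawReport]:
    with open(path, newline="", encoding="utf-8") as fh:
        return _reports_from_rows(csv.DictReader(fh), str(path))


def read_reports_jsonl(path: str | Path) -> list[RawReport]:
    rows = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                rows.append(json.loads(line))
    return _reports_from_rows(rows, str(path))


def read_reports(path: str | Path) -> list[RawReport]:
    """Dispatch on extension: ``.csv`` or JSON-lines (anything else)."""
    if str(path).endswith(".csv"):
        return read_reports_csv(path)
    return read_reports_jsonl(path)


def _reports_from_rows(rows: Iterable[dict], source: str) -> list[RawReport]:
    reports = []
    seen_ids: set[str] = set()
    for row in rows:
        rid = str(row["report_id"])
        if rid in seen_ids:
            raise ValueError(f"duplicate report_id {rid!r} in {source}")
        text = str(row["text"])
        if not text.strip():
            raise ValueError(f"empty text for report {rid!r} in {source}")
        seen_ids.add(rid)
        reports.append(RawReport(report_id=rid, condition=str(row["condition"]), text=text))
    return reports


def write_reports_csv(reports: Sequence[RawReport], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["report_id", "condition", "text"])
        for r in reports:
            writer.writerow([r.report_id, r.condition, r.text])


def write_corpus_jsonl(corpus: Corpus, path: str | Path) -> None:
    """Corpus as JSON-lines of sentence records plus a ``.summary.json``
    sidecar with report/sentence counts."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for s in corpus.sentences:
            fh.write(
                json.dumps(
                    {
                        "sentence_id": s.sentence_id,
                        "report_id": s.report_id,
                        "position": s.position,
                        "text": s.text,
                        "token_count": s.token_count,
                    }
                )
                + "\n"
            )
    summary = {
        "condition": corpus.condition,
        "n_reports": corpus.n_reports,
        "n_sentences": corpus.n_sentences,
    }
    path.with_suffix(path.suffix + ".summary.json").write_text(
        json.dumps(summary, indent=2), encoding="utf-8"
    )


def read_corpus_jsonl(path: str | Path, condition: str = "") -> Corpus:
    sentences = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            row = json.loads(line)
            sentences.append(
                SentenceRecord(
                    sentence_id=str(row["sentence_id"]),
                    report_id=str(row["report_id"]),
                    position=int(row["position"]),
                    text=str(row["text"]),
                    token_count=int(row["token_count"]),
                )
            )
    corpus = Corpus(condition=condition, sentences=sentences)
    corpus.n_reports = len({s.report_id for s in sentences})
    return corpus
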