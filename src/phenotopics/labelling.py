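"""Topic labelling via a pluggable local generative-model backend.

A prompt is assembled deterministically from each topic's three keyword lists
and its representative sentences; the backend turns it into a short label.
Because generative backends are stochastic, several attempts per topic are
retained so label wording stability can be inspected.  Labelling never
touches the model itself — it is a read-only annotation stage.

The default :class:`MockLabelBackend` joins the top c-TF-IDF keywords and
exists so the full pipeline runs without any model download; a llama-cpp
style callable can be plugged in where available (run locally, so report text
never leaves the machine).
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from typing import Callable, Protocol, Sequence, runtime_checkable

from .corpus_io import Corpus
from .representation import TopicRepresentation

logger = logging.getLogger(__name__)

DEFAULT_PROMPT_TEMPLATE = """You are an expert summarizer of phenomenological \
(subjective-experience) reports. Based on the keyword sets and representative \
sentences below, produce one short, precise label (at most eight words) for \
this experiential topic. Reply with the label only.

[c-TF-IDF keywords]
{ctfidf}

[embedding-ranked keywords]
{embed}

[diversified (MMR) keywords]
{mmr}

[representative sentences]
{sentences}
"""


@runtime_checkable
class LabelBackend(Protocol):
    name: str
    deterministic: bool

    def generate(self, prompt: str) -> str: ...


@dataclass
class MockLabelBackend:
    """Deterministic offline labeller: top-3 c-TF-IDF keywords joined by '/'.

    It reads the keywords straight from the prompt's first keyword block, so
    it exercises the same interface a generative backend would.
    """

    name: str = "mock"
    deterministic: bool = True

    def generate(self, prompt: str) -> str:
        block = prompt.split("[c-TF-IDF keywords]\n", 1)[1].split("\n\n", 1)[0]
        keywords = [w.strip() for w in block.split(",") if w.strip()]
        return "/".join(keywords[:3])


@dataclass
class CallableLabelBackend:
    """Wrap any prompt -> text callable (e.g. a llama-cpp completion)."""

    fn: Callable[[str], str]
    name: str = "callable"
    deterministic: bool = False

    def generate(self, prompt: str) -> str:
        return self.fn(prompt)


@dataclass
class TopicLabel:
    topic_id: int
    label: str
    prompt_hash: str
    attempts: list[str] = field(default_factory=list)
    fallback_used: bool = False


def build_prompt(rep: TopicRepresentation, corpus: Corpus) -> str:
    """Deterministic prompt containing all three keyword lists (in rank order)
    and all representative sentence texts."""
    if not (rep.keywords_ctfidf or rep.keywords_embed or rep.keywords_mmr):
        raise ValueError(f"topic {rep.topic_id} has an empty representation")
    id_to_text = {s.sentence_id: s.text for s in corpus.sentences}
    sentences = [id_to_text.get(sid, "") for sid in rep.representatives]
    if rep.representative_texts:
        sentences = rep.representative_texts
    return DEFAULT_PROMPT_TEMPLATE.format(
        ctfidf=", ".join(t for t, _ in rep.keywords_ctfidf),
        embed=", ".join(t for t, _ in rep.keywords_embed),
        mmr=", ".join(t for t, _ in rep.keywords_mmr),
        sentences="\n".join(f"- {s}" for s in sentences),
    )


def prompt_hash(prompt: str) -> str:
    return hashlib.sha256(prompt.encode("utf-8")).hexdigest()


def _fallback_label(rep: TopicRepresentation) -> str:
    return "/".join(t for t, _ in rep.keywords_ctfidf[:3])


def label_topics(
    reps: Sequence[TopicRepresentation],
    corpus: Corpus,
    backend: LabelBackend,
    n_attempts: int = 1,
) -> list[TopicLabel]:
    """Label every topic; the recorded label is the first attempt.

    A backend failure on one topic falls back to the joined top-3 c-TF-IDF
    keywords for that topic (flagged); other topics are unaffected.
    """
    if n_attempts < 1:
        raise ValueError("n_attempts must be >= 1")
    labels = []
    for rep in reps:
        prompt = build_prompt(rep, corpus)
        attempts: list[str] = []
        failed = False
        for _ in range(n_attempts):
            try:
                attempts.append(backend.generate(prompt).strip())
            except Exception as exc:  # noqa: BLE001 - fall back, keep going
                logger.warning("backend %s failed on topic %d: %s", backend.name, rep.topic_id, exc)
                failed = True
                break
        if failed or not attempts or not attempts[0]:
            labels.append(
                TopicLabel(
                    topic_id=rep.topic_id,
                    label=_fallback_label(rep),
                    prompt_hash=prompt_hash(prompt),
                    attempts=attempts,
                    fallback_used=True,
                )
            )
        else:
            labels.append(
                TopicLabel(
                    topic_id=rep.topic_id,
                    label=attempts[0],
                    prompt_hash=prompt_hash(prompt),
                    attempts=attempts,
                )
            )
    return labels
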