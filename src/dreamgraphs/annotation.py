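"""Linguistic annotation: tokenize, POS-tag and lemmatize report text.

Annotation is a pluggable contract: anything with an
``annotate(text) -> list[AnnotatedToken]`` method works. Two implementations
ship here:

* :class:`LexiconAnnotator` — deterministic table lookup against a packaged
  ~200-entry Spanish toy lexicon. This is the default; it needs no model
  download and makes the whole pipeline reproducible byte-for-byte.
* :class:`SpacyAnnotator` — optional adapter around a pretrained pipeline
  (e.g. ``es_core_news_sm``), imported lazily. The downstream graph code
  cannot tell which annotator produced its input.

Only tokens tagged NOUN, VERB or ADJ (Universal POS) count as content words
and survive into graph construction; everything else — determiners,
prepositions, pronouns, punctuation, digits — is discarded without leaving
gaps.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Protocol, Sequence

CONTENT_POS = frozenset({"NOUN", "VERB", "ADJ"})

_SENT_SPLIT = re.compile(r"[.!?]+")
_TOKEN = re.compile(r"[^\s]+")
_STRIP_PUNCT = re.compile(r"^[^\w]+|[^\w]+$", re.UNICODE)


@dataclass(frozen=True)
class AnnotatedToken:
    surface: str
    pos: str
    lemma: str
    sentence_index: int

    def __post_init__(self) -> None:
        if not self.lemma:
            raise ValueError("lemma must be non-empty")
        if self.sentence_index < 0:
            raise ValueError("sentence_index must be non-negative")


@dataclass(frozen=True)
class LemmaSequence:
    """Content lemmas of one report, in narrative order.

    ``n_raw_tokens`` counts the word tokens before the content filter
    (punctuation-only and letterless tokens excluded).
    """

    report_id: str
    lemmas: tuple[str, ...]
    n_raw_tokens: int


class Annotator(Protocol):
    name: str

    def annotate(self, text: str) -> list[AnnotatedToken]: ...


def _has_letter(tok: str) -> bool:
    return any(unicodedata.category(c).startswith("L") for c in tok)


class LexiconAnnotator:
    """Deterministic annotator backed by a surface → (pos, lemma) table.

    Sentences split on ``.``, ``!``, ``?``. Tokens are whitespace-delimited
    words with leading/trailing punctuation stripped; tokens without letters
    are dropped. Unknown surfaces fall back to ``default_pos`` with the
    lowercased surface as lemma.
    """

    name = "lexicon"

    def __init__(self, table: dict[str, tuple[str, str]],
                 default_pos: str = "NOUN"):
        self.table = dict(table)
        self.default_pos = default_pos

    def annotate(self, text: str) -> list[AnnotatedToken]:
        tokens: list[AnnotatedToken] = []
        for s_idx, sentence in enumerate(_SENT_SPLIT.split(text)):
            for match in _TOKEN.finditer(sentence):
                surface = _STRIP_PUNCT.sub("", match.group())
                if not surface or not _has_letter(surface):
                    continue
                key = surface.lower()
                pos, lemma = self.table.get(key, (self.default_pos, key))
                tokens.append(AnnotatedToken(surface, pos, lemma.lower(), s_idx))
        # Renumber so sentence indices are contiguous even when the splitter
        # produces empty segments ("..." or trailing period).
        seen: dict[int, int] = {}
        out = []
        for t in tokens:
            if t.sentence_index not in seen:
                seen[t.sentence_index] = len(seen)
            out.append(AnnotatedToken(t.surface, t.pos, t.lemma,
                                      seen[t.sentence_index]))
        return out


class SpacyAnnotator:
    """Adapter for a pretrained spaCy pipeline (optional extra)."""

    name = "spacy"

    def __init__(self, model: str = "es_core_news_sm"):
        import spacy  # deferred: optional dependency

        self._nlp = spacy.load(model)

    def annotate(self, text: str) -> list[AnnotatedToken]:
        doc = self._nlp(text)
        out: list[AnnotatedToken] = []
        for s_idx, sent in enumerate(doc.sents):
            for tok in sent:
                if not _has_letter(tok.text):
                    continue
                out.append(AnnotatedToken(tok.text, tok.pos_,
                                          tok.lemma_.lower(), s_idx))
        return out


def parse_lexicon(lines: Sequence[str]) -> dict[str, tuple[str, str]]:
    """Parse surface<TAB>pos<TAB>lemma lines; '#' starts a comment line."""
    table: dict[str, tuple[str, str]] = {}
    for i, line in enumerate(lines, 1):
        line = line.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(f"lexicon line {i}: expected 3 tab-separated "
                             f"fields, got {len(parts)}")
        surface, pos, lemma = (p.strip() for p in parts)
        key = surface.lower()
        entry = (pos, lemma.lower())
        if key in table and table[key] != entry:
            raise ValueError(f"lexicon line {i}: conflicting entries for "
                             f"surface {surface!r}: {table[key]} vs {entry}")
        table[key] = entry
    return table


def build_lexicon_annotator(table_path: str | Path | None = None,
                            default_pos: str = "NOUN") -> LexiconAnnotator:
    """Build the fixture annotator from a TSV; packaged lexicon by default."""
    if table_path is None:
        ref = resources.files("dreamgraphs.data") / "lexicon_es.tsv"
        lines = ref.read_text(encoding="utf-8").splitlines()
    else:
        lines = Path(table_path).read_text(encoding="utf-8").splitlines()
    return LexiconAnnotator(parse_lexicon(lines), default_pos=default_pos)


def annotate_text(text: str, annotator: Annotator,
                  report_id: str = "") -> list[AnnotatedToken]:
    """Run the annotator, wrapping failures with the report id for context."""
    if not text or not text.strip():
        raise ValueError(f"report {report_id!r}: empty text")
    try:
        return annotator.annotate(text)
    except Exception as exc:  # pragma: no cover - depends on annotator
        raise RuntimeError(f"annotator {annotator.name!r} failed on report "
                           f"{report_id!r}: {exc}") from exc


def filter_content_lemmas(tokens: Sequence[AnnotatedToken],
                          report_id: str) -> LemmaSequence:
    """Keep NOUN/VERB/ADJ lemmas in order; duplicates are deliberately kept
    (lemma recurrence is what the downstream graph measures)."""
    lemmas = tuple(t.lemma for t in tokens if t.pos in CONTENT_POS)
    return LemmaSequence(report_id=report_id, lemmas=lemmas,
                         n_raw_tokens=len(tokens))


def annotate_report(text: str, annotator: Annotator,
                    report_id: str) -> LemmaSequence:
    """Convenience: annotate then filter to the content-lemma sequence."""
    return filter_content_lemmas(annotate_text(text, annotator, report_id),
                                 report_id)
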