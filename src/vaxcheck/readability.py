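"""Gulpease readability index for Italian text.

The Gulpease index scores a text in [0, 100] (100 = most readable) from three
counts: letters, words and sentences::

    score = 89 + (300 * n_sentences - 10 * n_letters) / n_words

clamped to [0, 100].  Texts scoring below 40 are considered difficult for
readers with a high-school education; 40 is therefore the default acceptance
target.

Tokenization conventions (fixed for determinism):

* letters: Unicode alphabetic characters, accented Italian letters included;
  digits and punctuation are never counted;
* words: apostrophe elisions split ("l'uso" is two words), hyphenated
  compounds count as one word;
* sentences: segments terminated by ``.``, ``!``, ``?`` or the ellipsis
  character; a run of terminators closes a single sentence, and a trailing
  unterminated segment still counts as one sentence.

The arithmetic applies to any text, but the calibration is Italian-specific;
scores for other languages are not meaningful readability measurements.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

from .errors import EmptyCorpusError, EmptyTextError

DEFAULT_TARGET = 40.0

_WORD_RE = re.compile(r"[^\W\d_]+(?:-[^\W\d_]+)*", re.UNICODE)
_LETTER_RE = re.compile(r"[^\W\d_]", re.UNICODE)
_SENTENCE_END_RE = re.compile(r"[.!?…]+")


@dataclass(frozen=True)
class ReadabilityResult:
    n_letters: int
    n_words: int
    n_sentences: int
    gulpease: float
    meets_target: bool


def tokenize_counts(text: str) -> dict[str, int]:
    """Letter, word and sentence counts for a non-empty text."""
    if not text or not text.strip():
        raise EmptyTextError("cannot score an empty text")
    n_letters = len(_LETTER_RE.findall(text))
    n_words = len(_WORD_RE.findall(text))
    if n_letters == 0 or n_words == 0:
        raise EmptyTextError("text contains no alphabetic words")

    n_sentences = 0
    last_end = 0
    for m in _SENTENCE_END_RE.finditer(text):
        # a terminator run closes one sentence iff it has words before it
        if _WORD_RE.search(text, last_end, m.start()):
            n_sentences += 1
        last_end = m.end()
    if _WORD_RE.search(text, last_end):  # unterminated tail
        n_sentences += 1
    n_sentences = max(n_sentences, 1)
    return {"n_letters": n_letters, "n_words": n_words, "n_sentences": n_sentences}


def gulpease(n_letters: int, n_words: int, n_sentences: int) -> float:
    """The Gulpease score from raw counts, clamped to [0, 100]."""
    if n_words < 1 or n_letters < 1 or n_sentences < 1:
        raise EmptyTextError("all counts must be at least 1")
    raw = 89.0 + (300.0 * n_sentences - 10.0 * n_letters) / n_words
    return min(100.0, max(0.0, raw))


def score_text(text: str, target: float = DEFAULT_TARGET) -> ReadabilityResult:
    """Tokenize, score and threshold one text."""
    counts = tokenize_counts(text)
    score = gulpease(**counts)
    return ReadabilityResult(
        n_letters=counts["n_letters"],
        n_words=counts["n_words"],
        n_sentences=counts["n_sentences"],
        gulpease=score,
        meets_target=score >= target,
    )


@dataclass(frozen=True)
class CorpusReadability:
    results: tuple[tuple[str, ReadabilityResult], ...]
    unweighted_mean: float
    word_weighted_mean: float
    below_target: tuple[str, ...]


def corpus_readability(
    texts: Iterable[tuple[str, str]] | Sequence[tuple[str, str]],
    target: float = DEFAULT_TARGET,
) -> CorpusReadability:
    """Score a labeled corpus and aggregate.

    Both the unweighted mean over texts and the word-count-weighted mean are
    reported, since a corpus-level readability figure can be defined either
    way; texts below the target are flagged by label.
    """
    items = list(texts)
    if not items:
        raise EmptyCorpusError("corpus is empty")
    results = tuple((label, score_text(text, target)) for label, text in items)
    scores = [r.gulpease for _, r in results]
    weights = [r.n_words for _, r in results]
    unweighted = sum(scores) / len(scores)
    weighted = sum(s * w for s, w in zip(scores, weights)) / sum(weights)
    below = tuple(label for label, r in results if not r.meets_target)
    return CorpusReadability(
        results=results,
        unweighted_mean=unweighted,
        word_weighted_mean=weighted,
        below_target=below,
    )
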