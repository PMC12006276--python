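"""Lexical discourse features: content density, MATTR, n-gram repetition.

All three operate on the word sequence of a transcript (punctuation
excluded) and quantify, respectively, the balance of content-bearing
versus function words, vocabulary range, and the reuse of exact phrases.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .transcript import AnnotatedToken, Transcript

__all__ = [
    "OPEN_CLASS_UPOS",
    "CLOSED_CLASS_UPOS",
    "LexicalParams",
    "UndefinedFeatureError",
    "content_density",
    "mattr",
    "ngram_repetition",
]

#: UD v2 open (content-bearing) word classes.  INTJ counts as open.
OPEN_CLASS_UPOS = frozenset({"ADJ", "ADV", "INTJ", "NOUN", "PROPN", "VERB"})
#: UD v2 closed (function) word classes.
CLOSED_CLASS_UPOS = frozenset({"ADP", "AUX", "CCONJ", "DET", "NUM", "PART", "PRON", "SCONJ"})


class UndefinedFeatureError(ValueError):
    """The feature is mathematically undefined on this input (e.g. a zero
    denominator).  Callers must propagate this as a missing value with a
    reason, never as a silent 0."""


@dataclass(frozen=True)
class LexicalParams:
    """Tunables for the lexical features.

    ``mattr_window`` is the sliding-window length in words (default 84,
    suited to ~90–170-word narrations).  ``ngram_orders`` are the phrase
    lengths pooled into the repetition score.  Word-type identity is the
    case-folded surface form, which removes sentence-initial
    capitalization artifacts.
    """

    mattr_window: int = 84
    ngram_orders: frozenset[int] = frozenset({2, 3, 4})
    case_fold: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "ngram_orders", frozenset(self.ngram_orders))
        if self.mattr_window < 1:
            raise ValueError("mattr_window must be >= 1")
        if any(k < 2 for k in self.ngram_orders) or not self.ngram_orders:
            raise ValueError("every n-gram order must be >= 2")

    def type_key(self, token: AnnotatedToken) -> str:
        return token.form.casefold() if self.case_fold else token.form


def content_density(transcript: Transcript) -> float:
    """Ratio of open-class to closed-class words.

    Open = {ADJ, ADV, INTJ, NOUN, PROPN, VERB}; closed = {ADP, AUX, CCONJ,
    DET, NUM, PART, PRON, SCONJ}; punctuation-class tokens count in
    neither.  Undefined when the transcript has no closed-class word.
    """
    n_open = 0
    n_closed = 0
    for tok in transcript.words():
        if tok.upos in OPEN_CLASS_UPOS:
            n_open += 1
        elif tok.upos in CLOSED_CLASS_UPOS:
            n_closed += 1
    if n_closed == 0:
        raise UndefinedFeatureError("no closed-class words: open/closed ratio undefined")
    return n_open / n_closed


def mattr(transcript: Transcript, params: LexicalParams = LexicalParams()) -> float:
    """Moving-average type-token ratio over the transcript word sequence.

    A window of exactly ``mattr_window`` words slides with step 1; each
    window contributes distinct-types/window-size and the score is the
    mean over all windows.  Texts shorter than the window fall back to
    the whole-text type-token ratio.
    """
    types = [params.type_key(t) for t in transcript.words()]
    n = len(types)
    if n == 0:
        raise UndefinedFeatureError("no words: type-token ratio undefined")
    w = params.mattr_window
    if n < w:
        return len(set(types)) / n
    # Incremental sliding distinct count: O(n) instead of O(n * w).
    counts: Counter[str] = Counter(types[:w])
    distinct = len(counts)
    total = distinct
    for i in range(w, n):
        out_t, in_t = types[i - w], types[i]
        if out_t != in_t:
            counts[out_t] -= 1
            if counts[out_t] == 0:
                del counts[out_t]
                distinct -= 1
            if counts[in_t] == 0:
                distinct += 1
            counts[in_t] += 1
        total += distinct
    return total / ((n - w + 1) * w)


def ngram_repetition(transcript: Transcript, params: LexicalParams = LexicalParams()) -> float:
    """Mean repeated-phrase rate over the configured n-gram orders.

    For each order n, n-grams are collected within sentences (a phrase
    does not cross a sentence boundary) over word types; the per-order
    rate is (total − distinct) / total occurrences, i.e. the fraction of
    n-gram tokens that repeat an earlier identical phrase.  The feature
    is the unweighted mean across orders, in [0, 1); higher means more
    verbatim phrase reuse.  Undefined when the transcript has fewer words
    than the largest order.
    """
    orders = sorted(params.ngram_orders)
    if transcript.word_count < max(orders):
        raise UndefinedFeatureError(
            f"fewer than {max(orders)} words: n-gram repetition undefined"
        )
    sent_types = [
        [params.type_key(t) for t in s.words()] for s in transcript.sentences
    ]
    rates = []
    for k in orders:
        grams: Counter[tuple[str, ...]] = Counter()
        total = 0
        for types in sent_types:
            for i in range(len(types) - k + 1):
                grams[tuple(types[i : i + k])] += 1
                total += 1
        # A transcript can clear the largest-order word count overall yet
        # have every sentence shorter than k; no occurrences => no repeats.
        rates.append((total - len(grams)) / total if total else 0.0)
    return sum(rates) / len(rates)
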