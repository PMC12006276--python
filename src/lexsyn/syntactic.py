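"""Syntactic discourse features: mean length of utterance, clause-to-
sentence ratio, and syntactic dependency length.

All three are computed on words only (punctuation excluded) so that the
scores do not depend on transcription punctuation conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .lexical import UndefinedFeatureError
from .transcript import AnnotatedToken, Sentence, Transcript

__all__ = [
    "ClauseRules",
    "mean_length_utterance",
    "clause_sentence_ratio",
    "dependency_length",
]


def _base(deprel: str) -> str:
    """UD relation subtypes are colon-suffixed (acl:relcl); strip them."""
    return deprel.split(":", 1)[0]


@dataclass(frozen=True)
class ClauseRules:
    """Which dependency relations mark a clause head.

    Subordinate clause heads carry one of ``subordinate_deprels`` (subtype
    prefix-aware, so ``acl:relcl`` matches ``acl``).  A ``conj`` dependent
    counts as a coordinate clause head when it is verbal (VERB or AUX) or
    governs its own subject — coordination of noun phrases does not open
    a new clause.
    """

    subordinate_deprels: frozenset[str] = frozenset({"csubj", "ccomp", "xcomp", "advcl", "acl"})
    subject_deprels: frozenset[str] = frozenset({"nsubj", "csubj"})
    verbal_upos: frozenset[str] = frozenset({"VERB", "AUX"})

    def __post_init__(self) -> None:
        object.__setattr__(self, "subordinate_deprels", frozenset(self.subordinate_deprels))
        object.__setattr__(self, "subject_deprels", frozenset(self.subject_deprels))
        object.__setattr__(self, "verbal_upos", frozenset(self.verbal_upos))
        if not self.subordinate_deprels:
            raise ValueError("subordinate_deprels must be nonempty")
        if "conj" in self.subordinate_deprels:
            raise ValueError("conj is handled by the coordinate rule")

    def is_subordinate(self, token: AnnotatedToken) -> bool:
        return _base(token.deprel) in self.subordinate_deprels

    def is_coordinate(self, token: AnnotatedToken, sentence: Sentence) -> bool:
        if _base(token.deprel) != "conj":
            return False
        if token.upos in self.verbal_upos:
            return True
        return any(
            t.head == token.index and _base(t.deprel) in self.subject_deprels
            for t in sentence.tokens
        )

    def clause_heads(self, sentence: Sentence) -> list[AnnotatedToken]:
        return [
            t
            for t in sentence.tokens
            if t.is_word and (self.is_subordinate(t) or self.is_coordinate(t, sentence))
        ]


def mean_length_utterance(transcript: Transcript) -> float:
    """Mean number of words per sentence; punctuation-only sentences are
    skipped.  Undefined when no sentence contains a word."""
    lengths = [len(s.words()) for s in transcript.sentences]
    lengths = [n for n in lengths if n > 0]
    if not lengths:
        raise UndefinedFeatureError("no sentence contains a word")
    return sum(lengths) / len(lengths)


def clause_sentence_ratio(
    transcript: Transcript, rules: ClauseRules = ClauseRules()
) -> float:
    """Subordinate plus coordinate clause heads across the transcript,
    divided by the number of sentences."""
    n_clauses = sum(len(rules.clause_heads(s)) for s in transcript.sentences)
    return n_clauses / len(transcript.sentences)


def _word_positions_and_heads(sentence: Sentence) -> list[tuple[int, int | None]]:
    """Map each word to (word-position, governor word-position).

    Positions are counted over words only, recomputed after punctuation
    removal.  A word whose governor is a punctuation token is reattached
    to that token's nearest word (or root) ancestor.  Returns a list of
    (position, head_position) with head_position None for the root.
    """
    tok_by_index = {t.index: t for t in sentence.tokens}
    wordpos: dict[int, int] = {}
    pos = 0
    for t in sentence.tokens:
        if t.is_word:
            pos += 1
            wordpos[t.index] = pos

    def word_ancestor(idx: int) -> int | None:
        # Walk up head links until a word or the root is reached.  The
        # tree invariant guarantees termination.
        cur = idx
        while cur != 0:
            tok = tok_by_index[cur]
            if tok.is_word:
                return wordpos[tok.index]
            cur = tok.head
        return None

    out: list[tuple[int, int | None]] = []
    for t in sentence.tokens:
        if not t.is_word:
            continue
        if t.head == 0:
            out.append((wordpos[t.index], None))
        else:
            out.append((wordpos[t.index], word_ancestor(t.head)))
    return out


def dependency_length(transcript: Transcript) -> float:
    """Mean normalized count of words intervening between each word and
    its governor.

    Per sentence: each non-root word at word-position i with governor at
    word-position j contributes max(0, |i − j| − 1) intervening words
    (adjacent pairs contribute 0); the root contributes 0.  The sentence
    score is the contribution sum divided by the sentence word count, and
    the transcript score is the unweighted mean over sentences.
    Punctuation is removed and positions recomputed before measuring.
    """
    scores = []
    for sent in transcript.sentences:
        pairs = _word_positions_and_heads(sent)
        if not pairs:
            continue
        total = 0
        for pos, head_pos in pairs:
            if head_pos is None:
                continue
            total += max(0, abs(pos - head_pos) - 1)
        scores.append(total / len(pairs))
    if not scores:
        raise UndefinedFeatureError("no sentence contains a word")
    return sum(scores) / len(scores)
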