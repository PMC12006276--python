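"""Domain model for dependency-annotated transcripts and CoNLL-U I/O.

A transcript is one narration by one subject at one timepoint, already
tokenized, sentence-segmented, POS-tagged and dependency-parsed upstream
(e.g. by a UD parser run on an ASR transcript).  This module owns the
reading/writing contract for the CoNLL-U exchange format and the single
"word" definition shared by every downstream feature: a word is any token
whose UPOS is not PUNCT, SYM or X.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

__all__ = [
    "UPOS_TAGS",
    "NON_WORD_UPOS",
    "AnnotatedToken",
    "Sentence",
    "Transcript",
    "ConlluParseError",
    "TranscriptValidationError",
    "read_conllu",
    "write_conllu",
    "content_words",
]

#: The 17 Universal Dependencies part-of-speech tags (UD v2).
UPOS_TAGS = frozenset(
    {
        "ADJ", "ADP", "ADV", "AUX", "CCONJ", "DET", "INTJ", "NOUN", "NUM",
        "PART", "PRON", "PROPN", "PUNCT", "SCONJ", "SYM", "VERB", "X",
    }
)

#: Tokens with these tags are not words: punctuation, symbols, unanalyzable
#: material.  Every feature filters on this set, so all features are
#: invariant to inserting or removing punctuation.
NON_WORD_UPOS = frozenset({"PUNCT", "SYM", "X"})


class ConlluParseError(ValueError):
    """A CoNLL-U line could not be parsed; carries the 1-based line number."""


class TranscriptValidationError(ValueError):
    """A sentence violates the single-rooted-tree contract."""


@dataclass(frozen=True)
class AnnotatedToken:
    """One syntactic word.

    ``head`` follows the CoNLL-U convention: 0 marks the sentence root,
    any other value is the 1-based index of the governor within the same
    sentence.
    """

    index: int
    form: str
    lemma: str
    upos: str
    head: int
    deprel: str

    def __post_init__(self) -> None:
        if self.index < 1:
            raise TranscriptValidationError(f"token index must be >= 1, got {self.index}")
        if self.head < 0:
            raise TranscriptValidationError(f"head must be >= 0, got {self.head}")
        if self.head == self.index:
            raise TranscriptValidationError(f"token {self.index} is its own governor")
        if self.upos not in UPOS_TAGS:
            raise TranscriptValidationError(f"unknown UPOS tag {self.upos!r}")

    @property
    def is_word(self) -> bool:
        return self.upos not in NON_WORD_UPOS


@dataclass(frozen=True)
class Sentence:
    """An ordered, contiguously indexed token sequence forming a single
    dependency tree."""

    tokens: tuple[AnnotatedToken, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "tokens", tuple(self.tokens))
        self.validate()

    def validate(self) -> None:
        n = len(self.tokens)
        if n == 0:
            raise TranscriptValidationError("sentence has no tokens")
        for pos, tok in enumerate(self.tokens, start=1):
            if tok.index != pos:
                raise TranscriptValidationError(
                    f"token indices not contiguous: expected {pos}, got {tok.index}"
                )
            if tok.head > n:
                raise TranscriptValidationError(
                    f"token {tok.index} has head {tok.head} beyond sentence length {n}"
                )
        roots = [t.index for t in self.tokens if t.head == 0]
        if len(roots) != 1:
            raise TranscriptValidationError(
                f"sentence must have exactly one root, found {len(roots)}"
            )
        # Cycle check: walking up from every token must reach the root.
        heads = {t.index: t.head for t in self.tokens}
        for start in heads:
            seen = set()
            cur = start
            while cur != 0:
                if cur in seen:
                    raise TranscriptValidationError(
                        f"cycle in head links involving token {start}"
                    )
                seen.add(cur)
                cur = heads[cur]

    def words(self) -> tuple[AnnotatedToken, ...]:
        return tuple(t for t in self.tokens if t.is_word)

    def __len__(self) -> int:
        return len(self.tokens)


@dataclass
class Transcript:
    """One subject-timepoint narration.

    ``meta`` is a free-form side channel (the simulator stores planted
    ground truth there); it is never serialized to CoNLL-U.
    """

    subject_id: str
    timepoint: str
    sentences: list[Sentence]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sentences:
            raise TranscriptValidationError(
                f"transcript {self.subject_id}/{self.timepoint} has no sentences"
            )

    @property
    def word_count(self) -> int:
        return sum(len(s.words()) for s in self.sentences)

    def words(self) -> list[AnnotatedToken]:
        out: list[AnnotatedToken] = []
        for s in self.sentences:
            out.extend(s.words())
        return out


def content_words(transcript: Transcript) -> list[AnnotatedToken]:
    """All non-punctuation tokens of a transcript in document order.

    This is the universal word filter: UPOS not in {PUNCT, SYM, X}.
    """
    return transcript.words()


def _parse_id(source: str | Path, default_stem: str | None) -> tuple[str, str]:
    """Split ``<subject>__<timepoint>`` into its parts; fall back to the
    whole string as subject with timepoint 'baseline'."""
    stem = default_stem if default_stem is not None else "transcript"
    if "__" in stem:
        subject, _, timepoint = stem.partition("__")
        return subject, timepoint
    return stem, "baseline"


def _iter_lines(source: str | Path) -> tuple[Iterator[str], str | None]:
    if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source and source.endswith(".conllu")):
        path = Path(source)
        return iter(path.read_text(encoding="utf-8").splitlines()), path.stem
    return iter(str(source).splitlines()), None


def read_conllu(source: str | Path) -> list[Transcript]:
    """Parse CoNLL-U text or a ``.conllu`` file into transcripts.

    Documents split on ``# newdoc`` comments; without any, the whole input
    is one transcript.  Subject and timepoint come from
    ``# newdoc id = <subject>__<timepoint>`` when present, else from the
    filename stem of the same shape.  Multiword-token range lines (``3-4``)
    are skipped in favor of their component tokens; empty nodes (decimal
    ids, enhanced dependencies) are dropped — only basic trees are kept.

    Raises :class:`ConlluParseError` naming the offending 1-based line
    number, or :class:`TranscriptValidationError` naming the sentence.
    """
    lines, stem = _iter_lines(source)

    docs: list[tuple[str | None, list[Sentence]]] = []
    cur_doc_id: str | None = None
    cur_sentences: list[Sentence] = []
    cur_rows: list[tuple[int, str, str, str, int, str]] = []
    started = False

    def flush_sentence(lineno: int) -> None:
        nonlocal cur_rows
        if not cur_rows:
            return
        try:
            sent = Sentence(tuple(AnnotatedToken(*row) for row in cur_rows))
        except TranscriptValidationError as exc:
            raise TranscriptValidationError(
                f"sentence ending at line {lineno}: {exc}"
            ) from exc
        cur_sentences.append(sent)
        cur_rows = []

    def flush_doc() -> None:
        nonlocal cur_sentences
        if cur_sentences:
            docs.append((cur_doc_id, cur_sentences))
        cur_sentences = []

    lineno = 0
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            flush_sentence(lineno)
            continue
        if line.startswith("#"):
            comment = line[1:].strip()
            if comment.startswith("newdoc"):
                flush_sentence(lineno)
                flush_doc()
                cur_doc_id = None
                if "=" in comment:
                    cur_doc_id = comment.split("=", 1)[1].strip()
                started = True
            continue
        cols = line.split("\t")
        if len(cols) != 10:
            raise ConlluParseError(
                f"line {lineno}: expected 10 tab-separated columns, got {len(cols)}"
            )
        tok_id = cols[0]
        if "-" in tok_id:  # multiword-token range: keep the components instead
            continue
        if "." in tok_id:  # empty node (enhanced deps): basic tree only
            continue
        try:
            index = int(tok_id)
            head = int(cols[6]) if cols[6] != "_" else 0
        except ValueError as exc:
            raise ConlluParseError(f"line {lineno}: non-integer ID or HEAD field") from exc
        cur_rows.append((index, cols[1], cols[2] if cols[2] != "_" else cols[1],
                         cols[3], head, cols[7]))
        started = True

    flush_sentence(lineno + 1)
    flush_doc()
    if not started or not docs:
        raise ConlluParseError("input contains no token lines")

    transcripts: list[Transcript] = []
    for doc_id, sentences in docs:
        subject, timepoint = _parse_id("", doc_id if doc_id is not None else stem)
        transcripts.append(Transcript(subject, timepoint, sentences))
    return transcripts


def write_conllu(transcripts: Sequence[Transcript], dest: str | Path | io.TextIOBase) -> None:
    """Write transcripts as standard 10-column CoNLL-U.

    Each transcript opens with ``# newdoc id = <subject>__<timepoint>``;
    unknown columns (XPOS, FEATS, DEPS, MISC) are written as ``_``.
    """
    buf = io.StringIO()
    for t in transcripts:
        buf.write(f"# newdoc id = {t.subject_id}__{t.timepoint}\n")
        for i, sent in enumerate(t.sentences, start=1):
            buf.write(f"# sent_id = {t.subject_id}__{t.timepoint}__s{i}\n")
            for tok in sent.tokens:
                buf.write(
                    f"{tok.index}\t{tok.form}\t{tok.lemma}\t{tok.upos}\t_\t_\t"
                    f"{tok.head}\t{tok.deprel}\t_\t_\n"
                )
            buf.write("\n")
    text = buf.getvalue()
    if isinstance(dest, (str, Path)):
        Path(dest).write_text(text, encoding="utf-8")
    else:
        dest.write(text)
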