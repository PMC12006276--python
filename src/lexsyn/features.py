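"""The six-feature discourse profile of a single transcript.

Three lexical features (content density, MATTR, n-gram repetition) and
three syntactic ones (mean length of utterance, clause-to-sentence ratio,
dependency length).  A feature that is undefined on a given transcript —
e.g. the open/closed ratio on a text with no function words — is carried
as an explicit missing value with a reason, never as a silent 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .lexical import LexicalParams, UndefinedFeatureError, content_density, mattr, ngram_repetition
from .syntactic import ClauseRules, clause_sentence_ratio, dependency_length, mean_length_utterance
from .transcript import Transcript

__all__ = [
    "LEXICAL_FEATURES",
    "SYNTACTIC_FEATURES",
    "FEATURE_NAMES",
    "FEATURE_FAMILIES",
    "FeatureVector",
    "extract_features",
]

LEXICAL_FEATURES = ("content_density", "mattr", "ngram_repetition")
SYNTACTIC_FEATURES = ("mlu", "clause_sentence_ratio", "dependency_length")
FEATURE_NAMES = LEXICAL_FEATURES + SYNTACTIC_FEATURES
FEATURE_FAMILIES = {"lexical": LEXICAL_FEATURES, "syntactic": SYNTACTIC_FEATURES}


@dataclass
class FeatureVector:
    """Feature values for one transcript; NaN marks an undefined feature,
    with the reason recorded in ``missing_reasons``."""

    subject_id: str
    timepoint: str
    values: dict[str, float]
    missing_reasons: dict[str, str] = field(default_factory=dict)

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def is_missing(self, name: str) -> bool:
        return math.isnan(self.values[name])


def extract_features(
    transcript: Transcript,
    lex: LexicalParams = LexicalParams(),
    rules: ClauseRules = ClauseRules(),
) -> FeatureVector:
    """Compute all six discourse features for one transcript."""
    calcs = {
        "content_density": lambda: content_density(transcript),
        "mattr": lambda: mattr(transcript, lex),
        "ngram_repetition": lambda: ngram_repetition(transcript, lex),
        "mlu": lambda: mean_length_utterance(transcript),
        "clause_sentence_ratio": lambda: clause_sentence_ratio(transcript, rules),
        "dependency_length": lambda: dependency_length(transcript),
    }
    values: dict[str, float] = {}
    reasons: dict[str, str] = {}
    for name, fn in calcs.items():
        try:
            values[name] = float(fn())
        except UndefinedFeatureError as exc:
            values[name] = float("nan")
            reasons[name] = str(exc)
    return FeatureVector(transcript.subject_id, transcript.timepoint, values, reasons)
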