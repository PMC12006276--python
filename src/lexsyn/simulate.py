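"""Synthetic narration generator with known ground truth.

No patient recordings ship with this package, so every downstream stage
is exercised on simulated cohorts: short fairy-tale-scale narrations
(~90–170 words) for three groups (healthy control, untreated patients,
treated patients) at two timepoints, with treatment effects injected into
the syntactic generator parameters.  Each generator knob maps to one
feature the pipeline extracts:

* ``sentence_length_mean``  → mean length of utterance,
* ``clause_rate``           → clause-to-sentence ratio,
* ``attachment_locality``   → dependency length,
* ``zipf_exponent``         → MATTR (more skew, fewer types),
* ``open_closed_rate``      → content density,
* ``repeat_prob``           → n-gram repetition.

Sentences carry a random *projective* dependency tree built by
right-frontier attachment with geometrically distributed attachment
distance, so expected dependency length is controllable.  Planted clause
heads are bookkept exactly, letting tests compare extracted counts
against ground truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np

from .features import extract_features, FeatureVector
from .lexical import LexicalParams
from .syntactic import ClauseRules
from .transcript import AnnotatedToken, Sentence, Transcript

__all__ = [
    "GeneratorParams",
    "GroupSpec",
    "CovariateSpec",
    "CohortDesign",
    "SimulatedCohort",
    "sample_sentence",
    "sample_transcript",
    "sample_cohort",
]

TIMEPOINTS = ("baseline", "followup")

_OPEN_TAGS = ("NOUN", "VERB", "ADJ", "ADV")
_OPEN_W = np.array([0.45, 0.30, 0.15, 0.10])
_CLOSED_TAGS = ("DET", "ADP", "PRON", "AUX", "CCONJ", "SCONJ", "PART")
_CLOSED_W = np.array([0.25, 0.22, 0.20, 0.12, 0.10, 0.06, 0.05])
# Filler relations deliberately exclude every clause-marking label
# (csubj/ccomp/xcomp/advcl/acl and conj), so planted clause heads are the
# only tokens the clause rules can match.
_FILLER_DEPRELS = ("nsubj", "obj", "obl", "nmod", "amod", "det", "case", "advmod", "mark", "cc")
_CLAUSE_DEPRELS = ("advcl", "ccomp", "xcomp", "acl", "conj")
_OPEN_CW = np.cumsum(_OPEN_W)
_CLOSED_CW = np.cumsum(_CLOSED_W)


@dataclass(frozen=True)
class GeneratorParams:
    """Knobs of the narration generator; defaults emulate a ~168-word
    narration with moderate syntactic complexity."""

    lexicon_size_open: int = 400
    lexicon_size_closed: int = 60
    zipf_exponent: float = 1.1
    open_closed_rate: float = 1.2
    sentence_length_mean: float = 12.0
    clause_rate: float = 1.0
    attachment_locality: float = 1.5
    repeat_prob: float = 0.05
    target_words: int = 168
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.lexicon_size_open < 1 or self.lexicon_size_closed < 1:
            raise ValueError("lexicon sizes must be positive")
        if self.zipf_exponent <= 0:
            raise ValueError("zipf_exponent must be positive")
        if self.open_closed_rate <= 0:
            raise ValueError("open_closed_rate must be positive")
        if self.sentence_length_mean < 1:
            raise ValueError("sentence_length_mean must be >= 1")
        if self.clause_rate < 0 or self.attachment_locality < 0:
            raise ValueError("rates must be nonnegative")
        if not 0 <= self.repeat_prob < 1:
            raise ValueError("repeat_prob must be in [0, 1)")
        if self.target_words < self.sentence_length_mean:
            raise ValueError("target_words must be >= sentence_length_mean")


_zipf_cache: dict[tuple[int, float], np.ndarray] = {}
_lexicon_cache: dict[tuple[str, int], np.ndarray] = {}


def _zipf_cdf(size: int, exponent: float) -> np.ndarray:
    key = (size, exponent)
    cdf = _zipf_cache.get(key)
    if cdf is None:
        p = np.arange(1, size + 1, dtype=float) ** (-exponent)
        cdf = np.cumsum(p / p.sum())
        _zipf_cache[key] = cdf
    return cdf


def _lexicon(prefix: str, size: int) -> np.ndarray:
    key = (prefix, size)
    lex = _lexicon_cache.get(key)
    if lex is None:
        width = len(str(size - 1))
        lex = np.array([f"{prefix}{r:0{width}d}" for r in range(size)], dtype=object)
        _lexicon_cache[key] = lex
    return lex


def _sample_rows(params: GeneratorParams, rng: np.random.Generator):
    """Draw one sentence as mutable token rows plus ground truth.

    Returns (forms, lemmas, upos, heads, deprels, truth) where truth holds
    the planted clause count and the dependency-length contributions of
    the tree (words only; the sentence-final punctuation token is added
    later and does not enter the truth).
    """
    n = 1 + rng.poisson(max(params.sentence_length_mean - 1.0, 0.0))

    # Projective tree via right-frontier attachment: word 1 is the root;
    # word i attaches to the frontier node nearest its drawn distance.
    heads = np.zeros(n, dtype=int)
    p_geom = 1.0 / (1.0 + params.attachment_locality)
    gaps = rng.geometric(p_geom, size=n) - 1
    frontier = [1]
    dep_contrib = 0
    for i in range(2, n + 1):
        want = i - 1 - gaps[i - 1]
        head = min(frontier, key=lambda j: abs(j - want))
        heads[i - 1] = head
        frontier = frontier[: frontier.index(head) + 1] + [i]
        dep_contrib += max(0, (i - head) - 1)

    # POS classes and Zipf word forms from the matching sub-lexicon.
    p_open = params.open_closed_rate / (1.0 + params.open_closed_rate)
    is_open = rng.random(n) < p_open
    upos = np.empty(n, dtype=object)
    forms = np.empty(n, dtype=object)
    open_idx = np.flatnonzero(is_open)
    closed_idx = np.flatnonzero(~is_open)
    if open_idx.size:
        tags = np.searchsorted(_OPEN_CW, rng.random(open_idx.size))
        upos[open_idx] = np.array(_OPEN_TAGS, dtype=object)[tags]
        ranks = np.searchsorted(
            _zipf_cdf(params.lexicon_size_open, params.zipf_exponent),
            rng.random(open_idx.size),
        )
        forms[open_idx] = _lexicon("w", params.lexicon_size_open)[ranks]
    if closed_idx.size:
        tags = np.searchsorted(_CLOSED_CW, rng.random(closed_idx.size))
        upos[closed_idx] = np.array(_CLOSED_TAGS, dtype=object)[tags]
        ranks = np.searchsorted(
            _zipf_cdf(params.lexicon_size_closed, params.zipf_exponent),
            rng.random(closed_idx.size),
        )
        forms[closed_idx] = _lexicon("c", params.lexicon_size_closed)[ranks]

    deprels = np.empty(n, dtype=object)
    deprels[0] = "root"
    if n > 1:
        fill = rng.integers(0, len(_FILLER_DEPRELS), size=n - 1)
        deprels[1:] = np.array(_FILLER_DEPRELS, dtype=object)[fill]

    # Plant clause heads on non-root words; they become verbal so both the
    # subordinate and the coordinate (verbal conj) rules fire exactly on them.
    k = min(int(rng.poisson(params.clause_rate)), n - 1)
    planted = 0
    if k > 0:
        positions = rng.choice(np.arange(2, n + 1), size=k, replace=False)
        labels = rng.integers(0, len(_CLAUSE_DEPRELS), size=k)
        for pos, lab in zip(positions, labels):
            deprels[pos - 1] = _CLAUSE_DEPRELS[lab]
            upos[pos - 1] = "VERB"
        planted = k

    truth = {"clauses_planted": planted, "dep_contrib_sum": dep_contrib, "n_words": n}
    return list(forms), list(upos), heads.tolist(), list(deprels), truth


def _build_sentence(forms, upos, heads, deprels, add_punct: bool = True) -> Sentence:
    tokens = [
        AnnotatedToken(i + 1, forms[i], forms[i], upos[i], heads[i], deprels[i])
        for i in range(len(forms))
    ]
    if add_punct:
        tokens.append(
            AnnotatedToken(len(forms) + 1, ".", ".", "PUNCT", 1, "punct")
        )
    return Sentence(tuple(tokens))


def sample_sentence(params: GeneratorParams, rng: np.random.Generator) -> Sentence:
    """One random sentence; ground truth rides in the transcript-level
    metadata when drawn through :func:`sample_transcript`."""
    forms, upos, heads, deprels, _ = _sample_rows(params, rng)
    return _build_sentence(forms, upos, heads, deprels)


def sample_transcript(
    params: GeneratorParams,
    rng: np.random.Generator | None = None,
    subject_id: str = "sim",
    timepoint: str = "baseline",
) -> Transcript:
    """One narration: sentences until at least ``target_words`` words.

    After drawing each sentence, every adjacent word pair is replaced —
    independently with probability ``repeat_prob`` — by a bigram already
    used earlier in the narration, emulating verbatim phrase reuse.  The
    transcript's ``meta`` records planted clause counts, the tree's true
    dependency-length contributions, and the generating parameters.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    sentences: list[Sentence] = []
    history: list[tuple[str, str]] = []
    words = 0
    clauses = 0
    dep_scores = []
    sent_word_counts = []
    while words < params.target_words:
        forms, upos, heads, deprels, truth = _sample_rows(params, rng)
        n = len(forms)
        if params.repeat_prob > 0 and history:
            hits = np.flatnonzero(rng.random(max(n - 1, 0)) < params.repeat_prob)
            for i in hits:
                f1, f2 = history[int(rng.integers(len(history)))]
                forms[i], forms[i + 1] = f1, f2
        history.extend((forms[i], forms[i + 1]) for i in range(n - 1))
        sentences.append(_build_sentence(forms, upos, heads, deprels))
        words += n
        clauses += truth["clauses_planted"]
        dep_scores.append(truth["dep_contrib_sum"] / truth["n_words"])
        sent_word_counts.append(n)
    transcript = Transcript(subject_id, timepoint, sentences)
    transcript.meta = {
        "params": dataclasses.asdict(params),
        "clauses_planted": clauses,
        "n_sentences": len(sentences),
        "sentence_word_counts": sent_word_counts,
        "true_dependency_length": float(np.mean(dep_scores)),
        "true_clause_sentence_ratio": clauses / len(sentences),
    }
    return transcript


@dataclass(frozen=True)
class GroupSpec:
    """One study arm: label, size, and its baseline generator settings."""

    label: str
    n: int
    params: GeneratorParams = GeneratorParams()

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("each group needs n >= 2")


@dataclass(frozen=True)
class CovariateSpec:
    """An optional clinical-scale-like covariate: subject baseline drawn
    Normal(mean, sd); followup adds a per-group shift plus within-subject
    noise of scale ``change_sd``."""

    name: str
    mean: float = 25.0
    sd: float = 3.0
    change_sd: float = 1.5
    followup_shift: dict = field(default_factory=dict)


@dataclass(frozen=True)
class CohortDesign:
    """Three-ish groups × two timepoints with multiplicative followup
    effects on ``sentence_length_mean`` and ``clause_rate``.

    ``effects[label]`` maps those two parameter names to multiplicative
    shifts applied at followup (1.0 = no change; a drift < 1 models
    untreated decline).  ``subject_sigma`` is the SD of a log-normal
    subject random effect multiplying ``sentence_length_mean`` at both
    timepoints, inducing the within-subject correlation a paired design
    relies on.
    """

    groups: tuple[GroupSpec, ...]
    effects: dict = field(default_factory=dict)
    subject_sigma: float = 0.1
    covariates: tuple[CovariateSpec, ...] = ()

    _SHIFTABLE = ("sentence_length_mean", "clause_rate")

    def __post_init__(self) -> None:
        object.__setattr__(self, "groups", tuple(self.groups))
        object.__setattr__(self, "covariates", tuple(self.covariates))
        if not self.groups:
            raise ValueError("design needs at least one group")
        labels = [g.label for g in self.groups]
        if len(set(labels)) != len(labels):
            raise ValueError("group labels must be unique")
        for label, shifts in self.effects.items():
            if label not in labels:
                raise ValueError(f"effects refer to unknown group {label!r}")
            for key, val in shifts.items():
                if key not in self._SHIFTABLE:
                    raise ValueError(f"cannot shift parameter {key!r}")
                if val <= 0:
                    raise ValueError("effect shifts must be positive")
        if self.subject_sigma < 0:
            raise ValueError("subject_sigma must be >= 0")


@dataclass
class SimulatedCohort:
    """Output bundle of :func:`sample_cohort`."""

    features: list[FeatureVector]
    transcripts: list[Transcript]
    design_rows: list[dict]
    truth: dict


def sample_cohort(
    design: CohortDesign,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    lex: LexicalParams = LexicalParams(),
    rules: ClauseRules = ClauseRules(),
    keep_transcripts: bool = False,
) -> SimulatedCohort:
    """Simulate the full longitudinal cohort and extract its features.

    Per subject: a log-normal random effect on ``sentence_length_mean``
    (shared across timepoints), a baseline transcript from group
    parameters, and a followup transcript from the effect-shifted
    parameters.  ``truth`` records the design and the per-subject random
    effects so recovery tests can condition on them.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    features: list[FeatureVector] = []
    transcripts: list[Transcript] = []
    design_rows: list[dict] = []
    subject_effects: dict[str, float] = {}
    for group in design.groups:
        shifts = design.effects.get(group.label, {})
        for i in range(group.n):
            sid = f"{group.label}{i:03d}"
            b = float(np.exp(rng.normal(0.0, design.subject_sigma))) if design.subject_sigma else 1.0
            subject_effects[sid] = b
            cov_base = {
                c.name: float(rng.normal(c.mean, c.sd)) for c in design.covariates
            }
            for tp in TIMEPOINTS:
                p = group.params
                slm = p.sentence_length_mean * b
                cr = p.clause_rate
                if tp == "followup":
                    slm *= shifts.get("sentence_length_mean", 1.0)
                    cr *= shifts.get("clause_rate", 1.0)
                p_tp = replace(
                    p,
                    sentence_length_mean=max(slm, 1.0),
                    clause_rate=cr,
                    target_words=p.target_words,
                    seed=None,
                )
                t = sample_transcript(p_tp, rng, subject_id=sid, timepoint=tp)
                features.append(extract_features(t, lex, rules))
                if keep_transcripts:
                    transcripts.append(t)
                row = {"subject_id": sid, "group": group.label, "timepoint": tp}
                for c in design.covariates:
                    val = cov_base[c.name]
                    if tp == "followup":
                        val += c.followup_shift.get(group.label, 0.0)
                        val += float(rng.normal(0.0, c.change_sd))
                    row[c.name] = val
                design_rows.append(row)
    truth = {
        "groups": [
            {"label": g.label, "n": g.n, "params": dataclasses.asdict(g.params)}
            for g in design.groups
        ],
        "effects": {k: dict(v) for k, v in design.effects.items()},
        "subject_sigma": design.subject_sigma,
        "subject_effects": subject_effects,
    }
    return SimulatedCohort(features, transcripts, design_rows, truth)
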