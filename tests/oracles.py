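"""Independent brute-force reference implementations.

Everything here is written from the feature definitions directly —
simple, quadratic-time, no code shared with the package — so the tests
can compare two genuinely separate routes to the same number.
"""

from __future__ import annotations

import itertools
import math

NON_WORD = {"PUNCT", "SYM", "X"}
OPEN = {"ADJ", "ADV", "INTJ", "NOUN", "PROPN", "VERB"}
CLOSED = {"ADP", "AUX", "CCONJ", "DET", "NUM", "PART", "PRON", "SCONJ"}
SUBORDINATE = {"csubj", "ccomp", "xcomp", "advcl", "acl"}


def words_of(sentence):
    return [t for t in sentence.tokens if t.upos not in NON_WORD]


def oracle_content_density(transcript):
    tags = [t.upos for s in transcript.sentences for t in words_of(s)]
    n_open = sum(1 for u in tags if u in OPEN)
    n_closed = sum(1 for u in tags if u in CLOSED)
    assert n_closed > 0
    return n_open / n_closed


def oracle_mattr(transcript, window):
    types = [t.form.casefold() for s in transcript.sentences for t in words_of(s)]
    n = len(types)
    assert n > 0
    if n < window:
        return len(set(types)) / n
    ratios = [
        len(set(types[i : i + window])) / window for i in range(n - window + 1)
    ]
    return sum(ratios) / len(ratios)


def oracle_ngram_repetition(transcript, orders=(2, 3, 4)):
    rates = []
    for k in orders:
        seen = []
        for s in transcript.sentences:
            types = [t.form.casefold() for t in words_of(s)]
            for i in range(len(types) - k + 1):
                seen.append(tuple(types[i : i + k]))
        rates.append((len(seen) - len(set(seen))) / len(seen) if seen else 0.0)
    return sum(rates) / len(rates)


def oracle_mlu(transcript):
    lengths = [len(words_of(s)) for s in transcript.sentences]
    lengths = [n for n in lengths if n > 0]
    return sum(lengths) / len(lengths)


def oracle_clause_count(sentence):
    """Subordinate heads + verbal/subject-governing conj dependents."""
    count = 0
    for t in sentence.tokens:
        if t.upos in NON_WORD:
            continue
        base = t.deprel.split(":")[0]
        if base in SUBORDINATE:
            count += 1
        elif base == "conj":
            governs_subj = any(
                o.head == t.index and o.deprel.split(":")[0] in {"nsubj", "csubj"}
                for o in sentence.tokens
            )
            if t.upos in {"VERB", "AUX"} or governs_subj:
                count += 1
    return count


def oracle_clause_sentence_ratio(transcript):
    return sum(oracle_clause_count(s) for s in transcript.sentences) / len(
        transcript.sentences
    )


def oracle_dependency_length(transcript):
    scores = []
    for s in transcript.sentences:
        words = words_of(s)
        if not words:
            continue
        pos = {t.index: i + 1 for i, t in enumerate(words)}
        by_index = {t.index: t for t in s.tokens}
        total = 0
        for t in words:
            head = t.head
            # climb through punctuation governors
            while head != 0 and by_index[head].upos in NON_WORD:
                head = by_index[head].head
            if head == 0:
                continue
            total += max(0, abs(pos[t.index] - pos[head]) - 1)
        scores.append(total / len(words))
    return sum(scores) / len(scores)


# ---------------------------------------------------------------------------
# exact rank-test null distributions by exhaustive enumeration


def exact_mannwhitney_p(x, y):
    """Two-sided Mann-Whitney p by enumerating all group assignments of
    the pooled sample (no ties assumed)."""
    pooled = list(x) + list(y)
    n1 = len(x)

    def ustat(idx):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        return sum(1 for a in xs for b in ys if a > b) + 0.5 * sum(
            1 for a in xs for b in ys if a == b
        )

    observed = sum(1 for a in x for b in y if a > b) + 0.5 * sum(
        1 for a in x for b in y if a == b
    )
    n2 = len(y)
    mu = n1 * n2 / 2
    obs_dev = abs(observed - mu)
    count = 0
    total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        total += 1
        if abs(ustat(set(idx)) - mu) >= obs_dev - 1e-12:
            count += 1
    return count / total


def exact_signed_rank_p(diffs):
    """Two-sided Wilcoxon signed-rank p by enumerating all 2^n sign
    patterns of the absolute differences (no zeros or tied |d| assumed)."""
    d = [abs(v) for v in diffs if v != 0]
    n = len(d)
    ranks = {v: r + 1 for r, v in enumerate(sorted(d))}
    w_obs = sum(ranks[abs(v)] for v in diffs if v > 0)
    mu = n * (n + 1) / 4
    obs_dev = abs(w_obs - mu)
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(ranks[d[i]] for i in range(n) if signs[i])
        if abs(w - mu) >= obs_dev - 1e-12:
            count += 1
    return count / 2**n
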