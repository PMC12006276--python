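"""Shared builders: hand-rolled tokens/sentences and a random small-
transcript generator that is independent of the package's simulator."""

from __future__ import annotations

import numpy as np
import pytest

from lexsyn import AnnotatedToken, Sentence, Transcript

UPOS_POOL = [
    "NOUN", "VERB", "ADJ", "ADV", "PRON", "DET", "ADP", "AUX",
    "CCONJ", "SCONJ", "NUM", "PART", "INTJ", "PROPN", "PUNCT",
]
DEPREL_POOL = [
    "nsubj", "obj", "obl", "nmod", "amod", "det", "case", "advmod",
    "advcl", "ccomp", "xcomp", "acl", "acl:relcl", "conj", "cc", "mark",
]


def tok(index, form="w", upos="NOUN", head=0, deprel="dep", lemma=None):
    return AnnotatedToken(index, form, lemma if lemma is not None else form, upos, head, deprel)


def sent(*specs):
    """Build a sentence from (form, upos, head[, deprel]) tuples."""
    tokens = []
    for i, spec in enumerate(specs, start=1):
        form, upos, head = spec[:3]
        deprel = spec[3] if len(spec) > 3 else ("root" if head == 0 else "dep")
        tokens.append(AnnotatedToken(i, form, form, upos, head, deprel))
    return Sentence(tuple(tokens))


def chain_sentence(forms, upos=None, deprels=None):
    """Each word governed by its left neighbor; word 1 is the root."""
    n = len(forms)
    upos = upos or ["NOUN"] * n
    deprels = deprels or (["root"] + ["dep"] * (n - 1))
    return Sentence(
        tuple(
            AnnotatedToken(i + 1, forms[i], forms[i], upos[i], i, deprels[i])
            for i in range(n)
        )
    )


def transcript_of(*sentences, subject="s1", timepoint="baseline"):
    return Transcript(subject, timepoint, list(sentences))


def random_small_transcript(rng, max_words=30, vocab=12):
    """A random valid transcript independent of lexsyn.simulate: random
    (possibly non-projective) trees built by attaching each token, in a
    random order, to an already-placed token."""
    n_sent = int(rng.integers(1, 4))
    sentences = []
    for _ in range(n_sent):
        n = int(rng.integers(2, max(3, max_words // n_sent + 1)))
        order = rng.permutation(n) + 1
        heads = {int(order[0]): 0}
        for k in range(1, n):
            heads[int(order[k])] = int(order[int(rng.integers(0, k))])
        tokens = []
        for i in range(1, n + 1):
            upos = UPOS_POOL[int(rng.integers(0, len(UPOS_POOL)))]
            deprel = "root" if heads[i] == 0 else DEPREL_POOL[int(rng.integers(0, len(DEPREL_POOL)))]
            form = f"v{int(rng.integers(0, vocab))}"
            tokens.append(AnnotatedToken(i, form, form, upos, heads[i], deprel))
        sentences.append(Sentence(tuple(tokens)))
    return Transcript("rnd", "baseline", sentences)


@pytest.fixture
def rng():
    return np.random.default_rng(20250926)


SAMPLE_CONLLU = """\
# newdoc id = subj01__baseline
# sent_id = subj01__baseline__s1
1\tThe\tthe\tDET\t_\t_\t2\tdet\t_\t_
2\tdog\tdog\tNOUN\t_\t_\t3\tnsubj\t_\t_
3\truns\trun\tVERB\t_\t_\t0\troot\t_\t_
4\tfast\tfast\tADV\t_\t_\t3\tadvmod\t_\t_
5\t.\t.\tPUNCT\t_\t_\t3\tpunct\t_\t_

# sent_id = subj01__baseline__s2
1\tIt\tit\tPRON\t_\t_\t2\tnsubj\t_\t_
2\tbarks\tbark\tVERB\t_\t_\t0\troot\t_\t_
3\twhen\twhen\tSCONJ\t_\t_\t5\tmark\t_\t_
4\tcats\tcat\tNOUN\t_\t_\t5\tnsubj\t_\t_
5\tarrive\tarrive\tVERB\t_\t_\t2\tadvcl\t_\t_
6\tquickly\tquickly\tADV\t_\t_\t5\tadvmod\t_\t_
7\t.\t.\tPUNCT\t_\t_\t2\tpunct\t_\t_
"""
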