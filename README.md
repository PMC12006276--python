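# lexsyn

Lexical and syntactic discourse features from dependency-annotated
speech transcripts, with the longitudinal group-comparison statistics
used in clinical language studies.

## The problem

Spontaneous connected speech — e.g. a short fairy-tale narration — is a
sensitive window on cognitive-linguistic function in neurodegenerative
disease. In Parkinson's disease, syntactic simplification (shorter
sentences, fewer embedded clauses) can appear early and may respond to
dopaminergic therapy. Quantifying this requires (i) objective features
computed from transcripts that have been tokenized, POS-tagged and
dependency-parsed (CoNLL-U format, Universal Dependencies conventions),
and (ii) a statistical procedure for comparing patient groups
cross-sectionally and tracking within-subject change across a baseline
and a follow-up visit.

`lexsyn` implements both, plus a fully parameterized synthetic cohort
generator so that every stage of the pipeline can be validated with
known ground truth — no patient data are required or included.

## The six features

For a transcript with word sequence w (punctuation excluded everywhere):

**Lexical**

- *Content density* — |open-class words| / |closed-class words|, with
  open = {ADJ, ADV, INTJ, NOUN, PROPN, VERB} and closed = {ADP, AUX,
  CCONJ, DET, NUM, PART, PRON, SCONJ}.
- *MATTR* — moving-average type-token ratio: mean of
  |types(w[i..i+W))| / W over all windows of size W (default 84, step 1);
  texts shorter than W fall back to whole-text TTR.
- *n-gram repetition* — for each order n ∈ {2,3,4}, the fraction of
  n-gram occurrences that repeat an earlier identical intra-sentence
  phrase, (T_n − D_n)/T_n, averaged over orders.

**Syntactic**

- *Mean length of utterance (MLU)* — mean words per sentence.
- *Clause-to-sentence ratio* — subordinate clause heads (deprel base in
  {csubj, ccomp, xcomp, advcl, acl}) plus coordinate clause heads
  (verbal `conj` dependents) divided by the number of sentences.
- *Dependency length* — per word, the number of words intervening
  between it and its governor, max(0, |i−j|−1) on word-only positions;
  summed per sentence, normalized by sentence word count, averaged over
  sentences.

The statistics module applies the conventional gated procedure:
Kolmogorov–Smirnov normality testing with Lilliefors-corrected critical
values decides between ANOVA + Fisher LSD and Kruskal–Wallis +
Mann–Whitney U at baseline, between paired t and Wilcoxon signed-rank
for follow-up − baseline change, and between Pearson and Spearman for
change–change correlations. Multiple comparisons are controlled by
Bonferroni adjustment within each three-feature family: α = 0.05/3 ≈
0.0167, reported alongside the raw 0.05 threshold.

## Worked example

```python
import lexsyn as lx

params = lx.GeneratorParams(seed=7)      # ~168-word synthetic narration
t = lx.sample_transcript(params)
fv = lx.extract_features(t)
print("words =", t.word_count, " sentences =", len(t.sentences))
for k, v in fv.values.items():
    print(f"{k:>22s} = {v:.4f}")
```

prints

```
words = 173  sentences = 13
       content_density = 1.3699
                 mattr = 0.5434
      ngram_repetition = 0.0271
                   mlu = 13.3077
 clause_sentence_ratio = 0.3846
     dependency_length = 1.0200
```

Reading: this narration has 1.37 content words per function word, a
moving-average type-token ratio of 0.54 (moderate lexical diversity),
2.7 % of its 2–4-grams are verbatim phrase repeats, sentences average
13.3 words with 0.38 clause embeddings each (a low Poisson draw around
the generating rate of 1.0/sentence), and the average word sits about
one word away from being adjacent to its governor.

The same pipeline runs from the shell on directories of CoNLL-U files:

```bash
lexsyn simulate --seed 1 --out-dir corpus/       # or bring your own corpus
lexsyn extract corpus/ --out features.csv
lexsyn analyze --features features.csv --design corpus/design.csv \
               --out report.json
```

`report.json` contains every omnibus, post hoc, paired-change and
correlation result with the test actually used, its raw p-value, and
significance flags at both thresholds; a flat `report.summary.tsv` is
written alongside.

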