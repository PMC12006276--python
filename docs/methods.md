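# Methods

## Scope and data model

`lexsyn` analyzes dependency-annotated transcripts of short spontaneous
narrations. Input is CoNLL-U: sentence-segmented tokens with UPOS tags,
head indices and dependency relation labels, as produced by any
Universal Dependencies parser. The package takes segmentation and
parses as given — it performs no ASR, tokenization or re-parsing.
Multiword-token range lines are skipped in favor of their syntactic
words; empty nodes and enhanced dependencies are ignored (basic trees
only). Subject and timepoint identity come from
`# newdoc id = <subject>__<timepoint>` comments or the filename stem.

A **word** is any token whose UPOS is not PUNCT, SYM or X; INTJ counts
as a word. This single filter is applied uniformly, so every feature is
invariant to inserting or deleting punctuation tokens. Word counts
reported by the package are therefore punctuation-free counts — a
convention of this implementation.

## Feature definitions and conventions

Where a feature admits more than one reasonable operationalization, the
choice made here is listed with its rationale.

- **Content density** = open/closed word-class ratio using the UD v2
  taxonomy (open: ADJ, ADV, INTJ, NOUN, PROPN, VERB; closed: ADP, AUX,
  CCONJ, DET, NUM, PART, PRON, SCONJ). Undefined (explicit missing
  value, never 0) when a transcript has no closed-class word.
- **MATTR**, window 84 words, step 1. Word-type identity is the
  case-folded *surface form*, not the lemma: case-folding removes
  sentence-initial capitalization artifacts, and surface forms keep the
  measure robust to lemmatizer errors in inflected languages. Texts
  shorter than the window fall back to whole-text TTR so the feature is
  total on all inputs.
- **n-gram repetition** is normalized to a rate, (T − D)/T per order,
  averaged over orders {2,3,4}. Raw repeat counts grow with text
  length; the rate form is length-stable and bounded in [0, 1). n-grams
  never cross sentence boundaries (a "phrase" is intra-sentence).
  Undefined when the transcript has fewer words than the largest order.
- **MLU**: mean words per sentence, punctuation-only sentences skipped.
- **Clause-to-sentence ratio**: a token heads a subordinate clause when
  its deprel base (the part before any `:` subtype) is one of csubj,
  ccomp, xcomp, advcl, acl; a `conj` dependent heads a coordinate
  clause when it is verbal (VERB/AUX) or governs its own subject
  (covers gapped coordination). Each matching token counts once, nested
  clauses included. The label inventory is configurable (`ClauseRules`)
  because no single inventory is canonical.
- **Dependency length** uses "intervening words" semantics:
  max(0, |i − j| − 1) on word-only positions recomputed after
  punctuation removal; adjacent pairs contribute 0, the root
  contributes 0. Dependents whose governor is a punctuation token are
  reattached to the governor's nearest word ancestor (preserving the
  dependent and the sentence word count) rather than dropped. Sentence
  scores (sum/word count) are averaged unweighted across sentences.

Undefined features propagate as NaN plus a recorded reason; downstream
analyses exclude them listwise, never impute.

## Statistical procedure

- **Normality gate**: KS test against a normal with sample-estimated
  mean/SD, using Lilliefors-corrected critical values (the plain KS
  test is anticonservative once parameters are estimated from the same
  sample; a plain-KS mode and an always-nonparametric mode are
  available by configuration). Samples with n < 4 or zero variance
  route to the nonparametric branch. Every gate decision is recorded in
  the report.
- **Cross-sectional** (baseline): all groups normal → one-way ANOVA
  with Fisher LSD pairwise t-tests on the pooled within-group mean
  square; otherwise Kruskal–Wallis with pairwise two-sided
  Mann–Whitney U. Post hocs are protected: reported only when the
  omnibus rejects at α. A single non-normal group routes the whole
  feature to the nonparametric branch. Groups with < 2 observations
  are excluded with a reason.
- **Longitudinal change** = followup − baseline per subject; paired t
  on the differences when they pass the gate, Wilcoxon signed-rank
  otherwise (zeros dropped per Wilcoxon's convention; exact null
  distribution for n ≤ 25 without tied magnitudes, normal approximation
  with continuity correction otherwise). All-zero differences are
  reported as explicit "no evidence", not as a test statistic. Groups
  with < 4 complete pairs are excluded with a reason.
- **Correlations** between change vectors: Pearson when both pass the
  gate, Spearman otherwise; n ≥ 5 and nonzero variance required.
- **Multiplicity**: Bonferroni within each three-feature family
  (lexical, syntactic): adjusted threshold α/3 = 0.0167 at α = 0.05.
  Because borderline paired-change p-values are interpreted differently
  under the raw and adjusted conventions, the report always carries
  both thresholds and both flags rather than a single verdict.
- **Severity profiles**: features can be z-scored against the control
  group's baseline distribution (default; pooled-baseline optional)
  with sign flips on mlu, clause_sentence_ratio, mattr and
  content_density so that higher always means greater severity.

All reported p-values are invariant to row order and subject
relabeling; identical inputs yield byte-identical CSV/JSON outputs.

## Synthetic cohort generator

The generator emulates the *structure* of a longitudinal
patient-control speech study — three arms (healthy control, untreated
patients, treated patients), two timepoints, ~90–170-word narrations —
not natural language itself. Each generator knob governs exactly one
extracted feature, which is what makes parameter-recovery and
calibration experiments interpretable:

| parameter | default | governs | rationale |
|---|---|---|---|
| `target_words` | 168 | transcript length | typical narration length in this task (~168 words, SD 40) |
| `sentence_length_mean` | 12 words | MLU | mid-range adult narrative MLU |
| `clause_rate` | 1.0 /sentence | clause ratio | roughly one embedding per sentence |
| `attachment_locality` | 1.5 | dependency length | mean geometric attachment gap |
| `zipf_exponent` | 1.1 | MATTR | word-frequency skew of a small narrative lexicon |
| `open_closed_rate` | 1.2 | content density | slight open-class excess |
| `repeat_prob` | 0.05 | n-gram repetition | occasional verbatim phrase reuse |
| `lexicon_size_open/closed` | 400 / 60 | vocabulary ceiling | narration-scale vocabularies |

Sentence length is 1 + Poisson(mean − 1), so the degenerate mean of 1
yields one-word sentences exactly. Dependency trees are random
*projective* trees built by right-frontier attachment with geometric
attachment-distance decay — simple, reproducible, and sufficient to
make dependency length controllable; linguistic realism of the trees is
a non-goal. Clause heads are planted by drawing a truncated-Poisson
count per sentence and relabeling non-root words with clause deprels
(made verbal), and the filler relation inventory excludes every
clause-marking label, so planted counts equal extracted counts exactly
(the truncation at short sentences means realized rates sit slightly
below nominal `clause_rate`; ground truth records realized counts).
Phrase repetition re-emits previously used bigrams with probability
`repeat_prob` per adjacent word pair, touching forms only. Each
sentence ends with a planted punctuation token so the
punctuation-filtering path is exercised end to end.

Cohorts add a log-normal subject random effect (SD 0.1) multiplying
`sentence_length_mean` at both timepoints — inducing the within-subject
correlation that paired tests exploit — and per-group multiplicative
followup effects on `sentence_length_mean` and `clause_rate` (the two
syntactic parameters through which a treatment benefit is modeled).
Optional covariate columns emulate clinical scales as Gaussian
baselines with per-group followup shifts.

**What passing tests do and do not show.** The generator's word
frequencies are exchangeable within a Zipf lexicon and its trees are
memoryless; real narrations have topical structure, morphology,
disfluencies and ASR errors. Calibration and recovery results therefore
validate the *pipeline* (features measure what the generator planted;
the gated tests keep their nominal error rates on these feature
distributions), not clinical effect sizes, which can only come from
real cohorts.

## Problem sizes and numerical choices

Simulation-based checks run at: 200 replicate studies with group sizes
68/17/92 and 120-word narrations for null calibration and effect
recovery (chosen to mirror a realistic study's arm sizes while keeping
a full calibration run in the minutes range on one CPU); 50 replicates
per level for monotone generator-feature trend checks; 2,000 replicates
for the paired-pipeline type-I band [0.03, 0.07]. The familywise
false-positive event for a family is "any of its three features
significant at α/3 in the baseline cross-sectional omnibus" — one test
per feature, so the nominal familywise rate is 0.05. Feature-vs-oracle
comparisons use 1e-12 relative tolerance; all feature computations are
deterministic double-precision arithmetic with no iterative numerics.
All randomness flows from a single seed through one `numpy` generator;
there is no hidden global RNG state.

## Known limitations

- Clause identification is purely label-based; parser errors in
  `conj`/`advcl` attachment translate directly into clause-ratio error.
- The coordinate-clause rule does not attempt to detect clausal
  coordination marked only by punctuation.
- MATTR with the 84-word default window reduces to whole-text TTR on
  very short transcripts, which is less comparable across lengths.
- The normality gate at small n (< ~20) has low power, so the
  parametric branch is chosen liberally there; this matches common
  practice but is a known weakness of gated procedures.
- The generator does not emulate morphology, ASR noise, topic effects
  or inter-feature correlations beyond those induced by shared sentence
  structure.
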