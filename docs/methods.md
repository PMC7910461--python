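# Methods

## Problem and pipeline

`cardioicd` assigns ICD-10 diagnosis codes to free-text cardiology
discharge letters. A letter usually carries several codes at once
(multilabel), and the code vocabulary is hierarchical: `I48.1`
(persistent atrial fibrillation) rolls up to the three-character `I48`
(atrial fibrillation and flutter). The pipeline runs in stages:

1. **Pseudonymization** — rule-based replacement of protected health
   information (dates, ages, names, institutions) with numbered
   placeholders `<DATUM-1>`, `<LEEFTIJD-1>`, `<PERSOON-1>`,
   `<INSTELLING-1>`. Longest-match-wins, left to right; repeated
   identical originals reuse their ordinal; the operation is idempotent
   because `<` and `>` are excluded from every PHI pattern.
2. **Preprocessing** — lowercase, collapse whitespace, drop standalone
   number tokens (digits embedded in words such as `dmii` or `i48` are
   kept: they are diagnostic cues). Placeholders stay atomic tokens.
   The vocabulary is built from the training split only, discarding
   tokens seen fewer than twice; indices are frequency-ordered with
   alphabetical tie-breaks, so encoding is fully deterministic.
3. **Word embeddings** — 300-dimensional skip-gram vectors with a
   symmetric window of 5 and negative sampling (unigram^0.75 noise),
   trained on the training letters and used to initialize each
   classifier's (trainable) embedding layer.
4. **Per-code classifiers (binary relevance)** — one small bidirectional
   GRU per retained code: embedding → BiGRU (100 units per direction,
   dropout 0.2, recurrent dropout 0.2, final states concatenated) →
   dense 128 relu → 2-unit softmax ("assign"/"not assign"). Padding
   index 0 is masked by carrying the hidden state through padded steps,
   which makes probabilities exactly invariant to trailing padding.
   Training one code never touches another: each model derives its seed
   from the code string itself.
5. **Multilabel decision** — a single global probability threshold chosen
   so that the number of (letter, code) cells predicted positive on the
   evaluation set matches the training set's label cardinality:
   with n letters and training cardinality c, the k = round(c·n) most
   probable cells are predicted. Cells strictly above the threshold
   count as positives; ties straddling the cut fall to the closest
   achievable count below.
6. **Evaluation** — sensitivity, specificity, PPV, NPV and
   F1 = 2TP/(2TP+FP+FN) per code and pooled over all cells (micro).
   Zero-denominator metrics are reported as missing and flagged, never
   silently zero. Coder agreement uses Cohen's kappa pooled over
   (letter, code) items with a cluster bootstrap over letters for the
   95% percentile interval.
7. **Interpretation** — per-code word coefficients, either from a
   ridge-regularized linear surrogate fitted on token-presence vectors
   against the classifier's probabilities, or by occlusion: the mean
   change in predicted log-odds when all occurrences of a token are
   removed from the letters containing it.

## Model training choices

The loss is 2-class cross-entropy; the optimizer is Adam (default
lr 1e-3, batch 32, at most 30 epochs). 20% of the training letters are
held out per code for early stopping (patience 5); the best-validation
parameters are restored. Five-fold cross-validation is available for
epoch/hyperparameter selection within the training split.

Two initialization details matter on corpora of a few thousand letters:

* **Update-gate bias +1.** The GRU's update gate is initialized to favor
  carrying state (the analogue of LSTM forget-bias-1). With a zero
  init, validation loss rises for several epochs before the lexical
  signal is found, and an aggressive early stop freezes the model at
  chance.
* **Embedding post-processing.** Skip-gram vectors trained on small
  corpora are dominated by a shared mean direction; used raw they make
  all tokens look alike to the recurrent layer, and pretrained
  initialization performed *worse* than random. The pretrainer removes
  the common mean and L2-normalizes rows to 0.5 before handing the
  matrix to the classifier.

A down-scaled profile (`ModelConfig.test_profile()`: embedding 32, GRU
16/direction, dense 16, lr 1e-2, patience 6, max sequence length 200) is
used by the test-suite and the acceptance script so full pipelines train
in minutes on one CPU; it changes capacity, not behavior. The default
profile keeps the reference sizes (300/100/128, max length 1500 — real
discharge letters average near a thousand tokens).

## Synthetic study corpora

Real coding corpora are privacy-restricted, so the generator emulates
the statistical structure the pipeline depends on, with defaults set to
a cardiology department's profile: ten codes (six main diagnoses, four
risk factors), mean label cardinality 4.7, median age 68 (IQR 58–77),
36% female, roughly two PHI spans per letter.

Each letter is template-based token soup — named sections
(`Reden van opname`, body, `Conclusie en beleid`), neutral clinical
filler, and planted signal:

* every assigned code plants two trigger tokens drawn from its profile
  (synonyms and medication names, e.g. `metformine`, `gliclazide`,
  `insuline`, `diabetes`, `dmii` for type-2 diabetes);
* risk-factor codes are **body-only**: their cues never appear in the
  summary paragraph, mirroring how risk factors are rarely restated
  there — this is what makes summary-only and full-text runs separable;
* with probability 0.35 one *non-assigned* code receives a **negated
  mention** that mirrors a genuine assignment exactly (same trigger
  count and placement) but with each trigger preceded by a negation
  word (`geen`, `nee`, `blanco`, `normale`; `geen` dominates). The
  negation word is thus the only feature separating these letters from
  true positives, so classifiers must use context, and the cue must
  acquire a negative coefficient;
* **label noise** is a per-letter coder error: with probability equal to
  the noise rate, one random code is flipped in the letter's gold set
  while the text is untouched. At 10% noise over 8 codes this is a
  1.25% per-cell error — the realistic regime where a letter
  occasionally carries a wrong code. (A 10% per-cell flip rate would
  cap even a perfect classifier's F1 near 0.87 and is not a useful
  study condition.)
* PHI is inserted at random token boundaries (never inside section
  headers) with exact character spans recorded as ground truth for the
  de-identifier.

Letter bodies default to 40–70 filler tokens and summaries to 12–20 —
an order of magnitude shorter than real letters, chosen so that full
pipelines run at test scale; the sequence-length mechanics (masking,
truncation, padding invariance) are what the tests must exercise, and
they are length-independent.

What the generator does **not** emulate: grammatical Dutch, realistic
section prose, correlated comorbidity structure (co-occurrence boosts
exist but default off), dosing logic, spelling variation, or coder
idiosyncrasies. Passing tests therefore demonstrate that the pipeline
recovers planted lexical structure under noise — not clinical-grade
performance on real letters.

## Numerical and degenerate-input conventions

* Empty corpus: label cardinality defined as 0.
* Precision of the de-id scorer with zero predictions: reported 1.0 with
  an explicit zero-prediction flag (avoids 0/0).
* Kappa with chance agreement 1: defined 1 when observed agreement is
  also 1, otherwise reported as NaN-with-flag.
* Threshold calibration returns the (k+1)-th largest probability, so all
  top-k cells are strictly above it; with k equal to the total cell
  count the threshold drops just below the minimum (floored at 0).
* All-equal probability matrices: the strict rule predicts nothing
  (closest achievable count below the target).
* Occlusion coefficients are computed on the log-odds scale because
  redundant planted cues saturate the probability itself; sign semantics
  are unchanged (positive = raises assignment probability).
* All randomness flows through `numpy.random.Generator` seeds; with BLAS
  threads pinned to 1 the whole pipeline is bit-reproducible.

## Open design points resolved

* Age/sex covariates enter as pseudo-tokens (`age_60`, `sex_f`)
  prepended to the sequence, keeping a single-input architecture; a
  dense-layer merge was considered and rejected for simplicity.
* The 2-unit softmax head is retained (mathematically equivalent to a
  sigmoid; the "assign" component is reported).
* Threshold calibration happens on the evaluation split's own
  predictions by default; a separate calibration split can be configured.
* Word coefficients are computed on training letters, describing what
  the model learned rather than how it generalizes.

## Known limitations

* The de-identifier is a minimal rule set (dates, ages, lexicon names
  and institutions) sufficient for the pipeline contract; it is not a
  certified clinical de-identifier.
* The numpy BGRU is single-CPU and sized for corpora of thousands of
  letters, not hundreds of thousands.
* Four-character code training is supported through the same binary
  relevance machinery, but the bundled generator's default profiles are
  three-character.
* Contextual embeddings (ELMo/BERT-style) are out of scope.
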