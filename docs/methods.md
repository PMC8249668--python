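# Methods

This note documents the modelling and numerical choices behind `sentweet`:
what the pipeline computes, the parameters that matter, what the synthetic
corpora do and do not emulate, and the places where the design was genuinely
open and a choice had to be made.

## Task and labels

The unit of analysis is a single tweet (≤ 280 characters) about sport-related
concussion. The label is the author's stance toward the *injury risk*:
`positive` = recognition of the seriousness of mild traumatic brain injury,
`negative` = disregard or lack of concern, `neutral` = no stance. The global
class order is fixed as (positive, negative, neutral) everywhere probabilities
or votes are indexed. Class priors in the emulated study corpus are
47% / 17% / 36%.

## Preprocessing

Cleaning runs in a fixed order chosen so that no step can corrupt the output
of an earlier one: (1) URL, mention and emoticon encoding; (2) hashtag
segmentation; (3) elongation trimming; (4) leading-`RT` removal and
punctuation stripping. URLs are encoded before emoticons because emoticon
surface forms (`:/`) occur inside URLs; elongation runs after encoding so it
cannot mangle a URL; punctuation stripping runs last so `<...>` encodings pass
through intact. Contractions keep their apostrophe so that `n't` survives to
tokenization as a negation cue, and number-bearing money/percent/time/date
patterns (`$5`, `50%`, `5:30`, `05/12/2018`) are protected because the entity
masker consumes them.

*Hashtag segmentation* maximizes the summed log unigram frequency over all
split points by dynamic programming, with camel-case and letter/digit
boundaries treated as free splits. Substrings absent from the bundled
dictionary pay a per-word plus per-character penalty
(log 10⁻⁸ − |w|·log 10), which keeps unknown material in one piece rather
than shredding it. The dictionary is a ~400-word frequency table bundled with
the package; segmentation is exactly reproducible because the table is
versioned.

*Elongation* reduces any character run of length ≥ 3 to 2; if the 2-run form
is not in the dictionary but the 1-run form is, it reduces to 1
(`helloooo` → `helloo`? no → `hello`). "Standard length" is not otherwise
defined, so the dictionary arbitrates.

*Retweets*: only a leading `RT` token marks a retweet; interior `RT` tokens
are content. This makes re-cleaning a cleaned text a no-op except for inputs
that carried stacked `RT RT ...` prefixes, where each pass consumes one
marker — an accepted edge case of the leading-marker rule.

*Tagging and lemmatization* use a deterministic rule-and-lexicon Penn
Treebank tagger bundled with the package: a ~250-word tag lexicon for closed
classes and frequent ambiguous words, suffix rules, and left-context rules
for noun/verb ambiguity. Tagging runs on surface forms (capitalization is
informative); lemmas are lowercased afterwards and conditioned on the tag
(`saw`/VBD → `see`, `saw`/NN → `saw`). Suffix stripping is conservative: a
candidate stem is accepted only if it appears in the frequency dictionary,
otherwise the surface form is kept — wrong lemmas are costlier than missed
conflations here, because lemmas key into the sentiment lexicon.

*Entity masking* replaces recognized spans by exactly seven class tags.
Money, percent, time and date come from surface patterns; person, location
and organization (plus literal month/weekday words) from a bundled
gazetteer keyed by lemma. The engine is deliberately rule-based so tests are
hermetic; the function signature accepts any `{surface: class}` mapping, so a
statistical tagger can be swapped in.

*Stopwords* are a fixed 146-word list. Negation cues (`not`, `no`, `never`,
`n't`, ...) and contrastive conjunctions (`but`, `however`, ...) are
deliberately excluded from it: both are load-bearing for the polarity-shift
rule downstream.

## Embedding

Each token is a 205-d vector `[pos | semantic₁..₂₀₀ | S₊ S₋ Sₙ | shift]`.

* **POS index**: the 36 Penn Treebank tags in alphabetical order map to
  1..36; special tokens (encodings and entity masks) map to 0. The index is
  fed as a raw scalar, preserving the printed 1+200+3+1 partition, not
  one-hot.
* **Semantic vector**: 200-d skip-gram with negative sampling, implemented in
  numpy. Defaults: window 5, `min_count` 2, 5 negative samples from the
  unigram^0.75 noise distribution, 10 epochs, linearly decaying learning rate
  from 0.025 (floor 10%). Training is single-threaded and seeded; identical
  corpus + seed gives bit-identical vectors. Out-of-vocabulary lemmas get the
  zero vector — indistinguishable from padding in the matrix itself, which is
  why every model also receives the boolean row mask.
* **Lexicon grades**: per-lemma positivity/negativity/neutrality, validated
  at load time to sum to 1 within 10⁻⁹; unknown lemmas fall back to
  (0, 0, 1). Lookup tries (lemma, coarse POS) then lemma alone. An adapter
  for the SentiWordNet 3.0 file format aggregates a term's synset scores by a
  mean weighted by reciprocal sense rank — one reasonable choice among
  several; the bundled fixture lexicon (211 entries) is what tests run on.
* **Polarity shift**: tokens after a negation cue are flagged inverted until
  the next clause boundary; a second cue inside the scope toggles back
  (double negation). Sentence punctuation is already stripped during
  cleaning, so in practice boundaries are the contrastive conjunctions.

Tweets are padded/truncated to n = 24 rows. The fixed budget (rather than
"longest tweet in the corpus") keeps the input shape independent of the
corpus; 24 matches the average-length convention used by the downstream
models.

## Classifiers

All seven architectures and the meta-learner are built on a small
reverse-mode autodiff engine over numpy arrays included in the package
(`sentweet.autodiff`), verified against central finite differences to ~10⁻¹⁰.

Shared training protocol: class-weighted categorical cross-entropy with
weights inversely proportional to class frequency (normalized to sum 1),
Adam (lr 0.001, β₁ 0.9, β₂ 0.999), batch size 100, 40 epochs, no early
stopping. Dropout 0.5 for the FFNN, 0.2 for every other family. Training is
deterministic given the seed. A `class_weight=None` switch trains with
uniform weights instead (used by the no-signal null check, see below).

Architecture notes, with the open choices made:

* **FFNN**: flatten → dense ReLU layers of the configured widths → softmax.
  Hidden activations are unspecified upstream; ReLU chosen.
* **CNN1** (single-layer CNN): one 1-d convolution per configured filter
  width, 64 filters each (configurable), ReLU, global max-pool over time,
  concatenation, dropout, dense softmax head.
* **CNNML** (multi-layer CNN): stacked 1-d convolutions of the configured
  widths, then global 1-d max-pooling to a vector, dropout, dense head.
* **GRU / LSTM**: one recurrent layer, width 205 to match the embedding
  dimension. Standard gate structure (sigmoid gates, tanh candidate), LSTM
  forget-gate bias initialized to 1. Padded rows carry the previous state
  through unchanged, so padding cannot alter predictions.
* **BiLSTM**: independent forward and backward cells; the backward branch is
  the forward recurrence applied to the time-reversed input; final states are
  concatenated (410-d) before the head.
* **TCN**: four levels of causal convolution, kernel 3, dilations
  2⁰..2³ = (1, 2, 4, 8), per-level effective history (k−1)·dᵢ = (2, 4, 8,
  16), cumulative field of view 30 — enough to cover the 24-row input.
  Residual connections (1×1 projection where channel counts differ) are
  enabled by default with a switch to disable. Classification reads the
  representation at the last time step.
* Weight init is Glorot-uniform everywhere, from the model's seeded
  generator.

**Restart search**: these models are small enough that initial weights
matter, so training repeats from seeds `base_seed, base_seed+1, ...`
(30 by default) and keeps the restart with the highest *validation weighted
F1*; ties go to the lowest seed, so the winner is exactly reproducible from
its recorded seed. Best-of-k validation scores are a running maximum, hence
monotone in k over a fixed seed stream.

## Ensemble

Hard voting takes the class with most one-hot votes; ties break first by
summed soft probabilities when available, then by the fixed priority
positive > neutral > negative (plumbing, recorded in config, not a claim
about the domain). Soft voting takes the argmax of the column-mean
probability vector.

The learned ensemble is a feed-forward network over the flattened votes:
3m inputs for m base models, hidden widths (3m, ⌈3m/3⌉) — (21, 7) for the
seven-model case — softmax head, trained under the shared protocol. It
consumes **hard** one-hot votes by default (a `mode="soft"` switch accepts
probability votes): the learned-aggregation description and the
hard-voting description of the final system are reconciled by a meta-learner
whose inputs are the hard votes. Plain majority voting is retained as a
baseline. When fitted end-to-end, meta-training votes are produced
out-of-fold (stratified k-fold refits of the base models), so the
meta-learner never sees votes from a model trained on the same tweet.

Model selection for the ensemble keeps every model whose score is at least
the mean score minus a tolerance (default 0.4 percentage points of F1).

## Evaluation

Weighted precision uses TP/(TP+FP) per class. (The source formula sheet
prints the same TP/(TP+FN) body for both precision and recall — a printing
error by inspection; the standard precision denominator is implemented, and
nothing downstream can distinguish the two readings when precision ≈ recall.)
Weighted recall Σₛ (nₛ/N)(TPₛ/nₛ) telescopes to trace/N, i.e. accuracy — the
identity is asserted in the tests as a cross-check. F1 is the harmonic mean,
0 when P + R = 0.

The protocol is a stratified 80/20 split (stratification keeps the 17%
negative class represented in both parts), 10-fold cross-validation inside
the training portion when requested, and final metrics computed once on the
untouched test split — not averaged over folds. Fine-tuning loads a fitted
model and continues training on a target corpus; 0 fine-tuning epochs
returns the source model unchanged.

## Synthetic corpora

The generator emulates the surface statistics of the study corpora: priors
0.47/0.17/0.36; tweet bodies of Poisson-distributed length (mean 12, max 24
tokens) drawn from a 150-word screened noise vocabulary; hashtags (25%),
mentions (30%), URLs (15%), emoticons (20%), elongations (10%) and leading
`RT` (25%) injected independently; every tweet also draws 1–2 neutral-lexicon
words, so the three classes are generatively exchangeable when no polar
signal is planted. Polar tweets receive 1–3 planted lexicon words of their
class with probability `signal_strength`; with probability `negation_rate` a
plant is rendered as a negation cue plus an *opposite*-polarity word with the
scope closed by a contrastive conjunction — recovering the label then
requires the polarity-shift rule, not just a bag of lexicon words. Pool and
noise words are screened through the actual normalization pipeline so that
planted signal survives preprocessing and no noise word lemmatizes into a
polar lexicon entry. Generation is deterministic given the seed.

What passing tests show: the pipeline recovers a planted lexicon-mediated
signal (weighted F1 ≈ 0.90 at signal 0.9, n = 2,000) and degrades to zero
skill when the signal is removed. What they do not show: performance on real
tweets — the generator has no topical drift, sarcasm, misspellings beyond
elongation, annotator noise, or class-conditional length/style effects, so
synthetic scores are an upper bound on realism, not an estimate of
real-corpus F1.

### The no-signal null check

With `signal_strength = 0` the corpus carries no label information, and a
zero-skill classifier should sit at the majority-class rate. That
expectation presumes majority-collapse behavior, which the class-*weighted*
objective is explicitly designed to prevent (a weighted-loss model on pure
noise spreads its predictions: accuracy ≈ 1/3 rather than ≈ 0.47, and its
prevalence-weighted F1 lands well above the majority predictor's — the
majority predictor is a very low bar on that metric, ≈ 0.31, which any
spread-out predictor exceeds). The null check therefore trains the same CNN
with uniform class weights and asserts that held-out *accuracy* is within
±0.05 of the majority-class rate; the acceptance script reports both the
accuracy and weighted-F1 numbers for the null and the majority baseline.

## Problem sizes and runtime

The acceptance runs use n = 2,000 synthetic tweets with best-of-3 restarts
for the recovery study (the full protocol's 30 restarts is the library
default; 3 is the reproduction script's choice to keep a complete run in the
low minutes on one CPU), 5,000/2,000 train/test vote matrices for the
asymmetric-reliability simulation, and exhaustive enumeration up to 3⁴ vote
patterns for the voting oracle. The pure-numpy recurrent models are the slow
path (an LSTM epoch over 1,600 tweets of 24 tokens is ~20 s); the CNN and
FFNN families train in seconds, which is why the system-level studies use
the single-layer CNN.

## Interfaces

All file formats are UTF-8 text: tweets as JSONL or CSV (`id`, `text`,
`label`), lexicon and gazetteer as TSV, stoplist one word per line, votes
and metric reports as CSV/JSON, word-vector models as vocabulary JSON plus a
dense `.npy` matrix. The `sentweet` CLI exposes the pipeline as
`simulate / preprocess / embed / train / predict / ensemble / evaluate`
subcommands; every stochastic stage takes `--seed`, each command logs a
SHA-256 hash of its configuration, and `train` accepts a JSON config file
whose values fill any option left at its default (explicit flags win).

## Known limitations

* The rule-based tagger/lemmatizer/NER trades recall for determinism; it is
  a fixture-grade engine, adequate for the bundled resources and synthetic
  corpora but not a replacement for a trained tagger on open-domain text.
* The emoticon table covers ASCII emoticons only (one category, `<smile>`);
  Unicode emoji pass through as ordinary tokens.
* Skip-gram vectors trained on a few thousand tweets are noisy; the lexicon
  and polarity columns carry most of the recoverable signal at that scale.
* The meta-learner's advantage over majority voting requires base models
  with *asymmetric* reliability; when all models are exchangeable the two
  aggregators coincide in expectation.
* Clause-boundary detection for negation scope relies on conjunctions
  because sentence punctuation is stripped earlier; long-range scopes across
  missing punctuation are over-extended.
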