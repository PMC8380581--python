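# Methods

This note documents the models, the synthetic data they are exercised on,
and the numerical and design choices a maintainer would want to know.  It
describes what the code computes; every empirical number quoted in the
README is printed by the code itself.

## Multiple-instance setting

A user is a bag of timeline-ordered posts; only the bag label (depressed /
control) is observed.  Under the standard MIL assumption a bag is positive
iff at least one instance is positive (`bag_label_oracle`, the max rule).
The networks relax the hard max: per-post probabilities are aggregated by
a recurrent encoder and attention, so the user decision can depend on how
much and how persistently mental-health content appears, not on a single
instance.  The interesting consequence of bag-only training is checked
explicitly in the test suite: the tweet-level head, trained with no post
labels at all, ranks hidden positive posts above negative ones.

### Instance-class orientation

With bag-only supervision, the *index* of the tweet head's
"mental-health" class is not identified: swapping the head's two outputs
can be absorbed by the downstream user encoder, so two equally good runs
may use opposite conventions.  `oriented_instance_scores` resolves the
convention from model outputs alone: the positive instance class is the
one whose mean per-post probability is higher among users the model
*predicts* positive than among users it predicts negative.  Hidden
instance labels are never consulted.

## Architecture

Both variants share: embedding lookup → word-level BiGRU → word attention
(tanh projection, learned context vector, masked softmax) → per-post
softmax head `p_j` → user representation → post-level BiGRU → tweet
attention → user softmax.  MILA concatenates the 7 pronoun-category
fractions `s_j` in front of `p_j` in the user representation; the pronoun
dimensionality is read from the feature object, not hard-coded.

Choices where the published description is silent or ambiguous:

* **Recurrent unit.**  GRU throughout.  (The source material's methods
  describe GRUs while its conclusion mentions bidirectional LSTMs; the
  GRU reading matches the displayed equations.)
* **GRU gate convention.**  The candidate state applies the reset gate to
  the recurrent term, `n = tanh(W_n x + b_n + r ∘ (U_n h))`.  The
  backward-through-time pass is hand-derived and checked against central
  finite differences in `tests/test_autodiff.py`.
* **Hidden sizes.**  Not reconstructable from the published parameter
  counts; defaults are `word_gru_hidden = user_gru_hidden =
  attention_dim = 32`, all configurable.  The experiments in the test
  suite use 16/16/16 with 32-dimensional embeddings — compact enough for
  a single CPU while leaving the architecture intact.
* **User representation.**  The full probability pair `p_j` is used
  (configurable to the positive-class scalar via
  `use_full_prob_vector=False`).
* **Masking.**  Attention is computed over valid positions only, and
  padded posts contribute zero rows to the user representation.  Padding
  a bag with empty posts or token columns therefore provably changes no
  output (tested to 1e-12).  A `mask_attention=False` switch restores
  naive attention over the padded grid for comparison; with bags padded
  to thousands of posts, unmasked attention is dominated by padding,
  which is why masking is the default.
* **Tweet-attention MLP.**  One tanh layer producing `u_j`, then the
  context-vector dot product — the minimal reading of the equations.

## Training

User-level cross-entropy; mini-batch gradient descent with Adam
(default) or AdaMod.  AdaMod keeps an exponential moving average `s_t` of
the element-wise adaptive rates `η_t = lr/(√v̂_t + ε)` and uses
`min(η_t, s_t)` as the actual rate, bounding early oversized steps;
β₃ = 0.9999 by default.  Adam is the package default because AdaMod's
long rate warm-up is wasteful at the small problem sizes used here; the
optimizer is one config field.

Defaults: learning rate 5e-3, batch 32 users, dropout 0.3 after each
BiGRU, global gradient-norm clip at 5, early stopping on validation loss
with patience 3 (experiments in the suite use patience 2, max 10 epochs).
Embedding row 0 (padding) is pinned to zero, including its gradient.
Everything is seeded: parameter init from `ModelConfig.seed`, shuffling
and dropout from `TrainConfig.seed`; single-threaded NumPy makes runs
bit-reproducible.  A non-finite loss aborts with a diagnostic rather than
silently continuing.

Float64 is used throughout; at these sizes exact gradient checks are
worth more than the float32 speedup.

## Synthetic corpus

The generator emulates the statistical structure of a self-declaration
cohort so the whole pipeline is testable offline:

* Two user groups (default 300 positive + 300 control; the cohort
  imbalance of a real crawl can be set via the two counts), 50 posts per
  user by default (Poisson-clipped if min < max; up to 3200 supported).
* Three post topics.  `health_self`: first-person templates over a
  health vocabulary (hidden instance label 1).  `health_other`: the same
  health vocabulary with a third-person subject — a friend's or
  celebrity's condition — including incidental first-person tokens
  ("she told me her …"), label 0.  `neutral`: everyday templates with a
  mixed pronoun slot, label 0.
* Topic rates: positives draw `health_self` at 0.2, controls at 0.01
  (pre-rejection); `health_other` (default 0) applies to both classes —
  setting it positive creates the anaphora-distractor condition.
* Bag-label consistency is enforced by rejection-resampling: positive
  users are redrawn until they contain at least one `health_self` post,
  controls until they contain none, so `label == bag_label_oracle(...)`
  holds exactly for every generated user.
* Ambiguity: a fraction of neutral posts (`casual_health_rate`, default
  0.08) uses one health word figuratively ("so exhausted of this
  traffic"), in both classes, so instance separation is not trivial.
  About 2% of posts are non-English (pseudo-foreign tokens) and posts are
  decorated with mentions, URLs, numerals and hashtags at configurable
  rates to exercise the preprocessing rules; a retweet flag is generated
  but unused by the models.
* `include_declaration_post` (default off) prepends the literal
  self-declaration post to positive users, mirroring how such cohorts are
  collected; it is off by default so the learning task is not reduced to
  spotting one fixed sentence.

What the generator does **not** emulate: real language (templates, not a
language model), timestamps and diurnal structure, user-specific style,
topic drift over time, and the heavy-tailed post-count distribution of a
real crawl.  Passing tests therefore demonstrate that the architecture,
weak-label mechanics, masking and evaluation protocol are correct and
that pronoun features carry the self/other signal when it exists — they
do not certify real-world screening performance.

## Preprocessing

Rewrites: `@mention → user`, URLs (`https?://…`, `www.…`) → `url`,
standalone numerals (`\d+([.,]\d+)*` between whitespace) → `number`,
`#tag → hashtag tag`.  The patterns are anchored so the mapping is
idempotent (property-tested on random strings).  Filters: fewer than 100
posts or less than 80% English posts removes a user; both bounds strict,
so exactly 100 posts or exactly 80% passes.  English detection is a
pluggable predicate: synthetic corpora carry a flag; a stopword-ratio
heuristic is provided for raw text.  Tokenization is lowercased
whitespace splitting truncated to 55 tokens; bags keep the 2000 most
recent posts ("recent" = tail of the timeline-ordered sequence).
Experiments on synthetic corpora use smaller `min_posts`/`max_posts`
consistent with 50-post bags.

## Pronoun features

LIWC is proprietary; a packaged plain-text lexicon defines six disjoint
pronoun categories whose per-post token fractions, plus their sum, form
`s_j` (7 features, matching LIWC's percentage-of-words convention).
Counts are integers and each category is divided by the token count once,
so `total = Σ categories` holds exactly.  Names score zero in every
category, as they would in LIWC.

## Evaluation protocol

Positives are shuffled (seeded) and split round-robin into four chunks
differing by at most one user; each round trains against one chunk plus
all controls, holding out a stratified 20%.  For a 1983/1699 cohort this
yields chunk sizes {496, 496, 496, 495}, per-round class shares
22.60%/77.40%, and a per-round test size of 439 — the n used in AICc.
Headline precision/recall/F1 are class-weighted (per-class values are
also reported); metrics are arithmetic means across rounds.  ROC/AUC is
trapezoidal over all thresholds (checked against a pairwise-comparison
estimator).  Log-likelihood clips probabilities at 1e-12 before the log.
AICc is undefined at n = K + 1 and raises; for networks with K ≫ n the
correction term is negative — the formula is applied as stated, which
reproduces the published comparison-table values from their printed
inputs.

## Known limitations

* Training is pure NumPy: fine for hundreds of users with 50-post bags,
  not for 3682 users × 2000 posts; the architecture supports those sizes
  but a session at that scale would need hours, not minutes.
* The directional MILA ≥ MIL comparison is measured on synthetic
  distractor corpora near the top of the accuracy range, where seed noise
  is a large fraction of the gap; it is a mean over five seeds, not a
  significance test (none is published to compare against).
* The stopword-based English heuristic is crude; for real data plug in a
  proper language identifier as the predicate.
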