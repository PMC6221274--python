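# Methods

## Problem and approach

The package classifies short spoken-language transcripts — one per
participant, elicited by a picture-description task — as coming from a
cognitively impaired speaker (`positive`: MCI or Alzheimer-type dementia)
or a healthy control. The premise is that impairment leaves traces in
*word-sequence* statistics, so the representation is the space of
higher-order word n-grams (n = 4, 5): each transcript becomes a sparse
indicator (or count) vector over the corpus's distinct n-grams. N-grams
are contiguous within-sentence sequences; no padding tokens are used and
n-grams never cross sentence boundaries.

Because clinical corpora are tiny (tens of transcripts) while the n-gram
space has thousands of dimensions, the sparse matrix is rank-reduced by
SVD before classification. Writing the document–n-gram matrix
X = U S Vᵀ, the model consumes the left-singular matrix U_k (one k-vector
per transcript); held-out transcripts are projected by X_new V_k S_k⁻¹.
The admissible rank is bounded by the number of fitted rows, so a corpus
of m transcripts yields at most m continuous features per instance —
which is exactly the regime in which a few dozen dense coordinates stand
in for thousands of sparse columns.

`SVDReducer` exposes two output conventions. `scale="singular"` returns
U_k S_k, the latent-semantic-analysis convention, which at full rank
preserves the Euclidean geometry of the fitted rows exactly; it is the
default and the right choice when the reduced coordinates are themselves
the object of study. `scale="unit"` returns U_k, whose entries are O(1);
the classification pipeline uses this form because tanh units saturate
(and gradients vanish) on inputs of magnitude ≫ 1, while U needs no
further standardization.

## The classifier family

One feed-forward architecture covers the three neural variants:

* **NNLM** — 1 tanh hidden layer on the raw sparse n-gram vectors;
* **DNNLM** — 3 tanh hidden layers on the same sparse vectors;
* **D2NNLM** — 3 tanh hidden layers on the SVD-reduced higher-order
  features, where the reduced coordinates play the role of the continuous
  projection layer (no separate linear projection is inserted).

Hidden activations are d_j = tanh(Σ_l M_jl c_l + b_j); the output layer
o_i = Σ_j V_ij d_j + k_i feeds a softmax over the two classes. Training
minimizes the mean negative log-likelihood of the targets plus an
elastic-net penalty on the weight matrices (biases unpenalized),

    E = −(1/B) Σ log p_target + l1 Σ|W| + l2 Σ W²,

by minibatch SGD. The training loss uses the natural log; perplexity
(below) uses base 2, which is the convention that makes the binary
chance level exactly 2.

Parameters that matter, with defaults and rationale:

| parameter | default | why |
|---|---|---|
| `epochs` | 500 | fixed pass budget; small data, no early stopping |
| `batch_size` | 9 | operating point of the winning small-corpus configuration; grids of 1–10 (small arm) or 1–50 are the intended search spaces |
| `learning_rate` | 0.01 | constant, no momentum; stable across the grid at this data scale |
| `l1`, `l2` | 1e-4 | "small values close to zero"; the l2 term is ε Σ W² exactly |
| `hidden_units` | 16 (grid 5/11/19 in the study protocol) | grid-searched per dataset; selection by validation percent error, ties broken by perplexity, then smaller H, then smaller batch |
| init | uniform ±√(6/(fan_in+fan_out)) | Glorot bound; seeded |

Determinism: initialization and epoch-level shuffling derive from
`random_state`; identical config + seed reproduces parameters bitwise,
and model archives are written with fixed zip timestamps so files are
byte-identical across runs. Gradient correctness is enforced by a
central-finite-difference check (relative deviation < 1e-4 on every
parameter, verified over random 1–5-layer, 1–32-unit architectures).

"Percent error" is implemented as the misclassification rate of the
argmax prediction, which is the only reading under which the reported
granularity of small held-out sets (e.g. 100/9 ≈ 11.1%) arises; a
squared-error variant (`squared_error_percent`) is available.

## The n-gram LM baseline

The non-neural baseline fits one additively smoothed n-gram distribution
per class over the pooled unique-n-gram vocabulary. By default the
unseen-n-gram bucket counts as one extra outcome so each class
distribution sums exactly to 1 (`unseen_bucket=False` gives plain
add-one over the vocabulary only). A transcript's class score is its
mean per-n-gram log2 probability; prediction is by likelihood ratio with
ties going to control, and the AUC confidence is
score(positive) − score(control). Backoff and interpolated smoothing are
out of scope.

## Evaluation

* **Perplexity** 2^B(q) with B(q) = −(1/N) Σ log2 q(x_i), where q(x_i)
  is the probability assigned to the true class: 1 = perfect,
  2 = uninformative for binary outcomes.
* **LPOCV AUC**: every (positive, control) pair is held out once; the
  model is refit on the remainder (per-round seeds derived from the
  master seed and round index) and the pair is scored. The
  Wilcoxon–Mann–Whitney estimate counts c(p, n) = 1 when the positive
  outscores the control. Ties score 0 — the literal counting rule — by
  default; the conventional 0.5-tie mode is a flag. An optional seeded
  subsample of rounds (`max_rounds`) exists for expensive trainers; full
  enumeration is the default protocol.
* **Variance**: Hanley–McNeil (1982),
  σ² = [A(1−A) + (n_P−1)(Q1−A²) + (n_N−1)(Q2−A²)]/(n_P n_N) with
  Q1 = A/(2−A), Q2 = 2A²/(1+A).
* **Significance**: SE = sd/√(n_P+n_N) by default (`se_denominator=
  "pairs"` gives sd/√(n_P n_N)); 95% CI = A ± 1.96·SE reported
  *unclipped* (display truncation at 1.000 is the caller's choice); p is
  a two-sided z-test of A against the chance value 0.5. These
  normal-theory conversions are crude at extreme AUCs; they are provided
  because they are the conventions of the small-sample clinical
  literature this package serves.

SVD fitting scope: in every LPOCV round, and in the holdout protocol,
the vocabulary and the SVD basis are fit on the training transcripts
only; held-out transcripts are projected onto that basis and their
out-of-vocabulary n-grams contribute zero. This avoids test-set leakage.
Splits are stratified by class (50/25/25 train/test/validation by
default) using seeded largest-remainder allocation.

## The synthetic-data generator

`synthgen` emulates the sparse-clinical regime: two groups of 19
transcripts, 8–15 sentences each of 4–12 words, over a 60-word
picture-description vocabulary — roughly two hundred sentences per
group. Sentences are first-order Markov walks. Each word has a small
successor set (default 4) with Dirichlet(0.7) weights; this
support-limited construction is what makes n-grams *recur* across
transcripts (about 1200 distinct 4-grams from ~2050 4-gram tokens, with
per-class distinct counts of a few hundred), mimicking how a fixed
picture constrains what everyone says. Dense transition rows would make
nearly every 4-gram unique to one transcript and destroy the phenomenon
under study.

The impaired group's transitions are the mixture
(1−δ)·base + δ·perturbation, where the perturbation re-draws a fraction
(default 0.5) of rows and δ ∈ [0,1] is the divergence dial: δ = 0 makes
the groups draws from one identical process (calibrated: a two-sample
chi-square on unigram counts is non-significant at α = 0.01 in ≥ 95% of
seeds); δ = 1 with a disjoint-support perturbation produces word pairs
no control ever utters.

What the generator does *not* emulate: discourse structure, syntax,
disfluencies, age/education confounds, annotation noise, or the
systematic but *subtle* deficits of real impaired speech — its
divergence is a clean Markov perturbation. Passing the end-to-end tests
therefore shows that the pipeline recovers sequential-statistics signal
at realistic sample sizes and separates nothing when no signal exists;
it does not show clinical validity on real transcripts.

## Problem sizes in the test suite and acceptance script

The study protocol (19+19 transcripts, full 361-round LPOCV, grid
H ∈ {5, 11, 19}, 500 epochs, batch 9) is run in full, averaged over 3
generator seeds, at δ = 0.8 and δ = 0. Unit and property tests use
smaller instances chosen to probe the same properties — e.g. the
divergence-monotonicity check uses 10+10 transcripts with a seeded
30-round LPOCV subsample, and the permutation-null check uses 120-epoch
fits — since the properties are scale-free while full fits are not.

## Known limitations

* The CI/p machinery assumes normality of the AUC estimate; with 19+19
  and AUC near 1 the bounds exceed [0, 1] (reported unclipped on
  purpose).
* The literal tie rule biases AUC downward for models emitting constant
  scores; that is the intended reading of the counting definition, and
  the 0.5 mode exists for conventional comparisons.
* Add-one smoothing is deliberately simple; the baseline underperforms
  any interpolated LM on real data.
* `chat_minimal` reads only speaker-prefixed main tiers and strips
  bracketed codes, fillers, and unintelligible-speech markers; it is not
  a CHAT parser.
* First-order Markov text cannot represent long-range dependencies, so
  differences between 4- and 5-gram feature spaces are weaker in
  synthetic corpora than in real speech.
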