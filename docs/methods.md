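# Methods

## Task and model

Text matching is treated as binary classification of a question pair
(s₁, s₂): 1 if the two questions share meaning/intent, 0 otherwise. Both
questions are character-tokenized (the standard choice for Chinese text,
where word segmentation is itself error-prone), truncated to a shared
maximum length n and right-padded with a dummy PAD token; a 0/1 mask marks
real positions.

The matcher is a Siamese five-layer network:

* **Input.** Embedding lookup (PAD row fixed to zero at initialization),
  then a highway transform ê = tanh(w_f e + b_f), g = σ(w_g ê + b_g),
  e′ = g⊙ê + (1−g)⊙e, letting the model interpolate per dimension between
  raw and transformed embeddings.
* **Representation.** A BiLSTM produces per-token states h (2H per token);
  cross-text attention over the interaction matrix sim_ks = e′₁ₖ·e′₂ₛ
  produces attended vectors â; each position becomes c = [h ; â].
* **Aggregation.** A second BiLSTM over the concatenated sequence.
* **Capsules.** I width-w convolutions (same padding, padded positions
  zeroed) over the aggregated sequence, each reduced by max over valid
  positions to one channel vector; each channel is mapped by J capsule
  transforms (shared d-dimensional bias, configured nonlinearity) into
  prediction vectors û_{i|j}; dynamic routing with T iterations produces J
  output capsules per sentence.
* **Prediction.** Fusion vector [C₁, C₂, C₁−C₂, cos(C₁,C₂)] (cosine of a
  zero vector is defined as 0), one ReLU hidden layer, sigmoid output,
  mean binary cross-entropy loss, decision threshold 0.5.

All weights are shared between the two sentences. The model is not input-
symmetric (the difference block C₁−C₂ is signed); no symmetrization is
applied.

## Interpretive choices where the architecture description is ambiguous

Several points of the architecture admit more than one reading; the package
fixes them as follows and exposes switches where both readings are useful.

* **Per-token representations.** h is taken as the full per-token state
  sequence, not a single sentence vector: the aggregation BiLSTM and the
  convolution both require positionwise inputs, so the "last hidden states"
  reading would degenerate the later layers.
* **Attention normalization.** The literal ratio a_ks = sim_ks / Σₛ sim_ks
  is defined only for positive row sums; the default is a masked softmax
  (`norm_mode: softmax`), with the literal form retained behind
  `norm_mode: literal` for fidelity experiments. In literal mode an
  all-zero column normalizes to zero weights (0/0 → 0); any other
  non-positive sum raises an error that points to softmax mode. The
  reverse-direction weights â₂ reuse the same similarity matrix normalized
  along the other axis.
* **Similarity source.** sim is computed on the highway-transformed
  embeddings e′ by default; `similarity_source: hidden` switches to the
  BiLSTM states h (the convention of the sequential-inference family this
  model extends).
* **Squash.** The default is the *printed* form s/(1+‖s‖), whose output
  norm is ‖s‖/(1+‖s‖); the canonical capsule squash s·‖s‖/(1+‖s‖²) is
  available as `squash_variant: standard`. Both are implemented because
  the printed denominator may be a typo; neither is asserted as intended.
* **Routing axes.** Coupling softmax runs over output capsules j for each
  input channel i; the logit update is the scalar agreement ⟨d_j, û_{i|j}⟩.
  The number of capsule transforms k is identified with the number of
  output capsules J — the only reading under which Σᵢ c_{i|j} û_{i|j} is
  well-formed.
* **Convolution-to-channel reduction.** How the variable-length convolution
  output becomes a fixed-size channel vector is unspecified; the package
  uses width-3 kernels with same padding and max-over-time restricted to
  valid positions. The kernel count I (default 16) and channel size
  (default 2H) are configurable and not fixed by the published table.
* **Pooling ablations.** Max/mean pooling over the channel axis replaces
  routing; the pooled vector is squashed so ablation outputs live on the
  same norm scale as routed capsules. With I = J, mean pooling coincides
  exactly with a single routing iteration (both apply uniform 1/J = 1/I
  weights), a closed-form identity the tests exploit.
* **Prediction head depth.** One hidden layer (width `head_hidden`,
  default 100) before the sigmoid unit; depth is otherwise unstated.
* **Dropout.** Rates are *drop* probabilities as printed (0.5 for the
  static-vector preset, 0.9 for the contextual preset). The 0.9 value is
  aggressive; older frameworks quoted keep-probabilities, and the text
  does not resolve which was meant, so the interpretation is explicit in
  the config rather than silently assumed.

## Numerical and implementation choices

All computation is float64 NumPy driven by a small in-package reverse-mode
autodiff core (`capstm.autodiff`); its primitive gradients and its
end-to-end gradients through the routing iterations are checked against
central finite differences in the test suite.

* Masking: padded steps carry the LSTM state through unchanged and are
  zeroed on output; attention masks excluded positions before
  normalization; convolution inputs are zeroed at padded positions and the
  time-max is restricted to valid ones. Together these make the match
  probability invariant (to 1e-6 and beyond) under extra padding.
* Squash adds 1e-24 inside the norm square root so the gradient at the
  origin stays finite; squash(0) is still exactly 0.
* Softmax subtracts the (constant) row maximum before exponentiation;
  masked softmax adds 1e-300 to the denominator only to make fully-masked
  rows return zeros instead of NaN.
* Cross-entropy clips probabilities to [1e-7, 1−1e-7].
* Initialization: Glorot-uniform weights, zero biases, LSTM forget-gate
  bias 1, embeddings uniform in [−0.1, 0.1] (PAD row zero), all from one
  seeded generator per model. Training shuffling and dropout masks derive
  from the training seed, so runs are bit-reproducible.
* Optimizer: Adam at the configured learning rate (the de-facto standard
  for this model family; only the rate itself is fixed by the published
  configuration). Early stopping (patience 5, max 50 epochs by default) is
  an addition; the best-dev-F checkpoint is retained, ties to the earliest
  epoch; `patience=0` trains exactly one epoch.
* Maximum length n defaults to 50 in the full presets; the published
  description never states n or a truncation policy.

## Synthetic corpus generator

The generator (`capstm.synthetic`) emulates the structure of short-question
matching corpora. A vocabulary of `vocab_size` CJK-range symbols (default
60) is split into `n_topics` topic tokens (default 10) and content tokens
grouped into synonym pairs. Each of `n_families` templates (default 6) is a
fixed content-token sequence of `template_length` tokens (default 8) with
one topic slot. A question realization substitutes each content token by
its synonym with probability `paraphrase_ops` (default 0.2) and applies one
adjacent swap with the same probability. Positives are two independent
realizations of the same (family, topic); negatives differ in topic, and
half of them (`hard_negative_fraction`) come from the *same* family — the
topic-swap hard case in which two questions are near-identical strings
about different subjects, mirroring the documented confusion mode of real
medical question pairs. The positive fraction defaults to 0.39, the class
balance of the corpus this architecture was originally evaluated on; each
split realizes exactly round(size · fraction) positives.

What the generator does *not* model: natural-language length variation,
topical vocabulary correlations, medical terminology, annotation noise, or
any semantics beyond topic identity and synonymy. Passing model contracts
on this data shows the architecture can learn paraphrase-vs-topic-swap
discrimination end to end; it does not certify performance on real
clinical text.

A linear bag-of-tokens baseline on |count(a) − count(b)| features reaches
≥ 0.85 dev accuracy at default difficulty (a tested property), confirming
the task is solvable and model-level contracts are meaningful.

## Study conditions

Model-level contracts run at two desk scales chosen for a single CPU:

* **Overfit study** (`mini` preset: E=24, H=16, I=6 channels of size 24,
  J=4, d=8, T=3, n=12, lr 0.003, no dropout): a 64-pair corpus must be fit
  to training F ≥ 0.95 within 100 epochs (no early stopping).
* **Generalization study** (`desk` preset: E=32, H=32, I=8 channels of
  size 32, J=6, d=16, T=3, n=16, lr 0.002, dropout 0.1): a 2,000/400/400
  corpus at default difficulty; the full model must reach test F ≥ 0.90,
  and the three ablations train under the same uniform budget (8 epochs,
  patience 3) for a fair comparison.

The attention-free variant converges far more slowly than the others: with
no cross-text interaction until the fusion vector, it can remain at the
all-negative prediction (F = 0 by convention) within this budget at some
seeds. This is reported as measured; it is consistent with the qualitative
finding that the attention interaction is the component that resolves
topic-swap hard negatives, and the full-vs-attention-free comparison on
the hard slice is asserted as a direction only.

## Known limitations

* No margin loss or reconstruction regularizer from the original capsule
  literature; single capsule layer; no EM/matrix routing.
* Contextual embeddings are consumed as a static per-token vector file;
  the package does not run a transformer.
* The published full-scale scores on the private clinical corpus are not
  reproducible here and are not targeted by any test.
* Training is single-threaded NumPy; the full-width presets are practical
  only for small corpora on CPU.
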