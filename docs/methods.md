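# Methods

## Problem

De-identification of clinical free text is cast as per-token sequence
labeling: every token of a note fragment receives one of 29 labels — 28
protected-health-information (PHI) classes (name, location, contact and
identifier subclasses, plus profession, age and date) or `non-PHI`.
Evaluation is binary at the token level: a prediction is correct when it
agrees with the gold label on PHI-vs-non-PHI, regardless of the specific PHI
class; precision, recall and F1 are micro-aggregated over the test corpus.
F1 is the headline metric because PHI tokens are rare (a few percent), which
makes accuracy uninformative.

The package's second concern is *how* the tagger is trained when the
annotated notes cannot leave their home institutions: it implements and
compares centralized pooling, cyclic weight transfer (round robin), DSSGD
(distributed selective stochastic gradient descent), and isolated local
training.

## The tagger

For input tokens t_1..t_n:

1. **Character-enhanced token embedding.**  Each token t_i is represented as
   e_i = [x_i ; h_for ; h_back], where x_i is a fixed pretrained word vector
   (lower-cased lookup; out-of-vocabulary words map to the zero vector) and
   h_for, h_back are the final hidden states of a bidirectional LSTM run over
   the token's characters, one-hot encoded in 128 dimensions (code points
   below 127 map to themselves, everything else shares the last component;
   character case is preserved).  All tokens share the character-LSTM
   weights.  The character half is defined for any string, so rare and
   unseen identifiers still get informative representations.
2. **Label prediction.**  A second bidirectional LSTM consumes (e_1..e_n) and
   emits per-position states d_i = [h_i^for ; h_i^back]; a feedforward head
   l_i = tanh(W_1 d_i + b_1), a_i = softmax(W_2 l_i + b_2) produces the label
   posterior, and predictions take the argmax (lowest index on ties, which
   makes degenerate cases deterministic).

The recurrent cell is a coupled-gate LSTM: the forget gate is tied to the
input gate (f = 1 − i) and a constant +1 is added inside the input-gate
sigmoid, biasing the cell toward retaining memory early in training (a unit
forget-bias analogue):

    i_t = σ(W_i [z_t, h_{t−1}] + b_i + 1)
    c_t = i_t ⊙ c_{t−1} + (1 − i_t) ⊙ tanh(W_c [z_t, h_{t−1}] + b_c)
    o_t = σ(W_o [z_t, h_{t−1}] + b_o)
    h_t = o_t ⊙ tanh(c_t),     h_0 = c_0 = 0.

All weights live in one flat parameter vector with a named index map
(`char_fwd.W_i`, …, `W_2`, `b_2`); the collaborative protocols exchange
entries of this vector by index.  At the full-scale dimensions (300-dim word
vectors, character hidden size 128, label hidden size 100) the embedding is
556-dimensional and the label-LSTM output 200-dimensional.

Softmax is computed with max-subtraction.  Inverted dropout (rate 0.5,
default) is applied to the embedding sequence during training only, one
seeded mask per fragment.  Weight matrices are initialized
Glorot-uniform (±sqrt(6/(fan_in+fan_out))), biases at zero; all
initialization, shuffling, dropout, subsampling and scheduling randomness
derives from explicit seeds, so every run is bitwise reproducible.

### Loss, gradient and the SGD step

Training minimizes the fragment cross-entropy E(p) = −Σ_i ln a_i[class(t_i)].
The gradient is computed by hand-written backpropagation through the head,
both label-LSTM directions, dropout, and both character-LSTM directions
(batched over a fragment's tokens with length masking).  Correctness is
established against central finite differences of the loss on small
configurations — the suite requires agreement within 1e-4 relative error —
and by a descent property (a small step along −∇E reduces E).

The SGD step is per-sample (one fragment at a time) with a fixed learning
rate, default 0.9.  By default the step uses the *length-normalized*
gradient, η·∇E/n — descent on the mean per-token cross-entropy.  The reason
is practical and visible at desk scale: the summed loss makes the step grow
linearly with fragment length, and at η = 0.9 a 20-token fragment saturates
the softmax within one epoch (training collapses to the majority class,
per-token loss ≈ 14), whereas the normalized step trains stably to F1 ≈ 0.99.
Framework implementations of sequence cross-entropy conventionally apply
this mean reduction.  `sgd_epoch(..., normalize=False)` gives the literal
unnormalized update; the exposed `loss`/`gradient` functions always refer to
the summed form.

## Training regimes

* **Centralized (A).**  Plain SGD over the pooled corpus — the
  non-protective upper baseline.
* **Round robin (B).**  K workers hold patient-disjoint subsets; each global
  epoch passes the full weight vector through workers 1..K in fixed order,
  each running one local epoch.  Data stay local; the whole model circulates.
* **DSSGD (C).**  Workers train locally and exchange *selected* updates via
  a parameter server holding the global vector p_glo and a per-parameter
  update counter.  One local epoch per worker: (1) download the
  floor(θ_d·len(p)) global values with the highest update counts (ties
  toward the lowest index; counters all start at zero, so the first download
  is the leading slice) and overwrite the local copies; (2) run one local
  SGD epoch; (3) form the cumulative delta against the post-download
  baseline; (4) keep entries with |Δ| strictly greater than τ, clamp to
  [−γ, +γ], and uniformly subsample down to floor(θ_u·len(p)) entries if
  more survive; (5) upload, the server adding values and incrementing
  counters.  θ_u is read as a fraction of the full parameter count, and the
  threshold–clamp–sample order is fixed; the downloaded values overwrite
  rather than blend.  Asynchrony is simulated in-process: each round the
  workers run in a seeded random order, each seeing the server exactly as
  the previous worker left it.  True lock-free concurrency, transport and
  encryption are out of scope; the server logs how often the γ clamp fires.
* **Local-only (D).**  K independent workers, no communication — the lower
  baseline that collaborative training must beat.

Bundled presets mirror the study design: 5 workers, η = 0.9 everywhere,
DSSGD with θ_u = 0.5, γ = 10, τ = 1e-4 and θ_d ∈ {0.1, 0.5}.  Degenerate
configurations collapse the regimes into one another, which the suite
verifies to 1e-10 on parameter trajectories: round robin with K = 1 and
DSSGD with one full-sharing worker (θ_d = θ_u = 1, τ = 0, γ = ∞) both equal
centralized training; DSSGD with θ_u = θ_d = 0 equals local-only.

## Synthetic corpus

The generator emulates the statistical shape of a longitudinal
de-identification corpus without containing any real data: a seeded bigram
sampler over a fixed lowercase clinical vocabulary produces filler prose;
PHI mentions are inserted with short non-PHI cue contexts ("seen on …",
"mrn …") at a rate calibrated so that ≈2.8% of tokens are PHI (the
calibration pre-samples the mention grammars to estimate mean mention
length); mentions draw from the 23 PHI classes present in the published
challenge data (uniform weights by default — the true class histogram is
unpublished — configurable per class).  Surrogate names come from bundled
word lists; digit-bearing classes (dates in four dialects, phones, record
and plan numbers, device/biometric/generic IDs, zips, ages) come from
per-class format grammars so the character channel has real signal.  Name
PHI is capitalized while filler prose is lowercase except fragment-initial
words, so capitalization is informative but not sufficient.  Patients have
several records; a patient's surrogate name recurs across their records;
fragments are 8–25 tokens (one line each).  Splits and worker partitions
are patient-disjoint (greedy largest-patient-first balancing on token
counts after a seeded shuffle).

What the generator does **not** reproduce: clinical semantics and discourse,
the real PHI class histogram and fragment-length distribution, annotation
noise, cross-hospital heterogeneity, and the ambiguity of real names against
capitalized medical vocabulary.  Passing the desk-scale comparisons
therefore shows that the implementation learns and that the protocols
behave and rank as designed — not that these F1 values would be attained on
real clinical text.

## Problem sizes and defaults

Desk-scale defaults keep the full comparison tractable on one CPU: ~50
patients / ~50k tokens per corpus (~30k training tokens after the 0.39
patient-disjoint test split), a reduced network (50-dim random word vectors
in [−0.1, 0.1], character hidden 16, label hidden 32, head 32; ≈39k
parameters), 20 epochs.  The full-scale study configuration (300/128/100/100,
200 epochs, ~598k training tokens) is reachable through the same config
surface.  At desk scale the regimes order as expected:
centralized and round robin at the top, DSSGD(θ_d = 0.1) close behind, and
isolated local training clearly behind (its workers see one fifth of the
data and spread widely).  How θ_d = 0.5 compares depends on scale and seed;
large downloads can disrupt local progress, but at desk scale the effect is
not consistently visible.

## Numerical and design notes

* The "+1" in the input gate and the coupled forget gate are implemented
  exactly as specified above; this is deliberately not a textbook LSTM.
* Per-position label-LSTM states feed the head (d_i, not a fixed d_1);
  fragment order matters and is tested.
* Out-of-vocabulary word vectors are zero — neutral next to the learned
  character embedding.  Word lookup folds case; the character channel does
  not.
* Tokenization is a deterministic regex (words with internal hyphens/periods
  kept whole, all other non-space characters single tokens) behind a plain
  function, so results do not depend on an external toolkit; fragments
  longer than a configurable cap (default 100 tokens) can be split.
* Degenerate F1 with no gold and no predicted PHI is defined as 1.0; it can
  only occur in per-fragment diagnostics, never in corpus-level scoring of
  a corpus that contains PHI.
* Checkpoints serialize the flat vector with hex-encoded floats, so
  save → load reproduces predictions bitwise.
* The per-class cross-entropy uses a floor of 1e-300 inside the logarithm;
  probabilities that small do not occur in practice (softmax with
  max-subtraction), it only guards the log.
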