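# phideid

Detection of protected health information (PHI) in clinical free text with a
character-enhanced bidirectional-LSTM tagger, trainable under four regimes —
centralized, round robin (cyclic weight transfer), **DSSGD** (distributed
selective stochastic gradient descent) and isolated local training — so that
the privacy/performance trade-off of collaborative training can be measured
directly.  A seeded synthetic-corpus generator reproduces the statistical
shape of a longitudinal de-identification corpus (≈2.8% PHI tokens, 23 PHI
classes, several records per patient, patient-disjoint splits), so the whole
comparison runs on one CPU with no access-restricted data.

Intended users: clinical-NLP and federated-learning researchers who need a
reproducible, dependency-light testbed for de-identification models and
selective parameter-sharing protocols.

## Model

Every token t_i of a note fragment receives one of 29 labels (28 PHI
classes/subclasses or `non-PHI`).  The tagger is:

    e_i = [ x_i ; char-biLSTM(t_i) ]          token embedding
    d_i = [ h_i^for ; h_i^back ]              fragment-level biLSTM, full output
    l_i = tanh(W1 d_i + b1)
    a_i = softmax(W2 l_i + b2)                posterior over 29 labels

where x_i is a fixed pretrained word vector and char-biLSTM runs over the
token's 128-dim one-hot characters.  The LSTM cell couples its gates
(forget = 1 − input) with a unit bias inside the input gate:

    i_t = σ(W_i [z_t, h_{t−1}] + b_i + 1)
    c_t = i_t ⊙ c_{t−1} + (1 − i_t) ⊙ tanh(W_c [z_t, h_{t−1}] + b_c)
    o_t = σ(W_o [z_t, h_{t−1}] + b_o),   h_t = o_t ⊙ tanh(c_t)

Training minimizes the cross-entropy E(p) = −Σ_i ln a_i[class(t_i)] by
per-sample SGD (η = 0.9 by default) with hand-written backpropagation over a
single flat parameter vector **p** — the object the collaborative protocols
exchange.  Under DSSGD each worker, once per local epoch, downloads the
floor(θ_d·len(p)) most-updated global parameters, trains locally, then
uploads its parameter deltas filtered by |Δ| > τ, clamped to [−γ, +γ] and
subsampled to floor(θ_u·len(p)) entries, through a server that tracks
per-parameter update counts.  Scoring is binary token-level PHI-vs-non-PHI
precision/recall/F1.  See `docs/methods.md` for assumptions, defaults and
limitations.

## Worked example

`examples/02_train_and_tag.py` trains the tagger centralized for 25 epochs
on a generated corpus (35 patients) and tags an unseen sentence:

```
test split: precision 0.960  recall 0.966  F1 0.963

tagging an unseen sentence:
  Patient
  Vera
  Stanhope  <-- clinician
  seen
  on
  03  <-- phone
  /  <-- phone
  14  <-- street
  /  <-- date
  2069  <-- date
  at
  Riverside  <-- hospital
  General  <-- hospital
  Hospital  <-- hospital
  mrn
  MR553901  <-- device-id
```

The headline numbers are binary: 96.6% of true PHI tokens were flagged as
PHI, and 96.0% of flagged tokens really were PHI.  The per-class guesses are
noisier (the record number is called a device ID, the date digits a phone) —
typical for a small model, and irrelevant to de-identification, where any
PHI label means "remove this token".

The other examples: `01_generate_corpus.py` (corpus statistics and an
annotated fragment), `03_compare_protocols.py` (final F1 of all four
regimes on one corpus), `04_dssgd_exchange.py` (the τ/γ/θ_u selection and
the server counters on a toy vector).  The `phideid` command wraps the same
library: `phideid generate | train | evaluate | curves` (see `--help`);
bundled presets `A`, `B`, `C_0.1`, `C_0.5`, `D` correspond to the five
study regimes.

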