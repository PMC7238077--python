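"""Train a small tagger centralized and tag a sentence.

Generates a compact corpus, trains the character-enhanced bi-LSTM for 25
epochs of plain SGD (learning rate 0.9), reports binary PHI precision /
recall / F1 on the patient-disjoint test split, then tags an unseen
sentence.  PHI detection leans on both channels: word identity for lexicon
names, character shape (capitalization, digits, separators) for record
numbers, dates and phones.
"""

from phideid.corpus import LabeledDocument, tokenize
from phideid.encoders import make_random_table
from phideid.evaluation import evaluate_tagger
from phideid.labels import build_label_scheme
from phideid.network import NetworkConfig, init_parameters, predict_labels
from phideid.synthetic import CorpusSpec, generate_corpus, split_train_test
from phideid.training import train_centralized

scheme = build_label_scheme()
corpus = generate_corpus(
    CorpusSpec(seed=0, n_patients=35, records_per_patient=(2, 4),
               tokens_per_record=(100, 250))
)
train, test = split_train_test(corpus, test_fraction=0.35, seed=0)
table = make_random_table({t for d in train for t in d.tokens}, dim=50, seed=0)
config = NetworkConfig(word_dim=50, char_hidden=16, label_hidden=32, ff_hidden=32)

p0 = init_parameters(config, seed=0)
trajectory = train_centralized(train, p0, table, epochs=25, eta=0.9, seed=0)
p = trajectory[-1]

m = evaluate_tagger(test, p, table, scheme)
print(f"test split: precision {m.precision:.3f}  recall {m.recall:.3f}  F1 {m.f1:.3f}")

sentence = "Patient Vera Stanhope seen on 03/14/2069 at Riverside General Hospital mrn MR553901"
tokens = tokenize(sentence)
doc = LabeledDocument("demo", "px", tuple(tokens), tuple(["non-PHI"] * len(tokens)))
print("\ntagging an unseen sentence:")
for tok, lab in zip(tokens, predict_labels(doc, p, table, scheme)):
    marker = f"  <-- {lab}" if lab != "non-PHI" else ""
    print(f"  {tok}{marker}")
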