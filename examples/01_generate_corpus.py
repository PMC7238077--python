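"""Generate a synthetic annotated pseudo-clinical corpus and inspect it.

Builds a small corpus (10 patients, 2-3 records each), prints its PHI token
rate and one annotated fragment, and writes it in the token/label text
format.  The PHI rate should land near the 2.8% that is typical of
longitudinal clinical notes; every PHI mention is a surrogate produced by a
per-class format grammar or word list.
"""

from phideid.corpus import write_token_label_file
from phideid.labels import build_label_scheme
from phideid.synthetic import CorpusSpec, generate_corpus

spec = CorpusSpec(
    seed=7, n_patients=10, records_per_patient=(2, 3), tokens_per_record=(80, 160)
)
corpus = generate_corpus(spec)
scheme = build_label_scheme()

tokens = sum(len(d) for d in corpus)
phi = sum(scheme.is_phi(lab) for d in corpus for lab in d.labels)
print(f"fragments: {len(corpus)}   tokens: {tokens}   PHI rate: {phi / tokens:.3f}")

with_phi = next(d for d in corpus if any(lab != "non-PHI" for lab in d.labels))
print(f"\nfragment {with_phi.doc_id} (patient {with_phi.patient_id}):")
for tok, lab in zip(with_phi.tokens, with_phi.labels):
    marker = f"  <-- {lab}" if lab != "non-PHI" else ""
    print(f"  {tok}{marker}")

write_token_label_file("synthetic_corpus.tsv", corpus)
print("\nwrote synthetic_corpus.tsv")
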