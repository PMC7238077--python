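"""Seeded generator of annotated pseudo-clinical corpora.

Emulates the statistical shape of a longitudinal de-identification corpus:
natural-language-like token streams in which roughly 2.8% of tokens are PHI,
PHI drawn from the 23 classes present in the published challenge data,
several records per patient (with the patient's surrogate name recurring
across their records), and patient-disjoint train/test splitting.

All identifiers are surrogates built from bundled word lists and per-class
format grammars — no real data.  Digit-bearing PHI (phones, dates, record
numbers, ...) is produced by format grammars in several dialects so the
character channel of the tagger has genuine signal to learn from; name-like
PHI is capitalized against mostly-lowercase filler prose (fragment-initial
filler words are also capitalized, so capitalization alone does not decide
PHI status).  Filler prose comes from a seeded bigram sampler over a fixed
synthetic clinical vocabulary.

The generator is a pure function of its :class:`CorpusSpec`: the same spec
(including seed) always yields the identical corpus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .corpus import LabeledDocument
from .labels import NON_PHI, PRESENT_PHI_LABELS

__all__ = ["CorpusSpec", "generate_corpus", "split_train_test"]

# --------------------------------------------------------------------------
# Surrogate lexicons (synthetic; resemblance to real persons is coincidental)

_FIRST_NAMES = (
    "Alma Arthur Bernice Calvin Clara Curtis Dora Edwin Elsie Felix Flora "
    "Gordon Hazel Hugo Irene Jasper Lena Marcus Mabel Nolan Opal Oscar "
    "Pearl Quentin Rosa Silas Stella Tobias Una Vera Victor Wilbur Yvonne "
    "Zane Audrey Bennett Cora Dexter Esther Franklin Greta Harvey Ida "
    "Jerome Kathryn Leland Mira Norris Olive Preston"
).split()

_LAST_NAMES = (
    "Abernathy Barlow Caldwell Dunmore Eastman Fairbanks Garrick Holloway "
    "Ingles Jarvis Kettering Lockhart Merriweather Norwood Ogletree "
    "Pemberton Quimby Rutherford Sablewood Thackeray Underhill Vanderbilt "
    "Westcott Yarborough Ashford Birchall Cranmore Delafield Ellsworth "
    "Fenwick Greenhalgh Hartwell Iverton Kingsley Larkspur Mortlake "
    "Nethercott Oakhurst Pellington Quarles Ravenel Stanhope Tillingford "
    "Umberson Valencourt Whitlock"
).split()

_PLACE_STEMS = (
    "Riverside Lakeview Hillcrest Brookfield Maplewood Cedarbrook Fairview "
    "Oakridge Pinehurst Stonebridge Westbrook Northgate Eastwood Southmoor "
    "Clearwater Ironwood Silverton Goldcrest Ashgrove Thornbury"
).split()

_HOSPITAL_SUFFIXES = (
    ("Medical", "Center"),
    ("General", "Hospital"),
    ("Memorial", "Hospital"),
    ("Community", "Clinic"),
    ("Regional", "Hospital"),
)

_ORG_SUFFIXES = ("Corporation", "Industries", "Laboratories", "Group", "Partners")

_CITIES = (
    "Marlowe Bexford Caldris Dunwich Elmsworth Farrowgate Gristol Harwick "
    "Ivoryton Junewood Kestrel Lornmouth Mabelton Nordale Ostermont "
    "Pellbrook Quarrytown Redmere Selwick Tarnford Ulverton Vinemont "
    "Wrenfield Yallow Zephyrhill"
).split()

_STATES = (
    "Ohio Maine Oregon Kansas Nevada Vermont Georgia Montana Arizona "
    "Colorado Nebraska Delaware Kentucky Missouri Wyoming Utah Iowa Idaho"
).split()

_COUNTRIES = (
    "Canada France Brazil Japan Norway Spain Kenya Chile India Portugal "
    "Austria Greece Ireland Mexico Peru"
).split()

_STREET_NAMES = (
    "Alder Birch Chestnut Dogwood Elm Foxglove Hawthorn Juniper Laurel "
    "Magnolia Poplar Rowan Sycamore Walnut Willow"
).split()

_STREET_KINDS = ("Street", "Avenue", "Road", "Lane", "Drive")

_PROFESSIONS = (
    "carpenter electrician librarian machinist florist bricklayer "
    "accountant surveyor locksmith beekeeper tailor welder archivist "
    "glazier printer cartographer upholsterer cooper chandler farrier"
).split()

_LOCATION_OTHER = ("Ward", "Unit", "Wing", "Pavilion", "Annex", "Bay")

_MONTHS = (
    "January February March April May June July August September "
    "October November December"
).split()

# Filler vocabulary: generic clinical-note prose words (all lowercase).
_FILLER_WORDS = (
    "the a an and or but with without of in on at for to from by during "
    "after before patient presented complains reports denies history exam "
    "examination reveals shows stable improved worsening chronic acute mild "
    "moderate severe bilateral left right upper lower pain swelling fever "
    "cough nausea fatigue dizziness headache appetite weight blood pressure "
    "pulse rate rhythm regular irregular heart lung sounds clear abdomen "
    "soft tender nontender bowel normal skin warm dry intact alert oriented "
    "follow up visit clinic discharge admission medication dose increased "
    "decreased continued started stopped tablet daily twice morning evening "
    "labs ordered pending results within limits glucose sodium potassium "
    "creatinine hemoglobin count elevated low plan assessment continue "
    "monitor recheck weeks days months tolerated well no new concerns "
    "reviewed discussed family diet exercise sleep stress denies chest "
    "shortness breath edema rash lesion noted resolved recommend referral "
    "physical therapy insulin metformin lisinopril aspirin prescribed "
    "allergies none known status post procedure surgery recovery wound "
    "healing sutures removed imaging chest x-ray unremarkable ultrasound "
    "follow instructions return if symptoms worsen hydration rest advised"
).split()


# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CorpusSpec:
    """Shape of a generated corpus.

    Defaults give a desk-scale corpus (~50 patients, ~50k tokens; after a
    0.39 patient-disjoint test split, ~30k training tokens) with the study's
    PHI token rate of about 2.8% and uniform weight over the 23 PHI classes
    present in the published data.
    """

    n_patients: int = 50
    records_per_patient: tuple[int, int] = (2, 6)
    tokens_per_record: tuple[int, int] = (100, 400)
    phi_token_rate: float = 0.028
    phi_class_weights: dict[str, float] | None = None
    vocab_size: int = 400
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not 0.0 < self.phi_token_rate < 0.5:
            raise ValueError("phi_token_rate must be in (0, 0.5)")
        lo, hi = self.records_per_patient
        if not 1 <= lo <= hi:
            raise ValueError("invalid records_per_patient range")
        lo, hi = self.tokens_per_record
        if not 10 <= lo <= hi:
            raise ValueError("tokens_per_record range must start at >= 10")
        if self.phi_class_weights is not None:
            keys = set(self.phi_class_weights)
            if keys != set(PRESENT_PHI_LABELS):
                raise ValueError(
                    "phi_class_weights must cover exactly the 23 present PHI classes"
                )
            total = sum(self.phi_class_weights.values())
            if not math.isclose(total, 1.0, rel_tol=1e-9):
                raise ValueError("phi_class_weights must sum to 1")

    def class_weights(self) -> tuple[tuple[str, ...], np.ndarray]:
        if self.phi_class_weights is None:
            w = np.full(len(PRESENT_PHI_LABELS), 1.0 / len(PRESENT_PHI_LABELS))
            return PRESENT_PHI_LABELS, w
        labels = PRESENT_PHI_LABELS
        return labels, np.array([self.phi_class_weights[lab] for lab in labels])


def _digits(rng: np.random.Generator, n: int) -> str:
    return "".join(str(d) for d in rng.integers(0, 10, size=n))


def _choice(rng: np.random.Generator, seq):
    return seq[int(rng.integers(0, len(seq)))]


def _person_name(rng: np.random.Generator) -> list[str]:
    return [_choice(rng, _FIRST_NAMES), _choice(rng, _LAST_NAMES)]


def _date_tokens(rng: np.random.Generator) -> list[str]:
    year = str(int(rng.integers(2058, 2078)))  # surrogate future years
    month = int(rng.integers(1, 13))
    day = int(rng.integers(1, 29))
    dialect = int(rng.integers(0, 4))
    if dialect == 0:
        return [f"{year}-{month:02d}-{day:02d}"]
    if dialect == 1:
        return [f"{month:02d}", "/", f"{day:02d}", "/", year]
    if dialect == 2:
        return [_MONTHS[month - 1], str(day), year]
    return [f"{day:02d}.{month:02d}.{year}"]


def _phone_tokens(rng: np.random.Generator) -> list[str]:
    dialect = int(rng.integers(0, 3))
    if dialect == 0:
        return [f"{_digits(rng, 3)}-{_digits(rng, 4)}"]
    if dialect == 1:
        return ["(", _digits(rng, 3), ")", f"{_digits(rng, 3)}-{_digits(rng, 4)}"]
    return [f"{_digits(rng, 3)}.{_digits(rng, 3)}.{_digits(rng, 4)}"]


def _entity_tokens(label: str, rng: np.random.Generator, ctx: dict) -> list[str]:
    """Surrogate tokens for one PHI mention of the given class."""
    if label == "patient":
        return list(ctx["patient_name"])
    if label == "clinician":
        return _person_name(rng)
    if label == "username":
        first, last = _person_name(rng)
        return [f"{first[0].lower()}{last.lower()}{_digits(rng, 2)}"]
    if label == "profession":
        return [_choice(rng, _PROFESSIONS)]
    if label == "hospital":
        return [_choice(rng, _PLACE_STEMS), *_choice(rng, _HOSPITAL_SUFFIXES)]
    if label == "organization":
        return [_choice(rng, _PLACE_STEMS), _choice(rng, _ORG_SUFFIXES)]
    if label == "street":
        return [
            _digits(rng, int(rng.integers(2, 4))),
            _choice(rng, _STREET_NAMES),
            _choice(rng, _STREET_KINDS),
        ]
    if label == "city":
        return [_choice(rng, _CITIES)]
    if label == "state":
        return [_choice(rng, _STATES)]
    if label == "country":
        return [_choice(rng, _COUNTRIES)]
    if label == "zip":
        return [_digits(rng, 5)]
    if label == "location-other":
        return [_choice(rng, _LOCATION_OTHER), f"{_digits(rng, 1)}{_choice(rng, 'ABCDEF')}"]
    if label == "age":
        return [str(int(rng.integers(18, 95)))]
    if label == "date":
        return _date_tokens(rng)
    if label == "phone":
        return _phone_tokens(rng)
    if label == "fax":
        return _phone_tokens(rng)
    if label == "email":
        first, last = _person_name(rng)
        domain = _choice(rng, _PLACE_STEMS).lower()
        return [f"{first[0].lower()}{last.lower()}@{domain}.org"]
    if label == "url":
        domain = _choice(rng, _PLACE_STEMS).lower()
        return [f"www.{domain}-health.org"]
    if label == "medical-record-number":
        return [f"MR{_digits(rng, 6)}"]
    if label == "health-plan-number":
        return [f"HP-{_digits(rng, 8)}"]
    if label == "device-id":
        return [f"DEV{_digits(rng, 4)}{_choice(rng, 'KLMNP')}"]
    if label == "biometric-id":
        return [f"BIO-{_digits(rng, 6)}"]
    if label == "id-number":
        return [f"{_choice(rng, 'ACEGJ')}{_choice(rng, 'RSTVX')}{_digits(rng, 6)}"]
    raise KeyError(f"no surrogate grammar for label {label!r}")


# Non-PHI context cues surrounding a mention: (prefix tokens, suffix tokens).
_CUES: dict[str, tuple[tuple[tuple[str, ...], tuple[str, ...]], ...]] = {
    "patient": ((("patient",), ()), (("pt",), ()), ((), ("was", "seen"))),
    "clinician": ((("dr",), ()), (("seen", "by", "dr"), ()), (("signed",), ())),
    "username": ((("entered", "by"), ()), (("user",), ())),
    "profession": ((("works", "as", "a"), ()), (("retired",), ())),
    "hospital": ((("at",), ()), (("transferred", "to"), ()), (("admitted", "at"), ())),
    "organization": ((("insured", "through"), ()), (("employed", "by"), ())),
    "street": ((("lives", "at"), ()), (("address",), ())),
    "city": ((("in",), ()), (("resident", "of"), ())),
    "state": ((("in",), ()), ((), ())),
    "country": ((("travelled", "to"), ()), (("from",), ())),
    "zip": ((("zip",), ()), ((), ())),
    "location-other": ((("moved", "to"), ()), (("located", "in"), ())),
    "age": (((), ("yo",)), (("age",), ()), ((), ("years", "old"))),
    "date": ((("on",), ()), (("seen", "on"), ()), (("since",), ()), ((), ())),
    "phone": ((("phone",), ()), (("call",), ()), (("contact", "at"), ())),
    "fax": ((("fax",), ()), (("faxed", "to"), ())),
    "email": ((("email",), ()), ((), ())),
    "url": ((("see",), ()), (("portal",), ())),
    "medical-record-number": ((("mrn",), ()), (("record",), ())),
    "health-plan-number": ((("plan",), ()), (("coverage",), ())),
    "device-id": ((("device",), ()), (("implant",), ())),
    "biometric-id": ((("biometric",), ()), ((), ())),
    "id-number": ((("id",), ()), (("number",), ())),
}


class _BigramSampler:
    """Cheap seeded Markov chain over the filler vocabulary."""

    def __init__(self, vocab: Sequence[str], seed: int, fanout: int = 6):
        self.vocab = list(vocab)
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0xF111]))
        n = len(self.vocab)
        self.successors = rng.integers(0, n, size=(n, fanout))
        self.state = 0

    def next_word(self, rng: np.random.Generator) -> str:
        row = self.successors[self.state]
        self.state = int(row[int(rng.integers(0, len(row)))])
        return self.vocab[self.state]


def _build_vocab(spec: CorpusSpec) -> list[str]:
    vocab = list(dict.fromkeys(_FILLER_WORDS))
    if spec.vocab_size < 20:
        raise ValueError("vocab_size must be >= 20")
    if spec.vocab_size <= len(vocab):
        return vocab[: spec.vocab_size]
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x50EC]))
    syll = "car din lor mex tab ral sen vod pli gam tho rus nel fid ost".split()
    while len(vocab) < spec.vocab_size:
        w = "".join(_choice(rng, syll) for _ in range(int(rng.integers(2, 4))))
        if w not in vocab:
            vocab.append(w)
    return vocab


def _estimate_snippet_sizes(
    spec: CorpusSpec, labels: tuple[str, ...], weights: np.ndarray
) -> tuple[float, float]:
    """Deterministic pre-sample of mean PHI / cue token counts per snippet."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xCA11]))
    ctx = {"patient_name": ["Alma", "Abernathy"]}
    phi_total = cue_total = 0.0
    n = 400
    for _ in range(n):
        lab = labels[int(rng.choice(len(labels), p=weights))]
        prefix, suffix = _choice(rng, _CUES[lab])
        phi_total += len(_entity_tokens(lab, rng, ctx))
        cue_total += len(prefix) + len(suffix)
    return phi_total / n, cue_total / n


def generate_corpus(spec: CorpusSpec) -> list[LabeledDocument]:
    """Generate a labeled pseudo-clinical corpus matching the spec.

    Records are emitted per patient; each record is cut into fragments
    (lines) of 8-25 tokens, the training/testing unit.  PHI mentions are
    inserted with a rate calibrated so the realized PHI token fraction is
    close to ``spec.phi_token_rate``.
    """
    labels_, weights = spec.class_weights()
    m_phi, m_cue = _estimate_snippet_sizes(spec, labels_, weights)
    r = spec.phi_token_rate
    # slot probability: solve r = p*m_phi / (p*(m_phi+m_cue) + (1-p))
    p_slot = r / (m_phi - r * (m_phi + m_cue - 1.0))
    if not 0.0 < p_slot < 1.0:
        raise ValueError(
            f"infeasible phi_token_rate {r} for the snippet grammar"
        )

    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xC0DE]))
    vocab = _build_vocab(spec)
    bigram = _BigramSampler(vocab, spec.seed)
    docs: list[LabeledDocument] = []

    for pi in range(spec.n_patients):
        patient_id = f"pt{pi:04d}"
        ctx = {"patient_name": _person_name(rng)}
        n_records = int(
            rng.integers(spec.records_per_patient[0], spec.records_per_patient[1] + 1)
        )
        for ri in range(n_records):
            doc_id = f"{patient_id}-r{ri}"
            n_target = int(
                rng.integers(spec.tokens_per_record[0], spec.tokens_per_record[1] + 1)
            )
            tokens: list[str] = []
            labels: list[str] = []
            frag_len = int(rng.integers(8, 26))
            frag_tokens: list[str] = []
            frag_labels: list[str] = []

            def flush_fragment() -> None:
                nonlocal frag_tokens, frag_labels, frag_len
                if frag_tokens:
                    # fragment-initial capitalization, as in real prose
                    if frag_labels[0] == NON_PHI:
                        frag_tokens[0] = frag_tokens[0].capitalize()
                    docs.append(
                        LabeledDocument(
                            doc_id, patient_id,
                            tuple(frag_tokens), tuple(frag_labels),
                        )
                    )
                frag_tokens, frag_labels = [], []
                frag_len = int(rng.integers(8, 26))

            emitted = 0
            while emitted < n_target:
                if rng.random() < p_slot:
                    lab = labels_[int(rng.choice(len(labels_), p=weights))]
                    prefix, suffix = _choice(rng, _CUES[lab])
                    ent = _entity_tokens(lab, rng, ctx)
                    frag_tokens.extend(prefix)
                    frag_labels.extend([NON_PHI] * len(prefix))
                    frag_tokens.extend(ent)
                    frag_labels.extend([lab] * len(ent))
                    frag_tokens.extend(suffix)
                    frag_labels.extend([NON_PHI] * len(suffix))
                    emitted += len(prefix) + len(ent) + len(suffix)
                else:
                    frag_tokens.append(bigram.next_word(rng))
                    frag_labels.append(NON_PHI)
                    emitted += 1
                if len(frag_tokens) >= frag_len:
                    flush_fragment()
            flush_fragment()
    return docs


def split_train_test(
    corpus: Sequence[LabeledDocument], test_fraction: float, seed: int
) -> tuple[list[LabeledDocument], list[LabeledDocument]]:
    """Patient-disjoint split; test token share approximates test_fraction."""
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    patients: dict[str, int] = {}
    for doc in corpus:
        patients[doc.patient_id] = patients.get(doc.patient_id, 0) + len(doc)
    if len(patients) < 2:
        raise ValueError("need at least 2 patients to split")
    total = sum(patients.values())
    ids = list(patients)
    rng = np.random.default_rng(seed)
    rng.shuffle(ids)
    test_ids: set[str] = set()
    test_tokens = 0
    for pid in ids:
        if test_tokens >= test_fraction * total or len(test_ids) == len(ids) - 1:
            break
        test_ids.add(pid)
        test_tokens += patients[pid]
    train = [d for d in corpus if d.patient_id not in test_ids]
    test = [d for d in corpus if d.patient_id in test_ids]
    return train, test
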