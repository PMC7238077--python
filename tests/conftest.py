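import dataclasses

import pytest

from phideid.corpus import LabeledDocument
from phideid.encoders import make_random_table
from phideid.labels import build_label_scheme
from phideid.network import NetworkConfig, init_parameters


@pytest.fixture(scope="session")
def scheme():
    return build_label_scheme()


@pytest.fixture(scope="session")
def tiny_config():
    """Small network for oracle tests: finite differences stay cheap."""
    return NetworkConfig(word_dim=6, char_hidden=4, label_hidden=3, ff_hidden=3)


@pytest.fixture(scope="session")
def tiny_table():
    vocab = ["alpha", "beta", "gamma", "912", "seen", "on", "mr123456"]
    return make_random_table(vocab, dim=6, seed=11)


@pytest.fixture()
def tiny_params(tiny_config):
    return init_parameters(tiny_config, seed=3)


def make_doc(tokens, labels, doc_id="d0", patient_id="p0"):
    return LabeledDocument(doc_id, patient_id, tuple(tokens), tuple(labels))


@pytest.fixture(scope="session")
def tiny_docs():
    """A handful of short fragments over the tiny vocabulary."""
    return [
        make_doc(["alpha", "beta", "912"], ["non-PHI", "non-PHI", "date"], "d0", "pA"),
        make_doc(["seen", "on", "912", "gamma"], ["non-PHI", "non-PHI", "date", "non-PHI"], "d1", "pA"),
        make_doc(["Beta", "Gamma"], ["patient", "patient"], "d2", "pB"),
        make_doc(["MR123456", "alpha"], ["medical-record-number", "non-PHI"], "d3", "pC"),
        make_doc(["gamma", "alpha", "alpha"], ["non-PHI", "non-PHI", "non-PHI"], "d4", "pD"),
        make_doc(["912", "beta"], ["date", "non-PHI"], "d5", "pE"),
    ]


def random_doc(rng, scheme, vocab=("alpha", "beta", "gamma", "912"), n=None):
    n = n or int(rng.integers(2, 6))
    tokens = [str(vocab[int(rng.integers(0, len(vocab)))]) for _ in range(n)]
    labels = [scheme.labels[int(rng.integers(0, len(scheme)))] for _ in range(n)]
    return make_doc(tokens, labels, f"r{int(rng.integers(1e6))}", "pr")


@pytest.fixture(scope="session")
def protocol_comparison():
    """Desk-scale comparison of training regimes, replicated over 3 seeds.

    For each seed: one synthetic corpus (~50 patients, ~30k training tokens
    after the patient-disjoint split), a reduced network, 20 epochs at the
    study hyperparameters; final binary-PHI F1 on the shared test split for
    centralized training, 5-worker DSSGD (theta_d=0.1 preset) and 5-worker
    isolated local training.  Shared by the protocol-ordering and
    learnability tests because it is the expensive part of the suite.
    """
    from phideid.experiments import PRESETS, run_experiment

    runs = []
    for seed in (0, 1, 2):
        run = {"seed": seed}
        for key, preset in (("centralized", "A"), ("dssgd", "C_0.1"), ("local", "D")):
            cfg = dataclasses.replace(PRESETS[preset], seed=seed, eval_every=20)
            result = run_experiment(cfg)
            finals = [r["f1"] for r in result.records if r["epoch"] == cfg.epochs - 1]
            if key == "centralized":
                run[key] = finals[0]
            else:
                run[key] = finals
        runs.append(run)
    return runs
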