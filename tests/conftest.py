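import numpy as np
import pytest

from fragdta.sequences import Alphabet, BioSequence
from fragdta.vocab import build_vocabulary
from fragdta.mlm import EncoderConfig, FragmentEncoder


DRUG_CHARS = "CNOS()=#123cnos"


def random_drug_text(rng, length):
    return "".join(rng.choice(list(DRUG_CHARS), size=length))


@pytest.fixture(scope="session")
def drug_vocab():
    rng = np.random.default_rng(42)
    corpus = [random_drug_text(rng, 30) for _ in range(20)]
    return build_vocabulary(corpus, Alphabet.DRUG_SMILES)


@pytest.fixture(scope="session")
def untrained_drug_encoder(drug_vocab):
    """Randomly initialised (deterministic-seed) encoder: exercises shapes
    and determinism without pre-training cost."""
    cfg = EncoderConfig(fragment_length=16, seed=7)
    return FragmentEncoder(cfg, drug_vocab)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_sequence(text, kind=Alphabet.DRUG_SMILES, ident=""):
    return BioSequence(text=text, kind=kind, ident=ident)
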