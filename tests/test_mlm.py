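"""Masked-language-model encoder: masking policy, encoding, fill-mask metric."""

import numpy as np
import pytest

from fragdta.mlm import (
    EncoderConfig,
    FragmentEncoder,
    fillmask_topk_precision,
    pretrain_encoder,
    sample_masking_plan,
)
from fragdta.sequences import Alphabet, BioSequence
from fragdta.vocab import build_vocabulary, tokenize_fragment


def test_config_validation():
    with pytest.raises(ValueError):
        EncoderConfig(hidden_size=60, attention_heads=7)
    with pytest.raises(ValueError):
        EncoderConfig(mask_probability=0.0)
    with pytest.raises(ValueError):
        EncoderConfig(fragment_length=600, max_positions=512)


class TestMaskingPlan:
    def test_masked_fraction_near_probability(self, drug_vocab):
        rng = np.random.default_rng(0)
        char_ids = [i for i in range(drug_vocab.size) if i not in drug_vocab.special_ids]
        ids = np.array(rng.choice(char_ids, size=(200, 18)))
        ids[:, 0] = drug_vocab.bos_id
        ids[:, -1] = drug_vocab.eos_id
        fractions = []
        for _ in range(30):
            _, sel = sample_masking_plan(ids, drug_vocab, 0.15, rng)
            fractions.append(sel[:, 1:-1].mean())
        assert abs(np.mean(fractions) - 0.15) < 0.02

    def test_specials_never_masked(self, drug_vocab):
        rng = np.random.default_rng(1)
        ids = np.full((50, 10), drug_vocab.pad_id)
        ids[:, 0] = drug_vocab.bos_id
        ids[:, -1] = drug_vocab.eos_id
        corrupted, sel = sample_masking_plan(ids, drug_vocab, 0.5, rng)
        assert not sel.any()
        assert np.array_equal(corrupted, ids)


class TestEncoding:
    def test_pooled_vector_length_is_u(self, untrained_drug_encoder):
        vec = untrained_drug_encoder.encode_fragment("C" * 16)
        assert vec.shape == (60,)

    def test_encoding_deterministic(self, untrained_drug_encoder):
        a = untrained_drug_encoder.encode_fragment("CCO" + "N" * 13)
        b = untrained_drug_encoder.encode_fragment("CCO" + "N" * 13)
        assert np.array_equal(a, b)

    def test_distinct_fragments_distinct_vectors(self, untrained_drug_encoder):
        a = untrained_drug_encoder.encode_fragment("C" * 16)
        b = untrained_drug_encoder.encode_fragment("N" * 16)
        assert not np.array_equal(a, b)

    def test_length_mismatch_rejected(self, untrained_drug_encoder):
        with pytest.raises(ValueError):
            untrained_drug_encoder.encode_fragment("C" * 10)

    def test_save_load_bitwise_identical(self, untrained_drug_encoder, tmp_path):
        untrained_drug_encoder.save(tmp_path / "enc")
        loaded = FragmentEncoder.load(tmp_path / "enc")
        frag = "CN(C)SO" + "C" * 9
        assert np.array_equal(
            untrained_drug_encoder.encode_fragment(frag), loaded.encode_fragment(frag)
        )
        assert loaded.checksum() == untrained_drug_encoder.checksum()


class TestPretraining:
    def test_two_runs_identical_and_loss_decreases(self):
        corpus = ["CCONCS" * 2, "NNOSCC" * 2, "COCSNN" * 2, "SCCNOC" * 2] * 16
        vocab = build_vocabulary(corpus, Alphabet.DRUG_SMILES)
        cfg = EncoderConfig(fragment_length=12, epochs=4, seed=3, batch_size=32)
        enc1 = pretrain_encoder(corpus, vocab, cfg)
        enc2 = pretrain_encoder(corpus, vocab, cfg)
        assert enc1.loss_history == enc2.loss_history
        before, after = enc1.heldout_losses
        assert after < before

    def test_mismatched_fragment_length_rejected(self):
        vocab = build_vocabulary(["CC"], Alphabet.DRUG_SMILES)
        with pytest.raises(ValueError):
            pretrain_encoder(["CC", "CCC"], vocab, EncoderConfig(fragment_length=2, epochs=1))


class TestFillMask:
    def test_precision_arithmetic_with_constant_predictor(self, untrained_drug_encoder):
        # a predictor that always answers 'C' scores TP=3, FP=1 on "CCCCX"
        enc = untrained_drug_encoder
        c_id = enc.vocab.token_to_id["C"]

        def always_c(ids):
            out = np.zeros((len(ids), ids.shape[1], enc.vocab.size))
            out[:, :, c_id] = 10.0
            return out

        enc_patched = FragmentEncoder(enc.config, enc.vocab, enc.model)
        enc_patched.masked_logits = always_c
        seq = BioSequence("CCCC(", Alphabet.DRUG_SMILES)
        per_char, overall = fillmask_topk_precision(enc_patched, [seq], k=1)
        assert overall == pytest.approx(0.75)
        assert per_char["C"] == pytest.approx(1.0)
        assert per_char["("] == pytest.approx(0.0)

    def test_oracle_predictor_scores_one_for_every_k(self, untrained_drug_encoder):
        enc = untrained_drug_encoder
        c_id = enc.vocab.token_to_id["C"]
        oracle = FragmentEncoder(enc.config, enc.vocab, enc.model)
        oracle.masked_logits = lambda ids: np.eye(enc.vocab.size)[
            np.full(ids.shape, c_id)
        ] * 5.0
        seq = BioSequence("C" * 40, Alphabet.DRUG_SMILES)
        for k in (1, 3, 10):
            _, overall = fillmask_topk_precision(oracle, [seq], k=k)
            assert overall == 1.0

    def test_topk_monotone_in_k(self, untrained_drug_encoder):
        rng = np.random.default_rng(4)
        chars = [t for t in untrained_drug_encoder.vocab.token_to_id if len(t) == 1]
        seqs = [
            BioSequence("".join(rng.choice(chars, size=30)), Alphabet.DRUG_SMILES)
            for _ in range(3)
        ]
        overall = [
            fillmask_topk_precision(untrained_drug_encoder, seqs, k=k)[1] for k in (1, 3, 10)
        ]
        assert overall[0] <= overall[1] <= overall[2]

    def test_k_larger_than_vocab_rejected(self, untrained_drug_encoder):
        with pytest.raises(ValueError):
            fillmask_topk_precision(
                untrained_drug_encoder,
                [BioSequence("CC", Alphabet.DRUG_SMILES)],
                k=10_000,
            )
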