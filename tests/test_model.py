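"""Supervised head: branch geometry, fusion, splits, training contracts."""

import numpy as np
import pytest

from fragdta.model import (
    AffinityModel,
    CNNBranch,
    GCNBranch,
    ModelConfig,
    PairRecord,
    split_dataset,
    train_affinity_model,
)
from fragdta.molgraph import smiles_to_graph
from fragdta.nn import Tensor
from fragdta.sequences import Alphabet, BioSequence


CFG = ModelConfig()


def small_dataset(n_drugs=6, n_targets=4, seed=0):
    rng = np.random.default_rng(seed)
    drugs = [
        BioSequence("C" * (10 + i), Alphabet.DRUG_SMILES, ident=f"d{i}") for i in range(n_drugs)
    ]
    targets = [
        BioSequence("M" * (50 + i), Alphabet.PROTEIN_SEQ, ident=f"t{i}") for i in range(n_targets)
    ]
    drug_feats = {d.text: rng.normal(size=(60, 24)) for d in drugs}
    target_feats = {t.text: rng.normal(size=(60, 24)) for t in targets}
    pairs = [PairRecord(d, t, float(rng.normal())) for d in drugs for t in targets]
    return pairs, drug_feats, target_feats


class TestCNNBranch:
    def test_flattened_width_is_2560(self):
        branch = CNNBranch(CFG, 1024, np.random.default_rng(0))
        assert branch.flattened_width((60, 24)) == 2560
        x = Tensor(np.random.default_rng(1).normal(size=(2, 1, 60, 24)))
        branch.eval()
        assert branch.features(x).shape == (2, 2560)

    def test_output_widths(self):
        rng = np.random.default_rng(0)
        drug_branch = CNNBranch(CFG, CFG.drug_fc, rng)
        target_branch = CNNBranch(CFG, CFG.target_fc, rng)
        x = Tensor(np.random.default_rng(1).normal(size=(3, 1, 60, 24)))
        drug_branch.eval(), target_branch.eval()
        assert drug_branch(x).shape == (3, 1024)
        assert target_branch(x).shape == (3, 2048)

    def test_all_zero_input_finite_in_eval(self):
        branch = CNNBranch(CFG, 1024, np.random.default_rng(0))
        branch.eval()
        out = branch(Tensor(np.zeros((1, 1, 60, 24))))
        assert np.isfinite(out.data).all()

    def test_shape_mismatch_rejected(self):
        branch = CNNBranch(CFG, 1024, np.random.default_rng(0))
        with pytest.raises(ValueError):
            branch(Tensor(np.zeros((1, 1, 30, 24))))


class TestGCNBranch:
    def test_pooled_width_1280_and_output_1024(self):
        branch = GCNBranch(CFG, np.random.default_rng(0))
        branch.eval()
        g = smiles_to_graph("CC(=O)OC1=CC=CC=C1C(=O)O")
        assert branch.pooled(g).shape == (1280,)
        assert branch([g]).shape == (1, 1024)

    def test_single_atom_molecule(self):
        branch = GCNBranch(CFG, np.random.default_rng(0))
        branch.eval()
        out = branch([smiles_to_graph("C")])
        assert out.shape == (1, 1024)
        assert np.isfinite(out.data).all()


class TestFusion:
    def test_concatenated_width_4096(self):
        model = AffinityModel(ModelConfig(seed=1))
        assert model.fused_width == 4096

    def test_zero_branches_zero_bias_head_gives_zero(self):
        model = AffinityModel(ModelConfig(seed=1))
        model.eval()
        z = Tensor(np.zeros((2, 1024)))
        z2 = Tensor(np.zeros((2, 2048)))
        out = model.fuse_and_predict(z, z2, Tensor(np.zeros((2, 1024))))
        assert np.allclose(out.data, 0.0)

    def test_single_scalar_per_pair(self):
        model = AffinityModel(ModelConfig(seed=1))
        model.eval()
        rng = np.random.default_rng(2)
        out = model.forward(rng.normal(size=(5, 60, 24)), rng.normal(size=(5, 60, 24)))
        assert out.shape == (5, 1)


class TestSplitDataset:
    def test_100_pairs_80_10_10(self):
        (tr, va, te), = split_dataset(100, seed=0)
        assert (len(tr), len(va), len(te)) == (80, 10, 10)

    def test_disjoint_and_exhaustive(self):
        (tr, va, te), = split_dataset(101, seed=3)
        allidx = np.concatenate([tr, va, te])
        assert len(np.unique(allidx)) == 101

    def test_kiba_row_sizes(self):
        (tr, va, te), = split_dataset(118_254, seed=0)
        assert (len(tr), len(va), len(te)) == (94_604, 11_825, 11_825)

    def test_repeats_distinct(self):
        splits = split_dataset(50, seed=0, repeats=3)
        assert len(splits) == 3
        assert not np.array_equal(splits[0][0], splits[1][0])

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(2)


class TestTraining:
    def test_missing_feature_error_names_entity(self):
        pairs, drug_feats, target_feats = small_dataset()
        del drug_feats[pairs[0].drug.text]
        with pytest.raises(KeyError, match="d0"):
            train_affinity_model(
                pairs, pairs[:2], drug_feats, target_feats, None,
                ModelConfig(use_gcn=False, epochs=1, batch_size=8),
            )

    def test_same_seed_identical_validation_loss(self):
        pairs, drug_feats, target_feats = small_dataset()
        cfg = ModelConfig(use_gcn=False, epochs=2, batch_size=12, seed=5)
        _, h1 = train_affinity_model(pairs[:16], pairs[16:20], drug_feats, target_feats, None, cfg)
        _, h2 = train_affinity_model(pairs[:16], pairs[16:20], drug_feats, target_feats, None, cfg)
        assert h1.valid_loss == h2.valid_loss

    def test_best_checkpoint_not_worse_than_first_epoch(self):
        pairs, drug_feats, target_feats = small_dataset()
        cfg = ModelConfig(use_gcn=False, epochs=4, batch_size=12, seed=5)
        _, hist = train_affinity_model(pairs[:16], pairs[16:20], drug_feats, target_feats, None, cfg)
        assert hist.best_valid_loss <= hist.valid_loss[0]

    def test_binary_mode_probabilities(self):
        pairs, drug_feats, target_feats = small_dataset()
        bin_pairs = [PairRecord(p.drug, p.target, float(i % 2)) for i, p in enumerate(pairs)]
        cfg = ModelConfig(use_gcn=False, mode="binary", epochs=2, batch_size=12, seed=5)
        model, _ = train_affinity_model(
            bin_pairs[:16], bin_pairs[16:20], drug_feats, target_feats, None, cfg
        )
        preds = model.predict(
            np.stack([drug_feats[p.drug.text] for p in bin_pairs[:4]]),
            np.stack([target_feats[p.target.text] for p in bin_pairs[:4]]),
        )
        assert ((preds >= 0) & (preds <= 1)).all()

    def test_prediction_invariant_to_batch_order(self):
        pairs, drug_feats, target_feats = small_dataset()
        model = AffinityModel(ModelConfig(use_gcn=False, seed=2))
        model.eval()
        Xd = np.stack([drug_feats[p.drug.text] for p in pairs[:6]])
        Xt = np.stack([target_feats[p.target.text] for p in pairs[:6]])
        fwd = model.predict(Xd, Xt)
        rev = model.predict(Xd[::-1].copy(), Xt[::-1].copy())
        assert np.allclose(fwd, rev[::-1], atol=1e-5)

    def test_gcn_branch_with_real_molecules(self):
        # graph-enabled path on a handful of real SMILES
        from fragdta.synthetic import REAL_SMILES

        rng = np.random.default_rng(0)
        drugs = [BioSequence(s, Alphabet.DRUG_SMILES, ident=f"d{i}") for i, s in enumerate(REAL_SMILES[:4])]
        targets = [BioSequence("M" * 60, Alphabet.PROTEIN_SEQ, ident="t0")]
        drug_feats = {d.text: rng.normal(size=(60, 24)) for d in drugs}
        target_feats = {t.text: rng.normal(size=(60, 24)) for t in targets}
        graphs = {d.text: smiles_to_graph(d.text) for d in drugs}
        pairs = [PairRecord(d, targets[0], float(rng.normal())) for d in drugs]
        cfg = ModelConfig(epochs=2, batch_size=4, seed=0)
        model, hist = train_affinity_model(pairs, pairs[:2], drug_feats, target_feats, graphs, cfg)
        assert np.isfinite(hist.train_loss).all()

    def test_save_load_round_trip(self, tmp_path):
        pairs, drug_feats, target_feats = small_dataset()
        cfg = ModelConfig(use_gcn=False, epochs=1, batch_size=12, seed=5)
        model, _ = train_affinity_model(pairs[:16], pairs[16:20], drug_feats, target_feats, None, cfg)
        model.save(tmp_path / "m")
        loaded = AffinityModel.load(tmp_path / "m")
        Xd = np.stack([drug_feats[p.drug.text] for p in pairs[:3]])
        Xt = np.stack([target_feats[p.target.text] for p in pairs[:3]])
        assert np.array_equal(model.predict(Xd, Xt), loaded.predict(Xd, Xt))
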