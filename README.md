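# fragdta

Fragment-level self-supervised featurization for drug–target binding
affinity (DTA) prediction, with a compound–protein interaction (CPI)
classification mode.

## The problem

Predicting how strongly a small molecule binds a protein is a regression
task over pairs (SMILES string, amino-acid sequence).  Labelled affinity
data is scarce, while unlabelled molecules and proteins are abundant —
and binding is thought to be dominated by *core fragments*: short
substructures of each partner.  `fragdta` therefore learns features at the
fragment level in two stages:

1. **Self-supervised stage.**  A small RoBERTa-style masked-language-model
   encoder per alphabet is pre-trained on fixed-length, non-overlapping
   fragments (16 characters for SMILES, 128 residues for proteins).
2. **Supervised stage.**  An adaptive sliding window with stride
   b = max(1, ⌊p/K⌋) cuts any sequence of length p into exactly K = 24
   overlapping fragments, and the frozen encoder's pooled outputs form a
   u × K = 60 × 24 feature matrix Ô per entity.  Two 2D-CNN branches (over
   the drug and target matrices), a global-pooling GCN over the drug's
   molecular graph, and a fully connected fusion head regress the affinity:

       â = f_D([ f̂_C(Ô_drug), f̆_C(Ŏ_target), f̂_G(graph) ])

   trained by MSE (or cross-entropy for binary CPI labels).  Evaluation
   uses concordance index (CI), MSE, the modified squared correlation rm²,
   AUPR (affinities binarized at an explicit threshold) and AUROC.

The networks run on a small, fully seeded numpy autograd engine shipped in
`fragdta.nn` — no GPU or deep-learning framework required — so everything
is reproducible and testable on one CPU at desk scale.

## Worked example

```python
import numpy as np
from fragdta import (
    SyntheticSpec, generate_sequences, generate_pairs,
    build_vocabulary, EncoderConfig, pretrain_encoder,
    extract_feature_matrix, ModelConfig, split_dataset,
    train_affinity_model, concordance_index, divide_training_fragments,
    Alphabet,
)

spec = SyntheticSpec(n_drugs=60, n_targets=40, n_pairs=1000, seed=1)
drugs, targets = generate_sequences(spec)
pairs = generate_pairs(spec, drugs, targets)          # planted-motif labels

frags = [f for d in drugs for f in divide_training_fragments(d, 16)]
vocab = build_vocabulary((d.text for d in drugs), Alphabet.DRUG_SMILES)
enc = pretrain_encoder(frags, vocab, EncoderConfig(fragment_length=16, epochs=25, seed=2))
print(enc.heldout_losses)     # held-out masked cross-entropy (before, after)

fm = extract_feature_matrix(enc, drugs[0], K=24)
print(fm.values.shape)        # (60, 24) for every sequence length
```

Running the full recovery experiment (this is what
`tests/test_acceptance.py` does) prints, with the numbers observed at
seed 1:

```
held-out masked CE: 4.34 -> 3.54      # the drug encoder learned corpus structure
feature matrix shape: (60, 24)
untrained model test CI: 0.50         # chance-level ranking before training
trained model test CI:  0.89          # planted fragment signal recovered
label-shuffled control: ~0.5          # no signal, no ranking skill
```

A CI of 0.5 is coin-flip ranking of held-out pairs; the jump after
training shows the pipeline recovers affinity signal planted purely in
fragment content.

The same pipeline is scriptable from the shell:

```bash
fragdta synth --out data/
fragdta pretrain --kind drug --corpus data/drugs.smi --out enc_drug/ --seed 0
fragdta pretrain --kind target --corpus data/targets.fasta --out enc_target/ --seed 0
fragdta train --pairs data/pairs.csv --drug-encoder enc_drug/ \
              --target-encoder enc_target/ --out model/ --seed 0
fragdta evaluate --model model/ --pairs data/pairs.csv \
                 --drug-encoder enc_drug/ --target-encoder enc_target/ --out report.json
```

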