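"""The supervised affinity head.

Three feature branches are fused to score one drug-target pair:

* a 2D-CNN over the drug's ``u x K`` fragment-feature matrix -> 1,024;
* a 2D-CNN over the target's ``u x K`` matrix -> 2,048;
* a global-pooling GCN over the drug's molecular graph -> 1,024.

Each CNN branch stacks three valid, unit-stride convolutions (64/128/256
filters, kernels 5/3/3), each followed by batch normalisation and ReLU,
with 3x3 stride-2 max pooling after the first two layers; under the default
60x24 input this flattens to exactly 2,560 features before the branch's
fully connected layer.  The GCN widens 78 -> 156 -> 1,280 and global-max
pools over atoms.  The concatenated 4,096-vector passes through a
1,024 -> 512 -> 1 fully connected head; regression mode emits the raw
scalar (trained by MSE), binary mode a logit (trained by cross-entropy).

The drug is described twice (CNN + GCN) and the target once, which is why
the drug CNN projects to 1,024 and the target CNN to 2,048: both entities
end up with 2,048 features in the fused vector.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .molgraph import ATOM_FEATURE_DIM, MolecularGraph
from .nn import Adam, BatchNorm2d, Conv2d, Dropout, Linear, Module, Tensor
from .sequences import BioSequence

__all__ = [
    "PairRecord",
    "ModelConfig",
    "CNNBranch",
    "GCNBranch",
    "AffinityModel",
    "train_affinity_model",
    "split_dataset",
]


@dataclass(frozen=True)
class PairRecord:
    """One labelled drug-target pair."""

    drug: BioSequence
    target: BioSequence
    label: float

    def __post_init__(self):
        if not np.isfinite(self.label):
            raise ValueError("pair label must be finite")


@dataclass(frozen=True)
class ModelConfig:
    u: int = 60
    K: int = 24
    cnn_filters: tuple = (64, 128, 256)
    cnn_kernels: tuple = (5, 3, 3)
    pool_size: int = 3
    pool_stride: int = 2
    drug_fc: int = 1024
    target_fc: int = 2048
    gcn_dims: tuple = (78, 156, 1280)
    gcn_fc: int = 1024
    head_dims: tuple = (1024, 512, 1)
    dropout: float = 0.1
    mode: str = "regression"  # or "binary"
    use_gcn: bool = True
    learning_rate: float = 1e-3
    batch_size: int = 1024
    epochs: int = 2000
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("regression", "binary"):
            raise ValueError("mode must be 'regression' or 'binary'")


class CNNBranch(Module):
    """Three-layer 2D CNN over a single-channel ``u x K`` feature matrix."""

    def __init__(self, cfg: ModelConfig, out_dim: int, rng):
        super().__init__()
        self.cfg = cfg
        chans = (1,) + tuple(cfg.cnn_filters)
        self.convs = [
            Conv2d(chans[i], chans[i + 1], cfg.cnn_kernels[i], rng) for i in range(3)
        ]
        self.bns = [BatchNorm2d(f) for f in cfg.cnn_filters]
        flat = self.flattened_width((cfg.u, cfg.K))
        self.fc = Linear(flat, out_dim, rng)
        self.out_dim = out_dim

    def flattened_width(self, input_shape: tuple[int, int]) -> int:
        """Pre-FC feature count for a given (height, width) input."""
        h, w = input_shape
        for i in range(3):
            k = self.cfg.cnn_kernels[i]
            h, w = h - k + 1, w - k + 1
            if i < 2:  # max pool after layers 1 and 2 only
                h = (h - self.cfg.pool_size) // self.cfg.pool_stride + 1
                w = (w - self.cfg.pool_size) // self.cfg.pool_stride + 1
        return self.cfg.cnn_filters[-1] * h * w

    def features(self, x: Tensor) -> Tensor:
        """Flattened convolutional features, shape (B, flattened_width)."""
        for i in range(3):
            x = self.bns[i](self.convs[i](x)).relu()
            if i < 2:
                x = x.max_pool2d(self.cfg.pool_size, self.cfg.pool_stride)
        return x.reshape(x.shape[0], -1)

    def __call__(self, x: Tensor) -> Tensor:
        if x.shape[2] != self.cfg.u or x.shape[3] != self.cfg.K:
            raise ValueError(
                f"expected input of shape (B, 1, {self.cfg.u}, {self.cfg.K}), got {x.shape}"
            )
        return self.fc(self.features(x))


def _norm_adjacency(g: MolecularGraph) -> np.ndarray:
    """Symmetrically normalised adjacency with self-loops, D^-1/2 (A+I) D^-1/2."""
    n = g.atom_count
    a = np.eye(n)
    for i, j in g.edges:
        a[i, j] = 1.0
        a[j, i] = 1.0
    d = a.sum(axis=1)
    dinv = 1.0 / np.sqrt(d)
    return a * dinv[:, None] * dinv[None, :]


class GCNBranch(Module):
    """Global-max-pooling graph convolution over the drug's atom graph."""

    def __init__(self, cfg: ModelConfig, rng):
        super().__init__()
        dims = (ATOM_FEATURE_DIM,) + tuple(cfg.gcn_dims)
        self.layers = [Linear(dims[i], dims[i + 1], rng) for i in range(3)]
        self.drop = Dropout(cfg.dropout)
        self.fc = Linear(cfg.gcn_dims[-1], cfg.gcn_fc, rng)
        self.pooled_width = cfg.gcn_dims[-1]

    def pooled(self, g: MolecularGraph) -> Tensor:
        if g.atom_count == 0:
            raise ValueError("cannot run the graph branch on an empty graph")
        a = Tensor(_norm_adjacency(g))
        h = Tensor(g.node_features)
        for layer in self.layers:
            h = (a @ layer(h)).relu()
        return h.max_along(axis=0)  # (pooled_width,)

    def __call__(self, graphs: Sequence[MolecularGraph]) -> Tensor:
        pooled = Tensor.stack([self.pooled(g) for g in graphs], axis=0)
        return self.fc(self.drop(pooled))


class AffinityModel(Module):
    """Two CNN branches + optional GCN branch + fully connected fusion head."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        rng = np.random.default_rng(cfg.seed)
        self.cfg = cfg
        self.drug_cnn = CNNBranch(cfg, cfg.drug_fc, rng)
        self.target_cnn = CNNBranch(cfg, cfg.target_fc, rng)
        self.gcn = GCNBranch(cfg, rng)
        fused = cfg.drug_fc + cfg.target_fc + cfg.gcn_fc
        self.fc1 = Linear(fused, cfg.head_dims[0], rng)
        self.fc2 = Linear(cfg.head_dims[0], cfg.head_dims[1], rng)
        self.out = Linear(cfg.head_dims[1], cfg.head_dims[2], rng)
        self.drop = Dropout(cfg.dropout)
        self.fused_width = fused
        self.reseed_dropout(np.random.default_rng(cfg.seed + 7))

    def reseed_dropout(self, rng) -> None:
        for m in [self] + self.modules():
            if isinstance(m, Dropout):
                m.reseed(rng)

    def fuse_and_predict(self, h_drug: Tensor, h_target: Tensor, h_graph: Tensor) -> Tensor:
        """Concatenate branch outputs (drug-CNN, target-CNN, drug-GCN) and score."""
        h = Tensor.concat([h_drug, h_target, h_graph], axis=1)
        h = self.drop(self.fc1(h).relu())
        h = self.drop(self.fc2(h).relu())
        return self.out(h)

    def forward(
        self,
        drug_mats: np.ndarray,
        target_mats: np.ndarray,
        graphs: Optional[Sequence[MolecularGraph]] = None,
    ) -> Tensor:
        """Score a batch.  ``drug_mats``/``target_mats``: (B, u, K) arrays.

        When ``graphs`` is None or the config disables the graph branch, its
        head segment is zeroed — the spec'd ablation that makes the model
        usable for sequence-only (e.g. synthetic) drugs.
        """
        B = drug_mats.shape[0]
        hd = self.drug_cnn(Tensor(drug_mats[:, None, :, :]))
        ht = self.target_cnn(Tensor(target_mats[:, None, :, :]))
        if graphs is not None and self.cfg.use_gcn:
            hg = self.gcn(graphs)
        else:
            hg = Tensor(np.zeros((B, self.cfg.gcn_fc)))
        return self.fuse_and_predict(hd, ht, hg)

    def save(self, directory) -> None:
        import json
        from dataclasses import asdict
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        (d / "config.json").write_text(json.dumps(asdict(self.cfg), indent=1))
        np.savez(d / "weights.npz", **self.state_dict())

    @classmethod
    def load(cls, directory) -> "AffinityModel":
        import json
        from pathlib import Path

        d = Path(directory)
        raw = json.loads((d / "config.json").read_text())
        for key in ("cnn_filters", "cnn_kernels", "gcn_dims", "head_dims"):
            raw[key] = tuple(raw[key])
        model = cls(ModelConfig(**raw))
        with np.load(d / "weights.npz") as z:
            model.load_state_dict({k: z[k] for k in z.files})
        model.eval()
        return model

    def predict(self, drug_mats, target_mats, graphs=None) -> np.ndarray:
        """Eval-mode predictions; binary mode returns probabilities."""
        self.eval()
        z = self.forward(drug_mats, target_mats, graphs).data.ravel()
        if self.cfg.mode == "binary":
            return 1.0 / (1.0 + np.exp(-z))
        return z


def _bce_with_logits(z: Tensor, y: np.ndarray) -> Tensor:
    """Numerically stable mean binary cross-entropy on logits."""
    zd = z.data
    y = np.asarray(y, dtype=zd.dtype)

    def bw(g):
        p = 1.0 / (1.0 + np.exp(-zd))
        z._accum(g * (p - y) / y.size)

    loss = np.mean(np.maximum(zd, 0) - zd * y + np.log1p(np.exp(-np.abs(zd))))
    return Tensor._make(np.asarray(loss), (z,), bw)


def split_dataset(
    n_pairs: int,
    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
    repeats: int = 1,
) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Repeated random train/validation/test splits.

    Validation and test sizes are floor allocations; the remainder goes to
    training, so e.g. 118,254 pairs at 8:1:1 give 94,604/11,825/11,825.
    Each repeat uses a distinct seed.
    """
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must sum to 1")
    if n_pairs < 3:
        raise ValueError("need at least three pairs to split")
    n_valid = int(n_pairs * ratios[1])
    n_test = int(n_pairs * ratios[2])
    n_train = n_pairs - n_valid - n_test
    out = []
    for r in range(repeats):
        perm = np.random.default_rng(seed + r).permutation(n_pairs)
        out.append(
            (
                np.sort(perm[:n_train]),
                np.sort(perm[n_train : n_train + n_valid]),
                np.sort(perm[n_train + n_valid :]),
            )
        )
    return out


@dataclass
class TrainingHistory:
    train_loss: list = field(default_factory=list)
    valid_loss: list = field(default_factory=list)
    best_epoch: int = -1
    best_valid_loss: float = float("inf")


def _gather(pairs, drug_features, target_features, graphs, use_graphs):
    """Stack cached features (and graphs) for a list of pairs."""
    dmats, tmats, gs, ys = [], [], [], []
    for p in pairs:
        dkey, tkey = p.drug.text, p.target.text
        if dkey not in drug_features:
            raise KeyError(f"no cached feature matrix for drug {p.drug.ident or dkey!r}")
        if tkey not in target_features:
            raise KeyError(f"no cached feature matrix for target {p.target.ident or tkey!r}")
        dmats.append(drug_features[dkey])
        tmats.append(target_features[tkey])
        if use_graphs:
            if graphs is None or dkey not in graphs:
                raise KeyError(f"no molecular graph for drug {p.drug.ident or dkey!r}")
            gs.append(graphs[dkey])
        ys.append(p.label)
    return np.stack(dmats), np.stack(tmats), gs, np.array(ys, dtype=float)


def train_affinity_model(
    train_pairs: list[PairRecord],
    valid_pairs: list[PairRecord],
    drug_features: dict,
    target_features: dict,
    graphs: Optional[dict] = None,
    cfg: ModelConfig = ModelConfig(),
    epoch_callback=None,
) -> tuple[AffinityModel, TrainingHistory]:
    """Train the supervised head on cached feature matrices.

    ``drug_features`` / ``target_features`` map sequence text to ``u x K``
    arrays; ``graphs`` maps drug text to :class:`MolecularGraph` (required
    only when the graph branch is enabled).  Uses Adam at the configured
    learning rate, minimising MSE (regression) or binary cross-entropy
    (binary), with best-on-validation checkpointing.  Reproducible per
    ``cfg.seed``.
    """
    model = AffinityModel(cfg)
    use_graphs = cfg.use_gcn and graphs is not None
    Xd, Xt, Gs, Y = _gather(train_pairs, drug_features, target_features, graphs, use_graphs)
    Vd, Vt, VGs, VY = _gather(valid_pairs, drug_features, target_features, graphs, use_graphs)

    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    shuffle_rng = np.random.default_rng(cfg.seed + 11)
    hist = TrainingHistory()
    best_state = model.state_dict()
    n = len(train_pairs)

    def valid_loss() -> float:
        model.eval()
        preds = model.forward(Vd, Vt, VGs if use_graphs else None)
        if cfg.mode == "binary":
            return float(_bce_with_logits(preds, VY.reshape(-1, 1)).data)
        return float(((preds.reshape(-1) - Tensor(VY)) ** 2.0).mean().data)

    for epoch in range(cfg.epochs):
        model.train()
        order = shuffle_rng.permutation(n)
        total, nb = 0.0, 0
        for lo in range(0, n, cfg.batch_size):
            idx = order[lo : lo + cfg.batch_size]
            preds = model.forward(
                Xd[idx], Xt[idx], [Gs[i] for i in idx] if use_graphs else None
            )
            if cfg.mode == "binary":
                loss = _bce_with_logits(preds, Y[idx].reshape(-1, 1))
            else:
                loss = ((preds.reshape(-1) - Tensor(Y[idx])) ** 2.0).mean()
            opt.zero_grad()
            loss.backward()
            opt.step()
            total += float(loss.data)
            nb += 1
        hist.train_loss.append(total / max(1, nb))
        vl = valid_loss()
        hist.valid_loss.append(vl)
        if vl < hist.best_valid_loss:
            hist.best_valid_loss = vl
            hist.best_epoch = epoch
            best_state = model.state_dict()
        if epoch_callback is not None:
            epoch_callback(epoch, model, hist)

    model.load_state_dict(best_state)
    model.eval()
    return model, hist
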