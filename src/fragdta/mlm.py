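"""Masked-language-model pre-training of fragment encoders.

One small RoBERTa-style transformer encoder is trained per alphabet (drug
SMILES, protein sequence) on fixed-length fragments, with dynamic masking:
the set of masked positions is re-sampled every epoch.  After pre-training
the encoder is frozen and used only as a feature extractor — each fragment
is summarised by the pooler output (a tanh-activated affine map of the
first-position final hidden state), a vector of length ``u``.

The encoder is intentionally tiny (hidden size 60, 6 heads, 3 layers): the
character alphabets have only a few dozen symbols, so a small model has
enough capacity, and the pooled dimension ``u`` directly sets the height of
the downstream feature matrices.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict, replace
from pathlib import Path

import numpy as np

from .fragments import divide_inference_fragments
from .nn import Adam, Dropout, Embedding, LayerNorm, Linear, Module, Tensor
from .sequences import BioSequence
from .vocab import Vocabulary, tokenize_fragment

__all__ = [
    "EncoderConfig",
    "FragmentEncoder",
    "pretrain_encoder",
    "fillmask_topk_precision",
    "sample_masking_plan",
]


@dataclass(frozen=True)
class EncoderConfig:
    """Hyper-parameters of one fragment encoder.

    ``hidden_size`` must be divisible by ``attention_heads``; the pooled
    output dimension ``u`` equals ``pooler_size``.
    """

    fragment_length: int = 16
    hidden_size: int = 60
    attention_heads: int = 6
    layers: int = 3
    max_positions: int = 512
    pooler_size: int = 60
    ffn_size: int = 240
    mask_probability: float = 0.15
    batch_size: int = 128
    learning_rate: float = 1e-4
    warmup_steps: int = 100
    epochs: int = 50
    dropout: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.hidden_size % self.attention_heads != 0:
            raise ValueError("hidden_size must be a multiple of attention_heads")
        if not 0.0 < self.mask_probability < 1.0:
            raise ValueError("mask_probability must be in (0, 1)")
        if self.max_positions < self.fragment_length + 2:
            raise ValueError("max_positions must cover fragment_length + 2 framing tokens")


def _gelu(x: Tensor) -> Tensor:
    inner = (x + (x ** 3.0) * 0.044715) * 0.7978845608028654
    return x * 0.5 * (inner.tanh() + 1.0)


class _SelfAttention(Module):
    def __init__(self, d: int, heads: int, rng):
        super().__init__()
        self.heads = heads
        self.dh = d // heads
        self.q = Linear(d, d, rng)
        self.k = Linear(d, d, rng)
        self.v = Linear(d, d, rng)
        self.o = Linear(d, d, rng)

    def __call__(self, x: Tensor) -> Tensor:
        B, L, D = x.shape
        h, dh = self.heads, self.dh

        def split(t: Tensor) -> Tensor:
            return t.reshape(B, L, h, dh).transpose(0, 2, 1, 3)

        q, k, v = split(self.q(x)), split(self.k(x)), split(self.v(x))
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(dh))
        attn = scores.softmax(axis=-1)
        ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(B, L, D)
        return self.o(ctx)


class _EncoderLayer(Module):
    def __init__(self, d: int, heads: int, ffn: int, p_drop: float, rng):
        super().__init__()
        self.attn = _SelfAttention(d, heads, rng)
        self.ln1 = LayerNorm(d)
        self.fc1 = Linear(d, ffn, rng)
        self.fc2 = Linear(ffn, d, rng)
        self.ln2 = LayerNorm(d)
        self.drop = Dropout(p_drop)

    def __call__(self, x: Tensor) -> Tensor:
        x = self.ln1(x + self.drop(self.attn(x)))
        x = self.ln2(x + self.drop(self.fc2(_gelu(self.fc1(x)))))
        return x


class _Transformer(Module):
    """Token + (fragment-internal) position embeddings, N encoder layers,
    an MLM head projecting to the vocabulary, and a tanh pooler over the
    first (BOS) position.  Positions are relative to the fragment, never to
    the parent sequence: cross-fragment positional information is withheld
    deliberately."""

    def __init__(self, vocab_size: int, cfg: EncoderConfig, rng):
        super().__init__()
        d = cfg.hidden_size
        self.tok = Embedding(vocab_size, d, rng)
        self.pos = Embedding(cfg.max_positions, d, rng)
        self.ln_emb = LayerNorm(d)
        self.layers = [
            _EncoderLayer(d, cfg.attention_heads, cfg.ffn_size, cfg.dropout, rng)
            for _ in range(cfg.layers)
        ]
        self.mlm_head = Linear(d, vocab_size, rng)
        self.pooler = Linear(d, cfg.pooler_size, rng)
        self.drop = Dropout(cfg.dropout)

    def hidden(self, ids: np.ndarray) -> Tensor:
        B, L = ids.shape
        x = self.tok(ids) + self.pos(np.broadcast_to(np.arange(L), (B, L)))
        x = self.drop(self.ln_emb(x))
        for layer in self.layers:
            x = layer(x)
        return x

    def logits(self, ids: np.ndarray) -> Tensor:
        return self.mlm_head(self.hidden(ids))

    def pooled(self, ids: np.ndarray) -> Tensor:
        h0 = self.hidden(ids)[:, 0, :]
        return self.pooler(h0).tanh()


def sample_masking_plan(
    ids: np.ndarray, vocab: Vocabulary, mask_probability: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Dynamic-masking corruption of a batch of token ids.

    Each non-special position is selected independently with probability
    ``mask_probability``; selected positions become the MASK token with
    probability 0.8, a random character token with probability 0.1, and are
    kept unchanged with probability 0.1.  BOS/EOS/PAD are never selected.

    Returns ``(corrupted_ids, selected_mask)``.
    """
    special = np.isin(ids, [vocab.bos_id, vocab.eos_id, vocab.pad_id])
    selected = (rng.random(ids.shape) < mask_probability) & ~special
    corrupted = ids.copy()
    roll = rng.random(ids.shape)
    char_ids = np.array(
        [i for t, i in vocab.token_to_id.items() if i not in vocab.special_ids]
    )
    corrupted[selected & (roll < 0.8)] = vocab.mask_id
    rand_pos = selected & (roll >= 0.8) & (roll < 0.9)
    corrupted[rand_pos] = rng.choice(char_ids, size=int(rand_pos.sum()))
    return corrupted, selected


class FragmentEncoder:
    """A trained masked-language-model fragment encoder."""

    def __init__(self, config: EncoderConfig, vocab: Vocabulary, model: _Transformer | None = None):
        self.config = config
        self.vocab = vocab
        if model is None:
            rng = np.random.default_rng(config.seed)
            model = _Transformer(vocab.size, config, rng)
        self.model = model
        self.model.eval()
        self.loss_history: list[float] = []
        self.heldout_losses: tuple[float, float] | None = None

    # -- encoding ---------------------------------------------------------
    def _ids_for(self, frags: list) -> np.ndarray:
        rows = []
        for f in frags:
            ids = f.ids if hasattr(f, "ids") else tokenize_fragment(f, self.vocab).ids
            if len(ids) != self.config.fragment_length + 2:
                raise ValueError(
                    f"fragment length {len(ids) - 2} does not match configured "
                    f"length {self.config.fragment_length}"
                )
            rows.append(ids)
        return np.array(rows, dtype=np.int64)

    def encode_fragment(self, frag) -> np.ndarray:
        """Pooled u-vector of a single (tokenized or raw) fragment."""
        return self.encode_fragments([frag])[0]

    def encode_fragments(self, frags: list) -> np.ndarray:
        """Pooled u-vectors of a batch of fragments, shape (n, u)."""
        self.model.eval()
        return self.model.pooled(self._ids_for(frags)).data

    def masked_logits(self, ids: np.ndarray) -> np.ndarray:
        self.model.eval()
        return self.model.logits(ids).data

    # -- persistence ------------------------------------------------------
    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        (d / "config.json").write_text(json.dumps(asdict(self.config), indent=1))
        self.vocab.save(d / "vocab.json")
        np.savez(d / "weights.npz", **self.model.state_dict())

    @classmethod
    def load(cls, directory) -> "FragmentEncoder":
        d = Path(directory)
        cfg = EncoderConfig(**json.loads((d / "config.json").read_text()))
        vocab = Vocabulary.load(d / "vocab.json")
        enc = cls(cfg, vocab)
        with np.load(d / "weights.npz") as z:
            enc.model.load_state_dict({k: z[k] for k in z.files})
        return enc

    def checksum(self) -> str:
        h = hashlib.sha256()
        for k, v in sorted(self.model.state_dict().items()):
            h.update(k.encode())
            h.update(np.ascontiguousarray(v).tobytes())
        return h.hexdigest()[:16]


def pretrain_encoder(
    corpus: list[str], vocab: Vocabulary, cfg: EncoderConfig, heldout_fraction: float = 0.1
) -> FragmentEncoder:
    """Pre-train a fragment encoder by dynamic masked-language modelling.

    ``corpus`` is a list of fragments sharing one length (shorter ones are
    assumed already padded).  A trailing slice is held out to verify that
    training actually reduced masked-token cross-entropy.  Fully
    reproducible given ``cfg.seed``.
    """
    if not corpus:
        raise ValueError("empty pre-training corpus")
    lengths = {len(f) for f in corpus}
    if lengths != {cfg.fragment_length}:
        raise ValueError(
            f"all fragments must have length {cfg.fragment_length}, saw lengths {sorted(lengths)}"
        )

    enc = FragmentEncoder(cfg, vocab)
    ids = enc._ids_for(list(corpus))
    n_held = max(1, int(round(len(corpus) * heldout_fraction))) if len(corpus) > 1 else 0
    train_ids = ids[: len(ids) - n_held] if n_held else ids
    held_ids = ids[len(ids) - n_held :] if n_held else ids

    rng = np.random.default_rng(cfg.seed)
    mask_rng = np.random.default_rng(cfg.seed + 1)

    def heldout_loss() -> float:
        # same fixed masking before and after training, so the two
        # cross-entropies are directly comparable
        corrupted, sel = sample_masking_plan(
            held_ids, vocab, cfg.mask_probability, np.random.default_rng(cfg.seed + 2)
        )
        if not sel.any():
            return float("nan")
        enc.model.eval()
        logits = enc.model.logits(corrupted)
        flat = logits.reshape(-1, vocab.size)
        rows = np.flatnonzero(sel.ravel())
        return float(flat[rows].cross_entropy(held_ids.ravel()[rows]).data)

    loss_before = heldout_loss()
    opt = Adam(enc.model.parameters(), lr=cfg.learning_rate, warmup_steps=cfg.warmup_steps)
    drop_rng = np.random.default_rng(cfg.seed + 3)
    for d in [enc.model.drop] + [m for m in enc.model.modules() if isinstance(m, Dropout)]:
        d.reseed(drop_rng)

    enc.model.train()
    n = len(train_ids)
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss, n_batches = 0.0, 0
        for lo in range(0, n, cfg.batch_size):
            batch = train_ids[order[lo : lo + cfg.batch_size]]
            corrupted, sel = sample_masking_plan(batch, vocab, cfg.mask_probability, mask_rng)
            if not sel.any():
                continue
            logits = enc.model.logits(corrupted)
            flat = logits.reshape(-1, vocab.size)
            rows = np.flatnonzero(sel.ravel())
            loss = flat[rows].cross_entropy(batch.ravel()[rows])
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data)
            n_batches += 1
        enc.loss_history.append(epoch_loss / max(1, n_batches))

    enc.model.eval()
    loss_after = heldout_loss()
    enc.heldout_losses = (loss_before, loss_after)
    return enc


def fillmask_topk_precision(
    enc: FragmentEncoder,
    sequences: list[BioSequence],
    k: int,
    K: int = 24,
) -> tuple[dict, float]:
    """Top-k fill-mask precision, per character and overall.

    For every sequence, each position from the second character to the last
    (0-based indices ``1 .. p-1``) is masked one at a time inside its
    enclosing inference fragment, and the encoder predicts the masked
    token.  A prediction is a true positive when the true character is
    among the ``k`` highest-scoring vocabulary tokens.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > enc.vocab.size:
        raise ValueError(f"k={k} exceeds vocabulary size {enc.vocab.size}")
    if not sequences:
        raise ValueError("no sequences given")

    l = enc.config.fragment_length
    tp: dict[str, int] = {}
    fp: dict[str, int] = {}
    for seq in sequences:
        fs = divide_inference_fragments(seq, l, K)
        rows, offsets, chars = [], [], []
        for t in range(1, seq.p):
            # first inference window containing position t; when the K
            # windows stop short of the sequence end ((K-1)*b + l < p),
            # fall back to the terminal window anchored at p - l
            idx = next((i for i, s in enumerate(fs.starts) if s <= t < s + l), None)
            if idx is not None:
                frag, start = fs.fragments[idx], fs.starts[idx]
            else:
                start = max(0, seq.p - l)
                frag = seq.text[start : start + l]
            ids = np.array(tokenize_fragment(frag, enc.vocab).ids, dtype=np.int64)
            off = t - start + 1  # +1 for BOS
            ids[off] = enc.vocab.mask_id
            rows.append(ids)
            offsets.append(off)
            chars.append(seq.text[t])
        logits = enc.masked_logits(np.array(rows))
        for r, (off, c) in enumerate(zip(offsets, chars)):
            scores = logits[r, off]
            topk = np.argsort(-scores, kind="stable")[:k]
            true_id = enc.vocab.char_id(c)
            if true_id in topk:
                tp[c] = tp.get(c, 0) + 1
            else:
                fp[c] = fp.get(c, 0) + 1
    per_char = {
        c: tp.get(c, 0) / (tp.get(c, 0) + fp.get(c, 0))
        for c in set(tp) | set(fp)
    }
    total_tp = sum(tp.values())
    total = total_tp + sum(fp.values())
    return per_char, total_tp / total
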