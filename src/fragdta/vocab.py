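"""Character-level vocabularies and fragment tokenization.

Tokens are single characters plus five specials (BOS/EOS/PAD/MASK/UNK).
Character-level is deliberate: the alphabets here are tiny (a few dozen
SMILES characters, ~20 amino acids), so subword merging buys nothing, and
two-letter element symbols like ``Cl`` are simply two tokens.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .sequences import PAD_CHAR, Alphabet

__all__ = ["SPECIAL_TOKENS", "Vocabulary", "TokenizedFragment", "build_vocabulary", "tokenize_fragment", "detokenize_fragment"]

BOS, EOS, PAD, MASK, UNK = "<s>", "</s>", "<pad>", "<mask>", "<unk>"
SPECIAL_TOKENS = (BOS, EOS, PAD, MASK, UNK)


@dataclass(frozen=True)
class Vocabulary:
    """Bijective map between tokens and consecutive integer ids.

    Special tokens occupy ids 0..4; observed characters follow in
    first-appearance order, making construction deterministic for a given
    corpus ordering.
    """

    token_to_id: dict
    kind: Alphabet

    @property
    def size(self) -> int:
        return len(self.token_to_id)

    @property
    def id_to_token(self) -> dict:
        return {i: t for t, i in self.token_to_id.items()}

    @property
    def bos_id(self) -> int:
        return self.token_to_id[BOS]

    @property
    def eos_id(self) -> int:
        return self.token_to_id[EOS]

    @property
    def pad_id(self) -> int:
        return self.token_to_id[PAD]

    @property
    def mask_id(self) -> int:
        return self.token_to_id[MASK]

    @property
    def unk_id(self) -> int:
        return self.token_to_id[UNK]

    @property
    def special_ids(self) -> frozenset:
        return frozenset(self.token_to_id[t] for t in SPECIAL_TOKENS)

    def char_id(self, c: str) -> int:
        if c == PAD_CHAR:
            return self.pad_id
        return self.token_to_id.get(c, self.unk_id)

    def save(self, path) -> None:
        payload = {"kind": self.kind.value, "token_to_id": self.token_to_id}
        Path(path).write_text(json.dumps(payload, indent=1, ensure_ascii=False))

    @classmethod
    def load(cls, path) -> "Vocabulary":
        payload = json.loads(Path(path).read_text())
        return cls(token_to_id=dict(payload["token_to_id"]), kind=Alphabet(payload["kind"]))


@dataclass(frozen=True)
class TokenizedFragment:
    """Integer ids of one fragment framed by BOS/EOS; length ``l + 2``."""

    ids: tuple[int, ...]
    source_start: int = 0


def build_vocabulary(corpus: Iterable[str], kind: Alphabet) -> Vocabulary:
    """Build a character vocabulary from a stream of strings.

    Ids are assigned deterministically: the five specials first, then each
    distinct character in order of first appearance.
    """
    token_to_id = {t: i for i, t in enumerate(SPECIAL_TOKENS)}
    seen_any = False
    for line in corpus:
        seen_any = True
        for c in line:
            if c == PAD_CHAR:
                continue
            if c not in token_to_id:
                token_to_id[c] = len(token_to_id)
    if not seen_any:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    return Vocabulary(token_to_id=token_to_id, kind=kind)


def tokenize_fragment(frag: str, vocab: Vocabulary, source_start: int = 0) -> TokenizedFragment:
    """Map a fragment to ids, framed by BOS/EOS; unknown characters -> UNK."""
    ids = (vocab.bos_id,) + tuple(vocab.char_id(c) for c in frag) + (vocab.eos_id,)
    return TokenizedFragment(ids=ids, source_start=source_start)


def detokenize_fragment(tok: TokenizedFragment, vocab: Vocabulary) -> str:
    """Inverse of :func:`tokenize_fragment` for in-vocabulary fragments."""
    rev = vocab.id_to_token
    out = []
    for i in tok.ids[1:-1]:
        t = rev[i]
        out.append(PAD_CHAR if t == PAD else t)
    return "".join(out)


def write_corpus(fragments: Iterable[str], path) -> int:
    """Write fragments one per line (pad characters stripped); returns count."""
    n = 0
    with open(path, "w") as fh:
        for f in fragments:
            fh.write(f.rstrip(PAD_CHAR) + "\n")
            n += 1
    return n


def read_corpus(path) -> list[str]:
    """Read a one-fragment-per-line corpus file."""
    with open(path) as fh:
        return [line.rstrip("\n") for line in fh if line.strip()]
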