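"""Fixed-shape fragment-feature matrices.

A drug or target of any length is summarised by a ``u x K`` matrix whose
``k``-th column is the pooled encoder vector of its ``k``-th adaptive
sliding-window fragment.  Because the window count is fixed at ``K``, every
entity yields the same shape regardless of sequence length — this is what
lets a plain 2D CNN consume the result.

Matrices are cached on disk (flat ``.npy`` array plus a JSON sidecar with
shape/dtype and provenance) keyed by encoder checksum, sequence hash, and
the fragmentation parameters, so the supervised stage never re-runs the
encoder.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .fragments import divide_inference_fragments
from .mlm import FragmentEncoder
from .sequences import Alphabet, BioSequence
from .vocab import tokenize_fragment

__all__ = ["FeatureMatrix", "extract_feature_matrix", "FeatureStore"]


@dataclass(frozen=True)
class FeatureMatrix:
    """The ``u x K`` low-level feature matrix of one drug or target."""

    values: np.ndarray
    entity_id: str
    kind: Alphabet

    @property
    def u(self) -> int:
        return self.values.shape[0]

    @property
    def K(self) -> int:
        return self.values.shape[1]


def extract_feature_matrix(
    enc: FragmentEncoder, seq: BioSequence, l: int | None = None, K: int = 24
) -> FeatureMatrix:
    """Encode the ``K`` inference fragments of ``seq`` into a ``u x K`` matrix.

    Columns are pooled fragment vectors in window order.  The encoder and
    the sequence must share an alphabet.
    """
    if enc.vocab.kind != seq.kind:
        raise ValueError(
            f"alphabet mismatch: encoder is {enc.vocab.kind.value}, sequence is {seq.kind.value}"
        )
    if l is None:
        l = enc.config.fragment_length
    fs = divide_inference_fragments(seq, l, K)
    toks = [tokenize_fragment(f, enc.vocab, source_start=s) for f, s in zip(fs.fragments, fs.starts)]
    vecs = enc.encode_fragments(toks)  # (K, u)
    return FeatureMatrix(values=vecs.T.copy(), entity_id=seq.ident, kind=seq.kind)


class FeatureStore:
    """On-disk cache of feature matrices.

    Files are named by a key hashing (encoder checksum, sequence, l, K);
    each entry is a raw ``.npy`` array with a ``.json`` sidecar.
    """

    def __init__(self, directory):
        self.dir = Path(directory)
        self.dir.mkdir(parents=True, exist_ok=True)

    @staticmethod
    def key(enc_checksum: str, seq: BioSequence, l: int, K: int) -> str:
        h = hashlib.sha256()
        h.update(enc_checksum.encode())
        h.update(seq.text.encode())
        h.update(f"|{seq.kind.value}|{l}|{K}".encode())
        return h.hexdigest()[:24]

    def get_or_compute(
        self, enc: FragmentEncoder, seq: BioSequence, l: int | None = None, K: int = 24
    ) -> FeatureMatrix:
        if l is None:
            l = enc.config.fragment_length
        key = self.key(enc.checksum(), seq, l, K)
        npy = self.dir / f"{key}.npy"
        meta = self.dir / f"{key}.json"
        if npy.exists() and meta.exists():
            info = json.loads(meta.read_text())
            values = np.fromfile(npy, dtype=info["dtype"]).reshape(info["shape"])
            return FeatureMatrix(values=values, entity_id=info["entity_id"], kind=Alphabet(info["kind"]))
        fm = extract_feature_matrix(enc, seq, l, K)
        fm.values.tofile(npy)
        meta.write_text(
            json.dumps(
                {
                    "shape": list(fm.values.shape),
                    "dtype": str(fm.values.dtype),
                    "entity_id": fm.entity_id,
                    "kind": fm.kind.value,
                    "l": l,
                    "K": K,
                }
            )
        )
        return fm
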