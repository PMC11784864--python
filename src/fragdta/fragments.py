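"""Fixed-length fragmentation of sequences.

Two modes exist, matching the two stages of the pipeline:

* **training** — a sequence of length ``p`` is cut into ``floor(p / l)``
  non-overlapping windows of length ``l``.  Non-overlap matters during
  masked-language-model pre-training: with overlapping windows the same
  character would be masked in one window yet visible in a neighbour,
  leaking the answer.

* **inference** — an *adaptive sliding window* produces exactly ``K``
  windows for every sequence, regardless of its length, by scaling the
  stride ``b = floor(p / K)`` (clamped to at least 1) with the sequence
  length.  A fixed fragment count is what lets every drug or target be
  summarised by a fixed-shape feature matrix downstream.

Window starts are capped at ``p - l`` so terminal windows slide back over
real characters instead of dangling past the end; windows that still extend
past the end (only possible when ``p < l``) are right-padded.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional

from .sequences import PAD_CHAR, BioSequence

__all__ = [
    "FragmentMode",
    "FragmentSet",
    "divide_training_fragments",
    "compute_offset",
    "divide_inference_fragments",
]


class FragmentMode(str, Enum):
    TRAINING = "training"
    INFERENCE = "inference"


@dataclass(frozen=True)
class FragmentSet:
    """Ordered fixed-length fragments of one sequence.

    ``fragments[i]`` always has length ``fragment_length`` (right-padded with
    the pad character if necessary) and begins at 0-based offset
    ``starts[i]`` in the source text.
    """

    source: BioSequence
    fragment_length: int
    mode: FragmentMode
    fragments: tuple[str, ...]
    starts: tuple[int, ...]
    K: Optional[int] = None

    def __len__(self) -> int:
        return len(self.fragments)

    def __iter__(self):
        return iter(self.fragments)


def _window(text: str, start: int, l: int) -> str:
    piece = text[start : start + l]
    if len(piece) < l:
        piece = piece + PAD_CHAR * (l - len(piece))
    return piece


def divide_training_fragments(seq: BioSequence, l: int) -> FragmentSet:
    """Cut ``seq`` into non-overlapping training fragments of length ``l``.

    Returns ``floor(p / l)`` fragments covering the prefix of length
    ``floor(p / l) * l``; trailing remainder characters are dropped.  A
    sequence shorter than ``l`` yields a single right-padded fragment.
    """
    if l < 1:
        raise ValueError(f"fragment length must be >= 1, got {l}")
    p = seq.p
    if p < l:
        return FragmentSet(
            source=seq,
            fragment_length=l,
            mode=FragmentMode.TRAINING,
            fragments=(_window(seq.text, 0, l),),
            starts=(0,),
        )
    n = p // l
    starts = tuple(k * l for k in range(n))
    frags = tuple(seq.text[s : s + l] for s in starts)
    return FragmentSet(
        source=seq,
        fragment_length=l,
        mode=FragmentMode.TRAINING,
        fragments=frags,
        starts=starts,
    )


def compute_offset(p: int, K: int) -> int:
    """Adaptive sliding-window stride ``b = floor(p / K)``, clamped to >= 1."""
    if K < 1:
        raise ValueError(f"K must be >= 1, got {K}")
    if p < 1:
        raise ValueError(f"sequence length must be >= 1, got {p}")
    return max(1, p // K)


def divide_inference_fragments(seq: BioSequence, l: int, K: int) -> FragmentSet:
    """Divide ``seq`` into exactly ``K`` adaptive, possibly overlapping windows.

    Window ``k`` (0-based) starts at ``min(k * b, max(0, p - l))`` with
    ``b = compute_offset(p, K)``; windows extending past the end are
    right-padded to length ``l``.  Adjacent windows overlap whenever
    ``b < l``, which is the typical regime.
    """
    if l < 1:
        raise ValueError(f"fragment length must be >= 1, got {l}")
    p = seq.p
    b = compute_offset(p, K)
    last = max(0, p - l)
    starts = tuple(min(k * b, last) for k in range(K))
    frags = tuple(_window(seq.text, s, l) for s in starts)
    return FragmentSet(
        source=seq,
        fragment_length=l,
        mode=FragmentMode.INFERENCE,
        fragments=frags,
        starts=starts,
        K=K,
    )
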