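"""Raw biological character sequences: SMILES strings and protein sequences.

Both alphabets are handled uniformly as character sequences; the model never
interprets chemistry or biology at this level, only characters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

#: Character used to right-pad fragments shorter than the fragment length.
#: It gets a dedicated vocabulary token and is never masked during
#: pre-training.
PAD_CHAR = "\x00"


class Alphabet(str, Enum):
    """Which character alphabet a sequence belongs to."""

    DRUG_SMILES = "drug_smiles"
    PROTEIN_SEQ = "protein_seq"


@dataclass(frozen=True)
class BioSequence:
    """A raw character sequence (SMILES or amino acids) with its alphabet kind.

    Parameters
    ----------
    text : str
        The characters. Must be non-empty and contain no whitespace or the
        pad character.
    kind : Alphabet
        Whether this is a drug SMILES or a protein sequence.
    """

    text: str
    kind: Alphabet
    ident: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if not self.text:
            raise ValueError("BioSequence text must be non-empty")
        if any(c.isspace() for c in self.text):
            raise ValueError("BioSequence text must not contain whitespace")
        if PAD_CHAR in self.text:
            raise ValueError("BioSequence text must not contain the pad character")

    def __len__(self) -> int:
        return len(self.text)

    @property
    def p(self) -> int:
        """Sequence length (number of characters)."""
        return len(self.text)
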