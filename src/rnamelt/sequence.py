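"""Validated RNA sequences.

Sequences are stored 5'->3' over {A, C, G, U}.  User-facing coordinates
(reports, text outputs, CT files) are 1-based inclusive; all in-memory
indices in this package are 0-based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

log = logging.getLogger(__name__)

#: default maximum chain length accepted without an explicit override
MAX_LENGTH = 140


class SequenceError(ValueError):
    """Input is not a valid RNA sequence."""


@dataclass(frozen=True)
class RnaSequence:
    """An RNA sequence; construct via :meth:`parse` for normalization."""

    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise SequenceError("empty sequence")
        bad = [(i, c) for i, c in enumerate(self.residues) if c not in "ACGU"]
        if bad:
            i, c = bad[0]
            raise SequenceError(f"non-nucleotide character {c!r} at position {i + 1}")

    @classmethod
    def parse(cls, text: str, max_length: int = MAX_LENGTH) -> "RnaSequence":
        """Normalize raw text: case-fold, T->U (with a note), validate length.

        Lengths above ``max_length`` (default 140 nt) are accepted with a
        warning; ensemble computations grow steeply with chain length.
        """
        seq = "".join(text.split()).upper()
        if "T" in seq:
            log.warning("DNA alphabet detected: converting T -> U")
            seq = seq.replace("T", "U")
        bad = [(i, c) for i, c in enumerate(seq) if c not in "ACGU"]
        if bad:
            i, c = bad[0]
            raise SequenceError(f"non-nucleotide character {c!r} at position {i + 1}")
        if max_length is not None and len(seq) > max_length:
            log.warning(
                "sequence length %d exceeds the recommended maximum %d",
                len(seq), max_length,
            )
        return cls(seq)

    def __len__(self) -> int:
        return len(self.residues)

    def __getitem__(self, i):
        return self.residues[i]

    def __str__(self) -> str:
        return self.residues


__all__ = ["RnaSequence", "SequenceError", "MAX_LENGTH"]
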