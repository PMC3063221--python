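"""Validated RNA sequences with 1-based coordinates.

All interval arithmetic in this package follows the convention used
throughout the recursion literature: positions are 1-based, intervals
``[i, j]`` are inclusive, and an interval of length ``L + 1`` starting at
``x`` is written ``x .. x + L``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

_VALID = frozenset("ACGU")


class SequenceError(ValueError):
    """Raised for sequences containing characters outside A, C, G, U/T."""


@dataclass(frozen=True)
class RnaSequence:
    """An RNA sequence over the alphabet {A, C, G, U}.

    Input is normalised on construction: lowercase is uppercased and
    DNA-style ``T`` is mapped to ``U``.  Any other character raises
    :class:`SequenceError` naming the offending 1-based position.

    Parameters
    ----------
    residues:
        The nucleotide string (at least one residue).
    name:
        Free-text identifier, e.g. the FASTA header.
    """

    residues: str
    name: str = ""

    def __post_init__(self) -> None:
        normalised = self.residues.upper().replace("T", "U")
        if not normalised:
            raise SequenceError(f"empty sequence {self.name!r}")
        for pos, ch in enumerate(normalised, start=1):
            if ch not in _VALID:
                raise SequenceError(
                    f"invalid residue {ch!r} at position {pos}"
                    + (f" in record {self.name!r}" if self.name else "")
                )
        object.__setattr__(self, "residues", normalised)

    @property
    def n(self) -> int:
        return len(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def base(self, i: int) -> str:
        """Residue at 1-based position ``i``."""
        if not 1 <= i <= self.n:
            raise IndexError(f"position {i} outside [1, {self.n}]")
        return self.residues[i - 1]

    def subsequence(self, i: int, j: int, name: str | None = None) -> "RnaSequence":
        """The inclusive 1-based interval ``[i, j]`` as a new sequence."""
        if not (1 <= i <= j <= self.n):
            raise IndexError(f"interval [{i}, {j}] outside [1, {self.n}]")
        return RnaSequence(self.residues[i - 1 : j], name or f"{self.name}[{i}-{j}]")
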