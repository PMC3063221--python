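"""FASTA input and plain-text result tables.

The unpaired-probability table follows the RNAplfold ``_lunp`` dialect:
a comment header, a column-label line, then one row per interval *end*
position ``i`` with one tab-separated column per interval length
``l = 1..u`` — column ``l`` of row ``i`` is the value for the interval
``[i-l+1, i]``, ``NA`` where the interval would start before position 1.
A flag switches the values from probabilities to opening energies
``-RT ln pu`` in kcal/mol.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

from .accessibility import AccessibilityResult
from .mfe_unpaired import MfeStructure
from .sequence import RnaSequence, SequenceError


def read_fasta(path: str | Path) -> list[RnaSequence]:
    """Read a (multi-record) FASTA file into validated RNA sequences.

    ``T`` is mapped to ``U`` and lowercase accepted; IUPAC ambiguity
    codes are rejected with an error naming the record and position.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise SequenceError(f"no FASTA records in {path}")
    return [RnaSequence(str(r.seq), name=r.id) for r in records]


def write_unpaired_table(
    result: AccessibilityResult,
    path: str | Path,
    max_len: int | None = None,
    opening_energies: bool = False,
) -> None:
    """Write the ``_lunp``-style table (or ``-RT ln pu`` energies)."""
    n = result.n
    u = min(max_len or result.max_len, result.max_len)
    RT = result.params.RT
    with open(path, "w") as fh:
        fh.write("#unpaired probabilities\n" if not opening_energies
                 else "#opening energies\n")
        fh.write(" #i$\t" + "\t".join(
            f"l={l}" if l == 1 else str(l) for l in range(1, u + 1)
        ) + "\n")
        for i in range(1, n + 1):
            cells = []
            for l in range(1, u + 1):
                x = i - l + 1
                if x < 1 or math.isnan(result.pu[x, i]):
                    cells.append("NA")
                elif opening_energies:
                    cells.append(f"{-RT * math.log(result.pu[x, i]):.2f}")
                else:
                    cells.append(f"{result.pu[x, i]:.6g}")
            fh.write(f"{i}\t" + "\t".join(cells) + "\n")


def read_unpaired_table(path: str | Path) -> dict[tuple[int, int], float]:
    """Read a table written by :func:`write_unpaired_table`.

    Returns ``{(end, length): value}``.
    """
    out: dict[tuple[int, int], float] = {}
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    for ln in lines[2:]:
        fields = ln.split("\t")
        i = int(fields[0])
        for l, cell in enumerate(fields[1:], start=1):
            if cell != "NA":
                out[(i, l)] = float(cell)
    return out


def write_structures(
    seq: RnaSequence,
    structures: Iterable[MfeStructure],
    path: str | Path,
) -> None:
    """Vienna-style records: header, sequence, dot-bracket ``(energy)``."""
    with open(path, "w") as fh:
        for s in structures:
            x, y = s.unpaired_interval
            fh.write(f">{seq.name or 'seq'} unpaired {x}..{y}\n")
            fh.write(seq.residues + "\n")
            fh.write(f"{s.dot_bracket} ({s.energy:6.2f})\n")
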