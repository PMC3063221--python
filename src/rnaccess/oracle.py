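"""Brute-force ground truth by exhaustive structure enumeration.

This module is the independent test surface for the dynamic programs: it
enumerates every (pseudo)knot-free secondary structure of a short
sequence, evaluates each structure's energy by direct loop decomposition,
and answers ensemble questions (partition functions, pair probabilities,
unpaired-interval probabilities, constrained minima) by explicit
summation.  It shares the energy model with the recursions but none of
their code paths.

The naive constrained-folding route implemented here — restrict the
ensemble to structures with an interval unpaired and divide by the full
partition function — is exactly the quadratic-blowup baseline that the
cubic-time interval algorithm supersedes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import cached_property

import numpy as np

from .energy_model import (
    EnergyParameters,
    hairpin_energy,
    interior_energy,
    multiloop_energy,
    pair_index,
)
from .sequence import RnaSequence

MAX_ENUMERATION_LENGTH = 25


@dataclass(frozen=True)
class EnumeratedStructure:
    """One secondary structure: sorted pair tuple, energy and weight."""

    pairs: tuple[tuple[int, int], ...]
    energy: float
    weight: float


@dataclass
class EnumeratedEnsemble:
    """Every legal structure of a sequence, with Boltzmann weights."""

    seq: RnaSequence
    params: EnergyParameters
    structures: list[EnumeratedStructure]

    @property
    def Z(self) -> float:
        return float(self.weights.sum())

    @cached_property
    def weights(self) -> np.ndarray:
        return np.array([s.weight for s in self.structures])

    @cached_property
    def loop_classes(self) -> list[dict[tuple[int, int], str]]:
        """Per structure: loop class (by child count) of each pair."""
        out = []
        for s in self.structures:
            kids = _children_map(s.pairs)
            out.append({
                pair: ("hairpin" if not k else
                       "interior" if len(k) == 1 else "multiloop")
                for pair, k in kids.items() if pair is not None
            })
        return out

    @cached_property
    def paired(self) -> np.ndarray:
        """Boolean (S, n+1) matrix: column ``i`` true if base ``i`` paired."""
        m = np.zeros((len(self.structures), self.seq.n + 1), dtype=bool)
        for row, s in enumerate(self.structures):
            for i, j in s.pairs:
                m[row, i] = m[row, j] = True
        return m


# -- enumeration ------------------------------------------------------


def _pairable_fn(seq: RnaSequence, allow_all_pairs: bool):
    if allow_all_pairs:
        return lambda i, j: True
    return lambda i, j: pair_index(seq.base(i), seq.base(j)) >= 0


def enumerate_pair_sets(
    seq: RnaSequence,
    min_hairpin_unpaired: int = 3,
    allow_all_pairs: bool = False,
) -> list[tuple[tuple[int, int], ...]]:
    """All non-crossing canonical pair sets with the hairpin minimum.

    Recursive interval enumeration, memoised on the interval: position
    ``i`` is either unpaired or paired with some admissible ``t``, and the
    inside and outside of ``(i, t)`` are enumerated independently.
    """
    if seq.n > MAX_ENUMERATION_LENGTH:
        raise ValueError(
            f"refusing to enumerate n = {seq.n} > {MAX_ENUMERATION_LENGTH}"
        )
    can_pair = _pairable_fn(seq, allow_all_pairs)
    memo: dict[tuple[int, int], list[tuple[tuple[int, int], ...]]] = {}

    def rec(i: int, j: int) -> list[tuple[tuple[int, int], ...]]:
        if j - i < min_hairpin_unpaired + 1:
            return [()]
        key = (i, j)
        if key in memo:
            return memo[key]
        out = list(rec(i + 1, j))
        for t in range(i + min_hairpin_unpaired + 1, j + 1):
            if not can_pair(i, t):
                continue
            for inner in rec(i + 1, t - 1):
                for outer in rec(t + 1, j):
                    out.append(tuple(sorted(((i, t),) + inner + outer)))
        memo[key] = out
        return out

    return rec(1, seq.n)


def _children_map(
    pairs: tuple[tuple[int, int], ...]
) -> dict[tuple[int, int] | None, list[tuple[int, int]]]:
    """Immediate-nesting map; key ``None`` holds the exterior-loop stems."""
    children: dict[tuple[int, int] | None, list[tuple[int, int]]] = {None: []}
    for p in pairs:
        children[p] = []
    for p in pairs:
        parent = None
        for q in pairs:
            if q is p:
                continue
            if q[0] < p[0] and p[1] < q[1]:
                if parent is None or q[0] > parent[0]:
                    parent = q
        children[parent].append(p)
    for v in children.values():
        v.sort()
    return children


def structure_energy(
    seq: RnaSequence,
    pairs: tuple[tuple[int, int], ...],
    p: EnergyParameters,
) -> float:
    """Energy of a structure by direct loop decomposition.

    Each pair closes exactly one loop, classified by its number of
    immediate children: hairpin (0), interior/bulge/stack (1) or
    multiloop (>= 2).  The exterior loop contributes nothing.
    """
    children = _children_map(pairs)
    energy = 0.0
    for key, kids in children.items():
        if key is None:
            continue
        i, j = key
        if not kids:
            energy += hairpin_energy(seq, i, j, p)
        elif len(kids) == 1:
            k, l = kids[0]
            energy += interior_energy(seq, i, j, k, l, p)
        else:
            unpaired = (j - i - 1) - sum(l - k + 1 for k, l in kids)
            energy += multiloop_energy(len(kids), unpaired, p)
    return energy


def enumerate_structures(
    seq: RnaSequence,
    p: EnergyParameters,
    allow_all_pairs: bool = False,
) -> EnumeratedEnsemble:
    """The full ensemble with energies and Boltzmann weights.

    The open chain is always present with weight 1.  Refuses sequences
    longer than :data:`MAX_ENUMERATION_LENGTH`.
    """
    structures = []
    for pairs in enumerate_pair_sets(
        seq, p.min_hairpin_unpaired, allow_all_pairs
    ):
        e = structure_energy(seq, pairs, p)
        structures.append(EnumeratedStructure(pairs, e, p.boltzmann(e)))
    return EnumeratedEnsemble(seq, p, structures)


# -- ensemble queries -------------------------------------------------


def _interval_unpaired_mask(ens: EnumeratedEnsemble, x: int, y: int) -> np.ndarray:
    if not 1 <= x <= y <= ens.seq.n:
        raise IndexError(f"interval [{x}, {y}] outside [1, {ens.seq.n}]")
    return ~ens.paired[:, x : y + 1].any(axis=1)


def brute_accessibility(ens: EnumeratedEnsemble, x: int, L: int) -> float:
    """P(interval ``x .. x+L`` completely unpaired) by explicit summation."""
    mask = _interval_unpaired_mask(ens, x, x + L)
    return float(ens.weights[mask].sum() / ens.Z)


def enclosing_loop_class(
    pairs: tuple[tuple[int, int], ...], x: int, y: int
) -> str:
    """Loop class the unpaired interval ``[x, y]`` lies in.

    ``exterior`` if no pair encloses it, otherwise the class of the loop
    closed by the innermost enclosing pair.
    """
    innermost = None
    for (i, j) in pairs:
        if i < x and y < j and (innermost is None or i > innermost[0]):
            innermost = (i, j)
    if innermost is None:
        return "exterior"
    kids = _children_map(pairs)[innermost]
    if not kids:
        return "hairpin"
    return "interior" if len(kids) == 1 else "multiloop"


def brute_accessibility_by_loop(
    ens: EnumeratedEnsemble, x: int, L: int
) -> dict[str, float]:
    """Split of the unpaired probability by enclosing loop class."""
    mask = _interval_unpaired_mask(ens, x, x + L)
    parts = {"exterior": 0.0, "hairpin": 0.0, "interior": 0.0,
             "multiloop": 0.0}
    y = x + L
    for idx in np.flatnonzero(mask):
        s = ens.structures[idx]
        innermost = None
        for (i, j) in s.pairs:
            if i < x and y < j and (innermost is None or i > innermost[0]):
                innermost = (i, j)
        cls = ("exterior" if innermost is None
               else ens.loop_classes[idx][innermost])
        parts[cls] += s.weight
    return {k: v / ens.Z for k, v in parts.items()}


def brute_pair_probabilities(ens: EnumeratedEnsemble) -> np.ndarray:
    """(n+1, n+1) matrix of P(pair (i, j)); 1-based, zero elsewhere."""
    n = ens.seq.n
    P = np.zeros((n + 1, n + 1))
    for s in ens.structures:
        for i, j in s.pairs:
            P[i, j] += s.weight
    return P / ens.Z


def brute_paired_partition_function(
    seq: RnaSequence, p: EnergyParameters, i: int, j: int
) -> float:
    """Partition function of interval ``[i, j]`` given that ``(i, j)`` pairs.

    Enumerates the subsequence and keeps only the structures containing
    the outermost pair.
    """
    sub = seq.subsequence(i, j)
    ens = enumerate_structures(sub, p)
    m = sub.n
    return float(sum(s.weight for s in ens.structures if (1, m) in s.pairs))


def brute_constrained_mfe(
    ens: EnumeratedEnsemble, x: int, L: int
) -> tuple[float, tuple[tuple[int, int], ...]]:
    """Minimum energy over structures leaving ``x .. x+L`` unpaired.

    The open chain guarantees feasibility.  Ties are broken toward fewer
    pairs, then lexicographically, for determinism.
    """
    mask = _interval_unpaired_mask(ens, x, x + L)
    best = None
    for idx in np.flatnonzero(mask):
        s = ens.structures[idx]
        key = (s.energy, len(s.pairs), s.pairs)
        if best is None or key < best:
            best = key
    assert best is not None
    return best[0], best[2]


# -- independent structure counting -----------------------------------


def count_structures_recurrence(n: int, min_hairpin_unpaired: int = 3) -> int:
    """Number of structures on ``n`` bases when every pair is allowed.

    Independent one-dimensional recurrence (Motzkin-like): position 1 is
    unpaired, or pairs with position ``t`` leaving ``t - 2`` inner and
    ``n - t`` outer bases.  Counts include the open chain.
    """
    f = [1] * (min_hairpin_unpaired + 1)
    for m in range(min_hairpin_unpaired + 1, n + 1):
        total = f[m - 1]
        for t in range(min_hairpin_unpaired + 2, m + 1):
            total += f[t - 2] * f[m - t]
        f.append(total)
    return f[n]


# -- fixtures ---------------------------------------------------------


def random_sequences(
    count: int,
    length_range: tuple[int, int],
    gc_bias: float = 0.5,
    seed: int | None = None,
) -> list[RnaSequence]:
    """Seeded random sequences; ``gc_bias`` is the total G+C probability."""
    if seed is None:
        raise ValueError("a seed is required for reproducible fixtures")
    rng = np.random.default_rng(seed)
    lo, hi = length_range
    probs = [(1 - gc_bias) / 2, gc_bias / 2, gc_bias / 2, (1 - gc_bias) / 2]
    out = []
    for k in range(count):
        n = int(rng.integers(lo, hi + 1))
        bases = rng.choice(list("ACGU"), size=n, p=probs)
        out.append(RnaSequence("".join(bases), name=f"random-{k}"))
    return out
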