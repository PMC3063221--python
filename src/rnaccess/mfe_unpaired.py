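"""Minimum free energy with a forced-unpaired interval, plus backtracking.

The partition-function recursions become their MFE counterparts by
replacing sums with minima and products with energy sums (the min-plus
semiring).  The same recursion code therefore fills, for every interval,
the minimum energy ``f_a(x, x+L)`` over structures that leave the
interval completely unpaired:

* ``F(i, j)`` — MFE of the interval (the min-plus ``Q``),
* ``C(i, j)`` — MFE given ``(i, j)`` pairs (the min-plus ``QB``),
* ``M/M1/M2(i, j)`` — multiloop segment minima,
* ``Cout(i, j)`` — MFE of everything exterior to pair ``(i, j)``,
* ``f_a(x, y)`` — min over the same exterior / hairpin / interior /
  multiloop interval decomposition used for the probabilities.

Backtracking one optimal structure for a given interval re-folds the
sequence with the interval's positions barred from pairing and then
traces the standard recursions.  Energies of backtracked structures are
exact table values; ties are broken by a fixed case order (exterior,
hairpin, interior with lexicographic inner pair, multiloop with the
smallest split), so output is deterministic.

The ``f_a(i, n)`` series doubles as a naive cotranscriptional picture:
the not-yet-transcribed suffix is the forced-unpaired interval, and each
entry is the MFE fold of the transcribed prefix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._core import MIN_PLUS, SequenceModel, UpdateCounts
from .accessibility import PART_NAMES, _assemble_core
from .energy_model import EnergyParameters, interior_energy
from .inside import InsideTables, _fill_inside_core
from .outside import _fill_outside_core, _record_helpers_core
from .sequence import RnaSequence

_EPS = 1e-6  # energy-matching tolerance during backtracking


@dataclass
class MfeTables:
    """Min-plus tables; ``fa``/``parts`` present after mfe_unpaired_all."""

    model: SequenceModel
    F: np.ndarray
    C: np.ndarray
    M: np.ndarray
    M1: np.ndarray
    M2: np.ndarray
    counts: UpdateCounts
    Cout: np.ndarray | None = None
    fa: np.ndarray | None = None
    parts: dict[str, np.ndarray] | None = None

    @property
    def seq(self) -> RnaSequence:
        return self.model.seq

    def mfe(self) -> float:
        """Minimum free energy of the unconstrained ensemble, kcal/mol."""
        return float(self.F[1, self.model.n])

    def f_a(self, x: int, L: int) -> float:
        """Minimum energy with ``x .. x+L`` forced unpaired."""
        if self.fa is None:
            raise RuntimeError("run mfe_unpaired_all first")
        y = x + L
        n = self.model.n
        if not (1 <= x <= y <= n):
            raise IndexError(f"interval [{x}, {y}] outside [1, {n}]")
        return float(self.fa[x, y])


@dataclass(frozen=True)
class MfeStructure:
    """A backtracked structure in dot-bracket notation."""

    dot_bracket: str
    energy: float
    unpaired_interval: tuple[int, int]

    @property
    def pairs(self) -> tuple[tuple[int, int], ...]:
        st, out = [], []
        for pos, ch in enumerate(self.dot_bracket, start=1):
            if ch == "(":
                st.append(pos)
            elif ch == ")":
                out.append((st.pop(), pos))
        return tuple(sorted(out))


def _min_plus_inside(
    seq: RnaSequence,
    p: EnergyParameters,
    force_unpaired: tuple[int, int] | None = None,
    max_pair_span: int | None = None,
) -> InsideTables:
    model = SequenceModel(
        seq, p, MIN_PLUS,
        force_unpaired=force_unpaired, max_pair_span=max_pair_span,
    )
    return _fill_inside_core(model)


def fill_mfe(seq: RnaSequence, p: EnergyParameters) -> MfeTables:
    """Fill the standard MFE matrices F, C and the multiloop minima."""
    t = _min_plus_inside(seq, p)
    return MfeTables(t.model, t.Q, t.QB, t.QM, t.QM1, t.QM2, t.counts)


def mfe_unpaired_all(
    seq: RnaSequence,
    p: EnergyParameters,
    tables: MfeTables | None = None,
    max_len: int | None = None,
) -> MfeTables:
    """``f_a(x, x+L)`` for every interval via the min-plus decomposition."""
    n = seq.n
    if max_len is None or max_len > n:
        max_len = n
    if tables is None:
        tables = fill_mfe(seq, p)

    fa = np.full((n + 2, n + 2), np.nan)
    if n < p.min_hairpin_unpaired + 2:
        for x in range(1, n + 1):
            fa[x, x : min(n, x + max_len - 1) + 1] = 0.0
        tables.fa = fa
        # only the (empty) exterior case exists on unpairable sequences
        tables.parts = {
            k: fa.copy() if k == "exterior" else fa + math.inf
            for k in PART_NAMES
        }
        return tables

    inside = InsideTables(tables.model, tables.F, tables.C, tables.M,
                          tables.M1, tables.M2, tables.counts)
    out = _fill_outside_core(inside)
    _record_helpers_core(inside, out)
    parts, counts = _assemble_core(inside, out, max_len)
    tables.Cout = out.Qout
    tables.parts = parts
    for name in PART_NAMES:
        fa = np.fmin(fa, parts[name]) if name != "exterior" \
            else parts[name].copy()
    tables.fa = fa
    tables.counts = tables.counts.merged(counts)
    return tables


# -- backtracking -----------------------------------------------------


def _close(a: float, b: float) -> bool:
    return abs(a - b) <= _EPS


def _backtrack_pairs(t: InsideTables) -> list[tuple[int, int]]:
    """Trace one optimal structure through the min-plus inside tables."""
    model = t.model
    seq, p, n = model.seq, model.params, model.n
    minh = p.min_hairpin_unpaired
    F, C, M, M1 = t.Q, t.QB, t.QM, t.QM1
    a_e, b_e = model.a, model.b
    c_e = model.params.ml_unpaired_e
    pairs: list[tuple[int, int]] = []
    todo: list[tuple[str, int, int]] = [("F", 1, n)]

    def interior_candidates(i, j):
        for k in range(i + 1, j - minh - 1):
            if k - i - 1 > p.max_interior_span:
                break
            for l in range(k + minh + 1, j):
                if (k - i - 1) + (j - l - 1) > p.max_interior_span:
                    continue
                yield k, l

    while todo:
        tag, i, j = todo.pop()
        if tag == "F":
            while i <= j:
                if _close(F[i, j], F[i + 1, j]):
                    i += 1
                    continue
                for l in range(i + minh + 1, j + 1):
                    if _close(F[i, j], C[i, l] + F[l + 1, j]):
                        todo.append(("C", i, l))
                        i = l + 1
                        break
                else:  # pragma: no cover - defensive
                    raise AssertionError(f"no F case matches at ({i},{j})")
        elif tag == "C":
            pairs.append((i, j))
            v = C[i, j]
            if _close(v, model.HP[i, j]):
                continue
            matched = False
            for k, l in interior_candidates(i, j):
                e = interior_energy(seq, i, j, k, l, p)
                if math.isfinite(e) and _close(v, e + C[k, l]):
                    todo.append(("C", k, l))
                    matched = True
                    break
            if matched:
                continue
            for k in range(i + minh + 3, j - minh - 1):
                if _close(v, a_e + M[i + 1, k - 1] + M1[k, j - 1]):
                    todo.append(("M", i + 1, k - 1))
                    todo.append(("M1", k, j - 1))
                    matched = True
                    break
            if not matched:  # pragma: no cover - defensive
                raise AssertionError(f"no C case matches at ({i},{j})")
        elif tag == "M1":
            for l in range(i + minh + 1, j + 1):
                if _close(M1[i, j], b_e + C[i, l] + c_e * (j - l)):
                    todo.append(("C", i, l))
                    break
            else:  # pragma: no cover - defensive
                raise AssertionError(f"no M1 case matches at ({i},{j})")
        else:  # M
            for k in range(i, j - minh):
                if _close(M[i, j], c_e * (k - i) + M1[k, j]):
                    todo.append(("M1", k, j))
                    break
                if _close(M[i, j], M[i, k - 1] + M1[k, j]):
                    todo.append(("M", i, k - 1))
                    todo.append(("M1", k, j))
                    break
            else:  # pragma: no cover - defensive
                raise AssertionError(f"no M case matches at ({i},{j})")
    return pairs


def _dot_bracket(n: int, pairs: list[tuple[int, int]]) -> str:
    chars = ["."] * n
    for i, j in pairs:
        chars[i - 1] = "("
        chars[j - 1] = ")"
    return "".join(chars)


def backtrack(
    seq: RnaSequence,
    p: EnergyParameters,
    tables: MfeTables,
    x: int,
    L: int,
) -> MfeStructure:
    """One optimal structure leaving ``x .. x+L`` unpaired.

    Re-folds with the interval barred from pairing (which reproduces
    ``f_a(x, x+L)`` exactly) and backtracks; deterministic under the
    fixed tie-break order.
    """
    y = x + L
    n = seq.n
    if not (1 <= x <= y <= n):
        raise IndexError(f"interval [{x}, {y}] outside [1, {n}]")
    t = _min_plus_inside(seq, p, force_unpaired=(x, y))
    pairs = _backtrack_pairs(t)
    return MfeStructure(_dot_bracket(n, pairs), float(t.Q[1, n]), (x, y))


def cotranscriptional_series(
    seq: RnaSequence,
    p: EnergyParameters,
    collapse: bool = True,
) -> list[MfeStructure]:
    """Optimal structures of the growing chain: ``f_a(i, n)`` for all i.

    Entry ``i`` forces the untranscribed suffix ``i .. n`` unpaired, i.e.
    folds the prefix ``1 .. i-1``; the final entry (empty suffix) is the
    full-sequence MFE structure.  With ``collapse`` consecutive duplicate
    structures are dropped.
    """
    n = seq.n
    out: list[MfeStructure] = []
    for i in range(1, n + 2):
        if i - 1 < p.min_hairpin_unpaired + 2:
            s = MfeStructure("." * n, 0.0, (i, n))
        else:
            prefix = seq.subsequence(1, i - 1)
            t = _min_plus_inside(prefix, p)
            pairs = _backtrack_pairs(t)
            s = MfeStructure(
                _dot_bracket(i - 1, pairs) + "." * (n - i + 1),
                float(t.Q[1, i - 1]),
                (i, n),
            )
        if collapse and out and out[-1].dot_bracket == s.dot_bracket:
            continue
        out.append(s)
    return out
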