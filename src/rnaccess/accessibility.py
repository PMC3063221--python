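"""Probabilities that whole intervals are unpaired, for all intervals.

The probability that interval ``[x, y]`` (length ``L + 1 = y - x + 1``)
contains no paired base is

``pu(x, y) = [ Q(1,x-1) Q(y+1,n) + Qub(x, y) ] / Q(1, n)``

where the first product collects the structures in which no pair encloses
the interval, and ``Qub`` sums over enclosing pairs ``(p, q)`` with
``p < x <= y < q``, classified by the loop the interval lies in:

* hairpin — the enclosing pair closes a hairpin loop; summed from the
  ``QH`` helper (``sum_{p < x} QH(p, y)``);
* interior loop — the interval sits on the 5' or the 3' unpaired side of
  an interior loop; summed from the ``QI5``/``QI3`` helpers;
* multiloop — the interval lies inside a multiloop, either before its
  first stem, between stems, or after its last stem.  With the helper
  arrays ``ML2R``/``ML1R``/``MLCR`` (sums over the enclosing pair's end
  ``q``) each case is a single O(n) sum over the start ``p``:

  - 5' of all stems: ``a * sum_p c^(y-p) ML2R(p, y)``,
  - between stems:  ``a c^(L+1) * sum_p QM(p+1, x-1) ML1R(p, y)``,
  - 3' of all stems: ``a c^(L+1) * sum_p QM2(p+1, x-1) MLCR(p, y)``.

The hairpin and interior sums over ``p`` telescope across intervals, so
after an O(n^2) prefix pass they cost O(1) per interval; the multiloop
sums are O(n).  All intervals together are therefore O(n^3) — the same
complexity class as the partition function itself — instead of the
O(n^4) obtained by re-running a per-length algorithm for every length.

The four per-interval parts are exposed; they are nonnegative and sum to
``pu`` exactly, giving e.g. the probability that an interval is unpaired
*and* inside a hairpin loop.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from ._core import Algebra, SequenceModel, UpdateCounts
from .energy_model import EnergyParameters
from .inside import InsideTables, fill_inside
from .outside import OutsideTables, fill_outside, record_accessibility_helpers
from .sequence import RnaSequence

PART_NAMES = ("exterior", "hairpin", "interior", "multiloop")


@dataclass
class AccessibilityResult:
    """Unpaired-interval probabilities with loop-type decomposition.

    ``pu[x, y]`` is indexed by 1-based start/end (inclusive); entries for
    intervals longer than ``max_len`` are NaN.  ``parts`` holds the four
    nonnegative components (exterior, hairpin, interior, multiloop) that
    sum to ``pu``.
    """

    seq: RnaSequence
    params: EnergyParameters
    pu: np.ndarray
    parts: dict[str, np.ndarray]
    max_len: int
    counts: UpdateCounts

    @property
    def n(self) -> int:
        return self.seq.n

    def probability(self, x: int, L: int) -> float:
        """``pu`` for the interval ``x .. x+L``."""
        y = x + L
        if not (1 <= x <= y <= self.n):
            raise IndexError(f"interval [{x}, {y}] outside [1, {self.n}]")
        v = float(self.pu[x, y])
        if math.isnan(v):
            raise ValueError(
                f"interval length {L + 1} exceeds max_len={self.max_len}"
            )
        return v

    def opening_energy(self, x: int, L: int) -> float:
        """``dG_open = -RT ln pu`` for the interval ``x .. x+L``."""
        return -self.params.RT * math.log(self.probability(x, L))


def _suffix(alg: Algebra, A: np.ndarray) -> np.ndarray:
    """``S[:, y] = reduce over columns y+1.. of A`` (strict suffix)."""
    S = np.full_like(A, alg.zero)
    for y in range(A.shape[1] - 2, -1, -1):
        S[:, y] = alg.add(S[:, y + 1], A[:, y + 1])
    return S


def _assemble_core(
    inside: InsideTables,
    out: OutsideTables,
    max_len: int,
) -> tuple[dict[str, np.ndarray], UpdateCounts]:
    """Per-interval parts in the model's weight domain, unnormalised."""
    model = inside.model
    alg, n = model.alg, model.n
    counts = UpdateCounts()
    Q, QM, QM2 = inside.Q, inside.QM, inside.QM2
    cpow, spow = model.cpow, model.spow

    # O(1)-per-interval lookups for the hairpin and interior cases
    CH = alg.accumulate(out.QH, axis=0)
    CI5 = alg.accumulate(_suffix(alg, out.QI5), axis=0)
    CI3 = alg.accumulate(_suffix(alg, out.QI3), axis=0)
    counts.cubic += 5 * n * n

    parts = {name: np.full((n + 2, n + 2), np.nan) for name in PART_NAMES}
    for x in range(1, n + 1):
        for y in range(x, min(n, x + max_len - 1) + 1):
            L1 = y - x + 1
            parts["exterior"][x, y] = alg.mul(
                alg.mul(Q[1, x - 1], Q[y + 1, n]), spow[L1]
            )
            parts["hairpin"][x, y] = CH[x - 1, y]
            parts["interior"][x, y] = alg.add(CI5[x - 1, y], CI3[x - 1, y])

            ml = alg.zero
            if x >= 2:
                # interval 5' of every stem
                ml = alg.reduce(alg.mul(
                    cpow[y - 1 : y - x : -1], out.ML2R[1:x, y]
                ))
                counts.cubic += x - 1
            if x >= 3:
                between = alg.reduce(alg.mul(
                    QM[2:x, x - 1], out.ML1R[1 : x - 1, y]
                ))
                after = alg.reduce(alg.mul(
                    QM2[2:x, x - 1], out.MLCR[1 : x - 1, y]
                ))
                ml = alg.add(ml, alg.mul(cpow[L1], alg.add(between, after)))
                counts.cubic += 2 * (x - 2)
            parts["multiloop"][x, y] = alg.mul(model.a, ml)
    return parts, counts


def accessibility_all(
    seq: RnaSequence,
    p: EnergyParameters,
    inside: InsideTables | None = None,
    outside: OutsideTables | None = None,
    max_len: int | None = None,
    *,
    scale: float = 1.0,
) -> AccessibilityResult:
    """``pu(x, x+L)`` for every interval, with loop-type decomposition.

    ``inside``/``outside`` may be passed to reuse filled tables (the
    outside tables must include the accessibility helpers); by default
    everything is computed here.  ``max_len`` caps the interval length
    (default: all lengths).  Sequences too short to form any pair are
    answered directly with ``pu = 1``.
    """
    n = seq.n
    if max_len is None:
        max_len = n
    if max_len > n:
        warnings.warn(f"max_len={max_len} clipped to sequence length {n}")
        max_len = n
    if max_len < 1:
        raise ValueError("max_len must be >= 1")

    if n < p.min_hairpin_unpaired + 2:
        # no pair is formable: every interval is unpaired with certainty
        pu = np.full((n + 2, n + 2), np.nan)
        parts = {k: np.full((n + 2, n + 2), np.nan) for k in PART_NAMES}
        for x in range(1, n + 1):
            for y in range(x, min(n, x + max_len - 1) + 1):
                pu[x, y] = 1.0
                parts["exterior"][x, y] = 1.0
                for k in PART_NAMES[1:]:
                    parts[k][x, y] = 0.0
        return AccessibilityResult(seq, p, pu, parts, max_len, UpdateCounts())

    if inside is None:
        inside = fill_inside(seq, p, scale=scale)
    if outside is None:
        outside = fill_outside(seq, p, inside)
        record_accessibility_helpers(seq, p, inside, outside)
    if not outside.has_helpers:
        raise RuntimeError(
            "outside tables lack accessibility helpers; call "
            "record_accessibility_helpers first"
        )

    parts, counts = _assemble_core(inside, outside, max_len)
    Z = inside.total
    for name in PART_NAMES:
        parts[name] = parts[name] / Z
    pu = sum(parts.values())
    counts = counts.merged(outside.helper_counts)
    return AccessibilityResult(seq, p, pu, parts, max_len, counts)


def loop_type_decomposition(
    result: AccessibilityResult, x: int, L: int
) -> tuple[float, float, float, float]:
    """The (exterior, hairpin, interior, multiloop) parts of ``pu(x, x+L)``.

    Each part is the probability that the interval is unpaired *and* lies
    in the given loop context; the four sum to ``pu``.
    """
    y = x + L
    if not (1 <= x <= y <= result.n):
        raise IndexError(f"interval [{x}, {y}] outside [1, {result.n}]")
    return tuple(float(result.parts[k][x, y]) for k in PART_NAMES)


def opening_energies(
    result: AccessibilityResult, p: EnergyParameters
) -> np.ndarray:
    """``dG_open(x, y) = -RT ln pu(x, y)`` in kcal/mol (NaN where unset).

    Always nonnegative, zero exactly where ``pu = 1``; never infinite
    because the open chain gives every interval positive probability.
    """
    with np.errstate(invalid="ignore", divide="ignore"):
        return -p.RT * np.log(result.pu)
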