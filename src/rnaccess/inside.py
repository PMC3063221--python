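"""Forward (inside) recursion of the partition function.

Fills the triangular tables by increasing interval span:

* ``Q(i, j)`` — partition function of interval ``[i, j]``; ``Q(a, b) = 1``
  for ``a >= b``.  Decomposed by whether ``i`` is unpaired or pairs some
  ``l``: ``Q(i,j) = Q(i+1,j) + sum_l QB(i,l) Q(l+1,j)``.
* ``QB(i, j)`` — partition function given ``(i, j)`` paired.  The pair
  closes a hairpin loop, an interior loop (stacks and bulges included,
  size-capped), or a multiloop:
  ``QB = hp(i,j) + sum_{k,l} il(i,j,k,l) QB(k,l)
  + a sum_k QM(i+1,k-1) QM1(k,j-1)``.
* ``QM1(i, j)`` — multiloop segment with exactly one stem whose 5' base is
  ``i``: ``QM1(i,j) = sum_l b QB(i,l) c^(j-l)``.
* ``QM(i, j)`` — multiloop segment with at least one stem, decomposed
  unambiguously by the start ``k`` of its last stem:
  ``QM(i,j) = sum_k (c^(k-i) + QM(i,k-1)) QM1(k,j)``.
* ``QM2(i, j)`` — at least two stems: ``sum_k QM(i,k-1) QM1(k,j)``.

The decomposition counts every structure exactly once.  The same code
runs in the min-plus semiring to fill the MFE matrices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._core import MIN_PLUS, SUM_PRODUCT, Algebra, SequenceModel, UpdateCounts
from .energy_model import EnergyParameters
from .sequence import RnaSequence


@dataclass
class InsideTables:
    """Inside partition-function tables (1-based, upper-triangular)."""

    model: SequenceModel
    Q: np.ndarray
    QB: np.ndarray
    QM: np.ndarray
    QM1: np.ndarray
    QM2: np.ndarray
    counts: UpdateCounts

    @property
    def seq(self) -> RnaSequence:
        return self.model.seq

    @property
    def params(self) -> EnergyParameters:
        return self.model.params

    @property
    def total(self) -> float:
        """``Q(1, n)`` in the model's (possibly rescaled) domain."""
        return float(self.Q[1, self.model.n])


def _fill_inside_core(model: SequenceModel) -> InsideTables:
    alg, n = model.alg, model.n
    counts = UpdateCounts()
    minh = model.params.min_hairpin_unpaired

    Q = model.zeros()
    QB = model.zeros()
    QM = model.zeros()
    QM1 = model.zeros()
    QM2 = model.zeros()
    # empty intervals: Q(a, b) = semiring one for a > b
    a_idx = np.arange(n + 2)
    Q[a_idx[:, None] > a_idx[None, :]] = alg.one

    cpow = model.cpow
    # overflow (and the inf*0 it induces) is detected after the fill
    err = np.errstate(over="ignore", invalid="ignore")
    err.__enter__()
    for span in range(0, n):
        for i in range(1, n - span + 1):
            j = i + span

            if model.pairable[i, j]:
                v = model.HP[i, j]
                m = model.inner_kernel_size(span)
                if m > 1:
                    k_idx = i + 1 + model.kern_dk[1:m]
                    l_idx = j - 1 - model.kern_dl[1:m]
                    v = alg.add(v, alg.reduce(
                        alg.mul(model.kern[1:m], QB[k_idx, l_idx])
                    ))
                    counts.capped += m - 1
                if span >= 2:
                    stack = model.stack_w[
                        model.ptype[i, j], model.ptype_rev[i + 1, j - 1]
                    ]
                    v = alg.add(v, alg.mul(stack, QB[i + 1, j - 1]))
                    counts.capped += 1
                # multiloop closing: k is the start of the last stem
                if j - minh - 1 >= i + minh + 3:
                    ks = np.arange(i + minh + 3, j - minh - 1)
                    ml = alg.reduce(
                        alg.mul(QM[i + 1, ks - 1], QM1[ks, j - 1])
                    )
                    v = alg.add(v, alg.mul(model.a, ml))
                    counts.cubic += len(ks)
                QB[i, j] = v

            if span >= minh + 1:
                # QM1: i pairs some l, trailing bases unpaired
                ls = np.arange(i + minh + 1, j + 1)
                QM1[i, j] = alg.mul(model.b, alg.reduce(
                    alg.mul(QB[i, ls], cpow[j - ls])
                ))
                # QM / QM2 by the start k of the last stem
                ks = np.arange(i, j - minh)
                before = alg.add(cpow[ks - i], QM[i, ks - 1])
                stems = QM1[ks, j]
                QM[i, j] = alg.reduce(alg.mul(before, stems))
                QM2[i, j] = alg.reduce(alg.mul(QM[i, ks - 1], stems))
                counts.cubic += 3 * len(ks) + len(ls)

            # Q: i unpaired, or i pairs l
            v = alg.mul(model.unp, Q[i + 1, j])
            if span >= minh + 1:
                ls = np.arange(i + minh + 1, j + 1)
                v = alg.add(v, alg.reduce(
                    alg.mul(QB[i, ls], Q[ls + 1, j])
                ))
                counts.cubic += len(ls)
            Q[i, j] = v

    err.__exit__(None, None, None)
    return InsideTables(model, Q, QB, QM, QM1, QM2, counts)


def fill_inside(
    seq: RnaSequence,
    p: EnergyParameters,
    *,
    scale: float = 1.0,
    allow_all_pairs: bool = False,
    max_pair_span: int | None = None,
) -> InsideTables:
    """Fill the inside tables for ``seq`` under parameters ``p``.

    Raises ``FloatingPointError`` if any entry overflows double range;
    pass ``scale > 1`` (per-nucleotide rescaling) for long sequences.
    ``allow_all_pairs`` admits every pair (structure counting);
    ``max_pair_span`` restricts pair spans (local folding).
    """
    model = SequenceModel(
        seq, p, SUM_PRODUCT,
        scale=scale, allow_all_pairs=allow_all_pairs,
        max_pair_span=max_pair_span,
    )
    tables = _fill_inside_core(model)
    if not np.isfinite(tables.Q[1:, 1:]).all():
        raise FloatingPointError(
            "partition function overflowed double precision; rerun with a "
            "per-nucleotide scaling factor (scale > 1)"
        )
    return tables


def ensemble_free_energy(t: InsideTables, p: EnergyParameters) -> float:
    """Free energy of the full ensemble, ``-RT ln Q(1, n)`` in kcal/mol.

    Undoes any per-nucleotide rescaling.  Always <= the minimum free
    energy of any single structure.
    """
    if t.model.alg.tropical:
        raise ValueError("ensemble free energy is defined for the "
                         "sum-product tables")
    return -p.RT * (math.log(t.total) + t.model.n * math.log(t.model.scale))
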