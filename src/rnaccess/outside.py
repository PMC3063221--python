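"""Backward (outside) recursion: pair probabilities and helper arrays.

For every pairable ``(i, j)`` the outer partition function ``Qout(i, j)``
sums the Boltzmann weights of everything exterior to the pair, so that
``p(i, j) = Qout(i, j) * QB(i, j) / Q(1, n)``.  Entries are filled by
decreasing span:

* trivial case — nothing encloses ``(i, j)``:
  ``Q(1, i-1) * Q(j+1, n)``;
* interior loop — an enclosing pair ``(k, l)`` forms a (size-capped)
  interior loop with ``(i, j)``: ``sum Qout(k,l) il(k,l,i,j)``;
* multiloop — ``(i, j)`` is a stem of a multiloop closed by ``(k, l)``,
  with at least one further stem to its left, right, or both.

The multiloop double sum over ``(k, l)`` is kept linear per entry with
two auxiliary arrays, updated incrementally as outer entries become
available:

* ``OMa(k, y) = sum_{l > y} Qout(k,l) a b c^(l-1-y)``
  (closing pair starts at ``k``; everything right of the stem unpaired),
* ``OMb(x, l) = sum_{k < x} Qout(k,l) a b (QM(k+1,x-1) + c^(x-1-k))``
  (closing pair ends at ``l``; stems or unpaired left of the stem),

so that the multiloop part of ``Qout(i, j)`` is
``sum_l OMb(i,l) QM(j+1,l-1) + sum_k QM(k+1,i-1) OMa(k,j)``.
Each ``Qout`` entry feeds both arrays in O(n), which keeps the whole
backward pass cubic.

:func:`record_accessibility_helpers` stores the by-products the interval
algorithm needs: the hairpin array ``QH``, the interior-loop side arrays
``QI5``/``QI3``, and three multiloop arrays over enclosing-pair start
positions.  All are assembled from quantities this pass computes anyway.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._core import SUM_PRODUCT, SequenceModel, UpdateCounts
from .energy_model import EnergyParameters
from .inside import InsideTables, fill_inside
from .sequence import RnaSequence


@dataclass
class OutsideTables:
    """Outside tables, pair probabilities and accessibility helpers."""

    model: SequenceModel
    Qout: np.ndarray            #: outer partition function of pair (i, j)
    P: np.ndarray | None        #: pair probabilities (sum-product only)
    OMa: np.ndarray             #: multiloop aux, right side unpaired
    OMb: np.ndarray             #: multiloop aux, left side stems/unpaired
    counts: UpdateCounts
    # accessibility helpers, present after record_accessibility_helpers()
    QH: np.ndarray | None = None    #: QH(i, y): hairpin pairs (i, j>y)
    QI5: np.ndarray | None = None   #: QI5(i, k): i..k is a 5' loop side
    QI3: np.ndarray | None = None   #: QI3(l, j): l..j is a 3' loop side
    ML2R: np.ndarray | None = None  #: sum_q Qout(p,q) QM2(y+1, q-1)
    ML1R: np.ndarray | None = None  #: sum_q Qout(p,q) QM(y+1, q-1)
    MLCR: np.ndarray | None = None  #: sum_q Qout(p,q) c^(q-1-y)
    helper_counts: UpdateCounts = field(default_factory=UpdateCounts)

    @property
    def has_helpers(self) -> bool:
        return self.QH is not None


def _fill_outside_core(inside: InsideTables) -> OutsideTables:
    model = inside.model
    alg, n = model.alg, model.n
    counts = UpdateCounts()
    minh = model.params.min_hairpin_unpaired
    Q, QB, QM = inside.Q, inside.QB, inside.QM

    Qout = model.zeros()
    OMa = model.zeros()
    OMb = model.zeros()
    ab = alg.mul(model.a, model.b)
    cpow = model.cpow
    kern, kdk, kdl = model.kern, model.kern_dk, model.kern_dl

    for span in range(n - 1, minh, -1):
        for i in range(1, n - span + 1):
            j = i + span
            if not model.pairable[i, j]:
                continue
            # no enclosing pair
            v = alg.mul(Q[1, i - 1], Q[j + 1, n])
            # enclosing interior loop: (k, l) = (i-1-dk, j+1+dl)
            k_idx = np.clip(i - 1 - kdk[1:], 0, n + 1)
            l_idx = np.clip(j + 1 + kdl[1:], 0, n + 1)
            v = alg.add(v, alg.reduce(
                alg.mul(kern[1:], Qout[k_idx, l_idx])
            ))
            counts.capped += len(k_idx)
            if i > 1 and j < n:
                stack = model.stack_w[
                    model.ptype[i - 1, j + 1], model.ptype_rev[i, j]
                ]
                v = alg.add(v, alg.mul(stack, Qout[i - 1, j + 1]))
                counts.capped += 1
            # multiloop: stems to the right of (i, j) ...
            if j + 2 <= n:
                ls = np.arange(j + 2, n + 1)
                v = alg.add(v, alg.reduce(
                    alg.mul(OMb[i, ls], QM[j + 1, ls - 1])
                ))
                counts.cubic += len(ls)
            # ... or only unpaired bases to the right
            if i >= 2:
                ks = np.arange(1, i)
                v = alg.add(v, alg.reduce(
                    alg.mul(QM[ks + 1, i - 1], OMa[ks, j])
                ))
                counts.cubic += len(ks)
            Qout[i, j] = v

        # fold this span's entries into the auxiliary arrays; inner pairs
        # have span smaller by >= 2, so they see a complete picture
        for i in range(1, n - span + 1):
            j = i + span
            if Qout[i, j] == alg.zero:
                continue
            w = alg.mul(Qout[i, j], ab)
            inner = np.arange(i + 1, j)
            OMa[i, inner] = alg.add(
                OMa[i, inner], alg.mul(w, cpow[j - 1 - inner])
            )
            OMb[inner, j] = alg.add(
                OMb[inner, j],
                alg.mul(w, alg.add(QM[i + 1, inner - 1], cpow[inner - i - 1])),
            )
            counts.cubic += 2 * len(inner)

    P = None
    if not alg.tropical:
        P = Qout * QB / inside.total
    return OutsideTables(model, Qout, P, OMa, OMb, counts)


def fill_outside(
    seq: RnaSequence,
    p: EnergyParameters,
    inside: InsideTables | None = None,
    **fill_kwargs,
) -> OutsideTables:
    """Fill the outside tables and the pair-probability matrix.

    ``inside`` may be passed to reuse already-filled forward tables;
    otherwise they are computed here (``fill_kwargs`` are forwarded to
    :func:`rnaccess.inside.fill_inside`).
    """
    if inside is None:
        inside = fill_inside(seq, p, **fill_kwargs)
    return _fill_outside_core(inside)


def _record_helpers_core(
    inside: InsideTables, out: OutsideTables
) -> OutsideTables:
    model = inside.model
    alg, n = model.alg, model.n
    counts = out.helper_counts
    QB, QM, QM2 = inside.QB, inside.QM, inside.QM2
    Qout = out.Qout
    cpow = model.cpow
    kern, kdk, kdl = model.kern, model.kern_dk, model.kern_dl

    # hairpin: QH(i, y) = sum_{j > y} Qout(i, j) hp(i, j), by recursion
    QH = model.zeros()
    for y in range(n - 1, 0, -1):
        QH[:, y] = alg.add(
            QH[:, y + 1], alg.mul(Qout[:, y + 1], model.HP[:, y + 1])
        )
        counts.cubic += n

    # interior-loop sides: for every inner pair (k, l) and capped offsets,
    # credit the 5' side to QI5(i, k) and the 3' side to QI3(l, j)
    QI5 = model.zeros()
    QI3 = model.zeros()
    for k in range(1, n + 1):
        for l in range(k + 4, n + 1):
            if not model.pairable[k, l] or QB[k, l] == alg.zero:
                continue
            i_idx = np.clip(k - 1 - kdk[1:], 0, n + 1)
            j_idx = np.clip(l + 1 + kdl[1:], 0, n + 1)
            vals = alg.mul(alg.mul(kern[1:], Qout[i_idx, j_idx]), QB[k, l])
            alg.scatter(QI5[:, k], i_idx, vals)
            alg.scatter(QI3[l, :], j_idx, vals)
            counts.capped += 2 * len(vals)
            if k > 1 and l < n:
                stack = model.stack_w[
                    model.ptype[k - 1, l + 1], model.ptype_rev[k, l]
                ]
                sval = alg.mul(alg.mul(stack, Qout[k - 1, l + 1]), QB[k, l])
                QI5[k - 1, k] = alg.add(QI5[k - 1, k], sval)
                QI3[l, l + 1] = alg.add(QI3[l, l + 1], sval)
                counts.capped += 2

    # multiloop helpers over enclosing-pair start positions p:
    #   ML2R(p, y): >= 2 stems right of y inside (p, q)
    #   ML1R(p, y): >= 1 stem  right of y inside (p, q)
    #   MLCR(p, y): everything right of y inside (p, q) unpaired
    ML2R = model.zeros()
    ML1R = model.zeros()
    MLCR = model.zeros()
    for y in range(1, n):
        qs = np.arange(y + 2, n + 1)
        if len(qs):
            qm_row = QM[y + 1, qs - 1]
            qm2_row = QM2[y + 1, qs - 1]
            block = Qout[1 : y + 1, qs]
            ML1R[1 : y + 1, y] = alg.matvec(block, qm_row)
            ML2R[1 : y + 1, y] = alg.matvec(block, qm2_row)
            counts.cubic += 2 * block.size
    for y in range(n - 1, 0, -1):
        MLCR[:, y] = alg.add(
            alg.mul(cpow[1], MLCR[:, y + 1]), Qout[:, y + 1]
        )
        counts.cubic += n

    out.QH, out.QI5, out.QI3 = QH, QI5, QI3
    out.ML2R, out.ML1R, out.MLCR = ML2R, ML1R, MLCR
    return out


def record_accessibility_helpers(
    seq: RnaSequence,
    p: EnergyParameters,
    inside: InsideTables,
    out: OutsideTables,
) -> OutsideTables:
    """Record the helper arrays the interval algorithm consumes.

    Must run after :func:`fill_outside`; raises ``RuntimeError`` on an
    unfilled outside object.
    """
    if out is None or out.Qout is None:
        raise RuntimeError("record_accessibility_helpers requires filled "
                           "outside tables")
    return _record_helpers_core(inside, out)


def write_pair_probabilities(
    out: OutsideTables, path, threshold: float = 1e-6
) -> None:
    """Dump ``i j p`` rows (tab-separated, 1-based) with ``p >= threshold``."""
    if out.P is None:
        raise ValueError("pair probabilities only exist for the "
                         "sum-product tables")
    n = out.model.n
    with open(path, "w") as fh:
        fh.write("# i\tj\tprob\n")
        for i in range(1, n + 1):
            for j in range(i + 1, n + 1):
                if out.P[i, j] >= threshold:
                    fh.write(f"{i}\t{j}\t{out.P[i, j]:.6e}\n")
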