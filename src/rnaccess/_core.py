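"""Shared machinery for the dynamic-programming recursions.

The forward/backward partition-function recursions and their minimum-free-
energy counterparts have identical decompositions; they differ only in the
algebra: sum/product over Boltzmann weights versus min/plus over energies.
Both are expressed here over a small semiring abstraction so the recursion
bodies are written exactly once.

:class:`SequenceModel` precomputes, for one sequence and parameter set,
everything the recursions index repeatedly: pair types, the hairpin weight
matrix, the capped interior-loop kernel (a flat list of (5' size, 3' size)
offsets with their size/asymmetry weights; the size cap is what keeps all
algorithms cubic), multiloop scalars, and optional per-nucleotide scaling
for long sequences in the sum-product domain.

Update counting: every recursion tallies its work into
:class:`UpdateCounts`.  ``cubic`` counts updates in loops whose trip count
grows with the sequence length; ``capped`` counts updates in the
constant-bounded interior-loop kernels (at most a few hundred per cell
regardless of n).  The cubic counter is the quantity whose growth
demonstrates the O(n^3) behaviour.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .energy_model import EnergyParameters, pair_index
from .sequence import RnaSequence


class Algebra:
    """A commutative semiring over floats: sum-product or min-plus."""

    def __init__(self, tropical: bool):
        self.tropical = tropical
        self.zero = math.inf if tropical else 0.0
        self.one = 0.0 if tropical else 1.0

    def add(self, x, y):
        return np.minimum(x, y) if self.tropical else np.add(x, y)

    def mul(self, x, y):
        return np.add(x, y) if self.tropical else np.multiply(x, y)

    def reduce(self, a):
        a = np.asarray(a)
        if a.size == 0:
            return self.zero
        return float(np.min(a)) if self.tropical else float(np.sum(a))

    def accumulate(self, a, axis):
        if self.tropical:
            return np.minimum.accumulate(a, axis=axis)
        return np.cumsum(a, axis=axis)

    def scatter(self, target, idx, vals):
        """``target[idx] (+)= vals`` in the semiring."""
        if self.tropical:
            np.minimum.at(target, idx, vals)
        else:
            np.add.at(target, idx, vals)

    def matvec(self, block, vec):
        """Row-wise semiring dot products of ``block`` with ``vec``."""
        if block.size == 0:
            return np.full(block.shape[0], self.zero)
        if self.tropical:
            return np.min(block + vec[None, :], axis=1)
        return block @ vec

    def from_energy(self, energy, RT: float):
        """Map kcal/mol energies into the semiring's weight domain."""
        if self.tropical:
            return np.asarray(energy, dtype=float)
        return np.exp(-np.asarray(energy, dtype=float) / RT)


SUM_PRODUCT = Algebra(tropical=False)
MIN_PLUS = Algebra(tropical=True)

_NO_PAIR = 6  # sentinel pair-type index; row/col 6 of stack_w is semiring zero


@dataclass
class UpdateCounts:
    """Tally of elementary DP updates, split by loop-length behaviour."""

    cubic: int = 0
    capped: int = 0

    @property
    def total(self) -> int:
        return self.cubic + self.capped

    def merged(self, other: "UpdateCounts") -> "UpdateCounts":
        return UpdateCounts(self.cubic + other.cubic,
                            self.capped + other.capped)


class SequenceModel:
    """Per-sequence precomputation for one algebra.

    Parameters
    ----------
    allow_all_pairs:
        Treat every ``(i, j)`` with a legal hairpin gap as pairable.  Used
        by the structure-counting cross-checks, where the partition
        function with all-zero energies counts structures.
    max_pair_span:
        Restrict pairs to ``j - i <= max_pair_span`` (the local-folding
        constraint of the sliding-window mode).
    scale:
        Per-nucleotide rescaling factor for the sum-product domain: every
        elementary weight is multiplied by ``scale**(-m)`` where ``m`` is
        the number of positions it accounts for, so that table entries
        stay within double range on long sequences.  1.0 disables it.
    """

    def __init__(
        self,
        seq: RnaSequence,
        params: EnergyParameters,
        algebra: Algebra = SUM_PRODUCT,
        *,
        scale: float = 1.0,
        allow_all_pairs: bool = False,
        max_pair_span: int | None = None,
        force_unpaired: tuple[int, int] | None = None,
    ):
        if scale <= 0:
            raise ValueError("scale must be positive")
        self.seq = seq
        self.params = params
        self.alg = algebra
        self.scale = scale
        n = self.n = seq.n
        p = params
        alg = algebra
        RT = p.RT

        # pair-type matrices, 1-based; value 6 = not a canonical pair
        ptype = np.full((n + 2, n + 2), _NO_PAIR, dtype=np.int8)
        ptype_rev = np.full((n + 2, n + 2), _NO_PAIR, dtype=np.int8)
        for i in range(1, n + 1):
            for j in range(i + 1, n + 1):
                t = pair_index(seq.base(i), seq.base(j))
                ptype[i, j] = t if t >= 0 else _NO_PAIR
                t = pair_index(seq.base(j), seq.base(i))
                ptype_rev[i, j] = t if t >= 0 else _NO_PAIR
        self.ptype = ptype
        self.ptype_rev = ptype_rev

        ii = np.arange(n + 2)[:, None]
        jj = np.arange(n + 2)[None, :]
        span_ok = (jj - ii - 1) >= p.min_hairpin_unpaired
        if max_pair_span is not None:
            span_ok &= (jj - ii) <= max_pair_span
        if allow_all_pairs:
            self.pairable = (ii < jj) & (ii >= 1) & (jj <= n) & span_ok
        else:
            self.pairable = (ptype != _NO_PAIR) & span_ok
        if force_unpaired is not None:
            x, y = force_unpaired
            banned = ((ii >= x) & (ii <= y)) | ((jj >= x) & (jj <= y))
            self.pairable = self.pairable & ~banned

        # scaling helpers (sum-product only; min-plus adds zeros)
        npow = max(n, p.max_interior_span) + 3
        if alg.tropical:
            self.spow = np.zeros(npow)
        else:
            self.spow = scale ** -np.arange(npow, dtype=float)

        # hairpin weight matrix
        hsize = np.full(n + 1, math.inf)
        for s in range(p.min_hairpin_unpaired, n + 1):
            hsize[s] = p.hairpin_size_energy(s)
        sizes = np.clip(jj - ii - 1, 0, n)
        HP = alg.from_energy(hsize[sizes], RT)
        if not alg.tropical:
            HP = HP * self.spow[np.clip(jj - ii + 1, 0, n + 2)]
        HP[~self.pairable] = alg.zero
        self.HP = HP

        # capped interior-loop kernel, flattened and sorted by total size.
        # Entry 0 (the stack) is a placeholder at semiring zero; stacks are
        # sequence-dependent and handled through stack_w.
        cap = p.max_interior_span
        dks, dls, energies = [], [], []
        for total in range(cap + 1):
            for dk in range(total + 1):
                dl = total - dk
                dks.append(dk)
                dls.append(dl)
                if total == 0:
                    energies.append(math.inf)
                elif dk == 0 or dl == 0:
                    energies.append(float(p.bulge_size[total]))
                else:
                    asym = min(p.asymmetry_cap,
                               p.asymmetry_per_nt * abs(dk - dl))
                    energies.append(float(p.interior_size[total]) + asym)
        self.kern_dk = np.array(dks)
        self.kern_dl = np.array(dls)
        kern = alg.from_energy(np.array(energies), RT)
        if not alg.tropical:
            kern = kern * self.spow[np.array(dks) + np.array(dls) + 2]
        self.kern = kern
        # number of kernel entries with total size <= t
        self.kcount = np.array(
            [(t + 1) * (t + 2) // 2 for t in range(cap + 1)]
        )
        self.cap = cap

        # stack weights with a guard row/col for non-canonical pairs:
        # forbidden normally, energy 0 when every pair is admitted
        # (the structure-counting limit)
        stack_e = np.full((7, 7), 0.0 if allow_all_pairs else math.inf)
        stack_e[:6, :6] = p.stack
        stack_w = alg.from_energy(stack_e, RT)
        if not alg.tropical:
            stack_w = stack_w * self.spow[2]
        self.stack_w = stack_w

        # multiloop scalars and powers of the unpaired-base factor
        if alg.tropical:
            self.a = p.ml_close_e
            self.b = p.ml_branch_e
            self.unp = 0.0
            self.cpow = p.ml_unpaired_e * np.arange(n + 2, dtype=float)
        else:
            self.a = p.ml_close * self.spow[2]
            self.b = p.ml_branch
            self.unp = self.spow[1]
            self.cpow = (p.ml_unpaired * self.spow[1]) ** np.arange(
                n + 2, dtype=float
            )

    def inner_kernel_size(self, span: int) -> int:
        """Kernel entries usable inside an outer pair of the given span."""
        t = min(self.cap, span - 2 - (self.params.min_hairpin_unpaired + 1))
        return 0 if t < 0 else int(self.kcount[t])

    def zeros(self) -> np.ndarray:
        return np.full((self.n + 2, self.n + 2), self.alg.zero)
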