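"""Reduced nearest-neighbor energy model for RNA secondary structure.

Every recursion in this package consumes loop free energies, or their
Boltzmann weights ``exp(-E / RT)``, through the functions defined here.
The model is a reduced Turner-style set:

* stacking free energies for the six canonical pair types
  (``CG, GC, GU, UG, AU, UA``; GU/UG are the wobble pairs),
* size-dependent hairpin-loop penalties (unpaired sizes 3..30) with
  Jacobson-Stockmayer logarithmic extrapolation beyond size 30,
* size-dependent bulge and generic interior-loop penalties (capped at a
  total unpaired size of 30, which is what keeps the algorithms cubic),
* a linear asymmetry penalty for interior loops with a cap,
* a linear multiloop model ``a + b * branches + c * unpaired``.

Dangling ends, terminal mismatches and tetraloop bonuses are deliberately
absent: the dynamic programs and the enumeration oracle share this model,
so algorithmic correctness is fully testable without the complete Turner
parameter set.

Energies are in kcal/mol; disallowed configurations have energy ``+inf``
and Boltzmann weight 0.  Temperatures are Kelvin and
``RT = 0.0019872 kcal/(mol K) * T``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path

import numpy as np

from .sequence import RnaSequence

#: Gas constant in kcal/(mol*K).
GAS_CONSTANT = 0.0019872

#: Canonical (Watson-Crick + wobble) pair types in fixed table order.
PAIR_TYPES = ("CG", "GC", "GU", "UG", "AU", "UA")

_PAIR_INDEX = {(t[0], t[1]): k for k, t in enumerate(PAIR_TYPES)}
_NUCS = frozenset("ACGU")


def pair_type(a: str, b: str) -> str | None:
    """Canonical pair type of nucleotides ``(a, b)``, or ``None``.

    Watson-Crick pairs (AU, UA, CG, GC) and wobble pairs (GU, UG) each map
    to a distinct type; all other combinations return ``None``.
    """
    if a not in _NUCS or b not in _NUCS:
        raise ValueError(f"invalid nucleotide in pair ({a!r}, {b!r})")
    k = _PAIR_INDEX.get((a, b))
    return None if k is None else PAIR_TYPES[k]


def pair_index(a: str, b: str) -> int:
    """Index of the pair type in :data:`PAIR_TYPES`, or ``-1``."""
    if a not in _NUCS or b not in _NUCS:
        raise ValueError(f"invalid nucleotide in pair ({a!r}, {b!r})")
    return _PAIR_INDEX.get((a, b), -1)


class ParameterError(ValueError):
    """Raised when a parameter file is incomplete or malformed."""


@dataclass(frozen=True)
class EnergyParameters:
    """Loop free energies and multiloop coefficients of the model.

    Size tables are stored as arrays indexed directly by loop size
    (index 0..30); sizes outside the allowed range hold ``+inf``.

    Attributes
    ----------
    stack:
        ``(6, 6)`` array over pair-type indices; ``stack[p, q]`` is the
        stacking energy with outer pair type ``p = type(i, j)`` and inner
        pair read 3'->5', ``q = type(j-1, i+1)``.
    hairpin_size, bulge_size, interior_size:
        Loop-size penalty tables, kcal/mol.
    asymmetry_per_nt, asymmetry_cap:
        Linear interior-loop asymmetry penalty and its cap.
    lxc:
        Coefficient of the ``lxc * ln(size / 30)`` extrapolation for
        hairpin loops larger than 30.
    ml_close_e, ml_branch_e, ml_unpaired_e:
        Multiloop energies for closing a loop, adding a branch, and an
        unpaired loop nucleotide.  Their Boltzmann weights are the
        multiloop factors ``a``, ``b`` and ``c`` of the recursions.
    temperature:
        Kelvin; default 310.15 (37 C), giving ``RT`` of about 0.61633.
    """

    stack: np.ndarray
    hairpin_size: np.ndarray
    bulge_size: np.ndarray
    interior_size: np.ndarray
    asymmetry_per_nt: float
    asymmetry_cap: float
    lxc: float
    ml_close_e: float
    ml_branch_e: float
    ml_unpaired_e: float
    temperature: float = 310.15
    min_hairpin_unpaired: int = 3
    max_interior_span: int = 30

    @property
    def RT(self) -> float:
        """Thermal energy kcal/mol at :attr:`temperature`."""
        return GAS_CONSTANT * self.temperature

    def boltzmann(self, energy: float) -> float:
        """``exp(-energy / RT)``; 0 for ``+inf`` energies."""
        if energy == math.inf:
            return 0.0
        return math.exp(-energy / self.RT)

    @property
    def ml_close(self) -> float:
        """Multiloop closing factor ``a = exp(-a_E / RT)``."""
        return self.boltzmann(self.ml_close_e)

    @property
    def ml_branch(self) -> float:
        """Multiloop branch factor ``b = exp(-b_E / RT)``."""
        return self.boltzmann(self.ml_branch_e)

    @property
    def ml_unpaired(self) -> float:
        """Multiloop unpaired-base factor ``c = exp(-c_E / RT)``."""
        return self.boltzmann(self.ml_unpaired_e)

    def hairpin_size_energy(self, size: int) -> float:
        """Hairpin penalty for ``size`` unpaired bases, extrapolated > 30."""
        if size < self.min_hairpin_unpaired:
            return math.inf
        if size <= 30:
            return float(self.hairpin_size[size])
        return float(self.hairpin_size[30]) + self.lxc * math.log(size / 30.0)

    def with_temperature(self, temperature: float) -> "EnergyParameters":
        """Same table at a different temperature (energies are treated as
        temperature-independent free energies; only RT changes)."""
        if temperature <= 0:
            raise ParameterError("temperature must be positive (Kelvin)")
        return replace(self, temperature=temperature)

    # -- construction -------------------------------------------------

    @classmethod
    def load(cls, path: str | Path) -> "EnergyParameters":
        """Parse the plain-text parameter format bundled with the package."""
        scalars: dict[str, float] = {}
        tables: dict[str, list[float]] = {}
        section = None
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if line.startswith("[") and line.endswith("]"):
                section = line[1:-1]
                if section != "scalars":
                    tables[section] = []
                continue
            if section == "scalars":
                key, val = line.split()
                scalars[key] = float(val)
            elif section is not None:
                tables[section].extend(float(x) for x in line.split())
            else:
                raise ParameterError(f"data outside any section: {raw!r}")

        required_scalars = {
            "temperature_K", "ml_close", "ml_branch", "ml_unpaired",
            "asymmetry_per_nt", "asymmetry_cap", "lxc",
            "min_hairpin_unpaired", "max_interior_span",
        }
        missing = required_scalars - scalars.keys()
        if missing:
            raise ParameterError(f"missing scalars: {sorted(missing)}")
        for name, count in (("stack", 36), ("hairpin", 28),
                            ("bulge", 30), ("interior", 29)):
            if name not in tables:
                raise ParameterError(f"missing table [{name}]")
            if len(tables[name]) != count:
                raise ParameterError(
                    f"table [{name}] has {len(tables[name])} values, "
                    f"expected {count}"
                )

        def size_table(values: list[float], first_size: int) -> np.ndarray:
            t = np.full(31, math.inf)
            t[first_size : first_size + len(values)] = values
            return t

        params = cls(
            stack=np.array(tables["stack"]).reshape(6, 6),
            hairpin_size=size_table(tables["hairpin"], 3),
            bulge_size=size_table(tables["bulge"], 1),
            interior_size=size_table(tables["interior"], 2),
            asymmetry_per_nt=scalars["asymmetry_per_nt"],
            asymmetry_cap=scalars["asymmetry_cap"],
            lxc=scalars["lxc"],
            ml_close_e=scalars["ml_close"],
            ml_branch_e=scalars["ml_branch"],
            ml_unpaired_e=scalars["ml_unpaired"],
            temperature=scalars["temperature_K"],
            min_hairpin_unpaired=int(scalars["min_hairpin_unpaired"]),
            max_interior_span=int(scalars["max_interior_span"]),
        )
        if not np.allclose(params.stack, params.stack.T):
            raise ParameterError("stack table must be symmetric under the "
                                 "outer/inner-reversed convention")
        return params

    @classmethod
    def default(cls) -> "EnergyParameters":
        """The version-controlled parameter table bundled with the package."""
        with resources.as_file(
            resources.files("rnaccess.data").joinpath("default.par")
        ) as p:
            return cls.load(p)

    @classmethod
    def zeroed(cls) -> "EnergyParameters":
        """All-zero energies: every legal loop has Boltzmann weight 1.

        In this limit the partition function counts secondary structures,
        which is what the structure-counting cross-checks use.
        """
        zeros = np.zeros(31)
        return cls(
            stack=np.zeros((6, 6)),
            hairpin_size=zeros.copy(),
            bulge_size=zeros.copy(),
            interior_size=zeros.copy(),
            asymmetry_per_nt=0.0,
            asymmetry_cap=0.0,
            lxc=0.0,
            ml_close_e=0.0,
            ml_branch_e=0.0,
            ml_unpaired_e=0.0,
        )


# -- loop energies ----------------------------------------------------


def _check_bounds(seq: RnaSequence, *positions: int) -> None:
    for p in positions:
        if not 1 <= p <= seq.n:
            raise IndexError(f"position {p} outside [1, {seq.n}]")


def hairpin_energy(seq: RnaSequence, i: int, j: int,
                   p: EnergyParameters) -> float:
    """Free energy of the hairpin loop closed by pair ``(i, j)``.

    ``+inf`` if ``(i, j)`` cannot pair or the loop is shorter than the
    minimum hairpin size.
    """
    _check_bounds(seq, i, j)
    if i >= j:
        raise ValueError(f"need i < j, got ({i}, {j})")
    if pair_index(seq.base(i), seq.base(j)) < 0:
        return math.inf
    return p.hairpin_size_energy(j - i - 1)


def hairpin_weight(seq: RnaSequence, i: int, j: int,
                   p: EnergyParameters) -> float:
    """Boltzmann factor of the hairpin loop closed by ``(i, j)``."""
    return p.boltzmann(hairpin_energy(seq, i, j, p))


def interior_energy(seq: RnaSequence, i: int, j: int, k: int, l: int,
                    p: EnergyParameters) -> float:
    """Free energy of the interior loop between pairs ``(i, j)`` and ``(k, l)``.

    Covers stacks (``k = i+1, l = j-1``), bulges (one side empty) and
    generic interior loops (size penalty plus capped asymmetry).  ``+inf``
    if either pair is non-canonical or the total unpaired size exceeds
    ``max_interior_span``.
    """
    _check_bounds(seq, i, j, k, l)
    if not (i < k < l < j):
        raise ValueError(f"need i < k < l < j, got ({i}, {k}, {l}, {j})")
    po = pair_index(seq.base(i), seq.base(j))
    pi = pair_index(seq.base(l), seq.base(k))  # inner pair read 3'->5'
    if po < 0 or pi < 0:
        return math.inf
    n1, n2 = k - i - 1, j - l - 1
    total = n1 + n2
    if total > p.max_interior_span:
        return math.inf
    if total == 0:
        return float(p.stack[po, pi])
    if n1 == 0 or n2 == 0:
        return float(p.bulge_size[total])
    asym = min(p.asymmetry_cap, p.asymmetry_per_nt * abs(n1 - n2))
    return float(p.interior_size[total]) + asym


def interior_weight(seq: RnaSequence, i: int, j: int, k: int, l: int,
                    p: EnergyParameters) -> float:
    """Boltzmann factor of the interior loop between ``(i, j)`` and ``(k, l)``."""
    return p.boltzmann(interior_energy(seq, i, j, k, l, p))


def multiloop_energy(branches: int, unpaired: int,
                     p: EnergyParameters) -> float:
    """Linear multiloop energy ``a + b * branches + c * unpaired``.

    ``branches`` counts the interior stems only; the closing pair
    contributes the constant ``a`` term.
    """
    return (p.ml_close_e + p.ml_branch_e * branches
            + p.ml_unpaired_e * unpaired)
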