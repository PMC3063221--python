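# Methods

## Model

Secondary structures are pseudoknot-free sets of canonical base pairs
(Watson-Crick plus GU/UG wobble) in which every hairpin loop spans at
least `min_hairpin_unpaired = 3` unpaired bases. Each structure's free
energy is the sum of its loop energies under a reduced nearest-neighbor
model; the ensemble is Boltzmann-distributed with weights `exp(-E/RT)`,
`RT = 0.0019872 kcal/(mol K) × T`, default `T = 310.15 K` (37 °C,
`RT ≈ 0.61633 kcal/mol`).

The loop model (bundled table `src/rnaccess/data/default.par`,
kcal/mol at 37 °C, Turner-1999-style representative values):

| term | form | default |
|---|---|---|
| stack | `stack[type(i,j), type(j-1,i+1)]`, symmetric 6×6 | −3.4 … +1.3 |
| hairpin | size table 3–30, then `E(30) + lxc·ln(s/30)` | 5.4 … 7.6, `lxc = 1.07856` |
| bulge | size table 1–30 | 2.8 … 6.1 |
| interior | size table 2–30 + `min(cap, 0.5·|n1−n2|)` asymmetry | cap 3.0 |
| multiloop | `a + b·branches + c·unpaired` | `a = 3.4`, `b = 0.4`, `c = 0.0` |

Dangling ends, terminal mismatches, tetraloop bonuses and coaxial
stacking are deliberately omitted: every algorithm here is agnostic to
such refinements, and correctness is established by comparing the
dynamic programs against exhaustive enumeration *under the same model*,
which these simplifications do not weaken. Absolute energies and
probabilities therefore differ from full-Turner implementations; the
algorithmic quantities (and every invariant tested) do not depend on
the table values.

The total unpaired size of interior loops is capped at
`max_interior_span = 30`. This cap is what makes both the inside and the
outside recursion cubic, and it is applied identically in both so the
two passes describe the same ensemble.

## Recursions

Inside (by increasing span; the decomposition counts each structure
exactly once):

    Q(i,j)   = Q(i+1,j) + Σ_l QB(i,l) Q(l+1,j),        Q(a,b)=1 for a≥b
    QB(i,j)  = hp(i,j) + Σ_{k,l} il(i,j,k,l) QB(k,l)
               + a Σ_k QM(i+1,k-1) QM1(k,j-1)
    QM1(i,j) = b Σ_l QB(i,l) c^(j-l)
    QM(i,j)  = Σ_k (c^(k-i) + QM(i,k-1)) QM1(k,j)      (k = last stem start)
    QM2(i,j) = Σ_k QM(i,k-1) QM1(k,j)                  (≥ 2 stems)

Outside (by decreasing span): `Qout(i,j)` is the trivial exterior term
`Q(1,i-1)Q(j+1,n)` plus the enclosing interior-loop sum (same span cap)
plus the multiloop term. The naive multiloop term is a double sum over
the enclosing pair `(k,l)`; it is reduced to O(n) per entry with two
auxiliary arrays updated incrementally as entries of larger span are
finished:

    OMa(k,y) = Σ_{l>y} Qout(k,l)·a·b·c^(l-1-y)
    OMb(x,l) = Σ_{k<x} Qout(k,l)·a·b·(QM(k+1,x-1) + c^(x-1-k))
    ML(i,j)  = Σ_{l>j} OMb(i,l) QM(j+1,l-1) + Σ_{k<i} QM(k+1,i-1) OMa(k,j)

The two S-sums split the "at least one further stem" requirement into
"a stem right of (i,j)" and "stems left, nothing right", which is a
disjoint cover. Processing order guarantees no entry of too-small span
has been folded in when it could matter (an enclosing pair always has
span ≥ inner span + 2).

### Interval accessibility

`pu(x,y) = [Q(1,x-1)Q(y+1,n) + Qub(x,y)]/Q(1,n)` with `Qub` split by the
loop containing the interval:

* hairpin: `Σ_{i<x} QH(i,y)` with `QH(i,y) = Σ_{j>y} Qout(i,j) hp(i,j)`,
  computed by the constant-time recursion `QH(i,y) = QH(i,y+1) +
  Qout(i,y+1) hp(i,y+1)`;
* interior: the interval lies on the 5' or 3' unpaired side;
  `QI5(i,k)`/`QI3(l,j)` accumulate `Qout·il·QB` over the capped offset
  kernel during the helper pass, and per-interval sums telescope;
* multiloop, three disjoint cases by interval position — before the
  first stem (`a Σ_p c^(y-p) ML2R(p,y)`), between stems
  (`a c^(L+1) Σ_p QM(p+1,x-1) ML1R(p,y)`), after the last stem
  (`a c^(L+1) Σ_p QM2(p+1,x-1) MLCR(p,y)`) — where
  `ML2R/ML1R(p,y) = Σ_q Qout(p,q)·QM2/QM(y+1,q-1)` and
  `MLCR(p,y) = Σ_q Qout(p,q) c^(q-1-y)` (the latter by a constant-time
  recursion). "Stems right ≥ 2 / ≥ 1 / = 0" with "stems left = 0 / ≥ 1 /
  ≥ 2" makes the three cases a partition, so parts are individually
  meaningful probabilities and sum to `pu` exactly.

The hairpin and interior per-interval sums over the enclosing 5' end are
prefix sums, so after an O(n²) pass they are O(1) per interval; the
multiloop sums are O(n). Totals: O(n³) time, O(n²) memory.

Exactness of the decomposition is not argued from the algebra alone: on
every benchmark sequence all `pu` values, and each of the four parts,
are required to equal the enumeration oracle's constrained ratios to
better than 1e-9 relative (observed: ~1e-15).

## MFE variant

The identical recursion code runs in the min-plus (tropical) semiring —
sums become minima, products become energy sums — giving `F`, `C`,
`M/M1/M2`, the outside matrix and `f_a(x, x+L)` for all intervals. The
unambiguous multiloop decomposition is kept (redundant but harmless for
minimisation). Backtracking a structure for one interval re-folds with
every pair touching the interval forbidden (which attains `f_a`
exactly) and traces the standard recursions; case order is fixed —
exterior, hairpin, interior with lexicographic inner pair, multiloop
with the smallest split — and energy matching uses a 1e-6 kcal/mol
tolerance, so output is deterministic. Energies are printed to
0.01 kcal/mol. The `f_a(i, n)` series is reported as the minimum-energy
structure of each transcribed prefix (the unpaired suffix standing for
the untranscribed part); consecutive duplicates may be collapsed.

## Windows

`windowed_accessibility` folds each of the `n − W + 1` full-width
windows independently (pairs restricted to `span ≤ max_pair_span`) and
averages each interval over exactly the windows that contain it; near
the ends an interval simply lies in fewer windows. No truncated
"phantom" windows are introduced. With `W ≥ n` there is one window and
the output is bit-identical to the global computation. Per-window
refolding is used rather than a sliding update: at the problem sizes
this package targets the simple strategy is fast, and equality with
naive per-window averaging is the correctness contract in any case.

## Numerical choices

* Plain double precision; adequate to n ≈ 300 at 37 °C. Beyond that the
  partition function overflows and `fill_inside` raises, pointing to the
  per-nucleotide rescaling option (`scale > 1`): every elementary weight
  is multiplied by `scale^(-m)` for the `m` positions it covers, and all
  reported probabilities and free energies undo the rescaling exactly
  (tested: scaled and unscaled runs agree to 1e-9 relative).
* Probabilities are printed with 6 significant digits, energies with two
  decimals; table round-trips are tested at printed precision.
* Degenerate inputs: sequences shorter than 5 nt cannot pair and are
  answered directly (`pu ≡ 1`, `f_a ≡ 0`).
* A structure-counting mode (`allow_all_pairs` plus the all-zero
  parameter set) turns `Q(1,n)` into the number of secondary structures,
  cross-checked exactly against an independent one-dimensional
  recurrence; in that mode the non-canonical stack sentinel is 0 instead
  of +inf. The mode exists for validation, not for thermodynamics.

## Operation counting and complexity evidence

Every recursion tallies elementary updates into two counters: `cubic`
for loops whose trip count grows with n, and `capped` for the
interior-loop offset kernels, which touch at most `(31·32)/2 ≈ 500`
cells per entry regardless of n and are therefore O(1) per cell — a
constant-size stencil. Cubic-scaling evidence uses the `cubic` counter:
measured on nested prefixes (n = 64, 128, 256) of one random sequence,
doubling n multiplies the counts by ≈ 7.7–8.8 for the outside fill and
≈ 7.8 for the all-intervals accessibility pass, consistent with n³. The
capped counter grows ≈ 4× per doubling, as a Θ(n²) term must; at these
n it is still comparable in magnitude to the cubic term, which is why
total counts alone would understate the asymptotic ratio. Both counters
combined remain below 1% of the cost model of the superseded strategy
(one full fold re-run per interval length, ≈ n times one fold).

## What the synthetic benchmark does and does not show

Test sequences are drawn uniformly with a configurable GC fraction
(default 0.5) from a seeded generator; the standard benchmark is 50
sequences of lengths 8–18 — short enough for exhaustive enumeration
(ensembles of ~10⁴ structures in total) yet long enough to exercise
hairpins, stacks, bulges, interior loops and multiloops. Scaling is
measured on random prefixes up to n = 256; window equivalence on a
56-nt sequence with W = 18. These sizes were chosen so that the entire
validation runs in minutes on one core. Random uniform sequences have
no evolved structure; passing tests demonstrates *algorithmic*
correctness (DP = enumeration under the shared model) for every loop
topology expressible at these lengths, but says nothing about how well
the reduced energy table reproduces melting experiments or structures
of natural RNAs.

## Known limitations

* Reduced energy model — no dangles, terminal mismatches, special
  loops; absolute energies differ from full Turner-2004 sets.
* Temperature changes rescale RT only; enthalpy/entropy splits are not
  modelled.
* No pseudoknots; no joint probability of two intervals being
  simultaneously unpaired (the ensemble correlations make that a
  sampling problem, out of scope here); no RNA-RNA interaction
  energies — only the opening-cost side (`δG_open`) is provided.
* The cotranscriptional series is a sequence of equilibrium minima of
  growing prefixes, not folding kinetics.
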