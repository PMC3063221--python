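# rnaccess

Accessibility — the equilibrium probability that a stretch of an RNA
molecule is completely single-stranded — controls how well miRNAs,
siRNAs, bacterial sRNAs and single-strand-binding proteins can engage
their target sites, and how efficiently ribosomes find a Shine-Dalgarno
sequence. `rnaccess` computes these unpaired-interval probabilities for
**all** intervals of a sequence in O(n³) time and O(n²) memory, together
with the underlying McCaskill partition-function machinery, a
minimum-free-energy variant with structure backtracking, and a
sliding-window mode for long sequences. It is aimed at people building
RNA–RNA interaction or target-site pipelines, and at anyone who wants
exact ensemble quantities rather than sampled estimates.

## The quantities computed

Over the Boltzmann ensemble of pseudoknot-free secondary structures with
weights `exp(-E/RT)` under a reduced Turner-style nearest-neighbor
model, the package computes:

* `Q(i, j)` — partition function of interval `[i, j]`, via the standard
  inside recursion (`Q`, `Q^B`, `Q^M`, `Q^M1`, `Q^M2`);
* `p(i, j) = Q^out(i, j) · Q^B(i, j) / Q(1, n)` — base-pair
  probabilities from the outside recursion, with two auxiliary arrays
  keeping the multiloop part O(n) per pair;
* `p^u(x, x+L)` — the probability that `x .. x+L` is completely
  unpaired, for every interval:

  `p^u(x, x+L) = [ Q(1, x-1) · Q(x+L+1, n) + Q^ub(x, x+L) ] / Q(1, n)`

  where `Q^ub` sums over enclosing pairs, split by the loop type the
  interval lies in (hairpin, interior-loop side, or one of three
  multiloop positions). Each contribution reuses arrays recorded during
  the outside pass, so a single interval costs O(n) and all intervals
  together cost O(n³) — not the O(n⁴) of re-running a fixed-length scan
  per length;
* `δG_open(x, x+L) = -RT ln p^u` — the free-energy cost of forcing the
  interval open (the quantity RNA-interaction predictors add to their
  duplex energies);
* `f_a(x, x+L)` — the minimum free energy over structures leaving the
  interval unpaired (the same decomposition in min-plus algebra), with
  deterministic backtracking of an optimal structure, and the growing
  chain series `f_a(i, n)` as a naive cotranscriptional folding picture;
* window-averaged `p^u` for long sequences: every length-`W` window is
  folded with a bounded pair span and each interval is averaged over
  exactly the windows containing it.

Loop energies come from a reduced, fully documented nearest-neighbor
table bundled with the package (stacking, size-dependent hairpin / bulge
/ interior penalties, capped asymmetry, linear multiloop model; no
dangling ends or terminal mismatches). An exhaustive enumeration oracle
sharing the same energy model — but none of the recursion code — is part
of the package and is what every dynamic program is tested against.

## Worked example

```python
import rnaccess as ra

p = ra.EnergyParameters.default()          # 37 C, RT = 0.61633 kcal/mol
seq = ra.RnaSequence("GGGAAACCCAUGCAUGCGCGAAAGCAUGCA", name="demo")

ins = ra.fill_inside(seq, p)
print(ra.ensemble_free_energy(ins, p))     # -9.862246463817119

res = ra.accessibility_all(seq, p)
print(res.probability(1, 3))               # 0.18518044154809355
print(res.opening_energy(1, 3))            # 1.039396617949449
print(res.probability(4, 2))               # 0.9999977132241768

t = ra.mfe_unpaired_all(seq, p)
print(t.mfe(), t.f_a(1, 3))                # -9.7 -8.8
s = ra.backtrack(seq, p, t, 1, 3)
print(s.dot_bracket, s.energy)
# ..........(((((((......)))))))  -8.8
```

The 5'-terminal `GGG` likes to pair with the `CCC` at positions 7–9, so
forcing the first four bases open costs about 1.04 kcal/mol
(`p^u ≈ 0.185`), while the hairpin loop `AAA` at positions 4–6 is
essentially always unpaired (`p^u ≈ 0.999998`). Constraining positions
1–4 open raises the minimum free energy from −9.70 to −8.80 kcal/mol and
the optimal structure shifts to the 3' half of the molecule.

The same computations are available from the shell:

```sh
rnaccess -s GGGAAACCCAUGCAUGCGCGAAAGCAUGCA --name demo -u 10   # demo_lunp
rnaccess in.fa --mode windowed -W 80 -L 40 -u 20
rnaccess -s GGGAAACCCGGGAAACCC --mode cotranscriptional
```

Output tables use the RNAplfold `_lunp` dialect (row = interval end,
column = interval length, `NA` where undefined); `--openen` writes
`δG_open` instead of probabilities.

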