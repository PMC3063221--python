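# rnaccess reduced nearest-neighbor parameter set
#
# Free energies in kcal/mol at 37 C (310.15 K).  The model comprises
# stacking energies for the six canonical pair types, size-dependent
# hairpin / bulge / interior loop penalties with Jacobson-Stockmayer
# logarithmic extrapolation beyond size 30, a linear (Ninio) interior-loop
# asymmetry penalty with a cap, and a linear multiloop model
# a + b * branches + c * unpaired.  No dangling ends, terminal mismatches
# or tetraloop bonuses.  Values are representative Turner-1999-style
# nearest-neighbor free energies.
#
# Stack convention: row = outer pair type (i,j), column = inner pair type
# read 3'->5', i.e. the type of (j-1, i+1).  The matrix is symmetric under
# this convention.

[scalars]
temperature_K       310.15
ml_close            3.40
ml_branch           0.40
ml_unpaired         0.00
asymmetry_per_nt    0.50
asymmetry_cap       3.00
lxc                 1.07856
min_hairpin_unpaired 3
max_interior_span   30

# rows/cols: CG GC GU UG AU UA
[stack]
-2.40 -3.30 -2.10 -1.40 -2.10 -2.10
-3.30 -3.40 -2.50 -1.50 -2.20 -2.40
-2.10 -2.50  1.30 -0.50 -1.40 -1.30
-1.40 -1.50 -0.50  0.30 -0.60 -1.00
-2.10 -2.20 -1.40 -0.60 -1.10 -0.90
-2.10 -2.40 -1.30 -1.00 -0.90 -1.30

# unpaired loop sizes 3..30
[hairpin]
5.70 5.60 5.60 5.40 5.90 5.60 6.40 6.50 6.60 6.70 6.80 6.90 6.90 7.00
7.10 7.10 7.20 7.20 7.30 7.30 7.40 7.40 7.40 7.50 7.50 7.50 7.60 7.60

# bulge sizes 1..30
[bulge]
3.80 2.80 3.20 3.60 4.00 4.40 4.60 4.70 4.80 4.90 5.00 5.10 5.20 5.30
5.40 5.40 5.50 5.50 5.60 5.70 5.70 5.80 5.80 5.80 5.90 5.90 6.00 6.00
6.00 6.10

# total unpaired sizes 2..30
[interior]
1.50 1.60 1.70 1.80 2.00 2.20 2.30 2.40 2.50 2.60 2.70 2.80 2.90 2.90
3.00 3.10 3.10 3.20 3.30 3.30 3.40 3.40 3.50 3.50 3.50 3.60 3.60 3.70
3.70
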