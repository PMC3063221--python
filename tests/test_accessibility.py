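import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rnaccess.accessibility import (
    PART_NAMES,
    accessibility_all,
    loop_type_decomposition,
    opening_energies,
)
from rnaccess.inside import fill_inside
from rnaccess.oracle import brute_accessibility, brute_accessibility_by_loop
from rnaccess.sequence import RnaSequence

rna_strings = st.text(alphabet="ACGU", min_size=1, max_size=14)


def test_all_a_fully_accessible(params):
    seq = RnaSequence("AAAAAAAA")
    res = accessibility_all(seq, params)
    for x in range(1, 9):
        for L in range(0, 9 - x):
            assert res.probability(x, L) == pytest.approx(1.0)
            assert res.opening_energy(x, L) == pytest.approx(0.0)
            assert loop_type_decomposition(res, x, L)[0] == pytest.approx(1.0)


def test_full_interval_is_inverse_partition_function(accessibilities):
    """Only the open chain leaves [1, n] unpaired."""
    for seq, ens, res in accessibilities:
        assert res.probability(1, seq.n - 1) == pytest.approx(
            1.0 / ens.Z, rel=1e-9
        )


def test_pu_matches_constrained_enumeration(accessibilities):
    for seq, ens, res in accessibilities:
        for x in range(1, seq.n + 1):
            for L in range(0, seq.n - x + 1):
                assert res.probability(x, L) == pytest.approx(
                    brute_accessibility(ens, x, L), rel=1e-9
                ), (seq.residues, x, L)


def test_decomposition_closure_and_loop_classes(accessibilities):
    """Parts are nonnegative, sum to pu exactly, and each part matches the
    per-structure loop-type classification from the oracle."""
    for seq, ens, res in accessibilities:
        for x in range(1, seq.n + 1):
            for L in range(0, seq.n - x + 1):
                parts = loop_type_decomposition(res, x, L)
                assert all(v >= -1e-15 for v in parts)
                assert sum(parts) == pytest.approx(
                    res.probability(x, L), abs=1e-12
                )
                expected = brute_accessibility_by_loop(ens, x, L)
                for val, key in zip(parts, PART_NAMES):
                    assert val == pytest.approx(expected[key], abs=1e-12), \
                        (seq.residues, x, L, key)


def test_single_base_consistency_with_pair_probabilities(folded, params):
    """pu(i, i) + sum_j P(i, j) = 1."""
    for seq, _, ins, out in folded:
        res = accessibility_all(seq, params, ins, out)
        for i in range(1, seq.n + 1):
            paired = out.P[i, :].sum() + out.P[:, i].sum()
            assert res.probability(i, 0) + paired == pytest.approx(
                1.0, abs=1e-9
            )


def test_containment_monotonicity(accessibilities):
    """Sub-intervals are at least as accessible as their parents."""
    for seq, _, res in accessibilities:
        n = seq.n
        for x in range(1, n + 1):
            for y in range(x, n + 1):
                if y + 1 <= n:
                    assert res.pu[x, y] >= res.pu[x, y + 1] - 1e-12
                if x - 1 >= 1:
                    assert res.pu[x, y] >= res.pu[x - 1, y] - 1e-12


def test_opening_energy_definition(accessibilities, params):
    for seq, _, res in accessibilities:
        dg = opening_energies(res, params)
        for x in range(1, seq.n + 1):
            for y in range(x, seq.n + 1):
                assert dg[x, y] == pytest.approx(
                    -params.RT * math.log(res.pu[x, y]), abs=1e-12
                )
                assert dg[x, y] >= -1e-12


def test_max_len_caps_and_clips(params):
    seq = RnaSequence("GGGAAACCCAUGC")
    res = accessibility_all(seq, params, max_len=3)
    assert not math.isnan(res.pu[2, 4])
    assert math.isnan(res.pu[1, 5])
    with pytest.raises(ValueError):
        res.probability(1, 5)
    with pytest.warns(UserWarning, match="clipped"):
        accessibility_all(seq, params, max_len=99)


def test_short_sequences_shortcut(params):
    res = accessibility_all(RnaSequence("GCGC"), params)
    for x in range(1, 5):
        for y in range(x, 5):
            assert res.pu[x, y] == 1.0


def test_helpers_state_error(params):
    from rnaccess.outside import fill_outside

    seq = RnaSequence("GGGAAACCC")
    ins = fill_inside(seq, params)
    out = fill_outside(seq, params, ins)  # helpers not recorded
    with pytest.raises(RuntimeError, match="helpers"):
        accessibility_all(seq, params, ins, out)


def test_scaled_run_reproduces_unscaled_probabilities(params):
    seq = RnaSequence("GGGAAACCCAUGCAUGCGCG")
    r1 = accessibility_all(seq, params)
    r2 = accessibility_all(seq, params, scale=1.05)
    n = seq.n
    assert np.allclose(
        r1.pu[1 : n + 1, 1 : n + 1], r2.pu[1 : n + 1, 1 : n + 1],
        rtol=1e-9, equal_nan=True,
    )


@settings(max_examples=25, derandomize=True, deadline=None)
@given(rna_strings)
def test_pu_is_a_probability_everywhere(params, s):
    seq = RnaSequence(s)
    res = accessibility_all(seq, params)
    n = seq.n
    block = res.pu[1 : n + 1, 1 : n + 1]
    vals = block[~np.isnan(block)]
    assert np.all(vals > 0.0) and np.all(vals <= 1.0 + 1e-12)
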