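import math

import numpy as np
import pytest

from rnaccess.accessibility import accessibility_all
from rnaccess.mfe_unpaired import (
    backtrack,
    cotranscriptional_series,
    fill_mfe,
    mfe_unpaired_all,
)
from rnaccess.oracle import (
    brute_constrained_mfe,
    enumerate_structures,
    structure_energy,
)
from rnaccess.sequence import RnaSequence


def test_all_a_everything_zero(params):
    seq = RnaSequence("AAAAAAAAA")
    t = mfe_unpaired_all(seq, params)
    assert t.mfe() == 0.0
    for x in range(1, 10):
        for L in range(0, 10 - x):
            assert t.f_a(x, L) == 0.0
    s = backtrack(seq, params, t, 1, 8)
    assert s.dot_bracket == "." * 9 and s.energy == 0.0


def test_mfe_matches_enumeration_minimum(params, small_seqs):
    for seq in small_seqs:
        ens = enumerate_structures(seq, params)
        t = fill_mfe(seq, params)
        assert t.mfe() == pytest.approx(
            min(s.energy for s in ens.structures), abs=1e-9
        )
        # F = 0 on intervals too short to pair
        for i in range(1, seq.n + 1):
            for j in range(i, min(seq.n, i + 3) + 1):
                assert t.F[i, j] == 0.0


def test_f_a_matches_constrained_enumeration(params, small_seqs):
    for seq in small_seqs:
        ens = enumerate_structures(seq, params)
        t = mfe_unpaired_all(seq, params)
        for x in range(1, seq.n + 1):
            for L in range(0, seq.n - x + 1):
                expected, _ = brute_constrained_mfe(ens, x, L)
                assert t.f_a(x, L) == pytest.approx(expected, abs=1e-9), \
                    (seq.residues, x, L)


def test_f_a_monotone_in_interval_growth(params, small_seqs):
    """Forcing more bases open can only raise the minimum."""
    for seq in small_seqs:
        t = mfe_unpaired_all(seq, params)
        for x in range(1, seq.n + 1):
            for L in range(0, seq.n - x):
                assert t.f_a(x, L + 1) >= t.f_a(x, L) - 1e-12
        assert min(
            t.f_a(x, 0) for x in range(1, seq.n + 1)
        ) >= t.mfe() - 1e-12


def test_interval_one_to_n_is_open_chain(params, small_seqs):
    for seq in small_seqs:
        t = mfe_unpaired_all(seq, params)
        assert t.f_a(1, seq.n - 1) == 0.0
        s = backtrack(seq, params, t, 1, seq.n - 1)
        assert s.dot_bracket == "." * seq.n


def test_backtracked_structures_are_valid_and_optimal(params, small_seqs):
    for seq in small_seqs:
        t = mfe_unpaired_all(seq, params)
        for x, L in [(1, 0), (2, 2), (seq.n // 2, 1), (seq.n, 0)]:
            if x + L > seq.n:
                continue
            s = backtrack(seq, params, t, x, L)
            # the interval really is unpaired
            assert set(s.dot_bracket[x - 1 : x + L]) <= {"."}
            # brackets balance
            assert s.dot_bracket.count("(") == s.dot_bracket.count(")")
            # re-evaluated energy equals both the stored and the table value
            assert structure_energy(seq, s.pairs, params) == pytest.approx(
                s.energy, abs=1e-6
            )
            assert s.energy == pytest.approx(t.f_a(x, L), abs=1e-6)


def test_backtracking_is_deterministic(params):
    seq = RnaSequence("GGCGAAAGCCAUGCAUGG")
    t = mfe_unpaired_all(seq, params)
    a = backtrack(seq, params, t, 5, 2)
    b = backtrack(seq, params, t, 5, 2)
    assert a == b


def test_best_structure_bounded_by_constrained_partition_function(
    params, folded
):
    """exp(-f_a/RT) <= pu * Q(1,n): one structure never outweighs the
    whole constrained ensemble."""
    for seq, _, ins, out in folded:
        t = mfe_unpaired_all(seq, params)
        res = accessibility_all(seq, params, ins, out)
        for x in range(1, seq.n + 1):
            for L in range(0, seq.n - x + 1):
                lhs = math.exp(-t.f_a(x, L) / params.RT)
                rhs = res.probability(x, L) * ins.total
                assert lhs <= rhs * (1 + 1e-9)


class TestCotranscriptional:
    def test_all_a_single_entry(self, params):
        series = cotranscriptional_series(RnaSequence("A" * 12), params)
        assert len(series) == 1
        assert series[0].dot_bracket == "." * 12

    def test_prefix_energies_match_enumeration(self, params):
        seq = RnaSequence("GGGAAACCCGGGAAACCC")
        series = cotranscriptional_series(seq, params, collapse=False)
        assert len(series) == seq.n + 1
        for s in series:
            i, n = s.unpaired_interval
            assert set(s.dot_bracket[i - 1 :]) <= {"."}
            if i - 1 >= 5:
                pre = RnaSequence(seq.residues[: i - 1])
                ens = enumerate_structures(pre, params)
                assert s.energy == pytest.approx(
                    min(st.energy for st in ens.structures), abs=1e-9
                )

    def test_final_entry_is_full_mfe(self, params):
        seq = RnaSequence("GGGAAACCCGGGAAACCC")
        series = cotranscriptional_series(seq, params)
        t = fill_mfe(seq, params)
        assert series[-1].energy == pytest.approx(t.mfe(), abs=1e-9)
        assert series[-1].unpaired_interval == (seq.n + 1, seq.n)

    def test_collapse_drops_consecutive_duplicates(self, params):
        seq = RnaSequence("GGGAAACCCGGGAAACCC")
        full = cotranscriptional_series(seq, params, collapse=False)
        coll = cotranscriptional_series(seq, params, collapse=True)
        assert len(coll) <= len(full)
        assert all(
            a.dot_bracket != b.dot_bracket for a, b in zip(coll, coll[1:])
        )
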