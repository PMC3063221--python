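import math

import pytest

from rnaccess.accessibility import accessibility_all
from rnaccess.cli import main
from rnaccess.io import (
    read_fasta,
    read_unpaired_table,
    write_unpaired_table,
)
from rnaccess.sequence import RnaSequence, SequenceError

FIXED_30MER = "GGGAAACCCAUGCAUGCGCGAAAGCAUGCA"


class TestReadFasta:
    def test_single_record(self, tmp_path):
        f = tmp_path / "a.fa"
        f.write_text(">rec1 description\nGGGAAACCC\n")
        seqs = read_fasta(f)
        assert len(seqs) == 1
        assert seqs[0].name == "rec1"
        assert seqs[0].residues == "GGGAAACCC"

    def test_multi_record_lowercase_and_t_mapping(self, tmp_path):
        f = tmp_path / "b.fa"
        f.write_text(">x\nggtacc\n>y\nACGT\nacg\n")
        seqs = read_fasta(f)
        assert [s.residues for s in seqs] == ["GGUACC", "ACGUACG"]

    def test_ambiguity_code_rejected_with_position(self, tmp_path):
        f = tmp_path / "c.fa"
        f.write_text(">bad\nACGNACG\n")
        with pytest.raises(SequenceError, match=r"position 4.*'bad'"):
            read_fasta(f)

    def test_empty_file_rejected(self, tmp_path):
        f = tmp_path / "d.fa"
        f.write_text("")
        with pytest.raises(SequenceError):
            read_fasta(f)


class TestUnpairedTable:
    def test_all_a_prints_ones(self, tmp_path, params):
        seq = RnaSequence("AAAAAAAA", name="polya")
        res = accessibility_all(seq, params, max_len=3)
        path = tmp_path / "polya_lunp"
        write_unpaired_table(res, path)
        body = path.read_text().splitlines()
        assert body[0] == "#unpaired probabilities"
        assert body[1].startswith(" #i$\tl=1")
        tab = read_unpaired_table(path)
        assert all(v == 1.0 for v in tab.values())

    def test_na_where_interval_precedes_sequence(self, tmp_path, params):
        res = accessibility_all(RnaSequence("GGGAAACCC"), params, max_len=4)
        path = tmp_path / "t_lunp"
        write_unpaired_table(res, path)
        row1 = path.read_text().splitlines()[2].split("\t")
        assert row1[0] == "1"
        assert row1[2:] == ["NA", "NA", "NA"]

    def test_roundtrip_to_printed_precision(self, tmp_path, params):
        seq = RnaSequence(FIXED_30MER)
        res = accessibility_all(seq, params, max_len=10)
        path = tmp_path / "x_lunp"
        write_unpaired_table(res, path)
        tab = read_unpaired_table(path)
        for (i, l), v in tab.items():
            assert v == pytest.approx(res.pu[i - l + 1, i], rel=1e-5)

    def test_opening_energy_mode(self, tmp_path, params):
        seq = RnaSequence(FIXED_30MER)
        res = accessibility_all(seq, params, max_len=5)
        path = tmp_path / "x_openen"
        write_unpaired_table(res, path, opening_energies=True)
        tab = read_unpaired_table(path)
        for (i, l), v in tab.items():
            expected = -params.RT * math.log(res.pu[i - l + 1, i])
            assert v == pytest.approx(expected, abs=5e-3)
            assert v >= 0.0


class TestCli:
    def test_global_run_writes_lunp(self, tmp_path):
        fa = tmp_path / "in.fa"
        fa.write_text(f">demo\n{FIXED_30MER}\n")
        rc = main(["--ulength", "10", "-o", str(tmp_path), str(fa)])
        assert rc == 0
        assert (tmp_path / "demo_lunp").exists()

    def test_cli_defaults_match_library_defaults(self, tmp_path, params):
        """Golden check on a fixed 30-mer: the CLI table equals the one
        written straight from the library with default settings."""
        fa = tmp_path / "in.fa"
        fa.write_text(f">demo\n{FIXED_30MER}\n")
        assert main([str(fa), "-o", str(tmp_path / "cli")]) == 0
        res = accessibility_all(RnaSequence(FIXED_30MER, name="demo"), params)
        (tmp_path / "lib").mkdir()
        write_unpaired_table(res, tmp_path / "lib" / "demo_lunp")
        assert (tmp_path / "cli" / "demo_lunp").read_text() == (
            tmp_path / "lib" / "demo_lunp"
        ).read_text()

    def test_windowed_run(self, tmp_path):
        fa = tmp_path / "in.fa"
        fa.write_text(">w\n" + FIXED_30MER + FIXED_30MER + "\n")
        rc = main(["--mode", "windowed", "-W", "20", "-L", "15", "-u", "8",
                   "-o", str(tmp_path), str(fa)])
        assert rc == 0
        assert (tmp_path / "w_lunp").exists()

    def test_cotranscriptional_emits_structures(self, tmp_path, capsys):
        rc = main(["-s", "GGGAAACCCGGGAAACCC", "--name", "cx",
                   "--mode", "cotranscriptional", "-o", str(tmp_path)])
        assert rc == 0
        out = capsys.readouterr().out
        assert "(((...)))(((...)))" in out
        assert (tmp_path / "cx_mfe.txt").exists()

    def test_mfe_mode_requires_interval(self, tmp_path, capsys):
        rc = main(["-s", "GGGAAACCC", "--mode", "mfe", "-o", str(tmp_path)])
        assert rc == 1
        assert "interval" in capsys.readouterr().err

    def test_error_exit_on_bad_input(self, tmp_path, capsys):
        rc = main(["-s", "ACGN", "-o", str(tmp_path)])
        assert rc == 1
        assert "invalid residue" in capsys.readouterr().err

    def test_version_flag(self, capsys):
        with pytest.raises(SystemExit) as e:
            main(["--version"])
        assert e.value.code == 0
        assert "rnaccess" in capsys.readouterr().out
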