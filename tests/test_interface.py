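"""File formats, synthetic generation and the command-line interface."""

import random

import pytest
from click.testing import CliRunner

from wtrep import (
    Threshold,
    WeightedRepetition,
    brute_force_problem1,
    colour,
    filter_letters,
    read_iupac_fasta,
    read_probability_matrix,
    read_repetitions,
    records_for,
    solve_problem1,
    synthesize,
    write_probability_matrix,
    write_repetitions,
)
from wtrep.cli import main


class TestIupacFasta:
    def test_ambiguity_codes_expand_uniformly(self, tmp_path):
        path = tmp_path / "in.fa"
        path.write_text(">s1\nAMN\n")
        ((seq_id, ws),) = read_iupac_fasta(path)
        assert seq_id == "s1"
        assert dict(ws[0].entries) == {"A": 1.0}
        assert dict(ws[1].entries) == {"A": 0.5, "C": 0.5}
        assert dict(ws[2].entries) == {
            "A": 0.25,
            "C": 0.25,
            "G": 0.25,
            "T": 0.25,
        }

    def test_non_iupac_character_rejected_with_position(self, tmp_path):
        path = tmp_path / "in.fa"
        path.write_text(">s1\nAC!T\n")
        with pytest.raises(ValueError, match="position 2"):
            read_iupac_fasta(path)

    def test_two_base_codes_branch_at_threshold_half(self, tmp_path):
        # 0.5 is not greater than 1 - 1/2, so M/R/W/S/Y/K positions are black
        path = tmp_path / "in.fa"
        path.write_text(">s1\nAMRT\n")
        ((_, ws),) = read_iupac_fasta(path)
        t = Threshold.from_value(0.5)
        marks = colour(filter_letters(ws, t), t)
        assert marks.marks == "WBBW"


class TestProbabilityMatrix:
    def test_round_trip(self, tmp_path, table1):
        path = tmp_path / "m.tsv"
        write_probability_matrix(table1, path)
        back = read_probability_matrix(path)
        assert back == table1

    def test_table_colouring_survives_serialisation(self, tmp_path, table1, half):
        path = tmp_path / "m.tsv"
        write_probability_matrix(table1, path)
        back = read_probability_matrix(path)
        assert colour(filter_letters(back, half), half).marks == "WGWWBWWGWWW"

    def test_single_certain_row(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("# alphabet: a b\n0\t1.0\t0.0\n")
        ws = read_probability_matrix(path)
        assert len(ws) == 1
        assert dict(ws[0].entries) == {"a": 1.0}

    def test_bad_row_sum_rejected(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("# alphabet: a b\n0\t0.5\t0.4\n")
        with pytest.raises(ValueError, match="row 0"):
            read_probability_matrix(path)

    def test_non_consecutive_indices_rejected(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("# alphabet: a b\n1\t0.5\t0.5\n")
        with pytest.raises(ValueError, match="expected 0"):
            read_probability_matrix(path)


class TestRepetitionReports:
    def test_example_row_content(self, ex2, half, tmp_path):
        reps = solve_problem1(ex2, half)
        records = records_for("ex2", reps, ex2, half.squared())
        (row,) = [r for r in records if r.i == 1]
        assert (row.p, row.e, row.b, row.u) == (3, 2, "2:a", "aba")

    def test_round_trip(self, ex6, quarter, tmp_path):
        reps = solve_problem1(ex6, quarter)
        records = records_for("ex6", reps, ex6, quarter.squared())
        path = tmp_path / "reps.tsv"
        write_repetitions(records, path)
        assert read_repetitions(path) == sorted(records)

    def test_empty_result_is_header_only(self, tmp_path):
        path = tmp_path / "reps.tsv"
        write_repetitions([], path)
        assert path.read_text() == "id\ti\tp\te\tb\tu\tprob\n"
        assert read_repetitions(path) == []


class TestSynthesize:
    def test_deterministic_under_seed(self):
        a, truth_a = synthesize(60, ("a", "b"), 0.1, [(2, 3)], seed=7)
        b, truth_b = synthesize(60, ("a", "b"), 0.1, [(2, 3)], seed=7)
        assert a == b and truth_a == truth_b

    def test_certain_plant_recovered(self, half):
        ws, truth = synthesize(40, ("a", "b"), 0.0, [(2, 3)], seed=3)
        (planted,) = truth
        assert planted.b == frozenset()
        assert planted in solve_problem1(ws, half)

    def test_branching_plant_recovered_with_b(self, half):
        rng = random.Random(0)
        found_branching_root = False
        for seed in range(30):
            ws, truth = synthesize(
                14, ("a", "b"), 0.3, [(3, 2)], seed=seed, threshold=0.5
            )
            (planted,) = truth
            assert planted in brute_force_problem1(ws, half)
            if len(planted.b) == 1:
                found_branching_root = True
        assert found_branching_root

    def test_infeasible_plant_rejected(self):
        with pytest.raises(ValueError, match="planted"):
            synthesize(10, ("a", "b"), 0.0, [(4, 3)], seed=0)


class TestCli:
    def _write_matrix(self, tmp_path, ws):
        path = tmp_path / "in.tsv"
        write_probability_matrix(ws, path)
        return str(path)

    def test_find_reports_worked_example(self, tmp_path, ex6):
        runner = CliRunner()
        out = tmp_path / "out.tsv"
        result = runner.invoke(
            main,
            [
                "find",
                "--matrix",
                self._write_matrix(tmp_path, ex6),
                "--threshold",
                "0.25",
                "--problem",
                "all",
                "--output",
                str(out),
            ],
        )
        assert result.exit_code == 0, result.output
        rows = read_repetitions(out)
        assert any(
            (r.i, r.p, r.e, r.b, r.u) == (1, 2, 3, "", "ab") for r in rows
        )

    def test_threshold_out_of_range_is_usage_error(self, tmp_path, ex6):
        runner = CliRunner()
        result = runner.invoke(
            main,
            [
                "find",
                "--matrix",
                self._write_matrix(tmp_path, ex6),
                "--threshold",
                "1.5",
            ],
        )
        assert result.exit_code == 2

    def test_byte_identical_output_across_runs(self, tmp_path, ex2):
        runner = CliRunner()
        matrix = self._write_matrix(tmp_path, ex2)
        outputs = []
        for name in ("a.tsv", "b.tsv"):
            out = tmp_path / name
            result = runner.invoke(
                main,
                ["find", "--matrix", matrix, "--threshold", "0.5", "--output", str(out)],
            )
            assert result.exit_code == 0, result.output
            outputs.append(out.read_bytes())
        assert outputs[0] == outputs[1]

    def test_synth_pipes_into_find(self, tmp_path):
        runner = CliRunner()
        matrix = tmp_path / "synth.tsv"
        truth = tmp_path / "truth.tsv"
        result = runner.invoke(
            main,
            [
                "synth",
                "--n",
                "50",
                "--alphabet",
                "ab",
                "--black-density",
                "0.05",
                "--plant",
                "2,3",
                "--seed",
                "7",
                "--output",
                str(matrix),
                "--truth-output",
                str(truth),
            ],
        )
        assert result.exit_code == 0, result.output
        out = tmp_path / "found.tsv"
        result = runner.invoke(
            main,
            ["find", "--matrix", str(matrix), "--threshold", "0.5", "--output", str(out)],
        )
        assert result.exit_code == 0, result.output
        found = {(r.i, r.p, r.e, r.b) for r in read_repetitions(out)}
        for row in read_repetitions(truth):
            assert (row.i, row.p, row.e, row.b) in found

    def test_oracle_refuses_long_sequences(self, tmp_path):
        runner = CliRunner()
        ws, _ = synthesize(20, ("a", "b"), 0.0, [], seed=1)
        result = runner.invoke(
            main,
            [
                "oracle",
                "--matrix",
                self._write_matrix(tmp_path, ws),
                "--threshold",
                "0.5",
            ],
        )
        assert result.exit_code == 2
        assert "length 20" in result.output

    def test_oracle_agrees_with_solver_on_small_input(self, tmp_path, ex6):
        runner = CliRunner()
        matrix = self._write_matrix(tmp_path, ex6)
        out_solver = tmp_path / "solver.tsv"
        out_oracle = tmp_path / "oracle.tsv"
        for cmd, out in (("find", out_solver), ("oracle", out_oracle)):
            result = runner.invoke(
                main,
                [cmd, "--matrix", matrix, "--threshold", "0.25", "--output", str(out)],
            )
            assert result.exit_code == 0, result.output
        assert out_solver.read_text() == out_oracle.read_text()
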