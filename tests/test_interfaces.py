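"""File formats, configuration, plotting and the command-line pipeline."""
import numpy as np
import pytest
from click.testing import CliRunner

import mitostrand as m
from mitostrand.cli import main as cli_main
from mitostrand.config import RunConfig
from mitostrand.io import (
    read_alignments,
    read_concordance_counts,
    read_fasta,
    read_heteroplasmy_panel,
    read_pileup,
    read_variant_table,
    write_fasta,
    write_pileup,
    write_table,
)


class TestFasta:
    def test_round_trip(self, tmp_path, toy_ref):
        path = tmp_path / "ref.fasta"
        write_fasta(toy_ref, path)
        back = read_fasta(path)
        assert back.sequence == toy_ref.sequence and back.name == toy_ref.name

    def test_lowercase_normalized(self, tmp_path):
        (tmp_path / "lc.fasta").write_text(">x\nacgtacgt\n")
        assert read_fasta(tmp_path / "lc.fasta").sequence == "ACGTACGT"

    def test_two_records_rejected_naming_both(self, tmp_path):
        (tmp_path / "two.fasta").write_text(">a\nACGT\n>b\nACGT\n")
        with pytest.raises(ValueError, match="a, b"):
            read_fasta(tmp_path / "two.fasta")

    def test_ambiguous_bases_flagged(self, tmp_path):
        (tmp_path / "n.fasta").write_text(">x\nACGTNACGT\n")
        with pytest.warns(UserWarning, match="ambiguous"):
            ref = read_fasta(tmp_path / "n.fasta")
        assert ref.has_ambiguous


class TestPileup:
    def test_round_trip_bit_identical(self, tmp_path, toy_ref):
        counts, _ = m.simulate_base_counts(
            toy_ref, m.SimulationConfig(mean_depth=30, error_rate=0.01, seed=1)
        )
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_pileup(counts, toy_ref, p1)
        back, name, length = read_pileup(p1)
        assert name == toy_ref.name and length == len(toy_ref)
        assert (back.counts == counts.counts).all()
        write_pileup(back, toy_ref, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_missing_header_rejected(self, tmp_path):
        (tmp_path / "bad.tsv").write_text("position\tstrand\n")
        with pytest.raises(ValueError, match="header"):
            read_pileup(tmp_path / "bad.tsv")


class TestVariantTables:
    def test_read_variant_table(self, tmp_path):
        path = tmp_path / "calls.tsv"
        write_table(
            __import__("pandas").DataFrame(
                {
                    "sample": ["s1", "s1"],
                    "dataset": ["d", "d"],
                    "variant": ["m.100A>G", "m.5899_5900insC"],
                    "fraction_pct": [12.5, None],
                }
            ),
            path,
        )
        calls = read_variant_table(path)
        assert calls[0].fraction == 12.5
        assert calls[1].kind == "insertion" and calls[1].fraction is None

    def test_packaged_panels_load(self):
        rows = read_concordance_counts()
        assert len(rows) == 36
        assert sum(r.n_truth for r in rows if r.dataset == "PGM/ion_shear") == 214
        het = read_heteroplasmy_panel()
        assert set(het["variant"]) == {
            "m.12071T>C", "m.7989T>C", "m.9769T>C", "m.10866T>C",
            "m.8207C>T", "m.5609T>C", "m.7453G>A",
        }


class TestAlignments:
    def test_empty_sam_gives_empty_stream(self, tmp_path, toy_ref):
        sam = tmp_path / "empty.sam"
        m.write_sam([], toy_ref, sam)
        with read_alignments(sam) as stream:
            assert list(stream) == []

    def test_unmapped_records_skipped(self, tmp_path, toy_ref):
        sam = tmp_path / "u.sam"
        with open(sam, "w") as fh:
            fh.write("@HD\tVN:1.6\tSO:coordinate\n")
            fh.write(f"@SQ\tSN:{toy_ref.name}\tLN:{len(toy_ref)}\n")
            fh.write("u1\t4\t*\t0\t0\t*\t*\t0\t0\tACGT\t*\n")
        with read_alignments(sam) as stream:
            assert list(stream) == []

    def test_missing_reference_errors(self, tmp_path, toy_ref):
        sam = tmp_path / "r.sam"
        m.write_sam([], toy_ref, sam)
        with pytest.raises(ValueError, match="not in alignment file"):
            with read_alignments(sam, reference="nope"):
                pass


class TestRunConfig:
    def test_yaml_round_trip(self):
        cfg = RunConfig(bin_size=100, seed=9)
        assert RunConfig.from_yaml(cfg.to_yaml()) == cfg

    def test_unknown_keys_rejected(self):
        with pytest.raises(ValueError, match="unknown config keys"):
            RunConfig.from_yaml("bogus: 1")


class TestPlot:
    def test_plot_file_created(self, tmp_path, toy_ref):
        from mitostrand.plotting import plot_circular_coverage

        counts, _ = m.simulate_base_counts(toy_ref, m.SimulationConfig(mean_depth=40, seed=2))
        rc = m.relative_coverage(counts.depth_profile())
        out = tmp_path / "cov.png"
        plot_circular_coverage(rc, annotations=[(1, 500, "gene")], out_path=out)
        assert out.exists() and out.stat().st_size > 0


class TestCli:
    def test_smoke_pipeline(self, tmp_path):
        runner = CliRunner()
        out = tmp_path / "run"
        r = runner.invoke(cli_main, ["simulate", "--out-dir", str(out),
                                     "--mean-depth", "300", "--seed", "5"])
        assert r.exit_code == 0, r.output
        r = runner.invoke(cli_main, ["coverage", "--pileup", str(out / "pileup.tsv"),
                                     "--ref", str(out / "reference.fasta"),
                                     "--out-dir", str(out / "cov")])
        assert r.exit_code == 0, r.output
        assert (out / "cov" / "coverage_fractions.tsv").exists()
        r = runner.invoke(cli_main, ["bias", "--pileup", str(out / "pileup.tsv"),
                                     "--ref", str(out / "reference.fasta"),
                                     "--out-dir", str(out / "bias")])
        assert r.exit_code == 0, r.output
        assert (out / "bias" / "bias_curves.tsv").exists()

    def test_concord_on_packaged_panels(self, tmp_path):
        runner = CliRunner()
        r = runner.invoke(cli_main, ["concord", "--out-dir", str(tmp_path)])
        assert r.exit_code == 0, r.output
        assert "PGM: 96.6% detected" in r.output
        assert "MiSeq: 99.5% detected" in r.output

    def test_missing_input_nonzero_exit(self, tmp_path):
        runner = CliRunner()
        r = runner.invoke(cli_main, ["coverage", "--pileup", str(tmp_path / "nope.tsv"),
                                     "--ref", str(tmp_path / "nope.fasta"),
                                     "--out-dir", str(tmp_path / "o")])
        assert r.exit_code != 0
        assert not (tmp_path / "o").exists()

    def test_unknown_subcommand_usage_exit_2(self):
        r = CliRunner().invoke(cli_main, ["frobnicate"])
        assert r.exit_code == 2
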