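"""Panel data model, TSV round trips, and strand normalization."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import popkit as pk
from popkit.panel import _COMPLEMENT


class TestPanelModel:
    def test_default_panel_has_55_unambiguous_loci(self):
        panel = pk.default_panel()
        assert len(panel) == 55
        assert len(set(panel.locus_ids)) == 55
        assert not any(l.strand_ambiguous for l in panel)

    def test_default_panel_deterministic(self):
        a, b = pk.default_panel(), pk.default_panel()
        assert a == b

    @pytest.mark.parametrize("ref,alt", [("A", "A"), ("A", "N")])
    def test_invalid_locus_alleles_rejected(self, ref, alt):
        with pytest.raises(ValueError):
            pk.Locus("bad", ref, alt)

    def test_duplicate_locus_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            pk.AisnpPanel((pk.Locus("x", "A", "G"), pk.Locus("x", "C", "T")))


class TestFrequencyTableIO:
    def test_round_trip_identity(self, toy_table, tmp_path):
        path = tmp_path / "freq.tsv"
        pk.write_frequency_table(toy_table, path)
        back = pk.read_frequency_table(path, toy_table.panel)
        assert back.pop_ids == toy_table.pop_ids
        assert [p.sample_2n for p in back.populations] == [100, 80]
        np.testing.assert_allclose(back.freq, toy_table.freq, atol=5e-7)

    def test_round_trip_at_4_decimals_within_half_ulp(self, toy_panel, tmp_path):
        rng = np.random.default_rng(7)
        pops = [pk.Population(f"P{i}", f"P{i}X", 50) for i in range(5)]
        table = pk.PopFrequencyTable(toy_panel, pops, rng.uniform(0, 1, (5, 3)))
        path = tmp_path / "freq.tsv"
        pk.write_frequency_table(table, path, decimals=4)
        back = pk.read_frequency_table(path, toy_panel)
        np.testing.assert_allclose(back.freq, table.freq, atol=5e-5)

    def test_columns_reordered_to_panel_order(self, toy_panel, tmp_path):
        path = tmp_path / "freq.tsv"
        path.write_text(
            "pop_id\tabbrev\ttwo_n\tsnpC\tsnpA\tsnpB\n"
            "PopOne\tON1\t100\t0.2\t0.5\t0.5\n"
        )
        table = pk.read_frequency_table(path, toy_panel)
        np.testing.assert_allclose(table.freq[0], [0.5, 0.5, 0.2])

    def test_out_of_range_frequency_names_cell(self, toy_panel, tmp_path):
        path = tmp_path / "freq.tsv"
        path.write_text(
            "pop_id\tabbrev\ttwo_n\tsnpA\tsnpB\tsnpC\n"
            "PopOne\tON1\t100\t0.5\t1.2\t0.2\n"
        )
        with pytest.raises(pk.ParseError, match="PopOne.*snpB"):
            pk.read_frequency_table(path, toy_panel)

    def test_missing_locus_column_is_error(self, toy_panel, tmp_path):
        path = tmp_path / "freq.tsv"
        path.write_text("pop_id\tabbrev\ttwo_n\tsnpA\tsnpB\nPopOne\tON1\t100\t0.5\t0.5\n")
        with pytest.raises(pk.ParseError, match="snpC"):
            pk.read_frequency_table(path, toy_panel)

    def test_duplicate_pop_id_is_error(self, toy_panel, tmp_path):
        path = tmp_path / "freq.tsv"
        path.write_text(
            "pop_id\tabbrev\ttwo_n\tsnpA\tsnpB\tsnpC\n"
            "P\tAAA\t100\t0.5\t0.5\t0.5\nP\tBBB\t100\t0.1\t0.1\t0.1\n"
        )
        with pytest.raises(pk.ParseError, match="duplicate"):
            pk.read_frequency_table(path, toy_panel)

    def test_empty_population_list_round_trips(self, toy_panel, tmp_path):
        table = pk.PopFrequencyTable(toy_panel, [], np.zeros((0, 3)))
        path = tmp_path / "freq.tsv"
        pk.write_frequency_table(table, path)
        back = pk.read_frequency_table(path, toy_panel)
        assert back.pop_ids == []


class TestStrandNormalization:
    def test_truth_table_all_ten_base_pairs(self):
        """Enumerate every unordered base pair against a ref=A/alt=G locus:
        direct-strand pairs code by reference-allele count, reverse-complement
        pairs are flipped first, mixed pairs are errors."""
        panel = pk.AisnpPanel((pk.Locus("s", "A", "G"),))
        comp = _COMPLEMENT
        expected: dict[str, float | None] = {}
        for a in "ACGT":
            for b in "ACGT":
                if a > b:
                    continue
                call = f"{a}/{b}"
                if {a, b} <= {"A", "G"}:
                    expected[call] = float([a, b].count("A"))
                elif {a, b} <= {comp["A"], comp["G"]}:
                    expected[call] = float([comp[a], comp[b]].count("A"))
                else:
                    expected[call] = None
        assert len(expected) == 10
        for call, want in expected.items():
            df = pd.DataFrame({"s": [call]})
            if want is None:
                with pytest.raises(pk.StrandError):
                    pk.normalize_strand(df, panel)
            else:
                got = pk.normalize_strand(df, panel).calls[0, 0]
                assert got == want, call

    @pytest.mark.parametrize(
        "call,dosage",
        [("G/G", 0.0), ("C/T", 1.0), ("C/C", 0.0), ("A/A", 2.0), ("T/T", 2.0)],
    )
    def test_specific_calls(self, call, dosage):
        panel = pk.AisnpPanel((pk.Locus("s", "A", "G"),))
        got = pk.normalize_strand(pd.DataFrame({"s": [call]}), panel)
        assert got.calls[0, 0] == dosage

    def test_idempotent_on_dosage_input(self, toy_panel):
        df = pd.DataFrame(
            {"snpA": ["2", "1"], "snpB": ["0", "."], "snpC": ["1", "2"]}
        )
        once = pk.normalize_strand(df, toy_panel)
        again = pk.normalize_strand(
            pd.DataFrame(once.calls, columns=toy_panel.locus_ids), toy_panel
        )
        np.testing.assert_array_equal(once.calls, again.calls)

    def test_ambiguous_locus_rejected_by_default_trusted_on_request(self):
        panel = pk.AisnpPanel((pk.Locus("s", "A", "T"),))
        df = pd.DataFrame({"s": ["A/T"]})
        with pytest.raises(pk.StrandError, match="ambiguous"):
            pk.normalize_strand(df, panel)
        got = pk.normalize_strand(df, panel, ambiguous_strand="trust")
        assert got.calls[0, 0] == 1.0

    def test_frequency_estimation_commutes_with_dosage_coding(self):
        """Frequencies computed from a normalized genotype matrix equal mean
        dosage / 2, whichever strand the raw calls came in on."""
        panel = pk.AisnpPanel((pk.Locus("s1", "A", "G"), pk.Locus("s2", "C", "T")))
        raw = pd.DataFrame(
            {  # s2 calls arrive reverse-complemented (G/A strand)
                "s1": ["A/A", "A/G", "G/G", "A/G"],
                "s2": ["G/G", "G/A", "A/A", "G/A"],
            }
        )
        inds = [(f"i{k}", "P") for k in range(4)]
        geno = pk.normalize_strand(raw, panel, individuals=inds)
        table = pk.frequencies_from_genotypes(geno)
        np.testing.assert_allclose(table.row("P"), geno.calls.mean(axis=0) / 2)
        np.testing.assert_allclose(table.row("P"), [0.5, 0.5])


class TestGenotypeIO:
    def test_genotype_file_round_trip_with_missing(self, toy_panel, tmp_path):
        calls = np.array([[0.0, 1.0, 2.0], [2.0, np.nan, 0.0]])
        geno = pk.GenotypeMatrix(
            toy_panel, [("i1", "PopOne"), ("i2", "PopTwo")], calls
        )
        path = tmp_path / "geno.tsv"
        pk.write_genotypes(geno, path)
        back = pk.read_genotypes(path, toy_panel)
        assert back.individuals == geno.individuals
        np.testing.assert_array_equal(back.calls, calls)

    def test_base_encoding_autodetected(self, tmp_path):
        panel = pk.AisnpPanel((pk.Locus("s", "A", "G"),))
        path = tmp_path / "geno.tsv"
        path.write_text("individual_id\tpop_id\ts\ni1\tP\tA/G\ni2\tP\tG/G\n")
        geno = pk.read_genotypes(path, panel)
        np.testing.assert_array_equal(geno.calls[:, 0], [1.0, 0.0])

    def test_bad_dosage_value_rejected(self, toy_panel):
        with pytest.raises(pk.ParseError, match="snpA"):
            pk.GenotypeMatrix(toy_panel, [("i", "P")], np.array([[3.0, 0.0, 1.0]]))
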