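"""Panel loading/validation, genotype IO, orientation, duplicate QC."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from nsburden import (
    DuplicatePair,
    VariantPanel,
    default_panel,
    duplicate_concordance,
    load_genotypes_tsv,
    load_genotypes_vcf,
    load_panel,
    qc_gate,
    resistance_panel,
)
from nsburden.genotypes import GenotypeError
from nsburden.panel import PanelError, RESISTANCE_FLIPPED, Variant


class TestPanel:
    def test_default_panel_has_nine_reported_variants(self):
        panel = default_panel()
        assert len(panel) == 9
        assert panel.get("rs1129740").risk_allele == "A"
        assert panel.get("rs1129740").gene == "HLA-DQA1"
        assert panel.get("rs3134996").gene == "HLA-DR/DQ"

    def test_resistance_orientation_flips_seven_of_nine(self):
        disease = default_panel()
        resistance = resistance_panel()
        for v in disease:
            w = resistance.get(v.rsid)
            if v.rsid in RESISTANCE_FLIPPED:
                assert (w.risk_allele, w.other_allele) == (
                    v.other_allele,
                    v.risk_allele,
                )
            else:
                assert (w.risk_allele, w.other_allele) == (
                    v.risk_allele,
                    v.other_allele,
                )
        assert resistance.get("rs1129740").risk_allele == "G"
        assert resistance.get("rs9348883").risk_allele == "A"

    def test_load_panel_round_trip(self, tmp_path):
        path = tmp_path / "panel.tsv"
        default_panel().write_tsv(path)
        assert load_panel(path) == default_panel()

    def test_load_panel_rejects_duplicate_rsid(self, tmp_path):
        path = tmp_path / "panel.tsv"
        path.write_text(
            "rsid\tgene\trisk_allele\tother_allele\n"
            "rs1\tG1\tA\tG\nrs1\tG1\tA\tG\n"
        )
        with pytest.raises(PanelError, match="rs1"):
            load_panel(path)

    def test_load_panel_rejects_empty_file(self, tmp_path):
        path = tmp_path / "panel.tsv"
        path.write_text("")
        with pytest.raises(PanelError):
            load_panel(path)

    def test_non_acgt_allele_rejected(self):
        with pytest.raises(PanelError):
            Variant("rs1", "G1", "A", "N")
        with pytest.raises(PanelError):
            Variant("rs1", "G1", "A", "A")


class TestGenotypeTSV:
    def _write(self, tmp_path, rows, header=None):
        header = header or "sample\tphenotype\trs1\trs2\trs3"
        path = tmp_path / "geno.tsv"
        path.write_text("\n".join([header, *rows]) + "\n")
        return path

    def test_allele_pairs_oriented_to_risk_allele(self, tmp_path, tiny_panel):
        path = self._write(
            tmp_path,
            ["S1\tSSNS\tA/A\tC/T\tT/T", "S2\tSRNS\tG/A\t./.\tG/T"],
        )
        gm = load_genotypes_tsv(path, tiny_panel)
        assert gm.dosage.loc["S1"].tolist() == [2.0, 1.0, 0.0]
        assert gm.dosage.at["S2", "rs1"] == 1.0
        assert math.isnan(gm.dosage.at["S2", "rs2"])
        assert gm.phenotype.tolist() == ["SSNS", "SRNS"]

    def test_dosage_digits_and_phased_calls_accepted(self, tmp_path, tiny_panel):
        path = self._write(tmp_path, ["S1\tssns\t2\tC|T\t0"])
        gm = load_genotypes_tsv(path, tiny_panel)
        assert gm.dosage.loc["S1"].tolist() == [2.0, 1.0, 0.0]
        assert gm.phenotype["S1"] == "SSNS"  # casing normalised

    def test_foreign_allele_is_an_error_naming_sample_and_variant(
        self, tmp_path, tiny_panel
    ):
        path = self._write(tmp_path, ["S1\tSSNS\tA/C\tC/C\tT/T"])
        with pytest.raises(GenotypeError, match="S1.*rs1|rs1.*S1"):
            load_genotypes_tsv(path, tiny_panel)

    def test_unparseable_cell_is_an_error_not_silent_missing(
        self, tmp_path, tiny_panel
    ):
        path = self._write(tmp_path, ["S1\tSSNS\tA/G/A\tC/C\tT/T"])
        with pytest.raises(GenotypeError):
            load_genotypes_tsv(path, tiny_panel)

    def test_unknown_phenotype_label_rejected(self, tmp_path, tiny_panel):
        path = self._write(tmp_path, ["S1\tCURED\tA/G\tC/C\tT/T"])
        with pytest.raises(GenotypeError, match="CURED"):
            load_genotypes_tsv(path, tiny_panel)

    def test_non_panel_column_dropped_with_warning(self, tmp_path, tiny_panel):
        path = self._write(
            tmp_path,
            ["S1\tSSNS\tA/G\tC/C\tT/T\tA/A"],
            header="sample\tphenotype\trs1\trs2\trs3\trs99",
        )
        with pytest.warns(UserWarning, match="rs99"):
            gm = load_genotypes_tsv(path, tiny_panel)
        assert list(gm.dosage.columns) == ["rs1", "rs2", "rs3"]

    def test_round_trip_preserves_dosages_and_missing(
        self, tmp_path, tiny_panel, matrix_factory
    ):
        gm = matrix_factory(
            tiny_panel,
            [[0, 1, 2], [None, 2, 0], [1, None, None]],
            ["SSNS", "SRNS", "UNKNOWN"],
        )
        path = tmp_path / "out.tsv"
        gm.write_tsv(path)
        back = load_genotypes_tsv(path, tiny_panel)
        pd.testing.assert_frame_equal(back.dosage, gm.dosage)
        pd.testing.assert_series_equal(back.phenotype, gm.phenotype)

    @given(
        dosages=st.lists(
            st.lists(
                st.one_of(st.none(), st.integers(0, 2)), min_size=3, max_size=3
            ),
            min_size=1,
            max_size=8,
        )
    )
    def test_orientation_flip_maps_dosage_to_two_minus_d(self, dosages):
        """Reloading with risk/other alleles swapped gives 2 - d everywhere."""
        import tempfile
        from pathlib import Path

        from conftest import make_matrix

        panel = VariantPanel(
            [
                Variant("rs1", "G1", "A", "G"),
                Variant("rs2", "G2", "C", "T"),
                Variant("rs3", "G3", "G", "T"),
            ]
        )
        gm = make_matrix(panel, dosages, ["SSNS"] * len(dosages))
        with tempfile.TemporaryDirectory() as tmp:
            path = Path(tmp) / "geno.tsv"
            gm.write_tsv(path)
            flipped = load_genotypes_tsv(path, panel.reoriented())
        expected = 2.0 - gm.dosage  # NaN propagates: missing stays missing
        pd.testing.assert_frame_equal(flipped.dosage, expected)


class TestGenotypeVCF:
    VCF_HEADER = (
        "##fileformat=VCFv4.2\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "##contig=<ID=6>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\n"
    )

    def _write(self, tmp_path, records):
        path = tmp_path / "geno.vcf"
        path.write_text(self.VCF_HEADER + "".join(records))
        return path

    def test_vcf_gt_parsing_matches_tsv_semantics(self, tmp_path, tiny_panel):
        path = self._write(
            tmp_path,
            [
                "6\t100\trs1\tA\tG\t.\t.\t.\tGT\t0/0\t0/1\n",
                "6\t200\trs2\tT\tC\t.\t.\t.\tGT\t1|1\t./.\n",
                "6\t300\trs3\tT\tG\t.\t.\t.\tGT\t0/1\t1/1\n",
            ],
        )
        gm = load_genotypes_vcf(
            path, tiny_panel, phenotypes={"S1": "SSNS", "S2": "SRNS"}
        )
        # rs1 risk=A=REF: 0/0 -> 2 copies of A; rs2 risk=C=ALT, phased same
        assert gm.dosage.loc["S1"].tolist() == [2.0, 2.0, 1.0]
        assert gm.dosage.at["S2", "rs1"] == 1.0
        assert math.isnan(gm.dosage.at["S2", "rs2"])
        assert gm.phenotype.tolist() == ["SSNS", "SRNS"]

    def test_vcf_non_panel_record_skipped_with_warning(self, tmp_path, tiny_panel):
        path = self._write(
            tmp_path,
            [
                "6\t100\trs1\tA\tG\t.\t.\t.\tGT\t0/0\t0/1\n",
                "6\t150\trs99\tA\tG\t.\t.\t.\tGT\t0/0\t0/1\n",
                "6\t200\trs2\tT\tC\t.\t.\t.\tGT\t1/1\t0/0\n",
                "6\t300\trs3\tT\tG\t.\t.\t.\tGT\t0/1\t1/1\n",
            ],
        )
        with pytest.warns(UserWarning, match="rs99"):
            gm = load_genotypes_vcf(path, tiny_panel)
        assert list(gm.dosage.columns) == tiny_panel.rsids
        assert set(gm.phenotype) == {"UNKNOWN"}

    def test_vcf_allele_mismatch_with_panel_is_error(self, tmp_path, tiny_panel):
        path = self._write(
            tmp_path,
            [
                "6\t100\trs1\tA\tC\t.\t.\t.\tGT\t0/1\t0/0\n",
                "6\t200\trs2\tT\tC\t.\t.\t.\tGT\t1/1\t0/0\n",
                "6\t300\trs3\tT\tG\t.\t.\t.\tGT\t0/1\t1/1\n",
            ],
        )
        with pytest.raises(GenotypeError, match="rs1"):
            load_genotypes_vcf(path, tiny_panel)


class TestDuplicateConcordance:
    def test_identical_duplicates_pass_gate(self, tiny_panel, matrix_factory):
        gm = matrix_factory(
            tiny_panel,
            [[0, 1, 2], [0, 1, 2]],
            ["SSNS", "SSNS"],
            samples=["A", "A_dup"],
        )
        results = duplicate_concordance(gm, [DuplicatePair("A", "A_dup")])
        assert results[0].concordance == 1.0
        assert qc_gate(results)

    def test_single_discordant_call_fails_gate(self, tiny_panel, matrix_factory):
        gm = matrix_factory(
            tiny_panel,
            [[0, 1, 2], [0, 1, 1]],
            ["SSNS", "SSNS"],
            samples=["A", "A_dup"],
        )
        results = duplicate_concordance(gm, [DuplicatePair("A", "A_dup")])
        assert results[0].concordance == pytest.approx(2 / 3)
        assert not qc_gate(results)

    def test_missing_calls_excluded_from_denominator(
        self, tiny_panel, matrix_factory
    ):
        gm = matrix_factory(
            tiny_panel,
            [[0, None, 2], [0, 1, 2]],
            ["SSNS", "SSNS"],
            samples=["A", "A_dup"],
        )
        (res,) = duplicate_concordance(gm, [DuplicatePair("A", "A_dup")])
        assert res.n_compared == 2
        assert res.concordance == 1.0
        assert qc_gate([res])

    def test_fully_missing_pair_is_incomparable_and_fails_gate(
        self, tiny_panel, matrix_factory
    ):
        gm = matrix_factory(
            tiny_panel,
            [[None, None, None], [0, 1, 2]],
            ["SSNS", "SSNS"],
            samples=["A", "A_dup"],
        )
        (res,) = duplicate_concordance(gm, [DuplicatePair("A", "A_dup")])
        assert not res.comparable
        assert not qc_gate([res])

    def test_concordance_symmetric_in_pair_order(self, tiny_panel, matrix_factory):
        gm = matrix_factory(
            tiny_panel,
            [[0, 1, 2], [0, None, 1]],
            ["SSNS", "SSNS"],
            samples=["A", "B"],
        )
        fwd, rev = duplicate_concordance(
            gm, [DuplicatePair("A", "B"), DuplicatePair("B", "A")]
        )
        assert fwd.n_compared == rev.n_compared
        assert fwd.concordance == rev.concordance
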