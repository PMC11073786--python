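"""Reading, harmonizing, QC-filtering and writing summary-statistic tables."""

import numpy as np
import pandas as pd
import pytest

from omnigwas import stats, sumstats


class TestReadSumstats:
    def test_fills_z_and_p_from_beta_se(self, tmp_path, neale_writer, make_row):
        path = neale_writer(tmp_path / "f.tsv", [
            make_row(variant="rs1", beta=-3.837, se=0.2372),
            make_row(variant="rs2", pos=2000, beta=0.0, se=1.0),
        ])
        df = sumstats.read_sumstats(path, group="female")
        assert df.loc[0, "z"] == pytest.approx(-16.176, abs=1e-3)
        assert df.loc[0, "neglog10p"] == pytest.approx(-np.log10(7.9e-59), abs=0.05)
        assert df.loc[1, "z"] == 0.0 and df.loc[1, "p"] == 1.0

    def test_fills_z_from_beta_p_when_no_se(self, tmp_path, make_row):
        row = make_row(variant="rs4308991", beta=-0.007)
        del row["se"]
        row["pval"] = 2.01e-3
        pd.DataFrame([row]).to_csv(tmp_path / "f.tsv", sep="\t", index=False)
        cmap = {**sumstats.DEFAULT_COLUMN_MAP}
        del cmap["se"]
        df = sumstats.read_sumstats(tmp_path / "f.tsv", cmap, "female")
        assert df.loc[0, "z"] == pytest.approx(-3.0888, abs=1e-3)
        assert df.loc[0, "se"] == pytest.approx(0.007 / 3.0888, rel=1e-3)

    def test_missing_mapped_column_raises_with_name(self, tmp_path, neale_writer, make_row):
        path = neale_writer(tmp_path / "f.tsv", [make_row()])
        cmap = {**sumstats.DEFAULT_COLUMN_MAP, "info": "imputation_quality"}
        with pytest.raises(ValueError, match="imputation_quality"):
            sumstats.read_sumstats(path, cmap, "female")

    def test_requires_se_or_pval_mapping(self):
        cmap = {k: v for k, v in sumstats.DEFAULT_COLUMN_MAP.items()
                if k not in ("se", "pval")}
        with pytest.raises(ValueError, match="se"):
            sumstats.read_sumstats("unused.tsv", cmap, "female")

    def test_unparseable_cell_strict_vs_skip(self, tmp_path, neale_writer, make_row):
        path = neale_writer(tmp_path / "f.tsv", [
            make_row(variant="rs1"),
            make_row(variant="rs2", pos=2000, beta="not_a_number"),
        ])
        with pytest.raises(ValueError, match="line 3"):
            sumstats.read_sumstats(path, group="female", strict=True)
        df = sumstats.read_sumstats(path, group="female", strict=False)
        assert list(df["variant"]) == ["rs1"]

    def test_parses_scientific_notation_and_x_chromosome(self, tmp_path, neale_writer, make_row):
        path = neale_writer(tmp_path / "f.tsv", [
            make_row(variant="rs_x", chr="X", se="2.37E-01"),
        ])
        df = sumstats.read_sumstats(path, group="female")
        assert df.loc[0, "chr"] == 23
        assert df.loc[0, "se"] == pytest.approx(0.237)

    def test_se_wins_over_rounded_p(self, tmp_path, neale_writer, make_row, caplog):
        # p rounded to one significant digit disagrees with beta/se by >1%
        path = neale_writer(tmp_path / "f.tsv", [
            make_row(beta=0.10, se=0.05, pval=0.06),
        ])
        with caplog.at_level("WARNING"):
            df = sumstats.read_sumstats(path, group="female")
        assert df.loc[0, "z"] == pytest.approx(2.0)
        assert any("disagree" in r.message for r in caplog.records)

    def test_as_records_round_trip_invariants(self, tmp_path, neale_writer, make_row):
        path = neale_writer(tmp_path / "f.tsv", [make_row(variant="rs1", beta=0.2, se=0.04)])
        key, assoc = next(sumstats.as_records(
            sumstats.read_sumstats(path, group="male")))
        assert key.id == "rs1" and assoc.group == "male"
        assert assoc.z == pytest.approx(assoc.beta / assoc.se, rel=1e-9)
        assert assoc.neglog10p == pytest.approx(-np.log10(assoc.p), abs=1e-6)


def _frames(neale_writer, tmp_path, female_rows, male_rows):
    f = sumstats.read_sumstats(
        neale_writer(tmp_path / "f.tsv", female_rows), group="female")
    m = sumstats.read_sumstats(
        neale_writer(tmp_path / "m.tsv", male_rows), group="male")
    return f, m


class TestHarmonize:
    def test_identical_orientation_passthrough(self, tmp_path, neale_writer, make_row):
        f, m = _frames(neale_writer, tmp_path,
                       [make_row(beta=0.3)], [make_row(beta=0.5)])
        paired, rep = sumstats.harmonize_groups(f, m)
        assert rep.n_kept == 1 and rep.n_dropped_unmatched == 0
        assert paired.loc[0, "beta_M"] == pytest.approx(0.5)

    def test_swapped_orientation_flips_male_sign(self, tmp_path, neale_writer, make_row):
        f, m = _frames(
            neale_writer, tmp_path,
            [make_row(major_allele="G", minor_allele="A", beta=0.3)],
            [make_row(major_allele="A", minor_allele="G", beta=0.5, minor_AF=0.4)],
        )
        paired, _ = sumstats.harmonize_groups(f, m)
        assert paired.loc[0, "beta_M"] == pytest.approx(-0.5)
        assert paired.loc[0, "maf_M"] == pytest.approx(0.4)
        assert paired.loc[0, "major"] == "G" and paired.loc[0, "minor"] == "A"

    def test_unmatched_variants_counted(self, tmp_path, neale_writer, make_row):
        shared = [make_row(variant=f"rs{i}", pos=1000 + i) for i in range(3)]
        f, m = _frames(
            neale_writer, tmp_path,
            shared + [make_row(variant="rsF", pos=5000)],
            shared + [make_row(variant="rsM1", pos=6000),
                      make_row(variant="rsM2", pos=7000)],
        )
        paired, rep = sumstats.harmonize_groups(f, m)
        assert len(paired) == 3
        assert rep.n_dropped_unmatched == 3
        assert rep.n_input == 6

    def test_conflicting_position_dropped(self, tmp_path, neale_writer, make_row):
        f, m = _frames(neale_writer, tmp_path,
                       [make_row(pos=1000)], [make_row(pos=1001)])
        paired, rep = sumstats.harmonize_groups(f, m)
        # one variant id in the union, dropped for the position conflict
        assert paired.empty and rep.n_dropped_unmatched == 1

    def test_orientation_invariance_of_downstream_tests(
        self, tmp_path, neale_writer, make_row
    ):
        """Flipping every allele pair and beta sign in the male file leaves
        the omnibus statistic identical and preserves signed tests relative
        to the shared minor allele."""
        male_rows = [make_row(variant=f"rs{i}", pos=1000 + i,
                              beta=0.1 * (i - 1), se=0.05) for i in range(4)]
        flipped = [dict(r, major_allele=r["minor_allele"],
                        minor_allele=r["major_allele"], beta=-r["beta"],
                        minor_AF=1 - r["minor_AF"]) for r in male_rows]
        female_rows = [make_row(variant=f"rs{i}", pos=1000 + i, beta=0.07)
                       for i in range(4)]
        f1, m1 = _frames(neale_writer, tmp_path, female_rows, male_rows)
        res1 = stats.run_all_tests(sumstats.harmonize_groups(f1, m1)[0])
        f2, m2 = _frames(neale_writer, tmp_path, female_rows, flipped)
        res2 = stats.run_all_tests(sumstats.harmonize_groups(f2, m2)[0])
        for col in ("chi2_metaQ", "z_diff", "z_metaL", "beta_M", "maf_M"):
            assert np.allclose(res1[col], res2[col])


class TestVariantQC:
    def test_drop_reasons(self, urate_paired):
        pairs = urate_paired.copy()
        pairs.loc[pairs.index[0], "maf_F"] = 0.005
        pairs.loc[pairs.index[1], "info"] = 0.79
        kept, rep = sumstats.apply_variant_qc(pairs)
        assert rep.n_dropped_maf == 1 and rep.n_dropped_info == 1
        assert rep.n_kept == len(pairs) - 2

    def test_maf_checked_in_both_sexes(self, urate_paired):
        pairs = urate_paired.copy()
        pairs.loc[pairs.index[0], "maf_M"] = 0.005  # female maf still fine
        _, rep = sumstats.apply_variant_qc(pairs)
        assert rep.n_dropped_maf == 1

    def test_published_lead_snps_all_pass(self, testosterone_paired, urate_paired):
        for pairs in (testosterone_paired, urate_paired):
            kept, rep = sumstats.apply_variant_qc(pairs)
            assert rep.n_kept == len(pairs) and rep.n_dropped_maf == 0

    def test_idempotent(self, urate_paired):
        once, _ = sumstats.apply_variant_qc(urate_paired)
        twice, rep = sumstats.apply_variant_qc(once)
        pd.testing.assert_frame_equal(once, twice)
        assert rep.n_kept == rep.n_input

    def test_qc_report_counts_validate(self):
        with pytest.raises(ValueError):
            sumstats.QCReport(n_input=5, n_kept=3, n_dropped_maf=1)


class TestWriteResults:
    def test_empty_results_header_only(self, tmp_path, urate_paired):
        from omnigwas.stats import run_all_tests

        res = run_all_tests(urate_paired).iloc[:0]
        out = tmp_path / "empty.tsv"
        sumstats.write_results(res, out)
        lines = out.read_text().strip().splitlines()
        assert len(lines) == 1 and lines[0].startswith("variant\t")

    def test_round_trip_preserves_numeric_fields(self, tmp_path, urate_paired):
        from omnigwas.stats import run_all_tests

        res = run_all_tests(urate_paired)
        out = tmp_path / "res.tsv"
        sumstats.write_results(res, out, header_comments=["test run"])
        cmap = {"variant": "variant", "chr": "chr", "pos": "pos",
                "major": "major", "minor": "minor", "info": "info",
                "n": "n_F", "maf": "maf_F", "beta": "beta_F", "se": "se_F"}
        back = sumstats.read_sumstats(out, cmap, "female")
        for ours, theirs in (("maf_F", "maf"), ("beta_F", "beta"), ("se_F", "se")):
            assert np.allclose(res[ours], back[theirs], rtol=1e-6)
        raw = pd.read_csv(out, sep="\t", comment="#")
        assert np.allclose(raw["p_metaQ"], res["p_metaQ"], rtol=1e-4)
        assert np.allclose(raw["neglog10_p_metaQ"], res["neglog10_p_metaQ"], rtol=1e-6)

    def test_published_p_metaq_column_matches_printed(self, tmp_path, urate_paired, urate_published):
        from omnigwas.stats import run_all_tests

        out = tmp_path / "urate.tsv"
        sumstats.write_results(run_all_tests(urate_paired), out)
        written = pd.read_csv(out, sep="\t")
        printed = urate_published.set_index("variant")["p_metaQ"]
        for _, row in written.iterrows():
            assert row["neglog10_p_metaQ"] == pytest.approx(
                -np.log10(printed[row["variant"]]), abs=0.2
            )
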