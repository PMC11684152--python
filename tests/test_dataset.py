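import numpy as np
import pandas as pd
import pytest

from ftmseda import (
    ValidationError,
    detect_groups,
    encode_missing,
    filter_isotopes,
    read_generalized_input,
    summarize_dataset,
    transform_scale,
    write_generalized_output,
)
from conftest import build_dataset


def write_pair(tmp_path, data_rows, mol_rows, data_cols, mol_cols):
    d = tmp_path / "edata.csv"
    m = tmp_path / "emeta.csv"
    pd.DataFrame(data_rows, columns=data_cols).to_csv(d, index=False)
    pd.DataFrame(mol_rows, columns=mol_cols).to_csv(m, index=False)
    return d, m


class TestReadGeneralizedInput:
    def test_toy_roundtrip_identity(self, tmp_path):
        d, m = write_pair(
            tmp_path,
            [["100.1", 1.0, 2.0], ["200.2", 0.0, 3.0], ["300.3", 4.0, 0.0]],
            [["100.1", "C6H12O6"], ["200.2", "CH4"], ["300.3", "C2H6"]],
            ["Mass", "s1", "s2"], ["Mass", "Formula"],
        )
        ds = read_generalized_input(d, m, mass_col="Mass")
        assert ds.n_peaks == 3 and ds.n_samples == 2
        assert ds.mol_table.loc["100.1", "C"] == 6
        assert ds.provenance[0].name == "upload"

    def test_missing_c_and_h_errors(self, tmp_path):
        d, m = write_pair(tmp_path,
                          [["100.1", 1.0]], [["100.1", 5]],
                          ["Mass", "s1"], ["Mass", "O"])
        with pytest.raises(ValidationError, match="C and H are required"):
            read_generalized_input(d, m, mass_col="Mass")

    def test_duplicate_mass_ids_named(self, tmp_path):
        d, m = write_pair(tmp_path,
                          [["100.1", 1.0], ["100.1", 2.0]],
                          [["100.1", "CH4"], ["100.2", "CH4"]],
                          ["Mass", "s1"], ["Mass", "Formula"])
        with pytest.raises(ValidationError, match="100.1"):
            read_generalized_input(d, m, mass_col="Mass")

    def test_asymmetric_mass_sets_listed(self, tmp_path):
        d, m = write_pair(tmp_path,
                          [["100.1", 1.0]], [["999.9", "CH4"]],
                          ["Mass", "s1"], ["Mass", "Formula"])
        with pytest.raises(ValidationError, match="999.9"):
            read_generalized_input(d, m, mass_col="Mass")

    def test_formula_string_parsed_to_counts(self, tmp_path):
        d, m = write_pair(tmp_path,
                          [["1", 1.0]], [["1", "C6H12O6"]],
                          ["Mass", "s1"], ["Mass", "Formula"])
        ds = read_generalized_input(d, m, mass_col="Mass")
        row = ds.mol_table.loc["1"]
        assert [row[el] for el in "CHNOSP"] == [6, 12, 0, 6, 0, 0]


class TestEncodeMissing:
    def test_missing_code_becomes_sentinel_and_idempotent(self):
        ds = build_dataset([[0.0, 5.2], [1.0, 0.0]], ["s1", "s2"],
                           formulas=["CH4", "C2H6"], encoded=False)
        once = encode_missing(ds)
        assert np.isnan(once.peak_table.loc["m1", "s1"])
        assert once.peak_table.loc["m1", "s2"] == 5.2
        twice = encode_missing(once)
        pd.testing.assert_frame_equal(once.peak_table, twice.peak_table)

    def test_commutes_with_isotope_filter(self):
        ds = build_dataset([[0.0, 5.0], [1.0, 2.0], [3.0, 0.0]], ["s1", "s2"],
                           formulas=["CH4", "C2H6", "C3H8"],
                           isotopes=["", "C13", ""], encoded=False)
        a = filter_isotopes(encode_missing(ds), isotope_value="C13")
        b = encode_missing(filter_isotopes(ds, isotope_value="C13"))
        pd.testing.assert_frame_equal(a.peak_table, b.peak_table)


class TestTransformScale:
    def test_log2(self):
        ds = build_dataset([[8.0, np.nan]], ["s1", "s2"], formulas=["CH4"])
        out = transform_scale(ds, "log2")
        assert out.peak_table.loc["m1", "s1"] == 3.0
        assert np.isnan(out.peak_table.loc["m1", "s2"])

    def test_presence_absence(self):
        ds = build_dataset([[4.0, np.nan]], ["s1", "s2"], formulas=["CH4"])
        out = transform_scale(ds, "presence_absence")
        assert out.peak_table.loc["m1", "s1"] == 1.0
        assert out.peak_table.loc["m1", "s2"] == 0.0

    def test_double_log_rejected(self):
        ds = build_dataset([[8.0]], ["s1"], formulas=["CH4"])
        logged = transform_scale(ds, "log2")
        with pytest.raises(ValidationError, match="abundance"):
            transform_scale(logged, "log10")

    def test_nonpositive_observed_value_rejected(self):
        ds = build_dataset([[-3.0]], ["s1"], formulas=["CH4"])
        with pytest.raises(ValidationError, match="missing"):
            transform_scale(ds, "ln")


class TestFilterIsotopes:
    def test_flagged_peaks_removed(self):
        ds = build_dataset(np.ones((10, 2)), ["s1", "s2"],
                           formulas=["CH4"] * 10,
                           mass_ids=[f"m{i}" for i in range(10)],
                           isotopes=["C13", "C13"] + [""] * 8)
        out = filter_isotopes(ds, isotope_value="C13")
        assert out.n_peaks == 8
        assert out.provenance[-1].name == "filter_isotopes"

    def test_none_flagged_is_identity(self):
        ds = build_dataset([[1.0]], ["s1"], formulas=["CH4"], isotopes=[""])
        assert filter_isotopes(ds).n_peaks == 1

    def test_all_flagged_errors(self):
        ds = build_dataset([[1.0]], ["s1"], formulas=["CH4"], isotopes=["C13"])
        with pytest.raises(ValidationError, match="empty dataset"):
            filter_isotopes(ds, isotope_value="C13")

    def test_missing_column_errors(self):
        ds = build_dataset([[1.0]], ["s1"], formulas=["CH4"])
        with pytest.raises(ValidationError, match="Isotope"):
            filter_isotopes(ds)


class TestDetectGroups:
    def test_substring_assignment(self):
        gd = detect_groups(["A_d01_r1", "A_d04_r1"],
                           [("d01", "Depth0.1"), ("d04", "Depth0.4")])
        assert gd.mapping == {"A_d01_r1": "Depth0.1", "A_d04_r1": "Depth0.4"}

    def test_first_match_wins_on_overlap(self):
        gd = detect_groups(["x_d01", "x_d02"], [("d0", "all"), ("d01", "one")])
        assert set(gd.mapping.values()) == {"all"}

    def test_no_match_warns_with_empty_mapping(self):
        with pytest.warns(UserWarning):
            gd = detect_groups(["a", "b"], [("zzz", "G")])
        assert gd.mapping == {}

    def test_empty_pattern_errors(self):
        with pytest.raises(ValidationError):
            detect_groups(["a"], [("", "G")])

    def test_case_sensitive_by_default(self):
        with pytest.warns(UserWarning):
            assert detect_groups(["Depth1"], [("depth", "G")]).mapping == {}
        assert detect_groups(["Depth1"], [("depth", "G")],
                             case_sensitive=False).mapping == {"Depth1": "G"}


class TestSummarize:
    def test_counts_match_bruteforce(self, toy_ds):
        s = summarize_dataset(toy_ds)
        brute = toy_ds.peak_table.notna().sum()
        assert (s["n_observed"] == brute).all()

    def test_median_of_three(self):
        ds = build_dataset([[1.0], [2.0], [3.0]], ["s1"],
                           formulas=["CH4", "C2H6", "C3H8"])
        assert summarize_dataset(ds).loc["s1", "median"] == 2.0

    def test_all_missing_sample(self):
        ds = build_dataset([[np.nan, 1.0]], ["s1", "s2"], formulas=["CH4"])
        s = summarize_dataset(ds)
        assert s.loc["s1", "n_observed"] == 0
        assert np.isnan(s.loc["s1", "median"])


def test_write_read_roundtrip_cell_for_cell(tmp_path, toy_ds):
    d, m = tmp_path / "data.csv", tmp_path / "mol.csv"
    write_generalized_output(toy_ds, d, m)
    back = encode_missing(read_generalized_input(d, m, mass_col="Mass"))
    pd.testing.assert_frame_equal(back.peak_table, toy_ds.peak_table,
                                  check_exact=True)
    assert (back.mol_table["Formula"].fillna("")
            == toy_ds.mol_table["Formula"].fillna("")).all()
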