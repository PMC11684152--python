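import numpy as np
import pandas as pd
import pytest

from ftmseda import ValidationError, compute_properties, property_summary
from ftmseda.formulas import ELEMENTS, parse_formula
from ftmseda.properties import (
    BoundarySet,
    ai_dbe,
    assign_compound_class,
    elemental_composition_class,
    elemental_ratios,
    kendrick,
    nosc_gfe,
)
from conftest import build_dataset


def counts_frame(*formulas):
    rows = [parse_formula(f) for f in formulas]
    return pd.DataFrame(rows, columns=list(ELEMENTS), dtype=float)


class TestElementalRatios:
    def test_glucose(self):
        r = elemental_ratios(counts_frame("C6H12O6"))
        assert r["OtoC"].iloc[0] == 1.0 and r["HtoC"].iloc[0] == 2.0

    def test_nicotine_n_to_c(self):
        assert elemental_ratios(counts_frame("C10H14N2"))["NtoC"].iloc[0] == 0.2

    def test_n_to_p_missing_without_p(self):
        assert np.isnan(elemental_ratios(counts_frame("C10H14N2"))["NtoP"].iloc[0])

    def test_no_carbon_gives_missing_not_exception(self):
        df = pd.DataFrame([[0, 4, 0, 0, 0, 0]], columns=list(ELEMENTS), dtype=float)
        assert elemental_ratios(df).isna().all().all()


class TestKendrick:
    def test_base_unit_identity(self):
        km, kmd = kendrick(14.01565)
        assert km == pytest.approx(14.0, abs=1e-12)
        assert kmd == pytest.approx(0.0, abs=1e-12)

    def test_homologous_series_shares_defect(self):
        masses = 284.27153 + 14.01565 * np.arange(30)
        _, kmd = kendrick(masses)
        assert np.ptp(kmd) < 1e-9

    def test_stearic_acid_hand_arithmetic(self):
        km, kmd = kendrick(284.27153)
        expect_km = 284.27153 * 14 / 14.01565
        assert km == pytest.approx(expect_km, abs=1e-12)
        assert kmd == pytest.approx(np.ceil(expect_km) - expect_km, abs=1e-12)

    def test_defect_in_unit_interval(self):
        rng = np.random.default_rng(0)
        _, kmd = kendrick(rng.uniform(50, 900, 200))
        assert ((kmd >= 0) & (kmd < 1)).all()

    def test_round_convention_flag(self):
        _, kmd = kendrick(100.5, defect="round")
        assert -0.5 <= kmd < 0.5

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(ValidationError):
            kendrick(-1.0)


class TestNoscGfe:
    @pytest.mark.parametrize("formula,nosc", [
        ("CH4", -4.0),      # fully reduced carbon
        ("CO2", 4.0),       # fully oxidized carbon (H=0 handled via frame)
        ("C6H12O6", 0.0),
    ])
    def test_hand_evaluated_oxidation_states(self, formula, nosc):
        if formula == "CO2":
            df = pd.DataFrame([[1, 0, 0, 2, 0, 0]], columns=list(ELEMENTS), dtype=float)
        else:
            df = counts_frame(formula)
        assert nosc_gfe(df)["NOSC"].iloc[0] == pytest.approx(nosc, abs=1e-12)

    def test_glucose_gfe(self):
        assert nosc_gfe(counts_frame("C6H12O6"))["GFE"].iloc[0] == pytest.approx(60.3)

    def test_gfe_affine_in_nosc(self):
        df = counts_frame("CH4", "C6H12O6", "C18H36O2", "C5H9NO4S")
        out = nosc_gfe(df)
        assert np.allclose(out["GFE"], 60.3 - 28.5 * out["NOSC"])

    def test_nosc_bounded_on_plausible_formulas(self):
        from ftmseda import SimulationConfig, simulate_dataset

        ds, _, _ = simulate_dataset(SimulationConfig(n_peaks=1000, seed=7))
        ds = compute_properties(ds, calcs=("nosc_gfe",))
        nosc = ds.mol_table["NOSC"].dropna()
        assert len(nosc) > 0
        assert ((nosc >= -4) & (nosc <= 4)).all()


class TestAiDbe:
    def test_benzene_dbe(self):
        assert ai_dbe(counts_frame("C6H6"))["DBE"].iloc[0] == 4.0

    def test_benzene_ai(self):
        assert ai_dbe(counts_frame("C6H6"))["AI"].iloc[0] == pytest.approx(2 / 3)

    def test_glucose_ai_clamped_to_zero(self):
        assert ai_dbe(counts_frame("C6H12O6"))["AI"].iloc[0] == 0.0

    def test_clamp_off_gives_missing(self):
        out = ai_dbe(counts_frame("C6H12O6"), clamp=False)
        assert np.isnan(out["AI"].iloc[0])

    def test_modified_ai_halves_oxygen(self):
        # C10H8O2: AI denominator 10-2=8, num 1+10-2-4=5 -> 0.625
        # AImod denominator 10-1=9, num 1+10-1-4=6 -> 2/3
        df = counts_frame("C10H8O2")
        out = ai_dbe(df)
        assert out["AI"].iloc[0] == pytest.approx(5 / 8)
        assert out["AImod"].iloc[0] == pytest.approx(6 / 9)


class TestElementalClass:
    @pytest.mark.parametrize("formula,label", [
        ("C6H12O6", "CHO"), ("C5H9NO4S", "CHNOS"), ("C2H6", "CH"),
        ("C10H14N2", "CHN"),
    ])
    def test_labels(self, formula, label):
        assert elemental_composition_class(counts_frame(formula)).iloc[0] == label


class TestCompoundClass:
    def test_lipid_region(self):
        r = pd.DataFrame({"OtoC": [0.05], "HtoC": [2.0]})
        assert assign_compound_class(r).iloc[0] == "Lipid"

    def test_point_outside_everything_is_other(self):
        r = pd.DataFrame({"OtoC": [2.0], "HtoC": [3.0]})
        assert assign_compound_class(r).iloc[0] == "Other"

    def test_half_open_shared_edge(self):
        # O:C = 0.3 is max-exclusive for Lipid, min-inclusive for Protein
        r = pd.DataFrame({"OtoC": [0.3], "HtoC": [2.0]})
        assert assign_compound_class(r).iloc[0] == "Protein"

    def test_overlapping_classes_joined_by_precedence(self):
        # (0.05, 1.0) is inside Unsaturated hydrocarbon and Lignin... check
        bs = BoundarySet.default()
        r = pd.DataFrame({"OtoC": [0.05], "HtoC": [0.75]})
        label = assign_compound_class(r, bs).iloc[0]
        assert label == "Condensed hydrocarbon"

    def test_custom_boundary_csv(self, tmp_path):
        p = tmp_path / "b.csv"
        p.write_text("class,ocmin,ocmax,hcmin,hcmax,precedence\n"
                     "Everything,0,10,0,10,1\n")
        bs = BoundarySet.from_csv(p)
        r = pd.DataFrame({"OtoC": [0.5], "HtoC": [1.0]})
        assert assign_compound_class(r, bs).iloc[0] == "Everything"


class TestDatasetProperties:
    def test_unassigned_peaks_missing_everywhere(self, toy_ds):
        ds = compute_properties(toy_ds)
        row = ds.mol_table.loc["m5"]  # no formula
        for col in ("OtoC", "HtoC", "NOSC", "GFE", "AI", "DBE"):
            assert np.isnan(row[col])
        assert pd.isna(row["ElementalClass"]) and pd.isna(row["CompoundClass"])

    def test_gfe_affine_across_dataset(self):
        from ftmseda import SimulationConfig, simulate_dataset
        ds, _, _ = simulate_dataset(SimulationConfig(n_peaks=200, seed=1))
        ds = compute_properties(ds)
        m = ds.mol_table.dropna(subset=["NOSC"])
        assert np.allclose(m["GFE"], 60.3 - 28.5 * m["NOSC"])

    def test_property_summary_conservation(self, toy_ds):
        ds = compute_properties(toy_ds)
        s = property_summary(ds, "NOSC")
        assert s["hist_counts"].sum() == ds.mol_table["NOSC"].notna().sum()

    def test_constant_property_degenerate_summary(self):
        ds = build_dataset([[1.0], [2.0]], ["s1"], formulas=["C2H4", "C3H6"])
        ds = compute_properties(ds)  # both NOSC = -2
        s = property_summary(ds, "NOSC")
        assert s["overall"]["min"] == s["overall"]["median"] == s["overall"]["max"]

    def test_summary_of_uncomputed_property_errors(self, toy_ds):
        with pytest.raises(ValidationError):
            property_summary(toy_ds, "NOSC")
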