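"""Formulation arithmetic, blend designs and specificity mixtures."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nirqc.design import (
    CALIBRATION_TOTAL_MG,
    VALIDATION_TOTAL_MG,
    BlendDesign,
    Formulation,
    InfeasibleDesignError,
    InvalidFormulationError,
    SpecificityMixture,
    UndefinedFractionError,
    design_table,
    dha_fraction,
    formulation_percentages,
    hgc_formulation,
    make_blend_design,
    read_design_csv,
    set_sizes,
    specificity_proof_set,
    write_design_csv,
)

# Published reference weighings for the two blend series (varied API, fixed
# API, placebo, total; mg).  These are actual balance readings, so agreement
# with the nominal design is expected only to weighing accuracy.  The first
# mass column tracks the varied API, the second the fixed API.
AZ_SERIES_CAL = {  # AZ varied, AS fixed at 100% of label
    80: (836.6, 750.0, 465.2, 2051.8),
    85: (889.1, 749.6, 413.5, 2052.2),
    90: (942.5, 750.6, 360.6, 2053.7),
    95: (993.5, 750.5, 308.2, 2052.2),
    100: (1046.5, 750.3, 256.3, 2053.1),
    105: (1099.5, 750.1, 203.4, 2053.0),
    110: (1150.8, 750.2, 151.4, 2052.4),
    115: (1206.4, 750.1, 98.8, 2055.3),
    120: (1256.6, 750.2, 46.5, 2053.3),
}
AZ_SERIES_VAL = {
    80: (418.6, 375.5, 232.4, 1026.5),
    85: (445.5, 375.2, 205.8, 1026.4),
    90: (471.5, 375.4, 180.2, 1027.1),
    95: (496.2, 375.3, 154.5, 1026.0),
    100: (523.4, 374.9, 128.1, 1026.4),
    105: (549.2, 375.6, 101.6, 1026.4),
    110: (577.8, 375.4, 76.1, 1029.3),
    115: (602.9, 375.6, 49.6, 1028.1),
    120: (628.3, 375.3, 23.6, 1027.2),
}
AS_SERIES_CAL = {  # AS varied, AZ fixed at 100% of label
    80: (602.1, 1046.5, 405.0, 2053.6),
    85: (637.5, 1046.1, 368.1, 2051.7),
    90: (675.6, 1047.0, 330.7, 2053.3),
    95: (712.6, 1046.1, 293.7, 2052.4),
    100: (749.9, 1045.0, 256.4, 2051.3),
    105: (787.8, 1047.3, 217.6, 2052.7),
    110: (824.6, 1045.9, 181.0, 2051.5),
    115: (862.3, 1047.7, 143.5, 2053.5),
    120: (900.1, 1045.5, 105.9, 2051.5),
}
AS_SERIES_VAL = {
    80: (301.8, 535.5, 202.9, 1040.2),  # anomalous weighing: total 1.3% over
    85: (319.6, 524.1, 184.4, 1028.1),
    90: (338.0, 523.4, 165.5, 1026.9),
    95: (356.8, 523.0, 146.2, 1026.0),
    100: (375.6, 523.8, 127.7, 1027.1),
    105: (395.4, 522.9, 109.2, 1027.5),
    110: (412.6, 523.1, 90.8, 1026.5),
    115: (431.9, 523.3, 71.1, 1026.3),
    120: (450.3, 523.2, 53.5, 1027.0),
}


class TestFormulationPercentages:
    def test_capsule_reference_composition(self, formulation):
        """%w/w of the capsule fill matches the published composition to the
        printed precision (0.01%)."""
        expected = {"AZ": 51.06, "AS": 36.56, "cellulose": 12.18, "silica": 0.20}
        got = dict(formulation_percentages(formulation))
        for name, pct in expected.items():
            assert got[name] == pytest.approx(pct, abs=0.01)

    @pytest.mark.parametrize(
        "components, expected",
        [
            ((("X", 42.0),), [100.0]),
            ((("A", 250.0), ("B", 250.0)), [50.0, 50.0]),
        ],
    )
    def test_identity_and_symmetry(self, components, expected):
        got = [p for _, p in formulation_percentages(Formulation(components))]
        assert got == pytest.approx(expected)

    @given(
        st.lists(st.floats(0.01, 1e5), min_size=1, max_size=8).map(
            lambda ms: Formulation(tuple((f"c{i}", m) for i, m in enumerate(ms)))
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_percentages_sum_to_100(self, form):
        pct = [p for _, p in formulation_percentages(form)]
        assert sum(pct) == pytest.approx(100.0, abs=0.01)
        assert all(p > 0 for p in pct)

    def test_duplicate_or_nonpositive_rejected(self):
        with pytest.raises(InvalidFormulationError):
            Formulation((("A", 1.0), ("A", 2.0)))
        with pytest.raises(InvalidFormulationError):
            Formulation((("A", 0.0),))


class TestBlendDesign:
    def test_az_80_percent_masses(self, formulation):
        """Nominal masses at the 80% AZ level agree with direct arithmetic
        from the label fractions."""
        d = make_blend_design(formulation, "AZ")
        w_az = formulation.mass_fraction("AZ")
        w_as = formulation.mass_fraction("AS")
        assert d.varied_mass[0] == pytest.approx(0.8 * w_az * CALIBRATION_TOTAL_MG)
        assert d.varied_mass[0] == pytest.approx(838.87, rel=1e-3)
        assert d.fixed_mass[0] == pytest.approx(w_as * CALIBRATION_TOTAL_MG)
        assert d.fixed_mass[0] == pytest.approx(750.81, rel=1e-3)
        assert d.placebo_mass[0] == pytest.approx(463.96, rel=1e-2)

    def test_as_120_percent_mass(self, formulation):
        d = make_blend_design(formulation, "AS")
        assert d.varied_mass[-1] == pytest.approx(900.97, rel=1e-3)

    def test_qsp_identity_at_100(self, formulation):
        d = make_blend_design(formulation, "AZ")
        i = d.levels.index(100.0)
        w_both = formulation.mass_fraction("AZ") + formulation.mass_fraction("AS")
        assert d.placebo_mass[i] == pytest.approx(
            CALIBRATION_TOTAL_MG * (1 - w_both)
        )

    @pytest.mark.parametrize("api", ["AZ", "AS"])
    def test_masses_sum_exactly_to_total(self, formulation, api):
        d = make_blend_design(formulation, api)
        for v, f, p in zip(d.varied_mass, d.fixed_mass, d.placebo_mass):
            assert v + f + p == pytest.approx(d.total_mass, abs=1e-9)

    def test_infeasible_design_raises(self, formulation):
        with pytest.raises(InfeasibleDesignError):
            make_blend_design(formulation, "AZ", levels=(80.0, 200.0))
        with pytest.raises(InfeasibleDesignError):
            make_blend_design(formulation, "AZ", levels=(100.0, 80.0, 120.0))

    @pytest.mark.parametrize(
        "api, total, table",
        [
            ("AZ", CALIBRATION_TOTAL_MG, AZ_SERIES_CAL),
            ("AZ", VALIDATION_TOTAL_MG, AZ_SERIES_VAL),
            ("AS", CALIBRATION_TOTAL_MG, AS_SERIES_CAL),
            ("AS", VALIDATION_TOTAL_MG, AS_SERIES_VAL),
        ],
    )
    def test_nominal_masses_match_reference_weighings(
        self, formulation, api, total, table
    ):
        """Nominal design masses agree with the reference balance readings:
        API cells to 0.5% relative, qsp placebo cells to 0.5% of the blend
        mass (the small placebo cell absorbs the APIs' weighing error).
        Rows whose recorded total is itself >0.5% off nominal are
        mis-weighings and excluded."""
        d = make_blend_design(formulation, api, total_mass=total)
        for level, (varied, fixed, placebo, row_total) in table.items():
            if abs(row_total - total) / total > 0.005:
                continue
            i = d.levels.index(float(level))
            assert d.varied_mass[i] == pytest.approx(varied, rel=5e-3)
            assert d.fixed_mass[i] == pytest.approx(fixed, rel=5e-3)
            assert abs(d.placebo_mass[i] - placebo) < 0.005 * total


class TestSetSizes:
    @pytest.mark.parametrize(
        "levels, cal_reps, val_reps, expected",
        [(9, 6, 3, (54, 27)), (1, 1, 1, (1, 1)), (9, 2, 2, (18, 18))],
    )
    def test_counts(self, levels, cal_reps, val_reps, expected):
        assert set_sizes(levels, cal_reps, val_reps) == expected


class TestSpecificityMixtures:
    def test_ten_percent_dha_label(self):
        """The '10% DHA' challenge blend has DHA at exactly 10% of AS + DHA."""
        mix = next(m for m in specificity_proof_set() if m.label == "10% DHA")
        assert dha_fraction(mix) == pytest.approx(10.00, abs=0.01)

    @pytest.mark.parametrize(
        "as_mg, dha_mg, expected", [(100.0, 0.0, 0.0), (90.0, 10.0, 10.0)]
    )
    def test_dha_fraction_arithmetic(self, as_mg, dha_mg, expected):
        mix = SpecificityMixture("t", (("AS", as_mg), ("DHA", dha_mg)))
        assert dha_fraction(mix) == pytest.approx(expected)

    def test_undefined_fraction(self):
        mix = SpecificityMixture("t", (("AZ", 100.0),))
        with pytest.raises(UndefinedFractionError):
            dha_fraction(mix)

    def test_proof_set_masses_valid(self):
        for mix in specificity_proof_set():
            assert mix.total > 0
            assert all(m >= 0 for _, m in mix.masses)


class TestDesignIO:
    def test_csv_round_trip(self, formulation, tmp_path):
        d = make_blend_design(formulation, "AZ")
        path = tmp_path / "design.csv"
        write_design_csv(d, path)
        df = read_design_csv(path)
        assert len(df) == d.n_samples
        assert set(df["level_percent"]) == set(d.levels)
        assert (df["role"] == "calibration").all()

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("a,b\n1,2\n")
        with pytest.raises(ValueError, match="missing"):
            read_design_csv(path)
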