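"""The speciation chain: elementary steps, full-sample partitioning, clamping."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fefrac as ff
from fefrac.fractionation import (
    chain,
    fe2_amorphous,
    fe2_crystalline,
    fe2_total,
    fe3_amorphous,
    fe3_crystalline,
    fe3_total,
)
from fefrac.stoichiometry import ClampWarning

# Hand-computed speciation chains for the five shipped reference samples,
# derived by running the defining subtractions on the printed inputs.
EXPECTED_CHAINS = {
    "initial": dict(
        fe3=1.53 - 0.48,
        fe3_amorphous=1.11 - 0.0 - 1.7 * 0.05 - 0.48,
        fe3_crystalline=(1.53 - 0.48) - (1.11 - 0.0 - 1.7 * 0.05 - 0.48),
        fe2=2.24 - (1.53 - 0.48),
        fe2_crystalline=(0.34 - 0.05) / 1.1 + 2.7 * 0.018 + 0.0,
        fe2_amorphous=(2.24 - 1.05) - ((0.34 - 0.05) / 1.1 + 2.7 * 0.018),
        clamp_residual=0.0,
    ),
    "U2": dict(
        fe3=1.30 - 0.28,
        fe3_amorphous=0.0,  # raw 0.80 - 0.52 - 0.042 - 0.28 = -0.042
        fe3_crystalline=1.02,
        fe2=2.13 - 1.02,
        fe2_crystalline=0.399 + 0.00066 + 0.52,
        fe2_amorphous=1.11 - (0.399 + 0.00066 + 0.52),
        clamp_residual=0.0,
    ),
    "U3": dict(
        fe3=1.76 - 0.47,
        fe3_amorphous=0.0,  # raw 0.88 - 0.53 - 0.039 - 0.47 = -0.159
        fe3_crystalline=1.29,
        fe2=2.23 - 1.29,
        fe2_crystalline=0.427 + 0.0006 + 0.53,
        fe2_amorphous=0.0,  # raw 0.94 - 0.9576 = -0.0176
        clamp_residual=(0.427 + 0.0006 + 0.53) - 0.94,
    ),
    "A2": dict(
        fe3=0.94 - 0.30,
        fe3_amorphous=0.72 - 0.17 - 0.115 - 0.30,
        fe3_crystalline=0.64 - 0.135,
        fe2=2.67 - 0.64,
        fe2_crystalline=0.421 + 0.00149 + 0.17,
        fe2_amorphous=2.03 - (0.421 + 0.00149 + 0.17),
        clamp_residual=0.0,
    ),
    "A3": dict(
        fe3=1.49 - 0.21,
        fe3_amorphous=0.75 - 0.43 - 0.095 - 0.21,
        fe3_crystalline=1.28 - 0.015,
        fe2=3.20 - 1.28,
        fe2_crystalline=0.407 + 0.00087 + 0.43,
        fe2_amorphous=1.92 - (0.407 + 0.00087 + 0.43),
        clamp_residual=0.0,
    ),
}


class TestElementarySteps:
    def test_fe3_total_examples(self):
        assert fe3_total(1.53, 0.48) == pytest.approx(1.05, abs=1e-12)
        assert fe3_total(0.94, 0.30) == pytest.approx(0.64, abs=1e-12)
        assert fe3_total(0.7, 0.0) == 0.7
        with pytest.warns(ClampWarning):
            assert fe3_total(0.2, 0.5) == 0.0

    def test_fe3_amorphous_examples(self):
        assert fe3_amorphous(0.72, 0.17, 0.115, 0.30) == pytest.approx(0.135, abs=1e-12)
        with pytest.warns(ClampWarning):
            assert fe3_amorphous(0.80, 0.52, 0.042, 0.28) == 0.0
        assert fe3_amorphous(0, 0, 0, 0) == 0.0

    def test_fe3_crystalline_examples(self):
        assert fe3_crystalline(0.64, 0.135) == pytest.approx(0.505, abs=1e-12)
        assert fe3_crystalline(1.02, 0.0) == pytest.approx(1.02)
        assert fe3_crystalline(0.4, 0.4) == 0.0

    def test_fe2_total_examples(self):
        assert fe2_total(2.67, 0.64) == pytest.approx(2.03, abs=1e-12)
        assert fe2_total(2.23, 1.29) == pytest.approx(0.94, abs=1e-12)
        assert fe2_total(1.5, 0.0) == 1.5

    def test_fe2_crystalline_examples(self):
        assert fe2_crystalline(0.399, 0.00066, 0.52) == pytest.approx(0.91966, abs=1e-12)
        assert fe2_crystalline(0.407, 0.00087, 0.43) == pytest.approx(0.83787, abs=1e-12)
        assert fe2_crystalline(0, 0, 0) == 0.0

    def test_fe2_amorphous_examples(self):
        assert fe2_amorphous(2.03, 0.59249) == pytest.approx(1.43751, abs=1e-12)
        with pytest.warns(ClampWarning):
            assert fe2_amorphous(0.94, 0.9576) == 0.0
        assert fe2_amorphous(0.7, 0.0) == 0.7


class TestSpeciateFixtures:
    @pytest.mark.parametrize("sample_id", list(EXPECTED_CHAINS))
    def test_chain_matches_hand_arithmetic(self, fixture_speciation, sample_id):
        """Full chains on the reference samples reproduce the hand-derived
        values to 1e-9."""
        spec = fixture_speciation[sample_id]
        for pool, expected in EXPECTED_CHAINS[sample_id].items():
            assert getattr(spec, pool) == pytest.approx(expected, abs=1e-9), pool

    def test_clamps_logged_with_raw_values(self, fixture_speciation):
        u2, u3 = fixture_speciation["U2"], fixture_speciation["U3"]
        assert u2.raw["fe3_amorphous"] == pytest.approx(-0.042, abs=1e-9)
        assert u3.raw["fe3_amorphous"] == pytest.approx(-0.159, abs=1e-9)
        assert u3.raw["fe2_amorphous"] == pytest.approx(-0.0176, abs=1e-9)
        assert any("fe3_amorphous" in w for w in u2.warnings)
        assert any("fe2_amorphous" in w for w in u3.warnings)

    def test_amended_amorphous_fe2_exceeds_unamended(self, fixture_speciation):
        """Carbon amendment drives Fe into the amorphous ferrous pool."""
        s = fixture_speciation
        assert s["A2"].fe2_amorphous > s["U2"].fe2_amorphous
        assert s["A3"].fe2_amorphous > s["U3"].fe2_amorphous

    def test_fes_share_of_amorphous_fe2(self, fixture_speciation):
        a2 = ff.fes_share_of_amorphous_fe2(fixture_speciation["A2"])
        a3 = ff.fes_share_of_amorphous_fe2(fixture_speciation["A3"])
        assert a2 == pytest.approx(100 * 0.115 / 1.43751, abs=1e-6)
        assert a3 == pytest.approx(100 * 0.095 / 1.08213, abs=1e-6)
        # U3's amorphous FeII clamps to zero: the share is undefined, not 0
        assert ff.fes_share_of_amorphous_fe2(fixture_speciation["U3"]) is None


class TestSpeciateBehaviour:
    def _measurements(self, **overrides):
        base = dict(
            fe_total=ff.Measurement(2.0),
            fe2_ferrozine=ff.Measurement(0.3),
            fe_dcb=ff.Measurement(1.0),
            fe_aod=ff.Measurement(0.8),
            fe_fes=ff.Measurement(0.1),
            fe_pyrite=ff.Measurement(0.2),
            fe_siderite=ff.Measurement(0.2),
            fe_vivianite=ff.Measurement(0.01),
        )
        base.update(overrides)
        return ff.ExtractionMeasurements(**{k: v for k, v in base.items() if v is not None})

    def test_all_zero_measurements_give_all_zero_speciation(self):
        m = self._measurements(
            fe_total=ff.Measurement(0), fe2_ferrozine=ff.Measurement(0),
            fe_dcb=ff.Measurement(0), fe_aod=ff.Measurement(0),
            fe_fes=ff.Measurement(0), fe_pyrite=ff.Measurement(0),
            fe_siderite=ff.Measurement(0), fe_vivianite=ff.Measurement(0),
        )
        spec = ff.speciate(ff.SampleMetadata("zero"), m)
        assert spec.fe3 == spec.fe2 == spec.fe2_amorphous == 0.0
        assert spec.clamp_residual == 0.0
        assert spec.warnings == []

    def test_missing_mineral_input_rejected_with_field_name(self):
        m = self._measurements(fe_siderite=None)
        with pytest.raises(ValueError, match="fe_siderite"):
            ff.speciate(ff.SampleMetadata("x"), m)

    def test_derived_column_precedence_logs_discrepancy(self):
        """When both raw S and a derived pyrite column are present, the
        derived column wins and the disagreement is logged."""
        m = self._measurements(
            s_avs=ff.Measurement(0.05), s_crr=ff.Measurement(0.34),
            fe_fes=ff.Measurement(0.085),
        )
        spec = ff.speciate(ff.SampleMetadata("x"), m)
        assert spec.fe2_components["pyrite"] == 0.2  # derived, not 0.29/1.1
        assert any("fe_pyrite" in w and "overrides" in w for w in spec.warnings)

    def test_raw_inputs_used_when_derived_absent(self, paper_ratios):
        m = self._measurements(
            fe_fes=None, fe_pyrite=None,
            s_avs=ff.Measurement(0.05), s_crr=ff.Measurement(0.34),
        )
        spec = ff.speciate(ff.SampleMetadata("x"), m, paper_ratios)
        assert spec.fe2_components["fes"] == pytest.approx(0.085)
        assert spec.fe2_components["pyrite"] == pytest.approx(0.29 / 1.1)

    def test_solids_fraction_rescales_whole_basis_fields(self):
        """Whole-suspension S and P measurements are divided by the solids
        fraction; solid-phase extraction totals are not."""
        m = self._measurements(fe_fes=None, s_avs=ff.Measurement(0.05), s_crr=None,
                               fe_pyrite=ff.Measurement(0.2))
        half = ff.speciate(ff.SampleMetadata("x", solids_fraction=0.5), m)
        full = ff.speciate(ff.SampleMetadata("x", solids_fraction=1.0), m)
        assert half.fe2_components["fes"] == pytest.approx(2 * full.fe2_components["fes"])
        assert half.fe3 == full.fe3

    def test_strict_mode_raises_on_clamp(self, fixture_records):
        meta, m = fixture_records["U3"]
        with pytest.raises(ff.ClampError):
            ff.speciate(meta, m, strict=True)

    def test_implausible_ordering_flagged_not_rejected(self):
        m = self._measurements(fe2_ferrozine=ff.Measurement(1.5))  # > fe_dcb
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            spec = ff.speciate(ff.SampleMetadata("x"), m)
        assert any("exceeds fe_dcb" in w for w in spec.warnings)

    def test_monotonicity_in_fe_dcb(self):
        """With no clamps active, raising fe_dcb by delta moves delta of Fe
        from the ferrous to the ferric pool."""
        m0 = self._measurements()
        m1 = self._measurements(fe_dcb=ff.Measurement(1.1))
        s0 = ff.speciate(ff.SampleMetadata("x"), m0)
        s1 = ff.speciate(ff.SampleMetadata("x"), m1)
        assert s1.fe3 - s0.fe3 == pytest.approx(0.1, abs=1e-12)
        assert s0.fe2 - s1.fe2 == pytest.approx(0.1, abs=1e-12)


class TestConservation:
    @given(
        st.lists(st.floats(0, 10, allow_nan=False, allow_infinity=False),
                 min_size=8, max_size=8)
    )
    @settings(max_examples=300, deadline=None)
    def test_pools_sum_to_total_plus_residual(self, vals):
        """For any non-negative input, the four pools sum to fe_total plus
        exactly the clamped mass, and the residual is zero without clamps."""
        c = chain(*vals)
        total = (c["fe3_amorphous"] + c["fe3_crystalline"]
                 + c["fe2_crystalline"] + c["fe2_amorphous"])
        assert total == pytest.approx(c["fe_total"] + c["clamp_residual"],
                                      rel=1e-12, abs=1e-9)
        if not c["clamped_any"]:
            assert c["clamp_residual"] == 0.0

    def test_residual_zero_iff_no_conservation_clamp(self, fixture_speciation):
        for sid, spec in fixture_speciation.items():
            pools = sum(spec.pools().values())
            assert pools == pytest.approx(spec.fe_total + spec.clamp_residual, abs=1e-9)

    def test_fe3_split_exact(self, fixture_speciation):
        for spec in fixture_speciation.values():
            assert spec.fe3_amorphous + spec.fe3_crystalline == pytest.approx(spec.fe3, abs=1e-12)
            assert spec.fe3 + spec.fe2 == pytest.approx(spec.fe_total, abs=1e-9)
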