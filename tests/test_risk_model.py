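"""Unit and property tests for the deterministic dose → risk engine."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pterisk import published
from pterisk import risk_model as rm
from pterisk.errors import ConfigError, DomainError, NoReferenceValue, NoSlopeFactor


@pytest.fixture
def plain_constants():
    return rm.ExposureConstants(ingestion_rate=100, inhalation_rate=20, skin_adherence=0.07)


class TestDoseEquations:
    def test_oral_dose_hand_value(self, plain_constants):
        # 100*100*1e-6*350*10 / (70*3650), checked by hand
        r = rm.ReceptorProfile("adult", 70, 10, 5700)
        add = rm.add_oral(100.0, plain_constants, r)
        assert add == pytest.approx(1.3699e-4, rel=1e-4)

    def test_inhalation_dust_hand_value(self, plain_constants):
        r = rm.ReceptorProfile("adult", 70, 10, 5700)
        add = rm.add_inhalation(1360.0, plain_constants, r, mode="dust")
        assert add == pytest.approx(2.7397e-7, rel=1e-4)

    def test_dermal_hand_value(self, plain_constants):
        r = rm.ReceptorProfile("adult", 70, 5, 2000)
        add = rm.add_dermal(1000.0, plain_constants, r)
        assert add == pytest.approx(1.9178e-6, rel=1e-4)

    @pytest.mark.parametrize("fn,kwargs", [
        (rm.add_oral, {}),
        (rm.add_inhalation, {"mode": "dust"}),
        (rm.add_inhalation, {"mode": "air"}),
        (rm.add_dermal, {}),
    ])
    def test_zero_concentration_gives_zero_dose(self, fn, kwargs, plain_constants, adult):
        assert fn(0.0, plain_constants, adult, **kwargs) == 0.0

    @pytest.mark.parametrize("fn", [rm.add_oral, rm.add_inhalation, rm.add_dermal])
    def test_negative_concentration_rejected(self, fn, plain_constants, adult):
        with pytest.raises(DomainError):
            fn(-1.0, plain_constants, adult)

    def test_unknown_inhalation_mode_rejected(self, plain_constants, adult):
        with pytest.raises(ConfigError):
            rm.add_inhalation(1.0, plain_constants, adult, mode="vapour")

    def test_air_mode_skips_pef(self, plain_constants, adult):
        dust = rm.add_inhalation(5.0, plain_constants, adult, mode="dust")
        air = rm.add_inhalation(5.0, plain_constants, adult, mode="air")
        assert air / dust == pytest.approx(plain_constants.particulate_emission_factor)

    def test_doubling_pef_halves_inhalation_dose(self, plain_constants, adult):
        doubled = rm.with_constants(
            plain_constants,
            particulate_emission_factor=2 * plain_constants.particulate_emission_factor,
        )
        assert rm.add_inhalation(7.0, doubled, adult) == pytest.approx(
            rm.add_inhalation(7.0, plain_constants, adult) / 2
        )

    def test_dermal_child_adult_ratio_equals_adherence_ratio(self):
        # identical receptor physiology, group-specific adherence only
        adult_c = rm.default_constants("adult")
        child_c = rm.default_constants("child")
        r = rm.ReceptorProfile("adult", 50, 5, 3000)
        ratio = rm.add_dermal(10, child_c, r) / rm.add_dermal(10, adult_c, r)
        assert ratio == pytest.approx(0.2 / 0.07)

    @pytest.mark.parametrize("ed", [1.0, 5.0, 30.0])
    def test_residential_averaging_cancels_exposure_duration(self, ed, plain_constants):
        baseline = rm.ReceptorProfile("adult", 70, 1.0, 5700)
        varied = rm.ReceptorProfile("adult", 70, ed, 5700)
        for fn in (rm.add_oral, rm.add_inhalation, rm.add_dermal):
            a, b = fn(42.0, plain_constants, baseline), fn(42.0, plain_constants, varied)
            assert abs(a - b) <= 1e-12 * a

    def test_lifetime_averaging_scales_with_exposure_duration(self, plain_constants):
        short = rm.ReceptorProfile("adult", 70, 5, 5700)
        long = rm.ReceptorProfile("adult", 70, 30, 5700)
        add_s = rm.add_oral(10, plain_constants, short, rm.LIFETIME)
        add_l = rm.add_oral(10, plain_constants, long, rm.LIFETIME)
        assert add_l / add_s == pytest.approx(6.0)

    @given(c=st.floats(1e-6, 1e6), k=st.floats(1e-3, 1e3))
    def test_dose_linear_in_concentration(self, c, k):
        constants = rm.ExposureConstants(100, 20, 0.07)
        r = rm.ReceptorProfile("adult", 70, 10, 5700)
        for fn in (rm.add_oral, rm.add_inhalation, rm.add_dermal):
            assert fn(k * c, constants, r) == pytest.approx(k * fn(c, constants, r), rel=1e-12)

    @given(bw1=st.floats(10, 100), bw2=st.floats(10, 100))
    def test_dose_strictly_decreasing_in_body_weight(self, bw1, bw2):
        if bw1 == bw2:
            return
        lo, hi = sorted([bw1, bw2])
        constants = rm.ExposureConstants(100, 20, 0.07)
        light = rm.ReceptorProfile("adult", lo, 10, 5700)
        heavy = rm.ReceptorProfile("adult", hi, 10, 5700)
        assert rm.add_oral(10, constants, light) > rm.add_oral(10, constants, heavy)


class TestConstantsValidation:
    def test_zero_abs_rejected_by_default(self):
        with pytest.raises(DomainError):
            rm.ExposureConstants(100, 20, 0.07, dermal_absorption=0.0)

    def test_zero_abs_allowed_with_override_and_zeroes_dose(self, adult):
        degenerate = rm.ExposureConstants(100, 20, 0.07, dermal_absorption=0.0,
                                          allow_degenerate=True)
        assert rm.add_dermal(100.0, degenerate, adult) == 0.0

    @pytest.mark.parametrize("kwargs", [
        {"exposure_frequency": 0}, {"exposure_frequency": 366},
        {"ingestion_rate": -1}, {"particulate_emission_factor": 0},
        {"dermal_absorption": 1.5},
    ])
    def test_invalid_constants_rejected(self, kwargs):
        base = dict(ingestion_rate=100, inhalation_rate=20, skin_adherence=0.07)
        base.update(kwargs)
        with pytest.raises(DomainError):
            rm.ExposureConstants(**base)

    def test_receptor_below_one_year_residence_rejected(self):
        with pytest.raises(DomainError):
            rm.ReceptorProfile("adult", 70, 0.5, 5700)

    def test_packaged_defaults_match_intake_handbook_grid(self):
        adult = rm.default_constants("adult")
        child = rm.default_constants("child")
        assert (adult.ingestion_rate, child.ingestion_rate) == (100, 200)
        assert (adult.inhalation_rate, child.inhalation_rate) == (20, 7.6)
        assert (adult.skin_adherence, child.skin_adherence) == (0.07, 0.2)
        assert adult.exposure_frequency == 350
        assert adult.particulate_emission_factor == 1.36e9
        assert adult.conversion_factor == 1e-6
        assert adult.dermal_absorption == 0.001

    def test_packaged_toxicity_grid_spot_values(self, toxicity):
        assert toxicity["As"].rfd_ingestion == 3.00e-4
        assert toxicity["As"].csf_ingestion == 1.5e-3
        assert toxicity["Cr"].csf_inhalation == 41.0
        assert toxicity["Pb"].csf_dermal == 4.2e-1
        for el in ("Al", "Cu", "Ni", "Zn"):
            assert toxicity[el].csf_ingestion is None

    def test_yaml_override_changes_single_constant(self, tmp_path):
        override = tmp_path / "override.yaml"
        override.write_text("exposure:\n  adult:\n    exposure_frequency: 180\n")
        adult = rm.default_constants("adult", config_path=override)
        assert adult.exposure_frequency == 180
        assert adult.ingestion_rate == 100  # untouched keys keep defaults


class TestHazardAndCancer:
    def test_hq_is_ratio_identity(self, toxicity):
        assert rm.hazard_quotient(3e-4, toxicity["As"], "ingestion") == pytest.approx(1.0)
        assert rm.hazard_quotient(0.0, toxicity["As"], "dermal") == 0.0
        assert rm.hazard_quotient(1.2e-3, toxicity["As"], "ingestion") == pytest.approx(4.0)

    def test_hq_decreasing_in_reference_dose(self):
        weak = rm.ToxicityReference("As", 3e-4, 3e-4, 3e-4)
        strong = rm.ToxicityReference("As", 3e-4, 3e-2, 3e-4)
        assert rm.hazard_quotient(1e-3, weak, "ingestion") > \
            rm.hazard_quotient(1e-3, strong, "ingestion")

    def test_missing_reference_raises_not_zero(self):
        ref = rm.ToxicityReference("Al", 1e-1, 4e-4, 5e-3)
        with pytest.raises(NoSlopeFactor):
            ref.slope_for("ingestion")

    def test_unknown_route_rejected(self, toxicity):
        with pytest.raises(ConfigError):
            toxicity["As"].reference_for("gavage")

    def test_hazard_index_single_entry(self):
        hi = rm.hazard_index([0.5])
        assert hi.value == 0.5
        assert "not expected" in hi.classification

    def test_hazard_index_classification_threshold(self):
        assert "may appear" in rm.hazard_index([0.6, 0.6]).classification

    def test_hazard_index_empty_rejected(self):
        with pytest.raises(DomainError):
            rm.hazard_index([])

    def test_cancer_risk_hand_values(self, toxicity):
        assert rm.cancer_risk(2e-5, toxicity["Cr"].csf_ingestion) == pytest.approx(1.0e-5)
        assert rm.cancer_risk(1e-3, toxicity["As"].csf_ingestion) == pytest.approx(1.5e-6)
        assert rm.cancer_risk(0.0, 0.5) == 0.0

    def test_cancer_risk_clamped_at_certainty(self):
        with pytest.warns(UserWarning, match="clamped"):
            assert rm.cancer_risk(1.0, 41.0) == 1.0

    def test_cancer_risk_requires_slope(self):
        with pytest.raises(NoSlopeFactor):
            rm.cancer_risk(1e-5, None)

    def test_total_cancer_risk_bands(self):
        assert rm.total_cancer_risk([1e-7]).classification == "negligible"
        assert rm.total_cancer_risk([5e-5]).classification == "acceptable/low"
        assert rm.total_cancer_risk([2e-4]).classification == "unacceptable"
        zero = rm.total_cancer_risk([0.0, 0.0])
        assert zero.value == 0.0 and zero.classification == "negligible"

    @given(st.lists(st.floats(0, 10), min_size=1, max_size=30))
    def test_aggregates_conserve_sums_and_dominate_max(self, hqs):
        hi = rm.hazard_index(hqs)
        assert hi.value == pytest.approx(math.fsum(hqs), abs=1e-12)
        assert hi.value >= max(hqs)


class TestAssessReceptor:
    def test_zero_concentrations_zero_risk(self, adult):
        out = rm.assess_receptor({el: 0.0 for el in rm.ELEMENTS}, adult)
        assert out.hi.value == 0.0
        assert out.tcr.value == 0.0

    def test_missing_elements_listed(self, adult):
        with pytest.raises(DomainError, match="Cu.*Zn|Zn.*Cu"):
            rm.assess_receptor({"Al": 1, "As": 1, "Cr": 1, "Ni": 1, "Pb": 1}, adult)

    def test_single_route_hi_equals_single_hq(self, adult, toxicity):
        conc = {el: 0.0 for el in rm.ELEMENTS}
        conc["As"] = 50.0
        out = rm.assess_receptor(conc, adult, routes=("ingestion",))
        assert out.hi.value == pytest.approx(out.hq[("As", "ingestion")])
        assert out.tcr.value == pytest.approx(out.cr[("As", "ingestion")])

    def test_carcinogen_set_is_as_cr_pb_only(self, adult):
        out = rm.assess_receptor({el: 5.0 for el in rm.ELEMENTS}, adult)
        assert sorted({el for el, _ in out.cr}) == ["As", "Cr", "Pb"]
        assert len(out.hq) == 21  # 7 elements x 3 routes

    def test_matches_route_by_route_recomposition(self, adult, toxicity):
        # self-consistency oracle: rebuild from the elementary operations
        rng_conc = {el: float(3 + i) for i, el in enumerate(rm.ELEMENTS)}
        constants = rm.default_constants("adult")
        out = rm.assess_receptor(rng_conc, adult, constants=constants, refs=toxicity)
        for el in rm.ELEMENTS:
            c = rng_conc[el]
            expected = {
                "ingestion": rm.add_oral(c, constants, adult),
                "inhalation": rm.add_inhalation(c, constants, adult),
                "dermal": rm.add_dermal(c, constants, adult),
            }
            for route, dose in expected.items():
                assert out.add[(el, route)] == dose
                assert out.hq[(el, route)] == rm.hazard_quotient(dose, toxicity[el], route)
        assert out.hi.value == pytest.approx(math.fsum(out.hq.values()), abs=1e-15)
        assert out.tcr.value == pytest.approx(math.fsum(out.cr.values()), abs=1e-15)

    def test_to_frame_has_summary_rows(self, adult):
        frame = rm.assess_receptor({el: 1.0 for el in rm.ELEMENTS}, adult).to_frame()
        assert list(frame.columns) == ["element", "route", "ADD", "HQ", "CR"]
        assert {"HI", "TCR"} <= set(frame["element"])


class TestPublishedAggregationIdentities:
    """Summing the published per-route entries reproduces the published totals."""

    @pytest.mark.parametrize("group", ["adult", "child"])
    def test_hazard_index_matches_published(self, group):
        hi = rm.hazard_index(published.HQ_TABLE[group])
        assert hi.value == pytest.approx(published.REPORTED_HI[group], rel=0.02)

    @pytest.mark.parametrize("group", ["adult", "child"])
    def test_total_cancer_risk_matches_published(self, group):
        tcr = rm.total_cancer_risk(published.CR_TABLE[group])
        assert tcr.value == pytest.approx(published.REPORTED_TCR[group], rel=0.02)

    def test_child_hazard_classified_as_concerning(self):
        assert "may appear" in rm.hazard_index(published.HQ_TABLE["child"]).classification
        assert "not expected" in rm.hazard_index(published.HQ_TABLE["adult"]).classification

    def test_child_cancer_risk_classified_unacceptable(self):
        assert rm.total_cancer_risk(published.CR_TABLE["child"]).classification == "unacceptable"
        assert rm.total_cancer_risk(published.CR_TABLE["adult"]).classification == "acceptable/low"
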