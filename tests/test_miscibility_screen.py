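"""Flory-Huggins chi, pair assessment and the ranked screening report."""

import dataclasses
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hspscreen import (
    ChiCategory,
    ChiContext,
    HSPComponents,
    RaCategory,
    Role,
    Substance,
    SyntheticSpec,
    assess_pair,
    classify_by_chi,
    flory_huggins_chi,
    generate_synthetic_excipients,
    screen,
    total_parameter,
)

R_TIMES_T = 8.314 * 298.0  # J/mol


def _sub(name, dd, dp, dh, role=Role.POLYMER, inorganic=False):
    return Substance(name=name, role=role, hsp=HSPComponents(dd, dp, dh), inorganic=inorganic)


DRUG = _sub("drug", 17.29, 8.2, 11.2, role=Role.DRUG)


class TestFloryHugginsChi:
    def test_zero_when_totals_equal(self):
        ctx = ChiContext(drug_molar_volume=200.0)
        clone = _sub("clone", 17.29, 8.2, 11.2)
        assert flory_huggins_chi(DRUG, clone, ctx) == 0.0

    def test_hpmc_hand_arithmetic_at_vm_230(self, fixture):
        # independent closed-form: 230 * (sqrt(491.6241) - sqrt(525.61))^2 / RT
        ctx = ChiContext(drug_molar_volume=230.0)
        chi = flory_huggins_chi(fixture.drug, fixture.substance("HPMC 606"), ctx)
        expected = 230.0 * (math.sqrt(491.6241) - math.sqrt(525.61)) ** 2 / R_TIMES_T
        assert chi == pytest.approx(expected, abs=1e-12)
        assert chi == pytest.approx(0.053, abs=0.001)

    def test_inorganic_carrier_is_not_applicable(self, fixture, chi_context):
        assert flory_huggins_chi(fixture.drug, fixture.substance("SBA-15"), chi_context) is None

    def test_missing_context_is_an_error(self, fixture):
        with pytest.raises(ValueError):
            flory_huggins_chi(fixture.drug, fixture.substance("PVP K30"), None)
        with pytest.raises(ValueError):
            ChiContext(drug_molar_volume=-5.0)

    @settings(derandomize=True, max_examples=200)
    @given(
        dd=st.floats(0, 30, allow_nan=False),
        dp=st.floats(0, 30, allow_nan=False),
        dh=st.floats(0, 30, allow_nan=False),
        vm=st.floats(10, 1000, allow_nan=False),
    )
    def test_nonnegative_and_zero_iff_equal_totals(self, dd, dp, dh, vm):
        exc = _sub("x", dd, dp, dh)
        ctx = ChiContext(drug_molar_volume=vm)
        chi = flory_huggins_chi(DRUG, exc, ctx)
        assert chi >= 0
        assert (chi == 0) == (
            total_parameter(exc.hsp) == total_parameter(DRUG.hsp)
        )

    def test_linear_in_molar_volume(self, fixture):
        exc = fixture.substance("PVP K30")
        chi_1 = flory_huggins_chi(fixture.drug, exc, ChiContext(drug_molar_volume=50.0))
        chi_10 = flory_huggins_chi(fixture.drug, exc, ChiContext(drug_molar_volume=500.0))
        assert chi_10 == pytest.approx(10.0 * chi_1, rel=1e-12)

    def test_strictly_increasing_in_total_gap(self):
        ctx = ChiContext(drug_molar_volume=200.0)
        gaps = []
        for dh in (11.2, 13.0, 15.0, 18.0):
            chi = flory_huggins_chi(DRUG, _sub("x", 17.29, 8.2, dh), ctx)
            gaps.append(chi)
        assert gaps == sorted(gaps) and len(set(gaps)) == len(gaps)


class TestClassifyByChi:
    @pytest.mark.parametrize(
        ("chi", "expected"),
        [
            (0.076, ChiCategory.MISCIBLE),
            (0.6, ChiCategory.NOT_MISCIBLE),
            (0.5, ChiCategory.NOT_MISCIBLE),  # strict inequality at the cut-off
            (None, ChiCategory.NOT_APPLICABLE),
        ],
    )
    def test_categories(self, chi, expected):
        assert classify_by_chi(chi) is expected

    def test_negative_chi_rejected(self):
        with pytest.raises(ValueError):
            classify_by_chi(-0.1)


class TestAssessPair:
    def test_identical_hsp_is_doubly_miscible(self, chi_context):
        clone = _sub("clone", 17.29, 8.2, 11.2)
        a = assess_pair(DRUG, clone, chi_context)
        assert a.ra == 0.0 and a.chi == 0.0
        assert a.ra_class is RaCategory.MISCIBLE
        assert a.chi_class is ChiCategory.MISCIBLE

    def test_pvp_pair_from_fixture(self, fixture, chi_context):
        a = assess_pair(fixture.drug, fixture.substance("PVP K30"), chi_context)
        assert a.ra == pytest.approx(2.5566, abs=1e-4)
        assert a.ra_class is RaCategory.MISCIBLE

    def test_sba15_chi_not_applicable(self, fixture, chi_context):
        a = assess_pair(fixture.drug, fixture.substance("SBA-15"), chi_context)
        assert a.chi is None and a.chi_class is ChiCategory.NOT_APPLICABLE

    def test_non_drug_first_argument_rejected(self, fixture, chi_context):
        with pytest.raises(ValueError, match="role 'drug'"):
            assess_pair(fixture.substance("PVP K30"), fixture.drug, chi_context)

    def test_printed_value_discrepancy_noted(self, fixture, chi_context):
        a = assess_pair(
            fixture.drug,
            fixture.substance("PVP K30"),
            chi_context,
            printed_ra=fixture.printed_ra["PVP K30"],
        )
        assert any("4.11" in note and "2.56" in note for note in a.notes)


class TestScreen:
    def test_single_excipient_report(self, fixture, chi_context):
        report = screen(fixture.drug, [fixture.substance("PVP K30")], chi_context)
        assert len(report.assessments) == 1
        assert report.best_per_role == {"polymer": "PVP K30"}

    def test_fixture_screen_sorted_and_complete(self, fixture, chi_context):
        report = screen(fixture.drug, fixture.excipients, chi_context)
        assert len(report.assessments) == len(fixture.excipients)
        ras = [a.ra for a in report.assessments]
        assert ras == sorted(ras)

    def test_hpmc_has_lowest_chi_among_polymers(self, fixture, chi_context):
        report = screen(fixture.drug, fixture.excipients, chi_context)
        polymer_chis = {
            a.excipient: a.chi for a in report.assessments if a.role is Role.POLYMER
        }
        assert min(polymer_chis, key=polymer_chis.get) == "HPMC 606"
        assert report.best_per_role["polymer"] == "HPMC 606"

    def test_drug_clone_ranks_first(self, fixture, chi_context):
        clone = _sub("clone-of-drug", 17.29, 8.2, 11.2, role=Role.COFORMER)
        report = screen(fixture.drug, fixture.excipients + [clone], chi_context)
        assert report.assessments[0].excipient == "clone-of-drug"

    def test_empty_and_duplicate_inputs_rejected(self, fixture, chi_context):
        with pytest.raises(ValueError, match="non-empty"):
            screen(fixture.drug, [], chi_context)
        pvp = fixture.substance("PVP K30")
        with pytest.raises(ValueError, match="duplicate"):
            screen(fixture.drug, [pvp, pvp], chi_context)

    def test_report_regeneration_is_byte_identical(self, fixture, chi_context):
        def make():
            report = screen(
                fixture.drug,
                fixture.excipients,
                chi_context,
                printed_ra=fixture.printed_ra,
                printed_chi=fixture.printed_chi,
            )
            return report.to_csv(), report.to_markdown()

        assert make() == make()

    def test_screen_against_synthetic_population(self, chi_context):
        excipients = generate_synthetic_excipients(SyntheticSpec(n=50, seed=11))
        report = screen(DRUG, list(excipients), chi_context)
        assert len(report.assessments) == 50
        for a in report.assessments:
            assert a.ra >= 0
            if a.chi is None:
                assert a.chi_class is ChiCategory.NOT_APPLICABLE
            else:
                assert a.chi >= 0
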