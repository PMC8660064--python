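import math

import pytest

from sedem.errors import (
    InputValidationError,
    InsufficientDataError,
    InvalidMeasurementError,
)
from sedem.reference import PUNCH_DIAMETER_MM
from sedem.tablet_qc import (
    TabletBatchQC,
    batch_report,
    dissolution_profile,
    drug_content,
    friability,
    release_at,
    specific_crushing_strength,
    tensile_strength,
    weight_variation,
)


class TestTensileStrength:
    def test_trial5_reference(self):
        assert tensile_strength(12.07, 10.5, 3.34) == pytest.approx(0.219, abs=0.001)

    def test_trial8_reference(self):
        assert tensile_strength(5.3, 10.5, 3.61) == pytest.approx(0.089, abs=0.001)

    def test_vanishes_with_force(self):
        assert tensile_strength(1e-9, 10.5, 3.34) == pytest.approx(0.0, abs=1e-9)

    def test_nonpositive_rejected(self):
        with pytest.raises(InvalidMeasurementError):
            tensile_strength(0.0, 10.5, 3.34)


class TestSpecificCrushingStrength:
    def test_trial5_reference(self):
        assert specific_crushing_strength(12.07, 10.5, 3.34) == pytest.approx(0.344, abs=0.001)

    def test_trial8_reference(self):
        assert specific_crushing_strength(5.3, 10.5, 3.61) == pytest.approx(0.140, abs=0.001)

    def test_ratio_identity(self):
        # Ts / tau = 2/pi for any tablet
        ts = tensile_strength(7.7, 9.0, 3.2)
        tau = specific_crushing_strength(7.7, 9.0, 3.2)
        assert ts / tau == pytest.approx(2.0 / math.pi, rel=1e-12)

    def test_reference_table_reproduction(self, reference):
        # every printed Ts and tau cell from printed F and mean H at D=10.5
        for _, row in reference.tablets.iterrows():
            F, H = row["crushing_strength_kg"], row["thickness_mm"]
            assert tensile_strength(F, PUNCH_DIAMETER_MM, H) == pytest.approx(
                row["tensile_strength"], abs=0.001
            )
            assert specific_crushing_strength(F, PUNCH_DIAMETER_MM, H) == pytest.approx(
                row["specific_crushing_strength"], abs=0.001
            )


class TestFriability:
    def test_hand_arithmetic(self):
        assert friability(6.50, 6.47) == pytest.approx(0.4615, abs=1e-4)

    def test_no_loss(self):
        assert friability(6.50, 6.50) == 0.0

    def test_fail_threshold(self):
        loss = friability(6.50, 6.40)
        assert loss == pytest.approx(1.538, abs=0.001)
        assert loss >= 1.0  # over the <1 % limit

    def test_mass_gain_rejected(self):
        with pytest.raises(InvalidMeasurementError):
            friability(6.40, 6.50)


class TestWeightVariation:
    def test_example(self):
        mean, dev = weight_variation([250.0, 255.0, 245.0])
        assert mean == pytest.approx(250.0)
        assert dev == pytest.approx(2.0)

    def test_constant(self):
        assert weight_variation([250.0, 250.0]) == (250.0, 0.0)

    def test_insufficient(self):
        with pytest.raises(InsufficientDataError):
            weight_variation([])


class TestDrugContent:
    def test_ratio(self):
        assert drug_content(980.0, 1000.0) == pytest.approx(98.0)

    def test_identity(self):
        assert drug_content(1000.0, 1000.0) == pytest.approx(100.0)

    def test_zero_standard_rejected(self):
        with pytest.raises(InvalidMeasurementError):
            drug_content(980.0, 0.0)


class TestDissolution:
    def test_single_sample(self):
        prof = dissolution_profile([(15.0, 0.0883)], 900.0, 10.0, 100.0)
        assert prof == [(15.0, pytest.approx(79.47))]

    def test_all_zero(self):
        prof = dissolution_profile(
            [(0.0, 0.0), (5.0, 0.0), (15.0, 0.0)], 900.0, 10.0, 100.0
        )
        assert all(q == 0.0 for _, q in prof)

    def test_two_point_withdrawal_correction(self):
        # hand evaluation: Q2 = 100*(C2*900 + C1*10)/100
        prof = dissolution_profile([(5.0, 0.05), (15.0, 0.08)], 900.0, 10.0, 100.0)
        assert prof[0][1] == pytest.approx(45.0)
        assert prof[1][1] == pytest.approx(100.0 * (0.08 * 900 + 0.05 * 10) / 100.0)
        assert prof[1][1] == pytest.approx(72.5)

    def test_correction_disabled(self):
        prof = dissolution_profile(
            [(5.0, 0.05), (15.0, 0.08)], 900.0, 10.0, 100.0, withdrawal_correction=False
        )
        assert prof[1][1] == pytest.approx(72.0)

    def test_monotone_when_concentrations_nondecreasing(self):
        concs = [0.0, 0.02, 0.05, 0.07, 0.0702]
        prof = dissolution_profile(
            list(zip([0.0, 5.0, 15.0, 30.0, 60.0], concs)), 900.0, 10.0, 100.0
        )
        qs = [q for _, q in prof]
        assert qs == sorted(qs)

    def test_nonincreasing_times_rejected(self):
        with pytest.raises(InputValidationError):
            dissolution_profile([(5.0, 0.05), (5.0, 0.08)], 900.0, 10.0, 100.0)

    def test_release_at_interpolates(self):
        prof = [(0.0, 0.0), (10.0, 50.0), (20.0, 70.0)]
        assert release_at(prof, 15.0) == pytest.approx(60.0)
        assert release_at(prof, 10.0) == pytest.approx(50.0)


class TestBatchReport:
    def test_full_report(self):
        qc = TabletBatchQC(
            trial_id="T",
            crushing_strengths=(12.0, 12.14),
            diameter=10.5,
            thicknesses=(3.3, 3.38),
            individual_weights=(250.0, 255.0, 245.0),
            friability_mass_before=6.5,
            friability_mass_after=6.47,
            wetting_times=(240.0, 250.0, 260.0),
            disintegration_times=(12.0, 13.0),
            peak_area_sample=991.7,
            peak_area_standard=1000.0,
            dissolution_samples=((0.0, 0.0), (15.0, 0.0237)),
        )
        r = batch_report(qc)
        assert r.mean_crushing_strength == pytest.approx(12.07)
        assert r.tensile_strength == pytest.approx(0.219, abs=0.001)
        assert r.specific_crushing_strength / r.tensile_strength == pytest.approx(math.pi / 2)
        assert r.friability_pct == pytest.approx(0.4615, abs=1e-4)
        assert r.friability_pass
        assert r.drug_content_pct == pytest.approx(99.17)
        assert r.content_pass
        assert r.q15 == pytest.approx(21.33)

    def test_missing_core_fields(self):
        with pytest.raises(InsufficientDataError):
            batch_report(TabletBatchQC(trial_id="T"))
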