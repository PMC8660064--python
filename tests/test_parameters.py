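import math

import pytest

from sedem.errors import (
    InputValidationError,
    InsufficientDataError,
    InvalidMeasurementError,
    MissingFieldError,
)
from sedem.parameters import (
    RawMeasurements,
    SieveFractions,
    angle_of_repose,
    assemble_basic_parameters,
    carr_index,
    cohesion_index,
    density_from_mass_volume,
    hausner_ratio,
    homogeneity_index,
    interparticle_porosity,
    kgf_to_newton,
)


class TestDensity:
    def test_direct_ratio(self):
        assert density_from_mass_volume(100.0, 250.0) == pytest.approx(0.400)

    def test_identity(self):
        assert density_from_mass_volume(50.0, 50.0) == pytest.approx(1.000)

    @pytest.mark.parametrize("mass,volume", [(100.0, 0.0), (0.0, 250.0), (-1.0, 10.0)])
    def test_degenerate_input(self, mass, volume):
        with pytest.raises(InvalidMeasurementError):
            density_from_mass_volume(mass, volume)


class TestPorosity:
    def test_hand_arithmetic(self):
        assert interparticle_porosity(0.4, 0.5) == pytest.approx(0.5)

    def test_equal_densities(self):
        assert interparticle_porosity(0.5, 0.5) == 0.0

    def test_hand_evaluation(self):
        # (0.6 - 0.4) / (0.6 * 0.4)
        assert interparticle_porosity(0.4, 0.6) == pytest.approx(0.8333, abs=1e-4)

    def test_inverted_densities_rejected(self):
        with pytest.raises(InvalidMeasurementError):
            interparticle_porosity(0.6, 0.4)


class TestCarrIndex:
    @pytest.mark.parametrize(
        "da,dc,expected", [(0.4, 0.5, 20.0), (0.5, 0.5, 0.0), (0.25, 0.5, 50.0)]
    )
    def test_examples(self, da, dc, expected):
        assert carr_index(da, dc) == pytest.approx(expected)


class TestHausnerRatio:
    @pytest.mark.parametrize(
        "da,dc,expected", [(0.4, 0.5, 1.25), (0.5, 0.5, 1.0), (0.2, 0.6, 3.0)]
    )
    def test_examples(self, da, dc, expected):
        assert hausner_ratio(da, dc) == pytest.approx(expected)

    def test_zero_bulk_density(self):
        with pytest.raises(InvalidMeasurementError):
            hausner_ratio(0.0, 0.5)

    def test_carr_hausner_identity(self):
        # Ic = 100 * (1 - 1/IH) for any density pair
        for da, dc in [(0.3, 0.5), (0.45, 0.61), (0.7, 0.7)]:
            ic, ih = carr_index(da, dc), hausner_ratio(da, dc)
            assert ic == pytest.approx(100.0 * (1.0 - 1.0 / ih))


class TestAngleOfRepose:
    def test_flat_pile(self):
        assert angle_of_repose(0.0, 40.0) == 0.0

    def test_unit_slope(self):
        assert angle_of_repose(40.0, 40.0) == pytest.approx(45.0)

    def test_arctan_half(self):
        assert angle_of_repose(20.0, 40.0) == pytest.approx(math.degrees(math.atan(0.5)))
        assert angle_of_repose(20.0, 40.0) == pytest.approx(26.565, abs=1e-3)

    def test_zero_radius(self):
        with pytest.raises(InvalidMeasurementError):
            angle_of_repose(20.0, 0.0)


class TestCohesionIndex:
    def test_constant_list(self):
        assert cohesion_index([100.0, 100.0, 100.0]) == pytest.approx(100.0)

    def test_mean(self):
        assert cohesion_index([80.0, 120.0]) == pytest.approx(100.0)

    def test_empty(self):
        with pytest.raises(InsufficientDataError):
            cohesion_index([])

    def test_kgf_conversion(self):
        assert kgf_to_newton(1.0) == pytest.approx(9.80665)


class TestSieveFractions:
    def test_bad_total_rejected(self):
        with pytest.raises(InputValidationError):
            SieveFractions(fractions=((850.0, 50.0), (600.0, 40.0)), pan_percent=0.0)

    def test_nondecreasing_apertures_rejected(self):
        with pytest.raises(InputValidationError):
            SieveFractions(fractions=((600.0, 50.0), (850.0, 50.0)))

    def test_bin_mean_diameters(self, sieve_fractions):
        diams = {label: d for label, d, _ in sieve_fractions.bins()}
        assert diams["retained_600"] == pytest.approx(725.0)   # (850+600)/2
        assert diams["retained_425"] == pytest.approx(512.5)
        assert diams["pan_50"] == pytest.approx(25.0)


class TestHomogeneityIndex:
    def test_single_fraction_degenerate(self):
        sf = SieveFractions(fractions=((600.0, 0.0), (425.0, 100.0)), pan_percent=0.0)
        assert homogeneity_index(sf) == pytest.approx(1.0)

    def test_hand_evaluation(self):
        # Fm=60% at 512.5 um (600-425 fraction), 40% at 362.5 um (425-300):
        # 60 / (100 + 150*40)
        sf = SieveFractions(
            fractions=((600.0, 0.0), (425.0, 60.0), (300.0, 40.0)), pan_percent=0.0
        )
        assert homogeneity_index(sf) == pytest.approx(60.0 / 6100.0, rel=1e-9)
        assert homogeneity_index(sf) == pytest.approx(0.009836, abs=1e-6)

    def test_scale_invariance_after_renormalisation(self):
        apertures = (850.0, 600.0, 425.0)
        masses = (12.0, 31.0, 17.0)
        a = homogeneity_index(SieveFractions.from_raw_masses(apertures, masses, 5.0))
        b = homogeneity_index(
            SieveFractions.from_raw_masses(apertures, tuple(7.3 * m for m in masses), 7.3 * 5.0)
        )
        assert a == pytest.approx(b, rel=1e-12)


class TestAssemble:
    def test_pass_through_hygroscopicity(self, measurements):
        assert assemble_basic_parameters(measurements).H == pytest.approx(10.69)

    def test_density_composition(self, measurements):
        p = assemble_basic_parameters(measurements)
        assert p.Da == pytest.approx(0.4)
        assert p.Dc == pytest.approx(0.5)
        assert p.Ic == pytest.approx(20.0)
        assert p.IH == pytest.approx(1.25)
        assert p.Ie == pytest.approx(0.5)

    def test_constant_mean_disintegration(self, measurements):
        assert assemble_basic_parameters(measurements).DCD == pytest.approx(2.0)

    def test_deterministic(self, measurements):
        assert assemble_basic_parameters(measurements) == assemble_basic_parameters(measurements)

    def test_missing_field_names_parameters(self, measurements):
        import dataclasses

        broken = dataclasses.replace(measurements, tapped_volume=None)
        with pytest.raises(MissingFieldError) as err:
            assemble_basic_parameters(broken)
        assert set(err.value.parameters) == {"Dc", "Ie", "Ic", "IH"}

    def test_tapped_exceeding_bulk_rejected(self):
        with pytest.raises(InvalidMeasurementError):
            RawMeasurements(batch_id="x", bulk_volume=100.0, tapped_volume=150.0)
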