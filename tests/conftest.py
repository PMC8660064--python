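import pytest

from sedem.parameters import RawMeasurements, SieveFractions
from sedem.reference import load_reference


@pytest.fixture(scope="session")
def reference():
    return load_reference()


@pytest.fixture
def sieve_fractions():
    # plausible granule size distribution, sums to 100
    return SieveFractions(
        fractions=((850.0, 5.0), (600.0, 15.0), (425.0, 30.0), (300.0, 22.0),
                   (250.0, 12.0), (50.0, 10.0)),
        pan_percent=6.0,
    )


@pytest.fixture
def measurements(sieve_fractions):
    return RawMeasurements(
        batch_id="demo",
        granule_mass=100.0,
        bulk_volume=250.0,
        tapped_volume=200.0,
        cone_height=20.0,
        cone_radius=40.0,
        flow_time=6.0,
        loss_on_drying_pct=2.5,
        hygroscopicity_pct=10.69,
        compact_strengths=(100.0, 110.0, 90.0, 105.0, 95.0, 100.0, 98.0, 102.0, 101.0, 99.0),
        sieve_fractions=sieve_fractions,
        percent_fines=6.0,
        effervescence_times=(3.0, 3.1, 2.9, 3.0, 3.0, 3.0),
        disint_disk_times=(2.0, 2.0, 2.0, 2.0, 2.0, 2.0),
        disint_nodisk_times=(2.5, 2.4, 2.6, 2.5, 2.5, 2.5),
    )
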