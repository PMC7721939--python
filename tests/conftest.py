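import numpy as np
import pytest

from y90dosim import PhysicsConstants, TreatmentRecord
from y90dosim import phantom as phm


@pytest.fixture(scope="session")
def two_tumor_spec() -> phm.PhantomSpec:
    """A noiseless, unblurred whole-liver phantom with two tumors.

    Tumor uptake ratios 3.0 and 1.0 around a unit normal-liver
    concentration; the 6.1% shunt matches a typical planar measurement.
    """
    return phm.PhantomSpec(
        tumors=(
            phm.TumorSpec((100.0, 143.0, 143.0), 15.0, 3.0, "T1"),
            phm.TumorSpec((190.0, 143.0, 143.0), 12.0, 1.0, "T2"),
        ),
        lsf_percent=6.1,
        seed=7,
    )


@pytest.fixture(scope="session")
def two_tumor_truth(two_tumor_spec) -> phm.PhantomTruth:
    return phm.generate(two_tumor_spec)


@pytest.fixture(scope="session")
def treatment() -> TreatmentRecord:
    return TreatmentRecord(activity_Y90_GBq=1.3, lsf_percent=6.1)


@pytest.fixture(scope="session")
def consistent_constants() -> PhysicsConstants:
    return PhysicsConstants(consistency_mode="consistent")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
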