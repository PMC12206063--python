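import numpy as np
import pytest

from pppa.fluorophores import (FluorophoreModel, build_nonfluorescent,
                               build_preset)
from pppa.photophysics import MediumGeometry


@pytest.fixture(scope="session")
def katushka():
    return build_preset("katushka")


@pytest.fixture(scope="session")
def mneptune():
    return build_preset("mneptune")


@pytest.fixture(scope="session")
def mcardinal():
    return build_preset("mcardinal")


@pytest.fixture(scope="session")
def absorber():
    return build_nonfluorescent()


@pytest.fixture(scope="session")
def geom():
    return MediumGeometry()


def variant(model: FluorophoreModel, **overrides) -> FluorophoreModel:
    """Copy a fluorophore model with selected fields replaced."""
    fields = dict(name=model.name, extinction=model.extinction,
                  emission=model.emission,
                  se_cross_section=model.se_cross_section,
                  lifetime_ns=model.lifetime_ns,
                  quantum_yield=model.quantum_yield,
                  concentration_uM=model.concentration_uM)
    fields.update(overrides)
    return FluorophoreModel(**fields)


@pytest.fixture(scope="session")
def fast_relaxer(katushka):
    """Katushka-like species with quasi-instant relaxation (tau -> 0)."""
    return variant(katushka, name="fast", lifetime_ns=1e-4)


@pytest.fixture(scope="session")
def tomo_scene():
    """Noiseless multiwavelength tomographic difference data.

    Default three-tube phantom imaged with the 512-element ring array over
    pump wavelengths 560-640 nm (10 nm steps), probe fixed at 650 nm,
    delays 0 and 10 ns.  Returns phantom, array, wavelengths, the
    reconstructed difference images (0.1 mm grid) and the ground-truth
    difference p0 maps.
    """
    from pppa import tomography as tg
    from pppa.photophysics import PulsePair

    arr = tg.RingArray()
    phantom = tg.build_phantom()
    lams = np.arange(560.0, 641.0, 10.0)
    diffs, gt = [], []
    for lam in lams:
        m0 = tg.phantom_p0(phantom, PulsePair(float(lam), 650.0, 0.0,
                                              3.0, 12.0, 12.0))
        m10 = tg.phantom_p0(phantom, PulsePair(float(lam), 650.0, 10.0,
                                               3.0, 12.0, 12.0))
        gt.append(m0.intensity - m10.intensity)
        r0 = tg.backproject(tg.tomo_forward(m0, arr), pixel_mm=0.1)
        r10 = tg.backproject(tg.tomo_forward(m10, arr), pixel_mm=0.1)
        diffs.append(tg.difference_image(r0, r10))
    return {"phantom": phantom, "array": arr, "lams": lams,
            "diffs": diffs, "gt_maps": np.array(gt)}
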