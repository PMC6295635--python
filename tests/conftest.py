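import numpy as np
import pytest

from thermoscreen.phantom import HotspotSpec, PhantomSpec, generate_phantom
from thermoscreen.pipeline import analyze_thermogram


@pytest.fixture(scope="session")
def symmetric_phantom():
    """Noise-free, mirror-symmetric phantom (no hotspot)."""
    return generate_phantom(PhantomSpec(noise_sd=0.0, seed=11))


@pytest.fixture(scope="session")
def carcinoma_phantom():
    """Noise-free phantom with a 2.7 °C left hotspot and one-sided vasculature."""
    spec = PhantomSpec(
        noise_sd=0.0,
        hotspot=HotspotSpec(side="left", delta_t=2.7),
        vascular_density=(1.0, 0.0),
        vascular_symmetric=False,
        seed=7,
    )
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def symmetric_result(symmetric_phantom):
    t, _ = symmetric_phantom
    return analyze_thermogram(t)


def counts_to_vectors(tp: int, fp: int, tn: int, fn: int):
    """Expand a 2x2 table into (truth, prediction) vectors."""
    truth = np.array([1] * tp + [0] * fp + [0] * tn + [1] * fn)
    pred = np.array([1] * tp + [1] * fp + [0] * tn + [0] * fn)
    return truth, pred
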