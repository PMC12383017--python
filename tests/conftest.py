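import numpy as np
import pytest
from hypothesis import settings

import dynapool as dp

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def small_catch():
    """Deterministic 200-fish synthetic catch at survey-like noise."""
    cfg = dp.SyntheticConfig(n_fish=200, seed=7)
    return dp.simulate_population(cfg)


@pytest.fixture
def reference_species():
    return dp.REFERENCE_SPECIES


def exact_catch(n_per_age=3, b=3.0, a=1e-5, L_inf=500.0, k=0.2, t0=-0.5,
                max_age=10, species="exact"):
    """Noise-free catch lying exactly on the VBGF and power-law curves."""
    samples = []
    for t in range(max_age + 1):
        length = L_inf * (1 - np.exp(-k * (t - t0)))
        for _ in range(n_per_age):
            samples.append(dp.FishSample(
                species_id=species, sex="unknown", age=t,
                body_length=float(length), body_weight=float(a * length**b),
            ))
    return dp.SampleSet(samples=samples, species_id=species)
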