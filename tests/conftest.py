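import numpy as np
import pytest

from isomirpanel import GeneratorConfig, LabelVector, generate


@pytest.fixture()
def micro_xy():
    """The 4-sample worked example: alternating x with two label layouts."""
    x = np.array([0.0, 1.0, 0.0, 1.0])
    aligned = LabelVector(np.array(list("ABAB"), dtype=object))
    balanced = LabelVector(np.array(list("AABB"), dtype=object))
    return x, aligned, balanced


@pytest.fixture(scope="session")
def small_dataset():
    """A small but non-trivial benchmark: 6 planted among 60 noise, n=120."""
    cfg = GeneratorConfig(n_samples=120, n_noise=60, n_informative=6, seed=7)
    return generate(cfg)


@pytest.fixture(scope="session")
def default_dataset():
    """Generator defaults (480 noise + 20 planted, n=200), seed 1."""
    return generate(GeneratorConfig(seed=1))
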