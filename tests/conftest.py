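import numpy as np
import pytest

from ctacollat import phantom


@pytest.fixture(scope="session")
def default_spec():
    return phantom.PhantomSpec()


@pytest.fixture(scope="session")
def intact_phantoms(default_spec):
    """20 intact-skull good/poor phantom pairs keyed by seed."""
    from dataclasses import replace

    out = {}
    for seed in range(20):
        spec = replace(default_spec, seed=seed)
        out[seed] = {
            "good": phantom.generate_phantom(spec, phantom.GOOD),
            "poor": phantom.generate_phantom(spec, phantom.POOR),
        }
    return out


@pytest.fixture(scope="session")
def defect_phantoms(default_spec):
    """20 calvarial-defect phantoms."""
    from dataclasses import replace

    return {
        seed: phantom.generate_phantom(
            replace(default_spec, seed=seed, calvarial_defect=True), phantom.GOOD
        )
        for seed in range(20)
    }


def dice(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    return 2.0 * (a & b).sum() / (a.sum() + b.sum())


@pytest.fixture(scope="session")
def dice_fn():
    return dice
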