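import numpy as np
import pytest

from wntcalc import LIGAND_PRESETS, TransientParams, simulate_trace


@pytest.fixture(scope="session")
def noiseless_trace():
    """Symmetric noiseless Gaussian: baseline 1, amplitude 1.5, t0 200, sigma 20."""
    params = TransientParams(baseline=1.0, amplitude=1.5, center_time=200.0,
                             sigma=20.0, noise_sd=0.0)
    return params, simulate_trace(params, seed=0)


@pytest.fixture(scope="session")
def responding_presets():
    return {name: p for name, p in LIGAND_PRESETS.items()
            if p.transient is not None}


def gaussian_crossing_offsets(sigma: float, fraction: float) -> float:
    """|t - t0| at which a unit Gaussian falls to ``fraction`` of its peak."""
    return sigma * np.sqrt(2.0 * np.log(1.0 / fraction))
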