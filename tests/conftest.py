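import numpy as np
import pytest

from probekit.decay import DecayComponent


@pytest.fixture
def dppc_components():
    """Two-component decay of a gel-phase DPPC bilayer at 20 degC."""
    return [DecayComponent(0.56, 6.18), DecayComponent(0.44, 0.53)]


@pytest.fixture
def flat_spectrum():
    from probekit.photophysics import EmissionSpectrum

    lam = np.arange(370.0, 601.0, 1.0)
    return EmissionSpectrum(lam, np.full_like(lam, 100.0))
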