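import numpy as np
import pytest

from oecspin import FitOptions, Nucleus, SpinSystem

X_BAND = 9.369115  # GHz


@pytest.fixture
def table1_52():
    """Rhombic spin-5/2 g4.1 parameter set (two coupled ⁵⁵Mn nuclei)."""
    return SpinSystem(
        S=2.5, g_principal=(2.18, 2.16, 1.98), D=0.45, E=0.45 * 0.25,
        nuclei=(Nucleus(2.5, (194.2,) * 3), Nucleus(2.5, (45.2,) * 3)),
        temperature=8.0)


@pytest.fixture
def table1_32():
    """Near-rhombic spin-3/2 alternative parameter set."""
    return SpinSystem(
        S=1.5, g_principal=(2.18, 2.16, 1.98), D=0.3, E=0.3 * 0.3,
        nuclei=(Nucleus(2.5, (194.2,) * 3), Nucleus(2.5, (45.2,) * 3)),
        temperature=8.0)


@pytest.fixture
def light_fit_options():
    """Reduced-budget fit settings for test-scale optimization."""
    return FitOptions(n_starts=2, n_orientations=150, n_field_steps=48, max_nfev=40)


@pytest.fixture
def g41_axis():
    """2 G/point axis over the g4.1 observation window."""
    return np.linspace(400.0, 2900.0, 1250)
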