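import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from regiqa import EnergyProfile, SyntheticSpec, generate_profile
from regiqa.terms import AtomLabel, TermKey, TermType

settings.register_profile(
    "ci", derandomize=True, max_examples=200, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

A1 = AtomLabel.parse("a1")
B2 = AtomLabel.parse("b2")


@pytest.fixture
def toy_profile():
    """2-atom, 3-point profile with an exact additive partition."""
    e_a = np.array([-1.0, -1.1, -1.2])
    e_b = np.array([-2.0, -2.0, -2.1])
    v_cl = np.array([-0.5, -0.4, -0.3])
    v_xc = np.array([-0.1, -0.1, -0.2])
    terms = {
        TermKey.intra(TermType.E_INTRA, A1): e_a,
        TermKey.intra(TermType.E_INTRA, B2): e_b,
        TermKey.pair(TermType.V_CL, A1, B2): v_cl,
        TermKey.pair(TermType.V_XC, A1, B2): v_xc,
        TermKey.total(): e_a + e_b + v_cl + v_xc,
    }
    return EnergyProfile([0.0, 0.5, 1.0], terms)


@pytest.fixture
def synthetic_profile():
    spec = SyntheticSpec(n_atoms=6, m_points=15, noise_sigma=1e-4, seed=42)
    return generate_profile(spec)
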