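import numpy as np
import pytest

from crimedyn import Params3D, Params5D, Params9D


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def p3_super():
    """3D parameters well above threshold (r0 = 2.4)."""
    return Params3D(beta=2.0, delta=0.5, sigma=0.5, rho_x=1.0, rho_c=0.5)


@pytest.fixture
def p3_sub():
    """3D parameters well below threshold (r0 = 0.48)."""
    return Params3D(beta=0.4, delta=0.5, sigma=0.5, rho_x=1.0, rho_c=0.5)


@pytest.fixture
def p5_base():
    """5D contagion-only parameters above threshold (r0 ~ 2.38)."""
    return Params5D(beta=1.0, eps=0.0, delta1=0.3, sigma1=0.3, rho=0.5,
                    nu_p=0.3, nu_c=0.0, delta2=0.3, sigma2=0.4, phi=0.3)


@pytest.fixture
def p5_sweep():
    """5D parameters for the prison-term experiment (r0 ~ 4.2), chosen so
    the prison population saturates within the rho = 10 .. 0.1 grid."""
    return Params5D(beta=12.0, eps=0.0, delta1=0.5, sigma1=5.0, rho=1.0,
                    nu_p=1.0, nu_c=0.0, delta2=0.5, sigma2=5.0, phi=1.0)


@pytest.fixture
def p9_base():
    """9D contagion-only parameters with release leakage (Model 5)."""
    return Params9D(beta=1.2, eps=0.0,
                    delta1=0.3, sigma1=0.4, rho1=0.5, nu_p1=0.4, nu_c1=0.0, phi1=0.3,
                    delta2=0.25, sigma2=0.5, rho2=0.4, nu_p2=0.5, nu_c2=0.0, phi2=0.35,
                    delta3=0.2, sigma3=0.6, rho3=0.3)
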