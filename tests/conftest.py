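import numpy as np
import pytest

from dielrelax import synthetic
from dielrelax.models import (
    CompositeDielectricModel,
    ConductivityTerm,
    HNProcess,
    IsothermalSpectrum,
)


@pytest.fixture
def debye_model():
    return CompositeDielectricModel(
        eps_inf=3.0, processes=[HNProcess(2.0, 100.0, 1.0, 1.0, "debye")]
    )


@pytest.fixture
def debye_spectrum(debye_model):
    """Noiseless single-Debye tan(delta) spectrum on the standard grid."""
    f = np.logspace(-1, 6, 71)
    eps = debye_model.eps(f)
    return IsothermalSpectrum(
        temperature=293.15,
        frequencies=f,
        eps_real=np.real(eps),
        eps_imag=-np.imag(eps),
        meta={"sample_id": "debye"},
    )


@pytest.fixture
def two_process_protocol():
    """Secondary + constrained-amorphous process over a conductivity floor."""
    return synthetic.SyntheticProtocol(
        processes=[
            synthetic.ProcessLaw("beta", "arrhenius", 12.0, Ea=40.0,
                                 delta_eps=1.5, a=0.8, b=1.0),
            synthetic.ProcessLaw("alpha_c", "arrhenius", 11.0, Ea=55.0,
                                 delta_eps=3.0, a=0.6, b=1.0),
        ],
        conductivity=synthetic.ConductivityLaw(240.0, 1e-13, 25.0, 25.0, 0.5, 0.5),
        eps_inf=3.5,
        t_start_C=-60.0,
        t_stop_C=-40.0,
        t_step_C=10.0,
        noise_sd=0.0,
        sample_id="two_process",
    )


@pytest.fixture
def conductivity_term():
    return ConductivityTerm(sigma0=1e-10, n=0.5)
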