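import pytest

import crforce as cf


@pytest.fixture(scope="session")
def std():
    """Standard rate set (e=0.7, a=1.3, d=0.2, b=1) at r=10, K_mean=K_Hopf+0.05."""
    return cf.standard_params(r=10.0)


@pytest.fixture(scope="session")
def k_hopf_std(std):
    return cf.k_hopf(std)


def scaled_protocol(
    t_total=6000.0, t_transient=5000.0, rel_tol=1e-6, abs_tol=1e-9, sample_dt=0.02
):
    """Short protocol for tests: same sampling logic, reduced spans/tolerances."""
    return cf.SimProtocol(
        t_total=t_total,
        t_transient=t_transient,
        rel_tol=rel_tol,
        abs_tol=abs_tol,
        sample_dt=sample_dt,
    )


@pytest.fixture(scope="session")
def fast_proto():
    return scaled_protocol
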