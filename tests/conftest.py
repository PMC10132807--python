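import numpy as np
import pytest

import ompsim as om


@pytest.fixture
def kernel10() -> om.ResponseParams:
    """Single-time response kernel with tau_G = 10 ms."""
    return om.ResponseParams(tau_G=10.0)


@pytest.fixture
def small_config() -> om.RunConfig:
    """A short, cheap trial configuration for orchestration tests."""
    return om.RunConfig(
        signal=(
            om.SignalSpec(
                tau_s=100.0,
                sigma_j=1.0,
                correlation=om.Correlation.time_locked,
                duration=1.0,
            ),
        ),
        kernel=om.ResponseParams(tau_G=10.0),
        plasticity=om.OMPParams(lambda_M=0.02, lambda_A=0.1, lambda_H=0.0),
        chain=om.ChainConfig(n_segments=2, n_axons=4),
        experiment=om.ExperimentConfig(T_exp=2e4, n_e=5, sigma_D=5.0),
    )


def make_profile(times, values, sigma0) -> om.SyncProfile:
    """Build a bare profile for fitting tests."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    return om.SyncProfile(
        times=times,
        sigma_tau=values,
        sigma_tau0=float(sigma0),
        sigma_D_only=float(sigma0),
    )
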