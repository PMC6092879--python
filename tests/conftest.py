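import numpy as np
import pytest

from metatraj.cohort import MissingnessConfig, generate_cohort
from metatraj.model import default_parameters, default_spec
from metatraj.simulate import AlertThresholds


@pytest.fixture(scope="session")
def spec():
    return default_spec()


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def complete_cohort(spec, params):
    """Small cohort with no censoring and no missingness (all 26 values)."""
    table, _ = generate_cohort(
        150, params, spec,
        missingness=MissingnessConfig.none(),
        thresholds=AlertThresholds.none(),
        seed=101,
    )
    return table


@pytest.fixture(scope="session")
def mar_cohort(spec, params):
    """Cohort with 10% item-level MAR missingness, no censoring."""
    table, _ = generate_cohort(
        200, params, spec,
        missingness=MissingnessConfig.mar_rate(0.1),
        thresholds=AlertThresholds.none(),
        seed=202,
    )
    return table


def zeroed_params(params, **overrides):
    """Copy of a parameter set with all variances/covariances (and optionally
    more) removed; used to build degenerate path-tracing configurations."""
    p = params.copy()
    p.Psi_b = np.zeros((3, 3))
    p.Psi_zeta = np.zeros((9, 9))
    p.omega = 0.0
    p.theta = np.zeros(7)
    p.B = np.zeros((9, 2))
    p.Gamma_b = np.zeros_like(p.Gamma_b)
    p.Gamma_f = np.zeros_like(p.Gamma_f)
    p.kappa = np.zeros_like(p.kappa)
    for k, v in overrides.items():
        setattr(p, k, v)
    return p
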