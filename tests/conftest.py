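import numpy as np
import pytest

from propiokin import (
    FermentationState,
    KineticParameters,
    batch_scenario,
    fedbatch_scenario,
    simulate,
)


@pytest.fixture(scope="session")
def simple_params() -> KineticParameters:
    """Small hand-checkable parameter set used by arithmetic tests."""
    return KineticParameters(
        rs_max=0.8, Ks=0.1, kipa=20.0, kiaa=40.0, Yxs=0.3, ms=0.05,
        K1=2.0, K2=0.3, K3=0.4, K4=0.5, K5=0.2, K6=0.6, K7=0.1,
        K_pyr=1.0, beta_pa=0.1, beta_pyr=0.01, beta_aa=0.02, beta_sa=0.03,
    )


@pytest.fixture(scope="session")
def wgs7_batch():
    """Reference high-producer batch trajectory, hourly grid."""
    p, init, _ = batch_scenario("wgs7-like")
    t = np.arange(0.0, 72.5, 1.0)
    return simulate(init, p, t), p, init


@pytest.fixture(scope="session")
def wgs7_fedbatch():
    """Reference fed-batch trajectory with mass-balance bookkeeping."""
    p, init, feed, _ = fedbatch_scenario("wgs7-like")
    t = np.arange(0.0, 140.5, 1.0)
    ts = simulate(init, p, t, mode="fedbatch", feed=feed,
                  track_mass_balance=True)
    return ts, p, init, feed
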