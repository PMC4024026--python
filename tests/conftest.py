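import numpy as np
import pytest

import dcequant as dq

FIXTURE_SEED = 2014


@pytest.fixture(scope="session")
def acq():
    return dq.AcquisitionParams()


@pytest.fixture(scope="session")
def phantom():
    return dq.build_phantom()


@pytest.fixture(scope="session")
def noiseless(phantom, acq):
    """Noiseless simulation + full analysis chain on the default phantom."""
    vfa = dq.simulate_vfa(phantom, acq, 0.0, seed=FIXTURE_SEED)
    dyn, truth = dq.simulate_dynamic(phantom, acq, None, 0.0, seed=FIXTURE_SEED + 1)
    t1_map, m0_map = dq.map_t1_volume(vfa, acq)
    conc = dq.signal_to_concentration(dyn, t1_map, m0_map, acq, arrival_mask=phantom.tumor_mask)
    return dict(vfa=vfa, dyn=dyn, truth=truth, t1_map=t1_map, m0_map=m0_map, conc=conc)


@pytest.fixture(scope="session")
def noisy_snr50(phantom, acq):
    """Fixed-seed SNR-50 (rim baseline) simulation + analysis chain."""
    sigma = dq.noise_sigma_for_snr(phantom.classes[3], acq, 50.0)
    vfa = dq.simulate_vfa(phantom, acq, sigma, seed=FIXTURE_SEED)
    dyn, truth = dq.simulate_dynamic(phantom, acq, None, sigma, seed=FIXTURE_SEED + 1)
    t1_map, m0_map = dq.map_t1_volume(vfa, acq)
    conc = dq.signal_to_concentration(dyn, t1_map, m0_map, acq, arrival_mask=phantom.tumor_mask)
    return dict(sigma=sigma, vfa=vfa, dyn=dyn, truth=truth, t1_map=t1_map, m0_map=m0_map, conc=conc)
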