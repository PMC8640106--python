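import numpy as np
import pytest

import mrsphase as mp
from mrsphase import simulate as sim


@pytest.fixture(scope="session")
def basis():
    return mp.default_basis()


@pytest.fixture(scope="session")
def small_slaser():
    """Full spectral resolution, few channels/averages (fast)."""
    return mp.slaser_7t(n_channels=2, n_averages=4)


@pytest.fixture(scope="session")
def small_mega():
    return mp.mega_slaser_7t(n_channels=2, n_averages=4)


@pytest.fixture(scope="session")
def cohort():
    return sim.simulate_cohort(mp.CohortConfig(), seed=1)


@pytest.fixture(scope="session")
def subject(cohort):
    return cohort[0]


@pytest.fixture(scope="session")
def clean_session(subject, small_slaser):
    """Noiseless, distortion-free sLASER session."""
    return sim.synthesize_session(
        subject, "Baseline", small_slaser, mp.DistortionConfig.none(), seed=2
    )


@pytest.fixture(scope="session")
def clean_mega_session(subject, small_mega):
    return sim.synthesize_session(
        subject, "Baseline", small_mega, mp.DistortionConfig.none(), seed=3
    )


def single_lorentzian_spectrum(
    amp=10.0, shift_ppm=2.0, linewidth_hz=8.0, noise_sd=0.0, seed=0,
    acquisition=None,
):
    """A one-line test spectrum with known time-domain amplitude."""
    from mrsphase.preprocess import CombinedSpectrum

    acq = acquisition or mp.slaser_7t(n_channels=1, n_averages=1)
    model = mp.MetaboliteModel(
        name="peak",
        resonances=(mp.Resonance(shift_ppm, 1.0, linewidth_hz),),
        t2_ms=100.0,
        proton_count=1.0,
    )
    fid = amp * model.unit_fid(acq)
    if noise_sd:
        rng = np.random.default_rng(seed)
        fid = fid + noise_sd * (
            rng.standard_normal(acq.n_points) + 1j * rng.standard_normal(acq.n_points)
        )
    return CombinedSpectrum(fid, acq), model
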