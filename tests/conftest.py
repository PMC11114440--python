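import numpy as np
import pytest

from plihub.montage_io import DEFAULT_MONTAGE, EEGRecording
from plihub.synthetic_data import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_cohort():
    """A small, short recovery-scenario cohort shared across tests."""
    cfg = CohortConfig(
        n_per_group={"control": 4, "patient": 4}, duration_s=40, seed=7
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def warm_kernel(small_cohort):
    """Compile the PLI kernel once so timings elsewhere stay honest."""
    from plihub.connectivity import _pli_kernel

    z = np.exp(1j * np.random.default_rng(0).uniform(-np.pi, np.pi, (1, 2, 64)))
    _pli_kernel(np.ascontiguousarray(z.real), np.ascontiguousarray(z.imag))
    return True


def make_recording(data, fs=200.0, subject_id="s"):
    return EEGRecording(montage=DEFAULT_MONTAGE, data=np.asarray(data), fs=fs,
                        subject_id=subject_id)
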