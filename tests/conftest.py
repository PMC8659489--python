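import numpy as np
import pytest

from bradyflux.cohort import RawRecording, SimulationConfig, SubjectParams
from bradyflux.preprocess import ProcessedRecording


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


def make_subject_params(
    subject_id="S001",
    effect=1.0,
    base_amp=3.0,
    has_tremor=False,
    has_dyskinesia=False,
    seed_pre=101,
    seed_post=202,
) -> SubjectParams:
    return SubjectParams(
        subject_id=subject_id,
        effect=effect,
        base_amp=base_amp,
        has_tremor=has_tremor,
        tremor_freq=5.0,
        tremor_amp=0.6,
        tremor_axis=(1.0, 0.0, 0.0),
        has_dyskinesia=has_dyskinesia,
        dysk_freq=1.0,
        dysk_axis=(0.0, 1.0, 0.0),
        session_seed_pre=seed_pre,
        session_seed_post=seed_post,
    )


def make_processed(
    x, y, z, fs=120.0, subject_id="S001", state="pre", svm_raw=None
) -> ProcessedRecording:
    """Assemble a ProcessedRecording from given channel arrays."""
    x, y, z = (np.asarray(a, dtype=float) for a in (x, y, z))
    svm = np.sqrt(x**2 + y**2 + z**2)
    if svm_raw is None:
        svm_raw = svm
    return ProcessedRecording(
        subject_id=subject_id,
        state=state,
        fs=fs,
        t=np.arange(x.size) / fs,
        x=x,
        y=y,
        z=z,
        svm=svm,
        svm_raw=np.asarray(svm_raw, dtype=float),
        gravity_estimate=np.zeros((x.size, 3)),
    )


@pytest.fixture
def tiny_sim_config():
    """A few short sessions: enough windows to exercise the pipeline."""
    return SimulationConfig(n_subjects=3, session_minutes=6.0, seed=42)
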