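import pytest

from geodeface import PhantomSpec, make_phantom, anonymize


@pytest.fixture(scope="session")
def quick_phantom():
    """Small noisy phantom for unit tests (96^3 at 2 mm, ~1.5 s)."""
    spec = PhantomSpec(shape=(96, 96, 96), voxel_size=(2.0, 2.0, 2.0), seed=42)
    return make_phantom(spec)


@pytest.fixture(scope="session")
def quick_phantom_noisefree():
    spec = PhantomSpec(shape=(96, 96, 96), voxel_size=(2.0, 2.0, 2.0),
                       noise_sd=0.0)
    return make_phantom(spec)


@pytest.fixture(scope="session")
def default_phantom():
    """The full-size study phantom (128^3 at 1.5 mm)."""
    return make_phantom(PhantomSpec(seed=1))


@pytest.fixture(scope="session")
def default_anonymized(default_phantom):
    """Anonymization of the study phantom with its ground-truth landmarks."""
    v, truth = default_phantom
    out, report = anonymize(v, truth.landmarks, seed=7, return_artifacts=True)
    return out, report


@pytest.fixture(scope="session")
def quick_anonymized(quick_phantom):
    v, truth = quick_phantom
    out, report = anonymize(v, truth.landmarks, seed=3, return_artifacts=True)
    return out, report
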