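import numpy as np
import pytest

from ramanfuse.spectra import Spectrum, SpectrumMeta, cohort_from_spectra
from ramanfuse.synthetic import SyntheticConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small dried-state synthetic cohort with its ground truth."""
    cfg = SyntheticConfig(
        n_cancer=8, n_control=6, spots_per_sample=3, states=("dried",),
        spike_rate=0.0, seed=7,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def mean_cohort(small_cohort):
    from ramanfuse.preprocess import preprocess_pipeline

    cohort, _ = small_cohort
    mean, _ = preprocess_pipeline(cohort)
    return mean


def make_spectrum(y, x=None, **meta):
    y = np.asarray(y, float)
    x = np.arange(400.0, 400.0 + y.size) if x is None else np.asarray(x, float)
    return Spectrum(axis=x, intensities=y, meta=SpectrumMeta(**meta))


@pytest.fixture
def tiny_two_patient_cohort():
    """2 patients x 2 fluids of per-patient means on a shared axis."""
    x = np.linspace(400, 1800, 50)
    rng = np.random.default_rng(0)
    spectra = []
    for pid, label in (("P1", "cancer"), ("P2", "control")):
        for fluid in ("plasma", "saliva"):
            spectra.append(
                Spectrum(
                    axis=x,
                    intensities=rng.normal(1.0, 0.1, x.size),
                    meta=SpectrumMeta(
                        patient_id=pid, biofluid=fluid, state="dried",
                        spot="mean", label=label,
                    ),
                )
            )
    return cohort_from_spectra(
        spectra, {"P1": ("cancer", "II"), "P2": ("control", "none")}
    )
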