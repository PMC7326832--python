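import numpy as np
import pytest

from reims.simulate import balanced_design, generate_cohort, rectal_study_design
from reims.spectra import BinAxis, FeatureMatrix, Spectrum

# coarse axis used for desk-scale statistical checks (400 bins over 600-1000)
COARSE_AXIS = BinAxis(600.0, 1000.0, 1.0)


def make_spectrum(mz, intensity, sid="s1", pid="p1", sample="p1-a", label="normal"):
    return Spectrum(
        spectrum_id=sid,
        patient_id=pid,
        sample_id=sample,
        tissue_label=label,
        mz=np.asarray(mz, dtype=float),
        intensity=np.asarray(intensity, dtype=float),
    )


def random_spectrum(rng, sid="s1", n_peaks=50, label="normal"):
    mz = np.sort(rng.uniform(600.0, 1000.0, size=n_peaks))
    while np.any(np.diff(mz) == 0):
        mz = np.sort(rng.uniform(600.0, 1000.0, size=n_peaks))
    inten = rng.exponential(100.0, size=n_peaks)
    return make_spectrum(mz, inten, sid=sid, label=label)


def random_logged_matrix(rng, n=18, p=8, classes=("adenoma", "normal", "tumour")):
    """Small labelled matrix at stage 'logged' for chemometric unit tests."""
    X = rng.exponential(1.0, size=(n, p))
    labels = [classes[i % len(classes)] for i in range(n)]
    axis = BinAxis(600.0, 600.0 + p, 1.0)
    return FeatureMatrix(
        axis=axis,
        X=X,
        spectrum_ids=[f"s{i}" for i in range(n)],
        patient_ids=[f"p{i // 3}" for i in range(n)],
        sample_ids=[f"p{i // 3}-a" for i in range(n)],
        tissue_labels=labels,
        stage="logged",
    )


@pytest.fixture(scope="session")
def study_cohort():
    """The frozen study-shaped cohort: 47 patients, 77 samples, 266 spectra."""
    return generate_cohort(rectal_study_design(seed=20260920))


@pytest.fixture(scope="session")
def small_cohort():
    """A small balanced strong-effect cohort for fast end-to-end checks."""
    return generate_cohort(
        balanced_design(n_patients_per_class=3, spectra_per_sample=3, seed=7)
    )
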