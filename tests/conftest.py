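"""Shared fixtures: one default synthetic study per session plus derived
annotation/normalization products, so the heavier pipeline stages are
generated once and reused across test modules."""

import pytest

from sulfomics.fragment_annotation import align_spectra_to_features
from sulfomics.preprocess import impute_missing, lowess_normalize
from sulfomics.synthetic_study import generate_study


@pytest.fixture(scope="session")
def study():
    """Default synthetic administration study (fixed seed)."""
    return generate_study(seed=7)


@pytest.fixture(scope="session")
def profiles(study):
    """Per-feature sulfate profiles from the study's spectra."""
    return align_spectra_to_features(study.spectra, study.table.features)


@pytest.fixture(scope="session")
def normalized(study):
    """LOWESS-normalized, imputed feature table plus the QC report."""
    norm, report = lowess_normalize(study.table)
    return impute_missing(norm), report
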