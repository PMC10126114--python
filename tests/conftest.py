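import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")

from eapclust.pipeline import default_study_design, extract_features
from eapclust.synthetic import gen_unit_population


@pytest.fixture(scope="session")
def study_population():
    """Small emulated FS/RS population with ground-truth component names."""
    design = default_study_design()
    waveforms, labels = gen_unit_population(design, 600, seed=202)
    names = np.array([design[l].name for l in labels])
    return waveforms, names


@pytest.fixture(scope="session")
def study_features(study_population) -> tuple[pd.DataFrame, np.ndarray]:
    waveforms, names = study_population
    return extract_features(waveforms), names
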