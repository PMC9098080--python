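import numpy as np
import pytest

from usvpipe import synth
from usvpipe.frontend import FilterBankParams, SpectrogramParams, build_gammatone_bank

#: label set used for classifier training (11 syllable classes + FP)
TRAIN_CLASSES = ("c", "c2", "c3", "h", "d", "up", "u", "f", "us", "s", "ui", "FP")


@pytest.fixture(scope="session")
def spec_params():
    return SpectrogramParams()


@pytest.fixture(scope="session")
def bank_params():
    return FilterBankParams()


@pytest.fixture(scope="session")
def gammatone_bank(bank_params, spec_params):
    return build_gammatone_bank(bank_params, spec_params)


@pytest.fixture(scope="session")
def clean_recording():
    """Mixed-class synthetic recording at high SNR, with annotations."""
    specs = synth.random_specs(40, seed=11)
    specs = [synth.UsvSpec(**{**s.__dict__, "amplitude_db": max(s.amplitude_db, 30.0)})
             for s in specs]
    return synth.synthesize_recording(specs, seed=11)


@pytest.fixture(scope="session")
def tiny_gs_dataset():
    """Small labeled GS dataset over the 12 training classes."""
    from usvpipe.datasets import build_gs_dataset

    return build_gs_dataset(8, seed=5, classes=TRAIN_CLASSES)
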