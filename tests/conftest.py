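import numpy as np
import pytest

from microcaps.bonn import DatasetCase
from microcaps.synth import SynthConfig, gen_class_recordings


@pytest.fixture(scope="session")
def small_synth_recordings():
    """A small, easy two-class synthetic corpus (12 files per class,
    shorter files) shared across tests that need trainable data."""
    cfg = SynthConfig(seed=11, n_files_per_class=12, file_len=1024,
                      classes=("background", "ictal"))
    return {c: gen_class_recordings(cfg, c) for c in cfg.classes}


@pytest.fixture(scope="session")
def binary_case():
    return DatasetCase("background_vs_ictal", {"background": 0, "ictal": 1})


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
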