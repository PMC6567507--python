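import numpy as np
import pytest

from hairpin2pare.io_core import load_config


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_config():
    """A scaled-down configuration for fast end-to-end exercises."""
    return load_config(
        overrides={
            "design": {"replicates": 2},
            "simulate": {
                "n_precursors": 8,
                "n_decoys": 8,
                "depth": 20_000,
                "spacer_length": 400,
                "pare": {"n_target_transcripts": 4, "n_decoy_transcripts": 2},
            },
            "pare": {"n_shuffles": 20},
        }
    )
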