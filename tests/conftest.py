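import numpy as np
import pandas as pd
import pytest

from dsresist import synthetic as syn


@pytest.fixture(scope="session")
def small_screen():
    """Noise-free 12-drug paired screen with designated differential drugs."""
    truth, designated = syn.paired_screen_truth(
        n_drugs=12,
        n_sensitizing=4,
        n_coresistant=3,
        config=syn.ScreenConfig(noise_cv=0.0),
        seed=42,
    )
    readout, _ = syn.generate_screen(truth)
    return readout, truth, designated


@pytest.fixture(scope="session")
def exome_pair():
    """Small exome pair with one deletion and one gain block."""
    cfg = syn.ExomeConfig(
        chromosomes=(("chr1", 60), ("chr2", 80)),
        cnv_segments=(("chr2", 20, 40, -1.0),),
        n_somatic=10,
        n_germline=12,
    )
    return syn.generate_exome_pair(cfg, seed=7), cfg


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def toy_ddss():
    """6 drugs x 2 pairs with exactly two values beyond the +/-5 cutoff."""
    return pd.DataFrame(
        {
            "pairA": [7.2, 1.0, -2.0, 5.0, 0.5, -1.2],
            "pairB": [3.0, 0.2, -6.1, 4.9, 1.5, -0.3],
        },
        index=[f"d{i}" for i in range(6)],
    )
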