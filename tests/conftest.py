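import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("stable", derandomize=True, deadline=None)
settings.load_profile("stable")

sys.path.insert(0, str(Path(__file__).parent))  # expose oracles.py

from mirseed import SimConfig, generate_screen, score_screen  # noqa: E402

#: hsa-let-7a; its seed target hexamer is UACCUC
LET7 = "UGAGGUAGUAGGUUGUAUAGUU"


@pytest.fixture(scope="session")
def small_screen():
    """A small but structurally complete screen: 40 miRNAs × 3 genes,
    1 plate per gene, duplicate screening, mild bias."""
    cfg = SimConfig(
        n_mirnas=40,
        genes=("G1", "G2", "G3"),
        plates_per_gene=1,
        replicates=2,
        mirna_bias_sd=0.5,
        rng_seed=7,
    )
    wells, truth = generate_screen(cfg)
    return wells, truth


@pytest.fixture(scope="session")
def small_screen_scored(small_screen):
    wells, truth = small_screen
    return score_screen(wells), truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
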