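import numpy as np
import pandas as pd
import pytest

from emaplink import EMapMatrix
from emaplink.synthetic import SyntheticConfig, generate


@pytest.fixture
def tiny_emap() -> EMapMatrix:
    """Five genes, hand-filled scores, one missing pair (g1, g4)."""
    return EMapMatrix.from_pairs(
        ["g1", "g2", "g3", "g4", "g5"],
        {
            ("g1", "g2"): -2.5,
            ("g1", "g3"): 1.0,
            ("g1", "g5"): 0.5,
            ("g2", "g3"): -4.0,
            ("g2", "g4"): 3.0,
            ("g2", "g5"): 0.0,
            ("g3", "g4"): -1.0,
            ("g3", "g5"): 2.5,
            ("g4", "g5"): -0.5,
        },
        name="tiny",
    )


def duplicate_profile_truth(seed: int = 3):
    """Noise-free screens where same-module profiles are exact copies.

    With zero pairwise residual and zero screen noise, every value is purely
    the module-pair block effect, so genes sharing a module have bitwise
    identical profiles and their mutual correlation is exactly 1.0.
    """
    rng = np.random.default_rng(7)
    effects = {
        (i, j): float(rng.normal(0, 3.0)) for i in range(5) for j in range(i, 5)
    }
    cfg = SyntheticConfig(
        n_shared=30,
        n_a_only=12,
        n_b_only=12,
        n_modules=5,
        block_effects=effects,
        residual_sd=0.0,
        noise_sd=0.0,
        missing_frac_a=0.1,
        missing_frac_b=0.1,
        seed=seed,
    )
    return generate(cfg)


@pytest.fixture
def dup_truth():
    return duplicate_profile_truth()


def write_tsv(path, text: str) -> str:
    path.write_text(text)
    return str(path)
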