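import logging

import numpy as np
import pandas as pd
import pytest

from ssimpute.io import ReferencePanel

logging.getLogger("ssimpute").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(20240117)


@pytest.fixture
def small_panel(rng):
    """Deterministic 200-individual, 6-variant panel with one LD pair.

    Columns 0 and 1 are duplicates (perfect LD); column 2 is the reflection
    2 - g of column 0 (correlation -1); columns 3-5 are independent draws.
    """
    n = 200
    base = rng.binomial(2, 0.4, size=n).astype(float)
    others = rng.binomial(2, 0.3, size=(n, 3)).astype(float)
    dosages = np.column_stack([base, base, 2.0 - base, others])
    variants = pd.DataFrame(
        {
            "variant_id": [f"v{i}" for i in range(6)],
            "chromosome": "1",
            "position": [1000, 2000, 3000, 4000, 5000, 6000],
            "ref": "A",
            "alt": "G",
        }
    )
    return ReferencePanel(dosages, variants)


@pytest.fixture
def summary_frame():
    """Summary records matching small_panel positions, alt-allele coded."""
    return pd.DataFrame(
        {
            "variant_id": [f"v{i}" for i in range(6)],
            "chromosome": "1",
            "position": [1000, 2000, 3000, 4000, 5000, 6000],
            "effect_allele": "G",
            "other_allele": "A",
            "z": [1.5, 1.4, -1.5, 0.3, -0.2, 0.8],
            "sample_size": 10_000,
        }
    )
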