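import numpy as np
import pandas as pd
import pytest

from pfish.codebook import ColorLayout, generate_codebook


@pytest.fixture(scope="session")
def layout_15():
    return ColorLayout(5, 3)


@pytest.fixture(scope="session")
def codebook_82(layout_15):
    """The reference 15-bit book: 78 real guides (incl. 4 controls) + 4 blanks."""
    return generate_codebook(layout_15, n_targets=78, n_blanks=4, seed=7, n_controls=4)


@pytest.fixture(scope="session")
def codebook_small(layout_15):
    """A fast 20-entry book for decode round-trips."""
    return generate_codebook(layout_15, n_targets=18, n_blanks=2, seed=1, n_controls=4)


def make_spot_table(n_total: int, n_blank: int) -> pd.DataFrame:
    """Minimal decoded-spot table with given total / blank-match counts."""
    n_real = n_total - n_blank
    return pd.DataFrame(
        {
            "x": np.zeros(n_total),
            "y": np.zeros(n_total),
            "bits": [""] * n_total,
            "identity": ["guide_001"] * n_real + ["blank_001"] * n_blank,
            "is_blank": [False] * n_real + [True] * n_blank,
            "mean_intensity": np.ones(n_total),
            "std_intensity": np.zeros(n_total),
            "area": np.full(n_total, 10),
            "eccentricity": np.zeros(n_total),
            "qc_pass": np.ones(n_total, dtype=bool),
        }
    )
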