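import numpy as np
import pytest

from ivmr.summary_data import InstrumentSet


def random_instrument_set(rng: np.random.Generator, L: int, sd_scale: float = 1.0) -> InstrumentSet:
    """A generic random instrument set (signs mixed, unequal SEs)."""
    beta_x = rng.uniform(0.02, 0.2, L) * rng.choice([-1.0, 1.0], L)
    se_x = rng.uniform(0.005, 0.02, L)
    beta_y = rng.normal(0.0, 0.05, L)
    se_y = rng.uniform(0.01, 0.05, L)
    return InstrumentSet.from_arrays(beta_x, se_x, beta_y, se_y, sd_scale=sd_scale)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


@pytest.fixture
def make_instruments(rng):
    """Factory fixture for random instrument sets."""

    def _make(L: int = 6, sd_scale: float = 1.0) -> InstrumentSet:
        return random_instrument_set(rng, L, sd_scale=sd_scale)

    return _make


@pytest.fixture
def write_table(tmp_path):
    """Write a list of dict rows as a TSV file and return its path."""

    def _write(rows, name="table.tsv", columns=None):
        import pandas as pd

        df = pd.DataFrame(rows)
        if columns is not None:
            df = df[columns]
        path = tmp_path / name
        df.to_csv(path, sep="\t", index=False)
        return path

    return _write
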