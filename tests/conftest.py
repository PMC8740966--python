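import numpy as np
import pandas as pd
import pytest

from irchemo.spectra_io import SpectrumSet


def make_meta(ids, **fields):
    meta = pd.DataFrame({"spectrum_id": list(ids)})
    for k, v in fields.items():
        meta[k] = v
    return meta


@pytest.fixture
def full_grid():
    """The acquisition grid: 4000 -> 400 cm^-1 at 4 cm^-1 spacing."""
    return 4000.0 - 4.0 * np.arange(901)


@pytest.fixture
def small_set():
    """3 spectra x 5 points with minimal metadata."""
    wn = np.array([1800.0, 1796.0, 1792.0, 1788.0, 1784.0])
    rng = np.random.default_rng(0)
    return SpectrumSet(wn, rng.normal(size=(3, 5)), make_meta(["a", "b", "c"]))


@pytest.fixture
def fingerprint_set(full_grid):
    """20 random positive spectra on the full grid, two classes."""
    rng = np.random.default_rng(1)
    values = rng.uniform(0.1, 1.0, size=(20, len(full_grid)))
    meta = make_meta(
        [f"s{i:02d}" for i in range(20)],
        plant_type=["alpha"] * 10 + ["beta"] * 10,
        leaf_surface=["upper", "lower"] * 10,
    )
    return SpectrumSet(full_grid, values, meta)
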