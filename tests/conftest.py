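import numpy as np
import pytest

from phagesensor import default_layout, default_scenario
from phagesensor.layout import ChipLayout, CellSpec


@pytest.fixture(scope="session")
def scenario():
    """The default 8-analyte x 4-temperature two-class study design."""
    return default_scenario(seed=42)


@pytest.fixture(scope="session")
def layout():
    return default_layout()


@pytest.fixture(scope="session")
def small_layout():
    """A compact 3x3 layout (12 px cells, 8 px ROI) for Monte-Carlo tests."""
    cells = tuple(
        CellSpec(row=r, col=c, x0=2 + c * 14, y0=2 + r * 14, width=12, height=12)
        for r in range(3) for c in range(3)
    )
    return ChipLayout(image_width=44, image_height=44, cells=cells, roi_side=8)


@pytest.fixture(scope="session")
def noiseless_dataset(tmp_path_factory):
    """A noise-free synthetic dataset on disk, shared across tests."""
    from phagesensor import generate_dataset

    sc = default_scenario(seed=42, noise_sd=0.0)
    out = tmp_path_factory.mktemp("noiseless_ds")
    manifest = generate_dataset(sc, out)
    return sc, out, manifest


def random_pattern(rng: np.random.Generator, n_bins: int, analyte="X", temp=30.0):
    from phagesensor.features import ResponsePattern

    return ResponsePattern(
        analyte_id=analyte, temperature_c=temp,
        bins=rng.uniform(-255, 255, size=(n_bins, 3)),
    )
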