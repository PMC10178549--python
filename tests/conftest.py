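import numpy as np
import pytest

import ovotrace as ot
from ovotrace.synthetic import GeneratorConfig


@pytest.fixture(scope="session")
def small_table():
    """Moderate-noise synthetic table at reduced axis resolution (15 x 141)."""
    cfg = GeneratorConfig(
        wavelength_grid=np.linspace(400.0, 1100.0, 141),
        n_per_class=(5, 5, 5),
        seed=7,
    )
    return ot.generate(cfg)


@pytest.fixture(scope="session")
def labelled_blobs():
    """Well-separated 3-class feature blobs (no spectral structure needed)."""
    rng = np.random.default_rng(11)
    centers = np.array(
        [[2.0, 0, 0, 0, 2.0, 0], [0, 2.0, 0, 2.0, 0, 0], [0, 0, 2.0, 0, 0, 2.0]]
    )
    X = np.vstack([centers[k] + 0.15 * rng.standard_normal((12, 6)) for k in range(3)])
    y = np.repeat([0, 1, 2], 12)
    return ot.SpectraTable(
        wavelengths_nm=np.arange(6, dtype=float) + 500.0, X=X, y=y
    )
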