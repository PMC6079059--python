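import numpy as np
import pytest

from ramancharm.cube import CellMask, HyperspectralCube, Spectrum, WavenumberAxis


@pytest.fixture(scope="session")
def axis1024() -> WavenumberAxis:
    return WavenumberAxis(np.linspace(600.0, 3100.0, 1024))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture()
def gauss_spectrum(axis1024) -> Spectrum:
    """Smooth single-band spectrum with mild noise (A=10 at 750 cm^-1).

    The band is broad on the channel grid (sigma ~ 10 channels) so a
    running median does not mistake its apex for a single-channel spike.
    """
    nu = axis1024.values
    noise = 0.05 * np.random.default_rng(7).standard_normal(nu.size)
    y = 10.0 * np.exp(-((nu - 750.0) ** 2) / (2.0 * 25.0 ** 2)) + noise
    return Spectrum(y, axis1024)


@pytest.fixture()
def small_cube(axis1024, rng) -> HyperspectralCube:
    """4x5 cube of random smooth spectra (float64 for exactness checks)."""
    base = np.abs(rng.standard_normal((4, 5, 1)))
    shape = np.exp(
        -((axis1024.values - 1500.0) ** 2) / (2.0 * 300.0 ** 2)
    )[None, None, :]
    return HyperspectralCube(base * shape + 0.1, axis1024)


@pytest.fixture()
def blob_mask() -> CellMask:
    yy, xx = np.mgrid[0:32, 0:32]
    return CellMask(np.hypot(yy - 15.5, xx - 15.5) <= 10, "cell0")
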