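import numpy as np
import pytest

from fatqsm.core import AcquisitionParams, FatSpectrum, VolumeGrid


@pytest.fixture(scope="session")
def single_peak_spectrum() -> FatSpectrum:
    """One-peak fat spectrum at the dominant methylene resonance (-3.4 ppm,
    about -419 Hz at 3 T)."""
    return FatSpectrum.single_peak(-3.4)


@pytest.fixture(scope="session")
def two_peak_spectrum() -> FatSpectrum:
    return FatSpectrum(np.array([-3.4, -2.6]), np.array([0.75, 0.25]))


@pytest.fixture(scope="session")
def acq6() -> AcquisitionParams:
    """Six-echo GRE protocol (TE1 = 1.17 ms, dTE = 1.71 ms) at 2 mm voxels."""
    return AcquisitionParams.gre_protocol(voxel_mm=(2.0, 2.0, 2.0))


@pytest.fixture(scope="session")
def small_truth_maps():
    """Coarse rasterization of the nine-inclusion iron phantom (48^3, 3 mm)."""
    from fatqsm.phantom import default_phantom_spec, rasterize_maps

    return rasterize_maps(default_phantom_spec("iron"), shape=(48, 48, 48), voxel_mm=3.0)


def sphere_grid(n: int, vox: float = 1.0):
    ax = (np.arange(n) - (n - 1) / 2) * vox
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij", sparse=True)
    r = np.sqrt(x**2 + y**2 + z**2)
    return ax, x, y, z, r


@pytest.fixture(scope="session")
def unit_sphere_chi():
    """1000 ppb sphere of radius 20 mm on a 128^3 1 mm grid, plus the
    analytic Lorentz-corrected dipole field for comparison."""
    n = 128
    a = 20.0
    ax, x, y, z, r = sphere_grid(n)
    chi = np.where(r <= a, 1000.0, 0.0)
    cos2 = np.divide(z**2, r**2, out=np.zeros_like(r), where=r > 0)
    analytic = np.where(r > a, 1000.0 / 3.0 * (a / np.maximum(r, 1e-9)) ** 3 * (3 * cos2 - 1), 0.0)
    return VolumeGrid(chi, 1.0, "ppb"), analytic, r, a
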