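import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")

from pbodyquant import (NO_NOISE, PSFModel, StandardCurve,
                        build_correction_curve, generate_cell_stack,
                        single_cell_truth)

#: Default confocal-like PSF used throughout the suite (µm).
SIGMA = (0.13, 0.13, 0.34)

#: Default synthetic voxel size (dz, dy, dx) µm.
VOXELS = (0.12, 0.04, 0.04)


@pytest.fixture(scope="session")
def psf() -> PSFModel:
    return PSFModel(*SIGMA)


@pytest.fixture(scope="session")
def curve(psf):
    return build_correction_curve(psf, np.linspace(0.15, 2.5, 40))


@pytest.fixture(scope="session")
def noiseless_scene(psf):
    """One noiseless 0.6 µm P body at PC 100 in a single cell, plus its stack."""
    truth = single_cell_truth(pbody_diameter=0.6, pc=100.0, c_cyto=0.2,
                              psf=psf, noise=NO_NOISE, seed=1)
    stack, _ = generate_cell_stack(truth, VOXELS)
    return truth, stack


@pytest.fixture(scope="session")
def standard_curve():
    return StandardCurve(gain=500.0, offset=100.0, setting="A")


def mc_ball_integral(psf: PSFModel, diameter: float, n: int,
                     seed: int = 12345) -> float:
    """Monte-Carlo oracle: integral of the Gaussian PSF over a centered ball,
    by uniform sampling inside the ball (independent of the quadrature path)."""
    rng = np.random.default_rng(seed)
    R = diameter / 2.0
    r = R * rng.random(n) ** (1.0 / 3.0)
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1)[:, None]
    pts = r[:, None] * v
    s = np.array([psf.sigma_x, psf.sigma_y, psf.sigma_z])
    pdf = np.exp(-0.5 * np.sum((pts / s) ** 2, axis=1)) / (
        (2.0 * np.pi) ** 1.5 * np.prod(s))
    return float(4.0 / 3.0 * np.pi * R**3 * pdf.mean())
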