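"""Point-spread-function estimation and the sphere intensity-dilution correction.

A fluorescent object near or below the microscope's diffraction limit appears
dimmer than it is: the point-spread function (PSF) spreads the object's light
over a volume larger than the object, so the peak intensity recorded in the
image is only a fraction of the true peak.  For a uniform sphere of diameter
``d`` imaged through a normalized PSF ``h``, that fraction is

    CF(d) = (ball_d * h)(center) = ∫_{|x| ≤ d/2} h(x) dx,

the integral of the PSF over the ball.  ``build_correction_curve`` evaluates
this integral on a grid of diameters for an anisotropic Gaussian PSF, together
with the *apparent* diameter (FWHM of the blurred sphere's x-profile), and
``cf_lookup`` interpolates the correction factor for a measured FWHM.

The PSF itself is estimated from z-stacks of sub-resolution fluorescent beads
by 3-D Gaussian fitting with a quadrature correction for the finite bead size.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import yaml
from numpy.polynomial.legendre import leggauss
from scipy import ndimage, optimize

#: FWHM of a Gaussian with unit standard deviation.
FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))

#: Measured diameters below this multiple of the x-y PSF FWHM are unreliable.
MIN_DIAMETER_FACTOR = 1.1


@dataclass(frozen=True)
class PSFModel:
    """Separable anisotropic Gaussian PSF, standard deviations in µm."""

    sigma_x: float
    sigma_y: float
    sigma_z: float
    provenance: str = "configured"

    def __post_init__(self) -> None:
        if min(self.sigma_x, self.sigma_y, self.sigma_z) <= 0:
            raise ValueError("PSF sigmas must be positive")

    @property
    def fwhm(self) -> tuple[float, float, float]:
        return (
            FWHM_FACTOR * self.sigma_x,
            FWHM_FACTOR * self.sigma_y,
            FWHM_FACTOR * self.sigma_z,
        )

    @property
    def fwhm_xy(self) -> float:
        """Geometric-mean lateral FWHM (x and y are usually near-identical)."""
        return FWHM_FACTOR * float(np.sqrt(self.sigma_x * self.sigma_y))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "sigma_x_um": float(self.sigma_x),
                    "sigma_y_um": float(self.sigma_y),
                    "sigma_z_um": float(self.sigma_z),
                    "provenance": str(self.provenance),
                },
                fh,
            )

    @classmethod
    def from_yaml(cls, path) -> "PSFModel":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(d["sigma_x_um"], d["sigma_y_um"], d["sigma_z_um"],
                   d.get("provenance", "configured"))


def min_analyzable_diameter(psf: PSFModel) -> float:
    """Smallest measured FWHM diameter considered reliable: 1.1× the x-y PSF FWHM."""
    return MIN_DIAMETER_FACTOR * psf.fwhm_xy


# ---------------------------------------------------------------------------
# Sphere ⊛ Gaussian forward model (Gauss–Legendre quadrature)
# ---------------------------------------------------------------------------

def _gauss(u: np.ndarray, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * (u / sigma) ** 2) / (sigma * np.sqrt(2.0 * np.pi))


@lru_cache(maxsize=16)
def _leggauss(n: int):
    return leggauss(n)


def _disk_integral(rho: np.ndarray, sigma_y: float, sigma_z: float,
                   n_r: int = 96, n_phi: int = 64) -> np.ndarray:
    """∫ over the disk of radius rho of the 2-D Gaussian g(y)·g(z), vectorized."""
    rho = np.atleast_1d(np.asarray(rho, dtype=float))
    xr, wr = _leggauss(n_r)                      # nodes on [-1, 1]
    r = 0.5 * rho[:, None] * (xr + 1.0)          # (m, n_r) radial nodes on [0, rho]
    wr_scaled = 0.5 * rho[:, None] * wr
    phi = (np.arange(n_phi) + 0.5) * (2.0 * np.pi / n_phi)
    y = r[:, :, None] * np.cos(phi)
    z = r[:, :, None] * np.sin(phi)
    integrand = _gauss(y, sigma_y) * _gauss(z, sigma_z)
    phi_int = integrand.sum(axis=2) * (2.0 * np.pi / n_phi)
    return np.einsum("mr,mr->m", r * wr_scaled, phi_int)


def sphere_image_profile(psf: PSFModel, diameter: float,
                         x: np.ndarray, n_u: int = 192) -> np.ndarray:
    """x-axis profile through the center of a unit sphere convolved with the PSF.

    Returns ``I(x) = (ball * psf)(x, 0, 0)`` for a unit-intensity ball of the
    given diameter centered at the origin.
    """
    u, w = _chord_weights(psf, diameter, n_u)
    x = np.atleast_1d(np.asarray(x, dtype=float))
    return _gauss(x[:, None] - u[None, :], psf.sigma_x) @ w


def _chord_weights(psf: PSFModel, diameter: float, n_u: int = 192):
    """Quadrature nodes and weights reducing the sphere convolution to a
    1-D sum: I(x0) = Σ g(x0 - u_j; sigma_x) · w_j."""
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    R = 0.5 * diameter
    xu, wu = _leggauss(n_u)
    u = R * xu                                   # chord positions inside the ball
    disk = _disk_integral(np.sqrt(np.maximum(R * R - u * u, 0.0)),
                          psf.sigma_y, psf.sigma_z)
    return u, R * wu * disk


def correction_factor(psf: PSFModel, diameter: float) -> float:
    """CF(d): integral of the normalized Gaussian PSF over the ball of diameter d."""
    return float(sphere_image_profile(psf, diameter, np.array([0.0]))[0])


def apparent_diameter(psf: PSFModel, diameter: float) -> float:
    """FWHM of the blurred sphere's x-profile through its center, in µm."""
    u, w = _chord_weights(psf, diameter)
    peak = float(_gauss(-u, psf.sigma_x) @ w)
    half = 0.5 * peak

    def f(x0: float) -> float:
        return float(_gauss(x0 - u, psf.sigma_x) @ w) - half

    hi = 0.5 * diameter + 6.0 * psf.sigma_x
    x_half = optimize.brentq(f, 0.0, hi, xtol=1e-8)
    return 2.0 * x_half


@dataclass
class CorrectionCurve:
    """Diameter → intensity-dilution lookup built from a PSF model.

    ``cf`` is the fraction of the true peak intensity observed for a uniform
    sphere of each ``true_diameters`` entry; ``apparent_diameters`` is the
    FWHM the blurred sphere presents in the image.  ``min_diameter`` is the
    smallest measured FWHM the curve may be applied to.
    """

    true_diameters: np.ndarray
    apparent_diameters: np.ndarray
    cf: np.ndarray
    min_diameter: float

    def __post_init__(self) -> None:
        self.true_diameters = np.asarray(self.true_diameters, dtype=float)
        self.apparent_diameters = np.asarray(self.apparent_diameters, dtype=float)
        self.cf = np.asarray(self.cf, dtype=float)
        if not (len(self.true_diameters) == len(self.apparent_diameters) == len(self.cf)):
            raise ValueError("curve columns must have equal length")
        if np.any(np.diff(self.true_diameters) <= 0):
            raise ValueError("true_diameters must be strictly ascending")
        if np.any((self.cf <= 0) | (self.cf > 1.0 + 1e-9)):
            raise ValueError("cf values must lie in (0, 1]")

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# min_diameter_um={float(self.min_diameter)!r}\n")
            fh.write("true_diameter_um,apparent_diameter_um,cf\n")
            for t, a, c in zip(self.true_diameters, self.apparent_diameters, self.cf):
                fh.write(f"{float(t)!r},{float(a)!r},{float(c)!r}\n")

    @classmethod
    def from_csv(cls, path) -> "CorrectionCurve":
        with open(path) as fh:
            text = fh.read()
        min_d = None
        lines = []
        for line in text.splitlines():
            if line.startswith("#"):
                key, _, val = line.lstrip("# ").partition("=")
                if key.strip() == "min_diameter_um":
                    min_d = float(val)
            else:
                lines.append(line)
        import pandas as pd

        df = pd.read_csv(io.StringIO("\n".join(lines)))
        if min_d is None:
            raise ValueError("correction-curve CSV lacks min_diameter_um header")
        return cls(df["true_diameter_um"].to_numpy(),
                   df["apparent_diameter_um"].to_numpy(),
                   df["cf"].to_numpy(), min_d)

    def true_from_apparent(self, measured_diameter: float) -> float:
        """Invert the blur: estimate the true diameter from a measured FWHM."""
        if measured_diameter >= self.apparent_diameters[-1]:
            return float(measured_diameter)
        return float(np.interp(measured_diameter, self.apparent_diameters,
                               self.true_diameters))


def build_correction_curve(psf: PSFModel, true_diameters) -> CorrectionCurve:
    """Tabulate CF and apparent FWHM for spheres on an ascending diameter grid."""
    d = np.asarray(true_diameters, dtype=float)
    if d.ndim != 1 or len(d) < 2:
        raise ValueError("need an ascending grid of at least two diameters")
    if np.any(d <= 0) or np.any(np.diff(d) <= 0):
        raise ValueError("diameter grid must be positive and strictly ascending")
    cf = np.array([correction_factor(psf, di) for di in d])
    app = np.array([apparent_diameter(psf, di) for di in d])
    return CorrectionCurve(d, app, np.minimum(cf, 1.0), min_analyzable_diameter(psf))


def cf_lookup(curve: CorrectionCurve, measured_diameter: float) -> float:
    """Correction factor for a measured (apparent) FWHM diameter.

    Linear interpolation of ``cf`` against the curve's apparent diameters,
    clamped to 1 above the grid.  Diameters below the minimum analyzable
    threshold are rejected: their FWHM no longer tracks the object size.
    """
    # tolerate float dust at the 1.1×FWHM boundary
    if measured_diameter < curve.min_diameter - 1e-9:
        raise ValueError(
            f"measured diameter {measured_diameter:.3g} µm is below the minimum "
            f"analyzable diameter {curve.min_diameter:.3g} µm (1.1× the x-y PSF FWHM)"
        )
    if measured_diameter >= curve.apparent_diameters[-1]:
        return 1.0
    return float(np.interp(measured_diameter, curve.apparent_diameters, curve.cf))


# ---------------------------------------------------------------------------
# PSF estimation from bead stacks
# ---------------------------------------------------------------------------

def _gauss3d(coords, amp, cz, cy, cx, sz, sy, sx, offset):
    z, y, x = coords
    return offset + amp * np.exp(
        -0.5 * (((z - cz) / sz) ** 2 + ((y - cy) / sy) ** 2 + ((x - cx) / sx) ** 2)
    )


def _fit_bead(sub: np.ndarray, origin_um, voxel_size):
    dz, dy, dx = voxel_size
    zz, yy, xx = np.meshgrid(
        origin_um[0] + dz * np.arange(sub.shape[0]),
        origin_um[1] + dy * np.arange(sub.shape[1]),
        origin_um[2] + dx * np.arange(sub.shape[2]),
        indexing="ij",
    )
    offset0 = float(np.percentile(sub, 10))
    w = np.clip(sub - offset0, 0, None)
    if w.sum() <= 0:
        return None
    cz = float((zz * w).sum() / w.sum())
    cy = float((yy * w).sum() / w.sum())
    cx = float((xx * w).sum() / w.sum())
    sz0 = max(np.sqrt((w * (zz - cz) ** 2).sum() / w.sum()), dz / 2)
    sy0 = max(np.sqrt((w * (yy - cy) ** 2).sum() / w.sum()), dy / 2)
    sx0 = max(np.sqrt((w * (xx - cx) ** 2).sum() / w.sum()), dx / 2)
    p0 = [float(sub.max() - offset0), cz, cy, cx, sz0, sy0, sx0, offset0]
    try:
        popt, _ = optimize.curve_fit(
            _gauss3d,
            (zz.ravel(), yy.ravel(), xx.ravel()),
            sub.ravel(),
            p0=p0,
            maxfev=20000,
        )
    except RuntimeError:
        return None
    amp, cz, cy, cx, sz, sy, sx, offset = popt
    if amp <= 0:
        return None
    return (cz, cy, cx), (abs(sz), abs(sy), abs(sx))


def estimate_psf_from_beads(bead_stack, bead_diameter: float,
                            channel: str | None = None) -> PSFModel:
    """Estimate the Gaussian PSF from a z-stack of sub-resolution beads.

    Each isolated bead is fit with a 3-D Gaussian; the apparent standard
    deviations are corrected for the finite bead size by quadrature
    subtraction of the bead's Gaussian-equivalent sd (d/4), and the median
    across beads is returned.  Beads closer than 3 apparent FWHM to a
    neighbor are excluded as overlapping.
    """
    if bead_diameter <= 0:
        raise ValueError("bead diameter must be positive")
    img = bead_stack.channel(channel) if channel else bead_stack.data[0]
    vs = bead_stack.voxel_size
    bg = float(np.median(img))
    peak = float(img.max())
    if peak <= bg or not np.any(img > bg + 0.25 * (peak - bg)):
        raise ValueError("no beads found above background")
    mask = img > bg + 0.25 * (peak - bg)
    labels, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=int))
    if n == 0:
        raise ValueError("no beads found above background")
    fits = []
    for sl in ndimage.find_objects(labels):
        # expand the bounding box by 2× its own size for fitting context
        grown = []
        for s, dim in zip(sl, img.shape):
            w = s.stop - s.start
            grown.append(slice(max(s.start - 2 * w, 0), min(s.stop + 2 * w, dim)))
        sub = img[tuple(grown)]
        origin = (grown[0].start * vs[0], grown[1].start * vs[1], grown[2].start * vs[2])
        fit = _fit_bead(sub, origin, vs)
        if fit is not None:
            fits.append(fit)
    if not fits:
        raise ValueError("no beads could be fit")
    centers = np.array([f[0] for f in fits])
    sigmas = np.array([f[1] for f in fits])
    app_fwhm = FWHM_FACTOR * float(np.median(np.sqrt(sigmas[:, 1] * sigmas[:, 2])))
    keep = np.ones(len(fits), dtype=bool)
    for i in range(len(fits)):
        for j in range(i + 1, len(fits)):
            if np.linalg.norm(centers[i] - centers[j]) < 3.0 * app_fwhm:
                keep[i] = keep[j] = False
    if not keep.any():
        raise ValueError("all beads overlap (closer than 3 apparent FWHM)")
    sig = np.median(sigmas[keep], axis=0)
    bead_sd = bead_diameter / 4.0  # Gaussian-equivalent sd of a uniform ball
    corrected = np.sqrt(np.maximum(sig**2 - bead_sd**2, 0.0))
    if np.any(corrected <= 0):
        raise ValueError("apparent bead size smaller than the bead itself")
    return PSFModel(corrected[2], corrected[1], corrected[0],
                    provenance=f"beads d={bead_diameter} µm, n={int(keep.sum())}")
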