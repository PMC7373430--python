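"""Ground-truth-labeled synthetic data for every stage of the pipeline.

The generators emulate the statistical structure of confocal measurements of
yeast P bodies: ellipsoidal cells a few µm across with a dilute cytoplasmic
pool (~0.05-0.5 µM) containing spherical condensates 0.33-0.8 µm in diameter
at 1-20 µM, imaged through an anisotropic Gaussian PSF (lateral FWHM ~0.3 µm,
axial ~0.8 µm) with linear camera gain/offset, Poisson shot noise and Gaussian
read noise.  Kinetic traces, GFP standard curves, paired-partition tables and
interaction edge lists follow the same pattern: every output carries its
generating parameters, so downstream estimates can be checked against truth.

All generators draw from a single ``numpy`` Generator seeded per call; equal
seeds give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .image import ImageStack
from .kinetics import FRAPTrace
from .psf import PSFModel


@dataclass(frozen=True)
class NoiseModel:
    """Poisson shot noise (via a photons-per-a.u. scale) plus Gaussian read noise.

    ``photons_per_au=None`` disables the Poisson stage; ``read_sd=0`` the
    Gaussian stage.
    """

    photons_per_au: float | None = 20.0
    read_sd: float = 2.0

    @property
    def enabled(self) -> bool:
        return self.photons_per_au is not None or self.read_sd > 0


#: Noiseless camera, for forward-model equivalence tests.
NO_NOISE = NoiseModel(photons_per_au=None, read_sd=0.0)


@dataclass(frozen=True)
class CellTruth:
    """One ellipsoidal cell: center and axis *diameters* in µm, C_cyto in µM."""

    center: tuple[float, float, float]          # (x, y, z) µm
    axes: tuple[float, float, float]            # diameters (x, y, z) µm
    c_cyto: float                               # µM
    marker_c_cyto: float | None = None          # mCherry channel, µM-equivalent

    def __post_init__(self) -> None:
        if min(self.axes) <= 0:
            raise ValueError("cell axis diameters must be positive")
        if self.c_cyto < 0:
            raise ValueError("C_cyto must be >= 0")


@dataclass(frozen=True)
class PBodyTruth:
    """One spherical P body inside a parent cell."""

    center: tuple[float, float, float]          # (x, y, z) µm
    diameter: float                             # µm
    c_pbody: float                              # µM
    cell: int = 0                               # parent cell index
    marker_c_pbody: float | None = None

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("P-body diameter must be positive")
        if self.c_pbody < 0:
            raise ValueError("C_pbody must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """Full scene description behind one synthetic cell stack."""

    cells: tuple[CellTruth, ...]
    pbodies: tuple[PBodyTruth, ...]
    psf: PSFModel
    gain: float = 500.0                         # a.u. per µM
    offset: float = 100.0                       # a.u.
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "cells", tuple(self.cells))
        object.__setattr__(self, "pbodies", tuple(self.pbodies))
        for pb in self.pbodies:
            cell = self.cells[pb.cell]
            if pb.c_pbody < cell.c_cyto:
                raise ValueError("C_pbody must be >= C_cyto of the parent cell")
            # conservative sphere-in-ellipsoid containment check
            f = np.sqrt(sum(
                ((pc - cc) / (a / 2.0)) ** 2
                for pc, cc, a in zip(pb.center, cell.center, cell.axes)
            ))
            if f + pb.diameter / min(cell.axes) > 1.0:
                raise ValueError(
                    f"P body at {pb.center} lies outside (or touches the boundary "
                    f"of) its parent cell at {cell.center}"
                )

    @property
    def has_marker(self) -> bool:
        return any(c.marker_c_cyto is not None for c in self.cells) or any(
            p.marker_c_pbody is not None for p in self.pbodies
        )


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------

def _add_ellipsoid(field_arr: np.ndarray, voxel_size, center_xyz, semi_xyz,
                   value: float, oversample: int = 5) -> None:
    """Add ``value``×coverage of an ellipsoid to the field (in place).

    Voxels wholly inside/outside are exact; only boundary voxels are
    oversampled (``oversample`` points per axis).
    """
    dz, dy, dx = voxel_size
    cx, cy, cz = center_xyz
    ax, ay, az = semi_xyz
    nz, ny, nx = field_arr.shape
    # bounding box in voxel indices (voxel centers at index*pitch)
    iz = np.arange(max(int(np.floor((cz - az) / dz)) - 1, 0),
                   min(int(np.ceil((cz + az) / dz)) + 2, nz))
    iy = np.arange(max(int(np.floor((cy - ay) / dy)) - 1, 0),
                   min(int(np.ceil((cy + ay) / dy)) + 2, ny))
    ix = np.arange(max(int(np.floor((cx - ax) / dx)) - 1, 0),
                   min(int(np.ceil((cx + ax) / dx)) + 2, nx))
    if len(iz) == 0 or len(iy) == 0 or len(ix) == 0:
        return
    Z, Y, X = np.meshgrid(iz * dz, iy * dy, ix * dx, indexing="ij")
    r = np.sqrt(((X - cx) / ax) ** 2 + ((Y - cy) / ay) ** 2 + ((Z - cz) / az) ** 2)
    # normalized half-voxel diagonal bounds the within-voxel variation of r
    delta = np.sqrt((dx / (2 * ax)) ** 2 + (dy / (2 * ay)) ** 2 + (dz / (2 * az)) ** 2)
    cov = np.zeros_like(r)
    cov[r <= 1.0 - delta] = 1.0
    boundary = (r > 1.0 - delta) & (r < 1.0 + delta)
    if boundary.any():
        bz, by, bx = np.nonzero(boundary)
        off = (np.arange(oversample) + 0.5) / oversample - 0.5
        oz, oy, ox = np.meshgrid(off * dz, off * dy, off * dx, indexing="ij")
        sub = (
            ((X[boundary][:, None] + ox.ravel()[None, :] - cx) / ax) ** 2
            + ((Y[boundary][:, None] + oy.ravel()[None, :] - cy) / ay) ** 2
            + ((Z[boundary][:, None] + oz.ravel()[None, :] - cz) / az) ** 2
        )
        cov[bz, by, bx] = (sub <= 1.0).mean(axis=1)
    field_arr[np.ix_(iz, iy, ix)] += value * cov


def _render_concentration_field(shape, voxel_size, cells, pbodies,
                                channel: str) -> np.ndarray:
    """Ideal (pre-PSF) concentration field: cytoplasm value inside each cell,
    P-body value inside each sphere, zero outside."""
    fld = np.zeros(shape, dtype=float)
    for cell in cells:
        c = cell.c_cyto if channel == "primary" else (cell.marker_c_cyto or 0.0)
        if c != 0.0:
            _add_ellipsoid(fld, voxel_size, cell.center,
                           tuple(a / 2.0 for a in cell.axes), c)
    for pb in pbodies:
        parent = cells[pb.cell]
        if channel == "primary":
            delta = pb.c_pbody - parent.c_cyto
        else:
            delta = (pb.marker_c_pbody or 0.0) - (parent.marker_c_cyto or 0.0)
        if delta != 0.0:
            r = pb.diameter / 2.0
            _add_ellipsoid(fld, voxel_size, pb.center, (r, r, r), delta)
    return fld


def _apply_noise(ideal: np.ndarray, noise: NoiseModel,
                 rng: np.random.Generator) -> np.ndarray:
    out = ideal
    if noise.photons_per_au is not None:
        ppa = noise.photons_per_au
        out = rng.poisson(np.clip(out, 0, None) * ppa).astype(float) / ppa
    if noise.read_sd > 0:
        out = out + rng.normal(0.0, noise.read_sd, size=out.shape)
    return out


def generate_cell_stack(truth: GroundTruth, voxel_size,
                        shape: tuple[int, int, int] | None = None,
                        ) -> tuple[ImageStack, GroundTruth]:
    """Render a cell scene through the imaging forward model.

    concentration field → PSF convolution → × gain + offset → noise.
    Returns the stack (channels ``GFP`` and, if marker concentrations are
    set, ``mCherry``) and the unchanged ground truth.
    """
    vs = tuple(float(v) for v in np.broadcast_to(voxel_size, (3,)))  # (dz, dy, dx)
    dz, dy, dx = vs
    psf = truth.psf
    if max(dx, dy) > 0.5 * psf.fwhm_xy + 1e-12:
        raise ValueError(
            f"x-y voxel size {max(dx, dy):.3g} µm too coarse: must be ≤ half the "
            f"x-y PSF FWHM ({0.5 * psf.fwhm_xy:.3g} µm) for FWHM measurement"
        )
    if shape is None:
        margin = 4.0 * max(psf.sigma_x, psf.sigma_y, psf.sigma_z) + 0.5
        xmax = max(c.center[0] + c.axes[0] / 2 for c in truth.cells) + margin
        ymax = max(c.center[1] + c.axes[1] / 2 for c in truth.cells) + margin
        zmax = max(c.center[2] + c.axes[2] / 2 for c in truth.cells) + margin
        shape = (int(np.ceil(zmax / dz)) + 1, int(np.ceil(ymax / dy)) + 1,
                 int(np.ceil(xmax / dx)) + 1)

    sigma_vox = (psf.sigma_z / dz, psf.sigma_y / dy, psf.sigma_x / dx)
    channels, names = [], []
    kinds = ["primary"] + (["marker"] if truth.has_marker else [])
    rng = np.random.default_rng(truth.seed)
    for kind in kinds:
        fld = _render_concentration_field(shape, vs, truth.cells, truth.pbodies, kind)
        blurred = ndimage.gaussian_filter(fld, sigma_vox, mode="constant", truncate=6.0)
        ideal = truth.offset + truth.gain * blurred
        channels.append(_apply_noise(ideal, truth.noise, rng)
                        if truth.noise.enabled else ideal)
        names.append("GFP" if kind == "primary" else "mCherry")
    return ImageStack(np.stack(channels), vs, names), truth


def single_cell_truth(pbody_diameter: float = 0.6, pc: float = 30.0,
                      c_cyto: float = 0.2,
                      cell_axes: tuple[float, float, float] = (5.0, 4.4, 3.6),
                      cell_center: tuple[float, float, float] = (3.0, 3.0, 2.4),
                      psf: PSFModel | None = None, gain: float = 500.0,
                      offset: float = 100.0,
                      noise: NoiseModel = NO_NOISE, seed: int = 0,
                      marker: bool = False) -> GroundTruth:
    """Convenience scene: one mid-size yeast cell with one central P body."""
    psf = psf or PSFModel(0.13, 0.13, 0.34)
    marker_cyto = 0.1 if marker else None
    marker_pb = 10.0 if marker else None
    cell = CellTruth(cell_center, cell_axes, c_cyto, marker_c_cyto=marker_cyto)
    pb = PBodyTruth(cell_center, pbody_diameter, pc * c_cyto,
                    cell=0, marker_c_pbody=marker_pb)
    return GroundTruth((cell,), (pb,), psf, gain, offset, noise, seed)


def generate_bead_stack(psf: PSFModel, bead_diameter: float, n_beads: int,
                        seed: int, voxel_size=(0.1, 0.05, 0.05),
                        shape: tuple[int, int, int] = (40, 160, 160),
                        amplitude: float = 5000.0, background: float = 20.0,
                        noise: NoiseModel = NO_NOISE) -> ImageStack:
    """Isolated blurred spheres at random non-overlapping positions.

    ``amplitude`` is the sphere's pre-blur intensity density (a.u.);
    ``n_beads=0`` gives a background-only stack.
    """
    if bead_diameter <= 0:
        raise ValueError("bead diameter must be positive")
    vs = tuple(float(v) for v in np.broadcast_to(voxel_size, (3,)))
    dz, dy, dx = vs
    rng = np.random.default_rng(seed)
    extent = np.array([shape[0] * dz, shape[1] * dy, shape[2] * dx])  # (z, y, x)
    margin = np.array([bead_diameter / 2 + 4 * psf.sigma_z,
                       bead_diameter / 2 + 4 * psf.sigma_y,
                       bead_diameter / 2 + 4 * psf.sigma_x])
    if np.any(extent <= 2 * margin):
        raise ValueError("stack too small for the requested bead size and PSF")
    min_sep = 4.0 * (psf.fwhm_xy + bead_diameter)
    centers: list[np.ndarray] = []
    attempts = 0
    while len(centers) < n_beads:
        attempts += 1
        if attempts > 20000:
            raise ValueError(
                f"could not place {n_beads} non-overlapping beads in the stack"
            )
        cand = margin + rng.random(3) * (extent - 2 * margin)
        if all(np.linalg.norm(cand - c) >= min_sep for c in centers):
            centers.append(cand)
    fld = np.zeros(shape, dtype=float)
    r = bead_diameter / 2.0
    for cz, cy, cx in centers:
        _add_ellipsoid(fld, vs, (cx, cy, cz), (r, r, r), 1.0)
    sigma_vox = (psf.sigma_z / dz, psf.sigma_y / dy, psf.sigma_x / dx)
    blurred = ndimage.gaussian_filter(fld, sigma_vox, mode="constant", truncate=6.0)
    ideal = background + amplitude * blurred
    data = _apply_noise(ideal, noise, rng) if noise.enabled else ideal
    return ImageStack(data[None], vs, ["beads"])


# ---------------------------------------------------------------------------
# kinetic traces
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KineticGroundTruth:
    """Parameters behind one synthetic FRAP/iFRAP trace.

    The latent (noise- and bleach-free) trace is
    ``L(t) = I_inf + (I_0 - I_inf) exp(-k t)`` with, unless ``iinf`` is given,
    ``I_inf = I_0 + frac (1 - I_0)`` for recovery and ``I_inf = I_0 - frac``
    for decay.  ``acq_bleach_rate`` attenuates every acquired frame by
    ``exp(-rate·t)``; ``cyto_bleach_factor`` is the fraction of the
    cytoplasmic pool surviving the bleach pulse.
    """

    k: float                                    # s^-1
    frac: float                                 # recovery/decay fraction
    i0: float = 0.2
    iinf: float | None = None
    acq_bleach_rate: float = 0.0                # s^-1
    cyto_bleach_factor: float = 1.0
    noise_sd: float = 0.0                       # relative to pre-bleach level
    sample_interval: float = 5.0                # s
    duration: float = 150.0                     # s
    seed: int = 0
    mode: str = "recovery"

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("k must be >= 0")
        if not 0.0 <= self.frac <= 1.0:
            raise ValueError("frac must lie in [0, 1]")
        if self.sample_interval <= 0:
            raise ValueError("sample_interval must be positive")
        if not 0.0 < self.cyto_bleach_factor <= 1.0:
            raise ValueError("cyto_bleach_factor must lie in (0, 1]")
        if self.mode not in ("recovery", "decay"):
            raise ValueError("mode must be 'recovery' or 'decay'")

    def latent(self, t: np.ndarray) -> np.ndarray:
        """Noise- and bleach-free normalized trace."""
        if self.iinf is not None:
            iinf = self.iinf
        elif self.mode == "recovery":
            iinf = self.i0 + self.frac * (1.0 - self.i0)
        else:
            iinf = self.i0 - self.frac
        return iinf + (self.i0 - iinf) * np.exp(-self.k * np.asarray(t, dtype=float))


def generate_frap_trace(kt: KineticGroundTruth, roi_scale: float = 1000.0,
                        ref_scale: float = 800.0, cyto_scale: float = 300.0,
                        background: float = 50.0) -> FRAPTrace:
    """Raw-channel FRAP/iFRAP trace whose normalization recovers the latent curve.

    The raw ROI is the latent trace scaled to instrument units, attenuated by
    acquisition bleaching and (for recovery mode) by the bleach pulse's effect
    on the cytoplasmic pool, on top of a constant background; the reference
    channel carries the acquisition bleaching alone.
    """
    n = int(np.floor(kt.duration / kt.sample_interval)) + 1
    if n < 3:
        raise ValueError("duration must cover at least 3 samples")
    t = np.arange(n) * kt.sample_interval
    rng = np.random.default_rng(kt.seed)
    latent = kt.latent(t)
    acq = np.exp(-kt.acq_bleach_rate * t)
    if kt.mode == "recovery":
        roi = background + roi_scale * latent * acq / kt.cyto_bleach_factor
    else:
        roi = background + roi_scale * latent * acq
    if kt.noise_sd > 0:
        roi = roi + rng.normal(0.0, kt.noise_sd * roi_scale, size=n)
    return FRAPTrace(
        t=t,
        i_roi=roi,
        i_unbleached=background + ref_scale * acq,
        i_background=background,
        i_cyto_before=background + cyto_scale,
        i_cyto_after=background + cyto_scale * kt.cyto_bleach_factor,
        i_prebleach=background + roi_scale,
        mode=kt.mode,
    )


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def generate_paired_table(n: int, rho: float, mean_concs=(10.0, 10.0),
                          sd_log: float = 0.5, seed: int = 0) -> pd.DataFrame:
    """Bivariate-lognormal paired concentrations with log-scale correlation rho.

    Emulates two condensate proteins measured in the same P bodies; ``mean``
    sets the log-scale location (the marginal median concentration in µM).
    """
    if n < 3:
        raise ValueError("need n >= 3 pairs")
    if abs(rho) > 1:
        raise ValueError("|rho| must be <= 1")
    rng = np.random.default_rng(seed)
    cov = sd_log**2 * np.array([[1.0, rho], [rho, 1.0]])
    mu = np.log(np.asarray(mean_concs, dtype=float))
    logs = rng.multivariate_normal(mu, cov, size=n, method="svd")
    return pd.DataFrame({
        "pbody_id": np.arange(n),
        "cell_id": np.arange(n),
        "c_x_uM": np.exp(logs[:, 0]),
        "c_y_uM": np.exp(logs[:, 1]),
    })


def generate_standard_curve_data(gain: float, offset: float, concentrations,
                                 noise_sd: float = 0.0, seed: int = 0,
                                 setting: str = "A") -> pd.DataFrame:
    """GFP solution standard-curve points: intensity = gain·C + offset + noise."""
    conc = np.asarray(concentrations, dtype=float)
    if len(np.unique(conc)) < 2:
        raise ValueError("need at least 2 distinct concentrations")
    rng = np.random.default_rng(seed)
    intensity = gain * conc + offset
    if noise_sd > 0:
        intensity = intensity + rng.normal(0.0, noise_sd, size=len(conc))
    return pd.DataFrame({
        "concentration_uM": conc,
        "intensity_au": intensity,
        "setting": setting,
    })
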