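"""Absolute concentrations and partition coefficients.

Fluorescence intensities are converted to concentrations through a GFP
standard curve (intensity = gain·C + offset, one curve per acquisition
setting).  The measured P-body intensity — the mean of the brightest pixel
and its 8 neighbors in the max-intensity z-plane — underestimates the true
peak for objects near the diffraction limit; only the increment over the
cytoplasm is PSF-diluted, so the true peak is recovered as

    I_pbody = (I_pbody,measured - I_cyto) / CF + I_cyto

with the correction factor CF taken from the sphere-dilution curve at the
object's measured FWHM diameter.  The partition coefficient is
PC = C_pbody / C_cyto.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image import ImageStack
from .psf import CorrectionCurve, cf_lookup
from .segmentation import DetectedObject


@dataclass(frozen=True)
class StandardCurve:
    """Linear intensity↔concentration calibration for one acquisition setting."""

    gain: float                                 # a.u. per µM
    offset: float                               # a.u.
    setting: str
    r_squared: float = 1.0
    n: int = 2

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ValueError("standard-curve gain must be positive")

    def to_concentration(self, intensity: float) -> float:
        """Convert a.u. → µM."""
        return (intensity - self.offset) / self.gain


@dataclass
class PartitionMeasurement:
    """Per-object intensities, correction, concentrations and PC."""

    object_id: int
    i_pbody_measured: float                     # a.u.
    i_cyto: float                               # a.u.
    cf: float
    i_pbody: float                              # a.u. (PSF-corrected peak)
    c_pbody: float                              # µM
    c_cyto: float                               # µM
    pc: float
    diameter: float                             # µm (measured FWHM)
    flags: tuple[str, ...] = ()

    @property
    def is_punctate(self) -> bool:
        """The arbitrary puncta criterion: PC greater than two."""
        return self.pc > 2.0


def fit_standard_curve(points, setting: str) -> StandardCurve:
    """Ordinary least-squares line through (concentration µM, intensity a.u.)."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (concentration, intensity) pairs")
    conc, inten = pts[:, 0], pts[:, 1]
    if len(np.unique(conc)) < 2:
        raise ValueError("need at least 2 distinct concentrations")
    gain, offset = np.polyfit(conc, inten, 1)
    if gain <= 0:
        raise ValueError(f"fitted gain {gain:.3g} is not positive")
    pred = gain * conc + offset
    ss_res = float(np.sum((inten - pred) ** 2))
    ss_tot = float(np.sum((inten - inten.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return StandardCurve(float(gain), float(offset), setting, r2, len(conc))


def measure_pbody_intensity(stack: ImageStack, obj: DetectedObject,
                            channel: str | None = None) -> float:
    """Mean of the max pixel and its one-pixel ring (9 pixels) in the
    max-voxel z-plane."""
    img = stack.channel(channel) if channel else stack.data[0]
    (zi, yi, xi), _ = obj.max_voxel
    ny, nx = img.shape[1:]
    if not (1 <= yi <= ny - 2 and 1 <= xi <= nx - 2):
        raise ValueError("object maximum is adjacent to the image edge")
    patch = img[zi, yi - 1:yi + 2, xi - 1:xi + 2]
    return float(patch.mean())


def measure_cyto_intensity(stack: ImageStack, obj: DetectedObject,
                           cell_mask: np.ndarray, seed: int,
                           channel: str | None = None,
                           all_pbody_masks: np.ndarray | None = None,
                           edge_margin_um: float = 0.3) -> float:
    """Mean of three P-body-sized circular ROIs placed at random in the cytoplasm.

    The allowed region is the cell mask in the object's max-voxel z-plane,
    eroded ``edge_margin_um`` from the membrane (keeping the ROIs clear of
    PSF bleed-through at the cell boundary), minus all P-body masks dilated
    by 2 pixels.  ROI centers are drawn with a seeded generator; ROIs may
    not overlap each other or the P bodies.
    """
    img = stack.channel(channel) if channel else stack.data[0]
    (zi, _, _), _ = obj.max_voxel
    plane = img[zi]
    allowed = np.asarray(cell_mask[zi], dtype=bool)
    erosion_px = max(int(np.ceil(edge_margin_um /
                                 np.sqrt(stack.voxel_size[1] * stack.voxel_size[2]))), 2)
    allowed = ndimage.binary_erosion(allowed, iterations=erosion_px)
    excl = all_pbody_masks[zi] if all_pbody_masks is not None else obj.mask[zi]
    allowed &= ~ndimage.binary_dilation(excl, iterations=2)

    dy, dx = stack.voxel_size[1], stack.voxel_size[2]
    r_px = max(obj.fwhm_xy / 2.0 / np.sqrt(dy * dx), 1.0)
    disk = _disk_footprint(r_px)
    # centers where the full disk fits inside the allowed region
    fits = ndimage.binary_erosion(allowed, structure=disk)
    rng = np.random.default_rng(seed)
    centers: list[tuple[int, int]] = []
    candidates = np.flatnonzero(fits)
    rng.shuffle(candidates)
    for flat in candidates:
        cy, cx = np.unravel_index(flat, fits.shape)
        if all((cy - py) ** 2 + (cx - px) ** 2 >= (2 * r_px) ** 2
               for py, px in centers):
            centers.append((int(cy), int(cx)))
        if len(centers) == 3:
            break
    if len(centers) < 3:
        raise ValueError(
            "insufficient cytoplasm area for three disjoint P-body-sized ROIs"
        )
    means = []
    for cy, cx in centers:
        ys, xs = np.nonzero(disk)
        yy = cy + ys - disk.shape[0] // 2
        xx = cx + xs - disk.shape[1] // 2
        means.append(float(plane[yy, xx].mean()))
    return float(np.mean(means))


def _disk_footprint(r_px: float) -> np.ndarray:
    n = int(np.ceil(r_px))
    yy, xx = np.mgrid[-n:n + 1, -n:n + 1]
    return (yy**2 + xx**2) <= r_px**2


def correct_pbody_intensity(i_measured: float, i_cyto: float, cf: float) -> float:
    """Undo the PSF dilution of the P body's increment over the cytoplasm:
    ``(I_measured - I_cyto)/CF + I_cyto``."""
    if not 0.0 < cf <= 1.0:
        raise ValueError(f"CF must lie in (0, 1], got {cf!r}")
    if i_measured < i_cyto:
        warnings.warn(
            "measured P-body intensity below cytoplasm; corrected value will be "
            "below the cytoplasm level", stacklevel=2,
        )
    return (i_measured - i_cyto) / cf + i_cyto


def quantify_object(stack: ImageStack, obj: DetectedObject,
                    curve: StandardCurve, correction: CorrectionCurve,
                    cell_mask: np.ndarray, seed: int,
                    channel: str | None = None,
                    all_pbody_masks: np.ndarray | None = None,
                    ) -> PartitionMeasurement:
    """Measure, correct and calibrate one P body into a PartitionMeasurement."""
    cf = cf_lookup(correction, obj.fwhm_xy)
    i_meas = measure_pbody_intensity(stack, obj, channel=channel)
    i_cyto = measure_cyto_intensity(stack, obj, cell_mask, seed, channel=channel,
                                    all_pbody_masks=all_pbody_masks)
    flags = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        i_pbody = correct_pbody_intensity(i_meas, i_cyto, cf)
    if i_meas < i_cyto:
        flags.append("measured_below_cytoplasm")
    c_pbody = curve.to_concentration(i_pbody)
    c_cyto = curve.to_concentration(i_cyto)
    if c_cyto <= 0:
        raise ValueError("cytoplasm below calibration offset: C_cyto <= 0")
    return PartitionMeasurement(
        object_id=obj.label, i_pbody_measured=i_meas, i_cyto=i_cyto, cf=cf,
        i_pbody=i_pbody, c_pbody=c_pbody, c_cyto=c_cyto, pc=c_pbody / c_cyto,
        diameter=obj.fwhm_xy, flags=tuple(flags),
    )


def multiplicative_pc(*pcs: float) -> float:
    """Predicted partition coefficient of a fusion whose recruitment elements
    act independently: the product of the elements' individual PCs.

    (Each PC is exponentially related to a partitioning free energy, so the
    product corresponds to the sum of the free energies; a measured fusion PC
    above the product indicates synergy.)"""
    if not pcs:
        raise ValueError("need at least one partition coefficient")
    return float(np.prod(pcs))
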