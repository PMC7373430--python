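"""P-body and cell-boundary identification.

P bodies are segmented by maximum-entropy (Kapur) intensity thresholding —
the Fiji ``MaxEntropy`` convention of a 256-bin histogram between the image
minimum and maximum — either on the measurement channel itself or on a
marker channel (e.g. Edc3-mCherry) whose mask is then transferred.  Cell
boundaries use Otsu thresholding.  Object size is measured as the full width
at half maximum (FWHM) of line profiles through the brightest voxel, the
apparent diameter that indexes the PSF dilution-correction curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .image import ImageStack
from .psf import PSFModel, min_analyzable_diameter

_STRUCT26 = np.ones((3, 3, 3), dtype=int)


# ---------------------------------------------------------------------------
# histogram thresholds (256 uniform bins over [min, max]; Fiji convention)
# ---------------------------------------------------------------------------

def _histogram_256(image: np.ndarray):
    values = np.asarray(image, dtype=float).ravel()
    lo, hi = float(values.min()), float(values.max())
    if lo == hi:
        raise ValueError("cannot threshold a constant image")
    counts, edges = np.histogram(values, bins=256, range=(lo, hi))
    return counts.astype(float), edges


def kapur_maxentropy_threshold(image: np.ndarray) -> float:
    """Kapur maximum-entropy threshold.

    Returns the bin edge t maximizing the sum of the Shannon entropies of the
    background (< t) and foreground (≥ t) histogram classes.  Deterministic:
    ties take the lowest edge.
    """
    counts, edges = _histogram_256(image)
    p = counts / counts.sum()
    best_t, best_h = None, -np.inf
    # partial sums recomputed per candidate: the objective is exactly tied
    # across empty-bin runs, so the tie-break must not depend on summation
    # order
    for t in range(1, 256):
        pb, pf = p[:t].sum(), p[t:].sum()
        if pb <= 0 or pf <= 0:
            continue
        b = p[:t][p[:t] > 0] / pb
        f = p[t:][p[t:] > 0] / pf
        h = -(b * np.log(b)).sum() - (f * np.log(f)).sum()
        if h > best_h:
            best_h, best_t = h, t
    if best_t is None:
        raise ValueError("cannot threshold a constant image")
    return float(edges[best_t])


def otsu_threshold(image: np.ndarray) -> float:
    """Otsu threshold: the 256-bin edge maximizing between-class variance."""
    counts, edges = _histogram_256(image)
    p = counts / counts.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])
    best_t, best_v = None, -np.inf
    for t in range(1, 256):
        wb, wf = p[:t].sum(), p[t:].sum()
        if wb <= 0 or wf <= 0:
            continue
        mb = (p[:t] * centers[:t]).sum() / wb
        mf = (p[t:] * centers[t:]).sum() / wf
        v = wb * wf * (mb - mf) ** 2
        if v > best_v:
            best_v, best_t = v, t
    if best_t is None:
        raise ValueError("cannot threshold a constant image")
    return float(edges[best_t])


# ---------------------------------------------------------------------------
# detected objects
# ---------------------------------------------------------------------------

@dataclass
class DetectedObject:
    """A segmented P body."""

    label: int
    centroid: tuple[float, float, float]        # (x, y, z) µm
    max_voxel: tuple[tuple[int, int, int], float]  # ((z, y, x), intensity a.u.)
    fwhm_xy: float                              # µm
    mask: np.ndarray                            # boolean, full stack shape
    cell: int | None = None


@dataclass
class CellRecord:
    """A segmented cell with its axis diameters and resident objects."""

    cell_id: int
    mask: np.ndarray
    axes: tuple[float, float, float]            # diameters (x, y, z) µm
    mean_intensity: float
    objects: list[DetectedObject] = field(default_factory=list)


def _profile_halfwidth(profile: np.ndarray, peak_idx: int, half: float):
    """Distances (in pixels, interpolated) from the peak to the half-max
    crossings on each side; None if a side never falls below half."""
    out = []
    for step in (-1, 1):
        i = peak_idx
        crossing = None
        while 0 <= i + step < len(profile):
            j = i + step
            if profile[j] <= half:
                frac = (profile[i] - half) / (profile[i] - profile[j])
                crossing = abs(j - peak_idx) - 1 + frac
                break
            i = j
        if crossing is None:
            return None
        out.append(crossing)
    return out


def measure_fwhm_diameter(stack: ImageStack, obj: DetectedObject,
                          channel: str | None = None,
                          baseline: float | None = None) -> float:
    """FWHM diameter (µm) of an object: mean of the x and y line-profile
    widths at half of (peak − cytoplasm baseline), through the max voxel.

    The baseline is the local cytoplasm level; when not given it is estimated
    as the median intensity in an annulus around the object in the max-voxel
    z-plane.
    """
    img = stack.channel(channel) if channel else stack.data[0]
    (zi, yi, xi), peak = obj.max_voxel
    plane = img[zi]
    if baseline is None:
        baseline = _local_baseline(plane, obj.mask[zi], (yi, xi))
    if peak <= baseline:
        raise ValueError("object peak does not exceed the cytoplasm baseline")
    half = baseline + 0.5 * (peak - baseline)
    widths = []
    for profile, pitch, idx in ((plane[yi, :], stack.voxel_size[2], xi),
                                (plane[:, xi], stack.voxel_size[1], yi)):
        hw = _profile_halfwidth(profile, idx, half)
        if hw is None:
            raise ValueError("object not resolvable: profile never falls to half max")
        widths.append((hw[0] + hw[1]) * pitch)
    return float(np.mean(widths))


def _local_baseline(plane: np.ndarray, obj_plane_mask: np.ndarray,
                    center_yx: tuple[int, int],
                    gap: int = 6, width: int = 6) -> float:
    """Median intensity in a ring ``gap``..``gap+width`` pixels outside the
    object's own mask — the local cytoplasm level, past the PSF halo."""
    if not obj_plane_mask.any():
        # object's mask misses this plane; fall back to a small box exclusion
        yi, xi = center_yx
        obj_plane_mask = np.zeros_like(obj_plane_mask)
        obj_plane_mask[max(yi - 2, 0):yi + 3, max(xi - 2, 0):xi + 3] = True
    inner = ndimage.binary_dilation(obj_plane_mask, iterations=gap)
    outer = ndimage.binary_dilation(inner, iterations=width)
    ring = outer & ~inner
    if not ring.any():
        return float(np.median(plane[~inner])) if (~inner).any() else float(np.median(plane))
    return float(np.median(plane[ring]))


def detect_pbodies(stack: ImageStack, channel: str, psf: PSFModel,
                   marker_channel: str | None = None) -> list[DetectedObject]:
    """Identify P bodies by MaxEntropy thresholding.

    With a marker channel, the threshold, mask and FWHM size all come from
    the marker (the P-body definition is independent of the measured
    protein); intensities are read from the measurement channel.  Otherwise
    the measurement channel is thresholded and sized directly.  Components
    are 26-connected; objects whose FWHM diameter does not exceed the
    minimum analyzable diameter (1.1× the x-y PSF FWHM) are discarded.
    """
    meas = stack.channel(channel)
    seg = stack.channel(marker_channel) if marker_channel else meas
    try:
        thr = kapur_maxentropy_threshold(seg)
    except ValueError:
        return []
    mask = seg >= thr
    labels, n = ndimage.label(mask, structure=_STRUCT26)
    min_d = min_analyzable_diameter(psf)
    objects: list[DetectedObject] = []
    dz, dy, dx = stack.voxel_size
    size_channel = marker_channel if marker_channel else channel
    for lab in range(1, n + 1):
        comp = labels == lab
        sz, sy, sx = np.unravel_index(int(np.argmax(np.where(comp, seg, -np.inf))),
                                      seg.shape)
        idx = np.nonzero(comp)
        centroid = (float(idx[2].mean() * dx), float(idx[1].mean() * dy),
                    float(idx[0].mean() * dz))
        sizer = DetectedObject(lab, centroid,
                               ((int(sz), int(sy), int(sx)), float(seg[sz, sy, sx])),
                               fwhm_xy=np.nan, mask=comp)
        try:
            fwhm = measure_fwhm_diameter(stack, sizer, channel=size_channel)
        except ValueError:
            continue
        if fwhm <= min_d:
            continue
        mz, my, mx = np.unravel_index(int(np.argmax(np.where(comp, meas, -np.inf))),
                                      meas.shape)
        objects.append(DetectedObject(
            lab, centroid, ((int(mz), int(my), int(mx)), float(meas[mz, my, mx])),
            fwhm_xy=fwhm, mask=comp))
    return objects


def segment_cells(stack: ImageStack, channel: str | None = None) -> list[CellRecord]:
    """Segment cells by Otsu thresholding; measure axis diameters as the mask
    extents through the centroid along x, y and z.

    The threshold is computed with the top 0.5% of intensities winsorized:
    P bodies occupy far less than 0.5% of the voxels but can be bright enough
    to compress the cell/background histogram into a few bins.
    """
    img = stack.channel(channel) if channel else stack.data[0]
    clipped = np.minimum(img, np.percentile(img, 99.5))
    try:
        thr = otsu_threshold(clipped)
    except ValueError:
        return []
    mask = ndimage.binary_fill_holes(img >= thr)
    labels, n = ndimage.label(mask, structure=_STRUCT26)
    dz, dy, dx = stack.voxel_size
    cells: list[CellRecord] = []
    for lab in range(1, n + 1):
        comp = labels == lab
        idx = np.nonzero(comp)
        cz = int(round(idx[0].mean()))
        cy = int(round(idx[1].mean()))
        cx = int(round(idx[2].mean()))
        axes = (
            _run_length(comp[cz, cy, :], cx) * dx,
            _run_length(comp[cz, :, cx], cy) * dy,
            _run_length(comp[:, cy, cx], cz) * dz,
        )
        if min(axes) <= 0:
            continue
        cells.append(CellRecord(lab, comp, axes, float(img[comp].mean())))
    return cells


def _run_length(line: np.ndarray, at: int) -> int:
    """Length of the contiguous True run containing index ``at`` (0 if False)."""
    if not line[at]:
        return 0
    lo = at
    while lo > 0 and line[lo - 1]:
        lo -= 1
    hi = at
    while hi < len(line) - 1 and line[hi + 1]:
        hi += 1
    return hi - lo + 1


def assign_objects_to_cells(objects: list[DetectedObject],
                            cells: list[CellRecord]) -> None:
    """Attach each object to the cell whose mask contains its max voxel."""
    for obj in objects:
        (zi, yi, xi), _ = obj.max_voxel
        for cell in cells:
            if cell.mask[zi, yi, xi]:
                obj.cell = cell.cell_id
                cell.objects.append(obj)
                break


def filter_expression_outliers(cells: list[CellRecord]) -> list[CellRecord]:
    """Drop the bottom 10% and top 10% of cells by mean intensity.

    ``floor(0.1 n)`` cells are removed from each tail; ties at a boundary are
    broken by stable input order, and the survivors keep their input order.
    """
    if not cells:
        raise ValueError("need at least one cell")
    n = len(cells)
    k = int(np.floor(0.1 * n))
    if k == 0:
        return list(cells)
    order = np.argsort([c.mean_intensity for c in cells], kind="stable")
    dropped = set(order[:k]) | set(order[n - k:])
    return [c for i, c in enumerate(cells) if i not in dropped]
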