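# Methods

This note documents the models, numerical procedures and design choices
behind `pbodyquant`, in the order the pipeline runs them.

## Imaging forward model and synthetic data

The generators in `pbodyquant.synthetic` define the conditions under which
the pipeline is validated. A scene is a set of ellipsoidal cells (axis
diameters ~4–6 µm) holding spherical condensates (0.33–0.8 µm diameter).
The ideal image is a concentration field — C_cyto inside the cell, C_pbody
inside each sphere, zero outside — convolved with a separable anisotropic
Gaussian PSF and mapped to camera units by `I = gain·C + offset`. Noise is
Poisson on a photon image (`photons_per_au` scales a.u. to photons) followed
by additive Gaussian read noise.

Rasterization uses analytic boundary handling: voxels wholly inside or
outside a body are exact; only voxels straddling the surface are oversampled
(5 points per axis), so small spheres are rendered without aliasing.
Convolution uses `scipy.ndimage.gaussian_filter` with a 6σ kernel.

Parameter defaults (all overridable):

| parameter | default | rationale |
| --- | --- | --- |
| PSF σ (x, y, z) | 0.13, 0.13, 0.34 µm | lateral FWHM ≈ 0.31 µm, axial ≈ 0.80 µm, typical of a 1.4 NA confocal |
| C_cyto | 0.2 µM | mid-range cytoplasmic concentration of condensate residents |
| gain, offset | 500 a.u./µM, 100 a.u. | arbitrary linear camera; all results are gain-invariant |
| photons_per_au | 20 | ≈1.6% shot noise at cytoplasm level; frame-averaged point-scanning SNR, at which detection of the weakest/smallest objects still succeeds |
| read_sd | 2 a.u. | small relative to shot noise |
| voxel size | 0.12 × 0.04 × 0.04 µm (z, y, x) | lateral pitch ≪ ½ lateral FWHM so FWHM measurement and the 9-pixel average are fine-grained |
| FRAP cadence | 5 s × 150 s (31 frames) | the acquisition protocol the kinetic parameters refer to |

Kinetic traces are generated as the exact inverse of the normalization
below, so the noiseless round trip (generate → normalize → fit) recovers
(I0, I∞, k) to machine precision for any acquisition-bleach rate and
cytoplasm-bleach factor. Paired-partition tables are bivariate lognormal
with a prescribed log-scale correlation; the marginal median is set by the
`mean_concs` location parameter.

What the generator does **not** emulate: non-Gaussian (Airy/Gibson–Lanni)
optics, depth-dependent aberration, autofluorescence gradients, cell-to-cell
expression variability beyond the per-cell C_cyto, condensate aspherity,
motion, or fusion during acquisition. Passing tests therefore demonstrate
the *estimator chain* is unbiased under its own assumptions, not that those
assumptions hold for any given microscope.

## PSF estimation and the dilution-correction curve

Beads are detected above background, fit with 3-D Gaussians, and pairs
closer than 3 apparent FWHM are discarded. The finite bead size is removed
by quadrature subtraction of the ball's Gaussian-equivalent sd, taken as
d/4; the median over beads is returned. For 0.2 µm beads on a 0.13 µm PSF
this recovers σ to better than 1%.

CF(d) is the integral of the normalized PSF over the centered ball,
evaluated by nested Gauss–Legendre quadrature: the y–z disk integral at
each chord (96 radial × 64 angular nodes) reduces the problem to a 1-D
convolution along x (192 nodes). Accuracy is ~1e-4 relative, verified
against Monte-Carlo ball integration (uniform sampling in the ball) at 10⁶–
10⁷ samples and against brute-force rendered-and-blurred spheres.

The curve stores, per true diameter, both CF and the **apparent diameter**
(FWHM of the blurred sphere's profile through its center). Lookup is by
apparent diameter, because the pipeline only ever observes blurred sizes;
the inverse map provides a deblurred diameter estimate for volume
calculations (a flag restores the raw-FWHM convention). One genuinely
counterintuitive property, confirmed against an independent rendered-image
oracle: with a strongly anisotropic PSF, the apparent FWHM of a mid-size
sphere can be *smaller* than its true diameter, because the long axial PSF
drains proportionally more light from the rim (thin chords) than from the
center — e.g. a 1.0 µm sphere presents a 0.84 µm FWHM under
σ = (0.13, 0.13, 0.34) µm. The map remains strictly monotone, so inversion
is well defined.

Measured diameters below 1.1× the lateral PSF FWHM (geometric mean of x and
y) are rejected: below that, FWHM stops tracking object size and CF becomes
too steep to invert stably.

## Segmentation

Both thresholds use the Fiji convention: a 256-bin histogram between the
image minimum and maximum, exhaustive search over the 255 interior bin
edges, first maximizer on ties. Because the objective is exactly constant
across runs of empty bins, partial sums are recomputed per candidate rather
than accumulated, making the tie-break independent of summation order.
Kapur's criterion (sum of class Shannon entropies) segments condensates;
Otsu (between-class variance) segments cells, computed on an image whose
top 0.5% of intensities is winsorized so that a very bright condensate
cannot compress the cell/background histogram. Components are 26-connected;
cell masks are hole-filled, and axis diameters are the mask extents through
the centroid (quantized to the voxel grid, ±1 voxel per boundary).

Object size is the mean of the x and y line-profile FWHMs through the
brightest voxel, with linear interpolation at the half-maximum crossings.
The baseline is the local cytoplasm level, estimated as the median in a
ring 6–12 px outside the object's mask (past the PSF halo); an explicit
baseline can be supplied. With a marker channel (e.g. a constitutive
condensate protein in mCherry), thresholding, masking *and sizing* use the
marker; intensities are then read from the measurement channel, so weakly
partitioning proteins (PC ≈ 2) remain measurable.

Expression trimming removes the bottom and top 10% of cells (floor(0.1 n)
per tail) ranked by mean intensity with a stable sort, so boundary ties
resolve by input order.

## Quantification

The measured condensate intensity is the mean of the brightest pixel and
its 8 neighbors in the max-intensity z-plane. Cytoplasm is the mean of
three disjoint condensate-sized circular ROIs placed by a seeded RNG in the
same z-plane, inside the cell mask eroded by 0.3 µm (≈2.3 lateral σ, so the
membrane's PSF bleed cannot bias the estimate; a fixed 2-pixel erosion is
pitch-dependent and was measurably biased at fine pitches) and clear of all
condensate masks dilated by 2 px. Only the increment over the cytoplasm is
divided by CF — the cytoplasmic contribution is homogeneous and not diluted
by the PSF. Concentrations use the per-setting standard curve; curves are
matched to images by acquisition-setting id and mixing settings is an
error. A measured intensity below the cytoplasm is flagged, not clamped.

Validated recovery, at the defaults above: noiseless PC error < 5% for all
d ∈ {0.4, 0.6, 0.8} µm × PC ∈ {5, 30, 130}; with default noise the median
error over 50 seeds is < 9% in every cell of the grid (the worst corner is
the smallest, weakest object, where CF is steepest in the measured
diameter).

## Sequestration accounting

N_cyto = V_cell · 0.67 · C_cyto · N_A and N_pbody = Σ (π/6)d³ · C_pbody ·
N_A, with V_cell the ellipsoid volume from the three axis diameters and
0.67 the cytoplasmic volume fraction (a named, overridable constant).
F_P = N_pbody/(N_cyto + N_pbody); F_P,max rescales F_P by the reference
(most-sequestered) protein's value under the assumption that all condensates
share that protein's composition, and is flagged if it exceeds 1. Counts
are kept as floats and rounded only for reporting; N_A = 6.02214076e23.
Condensate volumes use the deblurred diameter by default.

## FRAP / iFRAP

Normalization (recovery):

    I_t(t) = [ (I_roi(t) − bg) / (I_unb(t) − bg) ] · (I_cyto,after − bg)/(I_cyto,before − bg) / P ,
    P      = (I_pre − bg) / (I_unb(0) − bg) ,

i.e. double normalization against an unbleached reference condensate
(removing acquisition bleaching), a constant factor for the cytoplasmic
pool bleached by the pulse, and rescaling so the pre-bleach level maps
to 1. The pre-bleach normalizer P deliberately omits the cytoplasm factor
(pre-bleach cytoplasm *is* the "before" state; including the constant in
both places would cancel it). The reciprocal cytoplasm convention is
available as a switch. iFRAP divides the bleach-corrected trace by its
first post-bleach frame, so I_t(0) = 1.

Fitting: `I(t) = I∞ + (I0 − I∞)e^(−kt)` by bounded least squares (k ≥ 0),
initialized from the first point, the mean of the last three points, and a
log-linear rate estimate, with 5 multiplicatively jittered restarts
(×{1, ½, 2, ¼, 4}); tolerances 1e-12, max 10⁴ evaluations. Fractional
recovery F = (I∞−I0)/(1−I0), fractional decay F = I0−I∞. A flat trace
returns frac = 0 with `k_identifiable=False` rather than an arbitrary rate;
non-convergence sets `converged=False` without raising. Time origin is the
first post-bleach frame.

## Co-partitioning statistics

Paired ratios are C_x,i/C_y,i per condensate; randomized ratios draw i ≠ j
uniformly with replacement (a derangement-permutation variant is
selectable). Spread comparisons are made on log ratios (ratios are
scale-asymmetric); raw-ratio results are reported alongside. Variance
equality uses the Fligner–Killeen test (scipy's implementation, which is
the standard median-centered rank/normal-scores recipe; verified against a
permutation null in the tests) and location shifts use a Wilcoxon rank-sum
with midranks — exact by complete enumeration for combined n ≤ 12,
otherwise normal approximation with tie and continuity corrections.
Significance labels: *** p<0.001, **** p<0.0005. The HC/LC rule is a
conjunction: HC iff PC ≥ 30 and C_pbody > 5 µM (strict on concentration).

A power caveat: at a log-scale pair correlation of 0.65 and 86 condensates,
the paired-vs-randomized Fligner–Killeen test at α = 0.001 rejects in ~78%
of replicates (87% with derangement pairing); ≥90% rejection requires a
log-scale correlation of about 0.70 — numerically consistent with a raw-scale
Pearson correlation of 0.65 on lognormal data, whose log-scale counterpart
is higher.

## Network centrality

Edge lists are undirected and unweighted; complex-collapse maps (e.g.
Lsm1…Lsm7 → "Lsm1-7") are applied before deduplication so a complex
inherits the union of its members' partners, intra-complex edges vanishing.
Valency is the degree. Eigenvector centrality is computed by power
iteration on **A + I**: the spectral shift leaves eigenvectors untouched
while making the dominant eigenvalue strictly largest in magnitude, so the
iteration converges on bipartite components where plain power iteration
oscillates — and, unlike damping toward a fixed vector, introduces no bias,
which is why the result matches a dense eigensolver to 1e-8 on every test
fixture. Tolerance 1e-12, max 10⁵ iterations, scores L2-normalized and
non-negative; reporting can be restricted to the component containing a
chosen node (typically RNA).

## Pipeline

`run_inventory` chains segmentation → expression trimming (pooled across
stacks) → quantification → per-cell accounting, and summarizes mean PC ±
SEM, mean C_pbody ± SEM, mean F_P and the HC/LC label. By default one
condensate per cell is analyzed (the brightest passing the size filter);
`all_pbodies=True` overrides. Per-object ROI seeds are derived
deterministically from the run seed, stack index, cell id and object label,
so reruns are bit-identical and the manifest (tool version, seed, config
hash) suffices to reproduce any table. The correction curve (default grid
0.15–2.5 µm, 40 points) is cached per PSF.

Problem sizes used in the validation suite — single-cell stacks of roughly
180×180×50 voxels, 50 noise replicates per sweep condition, 100-seed power
and calibration replicates, 10⁶–10⁷ Monte-Carlo samples per correction-factor
check — were chosen to keep each statistical tolerance comfortably inside
its Monte-Carlo error.

## Known limitations

- The Gaussian-PSF assumption is load-bearing for CF; an empirical bead PSF
  can be estimated but the correction curve is currently built only from
  the Gaussian fit to it.
- Cell axis measurement is automated mask-extent (±1 voxel quantization);
  budding cells are not split.
- The cytoplasm ROI is measured in a single z-plane (the condensate's
  max-intensity plane), matching the condensate measurement.
- No multiple-testing correction across proteins; p-values are
  per-comparison.
- Sub-minimum condensates are invisible to the inventory; F_P is therefore
  a lower bound, which is exactly what F_P,max is for.
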