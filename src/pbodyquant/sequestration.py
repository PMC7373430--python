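"""Molecule-count bookkeeping: how much of a protein do condensates hold?

Cells are treated as ellipsoids of which a fixed fraction (0.67 by default)
is cytoplasm; P bodies as spheres.  Concentrations (µM) and volumes (µm³)
convert to molecule counts through Avogadro's number, giving the fraction of
a protein's cellular pool sequestered in visible condensates (F_P), an upper
bound F_P,max rescaled by the most-sequestered reference protein, and the
average cellular concentration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Avogadro's number, molecules per mole.
AVOGADRO = 6.02214076e23

#: Fraction of total yeast cell volume that is cytoplasm.
CYTOPLASM_FRACTION = 0.67

# 1 µm³ = 1e-15 L; 1 µM = 1e-6 mol/L
_MOLECULES_PER_UM3_UM = 1e-15 * 1e-6 * AVOGADRO


@dataclass
class SequestrationResult:
    v_cell: float                               # µm³
    v_pbodies: list[float]                      # µm³
    n_cyto: float                               # molecules
    n_pbody: float                              # molecules
    f_p: float
    avg_cell_conc: float                        # µM


def cell_volume(x: float, y: float, z: float) -> float:
    """Ellipsoid volume (µm³) from axis diameters (µm): 4/3·π·(x/2)(y/2)(z/2)."""
    if min(x, y, z) <= 0:
        raise ValueError("axis diameters must be positive")
    return (4.0 / 3.0) * np.pi * (x / 2.0) * (y / 2.0) * (z / 2.0)


def molecules_in_cytoplasm(v_cell: float, c_cyto: float,
                           cytoplasm_fraction: float = CYTOPLASM_FRACTION) -> float:
    """N_cyto = V_cell · fraction · C_cyto · N_A (float; round only on report)."""
    if v_cell < 0 or c_cyto < 0:
        raise ValueError("volume and concentration must be >= 0")
    return v_cell * cytoplasm_fraction * c_cyto * _MOLECULES_PER_UM3_UM


def molecules_in_pbodies(diameters, concentrations) -> float:
    """N_pbody = Σ (π/6)d³ · C · N_A over the cell's P bodies."""
    d = np.asarray(diameters, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    if d.shape != c.shape:
        raise ValueError("diameters and concentrations must have equal length")
    if d.size == 0:
        return 0.0
    if np.any(d < 0) or np.any(c < 0):
        raise ValueError("diameters and concentrations must be >= 0")
    v = np.pi / 6.0 * d**3
    return float(np.sum(v * c) * _MOLECULES_PER_UM3_UM)


def fraction_in_pbodies(n_pbody: float, n_cyto: float) -> float:
    """F_P = N_pbody / (N_cyto + N_pbody)."""
    if n_pbody < 0 or n_cyto < 0:
        raise ValueError("molecule counts must be >= 0")
    total = n_pbody + n_cyto
    if total == 0:
        raise ValueError("cannot compute a fraction of zero molecules")
    return n_pbody / total


def fp_max(f_p: float, f_p_reference: float) -> float:
    """Upper-bound sequestration estimate: F_P rescaled so the reference
    (most-sequestered) protein's value maps to 1.

    Assumes all condensates in a cell share the reference protein's
    composition independent of size; may exceed 1 for noisy inputs (the
    caller should flag, not clamp).
    """
    if not 0.0 < f_p_reference <= 1.0:
        raise ValueError("reference fraction must lie in (0, 1]")
    if not 0.0 <= f_p <= 1.0:
        raise ValueError("f_p must lie in [0, 1]")
    return f_p / f_p_reference


def average_cellular_concentration(sum_vp_cp: float, v_cell: float,
                                   c_cyto: float,
                                   cytoplasm_fraction: float = CYTOPLASM_FRACTION,
                                   ) -> float:
    """(Σ V_p·C_p + V_cell·fraction·C_cyto) / (V_cell·fraction), in µM."""
    if v_cell <= 0:
        raise ValueError("cell volume must be positive")
    v_cyto = v_cell * cytoplasm_fraction
    return (sum_vp_cp + v_cyto * c_cyto) / v_cyto


def sequestration_summary(cell_axes, c_cyto: float, pbody_diameters,
                          pbody_concentrations,
                          cytoplasm_fraction: float = CYTOPLASM_FRACTION,
                          ) -> SequestrationResult:
    """Full per-cell accounting from axis diameters and measured concentrations."""
    v_cell = cell_volume(*cell_axes)
    d = np.asarray(pbody_diameters, dtype=float)
    c = np.asarray(pbody_concentrations, dtype=float)
    v_p = (np.pi / 6.0 * d**3).tolist()
    n_cyto = molecules_in_cytoplasm(v_cell, c_cyto, cytoplasm_fraction)
    n_pb = molecules_in_pbodies(d, c)
    f_p = fraction_in_pbodies(n_pb, n_cyto) if (n_pb + n_cyto) > 0 else 0.0
    avg = average_cellular_concentration(float(np.sum(np.array(v_p) * c)) if d.size else 0.0,
                                         v_cell, c_cyto, cytoplasm_fraction)
    return SequestrationResult(v_cell, v_p, n_cyto, n_pb, f_p, avg)
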