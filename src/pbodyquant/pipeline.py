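"""End-to-end orchestration: stacks → segmentation → quantification → summary.

``run_inventory`` drives the full chain on a set of 3-D stacks: cell and
P-body segmentation, expression-outlier trimming, PSF dilution correction,
standard-curve calibration, partition coefficients, and per-cell molecule
bookkeeping, emitting per-object and per-cell tables plus a per-run summary
(mean PC ± SEM, mean C_pbody ± SEM, mean F_P, HC/LC label) and a manifest
that reproduces the run.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from functools import lru_cache

import numpy as np
import pandas as pd

from . import __version__
from .copartition import classify_hc_lc
from .image import ImageStack, load_stack
from .psf import CorrectionCurve, PSFModel, build_correction_curve
from .quantification import StandardCurve, quantify_object
from .segmentation import (assign_objects_to_cells, detect_pbodies,
                           filter_expression_outliers, segment_cells)
from .sequestration import CYTOPLASM_FRACTION, sequestration_summary


@dataclass
class RunConfig:
    """Everything needed to reproduce an inventory run."""

    psf: PSFModel
    curve: StandardCurve
    seed: int = 0
    channel: str = "GFP"
    marker_channel: str | None = None
    correction_grid: tuple[float, float, int] = (0.15, 2.5, 40)  # µm (lo, hi, n)
    expression_trim: float = 0.10
    cytoplasm_fraction: float = CYTOPLASM_FRACTION
    all_pbodies: bool = False          # default: brightest passing P body per cell
    use_corrected_diameter: bool = True  # invert the blur for P-body volumes

    def config_hash(self) -> str:
        payload = {k: v for k, v in asdict(self).items()}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@lru_cache(maxsize=8)
def _cached_curve(psf: PSFModel,
                  grid: tuple[float, float, int]) -> CorrectionCurve:
    lo, hi, n = grid
    return build_correction_curve(psf, np.linspace(lo, hi, int(n)))


def _sem(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else float("nan")


def run_inventory(stacks: list[ImageStack] | list[str], config: RunConfig) -> dict:
    """Run the full quantitative inventory over a list of stacks (or paths).

    Returns ``{"objects": DataFrame, "cells": DataFrame,
    "summary": dict, "manifest": dict}``.
    """
    correction = _cached_curve(config.psf, config.correction_grid)

    object_rows: list[dict] = []
    cell_rows: list[dict] = []
    all_cells = []
    per_stack = []
    for si, stack in enumerate(stacks):
        if isinstance(stack, str):
            stack = load_stack(stack)
        cells = segment_cells(stack, channel=config.channel)
        objects = detect_pbodies(stack, config.channel, config.psf,
                                 marker_channel=config.marker_channel)
        assign_objects_to_cells(objects, cells)
        per_stack.append((si, stack, cells))
        all_cells.extend((si, c) for c in cells)

    kept = filter_expression_outliers([c for _, c in all_cells]) if all_cells else []
    kept_ids = {id(c) for c in kept}

    for si, stack, cells in per_stack:
        union_mask = None
        for c in cells:
            for o in c.objects:
                union_mask = o.mask if union_mask is None else (union_mask | o.mask)
        for cell in cells:
            if id(cell) not in kept_ids or not cell.objects:
                continue
            objs = sorted(cell.objects, key=lambda o: -o.max_voxel[1])
            if not config.all_pbodies:
                objs = objs[:1]
            diameters, concs = [], []
            for obj in objs:
                seed = config.seed + 104729 * si + 1009 * cell.cell_id + obj.label
                try:
                    m = quantify_object(stack, obj, config.curve, correction,
                                        cell.mask, seed % (2**31), channel=config.channel,
                                        all_pbody_masks=union_mask)
                except ValueError as err:
                    raise RuntimeError(
                        f"quantification failed at stack {si}, cell "
                        f"{cell.cell_id}, object {obj.label}: {err}"
                    ) from err
                d_true = (correction.true_from_apparent(m.diameter)
                          if config.use_corrected_diameter else m.diameter)
                diameters.append(d_true)
                concs.append(m.c_pbody)
                object_rows.append({
                    "stack": si, "cell_id": cell.cell_id, "object_id": m.object_id,
                    "diameter_um": m.diameter, "diameter_true_um": d_true,
                    "cf": m.cf, "i_pbody_measured": m.i_pbody_measured,
                    "i_cyto": m.i_cyto, "i_pbody": m.i_pbody,
                    "c_pbody_uM": m.c_pbody, "c_cyto_uM": m.c_cyto, "pc": m.pc,
                    "punctate": m.is_punctate, "flags": ";".join(m.flags),
                })
            c_cyto = object_rows[-1]["c_cyto_uM"]
            seq = sequestration_summary(cell.axes, c_cyto, diameters, concs,
                                        config.cytoplasm_fraction)
            cell_rows.append({
                "stack": si, "cell_id": cell.cell_id,
                "x_um": cell.axes[0], "y_um": cell.axes[1], "z_um": cell.axes[2],
                "v_cell_um3": seq.v_cell, "n_cyto": round(seq.n_cyto),
                "n_pbody": round(seq.n_pbody), "f_p": seq.f_p,
                "avg_conc_uM": seq.avg_cell_conc,
            })

    objects_df = pd.DataFrame(object_rows)
    cells_df = pd.DataFrame(cell_rows)
    if len(objects_df):
        pc = objects_df["pc"].to_numpy()
        cp = objects_df["c_pbody_uM"].to_numpy()
        summary = {
            "n_objects": int(len(objects_df)),
            "n_cells": int(len(cells_df)),
            "mean_pc": float(pc.mean()), "sem_pc": _sem(pc),
            "mean_c_pbody_uM": float(cp.mean()), "sem_c_pbody_uM": _sem(cp),
            "mean_f_p": float(cells_df["f_p"].mean()) if len(cells_df) else float("nan"),
            "class": classify_hc_lc(float(pc.mean()), float(cp.mean())),
        }
    else:
        summary = {"n_objects": 0, "n_cells": int(len(cells_df))}
    manifest = {
        "tool": "pbodyquant", "version": __version__,
        "seed": config.seed, "config_hash": config.config_hash(),
        "n_stacks": len(stacks),
    }
    return {"objects": objects_df, "cells": cells_df,
            "summary": summary, "manifest": manifest}
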