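"""FRAP and iFRAP normalization and single-exponential exchange-rate fitting.

Condensate components exchange with the surrounding cytoplasm.  Photobleaching
either the condensate (FRAP, fluorescence recovers) or everything else (iFRAP,
condensate fluorescence decays) and fitting the normalized trace to

    I(t) = I_inf + (I_0 - I_inf) * exp(-k t)

yields the exchange rate ``k`` (s^-1) and, from the fitted plateau values, the
fractional recovery ``F = (I_inf - I_0) / (1 - I_0)`` (FRAP) or fractional
decay ``F = I_0 - I_inf`` (iFRAP).

Normalization corrects the raw region-of-interest trace for background, for
photobleaching during image acquisition (via an unbleached reference
condensate), and — for FRAP in small cells — for the slight bleaching of the
cytoplasmic pool by the bleach pulse itself (via the cytoplasm intensity
before vs. just after the pulse).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize


@dataclass
class FRAPTrace:
    """A raw photobleaching time series plus its normalization scalars.

    ``t`` starts at 0 at the first post-bleach frame.  ``mode`` is
    ``"recovery"`` (FRAP) or ``"decay"`` (iFRAP).
    """

    t: np.ndarray
    i_roi: np.ndarray
    i_unbleached: np.ndarray
    i_background: float
    i_cyto_before: float
    i_cyto_after: float
    i_prebleach: float
    mode: str = "recovery"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.i_roi = np.asarray(self.i_roi, dtype=float)
        self.i_unbleached = np.asarray(self.i_unbleached, dtype=float)
        if self.mode not in ("recovery", "decay"):
            raise ValueError("mode must be 'recovery' or 'decay'")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time must be strictly increasing")
        if not (len(self.t) == len(self.i_roi) == len(self.i_unbleached)):
            raise ValueError("all channels must have the same length as t")

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# mode={self.mode}\n")
            fh.write(f"# i_background={float(self.i_background)!r}\n")
            fh.write(f"# i_cyto_before={float(self.i_cyto_before)!r}\n")
            fh.write(f"# i_cyto_after={float(self.i_cyto_after)!r}\n")
            fh.write(f"# i_prebleach={float(self.i_prebleach)!r}\n")
            fh.write("t_s,I_roi,I_unbleached\n")
            for row in zip(self.t, self.i_roi, self.i_unbleached):
                fh.write(",".join(repr(float(v)) for v in row) + "\n")

    @classmethod
    def from_csv(cls, path) -> "FRAPTrace":
        scalars = {}
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    key, _, val = line.lstrip("# ").partition("=")
                    scalars[key.strip()] = val.strip()
                elif not line.startswith("t_s"):
                    rows.append([float(v) for v in line.split(",")])
        arr = np.array(rows)
        return cls(
            arr[:, 0], arr[:, 1], arr[:, 2],
            i_background=float(scalars["i_background"]),
            i_cyto_before=float(scalars["i_cyto_before"]),
            i_cyto_after=float(scalars["i_cyto_after"]),
            i_prebleach=float(scalars["i_prebleach"]),
            mode=scalars.get("mode", "recovery"),
        )


@dataclass
class ExpFit:
    """Single-exponential fit result (normalized intensity units)."""

    i0: float
    iinf: float
    k: float
    frac: float
    residual_sd: float
    converged: bool
    k_identifiable: bool = True


def normalize_frap(trace: FRAPTrace, cyto_correction: str = "after_over_before") -> np.ndarray:
    """Normalize a FRAP trace to a dimensionless recovery curve (pre-bleach ≈ 1).

    The background-subtracted ROI is divided by the unbleached reference at
    each time point (removing acquisition bleaching), multiplied by the
    cytoplasm after/before ratio (accounting for bleach-pulse loss from the
    cytoplasmic pool), and rescaled so the pre-bleach value maps to 1.
    ``cyto_correction="before_over_after"`` selects the reciprocal convention.
    """
    if trace.mode != "recovery":
        raise ValueError("normalize_frap requires a recovery-mode trace")
    bg = trace.i_background
    denom_ref = trace.i_unbleached - bg
    if np.any(denom_ref <= 0):
        raise ValueError("unbleached reference must exceed background at all times")
    cb = trace.i_cyto_before - bg
    ca = trace.i_cyto_after - bg
    if cb <= 0 or ca <= 0:
        raise ValueError("cytoplasm intensities must exceed background")
    if cyto_correction == "after_over_before":
        cyto = ca / cb
    elif cyto_correction == "before_over_after":
        cyto = cb / ca
    else:
        raise ValueError("unknown cyto_correction")
    i_rec = (trace.i_roi - bg) / denom_ref * cyto
    # pre-bleach normalizer: same ROI/reference ratio evaluated before the
    # bleach pulse (cytoplasm factor is unity there by definition)
    pre = (trace.i_prebleach - bg) / denom_ref[0]
    if pre <= 0:
        raise ValueError("pre-bleach intensity must exceed background")
    return i_rec / pre


def normalize_ifrap(trace: FRAPTrace) -> np.ndarray:
    """Normalize an iFRAP trace so the first post-bleach frame equals 1."""
    if trace.mode != "decay":
        raise ValueError("normalize_ifrap requires a decay-mode trace")
    bg = trace.i_background
    denom_ref = trace.i_unbleached - bg
    if np.any(denom_ref <= 0):
        raise ValueError("unbleached reference must exceed background at all times")
    corrected = (trace.i_roi - bg) / denom_ref
    if corrected[0] <= 0:
        raise ValueError("first post-bleach frame must exceed background")
    return corrected / corrected[0]


def _exp_model(t, i0, iinf, k):
    return iinf + (i0 - iinf) * np.exp(-k * t)


def _fit_exponential(t: np.ndarray, i_t: np.ndarray, mode: str) -> ExpFit:
    t = np.asarray(t, dtype=float)
    i_t = np.asarray(i_t, dtype=float)
    if len(t) < 4:
        raise ValueError("need at least 4 points for a 3-parameter fit")
    if not np.all(np.isfinite(i_t)):
        raise ValueError("intensities must be finite")

    i0_init = float(i_t[0])
    iinf_init = float(i_t[-3:].mean())
    span = iinf_init - i0_init
    # flat trace: k is unidentifiable, report the mean level
    if np.ptp(i_t) < 1e-12 or abs(span) < 1e-12:
        mean = float(i_t.mean())
        resid = float(np.std(i_t - mean))
        frac = 0.0 if mode == "decay" else _recovery_frac(mean, mean)
        return ExpFit(mean, mean, 0.0, frac, resid, True, k_identifiable=False)

    # log-linear initial rate from the normalized approach to the plateau
    z = (iinf_init - i_t) / span
    good = z > 1e-3
    if good.sum() >= 2:
        slope = np.polyfit(t[good], np.log(z[good]), 1)[0]
        k_init = max(-slope, 1e-6)
    else:
        k_init = 1.0 / max(t[-1], 1e-9)

    best = None
    for jitter in (1.0, 0.5, 2.0, 0.25, 4.0):
        try:
            popt, _ = optimize.curve_fit(
                _exp_model, t, i_t,
                p0=[i0_init, iinf_init, k_init * jitter],
                bounds=([-np.inf, -np.inf, 0.0], [np.inf, np.inf, np.inf]),
                maxfev=10000, xtol=1e-12, ftol=1e-12,
            )
        except RuntimeError:
            continue
        sse = float(np.sum((_exp_model(t, *popt) - i_t) ** 2))
        if best is None or sse < best[1] - 1e-10:
            best = (popt, sse)
    if best is None:
        return ExpFit(i0_init, iinf_init, 0.0, 0.0, float("nan"), False)
    (i0, iinf, k), sse = best
    resid = float(np.sqrt(sse / len(t)))
    frac = (i0 - iinf) if mode == "decay" else _recovery_frac(i0, iinf)
    return ExpFit(float(i0), float(iinf), float(k), float(frac), resid, True)


def _recovery_frac(i0: float, iinf: float) -> float:
    if abs(1.0 - i0) < 1e-12:
        return 0.0
    return (iinf - i0) / (1.0 - i0)


def fit_recovery(t, i_t) -> ExpFit:
    """Fit a normalized FRAP trace; ``frac = (I_inf - I_0)/(1 - I_0)``."""
    return _fit_exponential(t, i_t, "recovery")


def fit_decay(t, i_t) -> ExpFit:
    """Fit a normalized iFRAP trace; ``frac = I_0 - I_inf``."""
    return _fit_exponential(t, i_t, "decay")
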