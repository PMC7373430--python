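"""Co-partitioning statistics for pairs of condensate proteins.

If two proteins are recruited cooperatively, their concentrations measured in
the same condensates correlate, and the spread of their per-condensate
concentration ratios is narrower than the spread obtained after randomizing
the pairing.  This module provides the paired/randomized ratio construction,
Pearson correlation, and the two rank-based tests used to compare groups:
the Wilcoxon rank-sum test (location) and the Fligner-Killeen test (equality
of variance), plus the HC/LC concentration classification.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    n: tuple[int, ...]

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value must lie in [0, 1]")

    @property
    def significance(self) -> str:
        """Star label: **** p<0.0005, *** p<0.001."""
        if self.p_value < 0.0005:
            return "****"
        if self.p_value < 0.001:
            return "***"
        return "ns"


def _validate_table(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    x = table["c_x_uM"].to_numpy(dtype=float)
    y = table["c_y_uM"].to_numpy(dtype=float)
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("concentrations must be positive")
    return x, y


def pearson_r(x, y) -> float:
    """Sample Pearson correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(x) != len(y):
        raise ValueError("need n >= 3 paired values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance")
    return float(stats.pearsonr(x, y).statistic)


def paired_ratios(table: pd.DataFrame) -> np.ndarray:
    """Per-condensate concentration ratios C_x,i / C_y,i, input order preserved."""
    x, y = _validate_table(table)
    return x / y


def randomized_ratios(table: pd.DataFrame, seed: int,
                      method: str = "replacement") -> np.ndarray:
    """Ratios C_x,i / C_y,j with the pairing randomized (i ≠ j), same length.

    ``method="replacement"`` draws both indices uniformly with replacement,
    redrawing self-pairs; ``"derangement"`` pairs each i with a uniformly
    drawn fixed-point-free permutation.
    """
    x, y = _validate_table(table)
    n = len(x)
    if n < 2:
        raise ValueError("need n >= 2 rows to randomize pairing")
    rng = np.random.default_rng(seed)
    if method == "replacement":
        i = np.empty(n, dtype=int)
        j = np.empty(n, dtype=int)
        for m in range(n):
            a = int(rng.integers(n))
            b = int(rng.integers(n))
            while b == a:
                b = int(rng.integers(n))
            i[m], j[m] = a, b
        return x[i] / y[j]
    if method == "derangement":
        while True:
            perm = rng.permutation(n)
            if not np.any(perm == np.arange(n)):
                return x / y[perm]
    raise ValueError("method must be 'replacement' or 'derangement'")


def fligner_killeen(*groups) -> TestResult:
    """Fligner-Killeen test of equal variances across ≥2 groups.

    Median-centered absolute values are ranked across the pooled sample,
    transformed by standard-normal quantiles, and compared by a chi-squared
    statistic on the group mean scores (k-1 df).
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) < 2 for a in arrays):
        raise ValueError("each group needs n >= 2")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        raise ValueError("degenerate input: all values equal")
    stat, p = stats.fligner(*arrays)
    return TestResult(float(stat), float(p), "fligner-killeen",
                      tuple(len(a) for a in arrays))


def wilcoxon_rank_sum(a, b, method: str = "auto") -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test with midranks for ties.

    ``method="auto"``: exact p by complete enumeration of rank assignments
    when the combined sample size is ≤ 12, otherwise the normal approximation
    with tie and continuity corrections.  ``"exact"``/``"normal"`` force a
    branch.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    if na < 1 or nb < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)               # midranks
    w_obs = float(ranks[:na].sum())              # rank sum of sample a
    u_obs = w_obs - na * (na + 1) / 2.0
    n = na + nb
    if method not in ("auto", "exact", "normal"):
        raise ValueError("method must be 'auto', 'exact' or 'normal'")
    if method == "exact" or (method == "auto" and n <= 12):
        mu = na * (n + 1) / 2.0
        extreme = 0
        total = comb(n, na)
        dev = abs(w_obs - mu)
        for idx in combinations(range(n), na):
            w = ranks[list(idx)].sum()
            if abs(w - mu) >= dev - 1e-9:
                extreme += 1
        p = extreme / total
        method = "wilcoxon-exact"
    else:
        mu_u = na * nb / 2.0
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = np.sum(counts**3 - counts) / (n * (n - 1))
        var_u = na * nb / 12.0 * ((n + 1) - tie_term)
        if var_u <= 0:
            p = 1.0
        else:
            z = (abs(u_obs - mu_u) - 0.5) / np.sqrt(var_u)
            p = 2.0 * stats.norm.sf(max(z, 0.0))
        method = "wilcoxon-normal"
    return TestResult(u_obs, min(float(p), 1.0), method, (na, nb))


#: HC classification cutoffs: partition coefficient and condensate concentration.
HC_PC_CUTOFF = 30.0
HC_CONC_CUTOFF_UM = 5.0


def classify_hc_lc(pc: float, c_pbody: float) -> str:
    """Label a protein highly concentrated (``HC``: PC ≥ 30 and C_pbody > 5 µM)
    or less concentrated (``LC``)."""
    if pc <= 0 or c_pbody <= 0:
        raise ValueError("pc and concentration must be positive")
    return "HC" if (pc >= HC_PC_CUTOFF and c_pbody > HC_CONC_CUTOFF_UM) else "LC"


def copartition_report(table: pd.DataFrame, seed: int) -> dict:
    """Summary of one paired-measurement table: correlation, ratio spreads and
    the paired-vs-randomized variance test (on log ratios and raw ratios)."""
    x, y = _validate_table(table)
    paired = paired_ratios(table)
    randomized = randomized_ratios(table, seed)
    log_test = fligner_killeen(np.log(paired), np.log(randomized))
    raw_test = fligner_killeen(paired, randomized)
    return {
        "n": len(table),
        "pearson_r": pearson_r(x, y),
        "pearson_r_log": pearson_r(np.log(x), np.log(y)),
        "paired_ratio_sd": float(np.std(paired, ddof=1)),
        "randomized_ratio_sd": float(np.std(randomized, ddof=1)),
        "paired_log_ratio_sd": float(np.std(np.log(paired), ddof=1)),
        "randomized_log_ratio_sd": float(np.std(np.log(randomized), ddof=1)),
        "fligner_log": log_test,
        "fligner_raw": raw_test,
    }
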