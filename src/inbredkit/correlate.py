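"""Pearson and first-order partial correlations with PCIT-style filtering.

For every trio of estimators (x, y, z) the three first-order partial
correlations are computed from the ordinary (pairwise-complete) Pearson
correlations, and the trio's tolerance is the mean ratio of partial to
direct correlation:

    epsilon = (1/3) (r_xy.z / r_xy + r_xz.y / r_xz + r_yz.x / r_yz)

A pair (x, y) is *discarded* against a third variable z when

    |r_xy| <= |epsilon r_xz|  and  |r_xy| <= |epsilon r_yz|

and *significant* otherwise.  Extending the rule across all admissible
third variables admits two readings: a pair is discarded when the
condition holds for at least one z (default) or for every z; both are
implemented (``rule="any" | "all"``).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "pearson_matrix", "partial_correlation", "TrioReport", "trio_report",
    "tolerance_epsilon", "PCITResult", "pcit_from_corr", "pcit_significance",
]


def pearson_matrix(table: pd.DataFrame, min_obs: int = 3) -> pd.DataFrame:
    """Pairwise-complete Pearson correlation matrix of a coefficient table.

    Entries with fewer than ``min_obs`` complete observations, or
    involving a constant column, are NaN (with a warning for constants).
    """
    constant = [c for c in table.columns if table[c].dropna().nunique() <= 1]
    if constant:
        warnings.warn(f"constant columns yield undefined correlations: {constant}")
    return table.corr(method="pearson", min_periods=min_obs)


def partial_correlation(r_xy: float, r_xz: float, r_yz: float) -> float:
    """First-order partial correlation r_xy.z from the three ordinary ones."""
    if abs(r_xz) >= 1.0 or abs(r_yz) >= 1.0:
        raise ValueError("degenerate conditioning: |r_xz| or |r_yz| is 1")
    num = r_xy - r_xz * r_yz
    den = math.sqrt((1.0 - r_xz ** 2) * (1.0 - r_yz ** 2))
    return num / den


@dataclass
class TrioReport:
    """Ordinary and partial correlations for one variable trio, plus epsilon."""

    x: str
    y: str
    z: str
    r_xy: float
    r_xz: float
    r_yz: float
    r_xy_z: float
    r_xz_y: float
    r_yz_x: float
    epsilon: float  # NaN when any ordinary correlation is zero/undefined


def trio_report(corr: pd.DataFrame, x: str, y: str, z: str) -> TrioReport:
    r_xy, r_xz, r_yz = corr.loc[x, y], corr.loc[x, z], corr.loc[y, z]
    p_xy = partial_correlation(r_xy, r_xz, r_yz)
    p_xz = partial_correlation(r_xz, r_xy, r_yz)
    p_yz = partial_correlation(r_yz, r_xy, r_xz)
    rep = TrioReport(x, y, z, r_xy, r_xz, r_yz, p_xy, p_xz, p_yz, math.nan)
    rep.epsilon = tolerance_epsilon(rep)
    return rep


def tolerance_epsilon(trio: TrioReport) -> float:
    """Mean ratio of partial to direct correlation for a trio.

    Undefined (NaN) when any ordinary correlation is zero; such trios are
    excluded from thresholding by the callers.
    """
    rs = (trio.r_xy, trio.r_xz, trio.r_yz)
    ps = (trio.r_xy_z, trio.r_xz_y, trio.r_yz_x)
    if any(not np.isfinite(r) or r == 0.0 for r in rs):
        return math.nan
    return sum(p / r for p, r in zip(ps, rs)) / 3.0


@dataclass
class PCITResult:
    """Outcome of the significance filter over a coefficient table."""

    corr: pd.DataFrame
    significant: pd.DataFrame  # boolean, symmetric, True on the diagonal
    trios: list
    rule: str


def pcit_from_corr(corr: pd.DataFrame, rule: str = "any") -> PCITResult:
    """Apply the epsilon-threshold discard rule to a correlation matrix.

    ``rule="any"``: a pair is discarded if the discard condition holds for
    at least one admissible third variable; ``"all"``: only if it holds
    for every admissible one.  Pairs with no admissible trio (fewer than
    three usable variables) are reported significant with a warning.
    """
    if rule not in ("any", "all"):
        raise ValueError("rule must be 'any' or 'all'")
    cols = list(corr.columns)
    sig = pd.DataFrame(True, index=cols, columns=cols)
    trios: list[TrioReport] = []
    if len(cols) < 3:
        warnings.warn("fewer than 3 variables: no trio exists, all pairs "
                      "reported significant")
        return PCITResult(corr, sig, trios, rule)
    trio_cache: dict[frozenset, Optional[TrioReport]] = {}

    def get_trio(x, y, z):
        key = frozenset((x, y, z))
        if key not in trio_cache:
            vals = [corr.loc[a, b] for a, b in itertools.combinations((x, y, z), 2)]
            if any(not np.isfinite(v) for v in vals) or any(abs(v) >= 1.0 for v in vals):
                trio_cache[key] = None
            else:
                rep = trio_report(corr, x, y, z)
                trio_cache[key] = rep
                trios.append(rep)
        return trio_cache[key]

    for x, y in itertools.combinations(cols, 2):
        verdicts = []
        for z in cols:
            if z in (x, y):
                continue
            rep = get_trio(x, y, z)
            if rep is None or not np.isfinite(rep.epsilon):
                continue
            r_xy = corr.loc[x, y]
            r_xz = corr.loc[x, z]
            r_yz = corr.loc[y, z]
            discard = (abs(r_xy) <= abs(rep.epsilon * r_xz)
                       and abs(r_xy) <= abs(rep.epsilon * r_yz))
            verdicts.append(discard)
        if not verdicts:
            warnings.warn(f"pair ({x}, {y}): no admissible third variable; "
                          "reported significant")
            continue
        discarded = any(verdicts) if rule == "any" else all(verdicts)
        if discarded:
            sig.loc[x, y] = sig.loc[y, x] = False
    return PCITResult(corr, sig, trios, rule)


def pcit_significance(table: pd.DataFrame, rule: str = "any",
                      min_obs: int = 3) -> PCITResult:
    """Pearson matrix plus the epsilon-threshold significance flags."""
    return pcit_from_corr(pearson_matrix(table, min_obs=min_obs), rule=rule)


def trios_frame(result: PCITResult) -> pd.DataFrame:
    """Per-trio report as a flat table (one row per evaluated trio)."""
    rows = [vars(t) for t in result.trios]
    return pd.DataFrame(rows)
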