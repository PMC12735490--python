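"""Spearman associations between synergy and donor-level features.

Correlation grids pair each synergy measure (acetate, propionate,
butyrate, total) with each feature column (alpha-diversity metric at a
timepoint, or an absolute SCFA concentration).  Donors are dropped
pairwise per cell, cells with fewer than ``n_min`` complete pairs are
missing, and significance is annotated per cell at ``alpha`` without
multiplicity adjustment by default (a BH-adjusted variant is a flag
away).

For small samples (n <= 9) the two-sided p-value is exact, computed by
enumerating the full rank-permutation null; larger samples use the
t-approximation.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._constants import SCFA_TYPES
from .stats import adjust_pvalues
from .synergy import RETAINED

EXACT_MAX_N = 9

GRID_COLUMNS = ("row", "column", "rho", "p", "n", "significant", "reason")


class AssociationError(ValueError):
    pass


@lru_cache(maxsize=16)
def _all_permutations(n: int) -> np.ndarray:
    return np.array(list(itertools.permutations(range(n))), dtype=np.intp)


def _exact_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided p from the full pairing-permutation null of the ranks."""
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    denom = np.sqrt((rx_c**2).sum() * (ry_c**2).sum())
    perms = _all_permutations(rx.size)
    rhos = (ry_c[perms] @ rx_c) / denom
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def spearman(x, y, exact_max_n: int = EXACT_MAX_N) -> tuple[float, float, int]:
    """Spearman rank correlation with average ranks for ties.

    Returns ``(rho, p, n)`` after dropping incomplete pairs.  The
    two-sided p-value is exact (full permutation enumeration) for
    ``n <= exact_max_n``, asymptotic otherwise.  Constant inputs raise
    :class:`AssociationError` (rho undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise AssociationError("inputs must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = int(x.size)
    if n < 3:
        raise AssociationError(f"need >= 3 complete pairs, got {n}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise AssociationError("constant input: rho undefined")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= exact_max_n:
        p = _exact_p(rx, ry, rho)
    else:
        p = float(sps.spearmanr(x, y).pvalue)
    return rho, p, n


def correlation_grid(
    synergy_table: pd.DataFrame,
    features: pd.DataFrame,
    alpha: float = 0.05,
    n_min: int = 3,
    adjust: str | None = None,
    scfa_types=SCFA_TYPES,
) -> pd.DataFrame:
    """Spearman grid of synergy measures x feature columns.

    ``synergy_table`` is the filtered synergy table; only retained
    records contribute.  ``features`` is a donor-indexed matrix.  Cells
    with fewer than ``n_min`` complete pairs, or a constant vector, are
    reported with missing rho/p and a ``reason``.  ``adjust='bh'``
    applies BH across all computed cells before the significance call.
    """
    kept = synergy_table[synergy_table["filter_status"] == RETAINED]
    syn = kept.pivot_table(index="donor_id", columns="scfa_type", values="synergy_pct")
    donors = syn.index.intersection(features.index)
    if donors.empty:
        raise AssociationError("no overlapping donors between synergy table and features")
    syn = syn.loc[donors]
    feats = features.loc[donors]

    rows = []
    for scfa in scfa_types:
        for col in feats.columns:
            if scfa not in syn.columns:
                rows.append((scfa, col, np.nan, np.nan, 0, False, "no_retained_synergy"))
                continue
            x = syn[scfa].to_numpy(dtype=float)
            y = feats[col].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < n_min:
                rows.append((scfa, col, np.nan, np.nan, int(ok.sum()), False, "n_lt_min"))
                continue
            try:
                rho, p, n = spearman(x[ok], y[ok])
            except AssociationError:
                rows.append((scfa, col, np.nan, np.nan, int(ok.sum()), False, "constant_input"))
                continue
            rows.append((scfa, col, rho, p, n, False, ""))
    grid = pd.DataFrame(rows, columns=list(GRID_COLUMNS))
    tested = grid["p"].notna()
    if adjust == "bh" and tested.any():
        grid.loc[tested, "p_adjusted"] = adjust_pvalues(grid.loc[tested, "p"].tolist(), "bh")
        grid.loc[tested, "significant"] = grid.loc[tested, "p_adjusted"] < alpha
    else:
        grid.loc[tested, "significant"] = grid.loc[tested, "p"] < alpha
    return grid


def scfa_features(synergy_table: pd.DataFrame) -> pd.DataFrame:
    """Donor x absolute-SCFA feature matrix (observed mixture mM)."""
    return synergy_table.pivot_table(
        index="donor_id", columns="scfa_type", values="observed_mM"
    ).rename(columns=lambda c: f"{c}_mM")


def grid_to_matrix(grid: pd.DataFrame, value: str = "rho") -> pd.DataFrame:
    """Square-matrix view of a long-format grid, for heatmapping."""
    return grid.pivot(index="row", columns="column", values=value)
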