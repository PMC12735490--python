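"""Group statistics: paired tests, Tukey contrasts, multiplicity control.

Three analyses mirror the fermentation study design:

1. within each health condition, mixture vs each individual fiber via
   Tukey's studentized-range pairwise contrasts on a donor-blocked
   layout (repeated measurements from the same donors);
2. observed vs expected mixture values, paired two-tailed tests per
   (condition, SCFA) with Benjamini-Hochberg control across the family;
3. synergy-percentage comparisons across conditions (unpaired,
   Welch-type, since filtering yields unequal n) and between SCFA types
   within a condition (paired), with Holm-Sidak adjustment per family.

The BH and Holm-Sidak adjustments are implemented directly from their
step-up / step-down definitions in plain float arithmetic so that the
output is bit-for-bit the textbook value; tests cross-check against
statsmodels.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._constants import ACIDS, SCFA_TYPES
from .synergy import RETAINED

log = logging.getLogger(__name__)

RESULT_COLUMNS = (
    "family", "comparison", "n", "statistic", "direction",
    "p_raw", "p_adjusted", "method", "adjust_method", "significant", "suppressed",
)


@dataclass
class TestResult:
    family: str
    comparison: str
    n: int
    statistic: float
    direction: float
    p_raw: float
    method: str
    p_adjusted: float = np.nan
    adjust_method: str = "none"
    significant: bool = False
    suppressed: bool = False

    def to_row(self) -> dict:
        return asdict(self)


def results_frame(results: Sequence[TestResult]) -> pd.DataFrame:
    df = pd.DataFrame([r.to_row() for r in results])
    return df.reindex(columns=list(RESULT_COLUMNS)) if len(df) else pd.DataFrame(columns=list(RESULT_COLUMNS))


# ---------------------------------------------------------------------------
# multiple-testing adjustment

def adjust_pvalues(p: Sequence[float], method: str) -> list[float]:
    """Adjust p-values by ``'bh'`` (step-up FDR) or ``'holm_sidak'``.

    BH: adjusted p for the i-th smallest p is ``min(1, min_{j>=i} m*p_(j)/j)``.
    Holm-Sidak: step-down ``max_{j<=i} (1 - (1-p_(j))**(m-j+1))`` clipped at 1.
    Plain Python floats throughout, so results equal the definitional
    brute force bit-for-bit.
    """
    ps = [float(v) for v in p]
    m = len(ps)
    if any(not (0.0 <= v <= 1.0) for v in ps):
        raise ValueError("p-values must lie in [0, 1]")
    if m == 0:
        return []
    order = sorted(range(m), key=ps.__getitem__)
    adj_sorted = [0.0] * m
    if method == "bh":
        running = float("inf")
        for i in range(m - 1, -1, -1):  # from largest rank down
            running = min(running, m * ps[order[i]] / (i + 1))
            adj_sorted[i] = min(1.0, running)
    elif method == "holm_sidak":
        running = 0.0
        for i in range(m):
            running = max(running, 1.0 - (1.0 - ps[order[i]]) ** (m - i))
            adj_sorted[i] = min(1.0, running)
    else:
        raise ValueError(f"unknown adjustment method {method!r}")
    out = [0.0] * m
    for i, idx in enumerate(order):
        out[idx] = adj_sorted[i]
    return out


def _apply_adjustment(results: list[TestResult], method: str, alpha: float) -> None:
    live = [r for r in results if not r.suppressed]
    if not live:
        return
    adjusted = adjust_pvalues([r.p_raw for r in live], method)
    for r, q in zip(live, adjusted):
        r.p_adjusted = q
        r.adjust_method = method
        r.significant = bool(q < alpha)


# ---------------------------------------------------------------------------
# paired tests

def paired_test(
    x: Sequence[float],
    y: Sequence[float],
    method: str = "t",
    n_min: int = 3,
    comparison: str = "x_vs_y",
    family: str = "",
) -> TestResult:
    """Two-tailed paired test of matched per-donor values.

    ``direction`` is mean(x - y).  With fewer than ``n_min`` pairs the
    result is suppressed (no p emitted).  Zero-variance differences are
    the degenerate limit: p = 1 when the mean difference is 0, p = 0
    (with a warning) otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = int(x.size)
    direction = float(np.mean(x - y)) if n else np.nan
    if n < n_min:
        return TestResult(family, comparison, n, np.nan, direction, np.nan, method, suppressed=True)
    d = x - y
    if np.allclose(d.std(ddof=1) if n > 1 else 0.0, 0.0):
        if np.isclose(direction, 0.0):
            return TestResult(family, comparison, n, 0.0, direction, 1.0, method)
        warnings.warn(f"{comparison}: zero-variance differences with nonzero mean; p -> 0")
        stat = np.inf if direction > 0 else -np.inf
        return TestResult(family, comparison, n, stat, direction, 0.0, method)
    if method == "t":
        stat, p = sps.ttest_rel(x, y)
    elif method == "wilcoxon":
        stat, p = sps.wilcoxon(x, y, alternative="two-sided")
    else:
        raise ValueError(f"unknown paired test method {method!r}")
    return TestResult(family, comparison, n, float(stat), direction, float(p), method)


# ---------------------------------------------------------------------------
# Tukey pairwise contrasts

def tukey_contrasts(
    values: pd.DataFrame,
    blocked: bool = True,
    alpha: float = 0.05,
    n_min: int = 3,
    family: str = "tukey",
) -> pd.DataFrame:
    """All pairwise substrate contrasts via the studentized range.

    ``values`` is a donors x substrates table of one condition.  Donors
    with any missing cell are dropped (complete-block requirement) and
    logged.  With ``blocked=True`` (default) the donor effect is removed
    before the residual mean square, i.e. a randomized complete block
    design with error df ``(n-1)(k-1)``; ``blocked=False`` pools
    within-substrate residuals (df ``k(n-1)``).  Fewer than ``n_min``
    complete donors suppresses the whole family (empty output).
    """
    complete = values.dropna(axis=0)
    dropped = len(values) - len(complete)
    if dropped:
        log.info("%s: dropped %d donor(s) with missing substrate cells", family, dropped)
    n, k = complete.shape
    if n < n_min or k < 2:
        log.warning("%s: suppressed (n=%d complete donors < %d)", family, n, n_min)
        return results_frame([])

    y = complete.to_numpy(dtype=float)
    col_means = y.mean(axis=0)
    if blocked:
        resid = y - y.mean(axis=1, keepdims=True) - col_means + y.mean()
        df_err = (n - 1) * (k - 1)
    else:
        resid = y - col_means
        df_err = k * (n - 1)
    mse = float((resid**2).sum() / df_err)

    results = []
    for a, b in itertools.combinations(range(k), 2):
        diff = col_means[a] - col_means[b]
        if mse > 0:
            q = abs(diff) / np.sqrt(mse / n)
            p = float(sps.studentized_range.sf(q, k, df_err))
        else:
            q, p = (0.0, 1.0) if np.isclose(diff, 0.0) else (np.inf, 0.0)
        results.append(
            TestResult(
                family=family,
                comparison=f"{complete.columns[a]}_vs_{complete.columns[b]}",
                n=n,
                statistic=float(q),
                direction=float(diff),
                p_raw=p,
                method="tukey_blocked" if blocked else "tukey",
                p_adjusted=p,  # studentized range is already family-wise
                adjust_method="studentized_range",
                significant=bool(p < alpha),
            )
        )
    return results_frame(results)


# ---------------------------------------------------------------------------
# analysis suites

def observed_vs_expected_suite(
    records: pd.DataFrame,
    method: str = "t",
    alpha: float = 0.05,
    n_min: int = 3,
    use_filtered: bool = False,
) -> pd.DataFrame:
    """Paired observed-vs-expected tests per (condition, SCFA type).

    Operates on the synergy table (one row per donor x SCFA measure).
    By default all observed/expected pairs enter the tests — the
    reliability filter defines which synergy percentages are reported,
    not which raw concentrations exist — with only the n >= ``n_min``
    gate applied; ``use_filtered=True`` restricts to retained records.
    BH correction is applied across all emitted tests as one family.
    """
    data = records[records["filter_status"] == RETAINED] if use_filtered else records
    results = []
    for (cond, scfa), sub in data.groupby(["condition", "scfa_type"], sort=True):
        results.append(
            paired_test(
                sub["observed_mM"], sub["expected_mM"], method=method, n_min=n_min,
                comparison=f"{cond}:{scfa}:observed_vs_expected", family="observed_vs_expected",
            )
        )
    _apply_adjustment(results, "bh", alpha)
    return results_frame(results)


def synergy_comparison_suite(
    records: pd.DataFrame,
    axis: str = "across_conditions",
    method: str = "welch_t",
    alpha: float = 0.05,
    n_min: int = 3,
    scfa_types: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Compare retained synergy percentages across groups.

    ``axis='across_conditions'``: for each SCFA type (family), unpaired
    two-sample tests between every condition pair; Welch t by default
    (``method='mwu'`` for Mann-Whitney), since filtering yields unequal
    sample sizes.  ``axis='across_scfa_within_condition'``: for each
    condition (family), paired tests between SCFA types on donors
    retained for both.  Holm-Sidak adjustment per family.
    """
    kept = records[records["filter_status"] == RETAINED]
    all_results = []
    if axis == "across_conditions":
        scfa_types = list(scfa_types or SCFA_TYPES)
        for scfa in scfa_types:
            sub = kept[kept["scfa_type"] == scfa]
            family = f"across_conditions:{scfa}"
            groups = {c: g["synergy_pct"].to_numpy() for c, g in sub.groupby("condition")}
            results = []
            for a, b in itertools.combinations(sorted(groups), 2):
                xa, xb = groups[a], groups[b]
                n = int(min(len(xa), len(xb)))
                comparison = f"{a}_vs_{b}:{scfa}"
                if n < n_min:
                    results.append(TestResult(family, comparison, n, np.nan, np.nan, np.nan,
                                              method, suppressed=True))
                    continue
                direction = float(xa.mean() - xb.mean())
                if method == "welch_t":
                    stat, p = sps.ttest_ind(xa, xb, equal_var=False)
                elif method == "mwu":
                    stat, p = sps.mannwhitneyu(xa, xb, alternative="two-sided")
                else:
                    raise ValueError(f"unknown method {method!r}")
                results.append(TestResult(family, comparison, n, float(stat), direction,
                                          float(p), method))
            _apply_adjustment(results, "holm_sidak", alpha)
            all_results.extend(results)
    elif axis == "across_scfa_within_condition":
        scfa_types = list(scfa_types or ACIDS)
        paired_method = "t" if method == "welch_t" else method
        for cond, sub in kept.groupby("condition", sort=True):
            family = f"within_condition:{cond}"
            wide = sub.pivot_table(index="donor_id", columns="scfa_type", values="synergy_pct")
            results = []
            for a, b in itertools.combinations(scfa_types, 2):
                if a not in wide.columns or b not in wide.columns:
                    both = wide.iloc[:0]
                else:
                    both = wide[[a, b]].dropna()
                results.append(
                    paired_test(
                        both[a] if len(both) else [], both[b] if len(both) else [],
                        method=paired_method, n_min=n_min,
                        comparison=f"{a}_vs_{b}:{cond}", family=family,
                    )
                )
            _apply_adjustment(results, "holm_sidak", alpha)
            all_results.extend(results)
    else:
        raise ValueError(f"unknown axis {axis!r}")
    return results_frame(all_results)
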