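"""The synergy statistic: additive expectation, filtering, donor labels.

For each donor and SCFA measure, the additive null model for an
equal-proportion four-fiber blend is the arithmetic mean of the four
single-fiber concentrations; synergy is the percent excess of the
observed mixture concentration over that expectation::

    synergy % = (observed - expected) / expected * 100

Small or unreliable effects are filtered with uniform thresholds: a
record is excluded when the observed-expected difference is within
measurement error (|O - E| <= 0.5 mM) or when either value is below the
detection limit (1.0 mM); groups with fewer than 3 retained records
carry no statistics.  Donors are labelled synergy / no-synergy from the
sign of their retained total-SCFA synergy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._constants import ACIDS, DEFAULT_FIBERS, MIXTURE, TOTAL

RETAINED = "retained"
EXCL_ERROR = "excluded_measurement_error"
EXCL_DETECTION = "excluded_detection_limit"
EXCL_ZERO = "excluded_zero_expected"

SYNERGY_COLUMNS = (
    "donor_id", "condition", "scfa_type", "observed_mM", "expected_mM", "synergy_pct", "filter_status",
)


class SynergyError(ValueError):
    pass


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the record-level reliability filter.

    ``combine_rule='any'`` excludes a record when either the
    measurement-error or the detection-limit test fires (default);
    ``'all'`` excludes only when both fire.
    """

    error_threshold: float = 0.5
    detection_limit: float = 1.0
    n_min: int = 3
    combine_rule: str = "any"

    def __post_init__(self) -> None:
        if self.error_threshold < 0 or self.detection_limit < 0:
            raise SynergyError("filter thresholds must be >= 0")
        if self.n_min < 1:
            raise SynergyError("n_min must be >= 1")
        if self.combine_rule not in ("any", "all"):
            raise SynergyError("combine_rule must be 'any' or 'all'")


def expected_additive(fiber_values: Sequence[float]) -> float:
    """Additive expectation: mean of the four single-fiber values (mM)."""
    values = np.asarray(list(fiber_values), dtype=float)
    if values.size != 4:
        raise SynergyError(f"expected exactly 4 fiber values, got {values.size}")
    if not np.all(np.isfinite(values)) or np.any(values < 0):
        raise SynergyError("fiber values must be finite and >= 0")
    return float(values.mean())


def synergy_percent(observed: float, expected: float) -> float:
    """Percent excess of observed over the additive expectation."""
    if not expected > 0:
        raise SynergyError(f"synergy undefined for expected = {expected} (must be > 0)")
    return (observed - expected) / expected * 100.0


def compute_synergy(
    ferm: pd.DataFrame,
    fibers: Sequence[str] = DEFAULT_FIBERS,
    mixture_label: str = MIXTURE,
    total_expectation: str = "sum_of_acids",
) -> pd.DataFrame:
    """Build the per-(donor, SCFA) synergy table from a fermentation table.

    For every donor and SCFA measure present for the mixture, the
    expected value is the mean of that donor's four single-fiber
    concentrations; a missing fiber measurement raises, naming the
    substrate.  Records with non-positive expectation get status
    ``excluded_zero_expected`` and a missing ``synergy_pct``; all other
    statuses are assigned later by :func:`apply_filters`.

    ``total_expectation`` controls the additive null for total SCFA:
    ``'sum_of_acids'`` (default) sums the three per-acid expectations,
    which is algebraically identical to the mean of the four fiber
    totals when totals are derived as acetate+propionate+butyrate and
    keeps the null internally consistent with them (the zero-effect case
    is then exact to the last bit); ``'mean_of_totals'`` averages the
    fiber total rows directly, appropriate when totals were measured
    independently of the three acids.
    """
    if total_expectation not in ("sum_of_acids", "mean_of_totals"):
        raise SynergyError(f"unknown total_expectation {total_expectation!r}")
    fibers = [f.lower() for f in fibers]
    if len(fibers) != 4:
        raise SynergyError(f"expected exactly 4 fiber labels, got {len(fibers)}")
    wide = ferm.pivot_table(
        index=["donor_id", "condition", "scfa_type"],
        columns="substrate",
        values="concentration_mM",
        aggfunc="first",
    )
    if mixture_label not in wide.columns:
        raise SynergyError(f"no {mixture_label!r} substrate in table")
    wide = wide[wide[mixture_label].notna()]
    missing_cols = [f for f in fibers if f not in wide.columns]
    if missing_cols:
        raise SynergyError(f"missing fiber substrate(s) {missing_cols}")
    fiber_block = wide[fibers]
    incomplete = fiber_block.isna().any(axis=1)
    if incomplete.any():
        donor, _, scfa = fiber_block.index[incomplete.to_numpy()][0]
        missing = list(fiber_block.columns[fiber_block.loc[incomplete].iloc[0].isna()])
        raise SynergyError(f"donor {donor!r}, scfa {scfa!r}: missing fiber substrate(s) {missing}")

    observed = wide[mixture_label].to_numpy(dtype=float)
    expected = fiber_block.to_numpy(dtype=float).mean(axis=1)  # additive null: mean of 4 fibers
    if total_expectation == "sum_of_acids":
        exp_map = dict(zip(wide.index, expected))
        for pos, (donor, cond, scfa) in enumerate(wide.index):
            if scfa != TOTAL:
                continue
            acid_vals = [exp_map.get((donor, cond, a)) for a in ACIDS]
            if all(v is not None for v in acid_vals):
                expected[pos] = sum(acid_vals)  # ACIDS order, matching derived totals
    positive = expected > 0
    pct = np.full(observed.shape, np.nan)
    pct[positive] = (observed[positive] - expected[positive]) / expected[positive] * 100.0
    out = pd.DataFrame(
        {
            "donor_id": wide.index.get_level_values(0),
            "condition": wide.index.get_level_values(1),
            "scfa_type": wide.index.get_level_values(2),
            "observed_mM": observed,
            "expected_mM": expected,
            "synergy_pct": pct,
            "filter_status": np.where(positive, RETAINED, EXCL_ZERO),
        }
    )
    order = {s: i for i, s in enumerate(ACIDS + (TOTAL,))}
    out["_ord"] = out["scfa_type"].map(lambda s: order.get(s, len(order)))
    out = out.sort_values(["condition", "donor_id", "_ord"]).drop(columns="_ord")
    return out.reset_index(drop=True)


def apply_filters(records: pd.DataFrame, cfg: FilterConfig = FilterConfig()) -> pd.DataFrame:
    """Annotate each synergy record with its filter status.

    A record is ``retained`` iff |observed - expected| > error_threshold
    and min(observed, expected) >= detection_limit (under the default
    ``combine_rule='any'``).  When both exclusion tests fire, the
    measurement-error status takes precedence.  Annotation is pure and
    idempotent; ``synergy_pct`` of excluded records is kept for
    inspection but masked to NaN in a companion ``synergy_pct_retained``
    view used by the summaries.
    """
    out = records.copy()
    obs = out["observed_mM"].to_numpy(dtype=float)
    exp = out["expected_mM"].to_numpy(dtype=float)
    zero = ~(exp > 0)
    err = np.abs(obs - exp) <= cfg.error_threshold
    det = np.minimum(obs, exp) < cfg.detection_limit
    excluded = (err | det) if cfg.combine_rule == "any" else (err & det)

    status = np.full(len(out), RETAINED, dtype=object)
    status[excluded & det] = EXCL_DETECTION
    status[excluded & err] = EXCL_ERROR  # precedence over detection when both fire
    status[zero] = EXCL_ZERO
    out["filter_status"] = status
    out.loc[zero, "synergy_pct"] = np.nan
    out["synergy_pct_retained"] = out["synergy_pct"].where(out["filter_status"] == RETAINED)
    return out


def retained(records: pd.DataFrame) -> pd.DataFrame:
    return records[records["filter_status"] == RETAINED]


def summarize_synergy(
    records: pd.DataFrame,
    group_by: str = "all",
    n_min: int = 3,
) -> pd.DataFrame:
    """Descriptive statistics of retained synergy per group.

    ``group_by`` is ``'condition'``, ``'scfa_type'``,
    ``'condition_scfa'`` or ``'all'``.  Groups with fewer than ``n_min``
    retained records are still reported but flagged
    ``stats_suppressed`` (the minimum-n rule for inference).
    """
    keys = {
        "all": [],
        "condition": ["condition"],
        "scfa_type": ["scfa_type"],
        "condition_scfa": ["condition", "scfa_type"],
    }[group_by]
    kept = retained(records)
    if keys:
        grouped = kept.groupby(keys)["synergy_pct"]
    else:
        grouped = kept.assign(_all="all").groupby("_all")["synergy_pct"]
    summary = grouped.agg(n="count", mean="mean", sd="std", median="median", min="min", max="max")
    summary = summary.reset_index()
    if not keys:
        summary = summary.drop(columns="_all")
    summary["stats_suppressed"] = summary["n"] < n_min
    return summary


def classify_donors(records: pd.DataFrame, threshold: float = 0.0) -> pd.DataFrame:
    """Label each donor synergy / no-synergy from retained records.

    Default rule: a donor is ``synergy`` iff its retained total-SCFA
    synergy exceeds ``threshold`` (0%).  Donors whose total-SCFA record
    was filtered out fall back to the mean of their retained acid-level
    synergies; donors with no retained record at all are
    ``unassigned``.
    """
    kept = retained(records)
    labels = []
    for donor, sub in records.groupby("donor_id", sort=True):
        k = kept[kept["donor_id"] == donor]
        total = k[k["scfa_type"] == TOTAL]["synergy_pct"]
        if len(total):
            value = float(total.iloc[0])
        else:
            acid = k[k["scfa_type"].isin(ACIDS)]["synergy_pct"]
            value = float(acid.mean()) if len(acid) else np.nan
        if np.isnan(value):
            label = "unassigned"
        else:
            label = "synergy" if value > threshold else "no_synergy"
        labels.append((donor, sub["condition"].iloc[0], value, label))
    return pd.DataFrame(labels, columns=["donor_id", "condition", "synergy_value", "synergy_label"])
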