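"""Bias-corrected compositional differential abundance.

Sequencing counts carry an unknown per-sample sampling fraction (library
size x extraction efficiency), so raw log counts confound abundance with
depth.  This module implements a deliberately simple sampling-fraction
correction in the spirit of ANCOM-BC: the per-sample bias offset is
estimated as the median, across tested taxa, of the sample's log count
minus its group's mean log count; taxa are then compared between groups
by a Welch test on offset-corrected log counts, giving a natural-log
fold change (synergy relative to no-synergy), its standard error and a
BH-adjusted q per taxon.  It is a documented simplification — no
iterative EM bias estimation, no covariates — that preserves the
correction mechanism at a scale where every property is testable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import adjust_pvalues

DA_COLUMNS = ("taxon", "lfc", "se", "statistic", "p_raw", "q", "status", "prevalence_syn", "prevalence_no")

TESTED = "tested"
EXCL_PREVALENCE = "excluded_prevalence"
STRUCTURAL_ZERO = "structural_zero"


class DiffAbundError(ValueError):
    pass


def _group_masks(counts: pd.DataFrame, labels: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    lab = labels.reindex(counts.columns)
    if lab.isna().any():
        missing = list(lab.index[lab.isna()])[:5]
        raise DiffAbundError(f"samples without synergy label: {missing}")
    syn = (lab == "synergy").to_numpy()
    no = (lab == "no_synergy").to_numpy()
    if syn.sum() < 2 or no.sum() < 2:
        raise DiffAbundError(
            f"need >= 2 samples per group, got synergy={int(syn.sum())}, no_synergy={int(no.sum())}"
        )
    return syn, no


def estimate_sampling_fractions(
    log_counts: pd.DataFrame, labels: pd.Series
) -> pd.Series:
    """Per-sample log sampling-fraction offsets (centered to mean 0).

    ``log_counts`` is taxa x samples on the log scale (pseudocounted).
    For each sample, the offset is the median over taxa of
    ``log count - reference log count``, where the reference is the
    per-taxon median across *all* samples.  The median over taxa is
    robust to the minority of truly differential taxa, and the global
    (label-free) reference lets offsets express between-group sampling
    fraction differences - the bias this correction exists to remove; a
    group-specific reference would absorb its own group's depth into the
    reference and leave a common depth shift in every taxon's contrast.
    Offsets are identifiable only up to a constant and are centered to
    mean zero.
    """
    _group_masks(log_counts, labels)  # validates labels and group sizes
    arr = log_counts.to_numpy(dtype=float)
    reference = np.median(arr, axis=1, keepdims=True)
    offsets = np.median(arr - reference, axis=0)
    offsets = offsets - offsets.mean()
    return pd.Series(offsets, index=log_counts.columns, name="offset")


def differential_abundance(
    counts: pd.DataFrame,
    labels: pd.Series | pd.DataFrame,
    prevalence_min: float = 0.10,
    pseudocount: float = 1.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Synergy vs no-synergy differential abundance per taxon.

    ``labels`` maps sample id -> {'synergy', 'no_synergy'} (a metadata
    frame with ``sample_id``/``synergy_label`` columns is accepted).
    Taxa present in fewer than ``prevalence_min`` of the samples of both
    groups are ``excluded_prevalence``; taxa entirely absent from one
    group are ``structural_zero`` (fold change not estimable).  Tested
    taxa get a Welch test on offset-corrected ``log(count + pseudocount)``
    with lfc = difference of corrected group means (natural log,
    positive = enriched with synergy) and BH q across tested taxa.
    """
    if isinstance(labels, pd.DataFrame):
        labels = labels.set_index("sample_id")["synergy_label"]
    labels = labels[labels.isin(["synergy", "no_synergy"])]
    counts = counts[[c for c in counts.columns if c in labels.index]]
    syn, no = _group_masks(counts, labels)

    raw = counts.to_numpy(dtype=float)
    present = raw > 0
    prev_syn = present[:, syn].mean(axis=1)
    prev_no = present[:, no].mean(axis=1)
    structural = (prev_syn == 0) ^ (prev_no == 0)
    low_prev = (prev_syn < prevalence_min) & (prev_no < prevalence_min)
    testable = ~(structural | low_prev)
    if testable.sum() < 2:
        raise DiffAbundError("nothing testable: fewer than 2 taxa pass the filters")

    logs = pd.DataFrame(
        np.log(raw + pseudocount), index=counts.index, columns=counts.columns
    )
    offsets = estimate_sampling_fractions(logs.loc[counts.index[testable]], labels)
    corrected = logs.to_numpy() - offsets.to_numpy()[None, :]

    rows = []
    tested_idx = []
    for i, taxon in enumerate(counts.index):
        if structural[i]:
            rows.append((taxon, np.nan, np.nan, np.nan, np.nan, np.nan, STRUCTURAL_ZERO,
                         float(prev_syn[i]), float(prev_no[i])))
            continue
        if low_prev[i]:
            rows.append((taxon, np.nan, np.nan, np.nan, np.nan, np.nan, EXCL_PREVALENCE,
                         float(prev_syn[i]), float(prev_no[i])))
            continue
        a, b = corrected[i, syn], corrected[i, no]
        lfc = float(a.mean() - b.mean())
        se = float(np.sqrt(a.var(ddof=1) / a.size + b.var(ddof=1) / b.size))
        stat, p = sps.ttest_ind(a, b, equal_var=False)
        rows.append((taxon, lfc, se, float(stat), float(p), np.nan, TESTED,
                     float(prev_syn[i]), float(prev_no[i])))
        tested_idx.append(len(rows) - 1)

    out = pd.DataFrame(rows, columns=list(DA_COLUMNS))
    if tested_idx:
        qs = adjust_pvalues(out.loc[tested_idx, "p_raw"].tolist(), "bh")
        out.loc[tested_idx, "q"] = qs
    out["significant"] = out["q"] < alpha
    return out.sort_values("lfc", ascending=False, na_position="last").reset_index(drop=True)
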