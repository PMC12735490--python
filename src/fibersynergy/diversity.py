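"""Alpha diversity per sample: Shannon, richness, Pielou evenness.

Shannon entropy is computed in nats on raw proportions (no rarefaction
or coverage correction); richness is the number of observed taxa;
evenness is Shannon / ln(richness), undefined for single-taxon samples.
The change between baseline and post-fermentation samples of a donor is
``post - baseline`` for each metric.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._constants import TIMEPOINTS

METRICS = ("shannon", "richness", "evenness")


class DiversityError(ValueError):
    pass


def alpha_diversity(counts, base: float | None = None) -> dict:
    """Shannon (nats by default), observed richness and Pielou evenness.

    ``base`` switches the entropy logarithm (e.g. 2 for bits); evenness
    is base-invariant.  All-zero samples are an error.
    """
    c = np.asarray(counts, dtype=float)
    if c.ndim != 1:
        raise DiversityError("expected a single sample's count vector")
    if np.any(c < 0) or not np.all(np.isfinite(c)):
        raise DiversityError("counts must be finite and >= 0")
    total = c.sum()
    if total == 0:
        raise DiversityError("empty sample")
    richness = int(np.count_nonzero(c))
    shannon = float(sps.entropy(c, base=base))
    if richness >= 2:
        evenness = float(sps.entropy(c) / np.log(richness))
    else:
        evenness = np.nan
    return {"shannon": shannon, "richness": richness, "evenness": evenness}


def diversity_table(counts: pd.DataFrame, metadata: pd.DataFrame, base: float | None = None) -> pd.DataFrame:
    """Per-sample diversity for every metadata sample present in ``counts``."""
    rows = []
    for _, rec in metadata.iterrows():
        sid = rec["sample_id"]
        if sid not in counts.columns:
            continue
        metrics = alpha_diversity(counts[sid].to_numpy(), base=base)
        rows.append({"sample_id": sid, "donor_id": rec["donor_id"],
                     "timepoint": rec["timepoint"], **metrics})
    return pd.DataFrame(rows, columns=["sample_id", "donor_id", "timepoint", *METRICS])


def delta_diversity(baseline: dict | pd.Series, post: dict | pd.Series) -> dict:
    """Post-minus-baseline change for one donor; missing evenness propagates."""
    if baseline.get("donor_id") != post.get("donor_id"):
        raise DiversityError(
            f"donor mismatch: {baseline.get('donor_id')!r} vs {post.get('donor_id')!r}"
        )
    out = {"donor_id": baseline.get("donor_id")}
    for metric in METRICS:
        out[metric] = float(post[metric]) - float(baseline[metric])
    return out


def diversity_features(div: pd.DataFrame) -> pd.DataFrame:
    """Donor x feature matrix of metrics at baseline, post, and delta.

    Columns are ``<metric>_<baseline|post|delta>``; delta columns exist
    only for donors with both timepoints.
    """
    wide = div.pivot_table(index="donor_id", columns="timepoint", values=list(METRICS))
    out = pd.DataFrame(index=wide.index)
    for metric in METRICS:
        for tp in TIMEPOINTS:
            if (metric, tp) in wide.columns:
                out[f"{metric}_{tp}"] = wide[(metric, tp)]
        if (metric, "baseline") in wide.columns and (metric, "post") in wide.columns:
            out[f"{metric}_delta"] = wide[(metric, "post")] - wide[(metric, "baseline")]
    out.index.name = "donor_id"
    return out
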