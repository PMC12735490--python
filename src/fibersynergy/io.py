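"""Readers, writers and validation for the pipeline's tabular formats.

Canonical on-disk formats:

* fermentation table — comma-delimited UTF-8 CSV with header
  ``donor_id,condition,substrate,scfa_type,concentration_mM``;
* taxa counts — TSV, first column ``taxon`` then one integer column per
  sample;
* sample metadata — TSV with header
  ``sample_id,donor_id,timepoint,synergy_label``;
* ground truth and reports — JSON.

Readers validate and never silently coerce: label case-folding and
derived ``total`` rows are logged.  A ``column_map`` lets externally
deposited tables with different headers be ingested without editing the
files.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from ._constants import ACIDS, FERMENTATION_COLUMNS, METADATA_COLUMNS, MIXTURE, TOTAL

log = logging.getLogger(__name__)


class SchemaError(ValueError):
    """Input file does not have the required columns."""


class ValidationError(ValueError):
    """Input file has the right shape but invalid content."""


def read_fermentation(
    path,
    column_map: Mapping[str, str] | None = None,
    known_substrates: set[str] | None = None,
) -> pd.DataFrame:
    """Read and validate a long-format fermentation table.

    ``column_map`` maps canonical column names to the file's header
    names.  Substrate and SCFA labels are case-folded to lower case
    (condition labels are kept verbatim); any fold is logged.  Unknown
    substrate labels are reported at WARNING level but kept, so
    user-defined fiber panels pass through.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    missing = [c for c in FERMENTATION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}; found {list(df.columns)}")
    df = df[list(FERMENTATION_COLUMNS)].copy()

    for col in ("substrate", "scfa_type"):
        lowered = df[col].astype(str).str.strip().str.lower()
        changed = int((lowered != df[col].astype(str)).sum())
        if changed:
            log.info("%s: case-folded %d %s label(s) to lower case", path.name, changed, col)
        df[col] = lowered
    df["donor_id"] = df["donor_id"].astype(str)
    df["condition"] = df["condition"].astype(str).str.strip()

    conc = pd.to_numeric(df["concentration_mM"], errors="coerce")
    bad = df.index[~np.isfinite(conc)]
    if len(bad):
        raise ValidationError(f"{path}: non-numeric concentration at row(s) {list(bad[:5])}")
    neg = df.index[conc < 0]
    if len(neg):
        raise ValidationError(f"{path}: negative concentration at row(s) {list(neg[:5])}")
    df["concentration_mM"] = conc.astype(float)

    dup = df.duplicated(subset=["donor_id", "substrate", "scfa_type"])
    if dup.any():
        first = df.loc[dup.idxmax(), ["donor_id", "substrate", "scfa_type"]].tolist()
        raise ValidationError(f"{path}: duplicated (donor, substrate, scfa_type) key, first {first}")

    bad_scfa = sorted(set(df["scfa_type"]) - set(ACIDS) - {TOTAL})
    if bad_scfa:
        raise ValidationError(f"{path}: unknown scfa_type label(s) {bad_scfa}")
    if known_substrates is not None:
        unknown = sorted(set(df["substrate"]) - {s.lower() for s in known_substrates} - {MIXTURE})
        if unknown:
            log.warning("%s: unknown substrate label(s) %s", path.name, unknown)
    return df.reset_index(drop=True)


def write_fermentation(df: pd.DataFrame, path) -> None:
    df[list(FERMENTATION_COLUMNS)].to_csv(path, index=False)


def ensure_total_rows(df: pd.DataFrame) -> pd.DataFrame:
    """Append per-(donor, substrate) ``total`` rows where absent.

    Total SCFA is acetate + propionate + butyrate.  Existing ``total``
    rows are kept as measured; derived rows are logged.
    """
    have_total = set(map(tuple, df.loc[df["scfa_type"] == TOTAL, ["donor_id", "substrate"]].values))
    acids = df[df["scfa_type"].isin(ACIDS)]
    sums = acids.groupby(["donor_id", "condition", "substrate"], as_index=False).agg(
        concentration_mM=("concentration_mM", "sum"), n_acids=("scfa_type", "nunique")
    )
    sums = sums[sums["n_acids"] == len(ACIDS)].drop(columns="n_acids")
    sums = sums[~sums.apply(lambda r: (r["donor_id"], r["substrate"]) in have_total, axis=1)]
    if len(sums):
        log.info("derived %d total-SCFA row(s) as acetate+propionate+butyrate", len(sums))
        sums["scfa_type"] = TOTAL
        df = pd.concat([df, sums[list(FERMENTATION_COLUMNS)]], ignore_index=True)
    return df


def read_taxa_table(path) -> pd.DataFrame:
    """Read a taxa x samples TSV of non-negative integer counts."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] == 0:
        raise ValidationError(f"{path}: no taxa")
    if df.index.duplicated().any():
        dupes = sorted(set(df.index[df.index.duplicated()]))
        raise ValidationError(f"{path}: duplicated taxon id(s) {dupes}")
    values = df.to_numpy()
    numeric = pd.DataFrame(df).apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(~np.isfinite(numeric.to_numpy()) | (numeric.to_numpy() % 1 != 0))
    if len(bad):
        i, j = bad[0]
        raise ValidationError(
            f"{path}: non-integer count at taxon {df.index[i]!r}, sample {df.columns[j]!r}"
            f" (value {values[i, j]!r})"
        )
    if (numeric.to_numpy() < 0).any():
        raise ValidationError(f"{path}: negative count")
    out = numeric.astype(np.int64)
    out.index.name = "taxon"
    return out


def write_taxa_table(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out.index.name = "taxon"
    out.to_csv(path, sep="\t")


def read_metadata(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    df = df[list(METADATA_COLUMNS)].astype(str)
    if df["sample_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicated sample_id")
    return df


def write_metadata(df: pd.DataFrame, path) -> None:
    df[list(METADATA_COLUMNS)].to_csv(path, sep="\t", index=False)


def validate_join(ferm: pd.DataFrame, meta: pd.DataFrame) -> dict:
    """Compare donor sets between a fermentation table and metadata.

    Returns ``{"shared": [...], "fermentation_only": [...],
    "metadata_only": [...]}``; raises :class:`ValidationError` when the
    intersection is empty, since no downstream analysis is then possible.
    """
    ferm_donors = set(ferm["donor_id"].astype(str))
    meta_donors = set(meta["donor_id"].astype(str))
    shared = sorted(ferm_donors & meta_donors)
    report = {
        "shared": shared,
        "fermentation_only": sorted(ferm_donors - meta_donors),
        "metadata_only": sorted(meta_donors - ferm_donors),
    }
    if not shared:
        raise ValidationError("no donors shared between fermentation table and metadata")
    if report["fermentation_only"] or report["metadata_only"]:
        log.warning(
            "donor sets differ: %d fermentation-only, %d metadata-only; proceeding on %d shared",
            len(report["fermentation_only"]), len(report["metadata_only"]), len(shared),
        )
    return report
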