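"""End-to-end orchestration: synergy -> stats -> labels -> diversity ->
associations -> differential abundance -> networks.

A single :class:`RunConfig` (built in code or loaded from YAML/JSON)
drives the whole analysis.  Every stage materializes its output table
under the run's output directory, so any stage can be audited or re-run
from stored intermediates, and a JSON report records the seed, a config
hash, per-stage record counts and every suppressed-statistics event.
A single global seed is split into independent per-stage seeds with
``numpy.random.SeedSequence``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association, diffabund, diversity, io, network, stats, synergy, synthetic
from ._constants import SCFA_TYPES

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class RunConfig:
    """Inputs, options and seed of one pipeline run.

    Either ``simulate=True`` (synthetic fermentation + taxa tables from
    the generator configs) or explicit input paths.  All thresholds
    default to the study's documented settings.
    """

    out_dir: str = "results/run"
    seed: int = 0
    simulate: bool = True
    fermentation_path: str | None = None
    taxa_baseline_path: str | None = None
    taxa_post_path: str | None = None
    metadata_path: str | None = None
    ferm_gen: synthetic.FermGenConfig = field(default_factory=synthetic.FermGenConfig)
    taxa_gen: synthetic.TaxaGenConfig = field(default_factory=synthetic.TaxaGenConfig)
    filters: synergy.FilterConfig = field(default_factory=synergy.FilterConfig)
    test_method: str = "t"
    alpha: float = 0.05
    n_min: int = 3
    da_timepoint: str = "post"
    da_prevalence_min: float = 0.10
    network: network.NetworkConfig = field(default_factory=network.NetworkConfig)
    hub_k: int = 5

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        with open(path, encoding="utf-8") as fh:
            payload = yaml.safe_load(fh) if path.suffix in (".yml", ".yaml") else json.load(fh)
        return cls.from_dict(payload)

    @classmethod
    def from_dict(cls, payload: dict) -> "RunConfig":
        payload = dict(payload)
        for key, typ in (
            ("ferm_gen", synthetic.FermGenConfig),
            ("taxa_gen", synthetic.TaxaGenConfig),
            ("filters", synergy.FilterConfig),
            ("network", network.NetworkConfig),
        ):
            if key in payload and isinstance(payload[key], dict):
                payload[key] = typ(**payload[key])
        cfg = cls(**payload)
        for key in ("fermentation_path", "metadata_path", "taxa_baseline_path", "taxa_post_path"):
            value = getattr(cfg, key)
            if value is not None and not Path(value).exists():
                raise PipelineError(f"config: {key} points at missing file {value}")
        return cfg

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload.pop("out_dir", None)  # output location is not scientific config
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _stage_seeds(seed: int, n: int = 4) -> list[int]:
    return [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(seed).spawn(n)]


def run(config: RunConfig) -> dict:
    """Execute the full analysis; returns the run report (also written
    to ``<out_dir>/report.json``)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    report: dict = {
        "seed": config.seed,
        "stage_seeds": seeds,
        "config_hash": config.config_hash(),
        "stages": {},
        "suppressed": [],
    }

    # --- inputs -----------------------------------------------------------
    stage = "inputs"
    try:
        if config.simulate:
            ferm_cfg = dataclasses.replace(config.ferm_gen, seed=seeds[0])
            ferm, truth = synthetic.generate_fermentation_table(ferm_cfg)
            truth.to_json(out / "ground_truth.json")
        else:
            if not config.fermentation_path:
                raise PipelineError("inputs: fermentation_path required when simulate=False")
            ferm = io.read_fermentation(config.fermentation_path)
            truth = None
        ferm = io.ensure_total_rows(ferm)
        io.write_fermentation(ferm, out / "fermentation.csv")
        report["stages"][stage] = {"fermentation_rows": int(len(ferm))}
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    # --- synergy ----------------------------------------------------------
    stage = "synergy"
    try:
        fibers = list(config.ferm_gen.fibers) if config.simulate else sorted(
            set(ferm["substrate"]) - {"mixture"}
        )
        syn = synergy.compute_synergy(ferm, fibers=fibers)
        syn = synergy.apply_filters(syn, config.filters)
        syn.to_csv(out / "synergy.csv", index=False)
        summary = synergy.summarize_synergy(syn, "all", n_min=config.filters.n_min)
        summary_cs = synergy.summarize_synergy(syn, "condition_scfa", n_min=config.filters.n_min)
        summary_scfa = synergy.summarize_synergy(syn, "scfa_type", n_min=config.filters.n_min)
        pd.concat([summary.assign(group="all"), summary_scfa, summary_cs]).to_csv(
            out / "synergy_summary.csv", index=False
        )
        total = syn[(syn["scfa_type"] == "total") & (syn["filter_status"] == "retained")]
        report["stages"][stage] = {
            "records": int(len(syn)),
            "retained": int((syn["filter_status"] == "retained").sum()),
            "mean_total_synergy_pct": float(total["synergy_pct"].mean()),
            "sd_total_synergy_pct": float(total["synergy_pct"].std(ddof=1)),
            "median_total_synergy_pct": float(total["synergy_pct"].median()),
            "max_total_synergy_pct": float(total["synergy_pct"].max()),
        }
        report["suppressed"] += [
            f"synergy_summary:{row.to_dict()}" for _, row in summary_cs[summary_cs["stats_suppressed"]].iterrows()
        ]
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    # --- group statistics -------------------------------------------------
    stage = "stats"
    try:
        ove = stats.observed_vs_expected_suite(
            syn, method=config.test_method, alpha=config.alpha, n_min=config.n_min
        )
        across = stats.synergy_comparison_suite(syn, "across_conditions", alpha=config.alpha,
                                                n_min=config.n_min)
        within = stats.synergy_comparison_suite(syn, "across_scfa_within_condition",
                                                alpha=config.alpha, n_min=config.n_min)
        tukey_frames = []
        for cond, sub in ferm[ferm["scfa_type"] == "total"].groupby("condition"):
            wide = sub.pivot_table(index="donor_id", columns="substrate", values="concentration_mM")
            tukey_frames.append(stats.tukey_contrasts(wide, alpha=config.alpha,
                                                      n_min=config.n_min, family=f"tukey:{cond}"))
        all_stats = pd.concat([ove, across, within, *tukey_frames], ignore_index=True)
        all_stats.to_csv(out / "stats.csv", index=False)
        report["stages"][stage] = {
            "tests": int(len(all_stats)),
            "significant": int(all_stats["significant"].fillna(False).sum()),
        }
        report["suppressed"] += all_stats.loc[all_stats["suppressed"] == True, "comparison"].tolist()  # noqa: E712
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    # --- donor labels & taxa tables ----------------------------------------
    stage = "labels"
    try:
        labels = synergy.classify_donors(syn)
        labels.to_csv(out / "donor_labels.csv", index=False)
        groups = {
            g: labels.loc[labels["synergy_label"] == g, "donor_id"].tolist()
            for g in ("synergy", "no_synergy")
        }
        report["stages"][stage] = {k: len(v) for k, v in groups.items()}
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    stage = "taxa"
    try:
        if config.simulate:
            base_cfg = dataclasses.replace(
                config.taxa_gen, seed=seeds[1], timepoint="baseline", enriched_taxa={}
            )
            post_cfg = dataclasses.replace(config.taxa_gen, seed=seeds[2], timepoint="post")
            counts_base, meta_base, _ = synthetic.generate_taxa_counts(base_cfg, groups)
            counts_post, meta_post, taxa_truth = synthetic.generate_taxa_counts(post_cfg, groups)
            meta = pd.concat([meta_base, meta_post], ignore_index=True)
            if taxa_truth.enriched:
                truth_all = truth or synthetic.GroundTruth()
                truth_all.enriched = taxa_truth.enriched
                truth_all.to_json(out / "ground_truth.json")
        else:
            meta = io.read_metadata(config.metadata_path)
            counts_base = (
                io.read_taxa_table(config.taxa_baseline_path) if config.taxa_baseline_path else None
            )
            counts_post = io.read_taxa_table(config.taxa_post_path)
            io.validate_join(ferm, meta)
            # donor labels come from the synergy classification, not the file
            meta = meta.drop(columns=["synergy_label"]).merge(
                labels[["donor_id", "synergy_label"]], on="donor_id", how="left"
            )
            meta["synergy_label"] = meta["synergy_label"].fillna("unassigned")
        io.write_metadata(meta, out / "metadata.tsv")
        io.write_taxa_table(counts_post, out / "taxa_post.tsv")
        if counts_base is not None:
            io.write_taxa_table(counts_base, out / "taxa_baseline.tsv")
        report["stages"][stage] = {"samples": int(len(meta)), "taxa": int(len(counts_post))}
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    # --- diversity & associations ------------------------------------------
    stage = "diversity"
    try:
        tables = [diversity.diversity_table(counts_post, meta[meta["timepoint"] == "post"])]
        if counts_base is not None:
            tables.append(diversity.diversity_table(counts_base, meta[meta["timepoint"] == "baseline"]))
        div = pd.concat(tables, ignore_index=True)
        div.to_csv(out / "diversity.csv", index=False)
        report["stages"][stage] = {"samples": int(len(div))}
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    stage = "associations"
    try:
        feats = diversity.diversity_features(div)
        grid_div = association.correlation_grid(syn, feats, alpha=config.alpha, n_min=config.n_min)
        grid_div.to_csv(out / "associations_diversity.csv", index=False)
        grid_scfa = association.correlation_grid(
            syn, association.scfa_features(syn), alpha=config.alpha, n_min=config.n_min
        )
        grid_scfa.to_csv(out / "associations_scfa.csv", index=False)
        both = pd.concat([grid_div, grid_scfa])
        tested = both["p"].notna()
        report["stages"][stage] = {
            "cells": int(len(both)),
            "tested": int(tested.sum()),
            "significant": int(both.loc[tested, "significant"].sum()),
        }
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    # --- differential abundance ---------------------------------------------
    stage = "differential_abundance"
    try:
        da_counts = counts_post if config.da_timepoint == "post" else counts_base
        da_meta = meta[meta["timepoint"] == config.da_timepoint]
        cols = [s for s in da_meta["sample_id"] if s in da_counts.columns]
        try:
            da = diffabund.differential_abundance(
                da_counts[cols], da_meta,
                prevalence_min=config.da_prevalence_min, alpha=config.alpha,
            )
            da.to_csv(out / "differential_abundance.csv", index=False)
            report["stages"][stage] = {
                "tested": int((da["status"] == "tested").sum()),
                "significant": int(da["significant"].fillna(False).sum()),
            }
        except diffabund.DiffAbundError as exc:
            # e.g. fewer than two donors in one synergy group: not a fatal
            # run error, but no differential abundance is reportable
            report["suppressed"].append(f"differential_abundance:{exc}")
            report["stages"][stage] = {"tested": 0, "significant": 0}
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    # --- networks -------------------------------------------------------------
    stage = "networks"
    try:
        nets = {}
        post_meta = meta[meta["timepoint"] == config.da_timepoint]
        for label in ("synergy", "no_synergy"):
            samples = post_meta.loc[post_meta["synergy_label"] == label, "sample_id"].tolist()
            if len(samples) < 5:
                report["suppressed"].append(f"network:{label}:n={len(samples)}")
                continue
            rho, p = network.taxa_correlation_matrix(
                da_counts[samples], prevalence_min=config.network.prevalence_min
            )
            g = network.build_network(rho, p, config.network, stratum=label)
            network.export_network(g, out / f"network_{label}.graphml", "graphml")
            network.export_network(g, out / f"network_{label}_edges.tsv", "edge_tsv")
            hubs = network.centrality_and_hubs(g, k=config.hub_k)
            hubs.to_csv(out / f"network_{label}_hubs.csv", index=False)
            nets[label] = {"nodes": g.number_of_nodes(), "edges": g.number_of_edges(),
                           "hubs": hubs["taxon"].tolist()}
        report["stages"][stage] = nets
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    report_blob = json.dumps(report, indent=2, sort_keys=True, default=str)
    report["report_hash"] = hashlib.sha256(report_blob.encode()).hexdigest()[:16]
    with open(out / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
    with open(out / "report.txt", "w", encoding="utf-8") as fh:
        syn_stage = report["stages"]["synergy"]
        fh.write(
            "fibersynergy run report\n"
            f"seed {config.seed}  config {report['config_hash']}\n"
            f"records {syn_stage['records']}, retained {syn_stage['retained']}\n"
            f"mean total-SCFA synergy {syn_stage['mean_total_synergy_pct']:.1f}%"
            f" +/- {syn_stage['sd_total_synergy_pct']:.1f}%"
            f" (median {syn_stage['median_total_synergy_pct']:.1f}%,"
            f" max {syn_stage['max_total_synergy_pct']:.1f}%)\n"
            f"suppressed events: {len(report['suppressed'])}\n"
        )
    return report
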