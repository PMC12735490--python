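"""Synthetic fermentation and taxa-count data with known ground truth.

The generators emulate the statistical structure of a 33-donor in vitro
fecal fermentation study (four health conditions; four single fibers plus
their mixture; acetate/propionate/butyrate measured by GC in mM) and of
genus-level 16S count tables, so that every downstream stage of the
pipeline can be validated against planted effects:

* a per-donor supra-additive mixture effect ("synergy") of known size is
  injected into the mixture concentrations, and
* designated taxa receive a known compositional fold-change in the
  synergy donor group.

The generators are purely statistical; they model the marginal
distributions and the planted effects, not fermentation kinetics or
cross-feeding mechanisms.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._constants import (
    ACIDS,
    DEFAULT_CONDITIONS,
    DEFAULT_FIBERS,
    FERMENTATION_COLUMNS,
    METADATA_COLUMNS,
    MIXTURE,
)


class ConfigError(ValueError):
    """A generator configuration field failed validation."""


def _require(condition: bool, field_name: str, message: str) -> None:
    if not condition:
        raise ConfigError(f"{field_name}: {message}")


@dataclass(frozen=True)
class FermGenConfig:
    """Configuration of the fermentation-table generator.

    Parameters
    ----------
    conditions
        Donor count per health-condition label.  Defaults to the cohort
        design HC:10, PD:10, CD:7, UC:7 (33 donors).
    fibers
        Exactly four single-fiber substrate labels.
    base_mean_mM
        Median per-fiber concentration (mM) of each acid for the
        reference condition, before condition/fiber multipliers.
    condition_factor, fiber_factor
        Multiplicative adjustments of the median per condition and per
        fiber (pectin-type fibers ferment strongest; disease conditions
        run lower than healthy controls).
    donor_sigma, cell_sigma
        Log-scale SD of the shared per-donor random effect and of the
        residual per-(donor, fiber, acid) variation of the log-normal
        concentration model.
    synergy_mean, synergy_sd
        Mean and SD (percent) of the per-donor injected synergy delta;
        the mixture concentration is ``mean(four fibers) * (1 + delta/100)``
        plus measurement noise.
    per_scfa_delta
        If true, draw an independent delta per (donor, acid) instead of
        one per donor.
    noise_sd
        SD (mM) of additive Gaussian measurement noise on every recorded
        concentration, truncated at zero.
    detection_limit
        Carried into the table metadata for downstream filtering (mM).
    """

    conditions: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_CONDITIONS))
    fibers: Sequence[str] = DEFAULT_FIBERS
    scfa_types: Sequence[str] = ACIDS
    base_mean_mM: Mapping[str, float] = field(
        default_factory=lambda: {"acetate": 40.0, "propionate": 15.0, "butyrate": 15.0}
    )
    condition_factor: Mapping[str, float] = field(
        default_factory=lambda: {"HC": 1.0, "PD": 0.8, "CD": 0.7, "UC": 0.7}
    )
    fiber_factor: Mapping[str, float] = field(
        default_factory=lambda: {"pectin": 1.3, "beta_glucan": 1.0, "fos": 1.1, "arabinoxylan": 0.8}
    )
    donor_sigma: float = 0.30
    cell_sigma: float = 0.25
    synergy_mean: float = 33.0
    synergy_sd: float = 20.0
    per_scfa_delta: bool = False
    noise_sd: float = 0.1
    detection_limit: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        _require(len(self.conditions) >= 1, "conditions", "at least one condition required")
        for label, n in self.conditions.items():
            _require(int(n) >= 1, "conditions", f"donor count for {label!r} must be >= 1")
        _require(len(self.fibers) == 4, "fibers", "exactly 4 fiber labels required")
        _require(len(set(self.fibers)) == 4, "fibers", "fiber labels must be distinct")
        _require(MIXTURE not in self.fibers, "fibers", f"{MIXTURE!r} is reserved")
        _require(len(self.scfa_types) >= 1, "scfa_types", "at least one acid required")
        for acid in self.scfa_types:
            _require(acid in self.base_mean_mM, "base_mean_mM", f"missing level for {acid!r}")
            _require(self.base_mean_mM[acid] > 0, "base_mean_mM", f"{acid!r} level must be > 0")
        _require(self.noise_sd >= 0, "noise_sd", "must be >= 0")
        _require(self.synergy_sd >= 0, "synergy_sd", "must be >= 0")
        _require(self.donor_sigma >= 0, "donor_sigma", "must be >= 0")
        _require(self.cell_sigma >= 0, "cell_sigma", "must be >= 0")
        _require(self.detection_limit >= 0, "detection_limit", "must be >= 0")


@dataclass(frozen=True)
class TaxaGenConfig:
    """Configuration of the Dirichlet-multinomial taxa-count generator.

    ``base_composition`` is the Dirichlet concentration vector shared by
    both groups; in the synergy group, each taxon listed in
    ``enriched_taxa`` has its concentration multiplied by its fold-change
    before the per-sample composition is drawn.  Library sizes are
    log-normal.  The default uniform concentration of 10 per taxon keeps
    compositional overdispersion moderate, so log-scale abundances are
    close to their compositional expectations.
    """

    n_taxa: int = 40
    n_samples_per_group: int = 20
    enriched_taxa: Mapping[str, float] = field(default_factory=dict)
    base_composition: Sequence[float] | None = None
    base_concentration: float = 10.0
    library_size_mean: float = 3e4
    library_size_sigma: float = 0.3
    timepoint: str = "post"
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_taxa >= 2, "n_taxa", "must be >= 2")
        _require(self.n_samples_per_group >= 2, "n_samples_per_group", "must be >= 2")
        for taxon, fold in self.enriched_taxa.items():
            _require(fold > 0, "enriched_taxa", f"fold-change for {taxon!r} must be > 0")
        if self.base_composition is not None:
            comp = np.asarray(self.base_composition, dtype=float)
            _require(comp.size == self.n_taxa, "base_composition", "length must equal n_taxa")
            _require(bool(np.all(comp > 0)), "base_composition", "must be strictly positive")
        _require(self.base_concentration > 0, "base_concentration", "must be > 0")
        _require(self.library_size_mean > 0, "library_size_mean", "must be > 0")
        _require(self.library_size_sigma >= 0, "library_size_sigma", "must be >= 0")

    def taxon_names(self) -> list[str]:
        return [f"taxon_{i:03d}" for i in range(self.n_taxa)]


@dataclass
class GroundTruth:
    """Planted effects: per-donor synergy deltas and enriched taxa.

    ``delta`` maps donor id -> {scfa_type: injected synergy %}; ``enriched``
    maps taxon id -> true compositional fold-change (>1 means higher in
    the synergy group; the natural-log fold change is ``ln(fold)``).
    """

    delta: dict[str, dict[str, float]] = field(default_factory=dict)
    enriched: dict[str, float] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        return cls(delta=payload.get("delta", {}), enriched=payload.get("enriched", {}))


def _donor_ids(conditions: Mapping[str, int]) -> list[tuple[str, str]]:
    out = []
    for cond, n in conditions.items():
        out.extend((f"{cond}_{i + 1:02d}", cond) for i in range(int(n)))
    return out


def generate_fermentation_table(cfg: FermGenConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a long-format fermentation table with injected synergy.

    For each donor and acid, the four single-fiber concentrations are
    log-normal draws around condition- and fiber-adjusted medians with a
    shared per-donor random effect; the mixture concentration is the
    per-donor mean of the four recorded fiber values scaled by
    ``1 + delta/100`` where ``delta ~ Normal(synergy_mean, synergy_sd)``
    is drawn once per donor (or per donor x acid).  Additive Gaussian
    measurement noise (SD ``noise_sd`` mM, truncated at 0) is applied to
    every recorded value, and per-substrate ``total`` rows are appended
    as the exact sum of the three acids.

    Returns the table (columns ``donor_id, condition, substrate,
    scfa_type, concentration_mM``) and the :class:`GroundTruth` of
    injected deltas.
    """
    rng = np.random.default_rng(cfg.seed)
    donors = _donor_ids(cfg.conditions)
    acids = list(cfg.scfa_types)
    fibers = list(cfg.fibers)

    truth = GroundTruth()
    rows: list[tuple] = []
    for donor_id, cond in donors:
        donor_effect = float(np.exp(rng.normal(0.0, cfg.donor_sigma)))
        if cfg.per_scfa_delta:
            deltas = {a: float(rng.normal(cfg.synergy_mean, cfg.synergy_sd)) for a in acids}
        else:
            d = float(rng.normal(cfg.synergy_mean, cfg.synergy_sd))
            deltas = {a: d for a in acids}
        truth.delta[donor_id] = dict(deltas)

        fiber_conc: dict[str, dict[str, float]] = {f: {} for f in fibers}
        for acid in acids:
            median = cfg.base_mean_mM[acid] * cfg.condition_factor.get(cond, 1.0)
            for fiber in fibers:
                cell = np.exp(rng.normal(0.0, cfg.cell_sigma))
                value = median * cfg.fiber_factor.get(fiber, 1.0) * donor_effect * cell
                value = max(0.0, value + rng.normal(0.0, cfg.noise_sd)) if cfg.noise_sd else value
                fiber_conc[fiber][acid] = float(value)
        for acid in acids:
            mean4 = float(np.mean([fiber_conc[f][acid] for f in fibers]))
            mix = mean4 * (1.0 + deltas[acid] / 100.0)
            if cfg.noise_sd:
                mix = max(0.0, mix + rng.normal(0.0, cfg.noise_sd))
            fiber_conc.setdefault(MIXTURE, {})[acid] = float(mix)

        for substrate in fibers + [MIXTURE]:
            for acid in acids:
                rows.append((donor_id, cond, substrate, acid, fiber_conc[substrate][acid]))
            rows.append(
                (donor_id, cond, substrate, "total", float(sum(fiber_conc[substrate][a] for a in acids)))
            )

    table = pd.DataFrame(rows, columns=list(FERMENTATION_COLUMNS))
    return table, truth


def generate_taxa_counts(
    cfg: TaxaGenConfig,
    donors_per_group: Mapping[str, Sequence[str]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate taxa x samples counts with planted group enrichment.

    Per sample, a composition is drawn from a Dirichlet whose
    concentration vector is ``base_composition`` for the no-synergy
    group and, for the synergy group, the same vector with each enriched
    taxon multiplied by its fold-change; counts are multinomial at a
    log-normal library size.

    ``donors_per_group`` optionally maps each group label to the donor
    ids of its samples (one sample per donor), overriding
    ``cfg.n_samples_per_group``; this is how the pipeline ties taxa
    samples to fermentation donors.

    Returns ``(counts, metadata, truth)`` where ``counts`` is a
    DataFrame indexed by taxon with one integer column per sample and
    ``metadata`` has columns ``sample_id, donor_id, timepoint,
    synergy_label``.
    """
    rng = np.random.default_rng(cfg.seed)
    taxa = cfg.taxon_names()
    if cfg.base_composition is not None:
        base = np.asarray(cfg.base_composition, dtype=float)
    else:
        base = np.full(cfg.n_taxa, cfg.base_concentration, dtype=float)

    unknown = set(cfg.enriched_taxa) - set(taxa)
    if unknown:
        raise ConfigError(f"enriched_taxa: unknown taxa {sorted(unknown)}")

    alphas = {"no_synergy": base.copy(), "synergy": base.copy()}
    for taxon, fold in cfg.enriched_taxa.items():
        alphas["synergy"][taxa.index(taxon)] *= fold

    if donors_per_group is None:
        groups = {
            group: [f"donor_{group}_{j + 1:03d}" for j in range(cfg.n_samples_per_group)]
            for group in ("synergy", "no_synergy")
        }
    else:
        unknown_groups = set(donors_per_group) - {"synergy", "no_synergy"}
        if unknown_groups:
            raise ConfigError(f"donors_per_group: unknown groups {sorted(unknown_groups)}")
        groups = {g: list(d) for g, d in donors_per_group.items() if len(d) > 0}

    columns: dict[str, np.ndarray] = {}
    meta_rows = []
    for group in ("synergy", "no_synergy"):
        donors = groups.get(group, [])
        if not donors:
            continue
        comps = rng.dirichlet(alphas[group], size=len(donors))
        sizes = rng.lognormal(np.log(cfg.library_size_mean), cfg.library_size_sigma, size=len(donors))
        for j, donor in enumerate(donors):
            sample_id = f"{donor}_{cfg.timepoint}"
            columns[sample_id] = rng.multinomial(int(round(sizes[j])), comps[j])
            meta_rows.append((sample_id, donor, cfg.timepoint, group))

    counts = pd.DataFrame(columns, index=pd.Index(taxa, name="taxon"), dtype=np.int64)
    metadata = pd.DataFrame(meta_rows, columns=list(METADATA_COLUMNS))
    truth = GroundTruth(enriched={t: float(f) for t, f in cfg.enriched_taxa.items()})
    return counts, metadata, truth
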