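#!/usr/bin/env python
"""Alpha diversity and its association with synergy.

Computes Shannon, richness and Pielou evenness per sample at baseline
and post-fermentation plus their change, then Spearman-correlates each
synergy measure with every diversity feature and with the absolute
observed SCFA concentrations (per-cell significance at 0.05, no
multiplicity adjustment, mirroring heatmap-style annotation).

Reads results/analysis/{data/*, synergy.csv}; writes diversity.csv,
associations_diversity.csv and associations_scfa.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from fibersynergy import association, diversity, io


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--results-dir", type=Path, default=Path("results/analysis"))
    args = parser.parse_args()
    out = args.results_dir
    data = out / "data"
    meta = io.read_metadata(data / "metadata.tsv")
    syn = pd.read_csv(out / "synergy.csv")

    tables = []
    for timepoint, filename in (("baseline", "taxa_baseline.tsv"), ("post", "taxa_post.tsv")):
        counts = io.read_taxa_table(data / filename)
        tables.append(diversity.diversity_table(counts, meta[meta["timepoint"] == timepoint]))
    div = pd.concat(tables, ignore_index=True)
    div.to_csv(out / "diversity.csv", index=False)

    feats = diversity.diversity_features(div)
    grid_div = association.correlation_grid(syn, feats)
    grid_div.to_csv(out / "associations_diversity.csv", index=False)
    grid_scfa = association.correlation_grid(syn, association.scfa_features(syn))
    grid_scfa.to_csv(out / "associations_scfa.csv", index=False)

    print(f"diversity: {len(div)} samples "
          f"(mean post-fermentation Shannon "
          f"{div.loc[div['timepoint'] == 'post', 'shannon'].mean():.3f} nats)")
    for name, grid in (("diversity", grid_div), ("absolute SCFA", grid_scfa)):
        tested = grid["p"].notna()
        n_sig = int(grid.loc[tested, "significant"].sum())
        print(f"synergy vs {name}: {int(tested.sum())} cells tested, "
              f"{n_sig} significant at 0.05"
              + (" (consistent with no real association)" if n_sig <= 2 else ""))


if __name__ == "__main__":
    main()
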