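"""Taxa-taxa co-occurrence networks per synergy stratum.

Edges are Spearman rank correlations between relative abundances across
the samples of one stratum (e.g. the acetate-synergy donors), kept when
BH-adjusted significance across all taxon pairs passes ``alpha`` and
|rho| >= ``rho_min``; edge sign follows the correlation sign.  Node
importance is degree centrality (count of incident edges), with hub taxa
the top-k nodes by degree.  Networks export to GraphML (Cytoscape
importable) and to an edge-list TSV, and re-import losslessly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import adjust_pvalues


class NetworkError(ValueError):
    pass


@dataclass(frozen=True)
class NetworkConfig:
    """Edge thresholds: BH ``alpha`` across all pairs and minimum |rho|."""

    alpha: float = 0.05
    rho_min: float = 0.6
    prevalence_min: float = 0.10
    drop_isolated: bool = True


def taxa_correlation_matrix(
    counts: pd.DataFrame, prevalence_min: float = 0.10
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Symmetric Spearman rho and p matrices over relative abundances.

    ``counts`` is taxa x samples within one stratum (>= 5 samples).
    Taxa below the prevalence threshold are dropped before correlation;
    ties get average ranks; the diagonal is rho = 1, p = 0.
    """
    if counts.shape[1] < 5:
        raise NetworkError(f"need >= 5 samples in stratum, got {counts.shape[1]}")
    prev = (counts > 0).mean(axis=1)
    kept = counts.loc[prev >= prevalence_min]
    if kept.shape[0] < 2:
        raise NetworkError("fewer than 2 taxa pass the prevalence filter")
    rel = kept / kept.sum(axis=0)
    rho, p = sps.spearmanr(rel.to_numpy().T)
    if np.ndim(rho) == 0:  # exactly two taxa: scipy returns scalars
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
        p = np.array([[0.0, float(p)], [float(p), 0.0]])
    np.fill_diagonal(rho, 1.0)
    np.fill_diagonal(p, 0.0)
    taxa = kept.index
    return (
        pd.DataFrame(rho, index=taxa, columns=taxa),
        pd.DataFrame(p, index=taxa, columns=taxa),
    )


def build_network(
    rho: pd.DataFrame,
    p: pd.DataFrame,
    cfg: NetworkConfig = NetworkConfig(),
    stratum: str = "",
) -> nx.Graph:
    """Signed co-occurrence graph from correlation matrices.

    BH is applied across all upper-triangle pairs; an edge is kept iff
    its q < ``cfg.alpha`` and |rho| >= ``cfg.rho_min``.  Isolated nodes
    are dropped by default.
    """
    taxa = list(rho.index)
    pairs = list(itertools.combinations(range(len(taxa)), 2))
    rho_arr = rho.to_numpy()
    p_arr = p.to_numpy()
    raw = [float(p_arr[i, j]) for i, j in pairs]
    qs = adjust_pvalues(raw, "bh") if raw else []

    g = nx.Graph(stratum=stratum, alpha=cfg.alpha, rho_min=cfg.rho_min)
    g.add_nodes_from(taxa)
    for (i, j), q in zip(pairs, qs):
        r = float(rho_arr[i, j])
        if q < cfg.alpha and abs(r) >= cfg.rho_min:
            g.add_edge(
                taxa[i], taxa[j], rho=r, q=float(q),
                sign="positive" if r >= 0 else "negative",
            )
    if cfg.drop_isolated:
        g.remove_nodes_from(list(nx.isolates(g)))
    for node in g.nodes:
        g.nodes[node]["degree"] = int(g.degree(node))
    return g


def centrality_and_hubs(g: nx.Graph, k: int = 5, centrality: str = "degree") -> pd.DataFrame:
    """Top-k hub taxa ranked by centrality.

    Degree centrality (edge count) by default; ``'betweenness'``
    optional.  Ties break by summed |rho| of incident edges, then
    lexicographic taxon id.  Empty networks give an empty ranking.
    """
    if centrality == "degree":
        cent = {n: float(g.degree(n)) for n in g.nodes}
    elif centrality == "betweenness":
        cent = nx.betweenness_centrality(g)
    else:
        raise NetworkError(f"unknown centrality {centrality!r}")
    strength = {
        n: float(sum(abs(d["rho"]) for _, _, d in g.edges(n, data=True))) for n in g.nodes
    }
    ranked = sorted(g.nodes, key=lambda n: (-cent[n], -strength[n], n))
    rows = [
        {"taxon": n, "centrality": cent[n], "degree": int(g.degree(n)), "strength": strength[n]}
        for n in ranked[: max(k, 0)]
    ]
    return pd.DataFrame(rows, columns=["taxon", "centrality", "degree", "strength"])


def export_network(g: nx.Graph, path, fmt: str = "graphml") -> None:
    """Write a network as GraphML or edge-list TSV (columns: source,
    target, rho, q, sign)."""
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(g, path)
    elif fmt == "edge_tsv":
        rows = [
            {"source": u, "target": v, "rho": d["rho"], "q": d["q"], "sign": d["sign"]}
            for u, v, d in g.edges(data=True)
        ]
        pd.DataFrame(rows, columns=["source", "target", "rho", "q", "sign"]).to_csv(
            path, sep="\t", index=False
        )
    else:
        raise NetworkError(f"unknown export format {fmt!r}")


def import_network(path, fmt: str = "graphml") -> nx.Graph:
    if fmt == "graphml":
        return nx.read_graphml(Path(path))
    if fmt == "edge_tsv":
        df = pd.read_csv(Path(path), sep="\t")
        g = nx.Graph()
        for _, row in df.iterrows():
            g.add_edge(row["source"], row["target"], rho=float(row["rho"]),
                       q=float(row["q"]), sign=str(row["sign"]))
        for node in g.nodes:
            g.nodes[node]["degree"] = int(g.degree(node))
        return g
    raise NetworkError(f"unknown import format {fmt!r}")
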