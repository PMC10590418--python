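"""Settlement overlays on the co-occurrence network.

Connects the inferred network and its module partition back to the
settlement experiment: per-node and per-module settlement-category
fractions (from per-sample relative abundances), module purity labels,
module-collapsed simplified networks, bridging nodes (edges crossing
modules), betweenness/degree screening for nodes of interest, and the
exclusivity / rare-family summaries.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd

from .core_microbiome import relative_abundance
from .io import CountTable, DataError, TaxonomyTable
from .modularity import ModulePartition

CATEGORY_ORDER = ("high", "medium", "low")


def _category_series(categories, sample_ids) -> pd.Series:
    cats = pd.Series(categories)
    missing = [s for s in sample_ids if s not in cats.index]
    if missing:
        raise DataError(f"sample(s) without settlement category: {missing[:5]}")
    return cats.loc[list(sample_ids)]


def node_settlement_fractions(table: CountTable, categories,
                              order: tuple[str, ...] = CATEGORY_ORDER) -> pd.DataFrame:
    """Per-ASV settlement-category fractions of total normalised abundance.

    Counts are normalised per sample (relative abundance); fraction_c is the
    ASV's summed normalised abundance over samples of category c divided by
    its summed abundance over all samples. ASVs with zero total abundance are
    flagged (``undefined`` = True) and carry NaN fractions.
    """
    rel = relative_abundance(table)
    cats = _category_series(categories, table.sample_ids)
    sums = pd.DataFrame(
        {c: rel.loc[:, (cats == c).to_numpy()].sum(axis=1) for c in order})
    total = sums.sum(axis=1)
    undefined = total == 0
    with np.errstate(invalid="ignore"):
        frac = sums.div(total, axis=0)
    frac[undefined] = np.nan
    frac["undefined"] = undefined
    return frac


def module_settlement_composition(table: CountTable, categories,
                                  partition: ModulePartition, module,
                                  order: tuple[str, ...] = CATEGORY_ORDER) -> pd.Series:
    """Settlement composition of one module: summed member normalised counts
    per category over the module's total."""
    members = [m for m in partition.members(module) if m in table.asv_ids]
    if not members:
        raise DataError(f"module {module!r} has no members in the table")
    rel = relative_abundance(table).loc[members]
    cats = _category_series(categories, table.sample_ids)
    sums = pd.Series({c: rel.loc[:, (cats == c).to_numpy()].sum().sum() for c in order})
    total = sums.sum()
    if total == 0:
        raise DataError(f"module {module!r} has zero total abundance")
    return sums / total


def label_module_purity(composition: pd.Series, purity_threshold: float = 0.75) -> str:
    """Dominant category if its fraction reaches the threshold, else "mixed"."""
    top = composition.idxmax()
    return str(top) if composition[top] >= purity_threshold else "mixed"


def collapse_modules(network: nx.Graph, partition: ModulePartition) -> nx.Graph:
    """Simplified network: one node per module, edge weight = number of
    parent edges crossing that module pair; intra-module edges dropped."""
    assign = partition.assignment
    missing = [v for v in network.nodes if v not in assign]
    if missing:
        raise DataError(f"partition does not cover node(s): {missing[:5]}")
    g = nx.Graph()
    sizes: dict = {}
    for v in network.nodes:
        sizes[assign[v]] = sizes.get(assign[v], 0) + 1
    for m, n in sizes.items():
        g.add_node(m, n_members=n)
    for u, v in network.edges():
        a, b = assign[u], assign[v]
        if a == b:
            continue
        if g.has_edge(a, b):
            g[a][b]["weight"] += 1
        else:
            g.add_edge(a, b, weight=1)
    return g


def bridging_nodes(network: nx.Graph, partition: ModulePartition) -> set:
    """Nodes with at least one incident edge crossing module boundaries."""
    assign = partition.assignment
    out = set()
    for u, v in network.edges():
        if assign[u] != assign[v]:
            out.add(u)
            out.add(v)
    return out


def betweenness_degree(network: nx.Graph, weighted: bool = False) -> pd.DataFrame:
    """Unnormalised betweenness (shortest-path count) and degree per node.

    Default topology is unweighted; with ``weighted`` the shortest paths use
    distance 1/|w|.
    """
    if weighted:
        h = network.copy()
        for u, v, d in h.edges(data=True):
            w = abs(float(d.get("weight", 1.0)))
            d["_dist"] = 1.0 / w if w > 0 else np.inf
        btw = nx.betweenness_centrality(h, normalized=False, weight="_dist")
    else:
        btw = nx.betweenness_centrality(network, normalized=False)
    deg = dict(network.degree())
    nodes = sorted(network.nodes, key=str)
    return pd.DataFrame({"betweenness": [btw[v] for v in nodes],
                         "degree": [deg[v] for v in nodes]},
                        index=pd.Index(nodes, name="node"))


def nodes_of_interest(annotations: pd.DataFrame, bridging: set,
                      betweenness_min: float = 3.0,
                      degree_range: tuple[int, int] = (2, 4)) -> set:
    """Bridging nodes with high betweenness and low degree.

    Selected iff betweenness >= betweenness_min, degree within
    degree_range (inclusive), and the node bridges modules.
    """
    lo, hi = degree_range
    sel = annotations[(annotations["betweenness"] >= betweenness_min)
                      & (annotations["degree"] >= lo)
                      & (annotations["degree"] <= hi)]
    return set(sel.index) & set(bridging)


def _aggregate_family(table: CountTable, taxonomy: TaxonomyTable) -> pd.DataFrame:
    fam = [taxonomy.rank_of(a, "family") for a in table.asv_ids]
    return table.counts.groupby(pd.Index(fam, name="family")).sum()


def exclusive_taxa(table: CountTable, categories, rank: str = "asv",
                   taxonomy: TaxonomyTable | None = None,
                   order: tuple[str, ...] = CATEGORY_ORDER) -> dict[str, set]:
    """Taxa whose every nonzero count falls in samples of one category.

    At family rank, member ASV counts are aggregated first, so a family split
    across categories is not exclusive even when each of its ASVs is.
    """
    if rank == "family":
        if taxonomy is None:
            raise DataError("family-rank exclusivity requires a taxonomy table")
        counts = _aggregate_family(table, taxonomy)
    elif rank == "asv":
        counts = table.counts
    else:
        raise ValueError(f"rank must be 'asv' or 'family', got {rank!r}")
    cats = _category_series(categories, table.sample_ids)
    present = counts > 0
    zero = ~present.any(axis=1)
    if zero.any():
        warnings.warn(f"excluding {int(zero.sum())} all-zero taxa from exclusivity")
        present = present[~zero]
    out: dict[str, set] = {c: set() for c in order}
    for c in order:
        in_c = (cats == c).to_numpy()
        only_c = present.loc[:, in_c].any(axis=1) & ~present.loc[:, ~in_c].any(axis=1)
        out[c] = set(present.index[only_c])
    return out


def rare_taxa(table: CountTable, taxonomy: TaxonomyTable, rank: str = "family",
              cutoff: float = 0.001) -> tuple[set, pd.DataFrame]:
    """Families with overall mean relative abundance below the cutoff.

    Returns the rare set and the ln(x+1)-transformed relative-abundance
    matrix (families × samples) for those families.
    """
    if rank != "family":
        raise ValueError("rare-taxon screening is defined at family rank")
    fam_counts = _aggregate_family(table, taxonomy)
    rel = relative_abundance(fam_counts)
    rare = set(rel.index[rel.mean(axis=1) < cutoff])
    mat = np.log1p(rel.loc[sorted(rare)])
    return rare, mat


def annotate_nodes(network: nx.Graph, partition: ModulePartition,
                   table: CountTable, categories,
                   betweenness_min: float = 3.0,
                   degree_range: tuple[int, int] = (2, 4)) -> pd.DataFrame:
    """Full per-node annotation: settlement fractions, degree, betweenness,
    bridging flag and node-of-interest flag, for every network node."""
    frac = node_settlement_fractions(table, categories)
    bd = betweenness_degree(network)
    bridging = bridging_nodes(network, partition)
    nodes = sorted(network.nodes, key=str)
    out = bd.join(frac.reindex(nodes), how="left")
    out["module"] = [partition.assignment[v] for v in nodes]
    out["bridging"] = [v in bridging for v in nodes]
    noi = nodes_of_interest(bd, bridging, betweenness_min, degree_range)
    out["node_of_interest"] = [v in noi for v in nodes]
    return out
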