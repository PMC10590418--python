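"""Co-occurrence network inference on compositional abundance data.

Pairwise associations between taxa across samples are screened with
Fisher-z tests on Pearson correlations of CLR-transformed counts
(Benjamini-Hochberg corrected), then pruned by a PC-style local
conditional-independence search: an edge is dropped the first time the
partial correlation of its endpoints, given a small conditioning subset
drawn from their current neighbourhoods, is not significantly nonzero.
The surviving edges form an undirected weighted network whose weights
are partial correlations given the endpoints' final neighbourhoods.

This is a local-to-global structure learner of the kind used to build
microbial co-occurrence networks from amplicon count tables; the CLR
step removes the compositional closure of relative abundances.
"""

from __future__ import annotations

from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .io import CountTable, DataError


def clr_transform(table: CountTable | pd.DataFrame | np.ndarray,
                  pseudocount: float = 1.0) -> pd.DataFrame | np.ndarray:
    """Centered log-ratio transform per sample column.

    x -> ln(x + pseudocount) minus the sample's mean log value; each
    column of the result sums to zero.
    """
    df = table.counts if isinstance(table, CountTable) else table
    arr = np.asarray(df, dtype=float) + pseudocount
    if (arr <= 0).any():
        raise DataError("CLR requires positive values after pseudocount")
    logs = np.log(arr)
    out = logs - logs.mean(axis=0, keepdims=True)
    if isinstance(df, pd.DataFrame):
        return pd.DataFrame(out, index=df.index, columns=df.columns)
    return out


def _fisher_z_pvalues(r: np.ndarray, n: int, n_cond: int = 0) -> np.ndarray:
    """Two-sided p-values for correlation(s) r at sample size n given n_cond vars."""
    dof = n - n_cond - 3
    if dof <= 0:
        raise DataError(f"need more than {n_cond + 3} samples for the Fisher-z test")
    r = np.clip(r, -0.999999, 0.999999)
    z = np.abs(np.arctanh(r)) * np.sqrt(dof)
    return 2.0 * stats.norm.sf(z)


def _bh_qvalues(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone step-up)."""
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(ranked, 1.0)
    return q


def _partial_corr(R: np.ndarray, i: int, j: int, S: tuple[int, ...]) -> float:
    """Partial correlation of i, j given S from the correlation matrix R."""
    if not S:
        return float(R[i, j])
    idx = [i, j, *S]
    sub = R[np.ix_(idx, idx)]
    try:
        P = np.linalg.inv(sub)
    except np.linalg.LinAlgError:
        P = np.linalg.pinv(sub)
    denom = P[0, 0] * P[1, 1]
    if denom <= 0:
        return 0.0
    return float(np.clip(-P[0, 1] / np.sqrt(denom), -1.0, 1.0))


def infer_network(matrix: pd.DataFrame | np.ndarray, alpha: float = 0.01,
                  max_k: int = 2, fdr: str = "bh",
                  seed: int | None = 0) -> nx.Graph:
    """Infer an undirected association network over the rows of ``matrix``.

    ``matrix`` holds real-valued (e.g. CLR) abundances, taxa as rows and
    samples as columns. Stage 1 retains pairs whose marginal correlation is
    significant after BH correction at ``alpha``; stage 2 removes an edge the
    first time a conditional-independence test (conditioning sets of size
    1..max_k drawn from the endpoints' neighbourhoods, PC-stable order)
    fails to reject at raw ``alpha``. The seed only shuffles the order in
    which conditioning subsets are tried.
    """
    if fdr not in ("bh", "none"):
        raise ValueError(f"unknown fdr mode {fdr!r}")
    if isinstance(matrix, pd.DataFrame):
        ids = [str(i) for i in matrix.index]
        X = matrix.to_numpy(dtype=float)
    else:
        X = np.asarray(matrix, dtype=float)
        ids = [f"t{i}" for i in range(X.shape[0])]
    p_taxa, n = X.shape
    if n < max_k + 4:
        raise DataError(f"need >= max_k+4={max_k + 4} samples, got {n}")

    sd = X.std(axis=1)
    const = sd == 0
    R = np.eye(p_taxa)
    if (~const).sum() >= 2:
        live = np.where(~const)[0]
        R[np.ix_(live, live)] = np.corrcoef(X[live])
    R = np.nan_to_num(R, nan=0.0)
    np.fill_diagonal(R, 1.0)

    iu = np.triu_indices(p_taxa, 1)
    r_flat = R[iu]
    p_flat = _fisher_z_pvalues(r_flat, n)
    q_flat = _bh_qvalues(p_flat) if fdr == "bh" else p_flat

    g = nx.Graph()
    g.add_nodes_from(ids)
    g.graph.update(alpha=alpha, max_k=max_k, fdr=fdr, n_samples=n)
    keep = q_flat < alpha
    edge_q = {}
    for i, j, q, r in zip(iu[0][keep], iu[1][keep], q_flat[keep], r_flat[keep]):
        g.add_edge(ids[i], ids[j])
        edge_q[(int(i), int(j))] = (float(q), float(r))

    rng = np.random.default_rng(seed)
    index = {a: k for k, a in enumerate(ids)}

    # PC-stable pruning: neighbourhoods are frozen per conditioning size
    for k in range(1, max_k + 1):
        adj = {v: set(g.neighbors(v)) for v in g.nodes}
        for u, v in sorted(g.edges()):
            if not g.has_edge(u, v):
                continue
            i, j = index[u], index[v]
            cands = sorted((adj[u] | adj[v]) - {u, v})
            if len(cands) < k:
                continue
            subsets = list(combinations(cands, k))
            rng.shuffle(subsets)
            for S in subsets:
                S_idx = tuple(index[s] for s in S)
                r = _partial_corr(R, i, j, S_idx)
                if _fisher_z_pvalues(np.array(r), n, k).item() > alpha:
                    g.remove_edge(u, v)
                    break

    # weights: partial correlation given the endpoints' final neighbourhoods
    for u, v in g.edges():
        i, j = index[u], index[v]
        S = sorted((set(g.neighbors(u)) | set(g.neighbors(v))) - {u, v})
        S_idx = tuple(index[s] for s in S[: max(0, n - 5)])
        w = _partial_corr(R, i, j, S_idx)
        if w == 0.0:
            w = float(R[i, j])
        key = (i, j) if (i, j) in edge_q else (j, i)
        q, r_marg = edge_q[key]
        g[u][v].update(weight=w, sign=1 if w >= 0 else -1, q=q, r_marginal=r_marg)
    return g


def network_summary(network: nx.Graph) -> dict:
    """Node/edge counts, density and connected-component count."""
    n = network.number_of_nodes()
    m = network.number_of_edges()
    density = 0.0 if n < 2 else 2.0 * m / (n * (n - 1))
    comps = nx.number_connected_components(network) if n else 0
    return {"nodes": n, "edges": m, "density": density, "components": comps}
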