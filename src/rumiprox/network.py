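"""Coabundance network analysis: thresholded correlation graphs, Markov
clustering, cluster enrichment and gene-set overlaps.

Nodes are genes (KO ids); an edge joins two genes whose relative-abundance
profiles across animals have Pearson correlation at or above the chosen
threshold. Only positive correlations form edges (coabundance semantics);
an absolute-value mode is available by flag.

Markov clustering (MCL) simulates a random walk on the weighted graph and
alternates *expansion* (squaring the column-stochastic flow matrix) with
*inflation* (element-wise powering plus column renormalization), pruning
tiny entries, until the flow matrix reaches its attractor structure.
*Pre-inflation* raises the edge weights to a power before the walk starts,
sharpening weight contrast. Clusters are read off the attractor rows. The
"scheme" pruning knob of the originating graph tool is mapped to a
per-column prune threshold plus a top-k entry cap, an approximation
documented in the methods note.

Cluster enrichment for trait gene sets uses the one-sided hypergeometric
upper tail, with Benjamini-Hochberg adjusted p-values reported alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse, stats
from statsmodels.stats.multitest import multipletests

from .abundance import AbundanceMatrix

logger = logging.getLogger(__name__)


@dataclass
class CoabundanceNetwork:
    graph: nx.Graph  # nodes = KO ids; edge attr "r"
    threshold: float
    isolated: list[str] = field(default_factory=list)

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def edge_table(self) -> pd.DataFrame:
        rows = [(u, v, d["r"]) for u, v, d in self.graph.edges(data=True)]
        return pd.DataFrame(rows, columns=["gene_i", "gene_j", "r"])


@dataclass
class Clustering:
    assignment: pd.Series  # gene -> cluster id (1 = largest)
    inflation: float
    pre_inflation: float
    converged: bool

    def members(self, cluster_id: int) -> list[str]:
        return list(self.assignment.index[self.assignment == cluster_id])

    @property
    def sizes(self) -> pd.Series:
        return self.assignment.value_counts().sort_index()


def correlation_matrix(matrix: AbundanceMatrix, method: str = "pearson") -> pd.DataFrame:
    vals = matrix.values
    if (vals.std(axis=0) == 0).any():
        bad = vals.columns[vals.std(axis=0) == 0].tolist()
        raise ValueError(f"constant genes (undefined correlation): {bad[:5]}; filter first")
    if matrix.shape[0] < 3:
        raise ValueError("need at least 3 animals for correlations")
    if method == "pearson":
        R = np.corrcoef(vals.to_numpy(float), rowvar=False)
    elif method == "spearman":
        R = stats.spearmanr(vals.to_numpy(float)).statistic
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return pd.DataFrame(R, index=vals.columns, columns=vals.columns)


def covering_threshold(matrix: AbundanceMatrix, grid_step: float = 0.01,
                       corr: pd.DataFrame | None = None,
                       absolute: bool = False) -> float:
    """Largest grid threshold at which no gene is isolated.

    t* is the largest multiple of ``grid_step`` such that every gene has
    at least one partner with r >= t*; one step higher, at least one gene
    drops out.
    """
    R = (corr if corr is not None else correlation_matrix(matrix)).to_numpy(float).copy()
    if absolute:
        R = np.abs(R)
    np.fill_diagonal(R, -np.inf)
    best_partner = R.max(axis=1)
    min_best = best_partner.min()
    t_star = np.floor(min_best / grid_step + 1e-12) * grid_step
    return float(min(round(t_star, 10), 1.0))


def build_network(matrix: AbundanceMatrix, threshold: float,
                  corr: pd.DataFrame | None = None,
                  absolute: bool = False) -> CoabundanceNetwork:
    """Threshold the gene-gene correlation matrix into a weighted graph.

    Isolated genes stay in the node list but are flagged.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    Rdf = corr if corr is not None else correlation_matrix(matrix)
    genes = list(Rdf.columns)
    R = Rdf.to_numpy(float)
    if absolute:
        R = np.abs(R)
    iu = np.triu_indices(len(genes), k=1)
    mask = R[iu] >= threshold
    g = nx.Graph()
    g.add_nodes_from(genes)
    g.add_weighted_edges_from(
        ((genes[i], genes[j], float(r)) for i, j, r in
         zip(iu[0][mask], iu[1][mask], R[iu][mask])), weight="r")
    isolated = [n for n in genes if g.degree(n) == 0]
    if isolated:
        logger.info("build_network t=%.2f: %d isolated nodes", threshold, len(isolated))
    return CoabundanceNetwork(graph=g, threshold=threshold, isolated=isolated)


def _column_prune(M: sparse.csc_matrix, prune_threshold: float, top_k: int) -> sparse.csc_matrix:
    M = M.tocsc()
    for j in range(M.shape[1]):
        lo, hi = M.indptr[j], M.indptr[j + 1]
        data = M.data[lo:hi]
        if len(data) == 0:
            continue
        keep = data >= prune_threshold
        if keep.sum() > top_k:
            cutoff = np.partition(data, -top_k)[-top_k]
            keep = data >= cutoff
        if not keep.all() and keep.any():
            data[~keep] = 0.0
    M.eliminate_zeros()
    return M


def _normalize_columns(M: sparse.csc_matrix) -> sparse.csc_matrix:
    sums = np.asarray(M.sum(axis=0)).ravel()
    sums[sums == 0] = 1.0
    D = sparse.diags(1.0 / sums)
    return (M @ D).tocsc()


def mcl_cluster(network: CoabundanceNetwork, inflation: float = 2.0,
                pre_inflation: float = 2.0, max_iter: int = 200,
                prune_threshold: float = 1e-5, top_k: int = 100,
                tol: float = 1e-8) -> Clustering:
    """Markov clustering of a coabundance network.

    Edge weights are raised to ``pre_inflation``; self-loops get each
    node's maximum incident weight (isolated nodes weight 1, so they end
    as singletons); then the flow matrix iterates expansion (matrix
    square), inflation (element-wise power, column renormalization) and
    pruning until the change falls below ``tol``. Clusters are read from
    attractor rows; a node attracted by several attractors joins the one
    with the lowest index, and cluster ids are relabelled 1..K by
    decreasing size (ties: smallest member index first).
    """
    nodes = network.nodes
    n = len(nodes)
    if n == 0:
        raise ValueError("empty network")
    idx = {g: i for i, g in enumerate(nodes)}
    rows, cols, vals = [], [], []
    for u, v, d in network.graph.edges(data=True):
        w = float(d["r"]) ** pre_inflation
        rows += [idx[u], idx[v]]
        cols += [idx[v], idx[u]]
        vals += [w, w]
    A = sparse.csc_matrix((vals, (rows, cols)), shape=(n, n))
    max_incident = np.asarray(A.max(axis=0).todense()).ravel() if A.nnz else np.zeros(n)
    max_incident[max_incident == 0] = 1.0
    A = A + sparse.diags(max_incident)
    M = _normalize_columns(A.tocsc())
    converged = False
    for it in range(max_iter):
        M2 = (M @ M).tocsc()
        M2.data = M2.data**inflation
        M2 = _column_prune(M2, prune_threshold, top_k)
        M2 = _normalize_columns(M2)
        diff = abs(M2 - M).max() if (M2 - M).nnz else 0.0
        M = M2
        if diff < tol:
            converged = True
            break
    if not converged:
        logger.warning("MCL did not converge in %d iterations (diff=%.2e); "
                       "returning current interpretation", max_iter, diff)
    M = M.tocsr()
    diag = M.diagonal()
    attractors = np.flatnonzero(diag > prune_threshold)
    owner = np.full(n, -1, dtype=int)
    for a in attractors[::-1]:  # lowest-indexed attractor wins
        row = M.getrow(a)
        members = row.indices[row.data > prune_threshold]
        owner[members] = a
        owner[a] = a
    # unattracted nodes (pruned away entirely) become singletons
    for j in np.flatnonzero(owner < 0):
        owner[j] = j
    # canonical owner: nodes sharing an attractor whose attractor itself
    # points elsewhere collapse to the root
    for _ in range(n):
        nxt = owner[owner]
        if (nxt == owner).all():
            break
        owner = nxt
    groups: dict[int, list[int]] = {}
    for j, o in enumerate(owner):
        groups.setdefault(int(o), []).append(j)
    ordered = sorted(groups.values(), key=lambda m: (-len(m), m[0]))
    assignment = pd.Series(0, index=pd.Index(nodes, name="ko"), dtype=int)
    for cid, members in enumerate(ordered, start=1):
        assignment.iloc[members] = cid
    return Clustering(assignment=assignment, inflation=inflation,
                      pre_inflation=pre_inflation, converged=converged)


def carry_forward(clustering: Clustering, selected_genes: set[str]) -> list[str]:
    """Union of all clusters holding at least one PLS-selected gene."""
    present = selected_genes & set(clustering.assignment.index)
    missing = selected_genes - present
    if missing:
        logger.info("carry_forward: %d selected genes not in network, skipped",
                    len(missing))
    if not present:
        raise ValueError("no selected gene appears in any cluster")
    keep_clusters = set(clustering.assignment.loc[sorted(present)])
    mask = clustering.assignment.isin(keep_clusters)
    return list(clustering.assignment.index[mask])


def enrich(clustering: Clustering, gene_sets: dict[str, set[str]],
           universe: set[str], alpha: float = 0.05,
           min_cluster_size: int = 2) -> pd.DataFrame:
    """Hypergeometric over-representation of each gene set in each cluster.

    p = P(X >= k) with X ~ Hypergeom(N=len(universe), K=len(set), n=len
    (cluster)); one row per (cluster, set); BH-adjusted p reported
    alongside the raw p. Singleton clusters are excluded by default.
    """
    N = len(universe)
    rows = []
    sizes = clustering.sizes
    for cid, size in sizes.items():
        members = set(clustering.members(cid)) & universe
        if size < min_cluster_size:
            continue
        for name, genes in gene_sets.items():
            K = len(genes & universe)
            k = len(genes & members)
            n_c = len(members)
            p = float(stats.hypergeom.sf(k - 1, N, K, n_c)) if k > 0 else 1.0
            rows.append({"cluster": cid, "gene_set": name, "universe": N,
                         "cluster_size": n_c, "set_size": K, "overlap": k,
                         "p": min(p, 1.0)})
    table = pd.DataFrame(rows)
    if len(table):
        table["p_bh"] = multipletests(table["p"], method="fdr_bh")[1]
        table["significant"] = table["p"] < alpha
    return table


def overlap_sets(selections: dict[str, list[str]]) -> dict:
    """Pairwise and composite overlaps among per-trait gene selections.

    Composite sets follow the reporting convention: ``FCR&ADG`` and
    ``RFI&DFI`` are unions ("identified for either trait"), ``FCR+ADG``
    and ``RFI+DFI`` are intersections ("identified for both").
    """
    if len(selections) < 2:
        raise ValueError("need at least 2 selections")
    sets = {t: set(g) for t, g in selections.items()}
    traits = list(sets)
    pairwise = {}
    for i, a in enumerate(traits):
        for b in traits[i + 1:]:
            pairwise[f"{a}∩{b}"] = sorted(sets[a] & sets[b])
    composite = {}
    for a, b in (("FCR", "ADG"), ("RFI", "DFI")):
        if a in sets and b in sets:
            composite[f"{a}&{b}"] = sorted(sets[a] | sets[b])
            composite[f"{a}+{b}"] = sorted(sets[a] & sets[b])
    everyone = set.union(*sets.values())
    exclusive = {t: sorted(sets[t] - set.union(*(sets[u] for u in traits if u != t)))
                 for t in traits}
    return {"pairwise": pairwise, "composite": composite,
            "exclusive_counts": {t: len(v) for t, v in exclusive.items()},
            "exclusive": exclusive, "union_size": len(everyone)}


def trait_gene_sets(selections: dict[str, list[str]]) -> dict[str, set[str]]:
    """Gene sets used for cluster enrichment: the four per-trait sets plus
    the composite union and intersection sets."""
    sets = {t: set(g) for t, g in selections.items()}
    out = dict(sets)
    for a, b in (("FCR", "ADG"), ("RFI", "DFI")):
        if a in sets and b in sets:
            out[f"{a}&{b}"] = sets[a] | sets[b]
    if "FCR" in sets and "ADG" in sets:
        out["FCR+ADG"] = sets["FCR"] & sets["ADG"]
    return out


def write_graphml(network: CoabundanceNetwork, clustering: Clustering | None, path) -> None:
    g = network.graph.copy()
    if clustering is not None:
        nx.set_node_attributes(
            g, {n: int(clustering.assignment.get(n, -1)) for n in g.nodes}, "cluster")
    nx.write_graphml(g, path)
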