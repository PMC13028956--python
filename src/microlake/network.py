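"""Co-occurrence networks over the most abundant taxa, modularity, and robustness.

Edges are Spearman correlations between taxa across samples, kept when
|rho| >= rho_min and the BH-adjusted p <= p_max. Robustness is the mean
proportion of nodes surviving random removal of a fixed fraction followed by
a cascade that deletes nodes left without any neighbour (secondary
extinction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .diversity import anova_tukey, bh_adjust, GroupTestResult, _proportions

__all__ = [
    "CoNetwork",
    "RobustnessResult",
    "build_network",
    "modularity",
    "robustness",
    "compare_robustness",
    "class_subnetwork",
    "write_edge_list",
]


@dataclass
class CoNetwork:
    graph: nx.Graph = field(repr=False)
    n_positive: int
    n_negative: int
    top_taxa: list

    @property
    def positive_fraction(self) -> float:
        m = self.n_positive + self.n_negative
        return self.n_positive / m if m else np.nan


def build_network(
    relabund,
    top_n: int = 100,
    rho_min: float = 0.6,
    p_max: float = 0.05,
    node_tags: pd.DataFrame | None = None,
) -> CoNetwork:
    """Correlation network over the ``top_n`` most abundant taxa.

    Spearman correlations are computed across samples for every taxon pair;
    an edge is kept when ``|rho| >= rho_min`` and the BH-adjusted p-value is
    at most ``p_max``. Isolated nodes are dropped. ``node_tags`` (indexed by
    taxon) attaches attributes, e.g. kingdom and abundance class.
    """
    P = _proportions(relabund)
    if P.shape[1] < 3:
        raise ValueError("need at least 3 samples for correlations")
    if top_n < 3:
        raise ValueError("top_n must be >= 3")
    top = P.mean(axis=1).sort_values(ascending=False).index[: min(top_n, P.shape[0])]
    X = P.loc[top].to_numpy(dtype=float)
    k = len(top)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho_mat, p_mat = stats.spearmanr(X, axis=1)
    if np.isscalar(rho_mat):  # two taxa only
        rho_mat = np.array([[1.0, rho_mat], [rho_mat, 1.0]])
        p_mat = np.array([[0.0, p_mat], [p_mat, 0.0]])
    iu = np.triu_indices(k, 1)
    pvals = p_mat[iu]
    rhos = rho_mat[iu]
    # constant taxa give NaN correlations; treat as no edge
    qvals = bh_adjust(np.where(np.isfinite(pvals), pvals, np.nan))
    keep = np.isfinite(rhos) & (np.abs(rhos) >= rho_min) & (qvals <= p_max)
    G = nx.Graph()
    n_pos = n_neg = 0
    for idx in np.flatnonzero(keep):
        i, j = iu[0][idx], iu[1][idx]
        r = float(rhos[idx])
        G.add_edge(
            str(top[i]), str(top[j]),
            rho=r, p=float(pvals[idx]), q=float(qvals[idx]),
            sign=1 if r > 0 else -1,
        )
        if r > 0:
            n_pos += 1
        else:
            n_neg += 1
    if node_tags is not None:
        for node in G.nodes:
            if node in node_tags.index:
                for col in node_tags.columns:
                    G.nodes[node][col] = node_tags.loc[node, col]
    return CoNetwork(graph=G, n_positive=n_pos, n_negative=n_neg, top_taxa=list(top))


def modularity(network: CoNetwork | nx.Graph):
    """Greedy (CNM) modularity maximization on the unweighted graph.

    Returns ``(Q, partition)`` where partition is a list of frozensets of
    node ids. Deterministic for a given graph.
    """
    G = network.graph if isinstance(network, CoNetwork) else network
    if G.number_of_edges() == 0:
        raise ValueError("modularity undefined for an edgeless graph")
    communities = nx.community.greedy_modularity_communities(G, weight=None)
    q = nx.community.modularity(G, communities, weight=None)
    return float(q), [frozenset(c) for c in communities]


@dataclass
class RobustnessResult:
    removal_fraction: float
    n_iterations: int
    mean: float
    se: float
    values: np.ndarray = field(repr=False)


def _surviving_fraction(G: nx.Graph, removed: set, n_total: int) -> float:
    keep = [v for v in G.nodes if v not in removed]
    H = G.subgraph(keep)
    survivors = sum(1 for v in H.nodes if H.degree(v) > 0)
    return survivors / n_total


def robustness(
    network: CoNetwork | nx.Graph,
    removal_fraction: float = 0.5,
    n_iter: int = 500,
    seed: int = 0,
) -> RobustnessResult:
    """Random-removal robustness of a network.

    Each iteration removes ``floor(f * n)`` uniformly chosen nodes, then any
    node left with no remaining neighbour is also lost (one isolation
    cascade); the retained proportion is survivors / original node count.
    """
    G = network.graph if isinstance(network, CoNetwork) else network
    n = G.number_of_nodes()
    if n < 4:
        raise ValueError("network needs >= 4 nodes")
    if not 0 < removal_fraction < 1:
        raise ValueError("removal_fraction must be in (0, 1)")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    nodes = np.array(list(G.nodes))
    n_remove = int(np.floor(removal_fraction * n))
    vals = np.empty(n_iter)
    for it in range(n_iter):
        removed = set(rng.choice(nodes, size=n_remove, replace=False))
        vals[it] = _surviving_fraction(G, removed, n)
    return RobustnessResult(
        removal_fraction=removal_fraction,
        n_iterations=n_iter,
        mean=float(vals.mean()),
        se=float(vals.std(ddof=1) / np.sqrt(n_iter)) if n_iter > 1 else 0.0,
        values=vals,
    )


def class_subnetwork(network: CoNetwork | nx.Graph, taxa) -> nx.Graph:
    """Induced subgraph on a taxon subset (e.g. one abundance class)."""
    G = network.graph if isinstance(network, CoNetwork) else network
    return G.subgraph([t for t in taxa if t in G]).copy()


def compare_robustness(
    networks: dict,
    removal_fraction: float = 0.5,
    n_iter: int = 500,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroupTestResult | None]:
    """Robustness of several networks with an ANOVA + Tukey-letter comparison.

    ``networks`` maps a name (region or abundance class) to a graph; graphs
    with fewer than 4 nodes are skipped with a warning. Returns the
    per-iteration long table and the group test (None if < 2 usable groups).
    """
    rows = []
    for k, (name, net) in enumerate(networks.items()):
        G = net.graph if isinstance(net, CoNetwork) else net
        if G.number_of_nodes() < 4:
            warnings.warn(f"network {name!r} has < 4 nodes; skipped")
            continue
        res = robustness(G, removal_fraction, n_iter, seed=seed + 7919 * k)
        for it, v in enumerate(res.values):
            rows.append({"network": name, "iteration": it, "robustness": v})
    df = pd.DataFrame(rows)
    if df.empty or df["network"].nunique() < 2:
        return df, None
    test = anova_tukey(df["robustness"], df["network"])
    return df, test


def write_edge_list(network: CoNetwork, path) -> None:
    rows = [
        {"source": u, "target": v, "rho": d["rho"], "p": d["p"], "sign": d["sign"]}
        for u, v, d in network.graph.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["source", "target", "rho", "p", "sign"]).to_csv(
        path, sep="\t", index=False
    )
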