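"""Heat-diffusion subnetwork discovery on protein-interaction networks.

Per-gene mutation scores ("heat") are diffused over an undirected
interaction graph with an insulated random-walk-with-restart; directed
exchanged-heat edges above a threshold delta are kept and strongly
connected components of size >= 2 are reported as candidate subnetworks.
Significance comes from degree-preserving network permutations with the
empirical p floored at 1/n_perm.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np

log = logging.getLogger(__name__)

#: exchanged-heat threshold printed by the reference analysis run
DEFAULT_DELTA = 0.00126036397514
#: restart probability of the insulated diffusion
DEFAULT_BETA = 0.4
#: MAF cutoff applied to variants feeding subnetwork heat (stricter than
#: the 0.03 used by the trio inheritance model)
NETWORK_MAF_MAX = 0.02


@dataclass
class Subnetwork:
    members: tuple
    size: int
    delta: float
    p_value: float | None = None

    def __post_init__(self):
        assert self.size == len(self.members) >= 2


def diffusion_matrix(graph: nx.Graph, beta: float = DEFAULT_BETA):
    """Insulated-diffusion matrix F = beta (I - (1-beta) W)^{-1}.

    ``W`` is the column-normalized adjacency, handled per connected
    component; every column of F sums to 1 (heat conservation).  Isolated
    nodes retain all their heat (identity column).  Returns ``(F, nodes)``
    with ``nodes`` fixing the row/column order.
    """
    if not 0 < beta < 1:
        raise ValueError("restart probability beta must lie in (0, 1)")
    nodes = list(graph.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    F = np.zeros((len(nodes), len(nodes)))
    for comp in nx.connected_components(graph):
        comp = sorted(comp, key=lambda v: index[v])
        idx = np.array([index[v] for v in comp])
        if len(comp) == 1:
            F[idx[0], idx[0]] = 1.0
            continue
        A = nx.to_numpy_array(graph, nodelist=comp)
        W = A / A.sum(axis=0, keepdims=True)
        Fc = beta * np.linalg.inv(np.eye(len(comp)) - (1 - beta) * W)
        F[np.ix_(idx, idx)] = Fc
    return F, nodes


def exchanged_heat(F: np.ndarray, heat) -> np.ndarray:
    """E = F diag(h): column j carries the heat node j sends to each row."""
    heat = np.asarray(heat, dtype=float)
    if np.any(heat < 0) or not np.all(np.isfinite(heat)):
        raise ValueError("heat must be finite and non-negative")
    return F * heat[None, :]


def extract_subnetworks(F: np.ndarray, heat, delta: float, nodes) -> list[Subnetwork]:
    """Strongly connected components of the delta-thresholded heat graph.

    A directed edge j -> i is kept when the exchanged heat E_ij exceeds
    ``delta``; components of size >= 2 are returned sorted by decreasing
    size then lexicographically.
    """
    heat = np.asarray(heat, dtype=float)
    if F.shape[0] != F.shape[1] or F.shape[0] != heat.size or len(nodes) != heat.size:
        raise ValueError("dimension mismatch between F, heat and nodes")
    if not np.any(heat > 0):
        return []
    E = exchanged_heat(F, heat)
    np.fill_diagonal(E, 0.0)
    srcs, dsts = np.nonzero(E.T > delta)  # edge source j -> target i
    D = nx.DiGraph()
    D.add_nodes_from(range(len(nodes)))
    D.add_edges_from(zip(srcs, dsts))
    subs = []
    for comp in nx.strongly_connected_components(D):
        if len(comp) >= 2:
            members = tuple(sorted(nodes[i] for i in comp))
            subs.append(Subnetwork(members=members, size=len(members), delta=delta))
    subs.sort(key=lambda s: (-s.size, s.members))
    return subs


def heat_from_events(events, cnv_genes=None, cnv_increment: float = 1.0) -> dict:
    """Per-gene heat: distinct probands with a qualifying SNV event, plus a
    configurable increment per CNV-hit gene."""
    heat: dict = {}
    if len(events):
        for gene, grp in events.groupby("gene"):
            heat[gene] = float(grp["individual"].nunique())
    for g in cnv_genes or ():
        heat[g] = heat.get(g, 0.0) + cnv_increment
    return heat


def heat_vector(heat: dict, nodes) -> np.ndarray:
    """Align a gene->heat mapping to a node ordering; off-network genes are
    dropped with a logged count."""
    off = set(heat) - set(nodes)
    if off:
        log.info("dropping %d heat genes absent from the network", len(off))
    return np.array([float(heat.get(v, 0.0)) for v in nodes])


def permute_network(graph: nx.Graph, n_swaps: int | None = None, seed: int = 0) -> nx.Graph:
    """Degree-preserving double-edge-swap permutation of a simple graph.

    Default ``n_swaps`` is 10x the edge count; swaps creating self-loops or
    multi-edges are rejected and retried (bounded).  Deterministic per seed.
    """
    g = graph.copy()
    m = g.number_of_edges()
    if m < 2:
        return g
    if n_swaps is None:
        n_swaps = 10 * m
    try:
        nx.double_edge_swap(g, nswap=n_swaps, max_tries=100 * n_swaps, seed=int(seed))
    except nx.NetworkXAlgorithmError:
        # graphs with few valid swaps (e.g. stars) exhaust the retry budget;
        # the partial result still preserves the degree sequence exactly
        log.info("edge-swap retry budget exhausted; returning partial permutation")
    return g


def subnetwork_significance(
    observed: list[Subnetwork],
    permuted: list[list[Subnetwork]],
    sizes=range(2, 11),
) -> dict:
    """Empirical p per subnetwork size s, floored at 1/n_perm, capped at 1.

    p(s) = max(1, #{permutations with at least the observed count of
    subnetworks of size >= s}) / n_perm.
    """
    n_perm = len(permuted)
    if n_perm < 1:
        raise ValueError("need at least one permutation")

    def count_ge(subs, s):
        return sum(1 for sub in subs if sub.size >= s)

    pvals = {}
    for s in sizes:
        obs = count_ge(observed, s)
        exceed = sum(1 for perm in permuted if count_ge(perm, s) >= obs)
        pvals[s] = min(1.0, max(1, exceed) / n_perm)
    return pvals


def _max_component_size(F, heat, delta, nodes):
    subs = extract_subnetworks(F, heat, delta, nodes)
    return subs[0].size if subs else 0


def select_delta(
    permuted_graphs: list[nx.Graph],
    heat: dict,
    beta: float = DEFAULT_BETA,
    size_targets=(5, 10, 15, 20),
) -> dict:
    """Candidate delta per target size from the permutation null.

    For each target L, the candidate is the median over permutations of the
    smallest exchanged-heat threshold at which the permuted network yields
    no subnetwork larger than L.
    """
    deltas: dict = {t: [] for t in size_targets}
    for g in permuted_graphs:
        F, nodes = diffusion_matrix(g, beta)
        h = heat_vector(heat, nodes)
        E = exchanged_heat(F, h)
        np.fill_diagonal(E, 0.0)
        weights = np.unique(E[E > 0])
        for target in size_targets:
            if _max_component_size(F, h, 0.0, nodes) <= target:
                deltas[target].append(0.0)
                continue
            # binary search the sorted edge weights for the smallest
            # threshold meeting the target (monotone in delta)
            lo, hi = 0, weights.size - 1
            best = weights[-1]
            while lo <= hi:
                mid = (lo + hi) // 2
                if _max_component_size(F, h, weights[mid], nodes) <= target:
                    best = weights[mid]
                    hi = mid - 1
                else:
                    lo = mid + 1
            deltas[target].append(float(best))
    out = {}
    for target, vals in deltas.items():
        if not vals:
            warnings.warn(f"no permutations available for target {target}", stacklevel=2)
            out[target] = None
        else:
            out[target] = float(np.median(vals))
    return out
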