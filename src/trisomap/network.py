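"""Seed-based PPI network construction, hub decomposition and null models.

Starting from a confidence-scored interaction edge table (STRING-style), the
module builds the minimum fully connected network around a set of functional
"seed" genes (MinPPINet): the subgraph induced on the seeds, made connected
by greedily inserting the globally shortest inter-component paths, whose
interior nodes become "connectors". The network can be overlaid with directed
regulatory edge classes (activation / inhibition / expression / repression /
complex / predicted), decomposed around betweenness-centrality hubs and their
second-level interactors, and tested against a degree-preserving null
obtained by double-edge-swap randomisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

SEED = "seed"
CONNECTOR = "connector"

REGULATORY_PRECEDENCE = ["activation", "inhibition", "expression", "repression", "complex"]
PREDICTED = "predicted"


# -------------------------------------------------------------------- edges


def load_edges(path: str | Path, min_confidence: float = 0.4) -> pd.DataFrame:
    """Read and filter a (node_a, node_b, score) edge table.

    Scores on a 0-1000 scale (STRING convention) are auto-detected and
    rescaled to [0, 1]. The threshold is inclusive. Duplicate edges collapse
    to their maximum confidence; self-loops are dropped.
    """
    table = pd.read_csv(path, sep="\t")
    if table.shape[1] < 3:
        raise ValueError("edge table needs two id columns and a score column")
    table = table.iloc[:, :3].copy()
    table.columns = ["node_a", "node_b", "confidence"]
    scores = pd.to_numeric(table["confidence"], errors="coerce")
    if scores.isna().any():
        bad = int(table.index[scores.isna()][0]) + 2  # +header +0-base
        raise ValueError(f"malformed score at line {bad}")
    if (scores < 0).any():
        raise ValueError("negative confidence scores")
    if scores.max() > 1.0:
        scores = scores / 1000.0
    if scores.max() > 1.0:
        raise ValueError("scores exceed 1 even after 0-1000 rescaling")
    table["confidence"] = scores
    table = table[table["node_a"] != table["node_b"]]
    table = table[table["confidence"] >= min_confidence]
    if table.empty:
        raise ValueError("no edges left after confidence filtering")
    key = table.apply(lambda r: tuple(sorted((str(r["node_a"]), str(r["node_b"])))), axis=1)
    table = table.assign(_key=key).sort_values("confidence").drop_duplicates("_key", keep="last")
    table[["node_a", "node_b"]] = pd.DataFrame(table["_key"].tolist(), index=table.index)
    return table.drop(columns="_key").sort_values(["node_a", "node_b"]).reset_index(drop=True)


def edges_to_graph(edges: pd.DataFrame) -> nx.Graph:
    G = nx.Graph()
    for _, r in edges.iterrows():
        G.add_edge(r["node_a"], r["node_b"], confidence=float(r["confidence"]))
    return G


# ---------------------------------------------------------------- MinPPINet


@dataclass
class PPINetwork:
    """Seed/connector network: nodes carry ``role`` and optional category
    flags (syntenic, gage_contributor, deg); edges carry confidence and,
    after regulatory annotation, an interaction class."""

    graph: nx.Graph
    seeds: list[str]
    connectors: list[str] = field(default_factory=list)
    missing_seeds: list[str] = field(default_factory=list)

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)


def _best_joining_path(
    G: nx.Graph, comp_a: set[str], comp_b: set[str]
) -> tuple[int, float, tuple[str, ...]] | None:
    """Minimal path between two components in the full graph, ranked by
    (length, summed 1-confidence, lexicographic node sequence)."""
    best: tuple[int, float, tuple[str, ...]] | None = None
    for u in sorted(comp_a):
        lengths = nx.single_source_shortest_path_length(G, u)
        reachable = [v for v in comp_b if v in lengths]
        if not reachable:
            continue
        dmin = min(lengths[v] for v in reachable)
        for v in sorted(x for x in reachable if lengths[x] == dmin):
            for path in nx.all_shortest_paths(G, u, v):
                cost = sum(
                    1.0 - G.edges[a, b].get("confidence", 1.0)
                    for a, b in zip(path, path[1:])
                )
                cand = (len(path) - 1, cost, tuple(path))
                if best is None or cand < best:
                    best = cand
    return best


def _prune_redundant_connectors(
    G: nx.Graph, kept: set[str], seed_set: set[str]
) -> set[str]:
    """Drop connectors whose removal keeps every seed in one component.

    The greedy merge can leave a connector redundant once later paths open
    alternative routes; pruning makes each remaining connector essential
    (its deletion disconnects the network or strands a seed).
    """
    changed = True
    while changed:
        changed = False
        for c in sorted(kept - seed_set):
            sub = G.subgraph(kept - {c})
            comps = list(nx.connected_components(sub))
            holder = next((comp for comp in comps if seed_set <= comp), None)
            if holder is not None:
                kept = set(holder)  # also sheds connectors stranded by the cut
                changed = True
                break
    return kept


def build_minppinet(
    edges: pd.DataFrame | nx.Graph, seeds: Iterable[str]
) -> PPINetwork:
    """Minimum fully connected network around the seed set.

    Greedy Steiner-style heuristic: start from the subgraph induced on the
    seeds; while more than one component remains, insert the globally
    shortest path (in the full filtered graph) joining two components, with
    deterministic tie-breaks by (length, summed 1-confidence, lexicographic
    node ids). Interior path nodes become connectors. Seeds absent from the
    edge universe or unreachable in the full graph are reported in
    ``missing_seeds`` rather than silently dropped.
    """
    G = edges if isinstance(edges, nx.Graph) else edges_to_graph(edges)
    seeds = sorted(set(seeds))
    present = [s for s in seeds if s in G]
    missing = [s for s in seeds if s not in G]
    if not present:
        raise ValueError("no seed is present in the edge universe")

    kept: set[str] = set(present)
    connectors: list[str] = []
    while True:
        sub = G.subgraph(kept)
        comps = sorted(nx.connected_components(sub), key=lambda c: sorted(c)[0])
        if len(comps) <= 1:
            break
        best = None
        best_pair = None
        for i in range(len(comps)):
            for j in range(i + 1, len(comps)):
                cand = _best_joining_path(G, set(comps[i]), set(comps[j]))
                if cand is not None and (best is None or cand < best):
                    best = cand
                    best_pair = (i, j)
        if best is None:
            # remaining components are mutually unreachable in the full graph:
            # keep the one holding the lexicographically first seed, report the rest
            keep_comp = comps[0]
            stranded = sorted(set().union(*comps[1:]) & set(present))
            missing.extend(stranded)
            kept = set(keep_comp)
            connectors = [c for c in connectors if c in kept]
            break
        interior = [n for n in best[2][1:-1]]
        for n in interior:
            if n not in kept:
                connectors.append(n)
        kept.update(best[2])

    seed_set = set(present) - set(missing)
    kept = _prune_redundant_connectors(G, kept, seed_set)
    connectors = [c for c in connectors if c in kept]

    out = G.subgraph(kept).copy()
    for n in out.nodes:
        out.nodes[n]["role"] = SEED if n in seed_set else CONNECTOR
    return PPINetwork(
        graph=out,
        seeds=sorted(seed_set),
        connectors=sorted(set(out.nodes) - seed_set),
        missing_seeds=sorted(missing),
    )


def set_node_flags(
    net: PPINetwork,
    syntenic: Iterable[str] = (),
    gage_contributors: Iterable[str] = (),
    degs: Iterable[str] = (),
) -> None:
    """Attach the node category flags used for network reporting."""
    syn, gage, deg = set(syntenic), set(gage_contributors), set(degs)
    for n in net.graph.nodes:
        net.graph.nodes[n]["syntenic"] = n in syn
        net.graph.nodes[n]["gage_contributor"] = n in gage
        net.graph.nodes[n]["deg"] = n in deg


# --------------------------------------------------------------- regulation


def annotate_regulatory(
    net: PPINetwork, reg_table: pd.DataFrame | None
) -> tuple[PPINetwork, list[tuple[str, str, list[str]]]]:
    """Overlay regulatory edge classes onto the network.

    ``reg_table`` has columns (source, target, interaction_class). Every
    network edge gets exactly one class: the highest-precedence annotation
    covering it (activation > inhibition > expression > repression > complex),
    or 'predicted' when unannotated. Returns the network and the list of
    conflicting annotations (edge, classes seen).
    """
    ann: dict[tuple[str, str], list[str]] = {}
    skipped = 0
    if reg_table is not None and len(reg_table):
        for _, r in reg_table.iterrows():
            u, v, cls = str(r.iloc[0]), str(r.iloc[1]), str(r.iloc[2])
            if u not in net.graph or v not in net.graph or not net.graph.has_edge(u, v):
                skipped += 1
                continue
            ann.setdefault(tuple(sorted((u, v))), []).append(cls)
    conflicts = []
    for u, v in net.graph.edges:
        classes = ann.get(tuple(sorted((u, v))), [])
        ranked = [c for c in REGULATORY_PRECEDENCE if c in classes]
        if len(set(classes)) > 1:
            conflicts.append((u, v, sorted(set(classes))))
        net.graph.edges[u, v]["interaction_class"] = ranked[0] if ranked else PREDICTED
    net.graph.graph["regulatory_skipped"] = skipped
    return net, conflicts


# --------------------------------------------------------------------- hubs


def hub_subnetwork(net: PPINetwork, hub: str, depth: int = 2) -> nx.Graph:
    """Subgraph induced on the hub, its neighbours and their neighbours."""
    if hub not in net.graph:
        raise ValueError(f"hub {hub!r} not in network")
    closure = {hub}
    frontier = {hub}
    for _ in range(depth):
        frontier = set().union(*(set(net.graph.neighbors(n)) for n in frontier)) - closure
        closure |= frontier
    return net.graph.subgraph(closure).copy()


def hub_control_metrics(net: PPINetwork, hub: str, depth: int = 2) -> tuple[float, float]:
    """Percentage of network nodes / seeds reachable within ``depth`` steps of
    the hub (the hub itself excluded from numerator and denominators)."""
    sub = hub_subnetwork(net, hub, depth)
    closure = set(sub.nodes) - {hub}
    other_nodes = set(net.graph.nodes) - {hub}
    other_seeds = set(net.seeds) - {hub}
    pct_nodes = 100.0 * len(closure) / len(other_nodes) if other_nodes else 0.0
    pct_seeds = 100.0 * len(closure & other_seeds) / len(other_seeds) if other_seeds else 0.0
    return pct_nodes, pct_seeds


def betweenness_hubs(net: PPINetwork, top_k: int | None = None) -> pd.DataFrame:
    """Rank nodes by exact normalised shortest-path betweenness.

    Includes level-1/level-2 interactor counts and 2-step control
    percentages over nodes and seeds. Deterministic: ties break by node id.
    """
    G = net.graph
    if G.number_of_nodes() < 3:
        raise ValueError("need at least 3 nodes")
    if not nx.is_connected(G):
        raise ValueError("network is disconnected; build it with build_minppinet")
    bc = nx.betweenness_centrality(G, normalized=True)
    rows = []
    for node in sorted(G.nodes):
        level1 = set(G.neighbors(node))
        level2 = set().union(*(set(G.neighbors(n)) for n in level1), level1) - {node}
        pct_nodes, pct_seeds = hub_control_metrics(net, node)
        rows.append(
            {
                "node": node,
                "betweenness": bc[node],
                "role": G.nodes[node].get("role", ""),
                "n_level1": len(level1),
                "n_level2": len(level2),
                "pct_nodes_controlled": pct_nodes,
                "pct_seeds_controlled": pct_seeds,
            }
        )
    table = (
        pd.DataFrame(rows)
        .sort_values(["betweenness", "node"], ascending=[False, True], kind="mergesort")
        .reset_index(drop=True)
    )
    return table.head(top_k) if top_k else table


def connector_relevance(net: PPINetwork) -> pd.Series:
    """Transparent relevance score for connector proteins.

    A deliberately simple stand-in for learned connector-relevance
    predictors: the product of each connector's betweenness percentile and
    degree percentile within the network, in [0, 1]. High scores mark
    connectors that both bridge and concentrate interactions.
    """
    G = net.graph
    if not net.connectors:
        return pd.Series(dtype=float)
    bc = pd.Series(nx.betweenness_centrality(G, normalized=True))
    deg = pd.Series(dict(G.degree()), dtype=float)
    bc_pct = bc.rank(pct=True)
    deg_pct = deg.rank(pct=True)
    score = (bc_pct * deg_pct).loc[net.connectors]
    return score.sort_values(ascending=False)


# --------------------------------------------------------------- null model


@dataclass
class NullModelResult:
    metric: str
    observed: float
    null_mean: float
    null_sd: float
    empirical_p: float
    n_replicates: int
    seed: int


def _edge_array(G: nx.Graph) -> tuple[np.ndarray, dict[str, int]]:
    index = {n: i for i, n in enumerate(sorted(G.nodes))}
    edges = np.array(
        [(index[u], index[v]) for u, v in sorted(tuple(sorted(e)) for e in G.edges)],
        dtype=np.int64,
    )
    return edges, index


def _get_swap_kernels():
    """Compile (once) the numba kernels for degree-preserving edge swaps."""
    from numba import njit

    @njit(cache=False)
    def swap_edges(edges, adj, n_swaps, max_attempts):
        E = edges.shape[0]
        accepted = 0
        attempts = 0
        while accepted < n_swaps and attempts < max_attempts:
            attempts += 1
            i = np.random.randint(E)
            j = np.random.randint(E)
            if i == j:
                continue
            a, b = edges[i, 0], edges[i, 1]
            c, d = edges[j, 0], edges[j, 1]
            if np.random.randint(2) == 1:
                c, d = d, c
            if a == c or b == d:
                continue
            if adj[a, c] or adj[b, d]:
                continue
            adj[a, b] = False
            adj[b, a] = False
            adj[c, d] = False
            adj[d, c] = False
            adj[a, c] = True
            adj[c, a] = True
            adj[b, d] = True
            adj[d, b] = True
            edges[i, 0], edges[i, 1] = a, c
            edges[j, 0], edges[j, 1] = b, d
            accepted += 1
        return accepted

    @njit(cache=False)
    def null_seed_internal(edges0, n_nodes, seed_mask, n_swaps, n_reps, rng_seed):
        np.random.seed(rng_seed)
        E = edges0.shape[0]
        adj0 = np.zeros((n_nodes, n_nodes), np.bool_)
        for i in range(E):
            adj0[edges0[i, 0], edges0[i, 1]] = True
            adj0[edges0[i, 1], edges0[i, 0]] = True
        out = np.empty(n_reps, np.int64)
        ok = np.empty(n_reps, np.bool_)
        for rep in range(n_reps):
            edges = edges0.copy()
            adj = adj0.copy()
            accepted = swap_edges(edges, adj, n_swaps, n_swaps * 200)
            ok[rep] = accepted == n_swaps
            cnt = 0
            for i in range(E):
                if seed_mask[edges[i, 0]] and seed_mask[edges[i, 1]]:
                    cnt += 1
            out[rep] = cnt
        return out, ok

    @njit(cache=False)
    def one_replicate(edges0, n_nodes, n_swaps, rng_seed):
        np.random.seed(rng_seed)
        E = edges0.shape[0]
        adj = np.zeros((n_nodes, n_nodes), np.bool_)
        for i in range(E):
            adj[edges0[i, 0], edges0[i, 1]] = True
            adj[edges0[i, 1], edges0[i, 0]] = True
        edges = edges0.copy()
        accepted = swap_edges(edges, adj, n_swaps, n_swaps * 200)
        return edges, accepted

    return null_seed_internal, one_replicate


_KERNELS = None


def _kernels():
    global _KERNELS
    if _KERNELS is None:
        _KERNELS = _get_swap_kernels()
    return _KERNELS


def randomized_copy(
    G: nx.Graph, seed: int, swaps_per_edge: int = 10, strict: bool = True
) -> nx.Graph:
    """One degree-preserving randomisation of ``G`` (double edge swaps)."""
    edges, index = _edge_array(G)
    names = {i: n for n, i in index.items()}
    _, one_replicate = _kernels()
    n_swaps = swaps_per_edge * edges.shape[0]
    new_edges, accepted = one_replicate(edges, len(index), n_swaps, seed % (2**31))
    if strict and accepted < n_swaps:
        raise ValueError("graph too small or rigid: could not reach the swap target")
    H = nx.Graph()
    H.add_nodes_from(G.nodes)
    H.add_edges_from((names[int(u)], names[int(v)]) for u, v in new_edges)
    return H


def _metric_value(G: nx.Graph, metric: str, seeds: Sequence[str]) -> float:
    if metric == "seed_internal_edges":
        sset = set(seeds)
        return float(sum(1 for u, v in G.edges if u in sset and v in sset))
    if metric == "global_clustering":
        return float(nx.transitivity(G))
    if metric == "mean_seed_distance":
        present = [s for s in seeds if s in G]
        dists = []
        for i, u in enumerate(present):
            lengths = nx.single_source_shortest_path_length(G, u)
            dists.extend(lengths[v] for v in present[i + 1 :] if v in lengths)
        return float(np.mean(dists)) if dists else float("nan")
    raise ValueError(f"unknown metric {metric!r}")


def degree_preserving_null(
    net: PPINetwork | nx.Graph,
    metric: str = "seed_internal_edges",
    n_replicates: int = 100_000,
    seed: int = 0,
    swaps_per_edge: int = 10,
    alternative: str = "greater",
) -> NullModelResult:
    """Empirical significance of a connectivity metric under the
    degree-preserving null.

    Each replicate restarts from the observed graph and applies
    ``swaps_per_edge * |E|`` accepted double edge swaps, preserving the exact
    degree sequence. The empirical p uses the (1 + #{null >= observed}) /
    (n + 1) correction so it is never zero.
    """
    if isinstance(net, PPINetwork):
        G, seeds = net.graph, net.seeds
    else:
        G, seeds = net, []
    edges, index = _edge_array(G)
    n_swaps = swaps_per_edge * edges.shape[0]
    observed = _metric_value(G, metric, seeds)

    if metric == "seed_internal_edges":
        mask = np.zeros(len(index), np.bool_)
        for s in seeds:
            if s in index:
                mask[index[s]] = True
        null_seed_internal, _ = _kernels()
        values, ok = null_seed_internal(
            edges, len(index), mask, n_swaps, n_replicates, seed % (2**31)
        )
        if not ok.all():
            raise ValueError("graph too small or rigid: could not reach the swap target")
        values = values.astype(float)
    else:
        rng = np.random.default_rng(seed)
        values = np.empty(n_replicates)
        for rep in range(n_replicates):
            H = randomized_copy(G, int(rng.integers(2**31)), swaps_per_edge)
            values[rep] = _metric_value(H, metric, seeds)

    if alternative == "greater":
        extreme = int((values >= observed).sum())
    elif alternative == "less":
        extreme = int((values <= observed).sum())
    else:
        raise ValueError("alternative must be 'greater' or 'less'")
    return NullModelResult(
        metric=metric,
        observed=float(observed),
        null_mean=float(values.mean()),
        null_sd=float(values.std(ddof=1)) if n_replicates > 1 else 0.0,
        empirical_p=(1 + extreme) / (n_replicates + 1),
        n_replicates=n_replicates,
        seed=seed,
    )


# --------------------------------------------------------------- topology


@dataclass
class TopologyDiagnostics:
    small_world_sigma: float
    clustering: float
    path_length: float
    null_clustering: float
    null_path_length: float
    powerlaw_alpha: float
    powerlaw_kmin: int
    powerlaw_ks: float
    dense_graph: bool


def fit_powerlaw_tail(degrees: Sequence[int]) -> tuple[float, int, float]:
    """Discrete maximum-likelihood power-law fit of a degree tail.

    Scans candidate k_min values, fits alpha = 1 + n / sum(ln(k/(kmin-1/2)))
    on the tail, and keeps the k_min minimising the KS distance between the
    empirical tail and the fitted Zipf survival (Clauset-style).
    """
    ks_best, alpha_best, kmin_best = np.inf, np.nan, 0
    degs = np.asarray([d for d in degrees if d > 0], dtype=float)
    for kmin in sorted(set(int(d) for d in degs)):
        tail = degs[degs >= kmin]
        if len(tail) < 10:
            continue
        alpha = 1.0 + len(tail) / np.log(tail / (kmin - 0.5)).sum()
        if not np.isfinite(alpha) or alpha <= 1.0:
            continue
        xs = np.sort(tail)
        emp_sf = 1.0 - np.arange(1, len(xs) + 1) / len(xs)
        # continuous-approximation survival for the fitted tail
        model_sf = (xs / (kmin - 0.5)) ** (1.0 - alpha)
        ks = float(np.max(np.abs(emp_sf - model_sf)))
        if ks < ks_best:
            ks_best, alpha_best, kmin_best = ks, float(alpha), int(kmin)
    return alpha_best, kmin_best, ks_best


def topology_diagnostics(
    net: PPINetwork | nx.Graph, n_null: int = 20, seed: int = 0
) -> TopologyDiagnostics:
    """Small-world sigma against the degree-preserving null plus a
    power-law fit of the degree tail."""
    G = net.graph if isinstance(net, PPINetwork) else net
    if G.number_of_nodes() < 20:
        raise ValueError("need at least 20 nodes")
    if not nx.is_connected(G):
        raise ValueError("network must be connected")
    C = nx.average_clustering(G)
    L = nx.average_shortest_path_length(G)
    rng = np.random.default_rng(seed)
    cs, ls = [], []
    for _ in range(n_null):
        H = randomized_copy(G, int(rng.integers(2**31)), strict=False)
        cs.append(nx.average_clustering(H))
        if nx.is_connected(H):
            ls.append(nx.average_shortest_path_length(H))
        else:
            giant = max(nx.connected_components(H), key=len)
            ls.append(nx.average_shortest_path_length(H.subgraph(giant)))
    c_rand = float(np.mean(cs))
    l_rand = float(np.mean(ls))
    sigma = (C / c_rand) / (L / l_rand) if c_rand > 0 and l_rand > 0 else float("inf")
    alpha, kmin, ks = fit_powerlaw_tail([d for _, d in G.degree()])
    n = G.number_of_nodes()
    density = 2.0 * G.number_of_edges() / (n * (n - 1))
    return TopologyDiagnostics(
        small_world_sigma=float(sigma),
        clustering=float(C),
        path_length=float(L),
        null_clustering=c_rand,
        null_path_length=l_rand,
        powerlaw_alpha=alpha,
        powerlaw_kmin=kmin,
        powerlaw_ks=ks,
        dense_graph=density > 0.5,
    )


# ---------------------------------------------------------------- exports


def write_sif(net: PPINetwork, path: str | Path) -> None:
    lines = [
        f"{u}\t{net.graph.edges[u, v].get('interaction_class', PREDICTED)}\t{v}"
        for u, v in sorted(tuple(sorted(e)) for e in net.graph.edges)
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def write_graphml(net: PPINetwork, path: str | Path) -> None:
    nx.write_graphml(net.graph, str(path))
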