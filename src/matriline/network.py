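"""Median-joining haplotype networks and the rho TMRCA utility.

The construction follows the median-joining scheme of Bandelt et al.
(1999): a minimum-spanning network (the epsilon-relaxed union of all
minimum spanning trees over Hamming distances) is augmented iteratively
with quasi-medians of connected triplets whenever adding one reduces the
total network (spanning) cost, to a fixpoint; median vectors not lying
on any shortest path between observed haplotypes are pruned. All
variable sites are weighted equally.

The rho statistic utility converts the size-weighted mean mutational
distance from a designated root haplotype into years via a clock rate
(default 3.13e-7 substitutions/site/year for the chicken control
region). It is a rough founder-age heuristic, not comparable to a
calibrated Bayesian node-age estimate.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import minimum_spanning_tree

from .diversity import HaplotypePartition

DEFAULT_CLOCK_RATE = 3.13e-7  # substitutions / site / year
MEDIAN_VARIANT_CAP = 64
DEFAULT_ROUND_CAP = 50


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _distance_matrix(states: list[str]) -> np.ndarray:
    n = len(states)
    arr = np.array([np.frombuffer(s.encode(), dtype=np.uint8) for s in states])
    d = np.zeros((n, n), dtype=np.int64)
    for j in range(arr.shape[1]):
        col = arr[:, j]
        d += col[:, None] != col[None, :]
    return d


def build_msn(states: list[str], epsilon: int = 0) -> nx.Graph:
    """Epsilon-relaxed minimum spanning network over Hamming distances.

    Edge weights are processed in ascending order; an edge of weight w
    joins the network iff its endpoints lie in different components of
    the graph built from all admitted edges of weight <= w - epsilon - 1.
    At epsilon = 0 this is exactly the union of all minimum spanning
    trees; larger epsilon admits near-minimal alternative links.
    """
    n = len(states)
    if n < 1:
        raise ValueError("no haplotypes")
    g = nx.Graph()
    g.add_nodes_from(range(n))
    if n == 1:
        return g
    d = _distance_matrix(states)
    weights = sorted(set(int(d[i, j]) for i in range(n) for j in range(i + 1, n)))
    edges_by_w = {
        w: [(i, j) for i in range(n) for j in range(i + 1, n) if d[i, j] == w] for w in weights
    }
    admitted: list[tuple[int, int, int]] = []
    for w in weights:
        # components over admitted edges with weight <= w - epsilon - 1
        snap = nx.Graph()
        snap.add_nodes_from(range(n))
        snap.add_edges_from((i, j) for i, j, ww in admitted if ww <= w - epsilon - 1)
        comp = {v: c for c, nodes in enumerate(nx.connected_components(snap)) for v in nodes}
        for i, j in edges_by_w[w]:
            if comp[i] != comp[j]:
                admitted.append((i, j, w))
    for i, j, w in admitted:
        g.add_edge(i, j, weight=w)
    return g


def quasi_medians(u: str, v: str, w: str) -> list[str]:
    """Quasi-median haplotypes of a triplet.

    Per site, the majority state when one exists; sites where all three
    states differ spawn every variant (Bandelt's quasi-median), capped
    at MEDIAN_VARIANT_CAP variants.
    """
    fixed: list[str] = []
    tie_sites: list[tuple[int, tuple[str, str, str]]] = []
    for idx, (a, b, c) in enumerate(zip(u, v, w)):
        if a == b or a == c:
            fixed.append(a)
        elif b == c:
            fixed.append(b)
        else:
            fixed.append("?")
            tie_sites.append((idx, (a, b, c)))
    if 3 ** len(tie_sites) > MEDIAN_VARIANT_CAP:
        raise ValueError(
            f"quasi-median of triplet spawns 3^{len(tie_sites)} variants "
            f"(cap {MEDIAN_VARIANT_CAP})"
        )
    if not tie_sites:
        return ["".join(fixed)]
    variants = []
    for combo in itertools.product(*[sts for _, sts in tie_sites]):
        s = list(fixed)
        for (idx, _), state in zip(tie_sites, combo):
            s[idx] = state
        variants.append("".join(s))
    return variants


def _mst_cost(states: list[str]) -> float:
    d = _distance_matrix(states)
    return float(minimum_spanning_tree(d.astype(float)).sum())


@dataclass
class MJNetwork:
    """Median-joining network over haplotype state vectors."""

    graph: nx.Graph  # nodes carry: states, kind, size, populations
    epsilon: int
    variable_positions: tuple[int, ...] = ()  # 1-based reference positions

    def observed_nodes(self) -> list[str]:
        return [v for v, data in self.graph.nodes(data=True) if data["kind"] == "observed"]

    def median_nodes(self) -> list[str]:
        return [v for v, data in self.graph.nodes(data=True) if data["kind"] == "median"]

    @property
    def total_cost(self) -> float:
        return float(sum(d["weight"] for _, _, d in self.graph.edges(data=True)))


def _median_join(
    states: list[str], epsilon: int, round_cap: int
) -> tuple[list[str], list[float]]:
    """Iterative median insertion; returns all node states (observed
    first) and the per-round spanning-cost trace (non-increasing)."""
    n_obs = len(states)
    nodes = list(states)
    costs = [_mst_cost(nodes)]
    for _ in range(round_cap):
        msn = build_msn(nodes, epsilon)
        candidates: set[str] = set()
        existing = set(nodes)
        for v in msn.nodes:
            for a, b in itertools.combinations(sorted(msn.neighbors(v)), 2):
                for qm in quasi_medians(nodes[a], nodes[v], nodes[b]):
                    if qm not in existing:
                        candidates.add(qm)
        if not candidates:
            break
        current = costs[-1]
        added = False
        # one scoring pass, then sequential re-validated greedy additions
        scored = sorted(
            (cand for cand in sorted(candidates)),
            key=lambda cand: _mst_cost(nodes + [cand]),
        )
        for cand in scored:
            c = _mst_cost(nodes + [cand])
            if c < current - 1e-9:
                nodes.append(cand)
                existing.add(cand)
                current = c
                added = True
        costs.append(current)
        if not added:
            break
    else:
        raise RuntimeError(
            f"median insertion did not converge within {round_cap} rounds "
            f"({len(nodes) - n_obs} medians added)"
        )
    return nodes, costs


def _prune_medians(nodes: list[str], n_obs: int, epsilon: int) -> list[str]:
    """Drop median vectors not on any shortest path between observed
    haplotypes (and, iteratively, degree-<=1 medians)."""
    keep = list(nodes)
    while True:
        msn = build_msn(keep, epsilon)
        n_med = len(keep) - n_obs
        if n_med == 0:
            break
        lengths = dict(nx.all_pairs_dijkstra_path_length(msn, weight="weight"))
        useful = set()
        obs_idx = range(n_obs)
        for a in obs_idx:
            for b in obs_idx:
                if a >= b:
                    continue
                dab = lengths[a][b]
                for m in range(n_obs, len(keep)):
                    if abs(lengths[a].get(m, np.inf) + lengths[m].get(b, np.inf) - dab) < 1e-9:
                        useful.add(m)
        degrees = dict(msn.degree)
        drop = [
            m
            for m in range(n_obs, len(keep))
            if m not in useful or degrees[m] <= 1
        ]
        if not drop:
            break
        keep = [s for i, s in enumerate(keep) if i < n_obs or i not in set(drop)]
    return keep


def add_median_vectors(
    part_or_states: HaplotypePartition | list[str],
    epsilon: int = 0,
    round_cap: int = DEFAULT_ROUND_CAP,
    populations: dict[str, dict[str, int]] | None = None,
    variable_positions: tuple[int, ...] = (),
) -> MJNetwork:
    """Full median-joining network of a haplotype partition.

    Accepts either a :class:`HaplotypePartition` (observed node sizes and
    ids taken from it) or a bare list of state strings (unit sizes).
    """
    if isinstance(part_or_states, HaplotypePartition):
        part = part_or_states
        states = list(part.representative_states)
        ids = list(part.haplotype_ids)
        sizes = [len(m) for m in part.members]
    else:
        states = list(part_or_states)
        ids = [f"Hap_{i + 1}" for i in range(len(states))]
        sizes = [1] * len(states)
    if len(states) < 1:
        raise ValueError("no haplotypes")
    if len(set(states)) != len(states):
        raise ValueError("haplotype states must be unique")
    n_obs = len(states)

    if n_obs == 1:
        all_nodes = states
    else:
        merged, _ = _median_join(states, epsilon, round_cap)
        all_nodes = _prune_medians(merged, n_obs, epsilon)

    msn = build_msn(all_nodes, epsilon)
    g = nx.Graph()
    names = []
    mv = 0
    for i, s in enumerate(all_nodes):
        if i < n_obs:
            name = ids[i]
            g.add_node(
                name,
                states=s,
                kind="observed",
                size=sizes[i],
                populations=(populations or {}).get(name, {}),
            )
        else:
            mv += 1
            name = f"mv{mv}"
            g.add_node(name, states=s, kind="median", size=0, populations={})
        names.append(name)
    for a, b, data in msn.edges(data=True):
        positions = [
            variable_positions[k] if variable_positions else k + 1
            for k, (x, y) in enumerate(zip(all_nodes[a], all_nodes[b]))
            if x != y
        ]
        g.add_edge(names[a], names[b], weight=int(data["weight"]), mutated_positions=positions)
    return MJNetwork(graph=g, epsilon=epsilon, variable_positions=tuple(variable_positions))


def mutation_steps(net: MJNetwork, a: str | list[str], b: str | list[str]) -> int:
    """Minimum total mutational steps between nodes (or node sets)."""
    a_set = [a] if isinstance(a, str) else list(a)
    b_set = [b] if isinstance(b, str) else list(b)
    for v in a_set + b_set:
        if v not in net.graph:
            raise KeyError(f"node {v!r} not in network")
    best = np.inf
    for u in a_set:
        lengths = nx.single_source_dijkstra_path_length(net.graph, u, weight="weight")
        for v in b_set:
            if v not in lengths:
                raise ValueError(f"nodes {u!r}, {v!r} are disconnected")
            best = min(best, lengths[v])
    return int(best)


@dataclass(frozen=True)
class RhoEstimate:
    root: str
    rho: float
    rate: float
    L: int
    tmrca_years: float


def estimate_tmrca_rho(
    net: MJNetwork, root: str, rate: float = DEFAULT_CLOCK_RATE, L: int = 1232
) -> RhoEstimate:
    """Rho approximation of the TMRCA from a designated root haplotype.

    rho = sum size(h) * steps(root, h) / sum size(h) over observed
    nodes; tmrca_years = rho / (rate * L). A rough heuristic only.
    """
    if root not in net.graph:
        raise KeyError(f"root {root!r} not in network")
    lengths = nx.single_source_dijkstra_path_length(net.graph, root, weight="weight")
    total_size = 0
    weighted = 0.0
    for v, data in net.graph.nodes(data=True):
        if data["kind"] != "observed":
            continue
        total_size += data["size"]
        weighted += data["size"] * lengths[v]
    if total_size == 0:
        raise ValueError("network has zero total sample size")
    rho = weighted / total_size
    return RhoEstimate(root=root, rho=rho, rate=rate, L=L, tmrca_years=rho / (rate * L))


# ---------------------------------------------------------------------------
# Exports


def write_graphml(net: MJNetwork, path: str | Path) -> None:
    g = net.graph.copy()
    for _, data in g.nodes(data=True):
        data["populations"] = ",".join(f"{k}:{v}" for k, v in sorted(data["populations"].items()))
    for _, _, data in g.edges(data=True):
        data["mutated_positions"] = ",".join(map(str, data["mutated_positions"]))
    nx.write_graphml(g, str(path))


def write_nexus_network(net: MJNetwork, path: str | Path) -> None:
    """PopArt-compatible NEXUS Network block (vertices + edges)."""
    nodes = list(net.graph.nodes(data=True))
    index = {name: i + 1 for i, (name, _) in enumerate(nodes)}
    with open(path, "w") as fh:
        fh.write("#NEXUS\n\nBEGIN NETWORK;\n")
        fh.write(f"DIMENSIONS NTAX={len(nodes)} NVERTICES={len(nodes)} "
                 f"NEDGES={net.graph.number_of_edges()};\n")
        fh.write("VERTICES\n")
        for name, data in nodes:
            fh.write(f"  {index[name]} {name} size={data['size']} kind={data['kind']},\n")
        fh.write(";\nEDGES\n")
        for k, (a, b, data) in enumerate(net.graph.edges(data=True), start=1):
            fh.write(f"  {k} {index[a]} {index[b]} weight={data['weight']},\n")
        fh.write(";\nEND;\n")


def write_edge_tsv(net: MJNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("node_a\tnode_b\tsteps\tmutated_positions\n")
        for a, b, data in sorted(net.graph.edges(data=True)):
            fh.write(
                f"{a}\t{b}\t{data['weight']}\t"
                f"{','.join(map(str, data['mutated_positions']))}\n"
            )
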