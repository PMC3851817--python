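"""Statistical-parsimony haplotype networks.

Haplotypes are joined in order of increasing mutational distance; a
connection of d steps inserts d-1 inferred (unsampled) intermediate nodes;
pairs beyond the parsimony connection limit stay in separate subnetworks,
and alternative equal-length connections are retained as loops (reticulation
displays the ambiguity rather than hiding it).

The connection limit is the largest number of steps for which the
probability of a parsimonious (homoplasy-free) connection still exceeds the
chosen level (0.95 by default).  It is computed from an exact occupancy
chain: under a Jukes-Cantor mutation process on L sites, the number of
visibly differing sites D after m mutations is a Markov chain
(D -> D+1 w.p. (L-D)/L; D -> D-1 w.p. D/(3L); D -> D otherwise), and the
probability of parsimony at observed distance j is the posterior
P(m = j | D = j) under a uniform prior over the true mutation count (the
likelihood P(D=j | m) decays super-geometrically in m for j << L, so the
posterior is proper).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache

import networkx as nx
import numpy as np

from .haplotypes import HaplotypeAlignment, InputError, collapse_haplotypes, n_differences


@dataclass
class HaplotypeNetwork:
    graph: nx.Graph
    connection_limit: int
    components: list[list[str]]
    root_weights: dict[str, tuple] = field(default_factory=dict)

    @property
    def sampled_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d.get("count", 0) > 0]

    @property
    def intermediate_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d.get("count", 0) == 0]

    @property
    def unsampled_fraction(self) -> float:
        total = self.graph.number_of_nodes()
        return len(self.intermediate_nodes) / total if total else 0.0

    def to_csv(self, nodes_path, edges_path) -> None:
        import csv

        with open(nodes_path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["node", "count", "populations"])
            for n, d in self.graph.nodes(data=True):
                w.writerow([n, d.get("count", 0), ";".join(d.get("populations", []))])
        with open(edges_path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["source", "target"])
            for a, b in self.graph.edges():
                w.writerow([a, b])

    def to_graphml(self, path) -> None:
        g = nx.Graph()
        for n, d in self.graph.nodes(data=True):
            g.add_node(n, count=d.get("count", 0),
                       populations=";".join(d.get("populations", [])))
        g.add_edges_from(self.graph.edges())
        nx.write_graphml(g, path)


@lru_cache(maxsize=None)
def _prob_parsimony(j: int, L: int, m_extra: int = 200) -> float:
    """P(true steps = j | observed distance j) from the occupancy chain."""
    if j == 0:
        return 1.0
    # likelihood P(D = j | m) for m = j .. j + m_extra via the chain
    target = j
    likes = []
    dist = np.zeros(min(L, j + m_extra + 2) + 1)
    dist[0] = 1.0
    dmax = len(dist) - 1
    for m in range(1, j + m_extra + 1):
        new = np.zeros_like(dist)
        d = np.arange(dmax + 1)
        up = (L - d) / L
        down = d / (3.0 * L)
        stay = 1.0 - up - down
        new[1:] += dist[:-1] * up[:-1]
        new[:-1] += dist[1:] * down[1:]
        new += dist * stay
        dist = new
        if m >= j:
            likes.append(dist[target])
            # stop once contributions are negligible
            if dist[target] < 1e-14 * sum(likes):
                break
    total = sum(likes)
    return likes[0] / total if total > 0 else 0.0


def parsimony_limit(L: int, alpha: float = 0.95) -> int:
    """Largest number of steps j with parsimony probability above alpha."""
    if L < 1:
        raise InputError("L must be >= 1")
    if not 0 < alpha < 1:
        raise InputError("alpha must be in (0, 1)")
    j = 0
    while j < L:
        if _prob_parsimony(j + 1, L) > alpha:
            j += 1
        else:
            break
    return j


def build_network(
    haps: HaplotypeAlignment | list[tuple[str, int, list[str]]],
    limit: int | None = None,
    alpha: float = 0.95,
) -> HaplotypeNetwork:
    """Agglomerative statistical-parsimony network.

    ``haps`` is a collapsed alignment or an explicit haplotype table
    [(sequence, count, member_ids), ...].  Pairs are connected in order of
    increasing mutational distance up to ``limit`` (defaulting to the 95%
    parsimony limit for the alignment length); equal-length alternative
    connections are kept as loops.
    """
    if isinstance(haps, HaplotypeAlignment):
        if not haps.haplotypes:
            haps = collapse_haplotypes(haps)
        pop_of = {r.id: r.population for r in haps.records}
        table = haps.haplotypes
        L = haps.site_count
    else:
        table = haps
        pop_of = {}
        L = len(table[0][0]) if table else 0
    if not table:
        raise InputError("no haplotypes to connect")
    if limit is None:
        limit = parsimony_limit(L, alpha)

    names = [f"H{i + 1}" for i in range(len(table))]
    g = nx.Graph()
    for name, (seq, count, members) in zip(names, table):
        pops = sorted({pop_of.get(m) for m in members if pop_of.get(m)})
        g.add_node(name, count=count, sequence=seq, populations=pops, sampled=True)

    dists = []
    for i, j in itertools.combinations(range(len(table)), 2):
        d = n_differences(table[i][0], table[j][0])
        dists.append((d, i, j))
    dists.sort()

    inter_count = [0]

    def connect(i, j, d):
        if d == 0:
            return
        if d == 1:
            g.add_edge(names[i], names[j])
            return
        prev = names[i]
        for step in range(d - 1):
            inter_count[0] += 1
            node = f"x{inter_count[0]}"
            g.add_node(node, count=0, populations=[], sampled=False)
            g.add_edge(prev, node)
            prev = node
        g.add_edge(prev, names[j])

    # process one distance level at a time against a component snapshot so
    # that equal-length alternative connections between the same pair of
    # subnetworks are all added (retained as loops)
    for d, group in itertools.groupby(dists, key=lambda t: t[0]):
        if d == 0 or d > limit:
            continue
        comp_of = {}
        for ci, comp in enumerate(nx.connected_components(g)):
            for node in comp:
                comp_of[node] = ci
        for _, i, j in group:
            if comp_of[names[i]] != comp_of[names[j]]:
                connect(i, j, d)

    components = [sorted(c) for c in nx.connected_components(g)]
    components.sort(key=lambda c: (-len(c), c))
    net = HaplotypeNetwork(
        graph=g, connection_limit=limit, components=components
    )
    classify_and_root(net)
    return net


def classify_and_root(net: HaplotypeNetwork) -> dict[str, str]:
    """Classify sampled nodes as tip (degree 1) or interior and rank root
    candidates by (degree, sampled frequency), highest first.

    The ranking approximates outgroup-probability root weighting: in an
    expansion setting the ancestral haplotype is expected to be the
    high-frequency, high-degree hub.
    """
    g = net.graph
    classes = {}
    weights = {}
    for n, d in g.nodes(data=True):
        if d.get("count", 0) > 0:
            classes[n] = "tip" if g.degree(n) == 1 else "interior"
            weights[n] = (g.degree(n), d.get("count", 0))
        else:
            classes[n] = "intermediate"
    ranking = sorted(weights, key=lambda n: (weights[n], n), reverse=True)
    net.root_weights = {n: weights[n] for n in ranking}
    for n in g.nodes:
        g.nodes[n]["class"] = classes[n]
    return classes


def tip_interior_proportions(
    net: HaplotypeNetwork, site_classes: dict[str, str]
) -> dict[str, dict[str, float]]:
    """Proportions of tip vs interior sampled haplotypes per user-defined
    site class (e.g. inside/outside a refugium polygon).  A haplotype
    belongs to a class when any of its populations does."""
    out: dict[str, dict[str, int]] = {}
    g = net.graph
    for n, d in g.nodes(data=True):
        if d.get("count", 0) == 0:
            continue
        klasses = {site_classes.get(p) for p in d.get("populations", [])}
        klasses.discard(None)
        for k in klasses:
            bucket = out.setdefault(k, {"tip": 0, "interior": 0})
            bucket[g.nodes[n]["class"]] += 1
    props = {}
    for k, b in out.items():
        tot = b["tip"] + b["interior"]
        props[k] = {
            "tip": b["tip"] / tot if tot else 0.0,
            "interior": b["interior"] / tot if tot else 0.0,
            "n": tot,
        }
    return props
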