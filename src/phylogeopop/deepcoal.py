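"""Deep-coalescence counting, minimize-deep-coalescence species trees, and
the coalescent hypothesis test.

The discordance cost between a gene tree and a population tree is Maddison's
number of deep coalescences (nDC): embed the gene tree minimally — each gene
node placed at the most tipward population-tree node compatible with its
descendant leaves — and sum, over population-tree branches, the number of
gene lineages exiting the branch rootward minus one.  The cost is purely
topological.

The hypothesis test follows the simulate-within-the-null design: gene
genealogies are simulated inside the null demographic model, their nDC
against the null population tree forms the null distribution, and the
observed gene tree's nDC is referred to its upper tail (large discordance
contradicts the model).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np

from .coalescent import GeneTree, GeneNode, PopulationTreeModel, simulate_gene_tree
from .haplotypes import InputError


@dataclass
class DeepCoalescenceResult:
    ndc_observed: dict[str, int]
    null_distribution: np.ndarray
    p: float
    reps: int
    seed: int | None
    null_label: str


# ---------------------------------------------------------------------------
# Population-tree topologies

@dataclass
class PopTopology:
    """Rooted (multifurcating allowed) population-tree topology."""

    name: str | None
    children: list["PopTopology"] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def leaf_names(self) -> list[str]:
        if self.is_leaf():
            return [self.name]
        out = []
        for c in self.children:
            out.extend(c.leaf_names())
        return out

    def newick(self) -> str:
        def sub(nd):
            if nd.is_leaf():
                return nd.name
            return "(" + ",".join(sorted(sub(c) for c in nd.children)) + ")"
        return sub(self) + ";"

    @classmethod
    def from_newick(cls, s: str) -> "PopTopology":
        s = s.strip().rstrip(";")

        def parse(txt: str) -> "PopTopology":
            txt = txt.strip()
            if not txt.startswith("("):
                return cls(name=txt.split(":")[0].strip())
            depth = 0
            parts = []
            last = 1
            close = txt.rfind(")")
            for i, c in enumerate(txt[1:close], start=1):
                if c == "(":
                    depth += 1
                elif c == ")":
                    depth -= 1
                elif c == "," and depth == 0:
                    parts.append(txt[last:i])
                    last = i + 1
            parts.append(txt[last:close])
            return cls(name=None, children=[parse(p) for p in parts])

        return parse(s)

    @classmethod
    def from_model(cls, model: PopulationTreeModel) -> "PopTopology":
        def sub(name):
            br = model.branches[name]
            if not br.children:
                return cls(name=name)
            node = cls(name=None, children=[sub(c) for c in br.children])
            if br.sample_size and br.children:
                # sampled internal branch: represent its own samples as an
                # extra leaf child carrying the branch name
                node.children.append(cls(name=name))
            return node
        return sub(model.root)


def _resolve_polytomies(node: GeneNode) -> GeneNode:
    """Binary-resolve gene-tree polytomies deterministically (sorted-label
    caterpillar) with a warning; nDC bookkeeping assumes binary gene trees."""
    kids = [_resolve_polytomies(c) for c in node.children]
    if len(kids) <= 2:
        node.children = kids
        return node
    warnings.warn("gene-tree polytomy resolved in sorted-label order")
    kids = sorted(kids, key=lambda nd: min(l.name for l in _leaves(nd)))
    while len(kids) > 2:
        b = kids.pop()
        a = kids.pop()
        kids.append(GeneNode(name="", time=node.time, children=[a, b]))
    node.children = kids
    return node


def _leaves(nd: GeneNode):
    out = []
    stack = [nd]
    while stack:
        x = stack.pop()
        if x.is_leaf():
            out.append(x)
        else:
            stack.extend(x.children)
    return out


def count_deep_coalescences(
    gene: GeneTree, pop: PopTopology | PopulationTreeModel,
    mapping: dict[str, str] | None = None,
) -> int:
    """Maddison's deep-coalescence cost of fitting ``gene`` into ``pop``.

    ``mapping`` sends each gene-tree leaf name to a population-tree tip; by
    default the leaf's recorded population is used.
    """
    if isinstance(pop, PopulationTreeModel):
        pop = PopTopology.from_model(pop)
    if mapping is None:
        mapping = gene.leaf_population_map()

    # index population nodes; record each node's tip set and parent
    pop_nodes: list[PopTopology] = []

    def collect(nd):
        pop_nodes.append(nd)
        for c in nd.children:
            collect(c)

    collect(pop)
    idx = {id(nd): i for i, nd in enumerate(pop_nodes)}
    parent = [None] * len(pop_nodes)
    for nd in pop_nodes:
        for c in nd.children:
            parent[idx[id(c)]] = idx[id(nd)]
    tipsets = [frozenset(nd.leaf_names()) for nd in pop_nodes]
    tip_index = {}
    for i, nd in enumerate(pop_nodes):
        if nd.is_leaf():
            tip_index[nd.name] = i

    # ancestors (inclusive) of each node, as index sets, tipward->rootward
    anc_chain = []
    for i in range(len(pop_nodes)):
        chain = []
        j = i
        while j is not None:
            chain.append(j)
            j = parent[j]
        anc_chain.append(chain)

    def mrca_of(tips: frozenset) -> int:
        # smallest tip set containing all: walk up from one tip
        start = tip_index[next(iter(tips))]
        for j in anc_chain[start]:
            if tips <= tipsets[j]:
                return j
        raise InputError("gene leaves map outside the population tree")

    root = _resolve_polytomies(gene.root)

    # map each gene node to its population node; count lineages exiting
    # each non-root population branch
    exits = [0] * len(pop_nodes)
    root_idx = idx[id(pop)]

    def place(nd: GeneNode) -> int:
        if nd.is_leaf():
            pop_name = mapping.get(nd.name, nd.population)
            if pop_name not in tip_index:
                raise InputError(f"gene leaf {nd.name!r} maps to unknown "
                                 f"population {pop_name!r}")
            return tip_index[pop_name]
        kids = [place(c) for c in nd.children]
        tips = frozenset().union(*(tipsets[k] for k in kids))
        here = mrca_of(tips)
        for k, child_node in zip(kids, nd.children):
            # the gene edge child->nd exits every pop branch strictly
            # between (inclusive of k) and here
            j = k
            while j != here:
                exits[j] += 1
                j = parent[j]
        return here

    top = place(root)
    # the single remaining lineage above the gene root traverses branches
    # from its placement up to the population root
    j = top
    while j != root_idx:
        exits[j] += 1
        j = parent[j]

    return sum(e - 1 for i, e in enumerate(exits) if i != root_idx and e > 0)


# ---------------------------------------------------------------------------
# Exhaustive MDC species-tree search

def _rooted_topologies(labels: list[str]):
    """Generate all rooted binary tree topologies over labels."""
    if len(labels) == 1:
        yield PopTopology(name=labels[0])
        return
    first, rest = labels[0], labels[1:]
    for sub in _rooted_topologies(rest):
        yield from _insert_everywhere(sub, first)


def _insert_everywhere(tree: PopTopology, label: str):
    # attach `label` on every edge, including above the root
    yield PopTopology(name=None, children=[_copy(tree), PopTopology(name=label)])
    if not tree.is_leaf():
        for i, child in enumerate(tree.children):
            for sub in _insert_everywhere(child, label):
                new_children = [
                    _copy(c) if j != i else sub for j, c in enumerate(tree.children)
                ]
                yield PopTopology(name=tree.name, children=new_children)


def _copy(nd: PopTopology) -> PopTopology:
    return PopTopology(name=nd.name, children=[_copy(c) for c in nd.children])


def mdc_species_tree(
    gene: GeneTree, populations: list[str] | None = None,
    mapping: dict[str, str] | None = None,
):
    """Exhaustive minimize-deep-coalescence search over rooted population
    trees (populations limited to 8; ties all reported)."""
    if mapping is None:
        mapping = gene.leaf_population_map()
    if populations is None:
        populations = sorted(set(mapping.values()))
    if len(populations) > 8:
        raise InputError(
            "exhaustive MDC search is limited to 8 populations; use a "
            "heuristic species-tree tool for larger problems"
        )
    best_cost = None
    best_trees = []
    for topo in _rooted_topologies(sorted(populations)):
        cost = count_deep_coalescences(gene, topo, mapping)
        if best_cost is None or cost < best_cost:
            best_cost = cost
            best_trees = [topo]
        elif cost == best_cost:
            best_trees.append(topo)
    # deduplicate identical shapes (insertion enumeration can repeat)
    seen = {}
    for t in best_trees:
        seen.setdefault(t.newick(), t)
    return sorted(seen.values(), key=lambda t: t.newick()), best_cost


# ---------------------------------------------------------------------------
# Hypothesis test

def simulate_null_ndc(
    model: PopulationTreeModel, reps: int, seed: int | None = None,
    sample_sizes: dict[str, int] | None = None,
) -> np.ndarray:
    """nDC values of ``reps`` gene trees simulated within ``model`` and fit
    back into the same population tree."""
    rng = np.random.default_rng(seed)
    topo = PopTopology.from_model(model)
    out = np.empty(reps, dtype=int)
    for r in range(reps):
        g = simulate_gene_tree(
            model, seed=int(rng.integers(2**31 - 1)), sample_sizes=sample_sizes
        )
        out[r] = count_deep_coalescences(g, topo)
    return out


def hypothesis_test(
    gene: GeneTree, null_model: PopulationTreeModel,
    alternatives: list[PopulationTreeModel] = (),
    reps: int = 1000, seed: int | None = None,
    mapping: dict[str, str] | None = None,
    null_distribution: np.ndarray | None = None,
) -> DeepCoalescenceResult:
    """One-tailed deep-coalescence test of a demographic null model.

    Simulates ``reps`` gene genealogies within the null model, counts nDC on
    the null population tree, and reports
    p = (1 + #{sim >= nDC_observed}) / (reps + 1).  The observed gene tree's
    nDC against each alternative population tree is reported for comparison.
    """
    if reps < 1:
        raise InputError("reps must be >= 1")
    observed = {
        null_model.label: count_deep_coalescences(gene, null_model, mapping)
    }
    for alt in alternatives:
        observed[alt.label] = count_deep_coalescences(gene, alt, mapping)
    if null_distribution is None:
        null_distribution = simulate_null_ndc(null_model, reps, seed)
    reps = len(null_distribution)
    obs = observed[null_model.label]
    p = (1 + int(np.sum(null_distribution >= obs))) / (reps + 1)
    return DeepCoalescenceResult(
        ndc_observed=observed, null_distribution=null_distribution,
        p=p, reps=reps, seed=seed, null_label=null_model.label,
    )
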