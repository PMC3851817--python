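"""Demographic population-tree models and neutral coalescent simulation.

Population trees are rooted trees whose branches carry piecewise-constant
female effective sizes (Ne) over absolute time intervals measured in
generations before present.  The haploid (matrilineal) convention is used:
with k lineages in a branch of size Ne, coalescences occur at rate
C(k,2)/Ne per generation, so E[T2] = Ne and theta = 2*Ne*mu gives the
expected pairwise difference.  A diploid convention (rate C(k,2)/(2Ne)) is
selectable for comparison with nuclear-genome tools.

Three competing glacial-cycle hypotheses are provided as model builders:

* ``expansion_contraction`` -- a single size-constant ancestor, a 90%
  reduction of Ne during the contraction window (LGM onset to colonization
  onset), then subdivision into tip populations at the colonization onset,
  with sizes summing back to the overall Ne.
* ``vicariance_ne_colonization`` -- a basal east-west split at the root,
  with one tip budding post-glacially from an eastern source.
* ``four_refugia`` -- four lineages diverging from the ancestor at the root.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .haplotypes import HaplotypeAlignment, InputError, SequenceRecord

GENERATION_TIME_YEARS = 1.0 / 3.0
T_TOTAL_GENERATIONS = 3.741e6
LGM_START_YEARS = 22_000.0
LGM_END_YEARS = 19_000.0
COLONIZATION_START_YEARS = 15_000.0


class ModelError(ValueError):
    pass


def theta_to_Ne(theta: float, mu: float) -> float:
    """Nef = theta / (2 mu); theta and mu must be on matching units
    (both per site or both per locus, mu per generation)."""
    if mu <= 0:
        raise InputError("mu must be positive")
    if theta < 0:
        raise InputError("theta must be nonnegative")
    return theta / (2.0 * mu)


def years_to_generations(years: float, T: float = GENERATION_TIME_YEARS) -> float:
    return years / T


@dataclass
class PopBranch:
    """One population lineage: from time ``t_bottom`` (tipward, generations
    before present) up to ``t_top`` (rootward), with Ne segments
    [(t_lo, t_hi, Ne), ...] covering that interval."""

    name: str
    t_bottom: float
    t_top: float
    ne_segments: list[tuple[float, float, float]]
    children: list[str] = field(default_factory=list)
    parent: str | None = None
    sample_size: int = 0

    def ne_at(self, t: float) -> float:
        for lo, hi, ne in self.ne_segments:
            if lo <= t < hi or (t == hi == self.t_top and hi == self.ne_segments[-1][1]):
                return ne
        raise ModelError(f"time {t} outside branch {self.name}")


@dataclass
class PopulationTreeModel:
    label: str
    branches: dict[str, PopBranch]
    root: str
    root_ne: float  # constant Ne above the root
    t_total: float

    def __post_init__(self):
        for br in self.branches.values():
            if br.t_top <= br.t_bottom and br.name != self.root:
                raise ModelError(f"branch {br.name} has nonpositive duration")
            for lo, hi, ne in br.ne_segments:
                if ne <= 0:
                    raise ModelError(f"nonpositive Ne on branch {br.name}")

    @property
    def tips(self) -> list[str]:
        return [b.name for b in self.branches.values() if not b.children]

    def slice_ne(self, t: float) -> float:
        """Sum of Ne across branches alive at time t (generations BP)."""
        total = 0.0
        for br in self.branches.values():
            if br.t_bottom <= t < br.t_top:
                total += br.ne_at(t)
        if t >= self.t_total:
            total += self.root_ne
        return total

    def topology_newick(self) -> str:
        def sub(name):
            br = self.branches[name]
            if not br.children:
                return name
            return "(" + ",".join(sub(c) for c in br.children) + ")" + name
        return sub(self.root) + ";"

    def to_json(self, path=None) -> str:
        obj = {
            "label": self.label, "root": self.root, "root_ne": self.root_ne,
            "t_total": self.t_total,
            "branches": {
                n: {
                    "t_bottom": b.t_bottom, "t_top": b.t_top,
                    "ne_segments": b.ne_segments, "children": b.children,
                    "parent": b.parent, "sample_size": b.sample_size,
                }
                for n, b in self.branches.items()
            },
        }
        s = json.dumps(obj, indent=1)
        if path:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    @classmethod
    def from_json(cls, src) -> "PopulationTreeModel":
        if isinstance(src, str) and src.lstrip().startswith("{"):
            obj = json.loads(src)
        else:
            with open(src) as fh:
                obj = json.load(fh)
        branches = {
            n: PopBranch(
                name=n, t_bottom=b["t_bottom"], t_top=b["t_top"],
                ne_segments=[tuple(s) for s in b["ne_segments"]],
                children=b["children"], parent=b["parent"],
                sample_size=b["sample_size"],
            )
            for n, b in obj["branches"].items()
        }
        return cls(
            label=obj["label"], branches=branches, root=obj["root"],
            root_ne=obj["root_ne"], t_total=obj["t_total"],
        )


def _segments(breaks_and_nes):
    """Helper: [(t_lo, t_hi, ne), ...] from ordered pieces."""
    return [tuple(x) for x in breaks_and_nes]


def build_hypothesis_model(
    kind: str,
    overall_ne: float,
    t_total: float = T_TOTAL_GENERATIONS,
    bottleneck_fraction: float = 0.1,
    expansion_start_years: float = COLONIZATION_START_YEARS,
    lgm_start_years: float = LGM_START_YEARS,
    generation_time: float = GENERATION_TIME_YEARS,
    n_tips: int = 4,
    proportions: list[float] | None = None,
    sample_sizes: list[int] | None = None,
) -> PopulationTreeModel:
    """Construct one of the three competing demographic population trees.

    Tip branch sizes are ``proportions`` of the overall Ne (equal by
    default); sample sizes default to 10 per tip.  All times internally in
    generations before present.
    """
    if proportions is None:
        proportions = [1.0 / n_tips] * n_tips
    if len(proportions) != n_tips:
        raise InputError("need one proportion per tip")
    if abs(sum(proportions) - 1.0) > 1e-9:
        raise InputError("tip proportions must sum to 1")
    if sample_sizes is None:
        sample_sizes = [10] * n_tips
    if len(sample_sizes) != n_tips or any(s < 1 for s in sample_sizes):
        raise InputError("need a sample size >= 1 per tip")

    t_exp = years_to_generations(expansion_start_years, generation_time)
    t_lgm = years_to_generations(lgm_start_years, generation_time)
    tip_names = [f"pop{i + 1}" for i in range(n_tips)]

    if kind == "expansion_contraction":
        anc = PopBranch(
            name="ancestor", t_bottom=t_exp, t_top=t_total,
            ne_segments=_segments([
                (t_exp, t_lgm, bottleneck_fraction * overall_ne),
                (t_lgm, t_total, overall_ne),
            ]),
            children=tip_names,
        )
        branches = {"ancestor": anc}
        for name, prop, ss in zip(tip_names, proportions, sample_sizes):
            branches[name] = PopBranch(
                name=name, t_bottom=0.0, t_top=t_exp,
                ne_segments=[(0.0, t_exp, prop * overall_ne)],
                parent="ancestor", sample_size=ss,
            )
        return PopulationTreeModel(
            label="expansion_contraction", branches=branches,
            root="ancestor", root_ne=overall_ne, t_total=t_total,
        )

    if kind == "vicariance_ne_colonization":
        # basal east-west split at the root; eastern tips (including the
        # post-glacially colonized ACP analogue, the last tip) diverge from
        # the eastern branch at the colonization onset
        if n_tips < 3:
            raise InputError("vicariance model needs at least 3 tips")
        west = tip_names[0]
        east_tips = tip_names[1:]
        w_prop = proportions[0]
        e_prop = 1.0 - w_prop
        branches = {}
        branches[west] = PopBranch(
            name=west, t_bottom=0.0, t_top=t_total,
            ne_segments=[(0.0, t_total, w_prop * overall_ne)],
            parent="root", sample_size=sample_sizes[0],
        )
        branches["east"] = PopBranch(
            name="east", t_bottom=t_exp, t_top=t_total,
            ne_segments=[(t_exp, t_total, e_prop * overall_ne)],
            children=list(east_tips), parent="root",
        )
        for i, name in enumerate(east_tips):
            branches[name] = PopBranch(
                name=name, t_bottom=0.0, t_top=t_exp,
                ne_segments=[(0.0, t_exp, proportions[1 + i] * overall_ne)],
                parent="east", sample_size=sample_sizes[1 + i],
            )
        branches["root"] = PopBranch(
            name="root", t_bottom=t_total, t_top=t_total,
            ne_segments=[], children=[west, "east"],
        )
        return PopulationTreeModel(
            label="vicariance_ne_colonization", branches=branches,
            root="root", root_ne=overall_ne, t_total=t_total,
        )

    if kind == "four_refugia":
        root = PopBranch(
            name="ancestor", t_bottom=t_total, t_top=t_total,
            ne_segments=[], children=tip_names,
        )
        branches = {"ancestor": root}
        for name, prop, ss in zip(tip_names, proportions, sample_sizes):
            branches[name] = PopBranch(
                name=name, t_bottom=0.0, t_top=t_total,
                ne_segments=[(0.0, t_total, prop * overall_ne)],
                parent="ancestor", sample_size=ss,
            )
        return PopulationTreeModel(
            label="four_refugia", branches=branches,
            root="ancestor", root_ne=overall_ne, t_total=t_total,
        )

    raise InputError(f"unknown hypothesis kind {kind!r}")


def single_population_model(
    ne: float, sample_size: int, label: str = "constant",
    t_total: float = T_TOTAL_GENERATIONS,
) -> PopulationTreeModel:
    br = PopBranch(
        name="pop1", t_bottom=0.0, t_top=t_total,
        ne_segments=[(0.0, t_total, ne)], sample_size=sample_size,
    )
    return PopulationTreeModel(
        label=label, branches={"pop1": br}, root="pop1",
        root_ne=ne, t_total=t_total,
    )


# ---------------------------------------------------------------------------
# Gene trees

@dataclass
class GeneNode:
    name: str
    time: float
    children: list["GeneNode"] = field(default_factory=list)
    population: str | None = None

    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class GeneTree:
    root: GeneNode

    def leaves(self) -> list[GeneNode]:
        out = []
        stack = [self.root]
        while stack:
            nd = stack.pop()
            if nd.is_leaf():
                out.append(nd)
            else:
                stack.extend(nd.children)
        return out

    def leaf_population_map(self) -> dict[str, str]:
        return {lf.name: lf.population for lf in self.leaves()}

    def tmrca(self) -> float:
        return self.root.time

    def newick(self) -> str:
        def sub2(nd: GeneNode, parent_time: float | None) -> str:
            if nd.is_leaf():
                label = nd.name
            else:
                label = "(" + ",".join(sub2(c, nd.time) for c in nd.children) + ")"
            if parent_time is None:
                return label
            return f"{label}:{parent_time - nd.time:.8g}"

        return sub2(self.root, None) + ";"

    def to_dendropy(self):
        import dendropy

        tns = dendropy.TaxonNamespace()
        return dendropy.Tree.get(
            data=self.newick(), schema="newick", taxon_namespace=tns
        )

    @classmethod
    def from_newick(cls, s: str, population_of=None) -> "GeneTree":
        import dendropy

        t = dendropy.Tree.get(data=s, schema="newick")
        t.calc_node_ages(ultrametricity_precision=False)

        def conv(nd) -> GeneNode:
            if nd.is_leaf():
                name = nd.taxon.label.replace(" ", "_") if nd.taxon else "leaf"
                pop = None
                if population_of is not None:
                    pop = population_of(name)
                elif "|" in name:
                    pop = name.split("|", 1)[0]
                return GeneNode(name=name, time=0.0, population=pop)
            kids = [conv(c) for c in nd.child_nodes()]
            return GeneNode(name="", time=float(nd.age or 0.0), children=kids)

        return cls(root=conv(t.seed_node))


def simulate_gene_tree(
    model: PopulationTreeModel, seed: int | None = None,
    sample_sizes: dict[str, int] | None = None,
    convention: str = "haploid",
) -> GeneTree:
    """Simulate one neutral gene genealogy within a population tree.

    Within each branch, k lineages coalesce at rate C(k,2)/Ne(t) per
    generation (haploid convention; ``diploid`` halves the rate).  At internal
    nodes surviving lineages merge into the parent branch; above the root a
    constant root Ne applies until one lineage remains.
    """
    rng = np.random.default_rng(seed)
    ploidy = 1.0 if convention == "haploid" else 2.0
    if convention not in ("haploid", "diploid"):
        raise InputError(f"unknown convention {convention!r}")

    sizes = {
        tip: (sample_sizes or {}).get(tip, model.branches[tip].sample_size)
        for tip in model.tips
    }
    counter = [0]

    def coalesce_segment(lineages, t_start, t_end, ne):
        """Coalesce within [t_start, t_end) at constant Ne; returns time."""
        t = t_start
        while len(lineages) > 1:
            k = len(lineages)
            rate = k * (k - 1) / 2.0 / (ploidy * ne)
            w = rng.exponential(1.0 / rate)
            if math.isfinite(t_end) and t + w > t_end:
                return lineages, t_end
            t += w
            i, j = sorted(rng.choice(k, size=2, replace=False))
            counter[0] += 1
            parent = GeneNode(
                name=f"c{counter[0]}", time=t,
                children=[lineages[i], lineages[j]],
            )
            lineages = [l for idx, l in enumerate(lineages) if idx not in (i, j)]
            lineages.append(parent)
        return lineages, t_end

    def run_branch(name: str) -> list[GeneNode]:
        br = model.branches[name]
        lineages: list[GeneNode] = []
        for i in range(sizes.get(name, 0)):
            lineages.append(
                GeneNode(name=f"{name}|s{i + 1}", time=br.t_bottom,
                         population=name)
            )
        for child in br.children:
            lineages.extend(run_branch(child))
        for lo, hi, ne in br.ne_segments:
            lineages, _ = coalesce_segment(lineages, lo, hi, ne)
        return lineages

    lineages = run_branch(model.root)
    if len(lineages) > 1:
        lineages, _ = coalesce_segment(
            lineages, model.branches[model.root].t_top, math.inf, model.root_ne
        )
    return GeneTree(root=lineages[0])


# ---------------------------------------------------------------------------
# Mutation

TN93_BASES = "ACGT"


def _tn93_rate_matrix(freqs, kappa1=2.0, kappa2=2.0):
    gA, gC, gG, gT = (freqs[b] for b in TN93_BASES)
    Q = np.zeros((4, 4))
    g = [gA, gC, gG, gT]
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            bi, bj = TN93_BASES[i], TN93_BASES[j]
            if {bi, bj} == {"A", "G"}:
                Q[i, j] = kappa1 * g[j]
            elif {bi, bj} == {"C", "T"}:
                Q[i, j] = kappa2 * g[j]
            else:
                Q[i, j] = g[j]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    # normalize to 1 expected substitution per unit time
    mu = -np.sum(np.array(g) * np.diag(Q))
    return Q / mu


def mutate_on_tree(
    tree: GeneTree, mu_locus_gen: float, L: int,
    model: str = "infinite_sites", seed: int | None = None,
    base_freqs: dict[str, float] | None = None,
) -> HaplotypeAlignment:
    """Drop mutations on a gene tree and emit an alignment.

    ``infinite_sites``: Poisson(branch_length * mu_locus_gen) mutations per
    branch, each at a fresh position (error if more than L total).
    ``finite_tn93``: site-by-site evolution under a TN93 generator scaled to
    mu_locus_gen / L expected substitutions per site per generation.
    """
    if mu_locus_gen < 0:
        raise InputError("mutation rate must be nonnegative")
    rng = np.random.default_rng(seed)
    leaves = tree.leaves()

    if model == "infinite_sites":
        free_positions = list(rng.permutation(L))
        seqs: dict[int, list[int]] = {}

        anc = ["A"] * L
        results: dict[str, list[str]] = {}

        def walk(nd: GeneNode, seq: list[str], parent_time: float | None):
            if parent_time is not None:
                blen = parent_time - nd.time
                nm = rng.poisson(blen * mu_locus_gen)
                if nm:
                    seq = list(seq)
                    for _ in range(nm):
                        if not free_positions:
                            raise OverflowError(
                                "infinite-sites overflow: more mutations than sites"
                            )
                        pos = free_positions.pop()
                        cur = seq[pos]
                        alts = [b for b in TN93_BASES if b != cur]
                        seq[pos] = alts[rng.integers(3)]
            if nd.is_leaf():
                results[nd.name] = seq
            else:
                for c in nd.children:
                    walk(c, seq, nd.time)

        walk(tree.root, anc, None)
        records = [
            SequenceRecord(
                id=lf.name, sequence="".join(results[lf.name]),
                population=lf.population,
            )
            for lf in sorted(leaves, key=lambda l: l.name)
        ]
        return HaplotypeAlignment(records=records)

    if model == "finite_tn93":
        from scipy.linalg import expm

        freqs = base_freqs or {b: 0.25 for b in TN93_BASES}
        Q = _tn93_rate_matrix(freqs) * (mu_locus_gen / L)
        pvec = np.array([freqs[b] for b in TN93_BASES])
        results = {}

        def walk2(nd: GeneNode, states: np.ndarray, parent_time: float | None):
            if parent_time is not None:
                P = expm(Q * (parent_time - nd.time))
                cum = P.cumsum(axis=1)
                u = rng.random(L)
                states = np.array(
                    [np.searchsorted(cum[s], x) for s, x in zip(states, u)]
                )
            if nd.is_leaf():
                results[nd.name] = states
            else:
                for c in nd.children:
                    walk2(c, states, nd.time)

        root_states = rng.choice(4, size=L, p=pvec)
        walk2(tree.root, root_states, None)
        records = [
            SequenceRecord(
                id=lf.name,
                sequence="".join(TN93_BASES[s] for s in results[lf.name]),
                population=lf.population,
            )
            for lf in sorted(leaves, key=lambda l: l.name)
        ]
        return HaplotypeAlignment(records=records)

    raise InputError(f"unknown mutation model {model!r}")
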