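import numpy as np
import pytest

from phylogeopop.haplotypes import (
    HaplotypeAlignment,
    SequenceRecord,
    SiteInfo,
)


@pytest.fixture
def tiny_alignment():
    """Four 10-bp sequences, two populations, one shared haplotype."""
    recs = [
        SequenceRecord("p1|a", "AAAAAAAAAA", "p1"),
        SequenceRecord("p1|b", "AAAAAAAAAA", "p1"),
        SequenceRecord("p2|c", "AAAAAAAAAT", "p2"),
        SequenceRecord("p2|d", "AAAAAAATAT", "p2"),
    ]
    pops = {
        "p1": SiteInfo(latitude=26.0, longitude=-82.0, n=2),
        "p2": SiteInfo(latitude=30.0, longitude=-84.0, n=2),
    }
    return HaplotypeAlignment(records=recs, populations=pops)


@pytest.fixture
def structured_alignment():
    """Small planted-structure dataset: 2 groups of 3 populations, fixed
    haplotype differences between groups."""
    recs = []
    pops = {}
    for i in range(6):
        seq = "AAAAAAAAAA" if i < 3 else "TTTTTAAAAA"
        for s in range(4):
            recs.append(SequenceRecord(f"p{i}|s{s}", seq, f"p{i}"))
        pops[f"p{i}"] = SiteInfo(latitude=26.0 + i, longitude=-84.0 + 0.3 * i, n=4)
    return HaplotypeAlignment(records=recs, populations=pops)


def brute_force_amova(sq, pop_of, group_of_pop):
    """Nested sums-of-squares AMOVA oracle, written from the definitions."""
    import itertools

    n = len(pop_of)
    pops = sorted(set(pop_of))
    ind_group = [group_of_pop[p] for p in pop_of]
    sstot = sum(sq[i, j] for i in range(n) for j in range(i + 1, n)) / n
    sswp = 0.0
    for p in pops:
        idx = [i for i in range(n) if pop_of[i] == p]
        sswp += sum(sq[i, j] for i, j in itertools.combinations(idx, 2)) / len(idx)
    sswg = 0.0
    for g in sorted(set(group_of_pop.values())):
        idx = [i for i in range(n) if ind_group[i] == g]
        sswg += sum(sq[i, j] for i, j in itertools.combinations(idx, 2)) / len(idx)
    ssag, ssap = sstot - sswg, sswg - sswp
    G = len(set(group_of_pop.values()))
    P = len(pops)
    dfag, dfap, dfwp = G - 1, P - G, n - P
    sizes = {p: pop_of.count(p) for p in pops}
    Ng = {
        g: sum(sizes[p] for p in pops if group_of_pop[p] == g)
        for g in set(group_of_pop.values())
    }
    s1 = sum(sizes[p] ** 2 / Ng[group_of_pop[p]] for p in pops)
    nprime = (n - s1) / dfap if dfap > 0 else 0.0
    ndp = (s1 - sum(sizes[p] ** 2 for p in pops) / n) / dfag
    ntp = (n - sum(v ** 2 for v in Ng.values()) / n) / dfag
    sc = sswp / dfwp if dfwp > 0 else 0.0
    sb = ((ssap / dfap) - sc) / nprime if dfap > 0 and nprime > 0 else 0.0
    sa = ((ssag / dfag) - sc - ndp * sb) / ntp
    return sa, sb, sc


def brute_force_ndc(gene, pop, mapping):
    """Exhaustive-embedding deep-coalescence oracle: minimize the
    extra-lineage count over all ancestry-consistent placements of gene
    nodes on the population tree."""
    import itertools

    nodes = []

    def coll(nd):
        nodes.append(nd)
        for c in nd.children:
            coll(c)

    coll(pop)
    idx = {id(n): i for i, n in enumerate(nodes)}
    parent = [None] * len(nodes)
    for n in nodes:
        for c in n.children:
            parent[idx[id(c)]] = idx[id(n)]
    tipsets = [frozenset(n.leaf_names()) for n in nodes]
    tipidx = {n.name: i for i, n in enumerate(nodes) if n.is_leaf()}
    anc = []
    for i in range(len(nodes)):
        ch = []
        j = i
        while j is not None:
            ch.append(j)
            j = parent[j]
        anc.append(ch)

    gnodes = []

    def collg(nd):
        for c in nd.children:
            collg(c)
        if not nd.is_leaf():
            gnodes.append(nd)

    collg(gene.root)

    def leaves(nd):
        out, st = [], [nd]
        while st:
            x = st.pop()
            if x.is_leaf():
                out.append(x)
            else:
                st.extend(x.children)
        return out

    allowed = {}
    for gn in gnodes:
        pops_below = frozenset(mapping[l.name] for l in leaves(gn))
        allowed[id(gn)] = [
            i for i in range(len(nodes)) if pops_below <= tipsets[i]
        ]

    def placeof(nd, assign):
        return tipidx[mapping[nd.name]] if nd.is_leaf() else assign[id(nd)]

    rooti = idx[id(pop)]

    def cost(assign):
        exits = [0] * len(nodes)

        def walk(nd):
            for c in nd.children:
                walk(c)
                j = placeof(c, assign)
                b = placeof(nd, assign)
                while j != b:
                    exits[j] += 1
                    j = parent[j]

        walk(gene.root)
        j = placeof(gene.root, assign)
        while j != rooti:
            exits[j] += 1
            j = parent[j]
        return sum(e - 1 for i, e in enumerate(exits) if i != rooti and e > 0)

    def consistent(assign):
        for gn in gnodes:
            for c in gn.children:
                if assign[id(gn)] not in anc[placeof(c, assign)]:
                    return False
        return True

    best = None
    for combo in itertools.product(*[allowed[id(g)] for g in gnodes]):
        assign = {id(g): p for g, p in zip(gnodes, combo)}
        if not consistent(assign):
            continue
        c = cost(assign)
        if best is None or c < best:
            best = c
    return best
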