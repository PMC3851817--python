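"""Allozyme allele-frequency analyses: diversity, private alleles, Nei's
genetic distance, neighbor-joining, principal coordinates, latitudinal cline
regression, and nonparametric two-sample comparisons.
"""

from __future__ import annotations

import csv
import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, stats as _st

from .haplotypes import DistanceMatrix, InputError, SiteInfo


@dataclass
class AllozymeDataset:
    """Population x locus x allele frequency table with site metadata.

    ``freqs[(population, locus)]`` is a dict allele -> frequency summing to 1;
    ``populations`` maps a population label to its :class:`SiteInfo`.
    """

    populations: dict[str, SiteInfo]
    loci: list[str]
    freqs: dict[tuple[str, str], dict[str, float]]

    def __post_init__(self):
        for (pop, locus), d in self.freqs.items():
            s = sum(d.values())
            if abs(s - 1.0) > 1e-9:
                raise InputError(
                    f"frequencies for {pop}/{locus} sum to {s}, expected 1"
                )
        for pop, info in self.populations.items():
            if info.n < 1:
                raise InputError(f"population {pop} has N < 1")

    def pop_labels(self) -> list[str]:
        return sorted(self.populations)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["population", "locus", "allele", "freq", "n"])
            for (pop, locus), d in sorted(self.freqs.items()):
                for allele, f in sorted(d.items()):
                    w.writerow([pop, locus, allele, repr(f),
                                self.populations[pop].n])

    @classmethod
    def from_csv(cls, path, site_info: dict[str, SiteInfo] | None = None):
        freqs: dict[tuple[str, str], dict[str, float]] = {}
        loci = []
        ns: dict[str, int] = {}
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                key = (row["population"], row["locus"])
                freqs.setdefault(key, {})[row["allele"]] = float(row["freq"])
                if row["locus"] not in loci:
                    loci.append(row["locus"])
                ns[row["population"]] = int(row.get("n", 1) or 1)
        if site_info is None:
            site_info = {
                p: SiteInfo(latitude=0.0, longitude=0.0, n=ns.get(p, 1))
                for p in {k[0] for k in freqs}
            }
        return cls(populations=site_info, loci=loci, freqs=freqs)


def expected_heterozygosity(
    ds: AllozymeDataset, unbiased: bool = False
) -> dict[str, float]:
    """Per-population mean He over loci; He(locus) = 1 - sum p^2 (Nei's
    expected heterozygosity), with the 2N/(2N-1) small-sample correction
    behind ``unbiased``."""
    out = {}
    for pop in ds.pop_labels():
        vals = []
        for locus in ds.loci:
            d = ds.freqs.get((pop, locus))
            if d is None:
                continue
            he = 1.0 - sum(f * f for f in d.values())
            if unbiased:
                twoN = 2 * ds.populations[pop].n
                he *= twoN / (twoN - 1)
            vals.append(he)
        out[pop] = float(np.mean(vals)) if vals else float("nan")
    return out


def private_allele_richness(
    ds: AllozymeDataset, grouping: dict[str, str]
) -> dict[str, float]:
    """hp: per-group count of alleles present (nonzero frequency) in exactly
    one group, averaged over loci (presence-based, no rarefaction)."""
    groups = sorted(set(grouping.values()))
    if len(groups) < 2:
        raise InputError("private-allele richness needs at least 2 groups")
    hp = {g: 0.0 for g in groups}
    for locus in ds.loci:
        present: dict[str, set] = {g: set() for g in groups}
        for pop in ds.pop_labels():
            d = ds.freqs.get((pop, locus), {})
            g = grouping.get(pop)
            if g is None:
                continue
            present[g].update(a for a, f in d.items() if f > 0)
        for g in groups:
            others = set().union(*(present[h] for h in groups if h != g))
            hp[g] += len(present[g] - others)
    n_loci = len(ds.loci)
    return {g: v / n_loci for g, v in hp.items()}


def nei_unbiased_D(
    ds: AllozymeDataset, i: str, j: str
) -> float:
    """Nei (1978) unbiased genetic distance between populations i and j.

    Within-population identities are corrected by (2N sum p^2 - 1)/(2N - 1);
    D = -ln(mean Jxy / sqrt(mean Jx * mean Jy)) with loci averaged before the
    ratio.  Complete fixation on different alleles gives +inf.
    """
    jx, jy, jxy = [], [], []
    for locus in ds.loci:
        dx = ds.freqs.get((i, locus))
        dy = ds.freqs.get((j, locus))
        if dx is None or dy is None:
            continue
        twoNx = 2 * ds.populations[i].n
        twoNy = 2 * ds.populations[j].n
        sx = sum(f * f for f in dx.values())
        sy = sum(f * f for f in dy.values())
        jx.append((twoNx * sx - 1) / (twoNx - 1) if twoNx > 1 else sx)
        jy.append((twoNy * sy - 1) / (twoNy - 1) if twoNy > 1 else sy)
        alleles = set(dx) | set(dy)
        jxy.append(sum(dx.get(a, 0.0) * dy.get(a, 0.0) for a in alleles))
    if not jxy:
        raise InputError(f"populations {i} and {j} share no typed loci")
    mx, my, mxy = (float(np.mean(v)) for v in (jx, jy, jxy))
    denom = math.sqrt(max(mx, 0.0) * max(my, 0.0))
    if denom <= 0 or mxy <= 0:
        return math.inf
    I = mxy / denom
    if I <= 0:
        return math.inf
    # the small-sample correction can push I above 1 for very similar
    # populations; the conventional treatment is D = 0, not D < 0
    return max(-math.log(I), 0.0)


def nei_distance_matrix(ds: AllozymeDataset) -> DistanceMatrix:
    pops = ds.pop_labels()
    n = len(pops)
    vals = np.zeros((n, n))
    for a, b in itertools.combinations(range(n), 2):
        vals[a, b] = vals[b, a] = nei_unbiased_D(ds, pops[a], pops[b])
    finite = vals[np.isfinite(vals)]
    sat = []
    if np.isinf(vals).any():
        cap = 2 * finite.max() if finite.size and finite.max() > 0 else 1.0
        for a, b in zip(*np.where(np.isinf(vals))):
            if a < b:
                sat.append((pops[a], pops[b]))
        vals[np.isinf(vals)] = cap
    return DistanceMatrix(labels=pops, values=vals, saturated_pairs=sat)


# ---------------------------------------------------------------------------
# Neighbor-joining

@dataclass
class NJNode:
    name: str | None
    children: list[tuple["NJNode", float]] = field(default_factory=list)

    def is_leaf(self):
        return not self.children

    def newick(self) -> str:
        def sub(nd):
            if nd.is_leaf():
                return nd.name
            inner = ",".join(f"{sub(c)}:{bl:.6g}" for c, bl in nd.children)
            return f"({inner})"
        return sub(self) + ";"

    def leaf_names(self) -> list[str]:
        if self.is_leaf():
            return [self.name]
        out = []
        for c, _ in self.children:
            out.extend(c.leaf_names())
        return out


def neighbor_joining(distmat: DistanceMatrix, midpoint_root: bool = True) -> NJNode:
    """Saitou-Nei neighbor joining with the Studier-Keppler Q criterion.

    Negative branch lengths are clamped to zero with the negative amount
    transferred to the sister edge; the returned tree is midpoint-rooted on
    the longest leaf-to-leaf path unless ``midpoint_root`` is False (then an
    arbitrary trifurcating root is returned).
    """
    labels = list(distmat.labels)
    if len(labels) < 3:
        raise InputError("neighbor joining needs at least 3 taxa")
    D = distmat.values.astype(float).copy()
    nodes = [NJNode(name=l) for l in labels]
    active = list(range(len(labels)))

    while len(active) > 2:
        n = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (n - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        ai, aj = np.unravel_index(np.argmin(Q), Q.shape)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = D[i, j]
        bi = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (n - 2))
        bj = dij - bi
        # clamp negatives, transferring the deficit to the sister edge
        if bi < 0:
            bj += -bi
            bi = 0.0
        if bj < 0:
            bi += -bj
            bj = 0.0
        new = NJNode(name=None, children=[(nodes[i], bi), (nodes[j], bj)])
        nodes.append(new)
        new_idx = len(nodes) - 1
        D = np.pad(D, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            D[new_idx, k] = D[k, new_idx] = 0.5 * (D[i, k] + D[j, k] - dij)
        active = [k for k in active if k not in (i, j)] + [new_idx]

    i, j = active
    blen = max(D[i, j], 0.0)
    root = NJNode(name=None, children=[(nodes[i], blen / 2), (nodes[j], blen / 2)])
    unrooted = NJNode(name=None, children=[(nodes[i], blen), (nodes[j], 0.0)])
    if not midpoint_root:
        return unrooted
    return _midpoint_root(root)


def _leaf_depths(nd: NJNode, depth=0.0):
    if nd.is_leaf():
        return {nd.name: depth}
    out = {}
    for c, bl in nd.children:
        out.update(_leaf_depths(c, depth + bl))
    return out


def _tree_edges(nd: NJNode, edges=None, parent=None):
    if edges is None:
        edges = []
    for c, bl in nd.children:
        edges.append((nd, c, bl))
        _tree_edges(c, edges, nd)
    return edges


def _midpoint_root(root: NJNode) -> NJNode:
    """Re-root on the midpoint of the longest leaf-to-leaf path."""
    # build adjacency over the unrooted graph
    adj: dict[int, list[tuple[NJNode, float]]] = {}
    index: dict[int, NJNode] = {}

    def add(a, b, w):
        adj.setdefault(id(a), []).append((b, w))
        adj.setdefault(id(b), []).append((a, w))
        index[id(a)] = a
        index[id(b)] = b

    edges = _tree_edges(root)
    if len(root.children) == 2:
        # splice out the artificial degree-2 root from the unrooted graph
        (c1, w1), (c2, w2) = root.children
        edges = [(a, b, w) for a, b, w in edges if a is not root]
        edges.append((c1, c2, w1 + w2))
    for parent, child, bl in edges:
        add(parent, child, bl)

    leaves = [nd for nd in index.values() if nd.is_leaf()]

    def dists_from(src):
        dist = {id(src): 0.0}
        prev = {id(src): None}
        stack = [src]
        while stack:
            nd = stack.pop()
            for nb, w in adj[id(nd)]:
                if id(nb) not in dist:
                    dist[id(nb)] = dist[id(nd)] + w
                    prev[id(nb)] = nd
                    stack.append(nb)
        return dist, prev

    best = (-1.0, None, None)
    d0, _ = dists_from(leaves[0])
    far1 = max(leaves, key=lambda l: d0[id(l)])
    d1, prev1 = dists_from(far1)
    far2 = max(leaves, key=lambda l: d1[id(l)])
    path_len = d1[id(far2)]
    # walk back from far2 to far1 to find the midpoint edge
    path = [far2]
    while path[-1] is not far1:
        path.append(prev1[id(path[-1])])
    target = path_len / 2.0
    acc = 0.0
    for a, b in zip(path, path[1:]):
        w = next(w for nb, w in adj[id(a)] if nb is b)
        if acc + w >= target - 1e-12:
            # midpoint lies on edge a-b, at (target - acc) from a
            return _reroot_on_edge(adj, a, b, target - acc)
        acc += w
    return root


def _reroot_on_edge(adj, a: NJNode, b: NJNode, dist_from_a: float) -> NJNode:
    w_ab = next(w for nb, w in adj[id(a)] if nb is b)

    def build(nd: NJNode, came_from: NJNode) -> NJNode:
        kids = []
        for nb, w in adj[id(nd)]:
            if nb is came_from:
                continue
            kids.append((build(nb, nd), w))
        if not kids:
            return NJNode(name=nd.name)
        return NJNode(name=nd.name, children=kids)

    left = build(a, b)
    right = build(b, a)
    return NJNode(
        name=None,
        children=[(left, dist_from_a), (right, w_ab - dist_from_a)],
    )


# ---------------------------------------------------------------------------
# PCoA

@dataclass
class PCoAResult:
    coordinates: np.ndarray
    eigenvalues: np.ndarray
    percent_variance: np.ndarray
    labels: list[str]


def pcoa(distmat: DistanceMatrix) -> PCoAResult:
    """Principal coordinates via Gower double-centering of -D^2/2.

    Axes are ordered by eigenvalue; negative eigenvalues are reported but
    excluded from the positive-sum percentage denominator.
    """
    D = distmat.values
    n = len(distmat.labels)
    if n < 3:
        raise InputError("PCoA needs at least 3 objects")
    if np.allclose(D, 0):
        raise InputError("all-zero distance matrix")
    A = -0.5 * D ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    B = J @ A @ J
    evals, evecs = linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    pos = evals > 1e-12
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    pct = np.zeros_like(evals)
    pos_sum = evals[pos].sum()
    if pos_sum > 0:
        pct[pos] = 100.0 * evals[pos] / pos_sum
    return PCoAResult(
        coordinates=coords, eigenvalues=evals, percent_variance=pct,
        labels=list(distmat.labels),
    )


# ---------------------------------------------------------------------------
# Cline regression and two-sample tests

@dataclass
class ClineRegression:
    slope: float
    intercept: float
    r_squared: float
    t: float
    p: float
    n: int


def cline_regression(values: dict[str, float], latitudes: dict[str, float]) -> ClineRegression:
    """OLS of a per-population statistic on latitude, exact t-test p."""
    pops = sorted(set(values) & set(latitudes))
    if len(pops) < 3:
        raise InputError("cline regression needs at least 3 populations")
    x = np.array([latitudes[p] for p in pops])
    y = np.array([values[p] for p in pops])
    if np.std(x) == 0:
        raise InputError("zero latitude variance")
    res = _st.linregress(x, y)
    t = res.slope / res.stderr if res.stderr > 0 else math.inf
    return ClineRegression(
        slope=res.slope, intercept=res.intercept,
        r_squared=res.rvalue ** 2, t=t, p=res.pvalue, n=len(pops),
    )


@dataclass
class TwoSampleTests:
    U: float
    z: float
    p_mw: float
    D: float
    p_ks: float


def two_sample_tests(a, b) -> TwoSampleTests:
    """Mann-Whitney U (exact when n+m <= 12, tie-corrected normal otherwise)
    and two-sample Kolmogorov-Smirnov with matching exact/asymptotic rule."""
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise InputError("both samples must be nonempty")
    small = a.size + b.size <= 12
    ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    method = "exact" if (small and not ties) else "asymptotic"
    mw = _st.mannwhitneyu(a, b, alternative="two-sided", method=method)
    U = min(mw.statistic, a.size * b.size - mw.statistic)
    mu = a.size * b.size / 2.0
    allv = np.concatenate([a, b])
    nm = a.size + b.size
    _, tie_counts = np.unique(allv, return_counts=True)
    tie_term = np.sum(tie_counts ** 3 - tie_counts) / (nm * (nm - 1))
    sigma = math.sqrt(a.size * b.size / 12.0 * ((nm + 1) - tie_term))
    z = (U - mu) / sigma if sigma > 0 else 0.0
    ks = _st.ks_2samp(a, b, method="exact" if small else "asymp")
    return TwoSampleTests(
        U=float(U), z=float(z), p_mw=float(mw.pvalue),
        D=float(ks.statistic), p_ks=float(ks.pvalue),
    )
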