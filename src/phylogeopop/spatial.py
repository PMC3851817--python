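"""Spatial genetic structure: AMOVA Phi-statistics, SAMOVA clustering,
Monmonier barrier inference with bootstrap support, and Mantel tests.

AMOVA follows the Excoffier method-of-moments decomposition of molecular
variance from a matrix of pairwise differences (used directly as squared
Euclidean distances).  SAMOVA searches, by simulated annealing over
Delaunay-contiguous partitions, for the grouping of populations that
maximizes the among-group fixation index Phi_CT.  Monmonier's
maximum-difference algorithm traces barriers across the Delaunay
triangulation of sampling sites, with edge support from bootstrap
resampling of alignment columns.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay, QhullError

from .haplotypes import (
    MISSING,
    DistanceMatrix,
    HaplotypeAlignment,
    InputError,
    base_frequencies,
)


@dataclass
class PhiStatistics:
    sigma2_a: float
    sigma2_b: float
    sigma2_c: float
    Phi_CT: float
    Phi_SC: float
    Phi_ST: float
    percent_among: float
    p_values: dict = field(default_factory=dict)
    df: tuple = ()


@dataclass
class SpatialPartition:
    K: int
    assignment: dict[str, int]
    contiguity_graph: list[tuple[str, str]]
    Phi_CT: float
    replicate_scores: list[float]
    p_value: float | None = None


@dataclass
class Barrier:
    edges: list[tuple[str, str]]
    support: list[float] | None = None
    mean_support: float | None = None
    degenerate: bool = False


# ---------------------------------------------------------------------------
# AMOVA

def _group_pop_sums(sq: np.ndarray, pop_of: list[int], n_pops: int):
    """Per-population-pair sums of squared distances and sizes."""
    sizes = np.bincount(pop_of, minlength=n_pops).astype(float)
    P = np.zeros((n_pops, n_pops))
    idx = np.asarray(pop_of)
    for p in range(n_pops):
        for q in range(p, n_pops):
            block = sq[np.ix_(idx == p, idx == q)]
            P[p, q] = P[q, p] = block.sum()
    return P, sizes


def _amova_components(P, sizes, group_of):
    """Variance components from population-pair aggregates.

    P[p, q] = sum over i in p, j in q of d^2(i, j) (full, both orders);
    SS within a unit U = sum_{i<j in U} d^2 / N_U = (sum_full / 2) / N_U.
    """
    n_pops = len(sizes)
    groups = sorted(set(group_of))
    N = sizes.sum()
    ss_total = P.sum() / 2.0 / N
    ss_wp = sum(P[p, p] / 2.0 / sizes[p] for p in range(n_pops) if sizes[p] > 0)
    ss_wg = 0.0
    for g in groups:
        members = [p for p in range(n_pops) if group_of[p] == g]
        Ng = sizes[members].sum()
        ss_g = P[np.ix_(members, members)].sum() / 2.0 / Ng
        ss_wg += ss_g
    ss_ag = ss_total - ss_wg
    ss_apwg = ss_wg - ss_wp

    G = len(groups)
    Pn = n_pops
    df_ag = G - 1
    df_ap = Pn - G
    df_wp = int(N) - Pn

    # coefficients (Excoffier et al. nested design)
    sum_n2_over_ng = 0.0
    sum_ng2 = 0.0
    for g in groups:
        members = [p for p in range(n_pops) if group_of[p] == g]
        Ng = sizes[members].sum()
        sum_n2_over_ng += float(np.sum(sizes[members] ** 2)) / Ng
        sum_ng2 += Ng ** 2
    sum_n2 = float(np.sum(sizes ** 2))
    n_prime = (N - sum_n2_over_ng) / df_ap if df_ap > 0 else 0.0
    n_dprime = (sum_n2_over_ng - sum_n2 / N) / df_ag if df_ag > 0 else 0.0
    n_tprime = (N - sum_ng2 / N) / df_ag if df_ag > 0 else 0.0

    sigma_c = ss_wp / df_wp if df_wp > 0 else 0.0
    if df_ap > 0 and n_prime > 0:
        ms_ap = ss_apwg / df_ap
        sigma_b = (ms_ap - sigma_c) / n_prime
    else:
        sigma_b = 0.0
    ms_ag = ss_ag / df_ag if df_ag > 0 else 0.0
    sigma_a = (ms_ag - sigma_c - n_dprime * sigma_b) / n_tprime if n_tprime > 0 else 0.0
    return sigma_a, sigma_b, sigma_c, (df_ag, df_ap, df_wp)


def amova(
    distmat: DistanceMatrix,
    populations: dict[str, str],
    groups: dict[str, str] | None = None,
    permutations: int = 1000,
    seed: int | None = None,
) -> PhiStatistics:
    """Hierarchical AMOVA on a matrix of pairwise differences.

    ``populations`` maps individual label -> population; ``groups`` maps
    population -> group (a single group yields the two-level design, with
    Phi_ST only).  Permutation p-values: Phi_CT permutes whole populations
    among groups (sizes kept), Phi_ST permutes individuals among populations.
    """
    labels = distmat.labels
    pops = sorted({populations[l] for l in labels})
    pop_index = {p: i for i, p in enumerate(pops)}
    pop_of = [pop_index[populations[l]] for l in labels]
    if groups is None:
        groups = {p: "all" for p in pops}
    group_labels = sorted(set(groups.values()))
    group_of = [group_labels.index(groups[p]) for p in pops]
    if any(np.bincount(group_of, minlength=len(group_labels)) < 1):
        raise InputError("every group needs at least one population")

    sq = distmat.values  # pairwise differences treated as squared distances
    P, sizes = _group_pop_sums(sq, pop_of, len(pops))
    sigma_a, sigma_b, sigma_c, dfs = _amova_components(P, sizes, group_of)
    total = sigma_a + sigma_b + sigma_c
    if total <= 0:
        raise InputError("zero total molecular variance")
    phi_ct = sigma_a / total
    phi_st = (sigma_a + sigma_b) / total
    phi_sc = sigma_b / (sigma_b + sigma_c) if (sigma_b + sigma_c) != 0 else 0.0

    p_values = {}
    if permutations and len(group_labels) > 1:
        rng = np.random.default_rng(seed)
        count_ct = 0
        garr = np.array(group_of)
        for _ in range(permutations):
            perm = rng.permutation(garr)
            sa, sb, sc, _ = _amova_components(P, sizes, list(perm))
            tot = sa + sb + sc
            if tot > 0 and sa / tot >= phi_ct - 1e-12:
                count_ct += 1
        p_values["Phi_CT"] = (1 + count_ct) / (permutations + 1)
    if permutations:
        rng = np.random.default_rng(None if seed is None else seed + 1)
        count_st = 0
        parr = np.array(pop_of)
        for _ in range(permutations):
            perm = rng.permutation(parr)
            Pp, sz = _group_pop_sums(sq, list(perm), len(pops))
            sa, sb, sc, _ = _amova_components(Pp, sz, group_of)
            tot = sa + sb + sc
            if tot > 0 and (sa + sb) / tot >= phi_st - 1e-12:
                count_st += 1
        p_values["Phi_ST"] = (1 + count_st) / (permutations + 1)

    return PhiStatistics(
        sigma2_a=sigma_a, sigma2_b=sigma_b, sigma2_c=sigma_c,
        Phi_CT=phi_ct, Phi_SC=phi_sc, Phi_ST=phi_st,
        percent_among=100.0 * sigma_a / total, p_values=p_values, df=dfs,
    )


def pairwise_phist(
    aln_or_distmat, populations: dict[str, str], linearize: bool = False
) -> DistanceMatrix:
    """Pairwise Phi_ST between populations from two-population AMOVAs on
    pairwise differences; optionally linearized as Phi/(1-Phi) (negative
    values truncated to 0; Phi_ST = 1 flagged infinite and capped)."""
    if isinstance(aln_or_distmat, HaplotypeAlignment):
        from .haplotypes import distance_matrix

        distmat = distance_matrix(aln_or_distmat, metric="differences")
    else:
        distmat = aln_or_distmat
    labels = distmat.labels
    pops = sorted({populations[l] for l in labels})
    for p in pops:
        if sum(1 for l in labels if populations[l] == p) < 2:
            raise InputError(f"population {p!r} has fewer than 2 individuals")
    vals = np.zeros((len(pops), len(pops)))
    flagged = []
    for a, b in itertools.combinations(range(len(pops)), 2):
        keep = [l for l in labels if populations[l] in (pops[a], pops[b])]
        idx = [labels.index(l) for l in keep]
        sub = DistanceMatrix(labels=keep, values=distmat.values[np.ix_(idx, idx)])
        sub_pops = {l: populations[l] for l in keep}
        # two-level design: populations are the "groups" of a 2-level AMOVA
        sq = sub.values
        pop_of = [0 if sub_pops[l] == pops[a] else 1 for l in keep]
        P, sizes = _group_pop_sums(sq, pop_of, 2)
        # one-level nesting: treat populations as groups with one pop each
        sa, sb, sc, _ = _amova_components(P, sizes, [0, 1])
        tot = sa + sb + sc
        phi = (sa + sb) / tot if tot > 0 else 0.0
        vals[a, b] = vals[b, a] = phi
    if linearize:
        lin = np.zeros_like(vals)
        finite_max = 0.0
        for i, j in itertools.combinations(range(len(pops)), 2):
            phi = max(0.0, vals[i, j])
            if phi >= 1.0 - 1e-12:
                flagged.append((pops[i], pops[j]))
                lin[i, j] = lin[j, i] = np.inf
            else:
                lin[i, j] = lin[j, i] = phi / (1.0 - phi)
                finite_max = max(finite_max, lin[i, j])
        if flagged:
            warnings.warn(
                f"{len(flagged)} pair(s) with Phi_ST = 1 excluded from "
                "linearized analyses"
            )
            lin[np.isinf(lin)] = 2.0 * finite_max if finite_max > 0 else 1.0
        vals = lin
    vals = np.where(vals < 0, 0.0, vals)
    return DistanceMatrix(labels=pops, values=vals, saturated_pairs=flagged)


# ---------------------------------------------------------------------------
# SAMOVA

def _delaunay_edges(coord_list: list[tuple[float, float]]):
    pts = np.asarray(coord_list, dtype=float)
    if len(pts) < 2:
        return [], None
    if len(pts) == 2:
        return [(0, 1)], None
    try:
        tri = Delaunay(pts)
    except QhullError:
        warnings.warn("collinear sites: coordinates jittered by 1e-6 degrees")
        rng = np.random.default_rng(0)
        pts = pts + rng.normal(scale=1e-6, size=pts.shape)
        tri = Delaunay(pts)
    edges = set()
    for simplex in tri.simplices:
        for a, b in itertools.combinations(simplex, 2):
            edges.add((min(a, b), max(a, b)))
    return sorted(edges), tri


def samova(
    aln: HaplotypeAlignment,
    coords: dict[str, tuple[float, float]] | None = None,
    K: int = 2,
    starts: int = 100,
    iters: int = 10000,
    seed: int | None = None,
    permutations: int = 1000,
) -> SpatialPartition:
    """Spatial analysis of molecular variance: simulated-annealing search for
    the Delaunay-contiguous K-partition of populations maximizing Phi_CT.

    Coordinates default to the alignment's population table.  The best
    partition over all random starts is returned, with a permutation p-value
    for its Phi_CT.
    """
    pops = sorted({r.population for r in aln.records if r.population})
    if coords is None:
        coords = {
            p: (info.latitude, info.longitude) for p, info in aln.populations.items()
        }
    if K < 2:
        raise InputError("K must be at least 2")
    if K > len(pops):
        raise InputError(f"K={K} exceeds the {len(pops)} populations")

    from .haplotypes import pairwise_difference_matrix

    pop_of = [pops.index(r.population) for r in aln.records]
    sq = pairwise_difference_matrix(aln)
    P, sizes = _group_pop_sums(sq, pop_of, len(pops))

    edge_list, _ = _delaunay_edges([coords[p] for p in pops])
    adj = {i: set() for i in range(len(pops))}
    for a, b in edge_list:
        adj[a].add(b)
        adj[b].add(a)

    def phi_ct_of(assign: np.ndarray) -> float:
        sa, sb, sc, _ = _amova_components(P, sizes, list(assign))
        tot = sa + sb + sc
        return sa / tot if tot > 0 else -np.inf

    rng = np.random.default_rng(seed)

    def grow_partition() -> np.ndarray:
        assign = -np.ones(len(pops), dtype=int)
        seeds = rng.choice(len(pops), size=K, replace=False)
        for g, s in enumerate(seeds):
            assign[s] = g
        frontier = True
        while (assign < 0).any():
            progressed = False
            order = rng.permutation(len(pops))
            for p in order:
                if assign[p] >= 0:
                    continue
                neigh_groups = {assign[q] for q in adj[p] if assign[q] >= 0}
                if neigh_groups:
                    assign[p] = rng.choice(sorted(neigh_groups))
                    progressed = True
            if not progressed:
                # disconnected graph: place remaining in a random group
                for p in np.where(assign < 0)[0]:
                    assign[p] = rng.integers(K)
        return assign

    def boundary_moves(assign):
        moves = []
        counts = np.bincount(assign, minlength=K)
        for p in range(len(pops)):
            if counts[assign[p]] <= 1:
                continue
            for q in adj[p]:
                if assign[q] != assign[p]:
                    moves.append((p, assign[q]))
        return moves

    best_assign = None
    best_score = -np.inf
    replicate_scores = []
    for _ in range(max(1, starts)):
        assign = grow_partition()
        score = phi_ct_of(assign)
        # calibrate start temperature from probe moves (~80% acceptance)
        probe_deltas = []
        for _ in range(20):
            mv = boundary_moves(assign)
            if not mv:
                break
            p, g = mv[rng.integers(len(mv))]
            old = assign[p]
            assign[p] = g
            probe_deltas.append(abs(phi_ct_of(assign) - score))
            assign[p] = old
        t_cur = (np.median(probe_deltas) / 0.223) if probe_deltas else 0.01
        t_cur = max(t_cur, 1e-6)
        cur_best, cur_best_assign = score, assign.copy()
        for it in range(iters):
            mv = boundary_moves(assign)
            if not mv:
                break
            p, g = mv[rng.integers(len(mv))]
            old = assign[p]
            assign[p] = g
            new_score = phi_ct_of(assign)
            delta = new_score - score
            if delta >= 0 or rng.random() < math.exp(delta / t_cur):
                score = new_score
                if score > cur_best:
                    cur_best, cur_best_assign = score, assign.copy()
            else:
                assign[p] = old
            if (it + 1) % 100 == 0:
                t_cur *= 0.95
        replicate_scores.append(cur_best)
        if cur_best > best_score:
            best_score = cur_best
            best_assign = cur_best_assign

    p_value = None
    if permutations:
        prng = np.random.default_rng(None if seed is None else seed + 99)
        count = 0
        for _ in range(permutations):
            perm = prng.permutation(best_assign)
            if phi_ct_of(perm) >= best_score - 1e-12:
                count += 1
        p_value = (1 + count) / (permutations + 1)

    return SpatialPartition(
        K=K,
        assignment={p: int(g) for p, g in zip(pops, best_assign)},
        contiguity_graph=[(pops[a], pops[b]) for a, b in edge_list],
        Phi_CT=float(best_score),
        replicate_scores=replicate_scores,
        p_value=p_value,
    )


# ---------------------------------------------------------------------------
# Monmonier barriers

def _trace_barrier(dist: np.ndarray, tri: Delaunay, crossed: set) -> list:
    """One maximum-difference barrier across the triangulation.

    Starts at the uncrossed Delaunay edge with maximal distance, then extends
    from both ends: entering a triangle through an edge, it exits through the
    adjacent edge of maximal distance not yet crossed, stopping at the convex
    hull or when closing a loop.  Ties break toward the lower edge index
    (sorted vertex pairs).
    """
    # adjacency: edge -> triangles containing it
    edge_tris: dict[tuple, list[int]] = {}
    for t_idx, simplex in enumerate(tri.simplices):
        for a, b in itertools.combinations(sorted(simplex), 2):
            edge_tris.setdefault((a, b), []).append(t_idx)

    candidates = [e for e in edge_tris if e not in crossed]
    if not candidates:
        return []
    start = max(candidates, key=lambda e: (dist[e[0], e[1]], [-e[0], -e[1]]))
    path = [start]
    crossed_local = {start}

    def extend(direction_tri, edge, prepend):
        while direction_tri is not None:
            simplex = sorted(tri.simplices[direction_tri])
            others = [
                tuple(sorted(pair))
                for pair in itertools.combinations(simplex, 2)
                if tuple(sorted(pair)) != edge
            ]
            options = [e for e in others if e not in crossed_local and e not in crossed]
            if not options:
                return
            nxt = max(options, key=lambda e: (dist[e[0], e[1]], [-e[0], -e[1]]))
            crossed_local.add(nxt)
            if prepend:
                path.insert(0, nxt)
            else:
                path.append(nxt)
            tris = edge_tris[nxt]
            nxt_tris = [t for t in tris if t != direction_tri]
            direction_tri = nxt_tris[0] if nxt_tris else None
            edge = nxt

    tris = edge_tris[start]
    if len(tris) >= 1:
        extend(tris[0], start, prepend=False)
    if len(tris) >= 2:
        extend(tris[1], start, prepend=True)
    return path


def monmonier_barriers(
    distmat: DistanceMatrix,
    coords: dict[str, tuple[float, float]],
    n_barriers: int = 1,
    bootstrap_alignment: HaplotypeAlignment | None = None,
    bootstrap_populations: dict[str, str] | None = None,
    bootstrap_reps: int = 100,
    seed: int | None = None,
) -> list[Barrier]:
    """Monmonier maximum-difference barriers on the Delaunay triangulation.

    When ``bootstrap_alignment`` is given, alignment columns are resampled
    with replacement ``bootstrap_reps`` times, a population-profile
    Tamura-Nei distance matrix is recomputed for each replicate, and each
    observed barrier edge's support is the percentage of replicate barriers
    crossing it.
    """
    labels = distmat.labels
    pts = [coords[l] for l in labels]
    if len(labels) < 3:
        raise InputError("need at least 3 sites for a triangulation")
    edge_list, tri = _delaunay_edges(pts)
    if tri is None:
        raise InputError("triangulation failed")
    vals = distmat.values
    degenerate = bool(np.allclose(vals[np.triu_indices(len(labels), 1)],
                                  vals[np.triu_indices(len(labels), 1)][0]))

    crossed: set = set()
    barriers = []
    for _ in range(n_barriers):
        path = _trace_barrier(vals, tri, crossed)
        if not path:
            break
        crossed.update(path)
        barriers.append(
            Barrier(
                edges=[(labels[a], labels[b]) for a, b in path],
                degenerate=degenerate,
            )
        )

    if bootstrap_alignment is not None and barriers:
        supports = _bootstrap_support(
            barriers, bootstrap_alignment, bootstrap_populations, labels,
            tri, n_barriers, bootstrap_reps, seed,
        )
        for b, sup in zip(barriers, supports):
            b.support = sup
            b.mean_support = float(np.mean(sup)) if sup else None
    return barriers


def population_profile_tn93(
    aln: HaplotypeAlignment, populations: dict[str, str],
    labels: list[str], column_weights: np.ndarray | None = None,
) -> np.ndarray:
    """TN93 distances between population allele-frequency profiles.

    For each column, the expected transition/transversion mismatch fractions
    between two populations are cross products of their base frequencies;
    weighted column sums feed the TN93 closed form (weights implement column
    bootstrap).
    """
    L = aln.site_count
    P = len(labels)
    lab_idx = {l: i for i, l in enumerate(labels)}
    base_idx = {b: i for i, b in enumerate("ACGT")}
    # per-column per-population base frequencies
    freqs = np.zeros((L, P, 4))
    counts = np.zeros((L, P, 4))
    for r in aln.records:
        p = lab_idx.get(populations.get(r.id, r.population))
        if p is None:
            continue
        for c, ch in enumerate(r.sequence):
            bi = base_idx.get(ch)
            if bi is not None:
                counts[c, p, bi] += 1
    tot = counts.sum(axis=2, keepdims=True)
    with np.errstate(invalid="ignore"):
        freqs = np.where(tot > 0, counts / np.where(tot == 0, 1, tot), 0.25)

    if column_weights is None:
        column_weights = np.ones(L)
    w = column_weights / column_weights.sum() if column_weights.sum() else column_weights

    A, C, G, T = (freqs[:, :, i] for i in range(4))
    # per-column cross products -> (L, P, P)
    P1c = np.einsum("lp,lq->lpq", A, G) + np.einsum("lp,lq->lpq", G, A)
    P2c = np.einsum("lp,lq->lpq", C, T) + np.einsum("lp,lq->lpq", T, C)
    R = A + G
    Y = C + T
    Qc = np.einsum("lp,lq->lpq", R, Y) + np.einsum("lp,lq->lpq", Y, R)
    P1 = np.einsum("l,lpq->pq", w, P1c)
    P2 = np.einsum("l,lpq->pq", w, P2c)
    Qm = np.einsum("l,lpq->pq", w, Qc)

    gfreq = base_frequencies(aln)
    gA, gC, gG, gT = (gfreq[b] for b in "ACGT")
    gR, gY = gA + gG, gC + gT
    k1 = 2 * gA * gG / gR
    k2 = 2 * gC * gT / gY
    k3 = 2 * (gR * gY - gA * gG * gY / gR - gC * gT * gR / gY)
    with np.errstate(invalid="ignore", divide="ignore"):
        w1 = 1 - P1 / k1 - Qm / (2 * gR)
        w2 = 1 - P2 / k2 - Qm / (2 * gY)
        w3 = 1 - Qm / (2 * gR * gY)
        d = -k1 * np.log(w1) - k2 * np.log(w2) - k3 * np.log(w3)
    d = np.where(np.isfinite(d), d, np.nan)
    finite = d[~np.isnan(d)]
    finite_max = float(finite.max()) if finite.size and finite.max() > 0 else 1.0
    d = np.where(np.isnan(d), 2 * finite_max, d)
    np.fill_diagonal(d, 0.0)
    return (d + d.T) / 2.0


def _bootstrap_support(
    barriers, aln, populations, labels, tri, n_barriers, reps, seed
):
    rng = np.random.default_rng(seed)
    if populations is None:
        populations = {r.id: r.population for r in aln.records}
    L = aln.site_count
    cross_counts = [dict() for _ in barriers]
    lab_idx = {l: i for i, l in enumerate(labels)}
    obs_edges = [
        [(lab_idx[a], lab_idx[b]) for a, b in bar.edges] for bar in barriers
    ]
    for _ in range(reps):
        wts = np.bincount(rng.integers(0, L, size=L), minlength=L).astype(float)
        d = population_profile_tn93(aln, populations, labels, column_weights=wts)
        crossed: set = set()
        for _b in range(len(barriers)):
            path = _trace_barrier(d, tri, crossed)
            crossed.update(tuple(sorted(e)) for e in path)
        for b_i, edges in enumerate(obs_edges):
            for e in edges:
                key = tuple(sorted(e))
                if key in crossed:
                    cross_counts[b_i][key] = cross_counts[b_i].get(key, 0) + 1
    supports = []
    for b_i, edges in enumerate(obs_edges):
        sup = [
            100.0 * cross_counts[b_i].get(tuple(sorted(e)), 0) / reps
            for e in edges
        ]
        supports.append(sup)
    return supports


# ---------------------------------------------------------------------------
# Mantel

def mantel(
    m1: DistanceMatrix, m2: DistanceMatrix,
    permutations: int = 10000, seed: int | None = None,
) -> tuple[float, float]:
    """Mantel correlation between two distance matrices with one-tailed
    (positive-association) permutation p; exact enumeration when n <= 7."""
    if m1.labels != m2.labels:
        raise InputError("matrices must share labels and order")
    n = len(m1.labels)
    if n < 4:
        raise InputError("Mantel test needs at least 4 objects")
    iu = np.triu_indices(n, k=1)
    x = m1.values[iu]
    y = m2.values[iu]
    if np.std(x) == 0 or np.std(y) == 0:
        raise InputError("constant distance matrix: correlation undefined")
    r_obs = float(np.corrcoef(x, y)[0, 1])

    B = m2.values
    if n <= 7:
        perms = list(itertools.permutations(range(n)))
        count = sum(
            1
            for p in perms
            if np.corrcoef(x, B[np.ix_(p, p)][iu])[0, 1] >= r_obs - 1e-12
        )
        p_val = count / len(perms)
    else:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(permutations):
            p = rng.permutation(n)
            if np.corrcoef(x, B[np.ix_(p, p)][iu])[0, 1] >= r_obs - 1e-12:
                count += 1
        p_val = (1 + count) / (permutations + 1)
    return r_obs, p_val
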