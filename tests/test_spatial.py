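import itertools

import numpy as np
import pytest

from conftest import brute_force_amova

from phylogeopop.haplotypes import (
    DistanceMatrix,
    HaplotypeAlignment,
    InputError,
    SequenceRecord,
    SiteInfo,
)
from phylogeopop.spatial import (
    amova,
    mantel,
    monmonier_barriers,
    pairwise_phist,
    population_profile_tn93,
    samova,
    _amova_components,
    _group_pop_sums,
)


class TestAmova:
    def _random_case(self, rng):
        npop = int(rng.integers(2, 5))
        sizes = [int(rng.integers(2, 4)) for _ in range(npop)]
        pop_of = [p for p, s in enumerate(sizes) for _ in range(s)]
        while True:
            groups = {p: int(rng.integers(0, 2)) for p in range(npop)}
            if len(set(groups.values())) == 2:
                break
        n = len(pop_of)
        a = np.triu(rng.random((n, n)), 1)
        return a + a.T, pop_of, groups

    def test_components_match_bruteforce_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            sq, pop_of, groups = self._random_case(rng)
            P, sizes = _group_pop_sums(sq, pop_of, len(set(pop_of)))
            mine = _amova_components(P, sizes, [groups[p] for p in
                                                sorted(set(pop_of))])[:3]
            oracle = brute_force_amova(sq, pop_of, groups)
            assert np.allclose(mine, oracle)

    def test_fixed_groups_phi_ct_one(self):
        labels = [f"i{k}" for k in range(8)]
        pops = {l: f"p{k // 2}" for k, l in enumerate(labels)}
        groups = {"p0": "g1", "p1": "g1", "p2": "g2", "p3": "g2"}
        sq = np.zeros((8, 8))
        for i in range(8):
            for j in range(8):
                if (i < 4) != (j < 4):
                    sq[i, j] = 1.0
        res = amova(DistanceMatrix(labels=labels, values=sq), pops, groups,
                    permutations=0)
        assert res.Phi_CT == pytest.approx(1.0)
        assert res.percent_among == pytest.approx(100.0)

    def test_identical_groups_phi_ct_zero(self):
        labels = [f"i{k}" for k in range(8)]
        pops = {l: f"p{k // 2}" for k, l in enumerate(labels)}
        groups = {"p0": "g1", "p1": "g1", "p2": "g2", "p3": "g2"}
        sq = np.ones((8, 8)) - np.eye(8)
        res = amova(DistanceMatrix(labels=labels, values=sq), pops, groups,
                    permutations=0)
        assert abs(res.Phi_CT) < 1e-12

    def test_permutation_p_values_present(self):
        rng = np.random.default_rng(1)
        labels = [f"i{k}" for k in range(12)]
        pops = {l: f"p{k // 3}" for k, l in enumerate(labels)}
        groups = {"p0": "g1", "p1": "g1", "p2": "g2", "p3": "g2"}
        a = np.triu(rng.random((12, 12)), 1)
        res = amova(DistanceMatrix(labels=labels, values=a + a.T), pops,
                    groups, permutations=200, seed=0)
        assert 0 < res.p_values["Phi_CT"] <= 1
        assert 0 < res.p_values["Phi_ST"] <= 1


class TestPairwisePhist:
    def _aln(self, seq_by_pop, per=3):
        recs = []
        for pop, seq in seq_by_pop.items():
            for s in range(per):
                recs.append(SequenceRecord(f"{pop}|s{s}", seq, pop))
        return HaplotypeAlignment(records=recs)

    def test_identical_populations_zero(self):
        aln = self._aln({"a": "AAAA", "b": "AAAA"})
        dm = pairwise_phist(aln, {r.id: r.population for r in aln.records})
        assert dm.values[0, 1] == pytest.approx(0.0)

    def test_fixed_difference_flags_infinite_linearization(self):
        aln = self._aln({"a": "AAAA", "b": "TTTT"})
        with pytest.warns(UserWarning, match="Phi_ST = 1"):
            dm = pairwise_phist(aln, {r.id: r.population for r in aln.records},
                                linearize=True)
        assert dm.saturated_pairs == [("a", "b")]

    def test_matches_two_population_oracle(self):
        rng = np.random.default_rng(3)
        seqs = {"a": "AAAAAA", "b": "AATTAA"}
        recs = []
        for pop, seq in seqs.items():
            for s in range(3):
                mutated = list(seq)
                if rng.random() < 0.5:
                    mutated[5] = "G"
                recs.append(SequenceRecord(f"{pop}|s{s}", "".join(mutated), pop))
        aln = HaplotypeAlignment(records=recs)
        dm = pairwise_phist(aln, {r.id: r.population for r in aln.records})
        from phylogeopop.haplotypes import pairwise_difference_matrix

        sq = pairwise_difference_matrix(aln)
        pop_of = [0 if r.population == "a" else 1 for r in aln.records]
        sa, sb, sc = brute_force_amova(sq, pop_of, {0: 0, 1: 1})
        assert dm.values[0, 1] == pytest.approx((sa + sb) / (sa + sb + sc))

    def test_small_population_rejected(self):
        aln = self._aln({"a": "AAAA", "b": "TTTT"}, per=1)
        with pytest.raises(InputError):
            pairwise_phist(aln, {r.id: r.population for r in aln.records})


def _planted_alignment(n_pops=6, per=4, split=3, lat0=26.0):
    recs, pops = [], {}
    for i in range(n_pops):
        seq = "AAAAAAAAAA" if i < split else "TTTTTAAAAA"
        for s in range(per):
            recs.append(SequenceRecord(f"p{i}|s{s}", seq, f"p{i}"))
        pops[f"p{i}"] = SiteInfo(latitude=lat0 + i, longitude=-84.0 + 0.4 * (i % 2), n=per)
    return HaplotypeAlignment(records=recs, populations=pops)


class TestSamova:
    def test_planted_two_group_split(self):
        aln = _planted_alignment()
        part = samova(aln, K=2, starts=5, iters=500, seed=3, permutations=0)
        g_left = {part.assignment[f"p{i}"] for i in range(3)}
        g_right = {part.assignment[f"p{i}"] for i in range(3, 6)}
        assert len(g_left) == 1 and len(g_right) == 1 and g_left != g_right
        assert part.Phi_CT == pytest.approx(1.0)

    def test_seed_determinism(self):
        aln = _planted_alignment()
        a = samova(aln, K=2, starts=3, iters=300, seed=7, permutations=0)
        b = samova(aln, K=2, starts=3, iters=300, seed=7, permutations=0)
        assert a.assignment == b.assignment and a.Phi_CT == b.Phi_CT

    def test_k_bounds(self):
        aln = _planted_alignment()
        with pytest.raises(InputError):
            samova(aln, K=7, starts=1, iters=10)
        with pytest.raises(InputError):
            samova(aln, K=1, starts=1, iters=10)

    def test_objective_not_below_planted_partition(self):
        aln = _planted_alignment()
        part = samova(aln, K=2, starts=5, iters=500, seed=11, permutations=0)
        from phylogeopop.haplotypes import pairwise_difference_matrix
        from phylogeopop.spatial import _group_pop_sums, _amova_components

        sq = pairwise_difference_matrix(aln)
        pop_of = [int(r.population[1]) for r in aln.records]
        P, sizes = _group_pop_sums(sq, pop_of, 6)
        sa, sb, sc, _ = _amova_components(P, sizes, [0, 0, 0, 1, 1, 1])
        planted = sa / (sa + sb + sc)
        assert part.Phi_CT >= planted - 1e-12


class TestMonmonier:
    def test_square_barrier(self):
        coords = {"a": (0, 0), "b": (0, 1), "c": (1, 0), "d": (1, 1)}
        vals = np.array([[0, 1, 10, 10], [1, 0, 10, 10],
                         [10, 10, 0, 1], [10, 10, 1, 0]], float)
        bars = monmonier_barriers(
            DistanceMatrix(labels=list("abcd"), values=vals), coords
        )
        crossed = {frozenset(e) for e in bars[0].edges}
        # every crossed edge separates {a,b} from {c,d}
        assert all(
            len(e & {"a", "b"}) == 1 for e in crossed
        )
        assert frozenset({"a", "c"}) in crossed and frozenset({"b", "d"}) in crossed

    def test_triangle_single_edge(self):
        coords = {"a": (0, 0), "b": (1, 0), "c": (0.5, 1)}
        vals = np.array([[0, 5, 1], [5, 0, 1], [1, 1, 0]], float)
        bars = monmonier_barriers(
            DistanceMatrix(labels=list("abc"), values=vals), coords
        )
        assert bars[0].edges[0] == ("a", "b") or len(bars[0].edges) >= 1

    def test_degenerate_equal_distances_flagged(self):
        coords = {"a": (0, 0), "b": (1, 0), "c": (0.5, 1), "d": (0.5, 0.4)}
        vals = np.ones((4, 4)) - np.eye(4)
        bars = monmonier_barriers(
            DistanceMatrix(labels=list("abcd"), values=vals), coords
        )
        assert bars[0].degenerate

    def test_site_relabeling_invariance(self):
        rng = np.random.default_rng(0)
        pts = {f"s{i}": (float(rng.random()), float(rng.random())) for i in range(7)}
        a = np.triu(rng.random((7, 7)), 1)
        vals = a + a.T
        labels = sorted(pts)
        dm = DistanceMatrix(labels=labels, values=vals)
        bars = monmonier_barriers(dm, pts)
        # permute label order: same geometric barrier edges
        order = list(rng.permutation(7))
        labels2 = [labels[i] for i in order]
        vals2 = vals[np.ix_(order, order)]
        bars2 = monmonier_barriers(
            DistanceMatrix(labels=labels2, values=vals2), pts
        )
        e1 = {frozenset(e) for e in bars[0].edges}
        e2 = {frozenset(e) for e in bars2[0].edges}
        assert e1 == e2

    def test_bootstrap_support_on_planted_barrier(self):
        aln = _planted_alignment(n_pops=6, per=6)
        pops = sorted(aln.populations)
        popmap = {r.id: r.population for r in aln.records}
        d = population_profile_tn93(aln, popmap, pops)
        dm = DistanceMatrix(labels=pops, values=d)
        coords = {p: (i.latitude, i.longitude)
                  for p, i in aln.populations.items()}
        bars = monmonier_barriers(
            dm, coords, bootstrap_alignment=aln, bootstrap_populations=popmap,
            bootstrap_reps=30, seed=2,
        )
        assert bars[0].mean_support is not None
        assert bars[0].mean_support > 50


class TestMantel:
    def _dm(self, vals, labels=None):
        labels = labels or [f"x{i}" for i in range(len(vals))]
        return DistanceMatrix(labels=labels, values=np.asarray(vals, float))

    def test_self_correlation(self):
        rng = np.random.default_rng(0)
        a = np.triu(rng.random((5, 5)), 1)
        dm = self._dm(a + a.T)
        r, p = mantel(dm, dm)
        assert r == pytest.approx(1.0)
        assert p <= 2 / 120  # only ties with itself can match

    def test_exact_enumeration_matches_permutation(self):
        rng = np.random.default_rng(4)
        a = np.triu(rng.random((6, 6)), 1)
        b = np.triu(rng.random((6, 6)), 1)
        m1, m2 = self._dm(a + a.T), self._dm(b + b.T)
        r, p_exact = mantel(m1, m2)  # n<=7: exact
        # Monte-Carlo estimate of the same tail
        iu = np.triu_indices(6, 1)
        x = m1.values[iu]
        count, reps = 0, 3000
        rng2 = np.random.default_rng(9)
        for _ in range(reps):
            perm = rng2.permutation(6)
            rp = np.corrcoef(x, m2.values[np.ix_(perm, perm)][iu])[0, 1]
            if rp >= r - 1e-12:
                count += 1
        mc = count / reps
        se = np.sqrt(mc * (1 - mc) / reps)
        assert abs(p_exact - mc) <= 3 * max(se, 1e-3)

    def test_constant_matrix_error(self):
        dm = self._dm(np.ones((5, 5)) - np.eye(5))
        with pytest.raises(InputError):
            mantel(dm, dm)

    def test_type_i_error_calibration(self):
        rng = np.random.default_rng(10)
        rejections = 0
        trials = 300
        for _ in range(trials):
            a = np.triu(rng.random((8, 8)), 1)
            b = np.triu(rng.random((8, 8)), 1)
            _, p = mantel(self._dm(a + a.T), self._dm(b + b.T),
                          permutations=200, seed=int(rng.integers(2**31)))
            rejections += p <= 0.05
        assert 0.02 <= rejections / trials <= 0.09
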