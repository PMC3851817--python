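import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phylogeopop.haplotypes import (
    AlignmentError,
    DistanceMatrix,
    HaplotypeAlignment,
    InputError,
    SequenceRecord,
    SiteInfo,
    UndefinedDistanceError,
    collapse_haplotypes,
    distance_matrix,
    great_circle_km,
    n_differences,
    p_distance,
    pool_to_threshold,
    read_fasta,
    tamura_nei_distance,
    write_fasta,
)


class TestReadWrite:
    def test_identical_pair_roundtrip(self, tmp_path):
        f = tmp_path / "a.fasta"
        f.write_text(">p1|a\nACGTACGTAC\n>p1|b\nACGTACGTAC\n")
        aln = read_fasta(f)
        assert aln.n == 2 and aln.site_count == 10
        assert aln.records[0].population == "p1"
        out = tmp_path / "b.fasta"
        write_fasta(aln, out)
        assert read_fasta(out).sequences() == aln.sequences()

    def test_unequal_lengths_rejected(self, tmp_path):
        f = tmp_path / "bad.fasta"
        f.write_text(">a\nACGTACGTAC\n>b\nACGTACGTA\n")
        with pytest.raises(AlignmentError):
            read_fasta(f)

    def test_duplicate_ids_rejected(self):
        with pytest.raises(InputError, match="duplicate"):
            HaplotypeAlignment(
                records=[SequenceRecord("x", "AAAA"), SequenceRecord("x", "AAAT")]
            )

    def test_unknown_residue_names_position(self):
        with pytest.raises(InputError, match="position 3"):
            SequenceRecord("x", "AAZA")

    def test_site_table_join(self, tmp_path):
        f = tmp_path / "a.fasta"
        f.write_text(">p1|a\nAAAA\n")
        s = tmp_path / "sites.csv"
        s.write_text("population,lat,lon,n\np1,29.5,-84.2,8\n")
        aln = read_fasta(f, site_table=s)
        assert aln.populations["p1"].latitude == 29.5


class TestCollapse:
    def test_basic_counts(self):
        aln = HaplotypeAlignment(
            records=[SequenceRecord(i, s) for i, s in
                     zip("abc", ["AAAA", "AAAA", "AAAT"])]
        )
        c = collapse_haplotypes(aln)
        assert sorted(h[1] for h in c.haplotypes) == [1, 2]
        assert sum(h[1] for h in c.haplotypes) == c.n

    def test_all_distinct(self):
        seqs = ["AAAA", "AAAT", "AATT", "ATTT"]
        aln = HaplotypeAlignment(
            records=[SequenceRecord(f"s{i}", s) for i, s in enumerate(seqs)]
        )
        assert len(collapse_haplotypes(aln).haplotypes) == 4

    def test_missing_policy(self):
        aln = HaplotypeAlignment(
            records=[SequenceRecord("a", "AANA"), SequenceRecord("b", "AAAA")]
        )
        assert len(collapse_haplotypes(aln, "ignore_N").haplotypes) == 1
        assert len(collapse_haplotypes(aln, "strict").haplotypes) == 2

    @given(st.lists(st.sampled_from(["AAAA", "AAAT", "AATT", "TTTT"]),
                    min_size=1, max_size=12))
    @settings(max_examples=50, deadline=None)
    def test_counts_preserved(self, seqs):
        aln = HaplotypeAlignment(
            records=[SequenceRecord(f"s{i}", s) for i, s in enumerate(seqs)]
        )
        c = collapse_haplotypes(aln)
        assert sum(h[1] for h in c.haplotypes) == len(seqs)
        members = [m for _, _, ms in c.haplotypes for m in ms]
        assert sorted(members) == sorted(r.id for r in aln.records)


class TestDistances:
    def test_p_distance_examples(self):
        assert p_distance("ACGT", "ACGT") == 0.0
        assert p_distance("A" * 10, "T" + "A" * 9) == pytest.approx(0.1)
        assert p_distance("AATT", "AAAA") == pytest.approx(0.5)

    def test_p_distance_no_comparable_sites(self):
        with pytest.raises(UndefinedDistanceError):
            p_distance("NN", "AA")

    def test_tn93_formula_oracle(self):
        # 2 transitions (A->G), 1 transversion (A->C) over 100 sites,
        # equal base frequencies: independent transcription of the
        # closed form
        s1 = "A" * 100
        s2 = "GGC" + "A" * 97
        d = tamura_nei_distance(s1, s2, freqs={b: 0.25 for b in "ACGT"})
        p1, q = 0.02, 0.01
        k1 = k2 = 0.25
        k3 = 2 * (0.25 - 0.0625 - 0.0625)
        w1 = 1 - p1 / k1 - q
        w2 = 1 - q
        w3 = 1 - 2 * q
        oracle = -k1 * math.log(w1) - k2 * math.log(w2) - k3 * math.log(w3)
        assert d == pytest.approx(oracle, abs=1e-12)

    def test_tn93_dominates_p_distance(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            s1 = "".join(rng.choice(list("ACGT"), size=60))
            idx = rng.choice(60, size=5, replace=False)
            s2 = list(s1)
            for i in idx:
                s2[i] = rng.choice([b for b in "ACGT" if b != s2[i]])
            s2 = "".join(s2)
            aln = HaplotypeAlignment(
                records=[SequenceRecord("a", s1), SequenceRecord("b", s2)]
            )
            d = tamura_nei_distance(s1, s2, aln)
            assert d >= p_distance(s1, s2) - 1e-12

    def test_tn93_matches_p_at_low_divergence(self):
        # one substitution over a long locus: correction is negligible
        L = 20000
        s1 = "ACGT" * (L // 4)
        s2 = "T" + s1[1:]
        aln = HaplotypeAlignment(
            records=[SequenceRecord("a", s1), SequenceRecord("b", s2)]
        )
        d = tamura_nei_distance(s1, s2, aln)
        assert abs(d - p_distance(s1, s2)) < 1e-6

    def test_symmetry(self):
        s1, s2 = "ACGTACGTAA", "ACGAACGTAT"
        aln = HaplotypeAlignment(
            records=[SequenceRecord("a", s1), SequenceRecord("b", s2)]
        )
        assert p_distance(s1, s2) == p_distance(s2, s1)
        assert tamura_nei_distance(s1, s2, aln) == tamura_nei_distance(s2, s1, aln)

    def test_saturated_pair_capped_in_matrix(self):
        recs = [
            SequenceRecord("a", "ACGTACGTAC"),
            SequenceRecord("b", "ACGTACGTAT"),
            SequenceRecord("c", "TGCATGCATG"),  # saturated vs a
        ]
        aln = HaplotypeAlignment(records=recs)
        with pytest.warns(UserWarning, match="saturated"):
            dm = distance_matrix(aln, metric="tn93")
        assert np.isfinite(dm.values).all()
        assert dm.saturated_pairs


class TestGeography:
    def test_great_circle_examples(self):
        assert great_circle_km((10, 20), (10, 20)) == 0.0
        assert great_circle_km((0, 0), (1, 0)) == pytest.approx(
            math.pi / 180 * 6371, abs=0.01
        )
        assert great_circle_km((0, 0), (0, 90)) == pytest.approx(
            math.pi / 2 * 6371, abs=0.1
        )

    def test_bad_coordinates(self):
        with pytest.raises(InputError):
            great_circle_km((91, 0), (0, 0))
        with pytest.raises(InputError):
            great_circle_km((0, 181), (0, 0))

    def test_triangle_inequality(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            pts = [(float(rng.uniform(-90, 90)), float(rng.uniform(-180, 180)))
                   for _ in range(3)]
            a = great_circle_km(pts[0], pts[1])
            b = great_circle_km(pts[1], pts[2])
            c = great_circle_km(pts[0], pts[2])
            assert c <= a + b + 1e-6


class TestPooling:
    def _aln(self, ns, lats):
        recs = []
        pops = {}
        for i, (n, lat) in enumerate(zip(ns, lats)):
            pops[f"p{i}"] = SiteInfo(latitude=lat, longitude=0.0, n=n)
            for s in range(n):
                recs.append(SequenceRecord(f"p{i}|s{s}", "AAAA", f"p{i}"))
        return HaplotypeAlignment(records=recs, populations=pops)

    def test_above_threshold_unchanged(self):
        aln = self._aln([9, 12], [25, 30])
        out = pool_to_threshold(aln, threshold=8)
        assert sorted(out.populations) == ["p0", "p1"]

    def test_chain_merging(self):
        # 3 is nearest to 6; after merging (3+6)=9 both pools pass
        aln = self._aln([9, 3, 6], [25.0, 30.0, 30.5])
        out = pool_to_threshold(aln, threshold=8)
        ns = sorted(i.n for i in out.populations.values())
        assert ns == [9, 9]
        assert not out.pooling_warning

    def test_total_below_threshold(self):
        aln = self._aln([2, 3], [25, 30])
        out = pool_to_threshold(aln, threshold=8)
        assert len(out.populations) == 1
        assert out.pooling_warning

    def test_all_pools_meet_threshold(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            ns = [int(rng.integers(1, 12)) for _ in range(6)]
            lats = [float(25 + rng.uniform(0, 8)) for _ in range(6)]
            out = pool_to_threshold(self._aln(ns, lats), threshold=8)
            if not out.pooling_warning:
                assert all(i.n >= 8 for i in out.populations.values())


class TestDistanceMatrixIO:
    def test_csv_roundtrip(self, tmp_path):
        vals = np.array([[0, 1.5], [1.5, 0]])
        dm = DistanceMatrix(labels=["a", "b"], values=vals)
        path = tmp_path / "d.csv"
        dm.to_csv(path)
        back = DistanceMatrix.from_csv(path)
        assert back.labels == dm.labels
        assert np.allclose(back.values, dm.values)
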