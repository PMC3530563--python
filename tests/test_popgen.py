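import numpy as np
import pytest

from fecalpop import popgen
from fecalpop.errors import EstimationError
from fecalpop.genotypes import GenotypeArray
from fecalpop.io_formats import SequenceSet

# Frozen oracle values, computed by direct transcription of the published
# variance-component (Weir & Cockerham) and AMOVA sum-of-squares arithmetic
# with exact rational arithmetic on the toy data below.
THETA_TOY = 11.0 / 56.0
PHI_TOY = 0.7777777777777777

TOY_GENOS = [
    [[1, 1]], [[1, 1]], [[1, 2]], [[1, 2]], [[2, 2]],
    [[1, 2]], [[2, 2]], [[2, 2]], [[2, 2]], [[1, 2]],
]
TOY_SEQS = SequenceSet(
    ["a1", "a2", "a3", "b1", "b2", "b3"],
    ["AAAAAAAAAA", "AAAAAAAAAT", "AAAAAAAATT", "GGGGGAAAAA", "GGGGGAAAAT", "GGGGGAAATA"],
)
TOY_SEQ_POPS = {"a1": "A", "a2": "A", "a3": "A", "b1": "B", "b2": "B", "b3": "B"}


def _toy_array():
    return GenotypeArray(
        [f"i{k}" for k in range(10)], ["L1"], np.array(TOY_GENOS), ["A"] * 5 + ["B"] * 5
    )


class TestDiversity:
    def test_two_heterozygotes_toy(self):
        arr = GenotypeArray(
            ["i1", "i2"], ["L1"], np.array([[[1, 2]], [[1, 2]]]), ["P", "P"]
        )
        rep = popgen.diversity(arr)
        assert rep.loc["P", "H_O"] == pytest.approx(1.0)
        assert rep.loc["P", "H_E"] == pytest.approx(2.0 / 3.0)
        assert rep.loc["P", "A"] == pytest.approx(2.0)

    def test_identical_homozygotes(self):
        arr = GenotypeArray(
            ["i1", "i2"], ["L1"], np.array([[[1, 1]], [[1, 1]]]), ["P", "P"]
        )
        rep = popgen.diversity(arr)
        assert rep.loc["P", "H_O"] == 0.0
        assert rep.loc["P", "H_E"] == 0.0
        assert rep.loc["P", "A"] == 1.0

    def test_nucleotide_diversity_from_pair_enumeration(self):
        # 2 haplotypes differing at 1 of 650 sites, 2 copies each:
        # 4 of 6 pairs differ -> pi = (4/6)/650
        base = "A" * 650
        var = "T" + "A" * 649
        seqs = SequenceSet(["x1", "x2", "y1", "y2"], [base, base, var, var])
        arr = GenotypeArray(
            ["x1", "x2", "y1", "y2"], ["L1"],
            np.array([[[1, 1]]] * 4), ["P"] * 4,
        )
        rep = popgen.diversity(arr, seqs, {i: "P" for i in seqs.ids})
        assert rep.loc["P", "pi_percent"] == pytest.approx(100 * (4 / 6) / 650)

    def test_singleton_population_excluded(self):
        arr = GenotypeArray(
            ["i1", "i2", "i3"], ["L1"],
            np.array([[[1, 2]], [[1, 2]], [[1, 1]]]), ["P", "P", "Q"],
        )
        with pytest.warns(UserWarning, match="excluded"):
            rep = popgen.diversity(arr)
        assert list(rep.index) == ["P"]


class TestHWE:
    def test_perfect_proportions_not_significant(self):
        pairs = [[1, 1]] * 25 + [[1, 2]] * 50 + [[2, 2]] * 25
        assert popgen.hwe_test(np.array(pairs)) > 0.2

    def test_total_heterozygote_deficit_is_significant(self):
        pairs = [[1, 1]] * 50 + [[2, 2]] * 50
        assert popgen.hwe_test(np.array(pairs)) < 0.001

    def test_monomorphic_is_one(self):
        assert popgen.hwe_test(np.array([[1, 1]] * 10)) == 1.0

    def test_multiallelic_null_is_well_behaved(self):
        rng = np.random.default_rng(0)
        freqs = rng.dirichlet(np.ones(4))
        alleles = rng.choice(4, size=(60, 2), p=freqs)
        p = popgen.hwe_test(np.sort(alleles, axis=1), n_mc=2000, seed=1)
        assert 0.0 < p <= 1.0

    def test_biallelic_exact_matches_enumeration_probabilities(self):
        # direct check of the complete-enumeration path on a tiny table
        pairs = np.array([[1, 1], [1, 2], [2, 2]])
        p = popgen.hwe_test(pairs)
        assert 0.0 < p <= 1.0


class TestLD:
    def test_duplicated_locus_is_detected(self):
        rng = np.random.default_rng(2)
        a = np.sort(rng.integers(1, 4, (60, 2)), axis=1)
        assert popgen.ld_test(a, a.copy(), n_perm=500, seed=0) < 0.01

    def test_independent_loci_not_significant(self):
        rng = np.random.default_rng(3)
        a = np.sort(rng.integers(1, 4, (60, 2)), axis=1)
        b = np.sort(rng.integers(1, 4, (60, 2)), axis=1)
        assert popgen.ld_test(a, b, n_perm=500, seed=0) > 0.05

    def test_bonferroni(self):
        assert popgen.bonferroni([0.01, 0.4]) == [0.02, 0.8]
        assert popgen.bonferroni([0.9, 0.9]) == [1.0, 1.0]


class TestWeirCockerham:
    def test_matches_hand_computed_variance_components(self):
        theta = popgen.weir_cockerham_theta(_toy_array(), ["A"] * 5 + ["B"] * 5)
        assert theta == pytest.approx(THETA_TOY, abs=1e-9)

    def test_fixed_differences_give_one(self):
        arr = GenotypeArray(
            [f"i{k}" for k in range(20)], ["L1"],
            np.array([[[1, 1]]] * 10 + [[[2, 2]]] * 10),
            ["A"] * 10 + ["B"] * 10,
        )
        theta, p = popgen.fst_microsat(arr, "A", "B", n_perm=99, seed=0)
        assert theta == pytest.approx(1.0)
        assert p < 0.05

    def test_null_theta_near_zero(self):
        rng = np.random.default_rng(4)
        genos = np.sort(rng.integers(1, 6, size=(80, 5, 2)), axis=2)
        arr = GenotypeArray(
            [f"i{k}" for k in range(80)],
            [f"L{l}" for l in range(5)],
            genos,
            ["A"] * 40 + ["B"] * 40,
        )
        theta, p = popgen.fst_microsat(arr, "A", "B", n_perm=199, seed=0)
        assert abs(theta) < 0.03
        assert p > 0.05

    def test_invariant_to_label_and_sample_order(self):
        arr = _toy_array()
        t1, _ = popgen.fst_microsat(arr, "A", "B", n_perm=9, seed=0)
        t2, _ = popgen.fst_microsat(arr, "B", "A", n_perm=9, seed=0)
        perm = np.random.default_rng(0).permutation(10).tolist()
        t3, _ = popgen.fst_microsat(arr.subset(perm), "A", "B", n_perm=9, seed=0)
        assert t1 == pytest.approx(t2, abs=1e-12)
        assert t1 == pytest.approx(t3, abs=1e-12)

    def test_monomorphic_data_rejected(self):
        arr = GenotypeArray(
            [f"i{k}" for k in range(8)], ["L1"],
            np.array([[[1, 1]]] * 8), ["A"] * 4 + ["B"] * 4,
        )
        with pytest.raises(EstimationError):
            popgen.fst_microsat(arr, "A", "B", n_perm=9)


class TestPhiST:
    def test_matches_hand_computed_ss_decomposition(self):
        phi, _ = popgen.phi_st_mtdna(
            TOY_SEQS, TOY_SEQ_POPS, "A", "B", distance_model="p_distance",
            n_perm=99, seed=0,
        )
        assert phi == pytest.approx(PHI_TOY, abs=1e-9)

    def test_identical_sequences_give_zero(self):
        seqs = SequenceSet([f"s{i}" for i in range(6)], ["ACGT"] * 6)
        pops = {f"s{i}": ("A" if i < 3 else "B") for i in range(6)}
        phi, p = popgen.phi_st_mtdna(seqs, pops, "A", "B", n_perm=99)
        assert phi == 0.0 and p == 1.0

    def test_disjoint_pools_approach_one(self):
        a = "A" * 50
        b = "G" * 25 + "A" * 25
        seqs = SequenceSet([f"s{i}" for i in range(8)], [a] * 4 + [b] * 4)
        pops = {f"s{i}": ("A" if i < 4 else "B") for i in range(8)}
        phi, p = popgen.phi_st_mtdna(seqs, pops, "A", "B", n_perm=199, seed=0)
        assert phi > 0.95
        assert p < 0.05

    def test_shared_pool_is_null_on_average(self):
        rng = np.random.default_rng(6)
        pool = ["A" * 20, "A" * 19 + "T", "C" + "A" * 19]
        phis, sig = [], 0
        for rep in range(20):
            ids = [f"s{i}" for i in range(30)]
            seqs = SequenceSet(ids, [pool[rng.integers(0, 3)] for _ in ids])
            pops = {i: ("A" if k < 15 else "B") for k, i in enumerate(ids)}
            phi, p = popgen.phi_st_mtdna(seqs, pops, "A", "B", n_perm=99, seed=rep)
            phis.append(phi)
            sig += p <= 0.05
        assert abs(np.mean(phis)) < 0.1
        assert sig <= 4  # ~type-I rate at alpha = 0.05

    def test_order_invariance(self):
        p1, _ = popgen.phi_st_mtdna(TOY_SEQS, TOY_SEQ_POPS, "A", "B", n_perm=9, seed=0)
        p2, _ = popgen.phi_st_mtdna(TOY_SEQS, TOY_SEQ_POPS, "B", "A", n_perm=9, seed=0)
        assert p1 == pytest.approx(p2, abs=1e-12)


class TestRegionalSubdivision:
    def test_single_region_gives_empty_matrix(self):
        seqs = SequenceSet(["s1", "s2"], ["ACGT", "ACGT"])
        mat = popgen.regional_subdivision(
            seqs, {"s1": "P", "s2": "P"}, {"s1": "R1", "s2": "R1"}, n_perm=9
        )
        assert mat.entries == {}

    def test_seeded_region_differentiates(self):
        # three regions from one pool, one seeded with a divergent pool
        rng = np.random.default_rng(8)
        pool = ["A" * 40, "A" * 39 + "T"]
        alien = ["G" * 20 + "A" * 20]
        ids, seq_list, regions = [], [], {}
        for r, n in (("R1", 10), ("R2", 10), ("R3", 10)):
            for k in range(n):
                sid = f"{r}_{k}"
                ids.append(sid)
                src = alien if r == "R3" else pool
                seq_list.append(src[rng.integers(0, len(src))])
                regions[sid] = r
        seqs = SequenceSet(ids, seq_list)
        mat = popgen.regional_subdivision(
            seqs, {i: "P" for i in ids}, regions, n_perm=199, seed=0
        )
        est12, p12, _ = mat.get("R1", "R2")
        est13, p13, _ = mat.get("R1", "R3")
        assert p13 < 0.05 and est13 > 0.5
        assert p12 > 0.05

    def test_matrix_layout(self):
        mat = popgen.PairwiseFstMatrix(["A", "B"], "mtdna_phi_st")
        mat.set("A", "B", 0.5, 0.01, 99)
        frame = mat.to_frame()
        assert frame.loc["B", "A"] == 0.5
        assert frame.loc["A", "B"] == 0.01


class TestHaplotypeCollapse:
    def test_collapse_orders_by_frequency(self):
        seqs = SequenceSet(
            ["s1", "s2", "s3", "s4"], ["ACGT", "AAAA", "ACGT", "ACGT"]
        )
        mapping, haps = popgen.collapse_haplotypes(seqs)
        assert mapping == {"s1": "H01", "s2": "H02", "s3": "H01", "s4": "H01"}
        assert haps.seqs == ["ACGT", "AAAA"]
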