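import itertools

import numpy as np
import pytest

from fecalpop import consensus as cns
from fecalpop import identity as idy
from fecalpop import synthetic_data as syn
from fecalpop.errors import ValidationError
from fecalpop.genotypes import MISSING, GenotypeArray
from fecalpop.io_formats import parse_sex_replicates


def enumerate_pid(freqs):
    """Oracle: enumerate ordered genotype pairs under HWE and count matches."""
    alleles = list(freqs)
    pid = 0.0
    for a, b in itertools.product(alleles, repeat=2):
        g_prob = freqs[a] * freqs[b]
        for c, d in itertools.product(alleles, repeat=2):
            if tuple(sorted((a, b))) == tuple(sorted((c, d))):
                pid += g_prob * freqs[c] * freqs[d]
    return pid


def enumerate_pid_sib(freqs):
    """Oracle: genotype-pair distribution for full sibs.

    Sibs share 2, 1 or 0 parental alleles with probability 1/4, 1/2, 1/4;
    enumerate the sib genotype accordingly and count identical pairs.
    """
    alleles = list(freqs)
    total = 0.0
    for a, b in itertools.product(alleles, repeat=2):  # first sib (ordered)
        g1 = tuple(sorted((a, b)))
        p1 = freqs[a] * freqs[b]
        # IBD = 2: identical genotype
        total += p1 * 0.25
        # IBD = 1: one shared allele (equally likely a or b), other random
        for shared in (a, b):
            for x in alleles:
                if tuple(sorted((shared, x))) == g1:
                    total += p1 * 0.5 * 0.5 * freqs[x]
        # IBD = 0: independent genotype
        for c, d in itertools.product(alleles, repeat=2):
            if tuple(sorted((c, d))) == g1:
                total += p1 * 0.25 * freqs[c] * freqs[d]
    return total


class TestProbabilityOfIdentity:
    def test_monomorphic_locus(self):
        stats = idy.probability_of_identity({"L1": {1: 1.0}})
        assert stats.per_locus_pid["L1"] == pytest.approx(1.0)
        assert stats.per_locus_pid_sib["L1"] == pytest.approx(1.0)

    def test_biallelic_half_half_matches_enumeration(self):
        freqs = {1: 0.5, 2: 0.5}
        stats = idy.probability_of_identity({"L1": freqs})
        assert stats.per_locus_pid["L1"] == pytest.approx(enumerate_pid(freqs), abs=1e-12)
        assert stats.per_locus_pid["L1"] == pytest.approx(0.375)
        assert stats.per_locus_pid_sib["L1"] == pytest.approx(
            enumerate_pid_sib(freqs), abs=1e-12
        )
        assert stats.per_locus_pid_sib["L1"] == pytest.approx(0.59375)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_frequencies_match_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.dirichlet(np.ones(rng.integers(2, 5)))
        freqs = dict(enumerate(p.tolist(), start=1))
        stats = idy.probability_of_identity({"L": freqs})
        assert stats.per_locus_pid["L"] == pytest.approx(enumerate_pid(freqs), abs=1e-10)
        assert stats.per_locus_pid_sib["L"] == pytest.approx(
            enumerate_pid_sib(freqs), abs=1e-10
        )
        assert stats.per_locus_pid["L"] <= stats.per_locus_pid_sib["L"]

    def test_cumulative_is_product(self):
        stats = idy.probability_of_identity(
            {"L1": {1: 0.5, 2: 0.5}, "L2": {1: 0.5, 2: 0.5}}
        )
        assert stats.cumulative_pid == pytest.approx(0.375**2)

    def test_frequencies_must_sum_to_one(self):
        with pytest.raises(ValidationError):
            idy.probability_of_identity({"L1": {1: 0.4, 2: 0.4}})


class TestAssignSex:
    @pytest.mark.parametrize(
        "calls,expected",
        [
            (["two_bands", "two_bands"], "M"),
            (["one_band", "one_band", "one_band"], "F"),
            (["one_band", "two_bands", "one_band"], "unknown"),
            (["one_band", "two_bands", "one_band", "two_bands"], "M"),
            (["one_band", "one_band"], "unknown"),
            (["fail", "fail"], "unknown"),
            (["one_band", "one_band", "one_band", "fail"], "F"),
        ],
    )
    def test_decision_rules(self, calls, expected):
        assert idy.assign_sex(calls) == expected


def _array(genos, pops=None):
    n = len(genos)
    return GenotypeArray(
        [f"s{i}" for i in range(n)],
        [f"L{l}" for l in range(len(genos[0]))],
        np.array(genos),
        pops or ["P"] * n,
    )


def _full(pairs12):
    """12-locus genotype built by repeating a pair list."""
    return pairs12


class TestMatchSamples:
    def _genotype(self, seed=0, loci=12):
        rng = np.random.default_rng(seed)
        return [[int(a), int(b)] for a, b in np.sort(rng.integers(100, 120, (loci, 2)), axis=1)]

    def test_identical_genotypes_merge(self):
        g = self._genotype()
        arr = _array([g, g])
        inds, audits, conflicts = idy.match_samples(arr)
        assert len(inds) == 1
        assert inds[0].member_sample_ids == ["s0", "s1"]
        assert audits[0].rule == "exact"

    def test_one_mismatch_requires_flag_and_sex(self):
        g1 = self._genotype()
        g2 = [list(p) for p in g1]
        g2[0] = [g1[0][0], g1[0][0]]  # dropout-like single-allele shift
        if g1[0][0] == g1[0][1]:
            g2[0] = [g1[0][0], g1[0][1] + 2]
        sexes = {"s0": "F", "s1": "F"}
        arr = _array([g1, g2], pops=["CCA", "CCA"])
        merged, _, _ = idy.match_samples(arr, sexes, one_mismatch_populations={"CCA"})
        assert len(merged) == 1
        not_merged, _, _ = idy.match_samples(arr, sexes)
        assert len(not_merged) == 2
        # sexes must match and be known
        unknown, _, _ = idy.match_samples(
            arr, {"s0": "F", "s1": "unknown"}, one_mismatch_populations={"CCA"}
        )
        assert len(unknown) == 2

    def test_two_allele_difference_never_merges(self):
        g1 = self._genotype()
        g2 = [list(p) for p in g1]
        g2[0] = [g1[0][0] + 40, g1[0][1] + 42]
        arr = _array([g1, g2], pops=["CCA", "CCA"])
        inds, _, _ = idy.match_samples(
            arr, {"s0": "F", "s1": "F"}, one_mismatch_populations={"CCA"}
        )
        assert len(inds) == 2

    def test_sex_conflict_blocks_exact_merge(self):
        g = self._genotype()
        arr = _array([g, g])
        inds, _, _ = idy.match_samples(arr, {"s0": "M", "s1": "F"})
        assert len(inds) == 2

    def test_haplotype_conflict_blocks_merge_and_is_reported(self):
        g = self._genotype()
        arr = _array([g, g])
        inds, _, _ = idy.match_samples(arr, haplotypes={"s0": "H1", "s1": "H2"})
        assert len(inds) == 2
        lax, _, conflicts = idy.match_samples(
            arr, haplotypes={"s0": "H1", "s1": "H2"}, require_haplotype_consistency=False
        )
        assert len(lax) == 1 and "haplotype_conflict" in lax[0].flags
        assert conflicts

    def test_insufficient_shared_loci_blocks(self):
        g1 = self._genotype()
        g2 = [list(p) for p in g1]
        for l in range(5):
            g2[l] = [MISSING, MISSING]
        arr = _array([g1, g2])
        inds, _, _ = idy.match_samples(arr, min_shared_loci=8)
        assert len(inds) == 2

    def test_partition_invariant_to_input_order(self):
        rng = np.random.default_rng(5)
        genos = [self._genotype(seed=i) for i in range(6)] * 2
        ids = [f"s{i}" for i in range(len(genos))]
        arr = GenotypeArray(ids, [f"L{l}" for l in range(12)], np.array(genos), ["P"] * 12)
        ref, _, _ = idy.match_samples(arr)
        perm = rng.permutation(len(genos))
        arr2 = arr.subset(perm.tolist())
        got, _, _ = idy.match_samples(arr2)
        part_ref = sorted(tuple(sorted(i.member_sample_ids)) for i in ref)
        part_got = sorted(tuple(sorted(i.member_sample_ids)) for i in got)
        assert part_ref == part_got

    def test_clean_simulation_recovers_truth_partition(self, clean_dataset):
        cfg, truth, table, meta, seqs, tmap = clean_dataset
        calls = cns.call_consensus(table)
        pops = dict(zip(meta["sample_id"], meta["population"]))
        sexes = {
            r.sample_id: idy.assign_sex(parse_sex_replicates(r.sex_replicates))
            for r in meta.itertuples()
        }
        arr = cns.consensus_to_array(calls, populations=pops)
        inds, _, conflicts = idy.match_samples(arr, sexes=sexes)
        assert not conflicts
        # adjusted Rand index of 1 == identical partitions
        recovered = {s: i.individual_id for i in inds for s in i.member_sample_ids}
        by_truth = {}
        for s, t in tmap.items():
            by_truth.setdefault(t, set()).add(s)
        by_rec = {}
        for s, r in recovered.items():
            by_rec.setdefault(r, set()).add(s)
        assert sorted(map(frozenset, by_truth.values())) == sorted(
            map(frozenset, by_rec.values())
        )
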