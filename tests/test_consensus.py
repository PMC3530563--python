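import itertools
import math
from collections import Counter

import numpy as np
import pandas as pd
import pytest

from fecalpop import consensus as cns
from fecalpop import synthetic_data as syn
from fecalpop.errors import ConfigError, EstimationError
from fecalpop.genotypes import from_true_individuals
from fecalpop.io_formats import GENOTYPE_COLUMNS


def _table(reps, sample="s1", locus="L1"):
    rows = [
        (sample, locus, i + 1, *(pair if pair else (None, None)))
        for i, pair in enumerate(reps)
    ]
    return pd.DataFrame(rows, columns=list(GENOTYPE_COLUMNS))


def _call(reps, het=2, hom=5):
    return cns.call_consensus(_table(reps), het, hom)["s1"].calls["L1"]


class TestCallConsensus:
    def test_het_at_threshold(self):
        call = _call([(100, 120), (100, 120)])
        assert call.call_type == "het"
        assert call.alleles == (100, 120)
        assert call.n_support == 2

    def test_hom_needs_five(self):
        assert _call([(100, 100)] * 5).call_type == "hom"
        assert _call([(100, 100)] * 4).call_type == "failed"

    def test_contradicted_hom_fails(self):
        call = _call([(100, 100)] * 4 + [(100, 120)])
        assert call.call_type == "failed"

    def test_singleton_false_allele_does_not_block_het(self):
        call = _call([(100, 120)] * 3 + [(100, 140)])
        assert call.call_type == "het" and call.alleles == (100, 120)

    def test_all_failed_sample_flagged(self):
        out = cns.call_consensus(_table([None, None]))
        assert "all_loci_failed" in out["s1"].flags

    def test_matches_exhaustive_rule_oracle(self):
        """Check the caller against a direct transcription of the acceptance
        rule over every replicate multiset of size <= 5 built from up to 3
        alleles (plus failed replicates)."""
        outcomes = [None] + [
            tuple(sorted(p)) for p in itertools.combinations_with_replacement((1, 2, 3), 2)
        ]
        het_t, hom_t = 2, 3

        def oracle(reps):
            nonfail = [r for r in reps if r is not None]
            pair_counts = Counter(nonfail)
            qualifying = {
                p: c for p, c in pair_counts.items() if p[0] != p[1] and c >= het_t
            }
            if qualifying:
                top = max(qualifying.values())
                winners = [p for p, c in qualifying.items() if c == top]
                return ("het", min(winners)) if len(winners) == 1 else ("failed", None)
            seen = {x for p in nonfail for x in p}
            if len(seen) == 1:
                (a,) = seen
                if pair_counts[(a, a)] >= hom_t:
                    return ("hom", (a, a))
            return ("failed", None)

        for size in range(1, 6):
            for reps in itertools.combinations_with_replacement(outcomes, size):
                want_type, want_alleles = oracle(reps)
                got = _call(list(reps), het=het_t, hom=hom_t)
                assert (got.call_type, got.alleles) == (want_type, want_alleles), reps


def brute_replicate_likelihood(obs, truth, d, f, n_alleles):
    """Independent enumeration of the dropout/false-allele observation model."""
    alleles = list(range(1, n_alleles + 1))
    a, b = truth
    total = 0.0
    for drop_a, drop_b in itertools.product([True, False], repeat=2):
        p_drop = (d if drop_a else 1 - d) * (d if drop_b else 1 - d)
        surviving = [x for x, dropped in ((a, drop_a), (b, drop_b)) if not dropped]
        if not surviving:
            if obs is None:
                total += p_drop
            continue
        vis = (surviving[0], surviving[-1]) if len(surviving) == 2 else (surviving[0],) * 2
        vis = tuple(sorted(vis))
        if obs is None:
            continue
        if tuple(sorted(obs)) == vis:
            total += p_drop * (1 - f)
        for slot in range(2):
            for target in alleles:
                if target == vis[slot]:
                    continue
                replaced = tuple(sorted((vis[1 - slot], target)))
                if replaced == tuple(sorted(obs)):
                    total += p_drop * f / (2 * (n_alleles - 1))
    return total


class TestReplicateLikelihood:
    @pytest.mark.parametrize("truth", [(1, 2), (1, 1), (3, 4)])
    @pytest.mark.parametrize("d,f", [(0.0, 0.0), (0.2, 0.0), (0.2, 0.05), (0.5, 0.3)])
    def test_matches_brute_force(self, truth, d, f):
        n_alleles = 4
        observations = [None] + [
            tuple(p) for p in itertools.combinations_with_replacement(range(1, 5), 2)
        ]
        total = 0.0
        for obs in observations:
            want = brute_replicate_likelihood(obs, truth, d, f, n_alleles)
            got = cns.replicate_likelihood(obs, truth, d, f, n_alleles)
            assert got == pytest.approx(want, abs=1e-12), (obs, truth)
            total += got
        assert total == pytest.approx(1.0, abs=1e-12)


class TestReliability:
    def test_error_free_het_is_certain(self):
        table = _table([(100, 120), (100, 120)])
        calls = cns.call_consensus(table)
        r = cns.genotype_reliability(calls, table, d_hat=0.0, f_hat=0.0)
        assert r["s1"] == pytest.approx(1.0)

    def test_hom_posterior_matches_bayes_enumeration(self):
        d, f = 0.2, 0.0
        reps = [(100, 100)] * 5
        table = _table(reps)
        calls = cns.call_consensus(table)
        r = cns.genotype_reliability(calls, table, d_hat=d, f_hat=f)
        # candidates: hom(100) and het(100, unseen); uniform prior
        lik_hom = brute_replicate_likelihood((1, 1), (1, 1), d, f, 2) ** 5
        lik_het = brute_replicate_likelihood((1, 1), (1, 2), d, f, 2) ** 5
        expected = lik_hom / (lik_hom + lik_het)
        assert r["s1"] == pytest.approx(expected, abs=1e-12)

    def test_more_replicates_never_reduce_reliability(self):
        prev = 0.0
        for n in range(5, 10):
            table = _table([(100, 100)] * n)
            calls = cns.call_consensus(table)
            r = cns.genotype_reliability(calls, table, d_hat=0.2, f_hat=0.05)["s1"]
            assert r >= prev - 1e-12
            prev = r

    def test_bad_rates_rejected(self):
        table = _table([(100, 100)] * 5)
        calls = cns.call_consensus(table)
        with pytest.raises(ConfigError):
            cns.genotype_reliability(calls, table, d_hat=1.2)

    def test_posterior_is_calibrated_on_simulation(self):
        """Among called loci with posterior ~1, nearly all calls are correct."""
        cfg = syn.SimulationConfig(
            seed=13, demes=("A", "B"), deme_sizes={"A": 40, "B": 40},
            barrier_assignment={"A": "east", "B": "west"}, focal_deme=None,
            recapture_mean_by_deme={}, recapture_mean=1.0,
            dropout_rate=0.2, false_allele_rate=0.05,
        )
        truth, table, meta, seqs, tmap = syn.simulate_dataset(cfg)
        calls = cns.call_consensus(table)
        cns.genotype_reliability(calls, table, d_hat=0.2, f_hat=0.05)
        geno = {i.individual_id: i.genotype for i in truth.individuals}
        confident_correct = confident_total = 0
        for sid, cg in calls.items():
            if cg.reliability < 0.99:
                continue
            for locus, call in cg.calls.items():
                if call.alleles is None:
                    continue
                l = int(locus[1:]) - 1
                confident_total += 1
                if tuple(sorted(geno[tmap[sid]][l])) == call.alleles:
                    confident_correct += 1
        assert confident_total > 100
        assert confident_correct / confident_total >= 0.98


class TestErrorRates:
    def test_concordant_data_gives_zero(self):
        table = _table([(100, 120)] * 4)
        assert cns.estimate_error_rates(table) == (0.0, 0.0)

    def test_single_replicates_rejected(self):
        rows = [("s1", "L1", 1, 100, 120), ("s1", "L2", 1, 100, 100)]
        table = pd.DataFrame(rows, columns=list(GENOTYPE_COLUMNS))
        with pytest.raises(EstimationError):
            cns.estimate_error_rates(table)

    def test_recovers_rates_against_truth(self, noisy_dataset):
        cfg, truth, table, meta, seqs, tmap = noisy_dataset
        arr = from_true_individuals(truth.individuals)
        d_hat, f_hat = cns.estimate_error_rates(table, arr, tmap)
        assert d_hat == pytest.approx(0.2, abs=0.03)
        assert f_hat == pytest.approx(0.05, abs=0.03)


class TestCleanRecovery:
    def test_consensus_equals_truth_with_no_errors(self, clean_dataset):
        cfg, truth, table, meta, seqs, tmap = clean_dataset
        calls = cns.call_consensus(table)
        geno = {i.individual_id: i.genotype for i in truth.individuals}
        for sid, cg in calls.items():
            for locus, call in cg.calls.items():
                l = int(locus[1:]) - 1
                assert call.call_type != "failed"
                assert call.alleles == tuple(sorted(geno[tmap[sid]][l]))
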