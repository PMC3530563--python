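"""Multiple-tubes consensus calling, genotype reliability and error rates.

Faecal DNA yields unreliable PCR amplifications, so each sample is genotyped
in several independent replicates and a genotype is accepted only once it has
been seen often enough: a heterozygote when both alleles co-occur in at least
``het_threshold`` replicates (default 2), a homozygote when a single allele —
and no other — appears in at least ``hom_threshold`` replicates (default 5).
Loci that meet neither rule fail.

Reliability is the posterior probability that a called genotype is the true
one under the two-parameter error model (per-allele dropout ``d``, per-
replicate false-allele substitution ``f``), multiplied across loci; samples
below a reliability floor (default 0.99) are flagged for further replication.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .errors import ConfigError, EstimationError
from .genotypes import MISSING, GenotypeArray
from .io_formats import validate_genotype_table

UNSEEN = -9  # pseudo-allele standing for "an allele never observed here"


@dataclass
class LocusCall:
    alleles: Optional[tuple[int, int]]  # None when failed
    n_support: int
    call_type: str  # 'het' | 'hom' | 'failed'


@dataclass
class ConsensusGenotype:
    sample_id: str
    calls: dict[str, LocusCall]
    reliability: float = float("nan")
    dropout_estimate: float = float("nan")
    flags: list[str] = field(default_factory=list)

    @property
    def n_called(self) -> int:
        return sum(1 for c in self.calls.values() if c.call_type != "failed")

    def allele_pair(self, locus: str) -> Optional[tuple[int, int]]:
        call = self.calls.get(locus)
        return call.alleles if call and call.alleles else None


def _replicates_by_locus(table: pd.DataFrame):
    """Yield (sample, locus, list of observed pairs) with None for failures."""
    for (sample, locus), sub in table.groupby(["sample_id", "locus_id"], sort=True):
        obs = []
        for a, b in zip(sub["allele_a"], sub["allele_b"]):
            if pd.isna(a):
                obs.append(None)
            elif pd.isna(b):
                obs.append((int(a), int(a)))  # half-call treated as single-allele
            else:
                obs.append((int(a), int(b)))
        yield str(sample), str(locus), obs


def call_consensus(
    table: pd.DataFrame,
    het_threshold: int = 2,
    hom_threshold: int = 5,
) -> dict[str, ConsensusGenotype]:
    """Collapse replicate genotypes into per-sample consensus genotypes.

    Alleles seen in only a single replicate are putative false alleles: they
    can never support a call, but a second allele observed at all still
    contradicts (fails) a homozygote.  Samples failing at every locus are
    flagged ``all_loci_failed``.
    """
    table = validate_genotype_table(table)
    out: dict[str, ConsensusGenotype] = {}
    all_loci = sorted(table["locus_id"].unique())
    for sample, locus, obs in _replicates_by_locus(table):
        cg = out.setdefault(sample, ConsensusGenotype(sample, {}))
        nonfail = [o for o in obs if o is not None]
        cg.calls[locus] = _call_locus(nonfail, het_threshold, hom_threshold)
    for sample, cg in out.items():
        for locus in all_loci:
            cg.calls.setdefault(locus, LocusCall(None, 0, "failed"))
        if cg.n_called == 0:
            cg.flags.append("all_loci_failed")
    return out


def _call_locus(nonfail: list[tuple[int, int]], het_threshold: int, hom_threshold: int) -> LocusCall:
    if not nonfail:
        return LocusCall(None, 0, "failed")
    pair_counts: dict[tuple[int, int], int] = {}
    allele_counts: dict[int, int] = {}
    for a, b in nonfail:
        pair_counts[(a, b)] = pair_counts.get((a, b), 0) + 1
        for x in {a, b}:
            allele_counts[x] = allele_counts.get(x, 0) + 1
    het_pairs = {p: c for p, c in pair_counts.items() if p[0] != p[1] and c >= het_threshold}
    if het_pairs:
        best = max(het_pairs.values())
        winners = sorted(p for p, c in het_pairs.items() if c == best)
        if len(winners) > 1:
            return LocusCall(None, 0, "failed")  # two replicated, conflicting hets
        return LocusCall(winners[0], best, "het")
    if len(allele_counts) == 1:
        (allele, count), = allele_counts.items()
        hom_support = pair_counts.get((allele, allele), 0)
        if hom_support >= hom_threshold:
            return LocusCall((allele, allele), hom_support, "hom")
    return LocusCall(None, 0, "failed")


# ---------------------------------------------------------------------------
# Replicate observation model
# ---------------------------------------------------------------------------

def replicate_likelihood(
    obs: Optional[tuple[int, int]],
    truth: tuple[int, int],
    d: float,
    f: float,
    n_alleles: int,
) -> float:
    """P(one replicate shows ``obs`` | true genotype, dropout d, false-allele f).

    The generative model mirrors the simulator: each true allele copy drops
    independently with probability ``d`` (both dropping = failed replicate);
    with probability ``f`` one of the two surviving calls is replaced by a
    uniformly chosen different allele from the locus's ``n_alleles`` alleles.
    Computed by exact enumeration of dropout patterns and replacements.
    """
    if n_alleles < 2:
        n_alleles = 2
    a, b = truth
    A = n_alleles
    # visible genotypes after dropout, with probabilities
    if a == b:
        visible = [((a, a), 1 - d * d), (None, d * d)]
    else:
        visible = [
            (tuple(sorted((a, b))), (1 - d) ** 2),
            ((a, a), d * (1 - d)),
            ((b, b), d * (1 - d)),
            (None, d * d),
        ]
    total = 0.0
    for vis, pv in visible:
        if pv == 0.0:
            continue
        if vis is None:
            if obs is None:
                total += pv
            continue
        if obs is None:
            continue
        if tuple(sorted(obs)) == vis:
            total += pv * (1 - f)
        if f > 0.0:
            # replacement: slot s in {0,1}, target t != vis[s], each w.p. f/(2(A-1))
            per = f / (2.0 * (A - 1))
            o = tuple(sorted(obs))
            for s in range(2):
                kept = vis[1 - s]
                # obs must contain `kept`; the other observed allele is the target
                cand = list(o)
                if kept in cand:
                    cand.remove(kept)
                    t = cand[0]
                    if t != vis[s] and _target_reachable(t, vis, o, s):
                        total += pv * per
    return total


def _target_reachable(t: int, vis: tuple[int, int], obs: tuple[int, int], s: int) -> bool:
    # replacement of vis[s] by t produces sorted(vis[1-s], t) == obs
    return tuple(sorted((vis[1 - s], t))) == tuple(sorted(obs))


def genotype_reliability(
    consensus: Mapping[str, ConsensusGenotype],
    table: pd.DataFrame,
    d_hat: float,
    f_hat: float = 0.0,
    reliability_threshold: float = 0.99,
) -> dict[str, float]:
    """Posterior probability that each sample's consensus is its true genotype.

    Candidate truths per locus are all genotypes composed of the alleles
    observed in that sample's replicates plus one "unseen allele"
    pseudo-candidate, with a uniform prior.  Samples whose multilocus
    reliability falls below ``reliability_threshold`` get a flag.
    """
    if not (0.0 <= d_hat < 1.0) or not (0.0 <= f_hat < 1.0):
        raise ConfigError("error-rate estimates must lie in [0, 1)")
    table = validate_genotype_table(table)
    locus_allele_n = {
        locus: len(
            set(sub["allele_a"].dropna().astype(int))
            | set(sub["allele_b"].dropna().astype(int))
        )
        for locus, sub in table.groupby("locus_id")
    }
    per_sample_locus: dict[str, dict[str, list]] = {}
    for sample, locus, obs in _replicates_by_locus(table):
        per_sample_locus.setdefault(sample, {})[locus] = obs
    out: dict[str, float] = {}
    for sample, cg in consensus.items():
        r = 1.0
        for locus, call in cg.calls.items():
            if call.call_type == "failed" or call.alleles is None:
                continue
            obs_list = per_sample_locus.get(sample, {}).get(locus, [])
            seen = sorted({x for o in obs_list if o is not None for x in o})
            n_all = max(locus_allele_n.get(locus, 2), len(seen) + 1)
            r *= _locus_posterior(call.alleles, obs_list, seen, d_hat, f_hat, n_all)
        cg.reliability = r
        cg.dropout_estimate = d_hat
        if r < reliability_threshold:
            cg.flags.append("low_reliability")
        out[sample] = r
    return out


def _locus_posterior(called, obs_list, seen, d, f, n_alleles) -> float:
    candidates = set()
    pool = list(seen) + [UNSEEN]
    for i, x in enumerate(pool):
        for y in pool[i:]:
            if x == UNSEEN and y == UNSEEN:
                continue
            candidates.add(tuple(sorted((x, y))))
    candidates.add(tuple(sorted(called)))
    log_post = {}
    for cand in candidates:
        ll = 0.0
        for obs in obs_list:
            p = replicate_likelihood(obs, cand, d, f, n_alleles)
            if p <= 0.0:
                ll = -math.inf
                break
            ll += math.log(p)
        log_post[cand] = ll
    m = max(log_post.values())
    if m == -math.inf:
        return 0.0
    weights = {c: math.exp(v - m) for c, v in log_post.items()}
    z = sum(weights.values())
    return weights.get(tuple(sorted(called)), 0.0) / z


# ---------------------------------------------------------------------------
# Error-rate estimation
# ---------------------------------------------------------------------------

def estimate_error_rates(
    table: pd.DataFrame,
    reference: Mapping[str, ConsensusGenotype] | GenotypeArray | None = None,
    truth_map: Mapping[str, str] | None = None,
    het_threshold: int = 2,
    hom_threshold: int = 5,
) -> tuple[float, float]:
    """Maximum-likelihood (d̂, f̂) from replicate discordance.

    The reference genotype per sample is the consensus call (computed here if
    not given); in simulations a :class:`GenotypeArray` of true genotypes plus
    a sample→individual ``truth_map`` may be passed instead, which turns the
    estimates into plug-in empirical rates against ground truth.

    Consensus references are only available at loci that passed the calling
    thresholds, which over-represents concordant replicates; the likelihood
    is therefore conditioned on the calling event (probability that the true
    genotype yields a het/hom call from that locus's replicate count), so the
    estimates stay unbiased.  Truth references need no such correction.
    """
    table = validate_genotype_table(table)
    multi = table.groupby(["sample_id", "locus_id"]).size()
    if (multi < 2).all():
        raise EstimationError("error rates need >=2 replicates for some sample x locus")
    condition_on_call = not isinstance(reference, GenotypeArray)
    if reference is None:
        reference = call_consensus(table, het_threshold, hom_threshold)

    # sufficient statistics: category counts for het and hom reference loci
    het_counts = np.zeros(5)  # both, single_true, fail, one_true_one_false, other
    hom_counts = np.zeros(4)  # true_hom, fail, true_plus_false, other
    locus_index = {l: i for i, l in enumerate(sorted(table["locus_id"].unique()))}
    n_alleles_tot = []
    for locus, sub in table.groupby("locus_id"):
        n_alleles_tot.append(
            len(set(sub["allele_a"].dropna().astype(int)) | set(sub["allele_b"].dropna().astype(int)))
        )
    A = max(2.0, float(np.mean(n_alleles_tot)))

    cond_events: dict[tuple[str, int], int] = {}  # (ref type, n_replicates) -> count
    for sample, locus, obs_list in _replicates_by_locus(table):
        ref_pair = _reference_pair(reference, truth_map, sample, locus, locus_index)
        if ref_pair is None:
            continue
        a, b = ref_pair
        if condition_on_call:
            key = ("het" if a != b else "hom", len(obs_list))
            cond_events[key] = cond_events.get(key, 0) + 1
        for obs in obs_list:
            if a != b:
                if obs is None:
                    het_counts[2] += 1
                elif set(obs) == {a, b}:
                    het_counts[0] += 1
                elif obs[0] == obs[1] and obs[0] in (a, b):
                    het_counts[1] += 1
                elif len(set(obs) & {a, b}) == 1:
                    het_counts[3] += 1
                else:
                    het_counts[4] += 1
            else:
                if obs is None:
                    hom_counts[1] += 1
                elif obs == (a, a):
                    hom_counts[0] += 1
                elif a in obs:
                    hom_counts[2] += 1
                else:
                    hom_counts[3] += 1

    if het_counts.sum() + hom_counts.sum() == 0:
        raise EstimationError("no reference genotypes available for error estimation")
    discordant = het_counts[1:].sum() + hom_counts[1:].sum()
    if discordant == 0:
        return 0.0, 0.0

    from scipy.stats import binom

    def negll(params):
        d, f = params
        d = min(max(d, 1e-9), 0.999)
        f = min(max(f, 1e-9), 0.999)
        p_het = np.array(
            [
                (1 - d) ** 2 * (1 - f) + 2 * d * (1 - d) * f / (A - 1),
                2 * d * (1 - d) * (1 - f) + (1 - d) ** 2 * f / (A - 1),
                d * d,
                ((1 - d) ** 2 + 2 * d * (1 - d)) * f * (A - 2) / (A - 1),
                1e-12,
            ]
        )
        p_hom = np.array([(1 - d * d) * (1 - f), d * d, (1 - d * d) * f, 1e-12])
        p_het = p_het / p_het.sum()
        p_hom = p_hom / p_hom.sum()
        nll = -(het_counts @ np.log(p_het) + hom_counts @ np.log(p_hom))
        # conditioning on the locus having been called from its replicates
        for (ref_type, n_rep), count in cond_events.items():
            if ref_type == "het":
                # called het ~ the true pair observed >= het_threshold times
                p_call = 1.0 - binom.cdf(het_threshold - 1, n_rep, p_het[0])
            else:
                # called hom ~ >= hom_threshold clean homozygous replicates
                # and every other replicate a failure
                ks = np.arange(hom_threshold, n_rep + 1)
                from scipy.special import comb

                p_call = float(
                    np.sum(comb(n_rep, ks) * p_hom[0] ** ks * p_hom[1] ** (n_rep - ks))
                )
            nll += count * math.log(max(p_call, 1e-300))
        return nll

    res = minimize(
        negll, x0=[0.1, 0.05], method="L-BFGS-B", bounds=[(1e-6, 0.95), (1e-6, 0.95)]
    )
    d_hat, f_hat = res.x
    return float(d_hat), float(f_hat)


def _reference_pair(reference, truth_map, sample, locus, locus_index):
    if isinstance(reference, GenotypeArray):
        if truth_map is None or sample not in truth_map:
            return None
        ind = truth_map[sample]
        if ind not in reference.ids or locus not in reference.loci:
            return None
        i = reference.ids.index(ind)
        l = reference.loci.index(locus)
        pair = reference.alleles[i, l]
        if (pair < 0).any():
            return None
        return int(pair[0]), int(pair[1])
    cg = reference.get(sample)
    if cg is None:
        return None
    return cg.allele_pair(locus)


def consensus_to_array(
    consensus: Mapping[str, ConsensusGenotype],
    loci: list[str] | None = None,
    populations: Mapping[str, str] | None = None,
) -> GenotypeArray:
    """Stack consensus genotypes into a :class:`GenotypeArray` (failed = -1)."""
    samples = sorted(consensus)
    if loci is None:
        loci = sorted({l for cg in consensus.values() for l in cg.calls})
    arr = np.full((len(samples), len(loci), 2), MISSING, dtype=int)
    for i, s in enumerate(samples):
        for j, locus in enumerate(loci):
            pair = consensus[s].allele_pair(locus)
            if pair is not None:
                arr[i, j] = pair
    pops = [populations.get(s, "NA") for s in samples] if populations else None
    return GenotypeArray(samples, loci, arr, pops)
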