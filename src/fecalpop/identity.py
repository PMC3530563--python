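"""Identity statistics, recapture matching and molecular sexing.

The probability of identity P_ID (and its full-sibling analogue P_ID-sib)
measures how safely two samples with the same multilocus genotype can be
declared recaptures of one animal.  Samples are collapsed to individuals by
connected-component matching: identical genotypes at all mutually called
loci always match; in exhaustively sampled focal populations a single allele
difference is additionally tolerated when the sexes agree, since dropout in
one consensus can shift one allele.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .errors import ValidationError
from .genotypes import MISSING, GenotypeArray


# ---------------------------------------------------------------------------
# Probability of identity
# ---------------------------------------------------------------------------

@dataclass
class IdentityStats:
    per_locus_pid: dict[str, float]
    per_locus_pid_sib: dict[str, float]

    @property
    def cumulative_pid(self) -> float:
        return float(np.prod(list(self.per_locus_pid.values())))

    @property
    def cumulative_pid_sib(self) -> float:
        return float(np.prod(list(self.per_locus_pid_sib.values())))


def probability_of_identity(
    allele_freqs: Mapping[str, Mapping[int, float]], tol: float = 1e-6
) -> IdentityStats:
    """P_ID and P_ID-sib per locus and cumulatively (product across loci).

    Per locus with allele frequencies p_i:
    ``P_ID = Σ p_i^4 + Σ_{i<j} (2 p_i p_j)^2`` and
    ``P_ID_sib = 0.25 + 0.5 Σ p_i^2 + 0.5 (Σ p_i^2)^2 - 0.25 Σ p_i^4``.
    """
    pid, pid_sib = {}, {}
    for locus, freqs in allele_freqs.items():
        p = np.asarray(list(freqs.values()), dtype=float)
        if abs(p.sum() - 1.0) > tol:
            raise ValidationError(f"allele frequencies at {locus!r} sum to {p.sum():.6f}")
        s2 = float(np.sum(p**2))
        s4 = float(np.sum(p**4))
        hets = 0.0
        for i in range(len(p)):
            for j in range(i + 1, len(p)):
                hets += (2.0 * p[i] * p[j]) ** 2
        pid[locus] = s4 + hets
        pid_sib[locus] = 0.25 + 0.5 * s2 + 0.5 * s2 * s2 - 0.25 * s4
    return IdentityStats(pid, pid_sib)


# ---------------------------------------------------------------------------
# Molecular sexing
# ---------------------------------------------------------------------------

def assign_sex(sex_replicates: Sequence[str]) -> str:
    """Resolve band-call replicates into M / F / unknown.

    Two bands (Zfx+Zfy) confirmed twice make a male; a single band confirmed
    three times with no two-band observation makes a female — dropout can
    hide the Y band but never create it, so any two-band call rules out F.
    """
    calls = [c for c in sex_replicates if c != "fail"]
    two = sum(1 for c in calls if c == "two_bands")
    one = sum(1 for c in calls if c == "one_band")
    if two >= 2:
        return "M"
    if two == 0 and one >= 3:
        return "F"
    return "unknown"


# ---------------------------------------------------------------------------
# Recapture matching
# ---------------------------------------------------------------------------

@dataclass
class Individual:
    individual_id: str
    member_sample_ids: list[str]
    genotype: np.ndarray  # (n_loci, 2), MISSING for failed
    sex: str
    haplotype_id: Optional[str]
    population: str
    flags: list[str] = field(default_factory=list)


@dataclass
class MatchAudit:
    """One pairwise merge decision, for the audit log."""

    sample_a: str
    sample_b: str
    rule: str  # 'exact' | 'one_mismatch'
    n_shared_loci: int
    n_allele_mismatches: int


def _pair_mismatches(g1: np.ndarray, g2: np.ndarray) -> tuple[int, int, int]:
    """(shared loci, total allele mismatches, loci with any mismatch)."""
    called = (g1 >= 0).all(axis=1) & (g2 >= 0).all(axis=1)
    shared = int(called.sum())
    mismatch_alleles = 0
    mismatch_loci = 0
    for l in np.where(called)[0]:
        a = list(g1[l])
        diff = 2
        for x in g2[l]:
            if x in a:
                a.remove(x)
                diff -= 1
        if diff:
            mismatch_loci += 1
            mismatch_alleles += diff
    return shared, mismatch_alleles, mismatch_loci


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def match_samples(
    genotypes: GenotypeArray,
    sexes: Mapping[str, str] | None = None,
    haplotypes: Mapping[str, str] | None = None,
    one_mismatch_populations: Iterable[str] = (),
    min_shared_loci: int = 8,
    require_haplotype_consistency: bool = True,
) -> tuple[list[Individual], list[MatchAudit], list[str]]:
    """Cluster samples into individuals by genotype matching.

    Returns (individuals, merge audit, conflict messages).  An edge joins two
    samples when their genotypes agree at every mutually called locus (with
    at least ``min_shared_loci`` of them), or — for samples from populations
    in ``one_mismatch_populations`` — when they differ by exactly one allele
    at one locus and their sexes match.  Sex or haplotype contradictions veto
    an edge; contradictions arising inside a component through transitivity
    are reported, never silently merged away.
    """
    n = len(genotypes)
    sexes = dict(sexes or {})
    haplotypes = dict(haplotypes or {})
    one_mm = set(one_mismatch_populations)
    pops = genotypes.populations or ["NA"] * n
    order = sorted(range(n), key=lambda i: genotypes.ids[i])
    uf = _UnionFind(n)
    audits: list[MatchAudit] = []
    for oi in range(n):
        i = order[oi]
        for oj in range(oi + 1, n):
            j = order[oj]
            shared, mm_alleles, mm_loci = _pair_mismatches(
                genotypes.alleles[i], genotypes.alleles[j]
            )
            if shared < min_shared_loci:
                continue
            sid_i, sid_j = genotypes.ids[i], genotypes.ids[j]
            sex_i, sex_j = sexes.get(sid_i, "unknown"), sexes.get(sid_j, "unknown")
            sex_conflict = {sex_i, sex_j} == {"M", "F"}
            hap_i, hap_j = haplotypes.get(sid_i), haplotypes.get(sid_j)
            hap_conflict = hap_i is not None and hap_j is not None and hap_i != hap_j
            if mm_alleles == 0:
                if sex_conflict or (require_haplotype_consistency and hap_conflict):
                    continue
                uf.union(i, j)
                audits.append(MatchAudit(sid_i, sid_j, "exact", shared, 0))
            elif mm_alleles == 1 and mm_loci == 1:
                if pops[i] not in one_mm or pops[j] not in one_mm:
                    continue
                if sex_i == "unknown" or sex_i != sex_j:
                    continue
                if require_haplotype_consistency and hap_conflict:
                    continue
                uf.union(i, j)
                audits.append(MatchAudit(sid_i, sid_j, "one_mismatch", shared, 1))
    components: dict[int, list[int]] = {}
    for i in order:
        components.setdefault(uf.find(i), []).append(i)
    individuals: list[Individual] = []
    conflicts: list[str] = []
    for k, root in enumerate(sorted(components, key=lambda r: genotypes.ids[r]), start=1):
        members = sorted(components[root], key=lambda i: genotypes.ids[i])
        member_ids = [genotypes.ids[i] for i in members]
        geno = _component_consensus(genotypes.alleles[members])
        member_sexes = {sexes.get(s, "unknown") for s in member_ids} - {"unknown"}
        member_haps = {haplotypes[s] for s in member_ids if haplotypes.get(s) is not None}
        flags = []
        if len(member_sexes) > 1:
            flags.append("sex_conflict")
            conflicts.append(f"component {member_ids}: conflicting sexes {sorted(member_sexes)}")
        if len(member_haps) > 1:
            flags.append("haplotype_conflict")
            conflicts.append(
                f"component {member_ids}: conflicting haplotypes {sorted(member_haps)}"
            )
        sex = member_sexes.pop() if len(member_sexes) == 1 else "unknown"
        hap = member_haps.pop() if len(member_haps) == 1 else None
        pop_counts: dict[str, int] = {}
        for i in members:
            pop_counts[pops[i]] = pop_counts.get(pops[i], 0) + 1
        population = max(sorted(pop_counts), key=lambda p: pop_counts[p])
        individuals.append(
            Individual(f"I{k:04d}", member_ids, geno, sex, hap, population, flags)
        )
    return individuals, audits, conflicts


def _component_consensus(member_alleles: np.ndarray) -> np.ndarray:
    """Per-locus majority genotype across a component's member samples."""
    n, L, _ = member_alleles.shape
    out = np.full((L, 2), MISSING, dtype=int)
    for l in range(L):
        pairs = [tuple(p) for p in member_alleles[:, l] if (p >= 0).all()]
        if not pairs:
            continue
        counts: dict[tuple[int, int], int] = {}
        for p in pairs:
            counts[p] = counts.get(p, 0) + 1
        best = max(counts.values())
        winners = sorted(p for p, c in counts.items() if c == best)
        out[l] = winners[0]
    return out


def individuals_to_array(individuals: Sequence[Individual], loci: list[str]) -> GenotypeArray:
    alleles = np.stack([ind.genotype for ind in individuals])
    return GenotypeArray(
        [ind.individual_id for ind in individuals],
        list(loci),
        alleles,
        [ind.population for ind in individuals],
    )
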