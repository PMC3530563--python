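"""Per-population diversity and pairwise differentiation statistics.

Nuclear differentiation uses the Weir–Cockerham variance-component estimator
θ of F_ST; mitochondrial differentiation uses the AMOVA Φ_ST computed from a
molecular distance matrix (Kimura 2-parameter by default), where the
pairwise distances play the role of squared Euclidean distances in the sum-
of-squares decomposition.  Significance of both comes from permuting
individuals between populations.  Hardy–Weinberg and linkage tests follow
the conditional exact-test logic with Monte-Carlo sampling of tables.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .errors import EstimationError, ValidationError
from .genotypes import GenotypeArray
from .io_formats import SequenceSet
from .phylo import pairwise_distances


# ---------------------------------------------------------------------------
# Diversity
# ---------------------------------------------------------------------------

def diversity(
    genotypes: GenotypeArray,
    sequences: Optional[SequenceSet] = None,
    seq_populations: Optional[Mapping[str, str]] = None,
    distance_model: str = "p_distance",
) -> pd.DataFrame:
    """Per-population A (mean alleles/locus), H_E, H_O and percent mtDNA π.

    H_E uses the small-sample correction ``(2n/(2n-1)) (1 - Σ p_i²)``;
    π is the mean pairwise sequence distance within the population, as a
    percentage.  Populations with a single individual are excluded.
    """
    rows = {}
    for pop, sub in genotypes.by_population().items():
        if len(sub) < 2:
            warnings.warn(f"population {pop!r} has <2 individuals; excluded")
            continue
        a_counts, he_vals, ho_vals = [], [], []
        for l in range(len(sub.loci)):
            called = sub.called_mask[:, l]
            n = int(called.sum())
            if n == 0:
                continue
            pairs = sub.alleles[called, l, :]
            freqs = np.asarray(list(sub.allele_freqs(l).values()))
            a_counts.append(len(freqs))
            he = (2 * n / (2 * n - 1)) * (1.0 - float(np.sum(freqs**2))) if n > 0 else np.nan
            he_vals.append(he)
            ho_vals.append(float(np.mean(pairs[:, 0] != pairs[:, 1])))
        pi = np.nan
        if sequences is not None and seq_populations is not None:
            ids = [i for i in sequences.ids if seq_populations.get(i) == pop]
            if len(ids) >= 2:
                dm = pairwise_distances(sequences.subset(ids), model=distance_model)
                iu = np.triu_indices(len(ids), k=1)
                pi = 100.0 * float(dm.values[iu].mean())
        rows[pop] = {
            "A": float(np.mean(a_counts)),
            "H_E": float(np.mean(he_vals)),
            "H_O": float(np.mean(ho_vals)),
            "pi_percent": pi,
        }
    return pd.DataFrame(rows).T


def collapse_haplotypes(
    sequences: SequenceSet, prefix: str = "H"
) -> tuple[dict[str, str], SequenceSet]:
    """Collapse identical aligned sequences to named haplotypes.

    Returns (sequence id -> haplotype id, unique haplotype set); haplotypes
    are numbered by decreasing frequency, ties broken by first occurrence.
    """
    sequences.require_alignment()
    groups: dict[str, list[str]] = {}
    for sid, seq in zip(sequences.ids, sequences.seqs):
        groups.setdefault(seq, []).append(sid)
    ordered = sorted(
        groups.items(), key=lambda kv: (-len(kv[1]), sequences.ids.index(kv[1][0]))
    )
    mapping: dict[str, str] = {}
    hap_ids, hap_seqs = [], []
    for i, (seq, members) in enumerate(ordered, start=1):
        hid = f"{prefix}{i:02d}"
        hap_ids.append(hid)
        hap_seqs.append(seq)
        for sid in members:
            mapping[sid] = hid
    return mapping, SequenceSet(hap_ids, hap_seqs)


# ---------------------------------------------------------------------------
# HWE and LD tests
# ---------------------------------------------------------------------------

def _log_table_prob(pairs: np.ndarray) -> float:
    """Log conditional probability of a genotype table given allele counts.

    Up to the constant shared by all tables with the same allele counts:
    ``h·log 2 − Σ_g log(n_g!)`` with h the number of heterozygotes.
    """
    h = int(np.sum(pairs[:, 0] != pairs[:, 1]))
    _, counts = np.unique(pairs[:, 0] * 100000 + pairs[:, 1], return_counts=True)
    return h * math.log(2.0) - float(np.sum(gammaln(counts + 1.0)))


def hwe_test(pairs: np.ndarray, n_mc: int = 10000, seed: int = 0) -> float:
    """Exact probability test for Hardy–Weinberg equilibrium at one locus.

    ``pairs`` is an (n, 2) array of called allele pairs.  For two alleles the
    table space is enumerated completely; otherwise the null distribution of
    table probabilities is sampled by Monte-Carlo re-pairing of the allele
    multiset (Guo & Thompson style).  Monomorphic loci return p = 1.
    """
    pairs = np.sort(np.asarray(pairs, dtype=int), axis=1)
    if len(pairs) < 1:
        raise EstimationError("no genotypes for HWE test")
    alleles, counts = np.unique(pairs.ravel(), return_counts=True)
    if len(alleles) < 2:
        return 1.0
    if len(alleles) == 2:
        return _hwe_exact_biallelic(pairs, counts)
    rng = np.random.default_rng(seed)
    obs = _log_table_prob(pairs)
    flat = pairs.ravel().copy()
    hits = 0
    for _ in range(n_mc):
        rng.shuffle(flat)
        perm = np.sort(flat.reshape(-1, 2), axis=1)
        if _log_table_prob(perm) <= obs + 1e-12:
            hits += 1
    return (hits + 1) / (n_mc + 1)


def _hwe_exact_biallelic(pairs: np.ndarray, allele_counts: np.ndarray) -> float:
    n = len(pairs)
    c1 = int(min(allele_counts))
    h_obs = int(np.sum(pairs[:, 0] != pairs[:, 1]))
    hs = np.arange(c1 % 2, c1 + 1, 2)
    logp = (
        hs * math.log(2.0)
        - gammaln((c1 - hs) / 2 + 1)
        - gammaln(hs + 1.0)
        - gammaln((2 * n - c1 - hs) / 2 + 1)
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    p_obs = probs[np.where(hs == h_obs)[0][0]]
    return float(probs[probs <= p_obs + 1e-12].sum())


def ld_test(
    pairs_a: np.ndarray, pairs_b: np.ndarray, n_perm: int = 2000, seed: int = 0
) -> float:
    """Permutation G-test for linkage disequilibrium between two loci.

    Composite genotypes at each locus form a contingency table; the null
    distribution of the G statistic comes from shuffling one locus's
    genotypes across individuals.
    """
    if len(pairs_a) != len(pairs_b):
        raise ValidationError("locus genotype arrays differ in length")
    code_a = _genotype_codes(pairs_a)
    code_b = _genotype_codes(pairs_b)
    obs = _g_stat(code_a, code_b)
    rng = np.random.default_rng(seed)
    shuffled = code_b.copy()
    hits = 0
    for _ in range(n_perm):
        rng.shuffle(shuffled)
        if _g_stat(code_a, shuffled) >= obs - 1e-12:
            hits += 1
    return (hits + 1) / (n_perm + 1)


def _genotype_codes(pairs: np.ndarray) -> np.ndarray:
    pairs = np.sort(np.asarray(pairs, dtype=int), axis=1)
    keys = pairs[:, 0] * 100000 + pairs[:, 1]
    _, codes = np.unique(keys, return_inverse=True)
    return codes


def _g_stat(a: np.ndarray, b: np.ndarray) -> float:
    table = np.zeros((a.max() + 1, b.max() + 1))
    np.add.at(table, (a, b), 1.0)
    rowsums = table.sum(axis=1, keepdims=True)
    colsums = table.sum(axis=0, keepdims=True)
    expected = rowsums * colsums / table.sum()
    mask = table > 0
    return 2.0 * float(np.sum(table[mask] * np.log(table[mask] / expected[mask])))


def bonferroni(p_values: Sequence[float]) -> list[float]:
    """Bonferroni-adjusted p-values (capped at 1)."""
    m = len(p_values)
    return [min(1.0, p * m) for p in p_values]


# ---------------------------------------------------------------------------
# Weir-Cockerham theta
# ---------------------------------------------------------------------------

def _locus_matrices(genotypes: GenotypeArray):
    """Per locus: (called indices, allele dosage matrix, het-carrier matrix)."""
    out = []
    for l in range(len(genotypes.loci)):
        called = np.where(genotypes.called_mask[:, l])[0]
        pairs = genotypes.alleles[called, l, :]
        alleles = np.unique(pairs)
        dosage = (pairs[:, 0][:, None] == alleles) * 1.0 + (pairs[:, 1][:, None] == alleles)
        het = ((pairs[:, 0] != pairs[:, 1])[:, None]) * ((dosage > 0) & (dosage < 2))
        out.append((called, dosage, het.astype(float)))
    return out


def _theta_components(locus_data, assignment: np.ndarray) -> tuple[float, float]:
    """Σa and Σ(a+b+c) over alleles and loci for a population assignment.

    ``assignment`` maps each individual row to a population code (>= 0);
    rows coded -1 are ignored.
    """
    num = 0.0
    den = 0.0
    r_all = int(assignment.max()) + 1
    for called, dosage, het in locus_data:
        codes = assignment[called]
        keep = codes >= 0
        codes = codes[keep]
        dos = dosage[keep]
        ht = het[keep]
        ni = np.bincount(codes, minlength=r_all).astype(float)
        present = ni >= 1
        r = int(present.sum())
        if r < 2 or ni[present].sum() < 2:
            continue
        ni = ni[present]
        nbar = ni.mean()
        if nbar <= 1:
            continue
        nc = (r * nbar - np.sum(ni**2) / (r * nbar)) / (r - 1)
        # per-population allele freqs and het frequencies
        n_alleles = dos.shape[1]
        sums = np.zeros((r_all, n_alleles))
        hsums = np.zeros((r_all, n_alleles))
        np.add.at(sums, codes, dos)
        np.add.at(hsums, codes, ht)
        sums = sums[present]
        hsums = hsums[present]
        p = sums / (2.0 * ni[:, None])
        h = hsums / ni[:, None]
        pbar = np.sum(ni[:, None] * p, axis=0) / (r * nbar)
        s2 = np.sum(ni[:, None] * (p - pbar) ** 2, axis=0) / ((r - 1) * nbar)
        hbar = np.sum(ni[:, None] * h, axis=0) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4.0) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
        )
        c = hbar / 2.0
        num += float(a.sum())
        den += float((a + b + c).sum())
    return num, den


def weir_cockerham_theta(genotypes: GenotypeArray, labels: Sequence[str]) -> float:
    """Multi-locus Weir–Cockerham θ over the populations in ``labels``."""
    pops = sorted(set(labels))
    code = {p: i for i, p in enumerate(pops)}
    assignment = np.array([code[l] for l in labels])
    locus_data = _locus_matrices(genotypes)
    num, den = _theta_components(locus_data, assignment)
    if den == 0.0:
        raise EstimationError("no polymorphic loci; theta undefined")
    return num / den


def fst_microsat(
    genotypes: GenotypeArray,
    pop_a: str,
    pop_b: str,
    n_perm: int = 10000,
    seed: int = 0,
) -> tuple[float, float]:
    """Pairwise Weir–Cockerham θ between two populations with permutation p.

    The null distribution shuffles individuals between the two populations;
    p is the fraction of permutations with θ at least as large as observed
    (with the observed arrangement counted once).
    """
    if genotypes.populations is None:
        raise ValidationError("genotypes carry no population labels")
    idx = [i for i, p in enumerate(genotypes.populations) if p in (pop_a, pop_b)]
    sub = genotypes.subset(idx)
    labels = np.array([0 if p == pop_a else 1 for p in sub.populations])
    if min((labels == 0).sum(), (labels == 1).sum()) < 2:
        raise EstimationError("need >=2 individuals per population")
    locus_data = _locus_matrices(sub)
    num, den = _theta_components(locus_data, labels)
    if den == 0.0:
        raise EstimationError("no polymorphic loci; theta undefined")
    theta = num / den
    rng = np.random.default_rng(seed)
    perm = labels.copy()
    hits = 0
    for _ in range(n_perm):
        rng.shuffle(perm)
        pn, pdn = _theta_components(locus_data, perm)
        t = pn / pdn if pdn else 0.0
        if t >= theta - 1e-12:
            hits += 1
    return theta, (hits + 1) / (n_perm + 1)


# ---------------------------------------------------------------------------
# AMOVA Phi_ST
# ---------------------------------------------------------------------------

def amova_phi_st(sq_dist: np.ndarray, labels: np.ndarray) -> float:
    """Φ_ST from the sum-of-squares decomposition of a squared-distance matrix."""
    n = len(labels)
    groups = np.unique(labels)
    iu = np.triu_indices(n, k=1)
    ss_total = float(sq_dist[iu].sum()) / n
    ss_within = 0.0
    sizes = []
    for g in groups:
        idx = np.where(labels == g)[0]
        sizes.append(len(idx))
        if len(idx) >= 2:
            sub = sq_dist[np.ix_(idx, idx)]
            ss_within += float(np.triu(sub, k=1).sum()) / len(idx)
    ss_among = ss_total - ss_within
    g = len(groups)
    df_a, df_w = g - 1, n - g
    if df_a == 0 or df_w == 0:
        return 0.0
    sigma_w = ss_within / df_w
    nprime = (n - sum(s * s for s in sizes) / n) / df_a
    sigma_a = (ss_among / df_a - sigma_w) / nprime
    tot = sigma_a + sigma_w
    if tot == 0.0:
        return 0.0
    return sigma_a / tot


def phi_st_mtdna(
    sequences: SequenceSet,
    populations: Mapping[str, str],
    pop_a: str,
    pop_b: str,
    distance_model: str = "K2P",
    n_perm: int = 10000,
    seed: int = 0,
) -> tuple[float, float]:
    """Pairwise AMOVA Φ_ST between two populations of mtDNA sequences.

    Distances under ``distance_model`` serve as the squared inter-haplotype
    distances of the AMOVA; p comes from permuting individuals between the
    two populations.  If every sequence is identical, Φ_ST = 0 with p = 1.
    """
    ids = [i for i in sequences.ids if populations.get(i) in (pop_a, pop_b)]
    sub = sequences.subset(ids)
    labels = np.array([0 if populations[i] == pop_a else 1 for i in ids])
    if min((labels == 0).sum(), (labels == 1).sum()) < 2:
        raise EstimationError("need >=2 sequences per population")
    dm = pairwise_distances(sub, model=distance_model)
    if np.allclose(dm.values, 0.0):
        return 0.0, 1.0
    phi = amova_phi_st(dm.values, labels)
    rng = np.random.default_rng(seed)
    perm = labels.copy()
    hits = 0
    for _ in range(n_perm):
        rng.shuffle(perm)
        if amova_phi_st(dm.values, perm) >= phi - 1e-12:
            hits += 1
    return phi, (hits + 1) / (n_perm + 1)


# ---------------------------------------------------------------------------
# Pairwise matrices and regional subdivision
# ---------------------------------------------------------------------------

@dataclass
class PairwiseFstMatrix:
    """Pairwise differentiation estimates with permutation p-values."""

    labels: list[str]
    marker: str  # 'microsatellite_theta' | 'mtdna_phi_st'
    entries: dict[tuple[str, str], tuple[float, float, int]] = field(default_factory=dict)

    def set(self, a: str, b: str, est: float, p: float, n_perm: int) -> None:
        key = tuple(sorted((a, b)))
        self.entries[key] = (est, p, n_perm)

    def get(self, a: str, b: str) -> tuple[float, float, int]:
        return self.entries[tuple(sorted((a, b)))]

    def to_frame(self) -> pd.DataFrame:
        """Estimates below the diagonal, p-values above (reporting layout)."""
        n = len(self.labels)
        out = pd.DataFrame(np.full((n, n), np.nan), index=self.labels, columns=self.labels)
        for (a, b), (est, p, _) in self.entries.items():
            ia, ib = self.labels.index(a), self.labels.index(b)
            lo, hi = min(ia, ib), max(ia, ib)
            out.iloc[hi, lo] = est
            out.iloc[lo, hi] = p
        return out


def pairwise_fst_matrix(
    genotypes: GenotypeArray, n_perm: int = 10000, seed: int = 0
) -> PairwiseFstMatrix:
    """All pairwise microsatellite θ values among the labelled populations."""
    pops = sorted(set(genotypes.populations or []))
    mat = PairwiseFstMatrix(pops, "microsatellite_theta")
    for k, (a, b) in enumerate(itertools.combinations(pops, 2)):
        est, p = fst_microsat(genotypes, a, b, n_perm=n_perm, seed=seed + k)
        mat.set(a, b, est, p, n_perm)
    return mat


def pairwise_phi_st_matrix(
    sequences: SequenceSet,
    populations: Mapping[str, str],
    distance_model: str = "K2P",
    n_perm: int = 10000,
    seed: int = 0,
    min_sequences: int = 2,
) -> PairwiseFstMatrix:
    """All pairwise mtDNA Φ_ST values among the labelled populations."""
    counts: dict[str, int] = {}
    for i in sequences.ids:
        pop = populations.get(i)
        if pop is not None:
            counts[pop] = counts.get(pop, 0) + 1
    pops = sorted(p for p, c in counts.items() if c >= min_sequences)
    dropped = sorted(set(counts) - set(pops))
    if dropped:
        warnings.warn(f"populations with <{min_sequences} sequences excluded: {dropped}")
    mat = PairwiseFstMatrix(pops, "mtdna_phi_st")
    for k, (a, b) in enumerate(itertools.combinations(pops, 2)):
        est, p = phi_st_mtdna(
            sequences, populations, a, b, distance_model=distance_model,
            n_perm=n_perm, seed=seed + k,
        )
        mat.set(a, b, est, p, n_perm)
    return mat


def regional_subdivision(
    sequences: SequenceSet,
    populations: Mapping[str, str],
    region_assignment: Mapping[str, str],
    distance_model: str = "K2P",
    n_perm: int = 10000,
    seed: int = 0,
) -> PairwiseFstMatrix:
    """Split one population into regions and redo the pairwise Φ_ST analysis.

    ``region_assignment`` maps sequence ids (of the split population) to
    region labels; sequences it does not mention keep their population label,
    so the result covers regions plus the external populations.
    """
    relabelled = {
        sid: region_assignment.get(sid, populations.get(sid))
        for sid in sequences.ids
        if region_assignment.get(sid, populations.get(sid)) is not None
    }
    return pairwise_phi_st_matrix(
        sequences, relabelled, distance_model=distance_model, n_perm=n_perm, seed=seed
    )
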