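"""Synthetic metapopulations, dung samples and replicate genotypes.

The generator emulates a savannah-elephant metapopulation split by a
dispersal barrier (a rift valley): maternally inherited mtDNA haplotype
pools are near-disjoint across the barrier because females are philopatric,
while nuclear microsatellite differentiation is weak because males mediate
gene flow.  Defaults mirror the study system: five demes (four parks plus a
recently recolonised focal area), 12 microsatellite loci with ~7 alleles
each, a 650 bp mtDNA control-region fragment, heavy recapture sampling in
the focal deme, and the standard two-parameter genotyping error model for
faecal DNA (allelic dropout plus false alleles).

Nuclear deme allele frequencies follow the Balding–Nichols F-model: deme
frequencies are Dirichlet-distributed around the ancestral frequencies with
concentration (1-F)/F, so the expected Weir–Cockerham F_ST equals the
``target_fst`` parameter.  A migration rate m may be given instead and is
mapped through the island-model relation F_ST = 1/(1 + 4Nm).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io_formats import GENOTYPE_COLUMNS, SequenceSet

DNA = np.array(list("ACGT"))

#: Deme labels follow the study populations: Amboseli (AM) and Tarangire (TA)
#: east of the barrier, Maasai Mara (MM) and Serengeti (SE) west of it, and a
#: focal community conservation area (CCA) recolonised from the west.
DEFAULT_DEMES = ("AM", "MM", "CCA", "SE", "TA")
DEFAULT_BARRIER = {"AM": "east", "TA": "east", "MM": "west", "SE": "west", "CCA": "west"}
DEFAULT_DEME_SIZES = {"AM": 47, "MM": 39, "CCA": 112, "SE": 59, "TA": 55}
DEFAULT_RECAPTURE = {"AM": 1.05, "MM": 1.15, "CCA": 2.8, "SE": 1.05, "TA": 1.05}


@dataclass
class SimulationConfig:
    """All knobs of the simulated study design.

    Rates are probabilities per event; ``dropout_rate`` is the per-allele,
    per-replicate dropout probability and ``false_allele_rate`` the
    per-replicate probability that one allele call is replaced by a spurious
    one.  ``recapture_mean`` is the mean number of dung samples per captured
    individual (shifted Poisson).
    """

    demes: tuple[str, ...] = DEFAULT_DEMES
    deme_sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_DEME_SIZES))
    barrier_assignment: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_BARRIER))
    n_loci: int = 12
    alleles_per_locus: int = 7
    target_fst: Optional[float] = 0.01
    migration_rate: Optional[float] = None  # overrides target_fst via 1/(1+4Nm)
    effective_size: int = 500  # N in the island-model mapping
    female_migration_rate: float = 0.0
    focal_deme: Optional[str] = "CCA"
    focal_source_side: str = "west"
    n_haplotypes_per_side: int = 4
    haplotype_divergence: int = 25  # substitutions between side ancestors
    within_side_divergence: int = 2  # max substitutions from the side ancestor
    within_side_concentration: float = 500.0  # Dirichlet conc. tying demes of a side
    seq_length: int = 650
    dropout_rate: float = 0.2
    false_allele_rate: float = 0.05
    recapture_mean: float = 1.05
    recapture_mean_by_deme: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RECAPTURE)
    )
    replicates_per_sample: int = 5
    sex_replicates_per_sample: int = 4
    seed: int = 0

    def validate(self) -> None:
        for name, val in (
            ("dropout_rate", self.dropout_rate),
            ("false_allele_rate", self.false_allele_rate),
            ("female_migration_rate", self.female_migration_rate),
        ):
            if not 0.0 <= val <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {val}")
        if self.migration_rate is not None and not 0.0 <= self.migration_rate <= 1.0:
            raise ConfigError("migration_rate must be in [0, 1]")
        if self.resolved_fst() is not None and not 0.0 <= self.resolved_fst() < 1.0:
            raise ConfigError(f"target F_ST {self.resolved_fst()} outside [0, 1)")
        for d in self.demes:
            if self.deme_sizes.get(d, 0) < 2:
                raise ConfigError(f"deme {d!r} needs size >= 2")
            if self.barrier_assignment.get(d) not in ("east", "west"):
                raise ConfigError(f"deme {d!r} lacks an east/west barrier assignment")
        if self.seq_length < 1:
            raise ConfigError("seq_length must be >= 1")

    def resolved_fst(self) -> Optional[float]:
        if self.migration_rate is not None:
            return 1.0 / (1.0 + 4.0 * self.effective_size * self.migration_rate)
        return self.target_fst


@dataclass
class TrueIndividual:
    """Ground-truth animal: complete genotype, sex, deme and mtDNA haplotype."""

    individual_id: str
    deme: str
    sex: str  # 'M' or 'F'
    genotype: np.ndarray  # (n_loci, 2) allele sizes in bp
    haplotype_id: str


@dataclass
class SimulatedTruth:
    """Everything the generator knows: individuals plus the frequency model."""

    individuals: list[TrueIndividual]
    haplotypes: SequenceSet
    haplotype_side: dict[str, str]
    allele_sizes: list[np.ndarray]  # per locus, bp values
    deme_allele_freqs: np.ndarray  # (n_demes, n_loci, alleles_per_locus)
    deme_haplotype_freqs: pd.DataFrame  # demes x haplotype ids
    config: SimulationConfig

    def by_deme(self, deme: str) -> list[TrueIndividual]:
        return [ind for ind in self.individuals if ind.deme == deme]


def _mutate(seq: np.ndarray, n_sub: int, rng: np.random.Generator) -> np.ndarray:
    """Apply ``n_sub`` substitutions at distinct positions."""
    seq = seq.copy()
    pos = rng.choice(len(seq), size=min(n_sub, len(seq)), replace=False)
    for p in pos:
        choices = [b for b in "ACGT" if b != seq[p]]
        seq[p] = rng.choice(choices)
    return seq


def simulate_metapopulation(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> SimulatedTruth:
    """Draw a metapopulation of true individuals under the configured model."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    fst = config.resolved_fst()
    n_loci, n_all = config.n_loci, config.alleles_per_locus
    demes = list(config.demes)

    # nuclear: ancestral frequencies, then Balding-Nichols deme frequencies
    allele_sizes = []
    for _ in range(n_loci):
        base = int(rng.integers(100, 280))
        allele_sizes.append(base + 2 * np.arange(n_all))
    anc = rng.dirichlet(np.full(n_all, 1.5), size=n_loci)  # (L, A)
    if fst and fst > 0:
        conc = (1.0 - fst) / fst
        deme_freqs = np.empty((len(demes), n_loci, n_all))
        for d in range(len(demes)):
            for l in range(n_loci):
                deme_freqs[d, l] = rng.dirichlet(anc[l] * conc)
    else:
        deme_freqs = np.broadcast_to(anc, (len(demes), n_loci, n_all)).copy()

    # mtDNA: two diverged side pools of haplotypes
    root = DNA[rng.integers(0, 4, size=config.seq_length)]
    side_anc = {"east": root, "west": _mutate(root, config.haplotype_divergence, rng)}
    hap_ids, hap_seqs, hap_side = [], [], {}
    for side, prefix in (("west", "W"), ("east", "E")):
        for i in range(config.n_haplotypes_per_side):
            hid = f"{prefix}{i + 1}"
            n_sub = int(rng.integers(0, config.within_side_divergence + 1)) if i else 0
            hap_ids.append(hid)
            hap_seqs.append("".join(_mutate(side_anc[side], n_sub, rng)))
            hap_side[hid] = side
    haplotypes = SequenceSet(hap_ids, hap_seqs)

    # per-side base haplotype frequencies; demes of a side share them up to
    # Dirichlet noise controlled by within_side_concentration
    side_base = {
        side: rng.dirichlet(np.full(config.n_haplotypes_per_side, 3.0))
        for side in ("west", "east")
    }
    hap_freq_rows = {}
    for deme in demes:
        side = config.barrier_assignment[deme]
        base = side_base[side]
        freqs = rng.dirichlet(base * config.within_side_concentration)
        row = np.zeros(len(hap_ids))
        ids_of_side = [i for i, h in enumerate(hap_ids) if hap_side[h] == side]
        row[ids_of_side] = freqs
        hap_freq_rows[deme] = row
    hap_freq_df = pd.DataFrame(hap_freq_rows, index=hap_ids).T

    # individuals
    individuals: list[TrueIndividual] = []
    counter = 0
    source_demes = [
        d
        for d in demes
        if config.barrier_assignment[d] == config.focal_source_side and d != config.focal_deme
    ]
    for di, deme in enumerate(demes):
        is_focal = deme == config.focal_deme
        for _ in range(config.deme_sizes[deme]):
            counter += 1
            ind_id = f"{deme}_ind{counter:04d}"
            if is_focal and source_demes:
                src = rng.choice(source_demes)
                src_i = demes.index(src)
            else:
                src, src_i = deme, di
            geno = np.empty((n_loci, 2), dtype=int)
            for l in range(n_loci):
                picks = rng.choice(n_all, size=2, p=deme_freqs[src_i, l])
                geno[l] = np.sort(allele_sizes[l][picks])
            # haplotype: philopatric mother, with optional cross-barrier migrant
            hap_deme = src
            if config.female_migration_rate > 0 and rng.random() < config.female_migration_rate:
                other = [
                    d
                    for d in demes
                    if config.barrier_assignment[d] != config.barrier_assignment[src]
                ]
                if other:
                    hap_deme = rng.choice(other)
            hp = hap_freq_df.loc[hap_deme].to_numpy()
            hap = hap_ids[int(rng.choice(len(hap_ids), p=hp / hp.sum()))]
            sex = "M" if rng.random() < 0.5 else "F"
            individuals.append(TrueIndividual(ind_id, deme, sex, geno, hap))

    return SimulatedTruth(
        individuals, haplotypes, hap_side, allele_sizes, deme_freqs, hap_freq_df, config
    )


def _observe_replicate(
    true_pair: np.ndarray,
    locus_alleles: np.ndarray,
    d: float,
    f: float,
    rng: np.random.Generator,
) -> tuple[Optional[int], Optional[int]]:
    """One PCR replicate of one locus under the dropout/false-allele model."""
    a, b = int(true_pair[0]), int(true_pair[1])
    keep_a = rng.random() >= d
    keep_b = rng.random() >= d
    if not keep_a and not keep_b:
        return (None, None)
    if keep_a and keep_b:
        calls = [a, b]
    else:
        surv = a if keep_a else b
        calls = [surv, surv]
    if f > 0 and rng.random() < f:
        slot = int(rng.integers(0, 2))
        others = locus_alleles[locus_alleles != calls[slot]]
        if len(others):
            calls[slot] = int(rng.choice(others))
    return (min(calls), max(calls))


def sample_dung(
    truth: SimulatedTruth,
    config: SimulationConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, SequenceSet, dict[str, str]]:
    """Generate dung samples, replicate genotypes, metadata and the truth map.

    Every individual yields at least one sample; extra samples follow a
    shifted Poisson with the deme's recapture mean.  Each sample carries
    ``replicates_per_sample`` replicate genotypes per locus, sex-typing band
    calls with Y-allele dropout, and its individual's mtDNA sequence.
    """
    if config is None:
        config = truth.config
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    d, f = config.dropout_rate, config.false_allele_rate
    rows, meta_rows = [], []
    seq_ids, seqs = [], []
    truth_map: dict[str, str] = {}
    deme_centers = {
        deme: (-2.0 + 0.5 * i, 35.0 + 0.5 * i) for i, deme in enumerate(config.demes)
    }
    sample_no = 0
    for ind in truth.individuals:
        mean = config.recapture_mean_by_deme.get(ind.deme, config.recapture_mean)
        n_samples = 1 + rng.poisson(max(mean - 1.0, 0.0))
        for _ in range(n_samples):
            sample_no += 1
            sid = f"s{sample_no:05d}"
            truth_map[sid] = ind.individual_id
            for l in range(config.n_loci):
                locus = f"L{l + 1:02d}"
                for rep in range(1, config.replicates_per_sample + 1):
                    a, b = _observe_replicate(
                        ind.genotype[l], truth.allele_sizes[l], d, f, rng
                    )
                    rows.append((sid, locus, rep, a, b))
            sex_calls = []
            for _ in range(config.sex_replicates_per_sample):
                if ind.sex == "M":
                    kx, ky = rng.random() >= d, rng.random() >= d
                    call = "two_bands" if (kx and ky) else ("fail" if not (kx or ky) else "one_band")
                else:
                    call = "one_band" if rng.random() >= d else "fail"
                sex_calls.append(call)
            lat, lon = deme_centers[ind.deme]
            meta_rows.append(
                (
                    sid,
                    ind.deme,
                    None,
                    lat + rng.normal(0, 0.05),
                    lon + rng.normal(0, 0.05),
                    ";".join(sex_calls),
                )
            )
            seq_ids.append(sid)
            seqs.append(truth.haplotypes[ind.haplotype_id])
    table = pd.DataFrame(rows, columns=list(GENOTYPE_COLUMNS))
    meta = pd.DataFrame(
        meta_rows,
        columns=["sample_id", "population", "collection_date", "lat", "lon", "sex_replicates"],
    )
    return table, meta, SequenceSet(seq_ids, seqs), truth_map


def simulate_dataset(config: SimulationConfig):
    """Convenience wrapper: metapopulation plus one sampling season."""
    rng = np.random.default_rng(config.seed)
    truth = simulate_metapopulation(config, rng)
    table, meta, seqs, truth_map = sample_dung(truth, config, rng)
    return truth, table, meta, seqs, truth_map
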