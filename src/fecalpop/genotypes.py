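"""In-memory container for called multilocus genotypes.

A :class:`GenotypeArray` holds one row per individual (or sample) and one
ordered allele pair per locus, with ``-1`` marking a failed locus.  It is the
exchange format between the consensus caller, identity analysis, population
statistics and the admixture sampler.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

MISSING = -1


@dataclass
class GenotypeArray:
    ids: list[str]
    loci: list[str]
    alleles: np.ndarray  # (n, n_loci, 2) int; MISSING for failed calls
    populations: list[str] | None = None

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=int)
        n, L = len(self.ids), len(self.loci)
        if self.alleles.shape != (n, L, 2):
            raise ValidationError(
                f"alleles shape {self.alleles.shape} != ({n}, {L}, 2)"
            )
        if self.populations is not None and len(self.populations) != n:
            raise ValidationError("populations length mismatch")
        # order each called pair (min, max); a pair is called iff both >= 0
        called = (self.alleles >= 0).all(axis=2)
        pairs = self.alleles[called]
        self.alleles[called] = np.sort(pairs, axis=1)
        half = (self.alleles >= 0).any(axis=2) & ~called
        if half.any():
            raise ValidationError("half-called pairs are not allowed in a GenotypeArray")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def called_mask(self) -> np.ndarray:
        """(n, n_loci) bool: locus successfully called."""
        return (self.alleles >= 0).all(axis=2)

    def subset(self, idx: Sequence[int]) -> "GenotypeArray":
        idx = list(idx)
        pops = [self.populations[i] for i in idx] if self.populations else None
        return GenotypeArray(
            [self.ids[i] for i in idx], list(self.loci), self.alleles[idx].copy(), pops
        )

    def by_population(self) -> dict[str, "GenotypeArray"]:
        if self.populations is None:
            raise ValidationError("no population labels attached")
        out = {}
        for pop in sorted(set(self.populations)):
            out[pop] = self.subset([i for i, p in enumerate(self.populations) if p == pop])
        return out

    def allele_counts(self, locus_index: int) -> dict[int, int]:
        vals = self.alleles[:, locus_index, :].ravel()
        vals = vals[vals >= 0]
        uniq, cnt = np.unique(vals, return_counts=True)
        return dict(zip(uniq.tolist(), cnt.tolist()))

    def allele_freqs(self, locus_index: int) -> dict[int, float]:
        counts = self.allele_counts(locus_index)
        tot = sum(counts.values())
        if tot == 0:
            return {}
        return {a: c / tot for a, c in counts.items()}

    def to_frame(self) -> pd.DataFrame:
        cols = {}
        for l, locus in enumerate(self.loci):
            cols[f"{locus}_a"] = self.alleles[:, l, 0]
            cols[f"{locus}_b"] = self.alleles[:, l, 1]
        df = pd.DataFrame(cols, index=self.ids)
        if self.populations is not None:
            df.insert(0, "population", self.populations)
        return df


def from_true_individuals(individuals, loci: Sequence[str] | None = None) -> GenotypeArray:
    """Build a GenotypeArray from simulated :class:`TrueIndividual` objects."""
    n_loci = individuals[0].genotype.shape[0]
    loci = list(loci) if loci is not None else [f"L{i + 1:02d}" for i in range(n_loci)]
    alleles = np.stack([ind.genotype for ind in individuals])
    return GenotypeArray(
        [ind.individual_id for ind in individuals],
        loci,
        alleles,
        [ind.deme for ind in individuals],
    )
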