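"""Readers and writers for every external representation the pipeline touches.

Tabular data are pandas DataFrames with documented columns; sequence sets are a
thin wrapper over Biopython's FASTA I/O.  Microsatellite alleles are stored as
raw fragment sizes in base pairs; Genepop export bins them to rank-ordered
3-digit codes with a persisted allele map so the mapping is invertible.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ParseError, ValidationError

#: Column order of the long-form replicate genotype table.
GENOTYPE_COLUMNS = ("sample_id", "locus_id", "replicate", "allele_a", "allele_b")

#: Allowed sex-typing band calls (Zfx/Zfy fragments).
BAND_CALLS = ("one_band", "two_bands", "fail")

IUPAC_ALPHABET = set("ACGTN-")


# ---------------------------------------------------------------------------
# Replicate genotype tables
# ---------------------------------------------------------------------------

def validate_genotype_table(df: pd.DataFrame) -> pd.DataFrame:
    """Check the invariants of a long-form replicate genotype table.

    Alleles are reordered so ``allele_a <= allele_b`` when both are present;
    a missing call is ``pd.NA`` in both allele columns (half-calls keep one).
    """
    missing_cols = set(GENOTYPE_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValidationError(f"genotype table missing columns: {sorted(missing_cols)}")
    df = df.loc[:, list(GENOTYPE_COLUMNS)].copy()
    for col in ("allele_a", "allele_b"):
        df[col] = df[col].astype("Int64")
    df["replicate"] = df["replicate"].astype(int)
    if (df["replicate"] < 1).any():
        raise ValidationError("replicate indices must be positive integers")
    dup = df.duplicated(subset=["sample_id", "locus_id", "replicate"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValidationError(
            f"duplicate replicate entry for sample={row.sample_id!r} "
            f"locus={row.locus_id!r} replicate={row.replicate}"
        )
    both = df["allele_a"].notna() & df["allele_b"].notna()
    a = df.loc[both, "allele_a"]
    b = df.loc[both, "allele_b"]
    df.loc[both, "allele_a"] = np.minimum(a, b)
    df.loc[both, "allele_b"] = np.maximum(a, b)
    # a half-call is stored in allele_a
    only_b = df["allele_a"].isna() & df["allele_b"].notna()
    df.loc[only_b, "allele_a"] = df.loc[only_b, "allele_b"]
    df.loc[only_b, "allele_b"] = pd.NA
    return df.reset_index(drop=True)


def read_genotype_table(path: str | Path, dialect: str = "long_csv") -> pd.DataFrame:
    """Read replicate genotypes from ``long_csv`` or ``genepop`` files.

    The long CSV dialect has a header row matching :data:`GENOTYPE_COLUMNS`;
    blank allele cells are missing.  The Genepop dialect holds one consensus
    genotype per individual (treated as replicate 1) with 2- or 3-digit allele
    codes; code 0 is missing.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "long_csv":
        return _read_long_csv(path)
    if dialect == "genepop":
        table, _ = read_genepop(path)
        return table
    raise ValidationError(f"unknown genotype dialect: {dialect!r}")


def _read_long_csv(path: Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        header = fh.readline().strip().split(",")
        if [h.strip() for h in header] != list(GENOTYPE_COLUMNS):
            raise ParseError(f"{path}:1: expected header {','.join(GENOTYPE_COLUMNS)}")
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = [p.strip() for p in line.split(",")]
            if len(parts) != 5:
                raise ParseError(f"{path}:{lineno}: expected 5 fields, got {len(parts)}")
            sample, locus, rep, a, b = parts
            try:
                rep_i = int(rep)
                a_i = int(a) if a else None
                b_i = int(b) if b else None
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer field ({exc})") from None
            rows.append((sample, locus, rep_i, a_i, b_i))
    df = pd.DataFrame(rows, columns=list(GENOTYPE_COLUMNS))
    return validate_genotype_table(df)


def write_genotype_table(df: pd.DataFrame, path: str | Path) -> None:
    df = validate_genotype_table(df)
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Genepop
# ---------------------------------------------------------------------------

def build_allele_map(df: pd.DataFrame) -> dict[str, dict[int, int]]:
    """Rank-order bp allele sizes per locus into 1-based Genepop codes."""
    amap: dict[str, dict[int, int]] = {}
    for locus, sub in df.groupby("locus_id", sort=True):
        alleles = sorted(
            set(sub["allele_a"].dropna().astype(int)) | set(sub["allele_b"].dropna().astype(int))
        )
        amap[str(locus)] = {bp: i + 1 for i, bp in enumerate(alleles)}
    return amap


def write_genepop(
    df: pd.DataFrame,
    populations: Mapping[str, str],
    path: str | Path,
    title: str = "fecalpop export",
    allele_map: Mapping[str, Mapping[int, int]] | None = None,
) -> dict[str, dict[int, int]]:
    """Write consensus (single-replicate) genotypes as a Genepop file.

    ``populations`` maps sample_id to a population label; samples are grouped
    into ``Pop`` blocks.  Returns the allele map used, so bp sizes can be
    recovered from the 3-digit codes.
    """
    df = validate_genotype_table(df)
    if (df.groupby(["sample_id", "locus_id"]).size() > 1).any():
        raise ValidationError("Genepop export requires one consensus row per sample and locus")
    amap = {k: dict(v) for k, v in (allele_map or build_allele_map(df)).items()}
    loci = sorted(df["locus_id"].unique())
    wide_a = df.pivot(index="sample_id", columns="locus_id", values="allele_a")
    wide_b = df.pivot(index="sample_id", columns="locus_id", values="allele_b")
    lines = [title]
    lines.extend(loci)
    by_pop: dict[str, list[str]] = {}
    for sample in wide_a.index:
        by_pop.setdefault(populations.get(sample, "NA"), []).append(sample)
    for pop in sorted(by_pop):
        lines.append("Pop")
        for sample in by_pop[pop]:
            codes = []
            for locus in loci:
                a = wide_a.loc[sample, locus]
                b = wide_b.loc[sample, locus]
                ca = amap[locus][int(a)] if pd.notna(a) else 0
                cb = amap[locus][int(b)] if pd.notna(b) else 0
                codes.append(f"{ca:03d}{cb:03d}")
            lines.append(f"{sample} ,  " + " ".join(codes))
    Path(path).write_text("\n".join(lines) + "\n")
    return amap


def read_genepop(
    path: str | Path,
    allele_map: Mapping[str, Mapping[int, int]] | None = None,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Parse a Genepop file into a genotype table plus sample→population map.

    Without an allele map the integer codes themselves are kept as allele
    values; with the map produced by :func:`write_genepop` the original bp
    sizes are restored.
    """
    lines = Path(path).read_text().splitlines()
    if len(lines) < 3:
        raise ParseError(f"{path}: not a Genepop file (too short)")
    # locus names: either one per line or comma-separated on line 2
    idx = 1
    loci: list[str] = []
    while idx < len(lines) and lines[idx].strip().lower() != "pop":
        loci.extend(x.strip() for x in lines[idx].split(",") if x.strip())
        idx += 1
    if idx == len(lines):
        raise ParseError(f"{path}: no 'Pop' separator found")
    inverse = None
    if allele_map is not None:
        inverse = {loc: {code: bp for bp, code in m.items()} for loc, m in allele_map.items()}
    rows = []
    pop_of: dict[str, str] = {}
    pop_idx = 0
    for lineno in range(idx, len(lines)):
        line = lines[lineno].strip()
        if not line:
            continue
        if line.lower() == "pop":
            pop_idx += 1
            continue
        if "," not in line:
            raise ParseError(f"{path}:{lineno + 1}: expected 'name , genotypes'")
        name, geno = line.split(",", 1)
        name = name.strip()
        tokens = geno.split()
        if len(tokens) != len(loci):
            raise ParseError(
                f"{path}:{lineno + 1}: {len(tokens)} genotypes for {len(loci)} loci"
            )
        pop_of[name] = f"pop{pop_idx}"
        for locus, tok in zip(loci, tokens):
            if not re.fullmatch(r"\d{4}|\d{6}", tok):
                raise ParseError(f"{path}:{lineno + 1}: malformed genotype {tok!r}")
            w = len(tok) // 2
            ca, cb = int(tok[:w]), int(tok[w:])
            if inverse is not None:
                a = inverse[locus].get(ca) if ca else None
                b = inverse[locus].get(cb) if cb else None
            else:
                a = ca or None
                b = cb or None
            rows.append((name, locus, 1, a, b))
    df = pd.DataFrame(rows, columns=list(GENOTYPE_COLUMNS))
    return validate_genotype_table(df), pop_of


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------

METADATA_COLUMNS = ("sample_id", "population", "collection_date", "lat", "lon", "sex_replicates")


def validate_metadata(df: pd.DataFrame) -> pd.DataFrame:
    """Validate sample metadata; sex replicates are a ';'-joined band-call list."""
    for col in METADATA_COLUMNS:
        if col not in df.columns:
            df = df.copy()
            df[col] = pd.NA
    df = df.loc[:, list(METADATA_COLUMNS)].copy()
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValidationError(f"duplicate sample_id in metadata: {dup!r}")
    for calls in df["sex_replicates"].dropna():
        for call in str(calls).split(";"):
            if call and call not in BAND_CALLS:
                raise ValidationError(f"unknown band call {call!r}")
    return df.reset_index(drop=True)


def read_metadata(path: str | Path) -> pd.DataFrame:
    return validate_metadata(pd.read_csv(path, dtype={"sample_id": str, "population": str}))


def write_metadata(df: pd.DataFrame, path: str | Path) -> None:
    validate_metadata(df).to_csv(path, index=False)


def parse_sex_replicates(value) -> list[str]:
    if value is None or (isinstance(value, float) and np.isnan(value)) or pd.isna(value):
        return []
    return [c for c in str(value).split(";") if c]


# ---------------------------------------------------------------------------
# Sequence sets
# ---------------------------------------------------------------------------

@dataclass
class SequenceSet:
    """A named set of DNA sequences (optionally an alignment)."""

    ids: list[str]
    seqs: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise ValidationError("ids and seqs differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise ValidationError("duplicate sequence id")
        self.seqs = [s.upper() for s in self.seqs]
        for sid, seq in zip(self.ids, self.seqs):
            bad = set(seq) - IUPAC_ALPHABET
            if bad:
                raise ValidationError(f"sequence {sid!r} contains invalid symbols {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.ids)

    def __getitem__(self, sid: str) -> str:
        return self.seqs[self.ids.index(sid)]

    @property
    def is_alignment(self) -> bool:
        return len({len(s) for s in self.seqs}) <= 1

    def require_alignment(self) -> None:
        if not self.is_alignment:
            raise ValidationError("sequences are not aligned (unequal lengths)")

    def subset(self, ids: Sequence[str]) -> "SequenceSet":
        return SequenceSet(list(ids), [self[i] for i in ids])


def read_fasta(path: str | Path) -> SequenceSet:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValidationError(f"{path}: empty FASTA")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"{path}: duplicate record id")
    return SequenceSet(ids, [str(r.seq) for r in records])


def write_fasta(sset: SequenceSet, path: str | Path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(seq), id=sid, description="") for sid, seq in zip(sset.ids, sset.seqs)
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# Q matrices
# ---------------------------------------------------------------------------

def write_qmatrix(q: pd.DataFrame, path: str | Path) -> None:
    """Write an ancestry matrix (index: individual; columns: population + Q1..QK)."""
    kcols = [c for c in q.columns if str(c).startswith("Q")]
    sums = q[kcols].sum(axis=1)
    if not np.allclose(sums, 1.0, atol=1e-6):
        raise ValidationError("Q rows must sum to 1")
    q.to_csv(path, index=True, index_label="individual_id")


def read_qmatrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="individual_id")


# ---------------------------------------------------------------------------
# Newick (tree writing lives with the Tree class; re-exported here)
# ---------------------------------------------------------------------------

def write_newick(tree, path: str | Path | None = None) -> str:
    """Serialise a :class:`fecalpop.phylo.Tree` to Newick text."""
    text = tree.to_newick()
    if path is not None:
        Path(path).write_text(text + "\n")
    return text
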