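"""Per-species scalar factors feeding the genome-size correlations.

Each species contributes: assembly size (Mb), genome-size fold GF relative
to the ancestral angiosperm haploid genome (1.73 pg x 978 Mb/pg = 1691.94
Mb), polyploidization fold PF = 2^m * 3^n from its counts of whole-genome
duplications (m) and triplications (n) since the angiosperm ancestor,
per-class repeat proportions, and the mean LTR insertion time in Myr.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotate import ClassProportions
from .genome import GenomeSequence

logger = logging.getLogger(__name__)

#: ancestral angiosperm haploid C-value (pg) and DNA mass-to-length constant
ANCESTRAL_C_VALUE_PG = 1.73
MB_PER_PG = 978.0

FACTOR_CLASSES = ("tandem", "LTR", "LINE", "SINE", "DNA")


def ancestral_size_mb(
    c_value_pg: float = ANCESTRAL_C_VALUE_PG, mb_per_pg: float = MB_PER_PG
) -> float:
    """Ancestral haploid genome size in Mb (default 1.73 pg x 978 = 1691.94)."""
    if c_value_pg <= 0 or mb_per_pg <= 0:
        raise ValueError("c_value_pg and mb_per_pg must be positive")
    return c_value_pg * mb_per_pg


ANCESTRAL_MB = ancestral_size_mb()


def genome_size_fold(genome_size_mb: float, ancestral_mb: float = ANCESTRAL_MB) -> float:
    """Genome-size fold: assembly size scaled by the ancestral genome size."""
    if genome_size_mb <= 0 or ancestral_mb <= 0:
        raise ValueError("sizes must be positive")
    return genome_size_mb / ancestral_mb


def polyploidization_fold(m: int, n: int) -> int:
    """PF = 2^m * 3^n for m duplications and n triplications.

    A species with no polyploidization since the angiosperm ancestor (the
    Amborella baseline) has PF = 1.
    """
    for name, v in (("m", m), ("n", n)):
        if isinstance(v, bool) or not float(v).is_integer():
            raise ValueError(f"{name} must be an integer, got {v!r}")
        if v < 0:
            raise ValueError(f"{name} must be non-negative, got {v!r}")
    return 2 ** int(m) * 3 ** int(n)


@dataclass
class SpeciesRecord:
    """All per-species factors used by the correlation suite."""

    species: str
    genome_size_mb: float
    m: int
    n: int
    proportions: ClassProportions | None = None
    mean_insertion_myr: float = math.nan
    ancestral_mb: float = ANCESTRAL_MB

    @property
    def gf(self) -> float:
        return genome_size_fold(self.genome_size_mb, self.ancestral_mb)

    @property
    def pf(self) -> int:
        return polyploidization_fold(self.m, self.n)

    def class_percent(self, repeat_class: str) -> float:
        if self.proportions is None:
            return math.nan
        return self.proportions.percent(repeat_class)


@dataclass
class SpeciesTable:
    """Species factor table plus the ancestral size used for scaling."""

    records: list[SpeciesRecord]
    ancestral_mb: float = ANCESTRAL_MB

    def __post_init__(self) -> None:
        labels = [r.species for r in self.records]
        if len(set(labels)) != len(labels):
            raise ValueError("species labels must be unique")

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {
                "species": r.species,
                "genome_size_mb": r.genome_size_mb,
                "gf": r.gf,
                "m": r.m,
                "n": r.n,
                "pf": r.pf,
                "mean_insertion_myr": r.mean_insertion_myr,
            }
            for cls in FACTOR_CLASSES:
                row[f"{cls}_pct"] = r.class_percent(cls)
            rows.append(row)
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")

    @classmethod
    def from_tsv(cls, path: str | Path, ancestral_mb: float = ANCESTRAL_MB) -> "SpeciesTable":
        df = pd.read_csv(path, sep="\t")
        records = []
        for _, row in df.iterrows():
            fractions = {
                cls: row[f"{cls}_pct"] / 100.0 for cls in FACTOR_CLASSES
                if f"{cls}_pct" in row and not pd.isna(row[f"{cls}_pct"])
            }
            props = ClassProportions(fractions=fractions, total=sum(fractions.values()))
            records.append(
                SpeciesRecord(
                    species=str(row["species"]),
                    genome_size_mb=float(row["genome_size_mb"]),
                    m=int(row["m"]),
                    n=int(row["n"]),
                    proportions=props,
                    mean_insertion_myr=float(row["mean_insertion_myr"]),
                    ancestral_mb=ancestral_mb,
                )
            )
        return cls(records=records, ancestral_mb=ancestral_mb)


def read_ploidy_table(path: str | Path) -> pd.DataFrame:
    """Read the WGD/WGT count table (columns: species, m, n[, source])."""
    df = pd.read_csv(path, sep="\t")
    missing = {"species", "m", "n"} - set(df.columns)
    if missing:
        raise ValueError(f"ploidy table missing columns: {sorted(missing)}")
    if df["species"].duplicated().any():
        dups = df.loc[df["species"].duplicated(), "species"].tolist()
        raise ValueError(f"duplicate species in ploidy table: {dups}")
    return df


def genome_size_mb_of(
    seqs: Sequence[GenomeSequence], exclude_n: bool = False
) -> float:
    """Total assembly length in Mb (optionally excluding N runs)."""
    if exclude_n:
        total = sum(s.length - s.residues.count("N") for s in seqs)
    else:
        total = sum(s.length for s in seqs)
    return total / 1e6


def assemble_species_table(
    genomes: Mapping[str, Sequence[GenomeSequence]],
    proportions: Mapping[str, ClassProportions],
    mean_insertion_myr: Mapping[str, float],
    ploidy: pd.DataFrame,
    ancestral_mb: float = ANCESTRAL_MB,
    exclude_n: bool = False,
) -> SpeciesTable:
    """Join assemblies, annotation proportions, datings and ploidy counts.

    Species listed in the ploidy table but lacking a genome are skipped with
    a warning; a missing mean insertion time propagates as NaN.
    """
    if ploidy["species"].duplicated().any():
        raise ValueError("duplicate species label in ploidy table")
    records = []
    for _, row in ploidy.iterrows():
        sp = str(row["species"])
        if sp not in genomes:
            warnings.warn(f"species {sp!r} in ploidy table has no genome; skipped")
            continue
        records.append(
            SpeciesRecord(
                species=sp,
                genome_size_mb=genome_size_mb_of(genomes[sp], exclude_n=exclude_n),
                m=int(row["m"]),
                n=int(row["n"]),
                proportions=proportions.get(sp),
                mean_insertion_myr=float(mean_insertion_myr.get(sp, math.nan)),
                ancestral_mb=ancestral_mb,
            )
        )
    table = SpeciesTable(records=records, ancestral_mb=ancestral_mb)
    stats = size_summary(table)
    logger.info(
        "species table: %d species, mean %.1f Mb, median %.1f Mb, %.1f-fold range",
        len(table), stats["mean_mb"], stats["median_mb"], stats["fold_range"],
    )
    return table


def size_summary(table: SpeciesTable) -> dict[str, float]:
    """Mean / median / fold-range of assembly sizes across the panel."""
    sizes = np.array([r.genome_size_mb for r in table.records], dtype=float)
    if sizes.size == 0:
        return {"mean_mb": math.nan, "median_mb": math.nan, "fold_range": math.nan}
    return {
        "mean_mb": float(sizes.mean()),
        "median_mb": float(np.median(sizes)),
        "fold_range": float(sizes.max() / sizes.min()),
    }
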