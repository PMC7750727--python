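"""Chromosome metadata.

Chromosomes are identified by their number in the A-genome reference
(chr01..chr11). Coordinates are 1-based inclusive, matching the VCF
convention used throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "ChromosomeSpec",
    "default_chromosomes",
    "read_chromosome_table",
    "write_chromosome_table",
    "chrom_map",
]


@dataclass(frozen=True)
class ChromosomeSpec:
    """A chromosome with its length and (optionally) centromere position.

    Parameters
    ----------
    name : str
        Chromosome label, e.g. ``"chr04"``.
    length : int
        Chromosome length in bp; must be positive.
    centromere_pos : int or None
        Centromere coordinate in bp (1-based), strictly inside the
        chromosome. When absent, arm assignment falls back to the
        chromosome midpoint.
    """

    name: str
    length: int
    centromere_pos: int | None = None

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"{self.name}: length must be positive, got {self.length}")
        if self.centromere_pos is not None and not (0 < self.centromere_pos < self.length):
            raise ValueError(
                f"{self.name}: centromere_pos {self.centromere_pos} outside (0, {self.length})"
            )

    @property
    def centromere(self) -> int:
        """Centromere position, falling back to the midpoint when unknown."""
        if self.centromere_pos is not None:
            return self.centromere_pos
        return self.length // 2


# Synthetic stand-in metadata for the 11 Musa chromosomes: lengths in the
# 25-40 Mb range typical of the A-genome reference assembly, centromeres
# placed off-centre so that first/second arms differ in size.
_DEFAULT_TABLE = [
    ("chr01", 28_000_000, 12_000_000),
    ("chr02", 24_000_000, 10_000_000),
    ("chr03", 30_000_000, 14_000_000),
    ("chr04", 32_000_000, 13_000_000),
    ("chr05", 29_000_000, 12_000_000),
    ("chr06", 33_000_000, 15_000_000),
    ("chr07", 29_000_000, 13_000_000),
    ("chr08", 35_000_000, 16_000_000),
    ("chr09", 38_000_000, 15_000_000),
    ("chr10", 33_000_000, 14_000_000),
    ("chr11", 25_000_000, 11_000_000),
]


def default_chromosomes(scale: float = 1.0) -> list[ChromosomeSpec]:
    """Return the default 11-chromosome metadata set.

    Parameters
    ----------
    scale : float
        Multiplier applied to lengths and centromere positions; useful
        for fast, small simulations (e.g. ``scale=0.1`` for ~3 Mb
        chromosomes).
    """
    return [
        ChromosomeSpec(name, max(int(length * scale), 2), max(int(cen * scale), 1))
        for name, length, cen in _DEFAULT_TABLE
    ]


def chrom_map(chroms: Iterable[ChromosomeSpec]) -> dict[str, ChromosomeSpec]:
    """Index chromosomes by name, enforcing uniqueness."""
    out: dict[str, ChromosomeSpec] = {}
    for c in chroms:
        if c.name in out:
            raise ValueError(f"duplicate chromosome name {c.name!r}")
        out[c.name] = c
    return out


def read_chromosome_table(path: str | Path) -> list[ChromosomeSpec]:
    """Read a chromosome metadata TSV (columns: chrom, length, centromere_pos).

    ``centromere_pos`` may be empty / NA for chromosomes without a known
    centromere.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "length"}
    if not required.issubset(df.columns):
        raise ValueError(f"chromosome table must have columns {sorted(required)}")
    chroms = []
    for _, row in df.iterrows():
        cen = row.get("centromere_pos")
        cen = None if pd.isna(cen) else int(cen)
        chroms.append(ChromosomeSpec(str(row["chrom"]), int(row["length"]), cen))
    chrom_map(chroms)  # uniqueness check
    return chroms


def write_chromosome_table(chroms: Sequence[ChromosomeSpec], path: str | Path) -> None:
    """Write chromosome metadata as TSV."""
    df = pd.DataFrame(
        {
            "chrom": [c.name for c in chroms],
            "length": [c.length for c in chroms],
            "centromere_pos": [c.centromere_pos for c in chroms],
        }
    )
    df.to_csv(path, sep="\t", index=False)
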