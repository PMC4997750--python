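"""Genome model: chromosome sizes, centromeres, and p/q arm coordinates.

The screening analysis reports events at chromosome-arm resolution ("3q gain",
"chr13 loss"), so the genome model carries, for every chromosome, its length and
an (approximate) centromere position splitting the p and q arms.  The bundled
default is an hg19-like female genome: 22 autosomes plus X, no Y.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

AUTOSOMES = tuple(f"chr{i}" for i in range(1, 23))
CHROM_X = "chrX"
DEFAULT_CHROMS = AUTOSOMES + (CHROM_X,)


def short_name(chrom: str) -> str:
    """'chr8' -> '8', 'chrX' -> 'X'; names without the prefix pass through."""
    return chrom[3:] if chrom.startswith("chr") else chrom


def is_autosome(chrom: str) -> bool:
    return short_name(chrom) not in ("X", "Y")


@dataclass(frozen=True)
class ChromArm:
    """One chromosome arm: half-open [start, end) in bp."""

    arm: str    # field-style id, e.g. "8q"
    chrom: str  # e.g. "chr8"
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GenomeSpec:
    """Ordered chromosomes with lengths and centromere positions (bp)."""

    names: tuple[str, ...]
    lengths: dict[str, int]
    centromeres: dict[str, int]
    _arms: list[ChromArm] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.names = tuple(self.names)
        if len(set(self.names)) != len(self.names):
            raise ValueError("chromosome names must be unique")
        for name in self.names:
            length = self.lengths[name]
            cen = self.centromeres[name]
            if length <= 0:
                raise ValueError(f"{name}: length must be > 0, got {length}")
            if not 0 < cen < length:
                raise ValueError(
                    f"{name}: centromere {cen} must lie strictly inside [0, {length})"
                )
        arms = []
        for name in self.names:
            cen = self.centromeres[name]
            sn = short_name(name)
            arms.append(ChromArm(f"{sn}p", name, 0, cen))
            arms.append(ChromArm(f"{sn}q", name, cen, self.lengths[name]))
        self._arms = arms

    @property
    def arms(self) -> list[ChromArm]:
        return list(self._arms)

    def arm(self, arm_id: str) -> ChromArm:
        for a in self._arms:
            if a.arm == arm_id:
                return a
        raise KeyError(f"unknown chromosome arm {arm_id!r}")

    def arms_of(self, chrom: str) -> tuple[ChromArm, ChromArm]:
        p, q = [a for a in self._arms if a.chrom == chrom]
        return p, q

    @property
    def autosomes(self) -> tuple[str, ...]:
        return tuple(n for n in self.names if is_autosome(n))

    def total_length(self, autosomes_only: bool = False) -> int:
        names = self.autosomes if autosomes_only else self.names
        return sum(self.lengths[n] for n in names)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": list(self.names),
                "length": [self.lengths[n] for n in self.names],
                "centromere": [self.centromeres[n] for n in self.names],
            }
        )


def genome_from_frame(df: pd.DataFrame) -> GenomeSpec:
    required = {"chrom", "length", "centromere"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"genome table missing columns: {sorted(missing)}")
    return GenomeSpec(
        names=tuple(df["chrom"].astype(str)),
        lengths=dict(zip(df["chrom"], df["length"].astype(int))),
        centromeres=dict(zip(df["chrom"], df["centromere"].astype(int))),
    )


def load_genome(path) -> GenomeSpec:
    """Read a genome table (TSV: chrom, length, centromere; '#' comments)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    return genome_from_frame(df)


@functools.lru_cache(maxsize=1)
def default_genome() -> GenomeSpec:
    """The bundled hg19-like female genome (22 autosomes + X)."""
    with resources.files("plasmacnv.data").joinpath("genome_hg19like.tsv").open() as fh:
        return load_genome(fh)
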