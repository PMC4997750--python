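"""Recurrent arm-level CNV catalog and the specificity classification rule.

Each catalog record is one recurrently gained or lost chromosome arm in the
tumor type of interest, with its false-discovery-rate q-value and the fraction
of tumors carrying it.  A called (arm, direction) is classified as:

* ``highly_specific``     -- q < 0.25 and frequency > 0.5
* ``moderately_specific`` -- q < 0.25 and frequency <= 0.5
* ``non_specific``        -- q >= 0.25, or absent from the catalog
"""

from __future__ import annotations

import enum
import functools
from dataclasses import dataclass
from importlib import resources

import pandas as pd

Q_CUTOFF = 0.25
FREQ_CUTOFF = 0.5


class Specificity(enum.IntEnum):
    """Ordered so that max() picks the most specific class."""

    non_specific = 0
    moderately_specific = 1
    highly_specific = 2

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


@dataclass(frozen=True)
class CatalogRecord:
    arm: str         # e.g. "8q"
    direction: str   # "gain" | "loss"
    q_value: float
    frequency: float


@dataclass
class CNVCatalog:
    records: list[CatalogRecord]

    def __post_init__(self) -> None:
        seen = set()
        for r in self.records:
            if r.direction not in ("gain", "loss"):
                raise ValueError(f"{r.arm}: direction must be gain|loss, got {r.direction}")
            if r.q_value < 0:
                raise ValueError(f"{r.arm} {r.direction}: q_value must be >= 0")
            if not 0 <= r.frequency <= 1:
                raise ValueError(
                    f"{r.arm} {r.direction}: frequency {r.frequency} outside [0, 1]"
                )
            key = (r.arm, r.direction)
            if key in seen:
                raise ValueError(f"duplicate catalog record {key}")
            seen.add(key)
        self._by_key = {(r.arm, r.direction): r for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def get(self, arm: str, direction: str) -> CatalogRecord | None:
        return self._by_key.get((arm, direction))

    def n_gains(self) -> int:
        return sum(r.direction == "gain" for r in self.records)

    def n_losses(self) -> int:
        return sum(r.direction == "loss" for r in self.records)

    def classify(self, arm: str, direction: str) -> Specificity:
        """Specificity class of one (arm, direction); total and deterministic."""
        rec = self.get(arm, direction)
        if rec is None or rec.q_value >= Q_CUTOFF:
            return Specificity.non_specific
        if rec.frequency > FREQ_CUTOFF:
            return Specificity.highly_specific
        return Specificity.moderately_specific

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "arm": [r.arm for r in self.records],
                "direction": [r.direction for r in self.records],
                "q_value": [r.q_value for r in self.records],
                "frequency": [r.frequency for r in self.records],
            }
        )


def catalog_from_frame(df: pd.DataFrame) -> CNVCatalog:
    required = {"arm", "direction", "q_value", "frequency"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"catalog missing columns: {sorted(missing)}")
    records = [
        CatalogRecord(
            arm=str(row.arm),
            direction=str(row.direction),
            q_value=float(row.q_value),
            frequency=float(row.frequency),
        )
        for row in df.itertuples()
    ]
    return CNVCatalog(records)


def load_catalog(path) -> CNVCatalog:
    """Read a catalog TSV (arm, direction, q_value, frequency; '#' comments).

    An empty file yields an empty catalog (every call then classifies as
    non_specific).
    """
    df = pd.read_csv(
        path, sep="\t", comment="#",
        dtype={"arm": str},
    )
    if df.empty:
        return CNVCatalog([])
    return catalog_from_frame(df)


@functools.lru_cache(maxsize=1)
def default_catalog() -> CNVCatalog:
    """The bundled synthetic HGSOC arm catalog (8 gains, 22 losses)."""
    with resources.files("plasmacnv.data").joinpath(
        "hgsoc_arm_catalog_synthetic.tsv"
    ).open() as fh:
        return load_catalog(fh)
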