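"""Shared fixtures: toy genomes/grids for exact oracle tests, and session-scoped
full-scale simulated panels with fitted models for the calibration/recovery
checks (built once; several test modules reuse them)."""

from __future__ import annotations

import numpy as np
import pytest

import plasmacnv as pc
from plasmacnv.aneuploidy import AneuploidyModel
from plasmacnv.genome import GenomeSpec
from plasmacnv.grid import BinGrid
from plasmacnv.profile import SampleProfile
from plasmacnv.simulate import simulate_panel


@pytest.fixture(scope="session")
def toy_genome() -> GenomeSpec:
    """Two autosomes + X, 10/8/6 Mb, centromeres mid-chromosome."""
    return GenomeSpec(
        names=("chr1", "chr2", "chrX"),
        lengths={"chr1": 10_000_000, "chr2": 8_000_000, "chrX": 6_000_000},
        centromeres={"chr1": 5_000_000, "chr2": 4_000_000, "chrX": 3_000_000},
    )


def build_grid(genome: GenomeSpec, bin_size: int = 1_000_000, gc=None) -> BinGrid:
    chroms, starts, ends = [], [], []
    for name in genome.names:
        length = genome.lengths[name]
        edges = list(range(0, length, bin_size)) + [length]
        for s, e in zip(edges[:-1], edges[1:]):
            chroms.append(name)
            starts.append(s)
            ends.append(e)
    n = len(chroms)
    if gc is None:
        gc = 0.35 + 0.3 * (np.arange(n) % 7) / 7.0
    return BinGrid(
        chrom=np.array(chroms, dtype=object),
        start=np.array(starts),
        end=np.array(ends),
        gc=np.asarray(gc, dtype=float),
        usable=np.ones(n, dtype=bool),
        bin_size=bin_size,
        genome=genome,
    )


@pytest.fixture(scope="session")
def toy_grid(toy_genome) -> BinGrid:
    return build_grid(toy_genome)  # 24 bins: 10 + 8 + 6


def profile_from_values(grid: BinGrid, values, sample_id="s") -> SampleProfile:
    """A profile with normalized values injected directly (no preprocessing)."""
    values = np.asarray(values, dtype=float)
    return SampleProfile(
        sample_id=sample_id,
        grid=grid,
        counts=np.zeros(grid.n_bins, dtype=np.int64),
        values=values,
        gc_corrected=True,
    )


# -- full-scale session fixtures -------------------------------------------

@pytest.fixture(scope="session")
def full_grid() -> BinGrid:
    return pc.make_default_grid()


@pytest.fixture(scope="session")
def cnv_model(full_grid):
    """Within-sample reference model fitted to a 20-sample simulated panel."""
    panel = simulate_panel(full_grid, 20, seed=1)
    return pc.WithinSampleReferenceModel(panel).fit()


@pytest.fixture(scope="session")
def aneuploidy_model(full_grid):
    """Aneuploidy screen fitted to a 100-sample simulated panel."""
    return AneuploidyModel(simulate_panel(full_grid, 100, seed=11)).fit()
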