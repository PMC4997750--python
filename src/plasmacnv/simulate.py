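"""Synthetic shallow-WGS cfDNA cohorts.

Generates reference panels and case/control cohorts of per-bin read counts with
the statistical structure the screening analysis assumes:

* total reads per sample drawn uniformly from 18-28 million (0.2-0.3x for
  36 bp single-end reads);
* a fixed per-grid bin baseline (multiplicative log-normal weights) shared by
  every sample, emulating mappability-like bin structure;
* a sample-specific linear GC bias, factor 1 + slope * (gc - 0.41) with
  slope ~ Normal(0, 0.5^2), floored at 0.1;
* overdispersed counts: negative binomial with dispersion r (default 1000),
  realized as a per-bin gamma multiplier times a Poisson count;
* cases carry a tumor truth profile (arm-level events drawn from the recurrent
  CNV catalog plus focal 1-10 Mb events) diluted linearly by the tumor
  fraction: expected bin weight x (1 + tf * (copy - 2) / 2).

The Poisson component is realized by a normal-quantile transform of one
uniform draw per bin (exact to <1 count at the ~7000-count bin means used
here).  Each sample consumes a fixed number of RNG draws regardless of target
depth, so simulations at different read depths from the same seed stream are
comonotone — a depth change moves every bin's count along its own quantile.
Identical seed and configuration give byte-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .catalog import CNVCatalog, default_catalog
from .genome import GenomeSpec, default_genome
from .grid import BinGrid, make_default_grid
from .profile import SampleProfile
from . import io as pio

GC_PIVOT = 0.41
GC_FACTOR_FLOOR = 0.1


@dataclass
class SimParams:
    """Study-scale simulation parameters (defaults mirror the assay)."""

    reads_range: tuple[float, float] = (18e6, 28e6)
    gc_slope_sd: float = 0.5
    baseline_sd: float = 0.1
    dispersion: float = 1000.0   # NB dispersion r; larger -> closer to Poisson
    baseline_seed: int = 17      # bin baseline is fixed per grid, not per sample


@dataclass(frozen=True)
class CNVEvent:
    chrom: str
    start: int
    end: int
    copy: int          # 0, 1, 3 or 4
    origin: str = "focal"   # "catalog" | "focal"

    def __post_init__(self) -> None:
        if self.copy not in (0, 1, 3, 4):
            raise ValueError(f"copy number must be in {{0,1,3,4}}, got {self.copy}")
        if self.end <= self.start:
            raise ValueError("event span is empty")


@dataclass
class TruthProfile:
    """Ground-truth tumor profile: tumor fraction plus CNV events."""

    tumor_fraction: float
    events: list[CNVEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0 <= self.tumor_fraction <= 1:
            raise ValueError(
                f"tumor fraction {self.tumor_fraction} outside [0, 1]"
            )
        by_chrom: dict[str, list[CNVEvent]] = {}
        for e in self.events:
            by_chrom.setdefault(e.chrom, []).append(e)
        for chrom, evs in by_chrom.items():
            evs = sorted(evs, key=lambda e: e.start)
            for a, b in zip(evs[:-1], evs[1:]):
                if b.start < a.end:
                    raise ValueError(f"overlapping truth events on {chrom}")


# ---------------------------------------------------------------------------
# count generation
# ---------------------------------------------------------------------------

def baseline_weights(grid: BinGrid, params: SimParams) -> np.ndarray:
    """Fixed per-grid multiplicative bin weights, exp(Normal(0, baseline_sd^2))."""
    rng = np.random.default_rng(params.baseline_seed)
    eta = rng.normal(0.0, params.baseline_sd, size=grid.n_bins)
    return np.exp(eta)


def _copy_numbers(grid: BinGrid, truth: TruthProfile) -> np.ndarray:
    """Per-bin copy number; a boundary bin takes the majority-overlap copy."""
    copy = np.full(grid.n_bins, 2, dtype=float)
    for ev in truth.events:
        idx = grid.chrom_indices(ev.chrom)
        if len(idx) == 0:
            continue
        ov = np.minimum(grid.end[idx], ev.end) - np.maximum(grid.start[idx], ev.start)
        width = grid.end[idx] - grid.start[idx]
        hit = ov * 2 > width     # strict majority of the bin
        copy[idx[hit]] = ev.copy
    return copy


def _draw_counts(
    grid: BinGrid,
    params: SimParams,
    rng: np.random.Generator,
    baseline: np.ndarray,
    copy: np.ndarray | None = None,
    tumor_fraction: float = 0.0,
    total_reads: float | None = None,
) -> np.ndarray:
    usable = grid.usable
    n_total = (
        rng.uniform(*params.reads_range) if total_reads is None else float(total_reads)
    )
    slope = rng.normal(0.0, params.gc_slope_sd)
    gcfac = np.maximum(1.0 + slope * (grid.gc - GC_PIVOT), GC_FACTOR_FLOOR)
    w = baseline * gcfac
    if copy is not None:
        w = w * (1.0 + tumor_fraction * (copy - 2.0) / 2.0)
    w = np.where(usable, w, 0.0)
    p = w / w.sum()
    lam = n_total * p

    r = params.dispersion
    g = rng.gamma(shape=r, scale=1.0 / r, size=grid.n_bins)  # NB mixing weights
    u = rng.random(grid.n_bins)
    mean = lam * g
    counts = np.rint(mean + np.sqrt(np.maximum(mean, 0.0)) * stats.norm.ppf(u))
    counts = np.maximum(counts, 0.0)
    counts[~usable] = 0
    return counts.astype(np.int64)


def simulate_panel(
    grid: BinGrid,
    n_samples: int,
    params: SimParams | None = None,
    seed: int | np.random.Generator = 0,
    sample_prefix: str = "panel",
    total_reads: float | None = None,
) -> list[SampleProfile]:
    """Copy-neutral reference samples (counts ~ NB around the bin baseline)."""
    if n_samples < 2:
        raise ValueError("a reference panel needs at least 2 samples")
    params = params or SimParams()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    baseline = baseline_weights(grid, params)
    return [
        SampleProfile(
            sample_id=f"{sample_prefix}_{i:03d}",
            grid=grid,
            counts=_draw_counts(grid, params, rng, baseline, total_reads=total_reads),
        )
        for i in range(n_samples)
    ]


def simulate_case(
    grid: BinGrid,
    truth: TruthProfile,
    params: SimParams | None = None,
    seed: int | np.random.Generator = 0,
    sample_id: str = "case",
    total_reads: float | None = None,
) -> SampleProfile:
    """One sample carrying `truth`, diluted by its tumor fraction.

    At tumor fraction 0 the draw is identical to a panel sample from the same
    seed stream.
    """
    params = params or SimParams()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    baseline = baseline_weights(grid, params)
    copy = _copy_numbers(grid, truth)
    counts = _draw_counts(
        grid,
        params,
        rng,
        baseline,
        copy=copy,
        tumor_fraction=truth.tumor_fraction,
        total_reads=total_reads,
    )
    return SampleProfile(sample_id=sample_id, grid=grid, counts=counts)


# ---------------------------------------------------------------------------
# truth profiles
# ---------------------------------------------------------------------------

def draw_tumor_profile(
    catalog: CNVCatalog,
    genome: GenomeSpec,
    tumor_fraction: float,
    focal_rate: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> TruthProfile:
    """Draw an HGSOC-like truth profile from the recurrent-CNV catalog.

    Each catalog record enters independently with probability equal to its
    tumor frequency (gain -> copy 3, loss -> copy 1 over the full arm).
    Poisson(focal_rate) additional focal events of length uniform 1-10 Mb are
    placed uniformly; any draw overlapping an earlier-drawn event is dropped
    (earlier-drawn events win).
    """
    if len(catalog) == 0:
        raise ValueError("catalog is empty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    events: list[CNVEvent] = []

    def overlaps(chrom: str, start: int, end: int) -> bool:
        return any(e.chrom == chrom and start < e.end and e.start < end for e in events)

    for rec in catalog.records:
        if rng.random() < rec.frequency:
            try:
                arm = genome.arm(rec.arm)
            except KeyError:
                continue
            if overlaps(arm.chrom, arm.start, arm.end):
                continue
            events.append(
                CNVEvent(
                    chrom=arm.chrom,
                    start=arm.start,
                    end=arm.end,
                    copy=3 if rec.direction == "gain" else 1,
                    origin="catalog",
                )
            )

    n_focal = rng.poisson(focal_rate) if focal_rate > 0 else 0
    chrom_names = list(genome.names)
    lengths = np.array([genome.lengths[c] for c in chrom_names], dtype=float)
    chrom_p = lengths / lengths.sum()
    for _ in range(n_focal):
        chrom = chrom_names[rng.choice(len(chrom_names), p=chrom_p)]
        size = int(rng.uniform(1e6, 10e6))
        if genome.lengths[chrom] <= size:
            continue
        start = int(rng.integers(0, genome.lengths[chrom] - size))
        end = start + size
        copy = 3 if rng.random() < 0.5 else 1
        if overlaps(chrom, start, end):
            continue
        events.append(CNVEvent(chrom=chrom, start=start, end=end, copy=copy))
    return TruthProfile(tumor_fraction=tumor_fraction, events=events)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

@dataclass
class GroupConfig:
    n: int
    tf_range: tuple[float, float] = (0.0, 0.0)  # log-uniform unless both 0
    focal_rate: float = 0.0
    stage_label: str = "NA"
    is_case: bool = False


@dataclass
class CohortConfig:
    """Defaults mirror the study design: 16 early + 16 advanced cases, 32 controls."""

    bin_size: int = 1_000_000
    n_panel: int = 20
    groups: dict[str, GroupConfig] = field(
        default_factory=lambda: {
            "early": GroupConfig(
                16, tf_range=(0.02, 0.25), focal_rate=2.0,
                stage_label="FIGO I-II", is_case=True,
            ),
            "advanced": GroupConfig(
                16, tf_range=(0.04, 0.40), focal_rate=3.0,
                stage_label="FIGO III-IV", is_case=True,
            ),
            "control": GroupConfig(32, stage_label="benign"),
        }
    )
    params: SimParams = field(default_factory=SimParams)


def _draw_tf(rng: np.random.Generator, tf_range: tuple[float, float]) -> float:
    lo, hi = tf_range
    if hi <= 0:
        return 0.0
    if lo <= 0:
        return float(rng.uniform(lo, hi))
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def simulate_cohort(
    config: CohortConfig,
    out_dir,
    seed: int = 0,
    genome: GenomeSpec | None = None,
    catalog: CNVCatalog | None = None,
    overwrite: bool = False,
) -> Path:
    """Write a full synthetic cohort: panel, cases, controls, manifest, truth.

    Controls are copy-neutral; cases carry catalog-drawn arm events plus focal
    events, diluted by a per-sample tumor fraction.  Identical config + seed
    give byte-identical output.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise FileExistsError(f"{out} exists and overwrite is not set")
    genome = genome or default_genome()
    catalog = catalog or default_catalog()
    grid = make_default_grid(genome, config.bin_size)
    (out / "panel").mkdir(parents=True, exist_ok=True)
    (out / "samples").mkdir(parents=True, exist_ok=True)
    pio.write_bin_grid(grid, out / "grid.tsv")

    rng = np.random.default_rng(seed)
    panel = simulate_panel(grid, config.n_panel, config.params, seed=rng)
    for p in panel:
        pio.write_bin_counts(p, out / "panel" / f"{p.sample_id}.tsv")

    manifest_rows = []
    truth_records = []
    for group_name, gcfg in config.groups.items():
        for i in range(gcfg.n):
            sid = f"{group_name}_{i:03d}"
            if gcfg.is_case:
                tf = _draw_tf(rng, gcfg.tf_range)
                truth = draw_tumor_profile(
                    catalog, genome, tf, focal_rate=gcfg.focal_rate, seed=rng
                )
            else:
                truth = TruthProfile(tumor_fraction=0.0, events=[])
            prof = simulate_case(grid, truth, config.params, seed=rng, sample_id=sid)
            rel = f"samples/{sid}.tsv"
            pio.write_bin_counts(prof, out / rel)
            manifest_rows.append(
                {
                    "sample_id": sid,
                    "group": "case" if gcfg.is_case else "control",
                    "stage_label": gcfg.stage_label,
                    "tumor_fraction": truth.tumor_fraction,
                    "counts_path": rel,
                }
            )
            truth_records.append(
                {
                    "sample_id": sid,
                    "tumor_fraction": truth.tumor_fraction,
                    "events": [
                        {"chrom": e.chrom, "start": e.start, "end": e.end, "copy": e.copy}
                        for e in truth.events
                    ],
                }
            )
    import pandas as pd

    pio.write_manifest(pd.DataFrame(manifest_rows), out / "manifest.tsv")
    (out / "truth.json").write_text(
        json.dumps(truth_records, indent=2, sort_keys=True) + "\n"
    )
    return out
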