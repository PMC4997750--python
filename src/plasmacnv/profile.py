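"""Per-sample bin profiles: raw counts, depth normalization, GC correction.

A :class:`SampleProfile` holds the raw read count of every grid bin for one
plasma sample plus, once computed, the normalized per-bin values.  Values are
fractions of the usable *autosomal* total: chromosome X is scorable but never
contributes to the denominator, so female-variable X dosage cannot perturb
autosomal statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess as _lowess

from .grid import BinGrid

GC_LOWESS_SPAN = 0.3
MIN_BINS_FOR_GC = 50
_GC_PASSES = 2


@dataclass
class SampleProfile:
    """Raw and normalized per-bin values for one sample on a fixed grid."""

    sample_id: str
    grid: BinGrid
    counts: np.ndarray            # int64 raw counts per bin
    values: np.ndarray | None = None  # normalized (and possibly GC-corrected)
    gc_corrected: bool = False

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (self.grid.n_bins,):
            raise ValueError(
                f"{self.sample_id}: counts length {len(self.counts)} != "
                f"grid bins {self.grid.n_bins}"
            )
        if np.any(self.counts < 0):
            raise ValueError(f"{self.sample_id}: negative raw counts")
        self.counts = self.counts.astype(np.int64)
        if self.values is not None:
            self.values = np.asarray(self.values, dtype=float)

    @property
    def total_reads(self) -> int:
        return int(self.counts.sum())

    @property
    def is_normalized(self) -> bool:
        return self.values is not None


def normalize_counts(profile: SampleProfile) -> SampleProfile:
    """Normalized value = count / (total count over usable autosomal bins).

    X-chromosome bins are divided by the same autosomal total; usable autosomal
    values therefore sum to exactly 1 while X adds a small excess by design.
    """
    grid = profile.grid
    aut = grid.usable_autosomal
    total = profile.counts[aut].sum()
    if total <= 0:
        raise ValueError(f"{profile.sample_id}: zero usable autosomal count")
    values = profile.counts / float(total)
    values[~grid.usable] = 0.0
    return replace(profile, values=values, gc_corrected=False)


def _lowess_trend(values: np.ndarray, gc: np.ndarray) -> np.ndarray:
    """Locally weighted value-vs-GC trend evaluated at every `gc`."""
    span = gc.max() - gc.min()
    if span <= 0:  # all bins share one GC value: the trend is a constant
        return np.full_like(gc, values.mean())
    fitted = _lowess(
        values, gc, frac=GC_LOWESS_SPAN, it=0, delta=0.01 * span, return_sorted=True
    )
    xs, ys = fitted[:, 0], fitted[:, 1]
    xs, uniq = np.unique(xs, return_index=True)
    return np.interp(gc, xs, ys[uniq])


def gc_correct(profile: SampleProfile, grid: BinGrid | None = None) -> SampleProfile:
    """Divide out the locally weighted value-vs-GC trend, then renormalize.

    The trend is fitted on usable autosomal bins only (span 0.3), evaluated at
    every usable bin's GC, and divided out in two passes (the second pass
    removes the small residual trend the renormalization re-introduces).

    The operation is idempotent by contract: a profile whose ``gc_corrected``
    flag is set is returned unchanged, so re-applying the correction never
    drifts the values.
    """
    if grid is None:
        grid = profile.grid
    if profile.values is None:
        raise ValueError("normalize_counts must run before gc_correct")
    if profile.gc_corrected:
        return replace(profile, values=profile.values.copy())
    aut = grid.usable_autosomal
    usable = grid.usable
    if aut.sum() < MIN_BINS_FOR_GC:
        warnings.warn(
            f"{profile.sample_id}: only {int(aut.sum())} usable autosomal bins; "
            "GC correction skipped",
            stacklevel=2,
        )
        return replace(profile, values=profile.values.copy(), gc_corrected=False)

    values = profile.values.copy()
    for _ in range(_GC_PASSES):
        trend = _lowess_trend(values[aut], grid.gc[aut])
        trend_all = np.interp(grid.gc, *_sorted_pair(grid.gc[aut], trend))
        trend_all = np.maximum(trend_all, 1e-12)
        values[usable] = values[usable] / trend_all[usable]
        values[usable] *= 1.0 / values[aut].sum()  # usable autosomal sum to 1
    return replace(profile, values=values, gc_corrected=True)


def _sorted_pair(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    xs, uniq = np.unique(xs, return_index=True)
    return xs, ys[uniq]


def prepare(profile: SampleProfile) -> SampleProfile:
    """normalize_counts followed by gc_correct (the standard preprocessing)."""
    return gc_correct(normalize_counts(profile))
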