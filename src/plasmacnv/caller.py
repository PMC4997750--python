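"""Within-sample-reference copy-number aberration caller.

The method scores each genomic bin of a test sample against a set of *reference
bins of the same sample*, chosen — from a panel of unaffected samples — as the
bins whose normalized values behave most similarly across the panel.  Because
bin and reference bins come from the same library, sample-wide biases
(total depth, residual GC structure, batch effects) cancel in the ratio

    r_i = v_i / mean_{j in ref(i)} v_j ,

and the per-bin z-score is r_i standardized by the panel's ratio statistics:
z_i = (r_i - mu_i) / sigma_i.  Individual z-scores are combined over a sliding
window by Stouffer's method, and runs of extreme windowed scores are merged
into gain/loss segments.

Reference bins exclude the bin's own chromosome by default so whole-chromosome
events are not self-normalized away.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import BinGrid
from .profile import SampleProfile, prepare

DEFAULT_K = 100
DEFAULT_WINDOW = 7
DEFAULT_Z_THRESHOLD = 3.5
DEFAULT_MERGE_GAP = 2
SIGMA_FLOOR_FRAC = 1e-4


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------

@dataclass
class ReferenceIndex:
    """Per-bin reference-bin sets plus panel ratio statistics.

    Arrays are indexed over the grid's usable bins (`bin_index` maps back to
    grid positions).  `ref` holds, for usable bin i, the k usable-bin row
    indices of its reference bins; `mu`/`sigma` are the panel mean and sample
    standard deviation (n-1 denominator) of the within-sample ratio r_i,
    estimated with leave-one-out reference selection (see
    :func:`build_reference_index`).
    """

    grid: BinGrid
    bin_index: np.ndarray      # usable-bin row -> grid bin index
    ref: np.ndarray            # (n_usable, k) int
    mu: np.ndarray             # (n_usable,)
    sigma: np.ndarray          # (n_usable,)
    k: int
    panel_size: int
    exclude_same_chrom: bool

    @property
    def n_usable(self) -> int:
        return len(self.bin_index)


@dataclass
class ZProfile:
    """Individual and windowed z-score tracks over the usable bins."""

    sample_id: str
    grid: BinGrid
    bin_index: np.ndarray          # usable-bin row -> grid bin index
    z: np.ndarray                  # individual per-bin z
    windowed: np.ndarray | None = None
    window: int | None = None

    def chrom_rows(self, chrom: str) -> np.ndarray:
        return np.flatnonzero(self.grid.chrom[self.bin_index] == chrom)


@dataclass
class Segment:
    """One called copy-number segment (bp, 0-based half-open)."""

    chrom: str
    start: int
    end: int
    direction: str       # "gain" | "loss"
    mean_z: float        # mean windowed Z over the segment's marked bins
    n_bins: int          # usable bins spanned

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"segment {self.chrom}:{self.start}-{self.end}: empty span")
        if self.direction not in ("gain", "loss"):
            raise ValueError(f"direction must be gain|loss, got {self.direction}")

    @property
    def size_mb(self) -> float:
        return (self.end - self.start) / 1e6


# ---------------------------------------------------------------------------
# reference index construction
# ---------------------------------------------------------------------------

def _panel_matrix(panel: list[SampleProfile], grid: BinGrid) -> np.ndarray:
    rows = []
    for p in panel:
        if p.values is None:
            raise ValueError(f"panel sample {p.sample_id} is not normalized")
        if not p.grid.same_coordinates(grid):
            raise ValueError(f"panel sample {p.sample_id} is on a different grid")
        rows.append(p.values)
    return np.asarray(rows)


def _topk_rows(D: np.ndarray, k: int, where: str = "") -> np.ndarray:
    """Indices of the k smallest entries per row; ties go to the lowest index.

    Rows must have at least k finite entries (infinite entries are
    ineligible); the set of selected indices is exact even at ties.
    """
    n = D.shape[0]
    out = np.empty((n, k), dtype=np.int64)
    # argpartition guarantees the k smallest *values*; tie identities fixed below
    part = np.argpartition(D, k - 1, axis=1)[:, :k]
    for i in range(n):
        row = D[i]
        finite = np.isfinite(row).sum()
        if finite < k:
            raise ValueError(
                f"{where or f'row {i}'}: only {int(finite)} eligible reference "
                f"bins for k={k}"
            )
        vk = row[part[i]].max()
        strict = np.flatnonzero(row < vk)
        if len(strict) == k:
            sel = strict
        else:
            ties = np.flatnonzero(row == vk)  # ascending index order already
            sel = np.concatenate([strict, ties[: k - len(strict)]])
        out[i] = np.sort(sel)
    return out


def build_reference_index(
    panel: list[SampleProfile],
    k: int = DEFAULT_K,
    exclude_same_chrom: bool = True,
) -> ReferenceIndex:
    """Choose reference bins by panel distance and compute ratio statistics.

    Distance between usable bins i and j is the sum over panel samples of
    (v_si - v_sj)^2.  ref(i) holds the k smallest-distance eligible bins (never
    i itself, never X-chromosome bins, and — by default — never bins on i's own
    chromosome), ties broken by grid order.

    mu and sigma are estimated leave-one-out: the ratio r_si of panel sample s
    uses reference bins selected from the distances of the other panel samples
    only.  Selecting references and measuring their ratio spread on the same
    samples would understate sigma (the selection favours bins whose noise
    happened to align in the panel), which mis-calibrates z on unseen samples;
    the held-out ratios match what a test sample experiences.  sigma is floored
    at 1e-4 * mu.
    """
    if len(panel) < 2:
        raise ValueError("reference panel needs at least 2 samples")
    if k < 1:
        raise ValueError("k must be >= 1")
    grid = panel[0].grid
    V_full = _panel_matrix(panel, grid)

    bin_index = np.flatnonzero(grid.usable)
    V = V_full[:, bin_index]                       # (n_panel, n_usable)
    chrom = grid.chrom[bin_index]
    autosomal = grid.autosomal[bin_index]
    n = len(bin_index)

    def describe(i: int) -> str:
        gi = bin_index[i]
        return f"bin {grid.chrom[gi]}:{grid.start[gi]}-{grid.end[gi]}"

    # d(i,j) = a_i + a_j - 2 G_ij with G the bin-by-bin Gram matrix
    a = np.einsum("si,si->i", V, V)
    G = V.T @ V
    D = a[:, None] + a[None, :] - 2.0 * G
    np.fill_diagonal(D, np.inf)
    D[:, ~autosomal] = np.inf                      # X bins never serve as references
    if exclude_same_chrom:
        for c in dict.fromkeys(chrom):
            rows = np.flatnonzero(chrom == c)
            D[np.ix_(rows, rows)] = np.inf

    finite_per_row = np.isfinite(D).sum(axis=1)
    if finite_per_row.min() < k:
        i = int(np.argmin(finite_per_row))
        raise ValueError(
            f"{describe(i)}: only {int(finite_per_row[i])} eligible reference "
            f"bins for k={k}"
        )
    ref = _topk_rows(D, k)

    R = np.empty_like(V)
    for s in range(len(panel)):
        diff = V[s][:, None] - V[s][None, :]
        D_loo = D - diff * diff                    # inf masks survive subtraction
        ref_s = _topk_rows(D_loo, k)
        R[s] = V[s] / V[s][ref_s].mean(axis=1)
    mu = R.mean(axis=0)
    sigma = R.std(axis=0, ddof=1)
    sigma = np.maximum(sigma, SIGMA_FLOOR_FRAC * np.abs(mu))
    return ReferenceIndex(
        grid=grid,
        bin_index=bin_index,
        ref=ref,
        mu=mu,
        sigma=sigma,
        k=k,
        panel_size=len(panel),
        exclude_same_chrom=exclude_same_chrom,
    )


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def score_bins(sample: SampleProfile, index: ReferenceIndex) -> ZProfile:
    """Individual per-bin z-scores of a test sample against the index."""
    if sample.values is None:
        raise ValueError(f"{sample.sample_id} is not normalized")
    if not sample.grid.same_coordinates(index.grid):
        raise ValueError(f"{sample.sample_id} is on a different grid than the index")
    v = sample.values[index.bin_index]
    ref_mean = v[index.ref].mean(axis=1)
    r = v / ref_mean
    z = (r - index.mu) / index.sigma
    return ZProfile(
        sample_id=sample.sample_id, grid=index.grid, bin_index=index.bin_index, z=z
    )


def windowed_scores(zprofile: ZProfile, w: int = DEFAULT_WINDOW) -> ZProfile:
    """Stouffer-combined z over a centered w-bin window, per chromosome.

    Z_i = (sum of z over the window) / sqrt(actual window size); windows are
    truncated at chromosome ends and never span chromosomes.
    """
    if w < 1 or w % 2 == 0:
        raise ValueError(f"window width must be odd and >= 1, got {w}")
    half = w // 2
    Z = np.empty_like(zprofile.z)
    chrom = zprofile.grid.chrom[zprofile.bin_index]
    for c in dict.fromkeys(chrom):
        rows = np.flatnonzero(chrom == c)
        z = zprofile.z[rows]
        m = len(z)
        cs = np.concatenate(([0.0], np.cumsum(z)))
        lo = np.maximum(np.arange(m) - half, 0)
        hi = np.minimum(np.arange(m) + half + 1, m)
        Z[rows] = (cs[hi] - cs[lo]) / np.sqrt(hi - lo)
    return ZProfile(
        sample_id=zprofile.sample_id,
        grid=zprofile.grid,
        bin_index=zprofile.bin_index,
        z=zprofile.z,
        windowed=Z,
        window=w,
    )


def call_segments(
    zprofile: ZProfile,
    call_threshold: float = DEFAULT_Z_THRESHOLD,
    merge_gap: int = DEFAULT_MERGE_GAP,
) -> list[Segment]:
    """Merge runs of extreme same-sign windowed scores into segments.

    Bins with |Z| >= call_threshold are marked.  Same-sign marked bins on one
    chromosome are merged when separated by at most `merge_gap` unmarked usable
    bins; a segment spans its first to last marked bin.  Direction follows the
    sign; mean_z is the mean windowed Z over the segment's marked bins.
    """
    if zprofile.windowed is None:
        raise ValueError("windowed scores must be computed before segmentation")
    grid = zprofile.grid
    chrom = grid.chrom[zprofile.bin_index]
    Z = zprofile.windowed
    segments: list[Segment] = []
    for c in dict.fromkeys(chrom):
        rows = np.flatnonzero(chrom == c)
        marked = np.flatnonzero(np.abs(Z[rows]) >= call_threshold)
        if len(marked) == 0:
            continue
        signs = np.sign(Z[rows[marked]])
        runs: list[list[int]] = [[marked[0]]]
        for prev, cur, s_prev, s_cur in zip(marked[:-1], marked[1:], signs[:-1], signs[1:]):
            if s_cur == s_prev and (cur - prev - 1) <= merge_gap:
                runs[-1].append(cur)
            else:
                runs.append([cur])
        for run in runs:
            first, last = rows[run[0]], rows[run[-1]]
            gi_first = zprofile.bin_index[first]
            gi_last = zprofile.bin_index[last]
            marked_rows = rows[run]
            mean_z = float(Z[marked_rows].mean())
            segments.append(
                Segment(
                    chrom=c,
                    start=int(grid.start[gi_first]),
                    end=int(grid.end[gi_last]),
                    direction="gain" if mean_z > 0 else "loss",
                    mean_z=mean_z,
                    n_bins=last - first + 1,
                )
            )
    return segments


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------

class WithinSampleReferenceModel:
    """Copy-number caller fitted to a panel of unaffected samples.

    Parameters
    ----------
    panel
        Unaffected samples on a shared grid.  Raw-count profiles are
        normalized and GC-corrected automatically (``prepare=False`` to skip).
    k
        Number of reference bins per bin.
    exclude_same_chrom
        Keep a bin's own chromosome out of its reference set (default True).
    """

    def __init__(
        self,
        panel: list[SampleProfile],
        k: int = DEFAULT_K,
        exclude_same_chrom: bool = True,
        prepare_profiles: bool = True,
    ):
        if prepare_profiles:
            panel = [p if p.gc_corrected else prepare(p) for p in panel]
        self.panel = panel
        self.k = k
        self.exclude_same_chrom = exclude_same_chrom

    def fit(self) -> "WithinSampleReferenceResults":
        index = build_reference_index(
            self.panel, k=self.k, exclude_same_chrom=self.exclude_same_chrom
        )
        return WithinSampleReferenceResults(self, index)


@dataclass
class CallResult:
    """Z-score tracks plus called segments for one sample."""

    zprofile: ZProfile
    segments: list[Segment]

    def plot(self, chrom: str | None = None, ax=None):
        from .plotting import plot_profile

        return plot_profile(self.zprofile, self.segments, chrom=chrom, ax=ax)


class WithinSampleReferenceResults:
    """Fitted reference index; scores and calls test samples."""

    def __init__(self, model: WithinSampleReferenceModel, index: ReferenceIndex):
        self.model = model
        self.index = index

    def score(self, sample: SampleProfile, prepare_profile: bool = True) -> ZProfile:
        if prepare_profile and not sample.gc_corrected:
            sample = prepare(sample)
        return score_bins(sample, self.index)

    def call(
        self,
        sample: SampleProfile,
        window: int = DEFAULT_WINDOW,
        z_threshold: float = DEFAULT_Z_THRESHOLD,
        merge_gap: int = DEFAULT_MERGE_GAP,
        prepare_profile: bool = True,
    ) -> CallResult:
        zp = windowed_scores(self.score(sample, prepare_profile), window)
        return CallResult(zp, call_segments(zp, z_threshold, merge_gap))

    def summary(self) -> str:
        idx = self.index
        lines = [
            "Within-sample reference copy-number model",
            "=" * 45,
            f"panel size:            {idx.panel_size}",
            f"usable bins:           {idx.n_usable}",
            f"reference bins per bin:{idx.k:>5}",
            f"same-chrom excluded:   {idx.exclude_same_chrom}",
            f"ratio mean mu:         {idx.mu.mean():.4f} "
            f"(range {idx.mu.min():.4f}-{idx.mu.max():.4f})",
            f"ratio sd sigma:        median {np.median(idx.sigma):.4g}",
        ]
        return "\n".join(lines)
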