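"""Profile plots: individual and windowed z-score tracks with called bars.

Non-normative visual output; the decision layer never depends on it.
"""

from __future__ import annotations

import numpy as np


def plot_profile(zprofile, segments=None, chrom: str | None = None, ax=None,
                 call_threshold: float = 3.5):
    """Plot the individual (blue) and windowed (red) z tracks for one sample.

    Purple bars underneath mark called segments.  Restrict to one chromosome
    with `chrom`; otherwise all chromosomes are concatenated with boundaries.
    """
    import matplotlib

    if ax is None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(12, 3.5))

    grid = zprofile.grid
    chroms = grid.chrom[zprofile.bin_index]
    if chrom is not None:
        rows = np.flatnonzero(chroms == chrom)
        x = grid.midpoint[zprofile.bin_index[rows]] / 1e6
        xlabel = f"{chrom} position (Mb)"
    else:
        rows = np.arange(len(zprofile.z))
        x = np.arange(len(rows), dtype=float)
        xlabel = "usable bin"
    ax.plot(x, zprofile.z[rows], color="tab:blue", lw=0.6, label="individual z")
    if zprofile.windowed is not None:
        ax.plot(x, zprofile.windowed[rows], color="tab:red", lw=1.0, label="windowed Z")
    ax.axhline(call_threshold, color="grey", lw=0.5, ls="--")
    ax.axhline(-call_threshold, color="grey", lw=0.5, ls="--")

    if segments:
        ymin = min(-5.0, float(np.min(zprofile.z[rows])) - 1)
        for seg in segments:
            if chrom is not None:
                if seg.chrom != chrom:
                    continue
                ax.axvspan(seg.start / 1e6, seg.end / 1e6, color="purple", alpha=0.2)
                ax.hlines(ymin, seg.start / 1e6, seg.end / 1e6, color="purple", lw=4)
            else:
                in_seg = (chroms == seg.chrom) & (
                    grid.start[zprofile.bin_index] >= seg.start
                ) & (grid.end[zprofile.bin_index] <= seg.end)
                hit = np.flatnonzero(in_seg)
                if len(hit):
                    ax.hlines(ymin, hit[0], hit[-1] + 1, color="purple", lw=4)
    if chrom is None:
        # chromosome boundaries
        edges = np.flatnonzero(chroms[1:] != chroms[:-1]) + 1
        for e in edges:
            ax.axvline(e, color="lightgrey", lw=0.4)
    ax.set_xlabel(xlabel)
    ax.set_ylabel("z-score")
    ax.set_title(zprofile.sample_id)
    ax.legend(loc="upper right", fontsize=8)
    return ax
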