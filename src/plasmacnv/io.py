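"""On-disk formats: bin grids, bin counts, segments (BED6+3), manifests, reports.

All tables are plain tab-separated text with a header; coordinates are 0-based
half-open everywhere.  Every writer/reader pair round-trips losslessly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .caller import Segment
from .grid import BinGrid
from .profile import SampleProfile


class ParseError(ValueError):
    """A malformed input file; the message names the offending line."""


def _read_tsv(path, columns: dict[str, type], optional: tuple[str, ...] = ()) -> pd.DataFrame:
    try:
        df = pd.read_csv(
            path, sep="\t", comment="#", dtype={"chrom": str},
            float_precision="round_trip",
        )
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"{path}: {exc}") from exc
    missing = set(columns) - set(optional) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    for col, typ in columns.items():
        if col not in df.columns or typ is str:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(coerced.isna() & df[col].notna())
        if len(bad):
            # +2: header line and 1-based numbering
            raise ParseError(
                f"{path}: malformed {col!r} value {df[col].iloc[bad[0]]!r} "
                f"on line {int(bad[0]) + 2}"
            )
        if coerced.isna().any():
            i = int(np.flatnonzero(coerced.isna())[0])
            raise ParseError(f"{path}: missing {col!r} value on line {i + 2}")
        df[col] = coerced.astype(typ)
    return df


# -- bin grid ---------------------------------------------------------------

def load_bin_grid(path, genome=None) -> BinGrid:
    """Read a bin-grid TSV (chrom, start, end, gc[, usable])."""
    df = _read_tsv(
        path,
        {"chrom": str, "start": np.int64, "end": np.int64, "gc": float, "usable": np.int64},
        optional=("usable",),
    )
    usable = df["usable"].astype(bool).to_numpy() if "usable" in df.columns else np.ones(len(df), bool)
    widths = (df["end"] - df["start"]).to_numpy()
    bin_size = int(np.median(widths)) if len(widths) else 0
    return BinGrid(
        chrom=df["chrom"].to_numpy(dtype=object),
        start=df["start"].to_numpy(),
        end=df["end"].to_numpy(),
        gc=df["gc"].to_numpy(),
        usable=usable,
        bin_size=bin_size,
        genome=genome,
    )


def write_bin_grid(grid: BinGrid, path) -> None:
    grid.to_frame().to_csv(path, sep="\t", index=False)


# -- bin counts -------------------------------------------------------------

def read_bin_counts(path, grid: BinGrid, sample_id: str | None = None) -> SampleProfile:
    """Read a per-sample count TSV (chrom, start, end, gc, count) onto `grid`.

    The file's bin coordinates must exactly match the grid; the first
    mismatching bin is named otherwise.
    """
    df = _read_tsv(
        path,
        {"chrom": str, "start": np.int64, "end": np.int64, "gc": float, "count": np.int64},
    )
    if len(df) != grid.n_bins:
        raise ParseError(
            f"{path}: {len(df)} bins but grid has {grid.n_bins}"
        )
    mismatch = (
        (df["chrom"].to_numpy(dtype=object) != grid.chrom)
        | (df["start"].to_numpy() != grid.start)
        | (df["end"].to_numpy() != grid.end)
    )
    if mismatch.any():
        i = int(np.flatnonzero(mismatch)[0])
        raise ParseError(
            f"{path}: bin {i} is {df['chrom'].iloc[i]}:{df['start'].iloc[i]}-"
            f"{df['end'].iloc[i]}, grid has {grid.chrom[i]}:{grid.start[i]}-{grid.end[i]}"
        )
    counts = df["count"].to_numpy()
    if np.any(counts < 0):
        i = int(np.flatnonzero(counts < 0)[0])
        raise ParseError(f"{path}: negative count on line {i + 2}")
    if sample_id is None:
        sample_id = Path(path).stem
    return SampleProfile(sample_id=sample_id, grid=grid, counts=counts)


def write_bin_counts(profile: SampleProfile, path) -> None:
    df = pd.DataFrame(
        {
            "chrom": profile.grid.chrom,
            "start": profile.grid.start,
            "end": profile.grid.end,
            "gc": profile.grid.gc,
            "count": profile.counts,
        }
    )
    df.to_csv(path, sep="\t", index=False)


# -- segments (BED6+3) ------------------------------------------------------

_BED_HEADER = "#chrom\tstart\tend\tname\tscore\tstrand\tsize_mb\tarms\tspecificity"


def write_segments(segments: list[Segment], path, annotations=None) -> None:
    """Write called segments as BED6+3.

    name = gain|loss, score = |mean windowed Z| capped at 1000, strand = '.',
    extra columns: size_mb, overlapped arm(s), specificity class.  When
    `annotations` (a parallel list of AnnotatedCNV) is omitted the extra
    columns hold '.'.
    """
    lines = [_BED_HEADER]
    for i, seg in enumerate(segments):
        arms, cls = ".", "."
        if annotations is not None:
            ann = annotations[i]
            arms = ",".join(a for a, _ in ann.arm_overlaps) or "."
            cls = str(ann.specificity)
        score = min(abs(seg.mean_z), 1000.0)
        lines.append(
            f"{seg.chrom}\t{seg.start}\t{seg.end}\t{seg.direction}\t{score:.3f}\t.\t"
            f"{seg.size_mb:.6g}\t{arms}\t{cls}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_segments(path) -> list[Segment]:
    segments = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        chrom, start, end, name, score = fields[0], int(fields[1]), int(fields[2]), fields[3], float(fields[4])
        segments.append(
            Segment(
                chrom=chrom,
                start=start,
                end=end,
                direction=name,
                mean_z=score if name == "gain" else -score,
                n_bins=0,
            )
        )
    return segments


# -- cohort manifest --------------------------------------------------------

MANIFEST_COLUMNS = ["sample_id", "group", "stage_label", "tumor_fraction", "counts_path"]


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str}, float_precision="round_trip")
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: manifest missing columns {sorted(missing)}")
    return df


def write_manifest(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


# -- reports ----------------------------------------------------------------

def write_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


def read_report(path) -> dict:
    return json.loads(Path(path).read_text())
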