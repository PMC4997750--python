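"""End-to-end cohort screening: counts files in, per-subject report out.

Thin composition of the caller, screen and evaluation layers, shared by the
command-line interface and scripted analyses.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from . import io as pio
from .aneuploidy import AneuploidyModel
from .caller import (
    DEFAULT_K,
    DEFAULT_MERGE_GAP,
    DEFAULT_WINDOW,
    DEFAULT_Z_THRESHOLD,
    WithinSampleReferenceModel,
)
from .catalog import CNVCatalog, default_catalog
from .evaluate import ArmEvent, confusion_table, performance_report
from .genome import GenomeSpec, default_genome
from .screen import SCREEN_MIN_SIZE_MB, annotate_segments, apply_size_rule, count_focal_aberrations


def load_panel(panel_dir, grid) -> list:
    paths = sorted(Path(panel_dir).glob("*.tsv"))
    if len(paths) < 2:
        raise ValueError(f"{panel_dir}: need >= 2 panel count files")
    return [pio.read_bin_counts(p, grid) for p in paths]


def screen_cohort(
    cohort_dir,
    genome: GenomeSpec | None = None,
    catalog: CNVCatalog | None = None,
    k: int = DEFAULT_K,
    window: int = DEFAULT_WINDOW,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
    merge_gap: int = DEFAULT_MERGE_GAP,
    min_size_mb: float = SCREEN_MIN_SIZE_MB,
    aneuploidy_screen: bool = True,
) -> dict:
    """Run the full analysis on a simulated/on-disk cohort directory.

    Expects `grid.tsv`, `panel/*.tsv`, `samples/*.tsv` and `manifest.tsv` as
    written by :func:`plasmacnv.simulate.simulate_cohort`.  Returns the report
    dict (also JSON-serializable).
    """
    cohort_dir = Path(cohort_dir)
    genome = genome or default_genome()
    catalog = catalog or default_catalog()
    grid = pio.load_bin_grid(cohort_dir / "grid.tsv", genome=genome)
    manifest = pio.read_manifest(cohort_dir / "manifest.tsv")

    panel = load_panel(cohort_dir / "panel", grid)
    cnv = WithinSampleReferenceModel(panel, k=k).fit()
    anp = AneuploidyModel(cnv.model.panel, prepare_profiles=False).fit() if (
        aneuploidy_screen and len(panel) >= 10
    ) else None

    calls = []
    subjects = {}
    for row in manifest.itertuples():
        profile = pio.read_bin_counts(cohort_dir / row.counts_path, grid, row.sample_id)
        from .profile import prepare

        prepared = prepare(profile)
        result = cnv.call(
            prepared, window=window, z_threshold=z_threshold,
            merge_gap=merge_gap, prepare_profile=False,
        )
        call = apply_size_rule(result.segments, row.sample_id, min_size_mb)
        calls.append(call)
        annotations = annotate_segments(call.qualifying, genome, catalog)
        subject = {
            "screen_status": call.status,
            "n_segments": len(call.segments),
            "n_focal": count_focal_aberrations(call.segments, min_size_mb),
            "qualifying_segments": [
                {
                    "chrom": s.chrom,
                    "start": s.start,
                    "end": s.end,
                    "direction": s.direction,
                    "size_mb": round(s.size_mb, 3),
                    "mean_windowed_z": round(s.mean_z, 3),
                    "arms": [a for a, _ in ann.arm_overlaps],
                    "specificity": str(ann.specificity),
                }
                for s, ann in zip(call.qualifying, annotations)
            ],
        }
        if anp is not None:
            subject["aneuploidy"] = anp.screen(prepared, prepare_profile=False).to_dict()
        subjects[row.sample_id] = subject

    counts = confusion_table(calls, manifest)
    pos_cases = {
        c.sample_id
        for c in calls
        if c.status == "positive"
        and manifest.set_index("sample_id").loc[c.sample_id, "group"] == "case"
    }
    events = []
    for sid in pos_cases | {
        c.sample_id for c in calls if c.status == "positive"
    }:
        for seg in subjects[sid]["qualifying_segments"]:
            events.append(
                ArmEvent(subject=sid, direction=seg["direction"], arms=tuple(seg["arms"]))
            )
    report = performance_report(
        counts, events=events, catalog=catalog, true_positive_ids=pos_cases
    )
    return {
        "subjects": subjects,
        "cohort": report.to_dict(),
        "summary": report.summary(),
    }
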