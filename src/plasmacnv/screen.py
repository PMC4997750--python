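"""The prespecified cancer screen rule and catalog annotation.

A subject screens positive when at least one called segment spans >= 15 Mb
(inclusive; the threshold is configurable).  Qualifying segments are mapped to
the chromosome arms they overlap by at least 25% of the segment's length, each
(arm, direction) is classified against the recurrent-CNV catalog, and a
segment's overall specificity class is the best (most specific) among its
arms.  Segments below the threshold are the "focal" aberrations counted
separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .caller import Segment
from .catalog import CNVCatalog, Specificity
from .genome import GenomeSpec

SCREEN_MIN_SIZE_MB = 15.0
ARM_OVERLAP_FRACTION = 0.25


@dataclass
class ScreenCall:
    """Per-subject screen decision."""

    sample_id: str
    status: str                       # "positive" | "negative"
    qualifying: list[Segment] = field(default_factory=list)
    segments: list[Segment] = field(default_factory=list)

    def __post_init__(self) -> None:
        assert (self.status == "positive") == (len(self.qualifying) > 0)


@dataclass
class AnnotatedCNV:
    """One segment with its arm assignment and catalog specificity class."""

    segment: Segment
    arm_overlaps: list[tuple[str, float]]   # (arm id, overlap fraction of segment)
    direction: str
    specificity: Specificity


def apply_size_rule(
    segments: list[Segment],
    sample_id: str = "sample",
    min_size_mb: float = SCREEN_MIN_SIZE_MB,
) -> ScreenCall:
    """Positive iff any segment's size_mb >= min_size_mb (inclusive)."""
    qualifying = [s for s in segments if s.size_mb >= min_size_mb]
    return ScreenCall(
        sample_id=sample_id,
        status="positive" if qualifying else "negative",
        qualifying=qualifying,
        segments=list(segments),
    )


def classify_arms(
    arms: list[str], direction: str, catalog: CNVCatalog
) -> Specificity:
    """Best (most specific) catalog class over a set of arms, one direction."""
    if not arms:
        return Specificity.non_specific
    return max(catalog.classify(a, direction) for a in arms)


def annotate_segments(
    segments: list[Segment],
    genome: GenomeSpec,
    catalog: CNVCatalog,
    overlap_fraction: float = ARM_OVERLAP_FRACTION,
) -> list[AnnotatedCNV]:
    """Assign each segment to arms (>= 25% overlap) and classify it."""
    out = []
    for seg in segments:
        if seg.chrom not in genome.names:
            raise ValueError(f"segment chromosome {seg.chrom} not in genome")
        if seg.end > genome.lengths[seg.chrom]:
            raise ValueError(
                f"segment {seg.chrom}:{seg.start}-{seg.end} extends past chromosome end"
            )
        length = seg.end - seg.start
        overlaps = []
        for arm in genome.arms_of(seg.chrom):
            ov = min(seg.end, arm.end) - max(seg.start, arm.start)
            if ov > 0 and ov / length >= overlap_fraction:
                overlaps.append((arm.arm, ov / length))
        cls = classify_arms([a for a, _ in overlaps], seg.direction, catalog)
        out.append(
            AnnotatedCNV(
                segment=seg,
                arm_overlaps=overlaps,
                direction=seg.direction,
                specificity=cls,
            )
        )
    return out


def count_focal_aberrations(
    segments: list[Segment], focal_max_mb: float = SCREEN_MIN_SIZE_MB
) -> int:
    """Number of called segments smaller than the screen threshold."""
    return sum(1 for s in segments if s.size_mb < focal_max_mb)
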