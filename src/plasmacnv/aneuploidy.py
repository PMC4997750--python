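"""NIPT-style whole-chromosome aneuploidy screen.

Emulates, at the method-class level, a routine prenatal-screening pipeline:
each target chromosome's read fraction is standardized against a reference
panel (the normalized chromosome value, NCV), high-risk calls are issued at
|z| >= 4, and a sample is reported "no call" when any non-target autosome —
the pipeline's normalizing material — itself deviates (|z| > 3).  Targets are
chromosomes 13, 18, 21 and X; Y is excluded (female study population).

The real clinical statistic and no-call criteria are proprietary; this module
is a generic approximation and flags itself as such in reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import is_autosome, short_name
from .profile import SampleProfile, prepare

DEFAULT_TARGETS = ("chr13", "chr18", "chr21", "chrX")
CALL_Z = 4.0
QC_Z = 3.0
MIN_PANEL = 10
APPROXIMATION_NOTE = (
    "generic normalized-chromosome-value approximation of a clinical NIPT "
    "statistic; no-call rule is not the proprietary criterion"
)


def chromosome_fractions(profile: SampleProfile) -> pd.Series:
    """Per-chromosome sum of usable-bin normalized values.

    Autosomal fractions sum to 1 (X is normalized by the autosomal total).
    """
    if profile.values is None:
        raise ValueError(f"{profile.sample_id} is not normalized")
    grid = profile.grid
    vals = np.where(grid.usable, profile.values, 0.0)
    out = {}
    for c in grid.chroms:
        out[c] = float(vals[grid.chrom_indices(c)].sum())
    return pd.Series(out)


@dataclass
class AneuploidyResult:
    """Screen outcome for one sample."""

    sample_id: str
    status: str                       # "reported" | "no_call"
    reason: str | None = None         # set when status == "no_call"
    calls: dict[str, str] = field(default_factory=dict)    # target -> risk call
    labels: dict[str, str] = field(default_factory=dict)   # target -> e.g. "monosomy 18"
    z: dict[str, float] = field(default_factory=dict)      # all chromosomes
    fractions: dict[str, float] = field(default_factory=dict)
    note: str = APPROXIMATION_NOTE

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "status": self.status,
            "reason": self.reason,
            "calls": self.calls,
            "labels": self.labels,
            "z": {k: round(v, 4) for k, v in self.z.items()},
            "note": self.note,
        }


def ncv_scores(
    fractions: pd.Series, panel_mean: pd.Series, panel_sd: pd.Series
) -> pd.Series:
    """z_c = (fraction_c - panel mean_c) / panel sd_c for every chromosome."""
    if (panel_sd <= 0).any():
        bad = panel_sd.index[panel_sd <= 0][0]
        raise ValueError(f"panel sd is zero for {bad}")
    return (fractions - panel_mean) / panel_sd


def classify_aneuploidy(
    z: pd.Series,
    sample_id: str = "sample",
    targets: tuple[str, ...] = DEFAULT_TARGETS,
    call_z: float = CALL_Z,
    qc_z: float = QC_Z,
    fractions: pd.Series | None = None,
) -> AneuploidyResult:
    """Risk calls at |z| >= call_z; no-call when a normalizing autosome deviates."""
    qc_chroms = [c for c in z.index if is_autosome(c) and c not in targets]
    disturbed = [c for c in qc_chroms if abs(z[c]) > qc_z]
    zdict = {c: float(z[c]) for c in z.index}
    frac = {} if fractions is None else {c: float(fractions[c]) for c in fractions.index}
    if disturbed:
        detail = ", ".join(f"{c} (z={z[c]:+.1f})" for c in disturbed)
        return AneuploidyResult(
            sample_id=sample_id,
            status="no_call",
            reason=f"unexpected profile on normalizing chromosomes: {detail}",
            z=zdict,
            fractions=frac,
        )
    calls, labels = {}, {}
    for t in targets:
        zt = float(z[t])
        if zt >= call_z:
            calls[t] = "high_risk_gain"
            labels[t] = f"trisomy {short_name(t)}"
        elif zt <= -call_z:
            calls[t] = "high_risk_loss"
            labels[t] = f"monosomy {short_name(t)}"
        else:
            calls[t] = "low_risk"
    return AneuploidyResult(
        sample_id=sample_id, status="reported", calls=calls, labels=labels,
        z=zdict, fractions=frac,
    )


class AneuploidyModel:
    """Whole-chromosome screen fitted to a reference panel of fractions."""

    def __init__(
        self,
        panel: list[SampleProfile],
        targets: tuple[str, ...] = DEFAULT_TARGETS,
        prepare_profiles: bool = True,
    ):
        if len(panel) < MIN_PANEL:
            raise ValueError(
                f"aneuploidy panel needs >= {MIN_PANEL} samples for stable sd, "
                f"got {len(panel)}"
            )
        if prepare_profiles:
            panel = [p if p.gc_corrected else prepare(p) for p in panel]
        self.panel = panel
        self.targets = targets

    def fit(self) -> "AneuploidyResults":
        fracs = pd.DataFrame([chromosome_fractions(p) for p in self.panel])
        return AneuploidyResults(
            model=self,
            panel_mean=fracs.mean(axis=0),
            panel_sd=fracs.std(axis=0, ddof=1),
            panel_size=len(self.panel),
        )


@dataclass
class AneuploidyResults:
    model: AneuploidyModel
    panel_mean: pd.Series
    panel_sd: pd.Series
    panel_size: int

    def score(self, sample: SampleProfile, prepare_profile: bool = True) -> pd.Series:
        if prepare_profile and not sample.gc_corrected:
            sample = prepare(sample)
        return ncv_scores(chromosome_fractions(sample), self.panel_mean, self.panel_sd)

    def screen(
        self,
        sample: SampleProfile,
        call_z: float = CALL_Z,
        qc_z: float = QC_Z,
        prepare_profile: bool = True,
    ) -> AneuploidyResult:
        if prepare_profile and not sample.gc_corrected:
            sample = prepare(sample)
        fractions = chromosome_fractions(sample)
        z = ncv_scores(fractions, self.panel_mean, self.panel_sd)
        return classify_aneuploidy(
            z,
            sample_id=sample.sample_id,
            targets=self.model.targets,
            call_z=call_z,
            qc_z=qc_z,
            fractions=fractions,
        )

    def summary(self) -> str:
        lines = [
            "NIPT-style aneuploidy screen",
            "=" * 40,
            f"panel size: {self.panel_size}",
            f"targets:    {', '.join(self.model.targets)}",
            "chromosome fraction mean (sd):",
        ]
        for c in self.panel_mean.index:
            lines.append(
                f"  {c:>6}: {self.panel_mean[c]:.5f} ({self.panel_sd[c]:.2e})"
            )
        return "\n".join(lines)
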