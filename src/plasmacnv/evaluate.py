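"""Cohort-level screening performance.

Confusion counts, sensitivity/specificity with exact (Clopper–Pearson) 95%
binomial confidence intervals, per-stage detection, per-arm gain/loss tallies
over true positives, and the count of true positives carrying at least one
highly specific recurrent CNV.  Also ships a worked-example cohort: the
screen-positive call lists of a published 64-subject HGSOC plasma study,
bundled as a plain-text fixture.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from importlib import resources

import pandas as pd
from scipy import stats

from .catalog import CNVCatalog, Specificity, default_catalog
from .screen import ScreenCall, classify_arms


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding for report display."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# exact binomial CI
# ---------------------------------------------------------------------------

def binomial_ci_exact(
    successes: int, trials: int, level: float = 0.95
) -> tuple[float, float]:
    """Two-sided exact Clopper–Pearson interval, in percent.

    Bounds are the beta-distribution quantiles
    lower = B(alpha/2; x, n-x+1), upper = B(1-alpha/2; x+1, n-x),
    with lower = 0 at x = 0 and upper = 100 at x = n.
    """
    if trials < 1:
        raise ValueError("trials must be >= 1")
    if not 0 <= successes <= trials:
        raise ValueError(f"successes {successes} outside [0, {trials}]")
    alpha = 1.0 - level
    if successes == 0:
        lower = 0.0
    else:
        lower = float(stats.beta.ppf(alpha / 2, successes, trials - successes + 1))
    if successes == trials:
        upper = 1.0
    else:
        upper = float(stats.beta.ppf(1 - alpha / 2, successes + 1, trials - successes))
    return 100.0 * lower, 100.0 * upper


# ---------------------------------------------------------------------------
# confusion counts
# ---------------------------------------------------------------------------

@dataclass
class ConfusionCounts:
    tp: int = 0
    fn: int = 0
    fp: int = 0
    tn: int = 0
    # stage_label -> (n detected, n total), cases only
    per_stage: dict[str, tuple[int, int]] = field(default_factory=dict)

    @property
    def n_cases(self) -> int:
        return self.tp + self.fn

    @property
    def n_controls(self) -> int:
        return self.fp + self.tn

    @property
    def total(self) -> int:
        return self.n_cases + self.n_controls


def confusion_table(calls: list[ScreenCall], manifest: pd.DataFrame) -> ConfusionCounts:
    """Cross screen calls with case/control labels from a manifest.

    The manifest needs columns sample_id, group (case|control) and
    stage_label; every call must match a manifest row.
    """
    labels = manifest.set_index("sample_id")
    counts = ConfusionCounts()
    stage: dict[str, list[int]] = {}
    for call in calls:
        if call.sample_id not in labels.index:
            raise ValueError(f"sample {call.sample_id} not in manifest")
        row = labels.loc[call.sample_id]
        positive = call.status == "positive"
        if row["group"] == "case":
            tally = stage.setdefault(str(row["stage_label"]), [0, 0])
            tally[1] += 1
            if positive:
                counts.tp += 1
                tally[0] += 1
            else:
                counts.fn += 1
        elif row["group"] == "control":
            if positive:
                counts.fp += 1
            else:
                counts.tn += 1
        else:
            raise ValueError(f"{call.sample_id}: group must be case|control")
    counts.per_stage = {k: (v[0], v[1]) for k, v in stage.items()}
    return counts


# ---------------------------------------------------------------------------
# arm tallies and highly-specific count
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ArmEvent:
    """One reported CNV of a subject, at arm resolution."""

    subject: str
    direction: str           # "gain" | "loss"
    arms: tuple[str, ...]    # arms the event maps to (>= 25% overlap)
    label: str = ""


def arm_event_tally(events: list[ArmEvent]) -> dict[tuple[str, str], int]:
    """Per-(arm, direction) count of subjects with >= 1 such event.

    A subject contributes at most once per (arm, direction), however many of
    its events touch that arm.
    """
    seen: set[tuple[str, str, str]] = set()
    tally: dict[tuple[str, str], int] = {}
    for ev in events:
        for arm in ev.arms:
            key = (ev.subject, arm, ev.direction)
            if key in seen:
                continue
            seen.add(key)
            tally[(arm, ev.direction)] = tally.get((arm, ev.direction), 0) + 1
    return tally


def subjects_with_highly_specific(
    events: list[ArmEvent], catalog: CNVCatalog
) -> set[str]:
    """Subjects having >= 1 event classified highly_specific by the catalog."""
    out = set()
    for ev in events:
        if classify_arms(list(ev.arms), ev.direction, catalog) == Specificity.highly_specific:
            out.add(ev.subject)
    return out


# ---------------------------------------------------------------------------
# performance report
# ---------------------------------------------------------------------------

@dataclass
class PerformanceReport:
    counts: ConfusionCounts
    sensitivity: float | None          # percent, full precision
    sensitivity_ci: tuple[float, float] | None
    specificity: float | None
    specificity_ci: tuple[float, float] | None
    per_stage: dict[str, tuple[int, int]]
    arm_tallies: dict[tuple[str, str], int] = field(default_factory=dict)
    n_highly_specific_tp: int | None = None

    def to_dict(self) -> dict:
        def pct(x):
            return None if x is None else round_half_up(x, 1)

        d = {
            "counts": {
                "tp": self.counts.tp,
                "fn": self.counts.fn,
                "fp": self.counts.fp,
                "tn": self.counts.tn,
            },
            "sensitivity_percent": pct(self.sensitivity),
            "sensitivity_ci95": None
            if self.sensitivity_ci is None
            else [pct(self.sensitivity_ci[0]), pct(self.sensitivity_ci[1])],
            "specificity_percent": pct(self.specificity),
            "specificity_ci95": None
            if self.specificity_ci is None
            else [pct(self.specificity_ci[0]), pct(self.specificity_ci[1])],
            "per_stage_detection": {
                k: {"detected": v[0], "total": v[1]} for k, v in self.per_stage.items()
            },
        }
        if self.arm_tallies:
            d["arm_tallies"] = {
                f"{arm} {direction}": n
                for (arm, direction), n in sorted(self.arm_tallies.items())
            }
        if self.n_highly_specific_tp is not None:
            d["true_positives_with_highly_specific_cnv"] = self.n_highly_specific_tp
        return d

    def summary(self) -> str:
        c = self.counts
        lines = [
            "Screening performance",
            "=" * 40,
            f"cases: {c.n_cases}  controls: {c.n_controls}",
            f"TP {c.tp}  FN {c.fn}  FP {c.fp}  TN {c.tn}",
        ]
        if self.sensitivity is not None:
            lo, hi = self.sensitivity_ci
            lines.append(
                f"sensitivity {round_half_up(self.sensitivity):.1f}% "
                f"(95% CI {round_half_up(lo):.1f}-{round_half_up(hi):.1f})"
            )
        else:
            lines.append("sensitivity undefined (no cases)")
        if self.specificity is not None:
            lo, hi = self.specificity_ci
            lines.append(
                f"specificity {round_half_up(self.specificity):.1f}% "
                f"(95% CI {round_half_up(lo):.1f}-{round_half_up(hi):.1f})"
            )
        else:
            lines.append("specificity undefined (no controls)")
        for stage, (det, tot) in self.per_stage.items():
            lines.append(f"  {stage}: {det}/{tot} detected")
        if self.n_highly_specific_tp is not None:
            lines.append(
                f"true positives with >=1 highly specific CNV: "
                f"{self.n_highly_specific_tp}/{c.tp}"
            )
        return "\n".join(lines)


def performance_report(
    counts: ConfusionCounts,
    events: list[ArmEvent] | None = None,
    catalog: CNVCatalog | None = None,
    true_positive_ids: set[str] | None = None,
    level: float = 0.95,
) -> PerformanceReport:
    """Point estimates, exact CIs and (optionally) catalog-derived summaries.

    `events` are the arm-level CNVs of screen-positive subjects; only those of
    `true_positive_ids` enter the tallies and the highly-specific count.
    """
    sens = sens_ci = spec = spec_ci = None
    if counts.n_cases > 0:
        sens = 100.0 * counts.tp / counts.n_cases
        sens_ci = binomial_ci_exact(counts.tp, counts.n_cases, level)
    if counts.n_controls > 0:
        spec = 100.0 * counts.tn / counts.n_controls
        spec_ci = binomial_ci_exact(counts.tn, counts.n_controls, level)
    tallies: dict[tuple[str, str], int] = {}
    n_high = None
    if events is not None:
        if true_positive_ids is None:
            true_positive_ids = {e.subject for e in events}
        tp_events = [e for e in events if e.subject in true_positive_ids]
        tallies = arm_event_tally(tp_events)
        if catalog is None:
            catalog = default_catalog()
        n_high = len(
            subjects_with_highly_specific(tp_events, catalog) & true_positive_ids
        )
    return PerformanceReport(
        counts=counts,
        sensitivity=sens,
        sensitivity_ci=sens_ci,
        specificity=spec,
        specificity_ci=spec_ci,
        per_stage=dict(counts.per_stage),
        arm_tallies=tallies,
        n_highly_specific_tp=n_high,
    )


# ---------------------------------------------------------------------------
# the worked-example cohort
# ---------------------------------------------------------------------------

EXAMPLE_GROUP_SIZES = {"early_cancer": 16, "advanced_cancer": 16, "control": 32}


def load_example_events() -> pd.DataFrame:
    """The bundled per-subject arm-level CNV calls (screen-positive subjects)."""
    with resources.files("plasmacnv.data").joinpath("example_cohort_calls.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


def example_cohort() -> tuple[list[ScreenCall], pd.DataFrame, list[ArmEvent]]:
    """Reconstruct the worked-example cohort: calls, manifest and arm events.

    Subjects listed in the fixture screened positive; the remaining subjects
    of each group (to the published group sizes) screened negative.
    """
    df = load_example_events()
    stage_of_group = {
        "early_cancer": "FIGO I-II",
        "advanced_cancer": "FIGO III-IV",
        "control": "benign",
    }
    positives = df.drop_duplicates("subject")[["subject", "group"]]
    calls: list[ScreenCall] = []
    manifest_rows = []
    for group, total in EXAMPLE_GROUP_SIZES.items():
        pos = positives[positives["group"] == group]["subject"].tolist()
        neg = [f"{group}_neg_{i:02d}" for i in range(total - len(pos))]
        for sid in pos + neg:
            manifest_rows.append(
                {
                    "sample_id": sid,
                    "group": "case" if group != "control" else "control",
                    "stage_label": stage_of_group[group],
                    "tumor_fraction": float("nan"),
                    "counts_path": "",
                }
            )
        # positive subjects: synthesize a qualifying >= 15 Mb placeholder segment
        from .caller import Segment

        for sid in pos:
            seg = Segment(
                chrom="chr1", start=0, end=20_000_000,
                direction="gain", mean_z=5.0, n_bins=20,
            )
            calls.append(
                ScreenCall(sample_id=sid, status="positive", qualifying=[seg], segments=[seg])
            )
        for sid in neg:
            calls.append(ScreenCall(sample_id=sid, status="negative"))
    events = [
        ArmEvent(
            subject=row.subject,
            direction=row.direction,
            arms=tuple(str(row.arms).split(",")),
            label=row.label,
        )
        for row in df.itertuples()
    ]
    manifest = pd.DataFrame(manifest_rows)
    return calls, manifest, events


def example_performance(catalog: CNVCatalog | None = None) -> PerformanceReport:
    """Recompute the worked-example performance numbers from the fixture."""
    calls, manifest, events = example_cohort()
    counts = confusion_table(calls, manifest)
    case_subjects = set(
        manifest[manifest["group"] == "case"]["sample_id"]
    )
    tp_ids = {
        c.sample_id for c in calls if c.status == "positive" and c.sample_id in case_subjects
    }
    return performance_report(
        counts, events=events, catalog=catalog, true_positive_ids=tp_ids
    )
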