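# Methods

`plasmacnv` implements a screening analysis for high-grade serous ovarian
carcinoma (HGSOC) from shallow whole-genome sequencing of plasma cell-free DNA
(cfDNA), at the read depths and read lengths of clinical NIPT platforms
(~18–28 million 36 bp single-end reads, 0.2–0.3× coverage). HGSOC is marked by
chromosomal instability: tumors shed DNA into plasma carrying arm-level gains
and losses, so a diluted copy-number signal is visible in binned read counts
without knowing any patient-specific mutation. The package covers the whole
analysis path — bin counts → normalization and GC correction → per-bin
z-scores against a within-sample reference → segmentation → a prespecified
screen rule → catalog annotation → cohort performance — plus a parallel
NIPT-style whole-chromosome screen and a simulator that generates cohorts with
the statistical structure the analysis assumes.

## Data model

The genome is an hg19-like female fixture (22 autosomes + X, lengths and
approximate centromere positions shipped as an editable TSV). All coordinates
are 0-based half-open; a segment's size in Mb is exactly `(end − start)/1e6`.
Samples are counted on a fixed grid of constant-size bins (default 1 Mb; the
source study states neither bin size nor genome build, so these are package
fixtures, not claims about the study). The short final bin of each chromosome
is kept but flagged unusable when under half the bin size; unusable bins are
excluded from every statistic. Normalized values are fractions of the usable
*autosomal* total; X bins are divided by the same denominator so X is scorable
(the study reports "monosomy X" calls) without letting female-variable X
dosage perturb autosomal statistics.

## GC correction

Per-bin values are divided by a locally weighted regression (lowess, span 0.3,
no robustness iterations, delta-accelerated) of value against GC fraction,
fitted on usable autosomal bins, then renormalized. Two passes are applied —
the second removes the small residual trend that division and renormalization
re-introduce. The operation is idempotent by contract: a profile flagged as
corrected is returned unchanged, so repeated application never drifts values.
(An iterated fixed point was tried and rejected: the divide-by-smoother map is
not a contraction — it stalls near 1e-3 relative change and slowly diverges.)
With fewer than 50 usable autosomal bins the correction is skipped with a
warning.

## Within-sample-reference CNV calling

The caller scores each bin of a test sample against *reference bins of the
same sample*, chosen from a panel of unaffected samples as the bins that
behave most similarly across the panel. Distance between usable bins i and j
is Σ_s (v_si − v_sj)² over panel samples; ref(i) is the k = 100 nearest
eligible bins (never i itself, never X bins, and never bins on i's own
chromosome, so whole-chromosome events are not self-normalized away), ties
broken by grid order. The within-sample ratio r_i = v_i / mean_{j∈ref(i)} v_j
cancels sample-wide biases; the per-bin score is z_i = (r_i − μ_i)/σ_i with
μ_i, σ_i the panel mean and sd (n−1) of the ratio, σ floored at 1e-4·μ.

μ and σ are estimated **leave-one-out**: the ratio of panel sample s uses
reference bins selected from the distances of the other panel samples only.
Selecting references and measuring their spread on the same samples
understates σ — the selection favours bins whose noise happened to align in
the panel — which we measured as a ~30% z-score inflation on held-out samples
at panel size 20; the held-out ratios match what a test sample experiences and
restore calibration (null per-bin z sd ≈ 1.05 at panel 20).

Individual z-scores are combined over a centered sliding window (default
w = 7 bins) by Stouffer's method, Z_i = Σ z / √(window size), truncated at
chromosome ends and never spanning chromosomes. Bins with |Z| ≥ 3.5 are
marked; runs of same-sign marked bins, allowing gaps of at most 2 unmarked
bins, become segments spanning first to last marked bin (no sub-bin
refinement: at the 15 Mb decision scale ±1 bin is immaterial). Direction
follows the sign; the reported mean windowed Z is taken over the marked bins,
which guarantees it matches the direction.

μ_i is close to but not exactly 1: bins in the tails of the bin-baseline
distribution have no equally extreme neighbours, so their reference-ratio mean
deviates (median |μ−1| < 0.05, worst bins ~0.2 under the default simulator).
This is harmless — z subtracts μ — but means μ is not a QC statistic.

## The cancer screen

A subject screens **positive** when at least one called segment spans
≥ 15 Mb (inclusive; the source protocol phrases the threshold both as "≥" and
as ">", and the inclusive headline form is adopted — the threshold is
configurable). Qualifying segments are mapped to every chromosome arm they
overlap by ≥ 25% of the segment's length (a whole-chromosome segment maps to
both arms unless an arm is under 25% of the chromosome, as for the acrocentric
chromosomes). Each (arm, direction) is classified against a recurrent-CNV
catalog: q < 0.25 and frequency > 0.5 → *highly specific*; q < 0.25 and
frequency ≤ 0.5 → *moderately specific*; otherwise *non-specific*. A
segment's class is the best among its arms. Segments below 15 Mb are counted
separately as focal aberrations. The bundled catalog is a constructed,
clearly-labelled synthetic stand-in for the published HGSOC tumor-atlas arm
lists (8 recurrent gains, 5 at > 50% tumor frequency; 22 recurrent losses, 18
at > 50%): the real per-arm q-values and frequencies are cited but not printed
in the source study, so the file carries representative values chosen to
classify the worked-example calls the way the study reports, and is meant to
be replaced by users with their own reference catalog.

Under the null, isolated windowed exceedances produce on the order of 1–2
focal (< 15 Mb) false calls per sample at the default threshold — this is why
only ≥ 15 Mb segments, which noise essentially never produces (measured 0/20
null samples), are screen-positive. Focal counts should be read comparatively
(cases vs controls), not as a calibrated null statistic.

## NIPT-style aneuploidy screen

The routine prenatal pipeline is emulated at the method-class level with the
normalized chromosome value: fraction_c = Σ values on chromosome c, and
z_c = (fraction_c − panel mean)/panel sd against a reference panel (default
100 simulated unaffected samples; minimum 10). Targets are chromosomes 13, 18,
21 and X (no Y: the study population is female). Calls: high-risk gain at
z ≥ +4, high-risk loss at z ≤ −4 ("monosomy 18", "monosomy X" labels for
losses), low-risk otherwise. A sample is **no-call** when any non-target
autosome — the pipeline's normalizing material — has |z| > 3. The clinical
statistic and no-call criteria are proprietary and unstated; this module is an
explicit approximation and says so in its reports.

A structural consequence of the no-call rule: with 19 normalizing autosomes,
even a perfectly calibrated screen has a no-call floor of
1 − (1 − 0.0027)^19 ≈ 5% on copy-neutral samples, and finite-panel t-tails
push it higher (we measure ~4–11% depending on seed at panel 100). Cancer-like
profiles with many arm events disturb the normalizers and go no-call almost
always — reproducing the study's observation that the whole-chromosome
pipeline fails on segmentally unstable genomes rather than detecting them.

## Evaluation

Screen calls are crossed with case/control labels into a confusion table with
per-stage sub-counts. Sensitivity and specificity are reported in percent with
two-sided exact Clopper–Pearson 95% intervals (beta-quantile form; validated
against a binomial-tail bisection oracle to 1e-6). The exact method is used
because it reproduces all four published interval bounds of the worked
example. Display rounding is decimal half-up to 1 decimal; full precision is
kept internally. Per-arm tallies count each subject at most once per
(arm, direction) — required to match the published per-arm n values — and the
count of true positives carrying ≥ 1 highly specific CNV is derived by
applying the classification rule, not read from a column.

The worked-example cohort (64 subjects: 16 early / 16 advanced HGSOC cases,
32 benign controls; per-subject arm-level call lists for the 15
screen-positive subjects) is bundled as a plain-text fixture and reproduces:
sensitivity 40.6% (95% CI 23.7–59.4), specificity 93.8% (79.2–99.2), 6/16 and
7/16 per-stage detection, gains 3q = 5, 8q = 7, 20q = 4, 12p = 3, losses
5q = 3, 8p = 3, 13q = 4, 15q = 3, and 12 of 13 true positives with ≥ 1 highly
specific CNV.

## Simulator

The simulator defines the study-scale conditions used by every calibration and
recovery check:

| parameter | default | meaning |
|---|---|---|
| reads per sample | Uniform(18e6, 28e6) | platform read-count range |
| bin baseline m_i | exp(N(0, 0.1²)), fixed per grid | mappability-like bin structure |
| GC slope | N(0, 0.5²) per sample, factor 1 + slope·(gc − 0.41), floor 0.1 | sample-specific GC bias |
| dispersion r | 1000 | negative-binomial overdispersion (var = m + m²/r) |
| tumor dilution | weight × (1 + tf·(copy − 2)/2) | linear euploid/tumor mixture |
| focal events | Poisson(rate), length Uniform(1, 10) Mb | sub-threshold aberrations |

Counts are negative binomial via a per-bin gamma multiplier times a Poisson
count; the Poisson quantile is taken by a normal approximation at one uniform
draw per bin (< 1 count error at the ~7000-count bin means used here). Each
sample consumes a fixed number of RNG draws regardless of target depth, so
runs at different depths from the same seed stream are comonotone — this is
what makes "same truth, same stream, different depth" comparisons meaningful.
Identical seed and configuration give byte-identical output files.

Case truth profiles draw each catalog arm independently with probability equal
to its tumor frequency (gain → copy 3, loss → copy 1 over the full arm) plus
Poisson-many focal events placed without overlap (earlier-drawn events win).
A bin crossing an event boundary takes the copy number covering the strict
majority of the bin. Default cohort design mirrors the study: 16 + 16 cases
and 32 controls, with a 20-sample reference panel. The real tumor fractions of
the study are unknown; the default per-group log-uniform ranges
(early 0.02–0.25, advanced 0.04–0.40) are exercise parameters chosen to
straddle the caller's detection threshold (≈ tf 0.1 for an arm-scale event at
these depths), not estimates.

What the simulator does **not** model: fragment-length distributions and
size selection, mappability and sequencing error, subclonal mixtures, and
real inter-sample covariance structure beyond a linear GC bias. Passing
calibration and recovery checks therefore demonstrate the statistical
machinery under the stated noise model, not clinical performance on real
plasma.

## Problem sizes and numerical choices

Calibration and recovery checks run at full scale (~3,050 bins at 1 Mb,
20-sample caller panel, 100-sample aneuploidy panel) with 20–100 replicates
per property — sizes chosen so the whole suite completes in a few minutes on
one CPU while keeping Monte-Carlo error well inside the asserted margins.
Reference-bin selection uses exact top-k with deterministic tie-breaking by
grid order; σ is floored at 1e-4·μ to avoid infinite z on degenerate panels;
lowess uses delta-acceleration (1% of the GC range); all rounding for display
is decimal half-up.

## Known limitations

* The caller reproduces a method class, not any specific released tool or its
  exact calls; parameters (k, window, threshold, merge gap, bin size) are
  defaults exposed in the API and CLI.
* Segment boundaries are marked-bin spans; no sub-bin breakpoint refinement,
  no CBS-style segmentation, and no copy-number quantification beyond
  direction.
* The aneuploidy no-call rule is an approximation of a proprietary criterion,
  with the ~5% structural no-call floor derived above.
* The bundled catalog is synthetic (see above); analyses of real data should
  substitute a catalog derived from tumor-atlas results.
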