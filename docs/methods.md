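# Methods

This note records the models, conventions and numerical choices behind
`gamclock`, in the spirit of a statistical-software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## The residual-based clock

**Model.** Expression of each clock gene is assumed linear in chronological
age (CA) on the scale it is measured on — the linear `2^−ΔCt` scale for
qPCR, normalized units for transcriptomic matrices. The per-subject aging
rate is the mean of residual-to-slope ratios, `Δ_i = (1/N) Σ_G σ_{G,i}/a_G`,
and `GamC_i = CA_i + Δ_i`. Interpretation: `σ_{G,i}/a_G` converts an
expression deviation into the number of years along gene G's age trend that
would produce it.

**Exact algebra.** OLS residuals satisfy `Σ_i σ_{G,i} = 0` and
`Σ_i σ_{G,i}·CA_i = 0`; therefore `mean(Δ) = 0`, `cov(Δ, CA) = 0`, and the
regression of GamC on CA has slope 1 and intercept 0, all to machine
precision in-sample. These are structural identities, not empirical
findings; they are what makes AR a pure per-individual deviation. They do
not hold out-of-sample (`apply_clock` scores new subjects against stored
regression lines, where a non-zero mean AR is a real cohort difference).

**ΔCt convention.** The reference baseline is the arithmetic mean of the
reference-gene Ct values — equivalently the geometric mean of their
linear-scale expression — which is the standard ΔCt practice when two
reference genes are used. Reference gene names are configuration
(`DEFAULT_REFERENCE_GENES`); the defaults are the pair used in the
qPCR protocol this pipeline targets.

**pNN50 denominator.** pNN50 (defined in the HRV panel but the same issue
arises for any "percentage of successive differences" statistic) divides
the count of successive NN differences exceeding 50 ms by the number of
successive differences (n−1), so a strictly alternating ±100 ms series
reads 100%. Some texts divide by the number of intervals (n); the two
differ by a factor (n−1)/n.

**Numerical guards.** A gene is rejected when
`|a_G| < 1e−3 · SD(expr)/SD(CA)` (configurable): `σ/a` diverges for
near-flat genes, and a gene that flat carries no age information anyway.
Zero-variance genes are excluded from screening with NaN statistics rather
than raising. Subjects missing some clock genes receive AR from the
remaining genes with N reduced (tracked per subject in `n_genes_used`).

**Gene screening.** Pearson on the linear expression scale against CA,
two-sided P, selection at P ≤ α (default 0.05). The screen is calibrated:
on an age-independent gene at n = 50 it excludes in ≈95% of replicates
(measured by the acceptance script as `null_gene_exclusion_rate`).

## Synthetic cohorts

`simulate_cohort` draws CA uniform on the age range, per-subject offsets
`δ_i ~ Normal(0, offset_sd)`, then mean-centers them and removes their
sample regression on CA (restoring the requested SD). The decorrelation is
deliberate: the clock's OLS step projects out anything collinear with CA,
so only the CA-orthogonal part of an injected offset is recoverable. With
centered, decorrelated offsets the identity `Δ̂_i = δ_i` is exact at zero
noise, which makes parameter-recovery tests sharp (RMSE < 0.5 years at
n = 200 is the tested contract). Defaults — 60 subjects, ages 20–100,
three genes with slopes around −0.01 expression units/year and noise SD
0.05–0.06, offset SD 8 years — emulate a single-site qPCR study of a few
dozen adults spanning the adult lifespan with a clock of three genes whose
expression declines mildly with age.

What the generator does **not** emulate: heteroscedastic qPCR noise,
batch/plate effects, non-linear age trends, correlated genes. Passing
recovery tests therefore show the estimator is correct under its own model,
not that real cohorts are this clean.

## RR-interval generation and the HRV panel

**IPFM generator.** Beats occur when `∫ (1+m(t))/T dt` crosses successive
integers, with `m(t)` a sum of one LF and one HF sinusoid (fractional
amplitudes < 0.5, frequencies constrained to the standard 0.04–0.15 and
0.15–0.4 Hz bands) and `T` the mean interval. The integral is accumulated
by trapezoid on a 1 ms grid and each crossing located by linear
interpolation (accurate to < 1 ms). A beat is placed at t = 0. Ectopic
beats are emulated by advancing a randomly chosen beat by 40% of its local
interval (configurable) and flagging it.

**Ectopic handling (analysis side).** An interval is flagged when it
deviates by more than 30% (configurable) from the median of its five
surrounding intervals; correction moves the offending beat to the midpoint
of its neighbours, i.e. replaces the flagged interval pair by linear
interpolation of beat times. This is a documented, testable stand-in for
operator-verified beat correction; it is not a published algorithm's
reimplementation.

**Windowing.** Default analysis trims 0.5 min from each end (a 5-min
recording yields 4 min). For longer, less stationary recordings the
minimum-SD rule selects the 4-min window with the lowest interval SD among
candidate starts every 30 s, ties to the earliest; this equals exhaustive
search by construction (tested).

**Time domain.** Population SDs (divide by n) throughout. Under this one
convention `SD1 = SDSD/√2` is an exact identity (asserted to 1e−9), and
`SD1² + SD2²` equals the summed variances of the lagged pair. pNN50 uses
a strict `> 50 ms` inequality.

**Frequency domain.** The instantaneous heart rate dHR is a cubic spline
through `60000/NN` placed at beat midpoints, sampled at 4 Hz over the full
window. The sub-0.03 Hz trend dMHR comes from a zero-phase (forward–
backward) 4th-order Butterworth low-pass — zero-phase so the trend removal
does not lag-distort `m = (dHR − dMHR)/dMHR`. Welch PSD: Hamming windows of
60 s, 50% overlap, per-segment mean detrend, one-sided; band powers by
trapezoid integration with interpolated band edges; `P_LFn` divides by the
0.04–0.4 Hz total (configurable to the full integrated power — sources
differ on whether VLF remnants belong in the denominator). A sinusoid of
amplitude A carries `A²/2` of power into its band (Parseval), the tested
calibration. Known limitation: deriving dHR from discrete beats attenuates
high frequencies (interval-averaging sinc response, ≈0.90 at 0.25 Hz for
1 s beats), so absolute HF powers from the spline route read a few percent
low; the exact counting-process derivative would remove this but is not
implemented.

**DFA.** Profile = cumulative sum of the centered series; non-overlapping
boxes taken from both ends; first-order polynomial detrend per box; F(s)
over ~16 log-spaced box sizes; α1 from 4–16 beats, α2 from 16–64
(configurable). Plain first-order DFA is biased upward over small boxes
(white noise reads ≈0.6 over 4–16). The default applies a modified-DFA
correction: F(s) is divided by the *exact* white-noise expectation
`sqrt(tr(Lᵀ(I−H)L)/s)` (L the in-box cumulative-sum operator, H the linear
detrend hat matrix) and rescaled to the `sqrt(s/15)` asymptote. White noise
then scales at 0.5 across both ranges; the correction is asymptotically
neutral for large boxes. It can be disabled (`bias_correction=False`) to
match plain DFA implementations.

**Degenerate inputs.** Constant series: all variability indices 0, DFA and
the Poincaré ratio undefined (NaN). Spectral indices require ≥ 60 s of
signal (one Welch segment, and the low-pass transient).

## Actigraphy

Epoch values are milli-g at 5 s epochs by default. A day is valid at
≥ 16 worn hours; a record at ≥ 2 valid days; non-worn epochs are excluded
everywhere and valid days weighted equally. When wear flags are absent, a
fallback heuristic marks 60-min rolling windows with value SD < 1 mg as
non-worn — an approximation of raw-signal non-wear detection, documented as
such; explicit flags are preferred.

MX metrics aggregate to 1-min means first (M_X = the X-th highest minute of
a day, averaged over valid days), matching the metrics' minute framing; AA,
IG and cut-point times use native epochs. Cut-point boundaries: IT < 30 mg,
LPA 30–100 (100 mg inclusive — "30–100" vs "> 100" dictates the boundary),
MPA (100, 400], VPA > 400, MVPA > 100; consequently IT+LPA+MPA+VPA equals
mean daily worn minutes and MVPA = MPA+VPA exactly. The intensity gradient
regresses ln(minutes per 25 mg bin) on ln(bin midpoint) over occupied bins
(≥ 3 required; empty bins dropped, not zero-filled). The log–log form is
used; a literal "ln(time) vs intensity" variant is not offered because the
underlying methodology is log–log.

The actigraphy generator draws i.i.d. epochs from a named law (constant,
gamma, lognormal, or deterministic "active blocks" with explicit MX ground
truth); the non-worn remainder of a day is one contiguous block at the day
start, emulating device-off overnight. It does not model diurnal
autocorrelation, so IG/MX values on simulated gamma days are calibration
checks, not realistic human profiles.

## Statistics

Spearman is computed on average ranks (identical to Pearson on ranks,
tested to 1e−12). A correlation family = all pairs of one invocation;
Benjamini–Hochberg across that family (equals the brute-force step-up
definition, tested); significance at FDR ≤ 0.05. Mann–Whitney uses the
exact distribution for tie-free groups up to 20 per side, otherwise the
tie-corrected normal approximation.

Paired analysis: `ΔP_i = post_i − pre_i` (positive = increased after
intervention), median and IQR reported. Wilcoxon signed-rank drops zero
differences before ranking (Wilcoxon's original treatment; the
zero-splitting variant is not implemented), and `n` in `|r| = |Z|/√n` is
the number of pairs actually ranked. Z is always computed from the tie- and
continuity-corrected normal standardization — even when the P-value comes
from the exact distribution — so the effect size is defined at any n.
Magnitude bands take the conventional anchors as lower bounds: ≥ 0.5 large,
≥ 0.3 medium, ≥ 0.1 small, else negligible. When every pair is unchanged, Z
is undefined and the effect is reported as |r| = 0. Type-I error of the
whole paired pipeline at nominal 0.05 is measured by the acceptance script
(1000 null replicates at n = 20).

## Transcriptomic bridge

Quantile normalization maps within-sample ranks to across-sample mean order
statistics; tied values receive the mean of their mapped values. The
transform is idempotent (exactly so for tie-free input; with ties the
averaging makes sorted columns agree only approximately — an inherent
property of mean-of-ties handling, not an implementation choice).
"Standardization" after normalization is optional per-gene z-scoring, off
by default. Quartile splits take the lowest and highest ⌊n/4⌋ subjects by
a stable sort (ties keep input order); n = 87 yields 21 per extreme
quartile. logFC is the difference of group means on the log2 scale,
Q4 − Q1; it is antisymmetric under group swap. Moderated (empirical-Bayes)
statistics and gene-set enrichment are deliberately out of scope; logFC is
the ranking statistic this module provides.

## Problem sizes

Tests and the acceptance script run on deliberately small problems —
cohorts of 50–200 subjects, 5-min RR series, 1–7 day actigraphy records,
500–1000 Monte-Carlo replicates — sized so the full suite completes in
seconds while keeping Monte-Carlo standard errors well below the asserted
margins.
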