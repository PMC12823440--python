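# Methods

## Overview

`kindeg` implements the analysis of a temporal luminescence drug screen:
a panel of kinase–Nluc reporter cell lines (88 canonical kinases, 10
mutants, plus GFP and destabilized-GFP controls) is assayed against a
kinase-inhibitor library, with luminescence read at 2, 6, 10, 14 and
18 h in two technical replicates on 1,536-well plates.  The pipeline has
a fixed stage order: normalize → prescreen → quality filters → centering
→ null models → scheme scores → hit calling → half-life fits → atlas
statistics.  All thresholds live on `PipelineConfig` with the assay's
defaults and can be overridden from YAML.

## Kinetic model of the synthetic generator

Each reporter decays with first-order kinetics, rate `k = ln2 / t½`.  On
the POC scale (100 = untreated steady state):

* inert compounds leave the reporter at 100 — synthesis and degradation
  stay balanced;
* translation or transcription shutoff (CHX, NVP-2) stops synthesis, so
  the signal decays as `100·e^(−kt)`;
* a degrader or stabilizer multiplies the degradation rate by `f`,
  giving `100·(1/f + (1 − 1/f)·e^(−fkt))`, which relaxes to the new
  steady state `100/f` (f > 1: degradation; f < 1: stabilization);
* toxic compounds decay all reporters identically at a configurable
  `k_tox` (default 0.1 h⁻¹), giving the prescreen something to remove;
* CHIR-99021 wells sit at the 0% anchor.

Effect onset is a pure time shift (the effect applies for `t ≥ onset`);
delayed degraders need no extra kinetics.  Concentrations are metadata
only — control-line plates carry each compound at both concentrations so
the prescreen's two-concentration fallback is exercised, but no
dose–response model is simulated.

Noise is multiplicative log-normal per well (default σ = 0.05) times a
smooth per-plate separable row/column gradient (each axis a linear ramp
with amplitude drawn uniformly in ±8%).  Baselines vary log-normally
across lines around 10⁶ counts.

Parameters that define the panel: kinase half-lives are log-normal
(median 4 h, log-sd 0.7) clipped to [1.1, 24] h — the panel is bracketed
by the dGFP short-lived control (1.1 h) and the GFP long-lived control
(30 h), mirroring the reporter design in which dGFP is the short-lived
extreme; no kinase reporter is shorter-lived than that control.
Activating mutants get half their parent's half-life (an
activity–stability trade-off).  HSP90 client status is assigned
categorically (20% strong / 25% weak / 35% non / 20% not defined), and
planted degraders target client kinases with probability 0.7 so the
client-enrichment statistics have signal to find.  PROTAC true positives
(10 by default) are strong degraders (f = 12) on dedicated targets.

What the generator does **not** emulate: dose–response shapes,
luciferase quenching, cytotoxicity beyond the shared-decay toxic class,
plate-edge evaporation beyond a linear gradient, mechanistic chaperone
biology, or correlated biological replicates.  Passing tests therefore
demonstrate correctness of the analysis on data obeying the stated
kinetic and noise model, not performance on any particular real screen.

## Normalization

Intraplate correction is a two-pass row/column median polish on the log
signal, estimated from non-control wells only and divided out in linear
space (zero-signal wells stay zero); the plate median is preserved.
Rows or columns with fewer than 6 usable wells contribute no effect — a
median over a couple of wells would absorb genuine compound signal
rather than a plate trend.  Plates with fewer than 16 non-control wells
are left uncorrected with a warning.

Anchor summaries trim wells deviating from the anchor median by more
than 3 × scaled MAD (1.4826·MAD) and average the survivors.  With two
wells the rule keeps both (the MAD cannot single out one of two).  A
plate/timepoint is invalid when an anchor retains fewer than two wells
or the DMSO mean does not exceed the CHIR mean.  POC is the affine
rescaling `100·(s − chir)/(dmso − chir)`, unclipped; when the CHIR
anchor is zero this degrades gracefully to `100·s/dmso`.

The prescreen evaluates replicate-mean control-line trajectories per
(compound, concentration).  The relative-change criterion is
`|POC(t)/POC(2 h) − 1| > 0.58` in either direction; a missing 2-h value
fails the criterion for that concentration.  Control compounds are
exempt — they are the assay's reference wells, not library members.

## Scoring

**Centering.**  The two-pass additive centering shifts each cell line's
series by `100 − median over library compounds of its 2-h values`, then
each library compound's series by `100 − median over lines of its
shifted 2-h values`.  Control compounds receive only the per-line shift:
a per-compound shift would subtract the genuine decay of the CHX/NVP-2
references and corrupt both the control-based null models and the
half-life fits.  Pairs without a 2-h value anchor at their earliest
available timepoint and are flagged.

**Null models.**  Control bases (DMSO, CHX, NVP-2) summarize well-level
centered values per (line, timepoint): location = mean, scale = s.d.
(ddof 1).  The 2-h-relative variant models per-well deltas
`value(t) − value(2 h)`.  Timepoints with fewer than 3 reference wells
fall back to the scale pooled across that line's timepoints; zero scales
are floored at 10⁻⁶.  The compound-population basis is evaluated
leave-one-out from per-(line, timepoint) running sums, so a strong hit
never masks itself.  At the anchor timepoint all deltas are exactly
zero, so 2-h-relative schemes can only score the four later timepoints.

**Scores and queries.**  "2σ" is inclusive (z ≤ −2 / z ≥ +2).  A pair
with any missing timepoint gets +1 on every scheme, applied once and
capped at 5, before TOT is summed — TOT is the sum of all eight scheme
scores for degradation and of the six non-CHX schemes for stabilization.
Degradation and stabilization are scored in independent passes over the
same centered tensor.  Hit exclusions carry provenance flags
(variance-filtered, reactive, curated, promiscuous > 10 kinase lines
strictly, control-line scorer).  The control-line-scorer exclusion is on
by default only for stabilization (matching the screen design); a config
switch enables it for degradation.  The threshold scan is an exhaustive
grid evaluation; its FDR proxy is (hits outside the true-positive
reference)/(total hits), the winner must recover every reference pair,
and ties break on fewest total hits then lexicographically smaller
thresholds (i.e. the most permissive of the tied queries).

## Half-life fitting

`100·e^(−τt)` with amplitude fixed at 100 (centered POC has no free
intercept), τ ≥ 0 by bound, ordinary least squares via
`scipy.optimize.curve_fit`.  The initial guess is the log-linear
regression slope of values clipped to (0, 100].  Half-lives are censored
at 100 h — an 18-h assay window cannot resolve slower turnover — and a
constant-100 trajectory reports τ = 0, censored.  Fits use the centered
trajectories, consistent with the scoring tensor; in the generator's
noiseless regime the two coincide and recovery is exact to machine
precision.

## Atlas statistics

"Downregulated" kinase = scores at least once in the binary degradation
map.  Enrichment tables use the sample (cross-product) odds ratio, with
an infinity sentinel for separated tables; the conditional MLE is logged
alongside.  P-values are two-sided Fisher's exact tests
(`scipy.stats.fisher_exact`); the test suite checks them against a full
hypergeometric enumeration for all tables with margins ≤ 25.  Spearman's
ρ uses average ranks; its p-value is the t approximation for n > 10 and
an exact permutation enumeration for n ≤ 10.  Jaccard distance of two
empty hit sets is defined as 0.  Hit frequency for the half-life
correlation counts distinct hit compounds per kinase line, controls and
excluded compounds removed.

## Problem sizes and numerical choices

The shipped analyses and acceptance checks run the full study geometry —
100 lines × 1,600 compounds × 5 timepoints × 2 replicates (~1.7 M
measurements, ~160 k scored pairs) — which completes in well under a
minute per screen on a single core; unit tests use 8–12-line panels.
Determinism: every stochastic step takes an explicit seed, outputs name
the config hash that produced them, and identical (config, seed) inputs
reproduce outputs bit-for-bit.

## Known limitations

* The stabilization query (`DMSO_norm ≥ 5 ∨ CPD_norm ≥ 5`) requires all
  five timepoints, including 2 h, to deviate; slow stabilizers on
  long-lived reporters are genuinely missed (≈7% of planted stabilizers
  at default settings), a property of the published query rather than of
  the implementation.
* Scheme scores against control bases degrade to fewer schemes (with a
  warning) when a control has no wells on a line; TOT then covers the
  available schemes.
* The FDR threshold scan needs a non-empty true-positive reference and
  reports a best-recall frontier with a warning when no grid point
  recovers all of it.
* Reproduction of a real screen's printed tallies requires that screen's
  processed data tables and its curated inclusion/exclusion lists as
  inputs; the pipeline accepts them as TSVs but does not ship them.
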