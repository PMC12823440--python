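# kindeg

Analysis pipeline for temporal kinase-degradation reporter screens — the
kind of experiment in which a panel of kinase–nanoluciferase fusion cell
lines is dosed with a kinase-inhibitor library and luminescence (a proxy
for kinase abundance) is read repeatedly over an 18-hour window.  The
package turns raw plate luminescence trajectories into a binary
degradation/stabilization hit map, fitted reporter half-lives, and the
downstream selectivity and enrichment statistics, and ships a synthetic
screen generator with planted ground truth so every stage can be
verified at desk scale.

Intended users: screening groups and computational chemists analysing
targeted-protein-degradation or inhibitor-induced destabilization
screens, and anyone who wants a fully testable reference implementation
of control-referenced kinetic hit calling.

## The method

**Normalization.** Raw signals are corrected for intraplate row/column
trends (median polish on the log signal, estimated from non-control
wells) and rescaled per plate and timepoint to percent over control:

    POC = 100 · (signal − CHIR) / (DMSO − CHIR)

where DMSO (100%) and CHIR-99021 (0%) anchors are means of
outlier-trimmed control wells (median ± 3 × scaled MAD).  A prescreen on
the GFP/dGFP control lines removes assay-interfering compounds: a
concentration fails if any POC < 48 or > 150, or if it drifts more than
58% from its 2-h value; the higher concentration is preferred, with
fallback to the lower one.

**Hit scoring.** Pairs with replicate s.d. > 30 POC at *all five*
timepoints are excluded, as are compounds with a median 2-h POC across
kinases < 70.  Series are centered around 100 POC at 2 h (first across
kinases, then across compounds).  Eight null models — the DMSO, CHX
(translation shutoff) and NVP-2 (transcription shutoff) control time
series and the leave-one-out compound population, each also in a
2-h-relative variant — yield per-timepoint z-scores; a scheme score is
the count of timepoints at least 2σ below (degradation) or above
(stabilization) the null, +1 for a missing timepoint, capped at 5.  The
degradation hit query is

    (DMSO_norm ≥ 5) ∨ (CHX_norm ≥ 2) ∨ (CPD_norm ≥ 5) ∨ (CHX_norm_2h ≥ 5) ∨ (TOT ≥ 10)

and stabilization uses `DMSO_norm ≥ 5 ∨ CPD_norm ≥ 5` (the CHX schemes
are excluded).  Compounds hitting more than 10 kinase lines, or scoring
on the GFP control line (stabilization), are excluded.  An exhaustive
threshold scan can re-derive the query by minimizing the false-discovery
proxy against PROTAC true positives.

**Half-lives and atlas.** Reporter half-lives come from nonlinear least
squares of `POC(t) = 100·e^(−τt)` on each line's CHX trajectory
(t½ = ln 2/τ, censored at 100 h).  Downstream statistics: selective
pairs (compound hits exactly one kinase), Jaccard distances between
kinase hit profiles, HSP90-client and binding-mode enrichment
(two-sided Fisher's exact tests, sample odds ratios), and the Spearman
correlation between half-life and scoring frequency.

## Worked example

The numbered scripts under `analysis/` run the whole study on a
synthetic screen (100 reporter lines × 1,600 compounds, 5 timepoints, 2
replicates, 200 planted degraders, 150 stabilizers, 10 PROTAC true
positives, 10 toxic compounds; large intermediates go to `scratch/`,
small tables to `results/`):

```sh
python analysis/01_simulate_screen.py
python analysis/02_normalize_prescreen.py
python analysis/03_score_and_call_hits.py
python analysis/04_fit_half_lives.py
python analysis/05_atlas_statistics.py
```

Output from one run (seed 20260920):

```
prescreen: 10 of 1596 compounds eliminated            # exactly the planted toxic class
degradation_hits            210                       # 200 degraders + 10 PROTACs
degradation_sensitivity     1.0
degradation_fdr             0.0
stabilization_hits          139                       # of 150 planted (slow stabilizers on
                                                      # long-lived reporters stay below 2σ at 2 h)
fitted 100 reporters; median |rel err| 1.20%, max 5.77%
  dGFP: fitted 1.08 h (true 1.10 h)
HSP90 strong-vs-non clients: OR 15.00, p 3.12e-03     # degraders were planted client-biased
binding mode type_I: OR 0.92, p 0.623                 # modes independent of effects: null
half-life vs scoring frequency: Spearman rho -0.010
mutant/WT pairs: median JD 1.00, 8 of 10 with JD >= 0.8
```

The same stages are available as a CLI (`kindeg simulate | normalize |
score | hits | halflife | stats | run`) and as library calls
(`kindeg.run_pipeline(raw, PipelineConfig())`).

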