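# mesfmon

Standardized flow-cytometry immune monitoring for kidney-transplant
recipients: bead-calibrated conversion of neutrophil CD64 (nCD64) and
monocyte HLA-DR (mHLA-DR) fluorescence to an absolute scale, and the
downstream statistics used to diagnose infection and sepsis.

## The problem

nCD64 rises sharply with pro-inflammatory activation; mHLA-DR falls with
immunosuppression. Both are usually read out as mean fluorescence
intensities (MFIs), which depend on PMT voltages, filters and antibody
lots — so values cannot be compared across instruments or labs. Running
calibration beads carrying known numbers of PE molecules per bead under
the *same* instrument setting gives a per-protocol regression

    log10(MFI) = a + b · log10(MESF)

whose inversion maps any sample MFI onto the absolute MESF scale
(molecules of equivalent soluble fluorochrome). With four bead levels the
line is tightly determined; measuring the same samples under four
instrument protocols then lets the intraclass correlation ICC(2,1) and
Bland–Altman agreement quantify how completely the calibration removes
the instrument effect.

On the MESF scale the package computes the composite indices

    CD64 index = (nCD64 / lymCD64) / (mCD64 / nCD64)
    SI         = 100 · nCD64 / mHLA-DR

and the clinical statistics layer: one-way ANOVA with Fisher's LSD
post-hoc directly from (n, mean, SD) group summaries, pooled/Welch
t-tests, Pearson χ² and Fisher's exact test, ROC with Youden-optimal
cutoffs, and univariate/multivariate logistic regression with Wald
intervals.

Because no patient-level data are public, a seeded synthetic generator
(`mesfmon.synthetic`) reproduces the study's structure — 26 healthy
controls, 65 stable and 50 infected recipients (19 septic; 26 bacterial /
13 viral / 11 fungal; 21 retested about a week later) — with
moment-matched lognormal marker distributions, a four-protocol instrument
model, four-level bead lots and gateable event-level cell clouds.

## Worked example

```bash
python analysis/02_standardization_reliability.py 1
```

prints (seed 1):

```
cross-protocol reliability (ICC, two-way random absolute agreement):
  nCD64    calibrated MESF ICC = 1.000   raw MFI ICC = 0.338
  mHLA-DR  calibrated MESF ICC = 0.999   raw MFI ICC = 0.114
```

i.e. after bead calibration the four protocols agree almost perfectly on
the absolute marker value, while the raw MFIs — which still carry each
protocol's gain and offset — agree poorly. The fitted curve parameters
printed above it recover the generating instrument gain/offset to three
decimals. `analysis/03_published_table_stats.py` recomputes the published
group-comparison p-values from the typed-in table summaries (e.g. nCD64
across pathogen subgroups p = 0.030, ΔSI exacerbation vs non-exacerbation
p = 0.003, sex χ² p = 0.036), and `analysis/04_infection_diagnostics.py`
reports the ROC of the nCD64 consensus MESF for infection (AUC ≈ 0.98 on
the synthetic cohort) with its Youden cutoff and the logistic risk
factors.

The numbered scripts under `analysis/` are thin drivers over the library
in `src/mesfmon`; all computation lives in the package modules
(`synthetic`, `gating`, `calibration`, `harmonization`, `indices`,
`stats`, `pipeline`) and everything is importable and tested.

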