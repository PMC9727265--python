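# Methods

## Measurement model

A true receptor quantity `x` (MESF units, PE-molecule equivalents) observed
under instrument protocol `p` yields

    MFI_p(x) = 10^(a_p + b_p · log10 x) · ε,   ε ~ lognormal, E[ε] = 1

with protocol gain `b_p > 0`, offset `a_p` (log10 fluorescence) and
multiplicative noise of coefficient of variation `cv`. This is the standard
log-domain linearity assumption for PMT-based cytometers, and it is exactly
the model the bead calibration inverts: ordinary least squares of
log10(bead peak MFI) on log10(known bead MESF) estimates `(a_p, b_p)`, and

    MESF(m) = 10^((log10 m − a_p) / b_p)

maps a sample MFI back to the absolute scale. The regression is fitted with
MFI as the response — the direction the bead-kit protocol defines — so
conversion inverts the fitted line rather than refitting the reverse
regression; the inverse exists because `b_p > 0` is enforced. A conversion
is scale-equivariant: multiplying all bead MFIs and the sample MFI by a
constant leaves the recovered MESF unchanged (the offset absorbs the gain),
which is what makes the MESF scale instrument-independent. R² below 0.98
raises a calibration-quality warning; the threshold is a package choice, as
four nearly collinear log-spaced levels should fit far better than that in
any healthy run.

## Harmonization

Four protocols measuring the same samples give a subjects × protocols MESF
matrix per marker. Reliability is ICC(2,1) — two-way random effects,
absolute agreement, single measurement — computed from the two-way ANOVA
mean squares:

    ICC(2,1) = (MS_R − MS_E) / (MS_R + (k−1) MS_E + k (MS_C − MS_E)/n).

Absolute agreement is the right form here because MESF standardization
claims the protocols agree on the *value*, not merely on the ranking. The
implementation is cross-checked in the tests against an independent
statistics package's ICC(A,1). Note the point estimate can fall below −1
on tiny, strongly discordant matrices; it is a variance-component ratio,
not a correlation.

Bland–Altman agreement compares each protocol against the per-subject mean
over all protocols: differences `d_i = x_ip − mean_i`, bias = mean(d),
limits of agreement = bias ± 1.96 SD(d). Outliers are subjects with
|d_i − bias| > 3 SD(d), per protocol comparison (the per-comparison SD, not
a pooled one — recorded in the report metadata). Exclusion runs once, and
the consensus MESF is the arithmetic mean of the remaining protocol values;
if every protocol is flagged for a subject the unfiltered mean is used with
a warning, so a consensus is always emitted. A subject with one grossly
corrupted cell typically appears outlying in *every* comparison (the
corrupted cell drags the per-subject mean), which the fallback handles.

## Composite indices and clinical rules

* CD64 index = (nCD64/lymCD64)/(mCD64/nCD64) = nCD64²/(lymCD64·mCD64);
  dimensionless and invariant under common rescaling of all three inputs.
* Sepsis Index SI = 100·nCD64/mHLA-DR; degree-zero homogeneous as well.
  Note mean-of-ratios ≠ ratio-of-means: the SI of group means is not the
  group mean SI.
* Longitudinal change Δx = x(test 2) − x(test 1); exacerbation ⇔ ΔSOFA > 0.
* Renal SOFA adjustment: stable transplant recipients carry chronically
  elevated creatinine, so the renal SOFA contribution is retained only when
  creatinine ≥ 171 μmol/L (the SOFA-renal ≥ 2 boundary) or creatinine has
  "obviously increased" during infection. The latter is not a defined
  quantity; it is implemented as a configurable relative ratio over
  baseline, default 1.5×.
* Diagnostic dichotomization uses strict `>` at the Youden-derived cutoffs
  (defaults 3089 MESF for nCD64, 2433 for mHLA-DR), configurable.

## Statistics layer

Group comparisons in this field are published as (n, mean ± SD) cells, so
ANOVA, LSD and t-tests are implemented directly from summary triples using
the exact algebraic identities (SSB = Σ nᵢ(mᵢ − grand)², SSW = Σ (nᵢ−1)sᵢ²);
they reproduce raw-data results exactly, as a test verifies against a
raw-data ANOVA. Fisher's LSD pools the within mean square over *all*
supplied groups with df = N − k and no multiplicity adjustment — for the
sepsis comparisons the pooling set is stable + sepsis + non-sepsis, which
is what reproduces the published cells; the pooling set is an explicit
argument. The pooled (Student) t is the default for two-group comparisons
because it reproduces the published longitudinal cells; Welch is
selectable. Pearson χ² is computed without Yates continuity correction
(again the variant that matches the published sex-distribution cell);
Fisher's exact test is the hypergeometric two-sided enumeration for 2×2.

ROC AUC uses the rank (Mann–Whitney) formulation with midrank tie
correction; the Youden cutoff maximizes sensitivity + specificity − 1 over
observed thresholds, ties broken toward the lower threshold; the AUC
p-value is the normal approximation to the Mann–Whitney statistic (with tie
term), as the published analyses do not state their method. Logistic
regression is a maximum-likelihood fit (Newton/IRLS via statsmodels) with
Wald z inference and 95% CI = exp(β ± 1.96 SE); the multivariable model
enters covariates with univariate p < 0.05 (configurable), matching the
two-column univariate/multivariate table layout. Separation or
non-convergence is flagged on the result, never raised, with a quasi-Newton
fallback so estimates are still reported.

## Synthetic-data generator

The generator's defaults *are* the study conditions: group sizes
26/65/(19+31), pathogen split 26/13/11, 21 retested (14 septic, 3
exacerbating), and group marker targets equal to the published mean ± SD
cells. Marker truths are lognormal with parameters chosen so the
*arithmetic* mean and SD equal the targets (σ² = ln(1+cv²),
μ = ln m − σ²/2): markers are positive and heavy-tailed, and moment
matching makes the generated tables reproduce the printed summaries in
expectation (verified at n = 5000 within 2% on the mean, 5% on the SD).

Quantities the published tables do not print are declared defaults, chosen
once at realistic magnitudes: lymphocyte CD64 ~60–180 MESF and monocyte
CD64 ~2000–5600 MESF per group (lymphocytes are CD64-negative, monocytes
constitutively positive; values set so the composite-index group means land
near the published ones), healthy-control TBNK counts at adult reference
magnitudes, bead lot {500, 5 000, 25 000, 60 000} MESF (no lot sheet is
public; values are configurable and arbitrary), and the four protocol
settings (three PMT voltages on one instrument, offsets +0.6/0/−0.4, plus a
second instrument with gain 0.97 and offset +0.2) at 5% multiplicative CV.
Event-level clouds place populations at fixed log10 locations on
CD45/CD14/side-scatter (SD 0.08 in log10), separated by ≥4 population SDs
from the rectangular gate boundaries, with the PE channel centered on the
protocol-transformed true marker value (unit-mean spread, CV 0.35); default
acquisition counts are 5 000 neutrophils / 1 000 monocytes / 2 000
lymphocytes per sample (the pipeline driver uses 2 000/500/1 000 — the
population *means* that feed every statistic are insensitive to count at
these sizes). Second-timepoint truths apply a log10 shift whose sign
follows the SOFA trajectory (exacerbation: mHLA-DR −0.30 ± 0.12, nCD64
+0.05 ± 0.15; recovery: +0.10 ± 0.08 and −0.40 ± 0.20), which reproduces
the direction of the published longitudinal effects with known ground
truth. Degenerate truths (≈0 receptor) are clamped to a 1-MESF floor with a
warning.

What the generator deliberately omits: spectral spillover/compensation,
doublets, debris, acquisition-time drift, and non-lognormal population
shapes. Passing tests therefore demonstrate that the pipeline's inference
machinery is correct under the stated measurement model — not that the
gates or cutoffs would transfer to a real instrument unchanged.

## Gating

The real study's gating strategy is not public; the package declares a
conventional scheme with configurable thresholds: on the nCD64 panel,
CD45-positive events are split by side scatter into lymphocytes (low),
monocytes (intermediate) and neutrophils (high); on the mHLA-DR panel,
monocytes are CD14-positive. Population MFI is the arithmetic mean by
default ("mean fluorescence intensity" taken literally), with the
geometric mean selectable and the choice recorded on every result, since
cytometry practice varies. Populations under 100 events carry a quality
warning. Bead peaks are located by 1-D k-means on log10 PE with quantile
initialization — beads are synthesized as single-parameter clusters, so 2-D
gating would add nothing — and merged peaks are an error naming the levels.

## Problem sizes and numerical choices

The reliability analyses run at n = 100 subjects × 4 protocols; the
event-level pipeline at 141 subjects × 4 protocols × 2 panels; the
binormal ROC check at 10⁵ per class; logistic CI coverage at 200
replicates of n = 500 — sizes at which every targeted property is
statistically decidable while the full suite runs in well under a minute.
Noise-free round-trips are asserted to 1e−9 relative; fitted-vs-oracle
agreement (logistic, ICC) to 1e−6 or better. All randomness flows from
explicit integer seeds; identical spec + seed is bit-identical.

## Known limitations

* ICC confidence intervals are not reported (point estimate only).
* No FCS file ingestion: event tables are CSV; the adapter surface
  (`EventTable.from_csv`) is where an FCS reader would plug in.
* The published per-protocol regression coefficients and patient-level
  ICCs/odds ratios are not reproducible without the raw data; the package
  asserts the corresponding *properties* on synthetic data instead.
* The multivariable logistic "unadjusted OR" wording in the source table
  layout is treated as a labelling slip: multivariate estimates are
  adjusted ORs and are reported as such.
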