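# Methods

This note documents the models, conventions and design choices behind
`msmelt`, in pipeline order. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Melt-curve model (simulator)

A melt trace is modelled as a two-state (helix/coil) mixture of the two
homoduplex species present after bisulfite PCR. Each species contributes
a logistic helicity

    h(T; Tm, w) = 1 / (1 + exp(4 (T − Tm) / w)),

which is 1 well below the melting temperature `Tm`, 0 well above, and
has its inflection at `Tm` (slope −1/w there). The observed fluorescence
interpolates between two drifting baseline lines:

    F(T) = L_post(T) + (L_pre(T) − L_post(T)) ·
           [ p'·h(T; Tm_meth, w) + (1 − p')·h(T; Tm_unmeth, w) ] + ε,

with `L_pre(T) = amplitude + pre_slope·(T − T_lo)`,
`L_post(T) = post_level + post_slope·(T − T_lo)` and ε i.i.d. Gaussian
with SD `noise_sd`. Heteroduplexes are deliberately omitted: MS-HRM of
fully converted template pools is dominated by the two homoduplex
species, and the two-state mixture is the simplest model producing the
characteristic normalized-curve family. No sequence-level
(nearest-neighbour) thermodynamics is attempted; `Tm_meth > Tm_unmeth`
is imposed directly because methylated product retains G:C pairs.

Defaults: grid 60–95 °C at 0.1 °C (typical instrument resolution);
*ELOVL2* Tm 74.0/78.5 °C, *EDARADD* 71.0/75.5 °C, transition width
1.5 °C — each transition sits between that marker's pre-melt
(fully double-stranded) and post-melt (fully melted) windows of
68–69/82–83 °C (*ELOVL2*) and 65–66/80–81 °C (*EDARADD*);
amplitude 100, post level 5, drifts −0.15 and −0.02 units/°C,
noise SD 0.5 units.

## PCR bias

Starting from template fractions (p, 1−p), each cycle multiplies the
methylated pool by `E_m` and the unmethylated pool by `E_u`, so after
`n` cycles the amplicon pool's methylated share is

    p' = p·E_m^n / (p·E_m^n + (1−p)·E_u^n).

For `E_m < E_u` this is concave-under-identity (`p' ≤ p`): bias against
methylated template. The *ELOVL2* default is `E_m = 0.96·E_u` over 40
cycles, giving a visibly non-linear standard curve; *EDARADD* is
unbiased (`E_m = E_u`) and its standard relation is linear.

A useful exact identity: because the noiseless Df is proportional to
`p'`, the simulated standard series follows the hyperbolic calibration
form *exactly* with `a = (E_m/E_u)^n` (0.96⁴⁰ ≈ 0.195). The tests use
this as a known ground truth for full-pipeline recovery.

## Normalization, difference plots, Df

Normalization fits least-squares **lines** (not single points) to the
raw fluorescence inside the pre- and post-melt windows and rescales

    value(T) = 100 · (F(T) − L_post(T)) / (L_pre(T) − L_post(T)),

restricted to [pre-window lo, post-window hi]. The result is invariant
to affine transforms of the raw signal (gain/offset), and robust to
linear baseline drift. Whether instrument software additionally applies
exponential background subtraction is not modelled; the two-line method
is this package's convention. Temperature shifting ("curve shift") is
not applied.

One numerical consequence worth knowing: the windows are narrow (1 °C)
relative to the normalized range (~15 °C), so the fitted lines are
extrapolated far outside their support and baseline-fit noise is
amplified roughly tenfold into the mid-range of the normalized curve.
With the default noise SD of 0.5 fluorescence units this puts a Df noise
floor of a few percentage points on identical samples; the replicate
averaging and the level-mean calibration absorb most of it.

The difference plot is `d(T) = sample(T) − baseline(T)` where the
baseline is the **mean normalized 0 %-standard curve across its
replicates**; mismatched grids are linearly interpolated onto the
coarser grid. `Df = max_T |d(T)|`. Df is computed per replicate well and
then averaged per sample (duplicate for samples, triplicate for
standards; one rule for both) — averaging Df values rather than curves
preserves replicate variance for QC.

## Calibration

* **Hyperbolic** (biased markers): the standard curve
  `a·M/(100−M) = Df/(Df_max − Df)` is fitted in the algebraically
  equivalent form `Df(M) = Df_max·a·M/(a·M + 100 − M)`, which is finite
  at M = 100 and so uses all eight levels. `Df_max` is the measured mean
  Df of the 100 % control and is held **fixed** during fitting (it is a
  defined quantity, not a free parameter); the single coefficient `a` is
  found by `scipy.optimize.curve_fit` (start 1.0, bounds 1e−6–1e3,
  tolerances 1e−12). Level means (not individual replicates) are the fit
  points. Inversion: `score = 100·r/(a + r)` with
  `r = Df/(Df_max − Df)`; `Df ≥ Df_max` clamps to score 100 with a
  warning.
* **Linear** (unbiased markers): OLS of nominal M on mean Df. Scores
  outside [0, 100] are flagged, not clamped — the line's own intercept
  is generally non-zero, so mildly off-range scores are an expected
  feature of the method, and transparency matters in forensic reporting.
  The linear inverse also accepts negative Df so that the score → Df →
  score round trip is exact over the whole [0, 100] score range.

## Synthetic cohorts and the aging signal

Cohorts follow the stratified design of the assay's training/test sets:
training strata (male/female) 5/5 under 20, 51/49 at 20–39, 45/36 at
40–59 and 5/1 over 60 (197 donors); test strata 2/3, 10/16, 13/6, 0/0
(50 donors). Ages are drawn uniformly within each stratum
([1, 20), [20, 40), [40, 60), [60, 74) years — the oldest stratum capped
at the assay's donor range). Per donor, true methylation scores are

    ELOVL2:  M1 = 5 + 20·ln(age) + N(0, 5.5),  clipped to [0, 100]
    EDARADD: M2 = 75 − 0.45·age  + N(0, 10.1),

and each marker is measured in duplicate melt curves with
`true_meth_fraction = score/100`. The coefficients and residual SDs are
synthetic (no published numeric score ranges exist to fit); the residual
SDs were set analytically from the generator's closed form

    r = σ_signal / sqrt(σ_signal² + σ_resid²),   σ_signal = |coef1|·sd(x),

so that the default strata give the score–age correlations the assay is
known for: r ≈ 0.87 for *ELOVL2* (vs ln age) and r ≈ −0.52 for
*EDARADD* (vs age). `melt_simulator.expected_pearson_r` computes this
closed form by quadrature over the strata and is what the Monte-Carlo
tests check against.

The smoking cohort is a matched design: 9 current smokers each
contributing a cigarette-butt and a saliva sample (identical donor
biology; a configurable `butt_effect_m1` score offset models a source
effect, 0 by default) plus 7 non-smokers' saliva samples, all donors
aged 40. A separate three-group beta-value generator
(`cohort_analysis.simulate_grouped_betas`) provides a synthetic
stand-in for public-array smoking cohorts.

What the generator does **not** emulate: bisulfite conversion errors,
primer mispriming, heteroduplex melting, cell-type composition effects,
batch/run effects, or any real inter-individual covariance between the
two markers beyond their common dependence on age. Passing tests
demonstrate that the analysis machinery is correct and well calibrated
under these idealized conditions, not that the accuracy figures
transfer to real saliva data.

## Age model

Per-marker relationships are fitted by OLS of score on ln(age)
(*ELOVL2*) or age (*EDARADD*), with Pearson's r reported on the same
regressor. Sex effects are tested by ANCOVA — OLS of
`score ~ regressor + sex` with a type-II F-test on the sex term
(α = 0.05 convention).

The age predictor is an epsilon-SVR with RBF kernel and the fixed
hyperparameters C = 1.1, gamma = 0.1, epsilon = 0.1 (epsilon is the
common default of e1071-style SVR implementations; the RBF kernel is
implied by a gamma parameter). Features (M1, M2) **and** the response
(age, untransformed years — the log relation lives in the feature-age
link) are standardized with training-set statistics; predictions are
de-standardized on output. Training uses scikit-learn's SVR; prediction
is re-expressed as the explicit kernel expansion over the stored support
vectors, so a JSON-serialized predictor reproduces the fitted model
exactly (asserted to 1e−9 in the tests). Negative or >100-year
predictions are flagged, never clamped.

Evaluation: MAD = mean |prediction − truth| in years; adjusted
R² = 1 − (1−R²)(n−1)/(n−p−1) with p = 2, where R² comes from the OLS
regression of truth on prediction (the package's declared convention —
several alternatives exist and none is canonical); per-bin MAD over the
age bins under 20, 20–39, 40–59, over 60. Under the default generator
the per-bin MAD rises with age — the flattening logarithmic *ELOVL2*
trajectory carries less age information per score unit in seniors — and
the 20-seed end-to-end test asserts a mean test-set MAD in the
5–8-year regime as a property of the generator's noise levels.

## Group comparisons

`one_way_anova` is the classical equal-variance fixed-effects ANOVA
(explicit between/within sums of squares, p from the F distribution; no
Welch correction), cross-checked in the tests against
`scipy.stats.f_oneway` and a brute-force oracle. It requires ≥ 2 groups
with ≥ 2 values each and rejects zero total variance;
`smoking_comparison` handles the all-predictions-identical corner
directly (F = 0, p = 1) since it is well defined there. The smoking
report gives per-group MADs against chronological age, the ANOVA on
predicted ages, and matched butt/saliva pairs side by side.

## Coordinates and problem sizes

Amplicon records store published coordinates verbatim under the 1-based
inclusive (UCSC browser) convention; `amplicon_length = end − start + 1`
gives 91 bp for the *ELOVL2* record. Note the two published amplicon
lengths are mutually inconsistent under any single convention (the
*EDARADD* record spans 140 bp inclusive where 139 bp is printed); the
package stays convention-pure and documents rather than resolves this.

Default problem sizes (chosen as the assay's own design): 197 training
+ 50 test donors, duplicate wells, triplicate 8-level standards; the
end-to-end property test repeats the full pipeline over 20 seeds and the
type-I-error simulations use 1000–2000 null replicates. A full pipeline
run takes a few seconds on one core.

## Known limitations

* The calibration's Df noise model is not propagated into score or age
  uncertainties (no bootstrap CIs); calibration residuals are reported
  instead.
* The hyperbolic fit weights level means equally; replicate-level
  weighting is not implemented.
* The SVR hyperparameters are fixed constants; no re-tuning search is
  provided.
* Df extreme-value noise (a max over the grid) biases low-level Df
  slightly upward, which inflates the fitted `a` by a few percent at
  the default noise level relative to its analytic value.
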