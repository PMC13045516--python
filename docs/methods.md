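# Methods

## Scope and models

bladekit quantifies bladder multiparametric MRI along two tracks: voxelwise
model-based fitting of diffusion-weighted (DW) and dynamic contrast-enhanced
(DCE) series into quantitative imaging biomarker (QIB) maps, and a
deep-feature classification pipeline for anatomical (T2-weighted) images.
All fitting operates on NIfTI volumes with masks that share the image grid
exactly; the package never resamples silently, because implicit resampling
corrupts quantitative maps. Bias-field correction and DICOM conversion are
upstream preprocessing steps, outside the package.

### Diffusion models

Signal attenuation versus diffusion weighting b (s/mm²) is modelled either
monoexponentially,

    S(b) = S0 · exp(−b · ADC),

or with the non-Gaussian intravoxel incoherent motion (NG-IVIM) model,

    S(b) = S0 · [ f · e^(−b·D*) + (1−f) · e^(−b·D + K(bD)²/6) ],

which separates capillary pseudo-diffusion (perfusion fraction f,
pseudo-diffusion coefficient D*) from tissue diffusion D, with the kurtosis
coefficient K capturing non-Gaussian water displacement in a complex
microstructure.

Fitting choices:

* **Monoexponential**: weighted log-linear least squares with weights ∝ S²
  (the first-order correct weighting after the log transform). Non-positive
  signals fall back to a bounded nonlinear fit and are flagged.
* **NG-IVIM**: segmented by default. Step 1 fits {S0_tissue, D, K} on
  b ≥ 200 s/mm² (at D* ≈ 25×10⁻³ mm²/s the perfusion term has decayed below
  1% there); step 2 fits {f, D*} on the full curve with step-1 values fixed;
  one bounded joint refinement of all five parameters follows
  (`scipy.optimize.least_squares`, trust-region reflective).
* **Bounds**: ADC and D in [1e-6, 4e-3] mm²/s, D* in [4e-3, 0.2] mm²/s,
  f in [0, 1], K in [0, 3]. These are physiological ranges that also prevent
  the D and D* terms from swapping roles. Fits landing on a bound, fits with
  D* < 2D (perfusion unidentifiable), fallbacks and non-convergence are all
  recorded in a bit-flag diagnostics map rather than silently reported.
* **Kurtosis validity**: the quadratic kurtosis expansion turns upward past
  its minimum at b·D = 3/K, which is unphysical; the exponent is clamped at
  that minimum so the modelled signal stays non-increasing and ≤ S0, with a
  diagnostic flag when the clamp engages.

### DCE chain

1. **VFA T1 mapping.** Pre-contrast T10 comes from multi-flip-angle spoiled
   gradient-echo (SPGR) data, S = M0·sinα·(1−E)/(1−E·cosα), E = exp(−TR/T10):
   a linearized fit of S/sinα against S/tanα (slope = E) followed by one
   bounded nonlinear refinement. T10 is bounded to [0.05, 10] s; a relative
   misfit above 1% (e.g. physically impossible equal signals at all angles)
   flags the fit.
2. **Signal → concentration.** Under the fast-exchange-limit relation
   R1(t) = R10 + r1·Ct(t), with M0 calibrated from the mean of the first
   n_baseline (default 3) pre-contrast frames and R10 = 1/T10. Each frame's
   R1 is recovered by exact algebraic inversion of the SPGR equation;
   saturated frames with no solution become NaN (flagged), never clamped.
   Defaults r1 = 3.9 mM⁻¹s⁻¹ and T10 = 1.16 s are typical bladder-protocol
   constants; TR and flip angle are always explicit configuration because
   they are acquisition properties. Negative concentrations from noise are
   retained for fitting (clamping would bias estimates).
3. **Patlak.** Ordinary least squares of Ct(t)/Cp(t) on
   ∫₀ᵗCp(τ)dτ / Cp(t) (trapezoidal cumulative integral): slope = Ktrans
   (min⁻¹), intercept = vp. Frames before bolus arrival or with Cp below 5%
   of its peak are excluded and counted. On data generated by the Patlak
   model itself the fit is exact (r² = 1) for any positive Cp.
4. **Extended Tofts.** Ct(t) = Ktrans·∫₀ᵗ e^(−kep(t−τ))·Cp(τ)dτ + vp·Cp(t),
   kep = Ktrans/ve always derived, never fit. The convolution uses
   trapezoidal quadrature on the AIF grid (second-order accurate; verified
   to converge under grid refinement against the constant-Cp closed form).
   The fit is bounded nonlinear least squares over {Ktrans, ve, vp} with
   three starts, one informed by a preliminary Patlak fit; the best residual
   wins. ve + vp > 1 after clamping is flagged.

The arterial input function is an explicit input (two-column time/mM table);
the phantom module ships a bi-exponential population shape. No hematocrit
correction is applied — the input is taken as plasma concentration directly.
Time is minutes internally; frame-time sidecars are seconds (converted).

### Deep-feature pipeline

Feature extraction is a contract: one fixed-length, deterministic vector per
2D image for a named backbone/tap-point. The shipped `stub` backbone is a
seeded random projection plus tanh — it makes the entire downstream pipeline
(selection, classification, evaluation) testable offline and is *not* a
claim of semantic features; real pretrained CNNs can be registered as
plug-ins. Scorers:

* ANOVA F and chi-squared via scikit-learn (`f_classif`, `chi2` — the
  chi-squared form is the per-class feature-sum statistic, which requires
  non-negative features; `train_eval` min-max scales features on the
  training fold before chi-squared scoring);
* Kruskal-Wallis H per feature via scipy (tie-corrected);
* ReliefF written here: k = 10 nearest hits/misses by Manhattan distance on
  range-normalized features, exhaustive over instances for n ≤ 500,
  validated exactly against a straight-from-definition brute-force
  reference;
* mRMR written here: greedy MID criterion on mutual information over
  equal-width 10-bin discretization, ties to the lowest feature index.

Classifiers are fixed, documented configurations (SVM: RBF, C = 1; decision
tree: Gini, unlimited depth, seeded; k-NN: k = 5, Euclidean). Splits are
stratified 70/30 holdout with an explicit seed. Feature selection always
runs inside `train_eval` on the training fold only; passing a method name
rather than precomputed scores is what makes the no-leakage guarantee
enforceable. AUC is computed by the Mann-Whitney pair-count definition
(midranks, ties = ½) and is identical to the trapezoidal area under the
threshold-sweep ROC polyline; zero-denominator confusion metrics are NaN
with an `undefined` flag, never 0.

## Phantoms — what they emulate and what they do not

Phantom generators are pure functions of (spec, seed): bit-identical on
repeat, with ground-truth maps stored before noise. Noiseless signals equal
the forward models to machine precision, so fitter validation is exact.
Defaults are the study conditions: 9 b-values {0, 30, 60, 100, 200, 400,
600, 800, 1000} s/mm² spanning perfusion and kurtosis regimes; 35 DCE frames
at 5 s/phase; flip angles {2°, 10°, 15°} at TR = 5 ms; cohort-mean ground
truth (ADC 1.22×10⁻³ mm²/s; f 0.24, D* 25.57×10⁻³, D 1.21×10⁻³ mm²/s,
K 0.41; T10 1.16 s; Ktrans 0.27 min⁻¹, ve 0.38, vp 0.03; Patlak
Ktrans 0.076 min⁻¹, vp 0.079). Noise is Rician on magnitude signals
(Gaussian available for speed), sd expressed relative to S0.

Phantoms are piecewise-constant slabs with ideal alignment: no anatomy,
partial volume, motion, B1 inhomogeneity or AIF measurement error. Passing
recovery tests therefore demonstrates correctness of the estimators under
the stated noise model — not clinical accuracy on patient data, where those
confounds dominate.

## Known estimator behaviour and limitations

* At Rician SNR 50 with the default b-scheme, the NG-IVIM maximum-likelihood
  estimate of D* is strongly right-skewed: its sampling mean overshoots the
  truth by roughly 20-30% even though the median is within ~10%. This was
  verified to be a property of the estimator itself (multi-start fits find
  the same global minimum; excluding bound-flagged voxels does not remove
  it). With only three b-values below 100 s/mm² the likelihood is nearly
  flat in D* toward large values. Consumers should treat ROI-mean D* at
  moderate SNR as upward-biased and prefer the median, more low-b samples,
  or higher SNR. ADC, f, D and K means are accurate to a few percent under
  the same conditions.
* Patlak Ktrans is systematically below the extended-Tofts Ktrans whenever
  kep > 0 (backflux is outside the Patlak model); this is asserted as an
  invariant, not a defect.
* The single-dataset null AUC of a classifier on spurious features varies
  far more between datasets than between splits (finite-sample feature-label
  correlations are shared by train and test folds); null-behaviour checks
  therefore average over independently generated datasets.
* Problem sizes in the test and acceptance runs (8×8×2 fitting grids,
  500-voxel noise studies, 100-curve DCE ensembles, 200×50 feature tables)
  were chosen so the full validation completes in well under a minute of
  fitting per model while keeping Monte-Carlo error small relative to the
  tolerances checked.
* Numerical tie-breaks are deterministic everywhere (lowest index wins);
  every stochastic step takes an explicit seed.
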