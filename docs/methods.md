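# Methods

`glioquant` implements a quantitative MRI analysis chain for glioma typing:
voxel-wise diffusion-kurtosis and dynamic contrast-enhanced (DCE) parameter
mapping, ROI extraction at a biopsy site and in contralateral
normal-appearing white matter (NAWM), and a statistical back end of
two-group tests, forward logistic regression with AIC accounting, and
ROC/Youden classification. Because the clinical data this kind of analysis
is applied to are generally not shareable, the package carries first-class
synthetic generators with known ground truth, so every stage can be
validated by forward-simulating and inverting.

## Diffusion kurtosis model

The direction-averaged diffusion signal is modelled as

    ln(S/S0) = -b * ADC + (b * ADC)^2 * K / 6

with ADC the apparent diffusion coefficient (mm^2/s) of the kurtosis model
(no separate monoexponential fit exists in this pipeline) and K the mean
kurtosis (MK). Signals are combined across gradient directions before
fitting — geometric mean for b > 0, arithmetic for b = 0 — because the model
is linear in log-signal; averaging per-direction fits instead would be a
defensible alternative but is not implemented. With S0 fixed by the b = 0
mean, the fit is ordinary least squares of ln(S/S0) on (b, b^2); the
estimator is deliberately the minimal one for this model, with no weighting
or Rician-likelihood correction.

Guards: valid voxels require the raw ADC in [-0.1, 1.1] x 4e-3 mm^2/s and
raw K in [-0.1, 1.1] x 3 (10% bands around the physiological ceilings
ADC <= 4e-3 mm^2/s, K <= 3), and ADC > 1e-5; reported values are clipped to
[0, ceiling]. Non-positive signals invalidate the voxel rather than raising.

## DCE chain

1. **T1 mapping** from variable flip angles (default 6/9/15 degrees,
   TR 4 ms) by the linearized spoiled-gradient-echo (DESPOT1) regression of
   S/sin(a) on S/tan(a); slope = E1 = exp(-TR/T1). Validity requires
   E1 in (0, 1), T1 in [100, 10000] ms, M0 > 0.
2. **Signal-to-concentration**: the baseline dynamic signal plus T10 imply
   M0; each frame is inverted for R1(t), and C(t) = (R1(t) - R10) / r1 with
   r1 = 6.3 L mmol^-1 s^-1 (gadobenate at 3 T) by default. Frames whose
   signal exceeds the SPGR range come back NaN; concentrations are clipped
   below at 0.
3. **Extended Tofts fit**: Ct(t) = vp Cp(t) + Ktrans * (Cp (*) exp(-kep t)),
   with the convolution evaluated by a recursive trapezoid (O(n)); bounded
   trust-region least squares from four fixed starts, best residual wins;
   ve = Ktrans/kep, enforced exactly so downstream consistency checks hold
   to machine precision. Fits that land on the parameter bounds
   (Ktrans >= 5 min^-1, kep >= 10 min^-1) or fail to converge are invalid.
4. **Semi-quantitative descriptors**, computed on percent relative
   enhancement (S - S0)/S0 x 100 (a config switch to concentration exists):
   bolus arrival = first frame exceeding 10% of the curve maximum; peak =
   curve maximum; TTP = t(peak) - t(arrival); AUC = trapezoidal integral
   over [arrival, arrival + 60 s]; wash-in = steepest forward-difference
   slope between arrival and peak; wash-out = sign-flipped least-squares
   slope from peak to the last frame. A flat curve invalidates the metrics.
5. **CBV** = 100 x integral(Ct) / integral(Cb) over the full acquisition,
   with the whole-blood curve Cb = Cp (1 - Hct), Hct = 0.45.

The arterial input is the Parker population AIF (two Gaussians plus a
sigmoid-modulated exponential, published constants), shifted by a 10 s bolus
arrival so Cp is exactly zero before injection. The dynamic series defaults
to 60 frames at 5 s spacing with a 15-degree flip angle — typical VIBE
settings; all of these are configuration fields, and because the units and
windows of the semi-quantitative descriptors are conventions of this
implementation, their cut-off values are not directly comparable across
implementations with different conventions.

## ROIs

ROIs are planar discs (drawn on one slice): a voxel belongs to the disc iff
its in-plane Euclidean distance from the center is <= radius, inclusive — a
radius-5 disc at an interior center therefore contains exactly 81 voxels.
Each patient has one biopsy ROI and one NAWM control ROI. Transfer between
grids goes through world coordinates via the two affines (nearest-voxel
rounding; radius rescaled by the in-plane voxel-size ratio). ROI means are
taken over valid-fit voxels only and withheld (NaN) when fewer than half of
the disc voxels are valid — an artifact rule, chosen so partially failed
fits cannot silently bias a mean.

## Statistics

Per parameter and contrast: Shapiro-Wilk in each group (alpha 0.05), Levene
mean-centered (alpha 0.05, the SPSS convention), then unpaired t-test (both
normal, homogeneous), Welch (both normal, inhomogeneous) or Mann-Whitney U
(any non-normal; exact p for combined n <= 20 without ties, asymptotic with
continuity correction otherwise). The homogeneous-but-non-normal cell is
dispatched to Mann-Whitney — rank tests keep their level under
non-normality — and this is an interpretive choice of the package.
Significance uses the Bonferroni-adjusted per-test level 0.05/12 (reported
as 0.004) for the 12 a-priori parameter hypotheses. The same battery run on
NAWM ROIs is the negative control: the cohort generator draws NAWM vectors
from one shared distribution, so any NAWM "effect" is a false positive.

Contrasts: (i) WHO grade 2 vs grades 3-4; (ii) IDH1/2 wildtype vs mutated
(missing status excluded); (iii) grade-3 oligodendroglioma vs high-grade
astrocytic tumors (grade-2 patients excluded).

## Classification

Univariate binary logistic regression per parameter (Newton ML, tolerance
1e-8; AIC = 2k - 2 logL with k counting the intercept), then forward
selection from the intercept-only model: the candidate with the smallest
likelihood-ratio p enters while p < 0.05; ties break by larger likelihood
gain, then name order. LR entry at 0.05 is the convention of clinical
statistics software; separation is detected from fitted probabilities
pinned to the labels and such models are reported but never selected.

ROC: AUC is the pairwise concordance statistic (ties = 1/2); the 95% CI and
the AUC-vs-0.5 p-value use DeLong's variance with a normal approximation;
orientation is folded so AUC >= 0.5 with the direction recorded. Cut-offs
scan the observed score values (decision rule: score >= cutoff) and the
Youden-optimal point is reported — on the raw measurement scale for single
parameters and on the predicted probability for combined models. Reported
performance is apparent (in-sample); there is no cross-validation, by
design.

## Synthetic data

Phantoms are block phantoms (regions split the grid along x) with
per-region T1, ADC, K, Ktrans, ve, vp; diffusion is isotropic because the
pipeline only evaluates direction-averaged scalars. Noise is Rician — two
independent Gaussian channels on the complex signal, magnitude taken —
which reproduces the upward noise floor that stresses the kurtosis fit at
b = 2500. The default noise scale in examples is sigma = 0.02 x S0.

Cohorts are generated at ROI level: per patient a 12-parameter biopsy
vector from the histology group's multivariate normal (SD = 30% of the
group mean; exchangeable correlation 0.3 among the ten DCE parameters,
reflecting their shared perfusion dependence) and an exchangeable NAWM
vector. Group mean vectors are chosen as plausible tissue values with
moderate overlap, so that single-parameter AUCs land in the 0.75-0.95 range
typical of clinical glioma biomarkers; no published per-group distributions
exist for this design, so these defaults aim at realism, not at mimicking
any specific dataset. The default case mix is 81 patients
(12/7/3/12/47 across the five histology strata) with IDH marginals 32
wildtype / 42 mutated / 7 missing; oligodendrogliomas are always IDH-mutated
and 1p/19q-codeleted, and surplus mutated/missing labels fall to the
glioblastoma stratum to honor the fixed marginals.

What the generators do **not** emulate: anatomy and partial volume, B1 and
motion artifacts, patient-specific AIFs, spatial correlation of noise, and
co-registration error beyond exact affine transfer. Passing recovery tests
therefore demonstrates the correctness of the estimators under their own
forward models, not robustness to the full physics of acquisition.

## Numerical choices and problem sizes

Phantom recovery checks use a 500-voxel DWI phantom (10 x 10 x 5) and a
9-voxel Tofts phantom at 60 frames x 5 s — the estimators are voxel-wise, so
small grids already exercise every code path. The null-calibration check
runs 10^4 two-group comparisons (n = 40/41, Gaussian) and verifies the
type-I rate at alpha = 0.004; the AUC null uses 500 replicates of n = 200.
Tie-breaks: Youden scan keeps the lowest optimal cut-off; forward selection
breaks ties by likelihood then name. Degenerate inputs (flat curves,
constant scores, all-invalid ROIs) are flagged, never raised through, so a
single bad voxel cannot abort a volume fit.

## Known limitations

- The kurtosis fit is unweighted log-linear OLS; at very low SNR the Rician
  floor biases MK (the dispersion, not the median bias, approaches 5% at
  sigma = 0.02).
- Extended Tofts assumes a well-mixed plasma compartment and the population
  AIF; no bolus-arrival fitting or B1 correction.
- Semi-quantitative descriptor units follow this package's conventions;
  cut-offs are not transferable to pipelines with different windows/units.
- Forward selection and Youden cut-offs are in-sample; reported AUCs are
  optimistic relative to held-out performance.
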