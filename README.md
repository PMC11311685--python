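# glioquant

Quantitative DCE-MRI and diffusion-kurtosis analysis for glioma typing.

Gliomas are graded and typed (WHO grade 2-4, IDH1/2 mutation status, 1p/19q
codeletion) from tissue obtained by biopsy or resection, but a reliable
non-invasive read-out from multiparametric MRI matters for follow-up and for
patients who cannot undergo surgery. `glioquant` implements the full
quantitative chain such studies rely on, with synthetic phantoms and cohorts
standing in for clinical data so that every stage is testable against known
ground truth. It is aimed at imaging scientists who want a reproducible,
end-to-end reference implementation of this analysis.

## What it computes

**Diffusion.** Voxel-wise apparent diffusion coefficient (ADC) and mean
kurtosis (MK) from multi-b-value DWI (b = 0-2500 s/mm², 6 directions per
b-value) under the kurtosis signal model

```
ln(S/S0) = -b·ADC + (b·ADC)²·K/6
```

fit by ordinary least squares in log-signal space after geometric direction
averaging.

**Perfusion/permeability.** From variable-flip-angle T1 mapping (DESPOT1)
and a dynamic post-contrast series: signal → concentration inversion of the
spoiled-gradient-echo equation, then the extended Tofts model

```
Ct(t) = vp·Cp(t) + Ktrans·∫ Cp(u)·exp(-kep·(t-u)) du,    ve = Ktrans/kep
```

driven by the Parker population AIF, plus the semi-quantitative curve
descriptors CBV, TTP, peak, AUC, wash-in and wash-out — twelve biomarkers in
total.

**Statistics.** Circular biopsy-site and contralateral NAWM ROI means feed a
two-group battery per contrast (Shapiro-Wilk → Levene → t / Welch /
Mann-Whitney, Bonferroni 0.05/12), univariate and forward-selected binary
logistic regression with AIC, and ROC analysis with DeLong confidence
intervals and Youden-index cut-offs.

See `docs/methods.md` for the model assumptions, defaults and limitations.

## Worked example

Simulate an 81-patient cohort (default case mix: 12 diffuse astrocytomas
grade 2, 7 grade 3, 3 + 12 oligodendrogliomas grade 2/3, 47 glioblastomas;
IDH 32 wildtype / 42 mutated / 7 missing), run the grade contrast and the
classification report:

```python
from glioquant import stats, classify, synthetic

cohort = synthetic.simulate_cohort(synthetic.CohortSpec(seed=1))
battery = stats.run_contrast_battery(cohort, "lgg_vs_hgg")
report, details = classify.build_report(cohort, "lgg_vs_hgg")
```

With seed 1 all 12 biopsy-ROI parameters differ significantly between
low-grade and high-grade tumors at the adjusted level 0.004 (e.g. Ktrans,
Welch test, p = 8.7e-16) while the NAWM control ROIs show none — the
built-in negative control. The classification table (excerpt):

```
model                      auc   ci_low  ci_high  cutoff  sens   spec   aic
Ktrans                     0.968  0.933   1.000    0.057   0.909  1.000  32.638
wash_out                   0.962  0.920   1.000    0.180   0.955  0.867  35.077
MK                         0.859  0.777   0.940    0.764   0.667  1.000  60.605
...
Ktrans + wash_out + TTP    0.994  0.983   1.000    0.940   0.924  1.000  20.373
```

Single-parameter rows report the Youden cut-off on the raw measurement
scale; the last row is the forward-selected combined model, whose cut-off
(0.940) is on the predicted-probability scale and which attains the highest
AUC and the lowest AIC — the combined diffusion + perfusion evaluation beats
every single biomarker in-sample.

The same pipeline is scriptable from the shell:

```bash
glioquant simulate --out-dir sim --seed 1            # phantoms + cohort CSV
glioquant fit-dki  --dwi sim/dwi.nii --bval sim/dwi.bval --out-dir maps
glioquant compare  --cohort sim/cohort.csv --contrast lgg_vs_hgg --out cmp.csv
glioquant classify --cohort sim/cohort.csv --contrast lgg_vs_hgg --out cls.csv
```

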