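# ecgbispec

Mode decomposition and bispectral feature analysis of 12-lead ECG for
discriminating two cardiomyopathy groups (e.g. dilated vs ischemic — two
heart-failure etiologies with similar presentation but different
treatment). The package implements the full analysis chain as a library
plus a CLI:

1. **Preprocessing** — 50 Hz notch, two-stage median-filter baseline
   removal, wavelet threshold denoising; Pan–Tompkins R-peak detection;
   segmentation into 601-sample beats (300 samples either side of the R
   peak, first/last beats discarded).
2. **Decomposition** — empirical mode decomposition (EMD sifting,
   `f(t) = Σ imf_i(t) + r(t)`) and variational mode decomposition (VMD:
   K band-limited modes `u_k` with center frequencies `ω_k`, solved by ADMM
   in the frequency domain).
3. **Mode selection** — Pearson correlation `r̄_jk` of each mode with its
   source beat, averaged into a 12-lead × 10-mode table; the first five
   modes are kept, and a correspondence analysis of the table yields
   lead/mode factor-loading coordinates.
4. **Bispectral features** — the direct bispectrum estimate
   `B(f1,f2) = X(f1)X(f2)X*(f1+f2)/N` per mode, and 15 features per mode:
   bispectral brightness/flatness/roll-off, two normalized bispectral
   entropies, log-amplitude sums and diagonal moments, the Burg AR(16)
   spectral peak, approximate/fuzzy/sample/permutation entropy and
   Lempel–Ziv complexity.
5. **Classification & comparison** — LR, SVM, DT, RF and KNN under
   stratified 10-fold cross-validation (ACC, SEN, SPE, PPV, NPV, AUC per
   fold), compared across classifiers by one-way MANOVA (Wilks' Λ, Rao F)
   with pairwise Hotelling T² post hoc tests and Bonferroni adjustment;
   a sampling-based Shapley estimator ranks feature importance.

Because clinical recordings of this kind are not freely shareable, the
package ships a synthetic 12-lead generator (`ecgbispec.synth`) whose
records carry P-QRS-T morphology at 1000 Hz, power-line/baseline/muscle
noise, and a controllable between-class difference in amplitude and
quadratic phase coupling — enough structure to exercise and test every
stage end to end.

## Worked example

```python
from ecgbispec import EcgClassificationModel, PipelineConfig, SynthConfig

model = EcgClassificationModel.from_synthetic(
    SynthConfig(n_subjects_per_class=10, n_beats_per_record=20, seed=123),
    PipelineConfig(leads=["II", "V3"], methods=("VMD",), cv_folds=10, seed=0),
)
results = model.fit()
print(results.summary())
```

```
ECG two-group discrimination experiment
=======================================================
records: 20  (positive class: A)
beats (feature rows): 720
classifiers: LR, SVM, DT, RF, KNN
cv folds: 10  seed: 0

[VMD] best lead per classifier (mean ACC +/- SD):
    LR    II  0.9917 +/- 0.0134
   SVM    II  0.9861 +/- 0.0146
    DT    II  0.9306 +/- 0.0327
    RF    II  0.9778 +/- 0.0219
   KNN    V3  0.9444 +/- 0.0454
```

Each line is one classifier's best lead by mean cross-validated accuracy,
with the across-fold standard deviation. Here the generator's default
class effect (a 1.3× amplitude scale plus a stronger phase-coupled triple
in class B) is recovered almost perfectly; with the null class effect the
same pipeline sits at chance. `results.classifier_comparison("VMD")`
returns the MANOVA + Hotelling post hoc table, and
`results.correlation_table("VMD")` the lead × mode correlation matrix.

The same chain runs from the shell, staged or monolithic:

```
ecgbispec run --config cfg.toml --outdir out/
ecgbispec synth --config cfg.toml --outdir out2/   # ... then preprocess, decompose, ...
```

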