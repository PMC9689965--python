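# restalpha

Resting-state EEG markers of motor-imagery BCI performance.

Motor-imagery brain–computer interfaces (MI-BCIs) work well for some users
and barely at all for others ("BCI inefficiency"), so a marker that predicts
a user's MI ability from a minute of resting EEG — before any training — is
of real practical value. `restalpha` implements, as a tested and reusable
pipeline, the analysis that links three resting-state EEG features to
multiclass MI classification performance, together with a synthetic cohort
generator that lets every stage run and be validated without any data
download.

The pipeline:

1. **MI performance scoring.** Four-class MI trials (left hand, right hand,
   both hands, feet) are band-passed to 8–30 Hz; one-vs-rest multiclass
   common spatial patterns (CSP; per class, the top-2 eigenvectors of
   S_c w = λ (S_c + S_rest) w) feed normalized log-variance features to a
   linear SVM (C = 1), scored by 10×10-fold cross-validation. Subjects are
   grouped H (≥ 60 %), M (40–60 %), L (< 40 %) by mean 4-class accuracy.
2. **Resting-state features.** After common average referencing, eyes-open
   and eyes-closed one-minute runs are cut into 1500-sample epochs and, per
   band (θ 4–8, α 8–13, β 13–30, γ 30–50 Hz) and channel, three features are
   averaged over epochs:
   - *RPL* — relative power level, `P_band / P_4–50 Hz` with `P = (1/N) Σ x²`;
   - *PSE* — power spectral entropy, `−Σ pᵢ ln pᵢ` of the normalized in-band
     periodogram PSD;
   - *LZC* — Lempel–Ziv (LZ76) complexity of the median-binarized epoch,
     normalized as `C(n)·log₂(n)/n`.
3. **Association.** Channel-wise Pearson correlation maps between each
   feature and MI performance; repeated-measures ANOVA of |r| across bands
   (Mauchly sphericity, Greenhouse–Geisser correction, pairwise paired
   t-tests); Welch t-tests between the H/M/L groups on the canonical
   channel-pair averages (C3/C4 for RPL, C4/Cp4 for PSE, C3/Cp4 for LZC,
   eyes-open alpha).
4. **Screening.** Linear-SVM classifiers (fold-wise standardized, stratified
   10-fold CV) that separate H from L subjects using each feature alone and
   the three combined, plus a three-class H/M/L model with its full
   prediction distribution.

The synthetic cohort generator plants a controllable cross-subject
correlation between resting alpha power fraction and MI class separability
(Gaussian copula), models contralateral event-related desynchronization for
the four MI classes, and reproduces the occipital eyes-closed alpha boost —
so the pipeline's statistical machinery can be validated against known
ground truth. See `docs/methods.md` for the model details.

## Worked example

```bash
restalpha demo --seed 9 --n-subjects 16 --out demo_out
```

runs the full synthetic pipeline (simulate → preprocess → features →
CSP+SVM scoring → correlation → screening; about a minute) and prints:

```
summary written to demo_out/summary.json
group sizes: H=3, M=4, L=9
```

`demo_out/summary.json` contains, among other quantities,

```json
"ground_truth_alpha_separability_r": 0.76635,
"alpha_rpl_c3c4_r": {"C3": 0.775853, "C4": 0.785315},
"mean_acc_4class_pct": 43.1521,
"screening": {"binary_accuracy_pct":
    {"RPL": 83.3333, "PSE": 100.0, "LZC": 91.6667, "combined": 100.0}, ...}
```

— the planted alpha-vs-separability correlation of this 16-subject demo
cohort (r = 0.77 as drawn; the demo preset plants a strong coupling), the
correlation the pipeline actually recovers between eyes-open alpha relative
power at C3/C4 and measured 4-class CSP+SVM accuracy (r ≈ 0.78 at both
channels), the cohort's mean 4-class accuracy, and the H-vs-L screening
accuracies of the three alpha features. Intermediate artifacts
(`features.csv`, `performance.csv`, `correlations.csv`,
`group_contrasts.csv`) are tidy CSVs.

Real recordings in PhysioNet-dialect EDF can be loaded with
`restalpha.read_edf`, which normalizes the dotted channel labels, reorders
channels into the canonical 64-channel montage and decodes T0/T1/T2 event
codes into task labels by run number.

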