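# Methods

## Analysis model

### MI performance

Trials are zero-phase band-passed to 8–30 Hz (4th-order Butterworth,
forward–backward, i.e. effective order 8) before spatial filtering. Per-trial
spatial covariances `X Xᵀ` are trace-normalized and averaged within class.
One-vs-rest multiclass CSP solves, per class c, the generalized eigenproblem

    S_c w = λ (S_c + S_rest) w

and keeps the eigenvectors of the two largest eigenvalues (8 filters for 4
classes). Eigenvector signs are fixed by making each filter's
largest-magnitude coefficient positive, so fits are deterministic. If the
composite covariance is numerically singular, diagonal shrinkage
`(1−λ)S + λ·tr(S)/d·I` is applied at increasing λ (1e-10, 1e-6, 1e-3) until
the solver succeeds.

Trial features are `log(w_jᵀ C w_j / Σ_k w_kᵀ C w_k)` — the log of each
filter's share of trial power, scale-invariant by construction. "Variance"
here is the mean square of the filtered signal (band-passed trials are
zero-mean); this makes the time-domain and covariance-based feature paths
agree exactly, which a test asserts.

Scoring is 10 repetitions of stratified 10-fold CV with a linear SVM, C = 1.
CSP is refit inside every training fold — no test trial influences the
spatial filters (the narrative convention of fitting once on all data is
available as `refit_csp=False` for protocol comparison, but leaks). The
per-repetition accuracy is the mean over folds; a subject's score is the
mean over repetitions. Repetition r shuffles folds with seed `master + r`.
Implementation note: each training fold's class covariance is formed as
(full class sum) − (test-fold sum), and features are computed from cached
per-trial covariances, which keeps 10×10 CV on 64 channels to a few
seconds per subject.

Group assignment uses the half-open convention [40, 60) → M, [60, 100] → H,
below 40 → L; the printed group ranges overlap at their ends, so the
boundary points had to be assigned by choice.

### Resting-state features

Common average reference is applied to the raw recording, each band is
filtered on the continuous one-minute record (so epoch boundaries carry no
filter transients), and the record is cut into consecutive non-overlapping
1500-sample epochs from sample 0 (6 epochs at 160 Hz). Features are computed
per epoch and averaged.

* **RPL.** Band power is the mean squared amplitude. The 4–50 Hz normalizer
  is defined as the *sum of the four band powers* — the bands partition
  4–50 Hz — which makes the four RPLs sum to 1 exactly (simplex invariant).
  The alternative (power of a single 4–50 Hz filtered signal) differs only
  through filter-edge effects; the partition definition is the one whose
  invariant is testable exactly.
* **PSE.** Plain rectangular-window periodogram of the band-filtered epoch,
  restricted to the bins inside the band, normalized to sum 1; Shannon
  entropy in nats. Bounded by ln(n_bins) (47 bins for alpha at 1500 samples
  / 160 Hz). Note that for *stochastic* flat-spectrum input (band-limited
  Gaussian noise) the expected single-periodogram entropy is ≈ ln N − 0.42
  nats (normalized exponential bin weights are Dirichlet(1,…,1)), about 11 %
  below the bound at 47 bins; the bound is approached only by signals whose
  periodogram is itself flat, which is what the flat-spectrum test
  constructs (unit-magnitude random-phase Fourier synthesis).
* **LZC.** The epoch is binarized at its median (ties → 1, making the rule
  deterministic and the feature scale-invariant), parsed by the LZ76 scheme
  with the pattern counter initialized at 1 (a constant sequence gives
  C(n) = 2), and normalized as `C(n)·log₂(n)/n`, under which i.i.d. random
  binary sequences approach 1. The printed normalization in the source
  material ("C(n) n log₂ n") is dimensionally inconsistent and was read as
  this standard form. The counter is a numba-compiled longest-match parser;
  an independently written brute-force parser (substring search) must agree
  exactly on 1000 random sequences.

### Association and screening

Pearson r with two-sided t-based p per (state, band, channel, feature) cell;
subjects aligned by id, listwise exclusion, zero-variance cells reported as
NaN (never silently 0), p-values floored at 1e-300. The band contrast treats
*channels as repeated-measures units* and |r| as the response: Mauchly's
sphericity test, Greenhouse–Geisser-corrected F (via pingouin), then all
pairwise paired t-tests. Treating channels as units is the only reading
under which a per-feature band ANOVA of a correlation map is defined.
Group contrasts are Welch (unequal-variance) t-tests. Significance is
reported uncorrected (the analysis convention this follows); a
Benjamini–Hochberg option across cells exists but is off by default.

Screening uses the three eyes-open alpha channel-pair scalars (RPL: C3/C4,
PSE: C4/Cp4, LZC: C3/Cp4). Each model is a linear SVM (C = 1) behind a
StandardScaler fitted on training folds only, stratified 10-fold CV, run
once (no repetition); class imbalance is left unweighted, with a
class-weight option exposed. Reported accuracy is the pooled confusion
diagonal share, which equals fold-mean accuracy up to fold-size rounding and
is exactly consistent with the reported confusion matrix. When a group is
smaller than the fold count, folds are reduced with a warning.

## Synthetic cohort generator

The generator emulates the study conditions end-to-end: per subject, one
eyes-open and one eyes-closed 60 s resting run (64 channels, 160 Hz) and 75
four-class MI trials per class (4 s each), defaults matching 25 trials ×
3 runs.

**Subject parameters.** A Gaussian copula draws, per subject, a latent pair
with correlation `2·sin(π·ρ/6)` (so the uniform-margin Pearson correlation
equals the requested `planted_rho`). One margin maps linearly to the
separability range (default 0.05–0.95); the other maps to the alpha power
fraction (default range 0.15–0.60) through `u^γ`. The link exponent γ
(default 1) controls how nonlinear the alpha–separability relation is; the
screening preset uses γ = 5, which clusters low- and medium-separability
subjects at low alpha while high performers stand out — the nonlinear group
pattern the screening classifiers exploit. The non-alpha band fractions
split the remaining power following the band profile with per-subject
lognormal jitter (σ = 0.6) uncorrelated with separability, so alpha remains
the dominant correlate of performance among the four bands.

**Resting signals.** Per channel: 1/f^β background (β = 1, 10 % of 4–50 Hz
power by default) plus independent band-limited Gaussian components scaled
to the subject's band fractions. Theta/beta/gamma components use exactly the
analysis Butterworth filters (so RPL calibration does not depend on filter
shape mismatch); the alpha component is a narrowband 9–11 Hz rhythm, which
makes a high alpha fraction also mean a more peaked, more regular alpha band
— hence spectral entropy and Lempel–Ziv complexity *fall* as alpha power
rises, giving the negative PSE/LZC correlations alongside the positive RPL
correlation. Eyes-closed runs add a *common* narrowband alpha source on 18
posterior channels with subject-specific power (≈ 8× the nominal alpha
fraction, lognormal across subjects, independent of separability); because
CAR mixes this coherent source into every channel, it adds
performance-unrelated alpha variance at motor channels and weakens
eyes-closed correlations — the mechanism offered for eyes-open markers
outperforming eyes-closed ones.

**MI trials.** Unit-variance broadband noise on all 64 channels plus a mu
rhythm (9–11 Hz, power 1.5) on the sensorimotor strip. A trial of class c
scales mu variance on its ERD group by `1 − s·0.5` (s = subject
separability): right hand → {C3,C5,Cp3,Cp5}, left hand → {C4,C6,Cp4,Cp6},
both hands → both groups, feet → {Cz,Cpz,Fz}. At s = 0 all class
covariances coincide and CSP+SVM scores at chance; the calibrated curve runs
≈ 33 % (s = 0.3) → 60 % (s = 0.6) → 89 % (s = 0.95), monotone and roughly
linear over the default range, crossing the 40 %/60 % group boundaries at
s ≈ 0.42/0.60 — these two values define each subject's *intended* group in
the ground-truth table.

**Reproducibility.** Every quantity derives from `numpy` SeedSequences keyed
by (master seed, stream id, subject), so cohorts are bit-identical for a
seed and a subject's data does not change when the cohort grows.

**What the generator does not model.** No volume conduction or forward
model (channels are independent up to the common posterior source), no
ocular/muscle artifacts, no non-stationarity within a run, no 1/f knee, no
line noise. Passing tests therefore demonstrate that the *analysis
machinery* is correct and well-calibrated (filters, features, CSP, CV
protocol, statistics, screening), not that the effect sizes transfer to real
recordings.

## Problem sizes and numerical choices

The validation suite uses cohorts of 100 subjects (correlation recovery,
planted ρ = 0.5) and 105 subjects (screening preset); the acceptance script
uses 60 and 105. Chance-level calibration uses 20 trials/class with permuted
labels over 10 seeds. Filters are SOS-form Butterworth run forward–backward;
MI trials are filtered in float32 (the covariances and classifier are
insensitive at that precision; resting features stay float64). Degenerate
inputs are defined, not silent: all-zero epochs raise for RPL/PSE, constant
epochs binarize to all-ones for LZC (C(n) = 2), zero-variance correlation
cells are NaN, singular covariances get shrinkage, groups too small for the
fold count reduce folds with a warning.

## Known limitations

* EDF export writes 16-bit EDF+C with 1 s records and integer sampling
  rates only — sufficient for this dataset's dialect and round-trip tests,
  not a general EDF writer.
* The three-class screening model inherits the binary models' feature set;
  no per-model feature selection is attempted.
* The repeated-measures ANOVA treats channels as independent units; spatial
  correlation between channels makes its p-values optimistic. The pairwise
  paired t-tests it gates share this caveat (they are reported uncorrected,
  by design).
* Adjacent analysis bands share Butterworth transition regions and their
  outputs correlate at ≈ 0.08; band powers are therefore not an exact
  orthogonal decomposition, and the RPL simplex holds by the normalizer's
  definition, not by orthogonality.
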