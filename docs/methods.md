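# Methods

This note documents the models, defaults and numerical choices behind
`vigorspec`: what the synthetic spectra contain, how each analysis stage is
defined, and where the design was genuinely open.

## The synthetic spectrum model

A replicate spectrum in band *b* on grid λ is

I(λ) = B + Σₗ Aₗ · φ(λ; λₗ, wₗ) + ε(λ),

where B is a flat continuum baseline (default 20 a.u.), φ is a unit-height
pseudo-Voigt profile — an equal-weight Gaussian/Lorentzian mix with FWHM wₗ
(0.06 nm for lines below 330 nm, 0.12 nm above) — and ε is i.i.d. Gaussian
noise (default SD 1 a.u.). Amplitudes factorize as

Aₗ = aₗ · vₗ · cₗ · s · tₗ · jₗ with

- aₗ — the line's mean amplitude from the packaged library (60–500 a.u.;
  the strongest lines are Ca II 393.36, K I 766.49 and Mg II 279.55);
- vₗ — vigor effect: ×1.3 on every Mg, Ca and K line for high-vigor
  samples (these elements drive the enzymatic chemistry of germination and
  are the features a vigor classifier should latch onto);
- cₗ — cultivar nuisance: ×1.2 on every Na and Si line for Paiaguás
  samples, giving the data a second, vigor-irrelevant cluster structure;
- s — one log-normal *global* per-sample factor (CV 0.10) modelling
  sample-to-sample ablation-efficiency differences. It rescales the whole
  spectrum and is therefore removed by SNV — which is precisely why SNV is
  the first preprocessing step;
- tₗ — independent per-sample, per-line log-normal variability (CV 0.02),
  the part of biological/matrix variation SNV cannot remove;
- jₗ — per-replicate, per-line log-normal shot jitter (CV 0.10).

All log-normal factors have mean 1. Lines shared by both detector bands
reuse the same s and tₗ; shot jitter is drawn per band because the two
bands are acquired as separate shots.

Grids: UV 175–330 nm at 0.02 nm and VIS 275–771 nm at 0.05 nm — round
steps near the instrument-class resolution (tens of pm). The VIS band
nominally ends at 750 nm in this class of echelle spectrometers, but the
monitored K I doublet lies at 766.49/769.90 nm, so the default grid extends
to 771 nm to cover those lines and their background windows.

The default composition is 120 samples — 20 Marandu-HV, 40 Paiaguás-HV,
40 Marandu-LV, 20 Paiaguás-LV — with 50 replicates per sample per band.

**Corrupted replicates.** `inject_outliers` flags
round(n_samples · n_replicates · fraction) sample-replicate pairs
(round-half-away-from-zero; default fraction 0.02) and distorts them in
both bands with one of three modes: a linear baseline ramp spanning six
times the spectral range, peak suppression (clipping to just above the
continuum, emulating a failed ablation), or a huge spurious spike at a
random wavelength. All three reduce the SNV-SAM similarity to the sample
mean far below the 0.90 threshold (empirically ≤ 0.41 under defaults,
while clean replicates stay ≥ 0.96). The ground-truth corruption list is
returned so filter tests are exact.

**What the generator does not emulate** — and hence what passing tests do
not certify about real instruments: physical plasma effects
(Saha–Boltzmann level populations, self-absorption, matrix effects),
wavelength-calibration drift, detector nonlinearity, correlated (pink)
noise, or baseline curvature. The within-class structure is log-normal and
line-local; real biological variation may be more structured.

## Preprocessing

Per replicate: SNV, x ↦ (x − mean(x)) / sd(x) with the n−1 (sample)
standard-deviation convention — stated so results are bit-reproducible; a
zero-variance spectrum is an error. Per sample and band: the SAM
similarity of each SNV replicate to the arithmetic mean of *all* SNV
replicates is cos θ = ⟨a, r⟩ / (‖a‖‖r‖); replicates below 0.90 are
discarded in a single pass (the reference mean is not recomputed after
discards — the simplest auditable variant), survivors are averaged
pointwise. If every replicate fails the threshold the sample is reported
unusable rather than silently averaged. SAM is reported as a cosine, not
an angle: a 0.90 threshold where larger means more similar is a cosine
convention.

## Acquisition-condition optimization

`factorial_design()` returns the 8 corner points (energy, delay, gate
coded ±1, ordered energy-major) plus 3 center replicates, with the fixed
coded→real map 29.73/42.29/54.86 mJ, 0.5/1.0/1.5 µs, 1/11/20 µs.

SBR uses the peak maximum in a ±0.3 nm signal window minus the pooled mean
of two flanking line-free background windows, divided by that background —
the common net-signal-over-background reading; a non-positive background
is an error. Per line, desirability is one-sided linear min–max scaling
across the 11 experiments (best SBR → 1, worst → 0); an all-equal response
maps to 0.5 with a logged warning so a single flat line cannot abort the
design. OD is the arithmetic mean of the per-line DIs — well-defined even
when some DI = 0, which is exactly why the arithmetic rather than
geometric mean is used. `select_best` is argmax OD with ties to the lowest
experiment id. Main effects are mean(+1) − mean(−1) contrasts over the 8
corners, with two-factor interactions via coded-level products;
significance testing of a regression model is deliberately out of scope.
Whether DI should be scaled within each line across experiments (chosen
here) or against absolute SBR anchors is an open convention; the
within-line scaling is the one that makes DI dimensionless per line.

## Classification

The 30-sample external set (15 HV + 15 LV, drawn with a seeded RNG,
cultivar deliberately ignored) is fixed before any model fitting and
shared by both bands. PCA mean-centers (no column autoscaling) and takes
SVD loadings in decreasing-variance order, with the sign convention that
each loading's largest-magnitude entry is positive. PCA is fitted once on
the 90-sample training block and LOO-CV runs in score space; refitting PCA
inside every fold is available via `pca_in_fold=True`. The single-fit
variant is mildly optimistic for model *selection* but touches no
validation data; the external accuracy is unbiased either way.

Classifiers:

- **KNN** — Euclidean, uniform vote over k neighbours; distance ties break
  to the lower training index (stable sort), vote ties to the single
  nearest neighbour's label. Hand-written so these tie rules are explicit.
- **LDA** — pooled-covariance discriminant via scikit-learn; the three
  solver options (svd, lsqr, eigen) are numerical routes to the same
  discriminant and are required by tests to agree.
- **QDA** — Gaussian discriminant with per-class covariance shrunk as
  Σᵣ = (1−r)·Σ̂ + r·(tr Σ̂/p)·I, i.e. toward the average-variance sphere.
  This differs from scikit-learn's `reg_param` (which shrinks toward the
  unscaled identity), so it is implemented directly; scikit-learn QDA at
  r = 0 serves as an independent cross-check in the tests. A singular
  covariance at r = 0 raises with advice to regularize.
- **SVM** — scikit-learn RBF SVC with γ = 1/(p · Var(X)) (`gamma="scale"`)
  and penalty C. The C grid includes 1.0 alongside {0.1, 10, 10², 10³,
  10⁴} because reported best models in this workflow family use C = 1.

Grid search evaluates an explicit leave-one-out loop for every
(n_PCs, hyperparameter) cell — PCs 1–20 crossed with k = 1..45 (KNN),
3 solvers (LDA), r = 0.0..0.5 (QDA; 0.0 included since unregularized QDA
is the commonly reported best), and 6 C values (SVM). Ties between
equally accurate cells resolve to the fewest PCs, then the earliest
hyperparameter in grid order — a stated convention, since equal-accuracy
plateaus are common at this separability. Heat maps are exported as CSV
(rows = PCs, columns = hyperparameter, 4 decimals).

## Orchestration and reproducibility

`run_all` executes simulate → preprocess → split → grid search (all four
algorithms, both bands) → external validation. Stage seeds derive from the
master seed by SHA-256 hashing of the stage name (kept below 2³¹), so
adding a stage never shifts another stage's randomness; identical configs
produce byte-identical CSV/JSON artifacts. Raw replicate CSVs (~1 GB at
default size) are written only by the `simulate` subcommand; `run_all`
keeps them in memory and writes derived artifacts.

## Problem sizes used in the test suite

The unit tests run on a 16-sample, 6-replicate, single-band (250–300 nm)
configuration. The end-to-end checks run the full default study (120
samples × 50 replicates × 2 bands, full grids; about a minute). The
no-signal control uses the default composition at 6 replicates, UV only at
0.1 nm, and a reduced grid (PCs {2, 5, 8}, 2–3 hyperparameter values per
algorithm), pooling external accuracy over 20 seeds per algorithm against
a 99% binomial band around ½ — external accuracy is unbiased under any
training-side model selection, so the reduced grid does not change what
the control certifies. The control switches off *both* the vigor and the
cultivar effect: under the unbalanced composition (HV is two-thirds
Paiaguás, LV two-thirds Marandu) the cultivar signature on the Na/Si lines
alone genuinely predicts vigor at up to 2/3 accuracy, so a
vigor-effect-only null is not a no-signal condition.

## Known limitations

- The generator's class structure is multiplicative and line-local;
  perfect external accuracy on it demonstrates the pipeline's correctness,
  not that real seed lots are this separable.
- The single-pass SAM filter never revisits the reference mean; with very
  high corruption fractions the polluted reference could mask outliers.
- The SBR peak estimator is the window maximum, not an integrated line
  area; for heavily saturated or self-absorbed lines an area estimator
  would be preferable.
- LOO-CV with PCA fitted outside the fold slightly overestimates
  cell-level accuracy; use `pca_in_fold=True` (quadratically slower) when
  unbiased internal estimates matter.
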