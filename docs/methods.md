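# Methods

`evraman` reimplements a single-particle Raman analysis pipeline for
extracellular vesicles (EVs): individual vesicles are optically trapped, a
Raman spectrum is acquired per particle, and the resulting ensembles are
preprocessed, visualized, classified, and decomposed into biomolecular
components.  Because no real per-particle dataset is bundled, every stage is
exercised against a synthetic spectrum generator whose statistical structure
matches the assumptions of the downstream analysis.  This note records the
models, the parameters that matter, and the design decisions taken where the
method left choices open.

## Synthetic single-EV spectra

Each simulated acquisition is

```
I(ν) = a · Σ_c w_c S_c(ν) + b(ν) + PBS(ν) + ε(ν) + spikes
```

* **Component spectra** `S_c`: four non-negative, unit-L2-norm spectra
  (protein, nucleic acid, phosphatidylcholine-like lipid,
  sphingomyelin-like lipid) built from pseudo-Voigt bands (Lorentzian
  fraction 0.5, default FWHM 12 cm⁻¹ — typical condensed-phase Raman
  linewidths) at standard EV band positions: phenylalanine 1004,
  tyrosine/glycan 845/884, amide-III 1256/1337, DNA ring breathing 723,
  PO₂⁻ backbone 1084, lipid C–C 1064 / CH₂ twist 1295 / CH₂ bend 1442, and
  the 989 cm⁻¹ sphingomyelin marker.  Relative band heights are generator
  choices that keep all pairwise cosines below 0.9; the two lipid species
  share three bands and are deliberately the hardest pair (cosine ≈ 0.66).
* **Composition** `w`: per-EV weights drawn from a Dirichlet distribution
  around the class mean with concentration 1000, i.e. a within-class
  compositional spread of ≈ 1.5 percentage points per component.  This
  realizes tight, unimodal per-class compositional distributions, chosen so
  that mean-composition differences of about two percentage points are the
  boundary of class separability — the regime the classification stage is
  designed to probe.  Default class means: noncancer
  (0.35, 0.30, 0.25, 0.10), cancer (0.30, 0.15, 0.40, 0.15) in the order
  above, realizing the orderings the analysis relies on (noncancer richer in
  nucleic acid, poorer in total lipid).
* **Backgrounds**: a smooth per-spectrum quadratic baseline drift
  (amplitude 150 counts, jittered coefficients) and a PBS/water template
  (broad 1640 cm⁻¹ water bending band, weak 980 cm⁻¹ phosphate feature,
  amplitude 120 counts).
* **Noise**: Gaussian with variance affine in the local total count level —
  the shot-noise approximation for CCD detection.  The signal-to-noise
  parameter (peak signal over noise σ at the peak) defaults to 60,
  corresponding to shot-noise-limited detection at a few thousand
  photoelectrons per channel, a realistic 10–20 s trapped-particle regime.
  The value was fixed from a subspace-resolvability analysis: at SNR ≈ 30
  the two weak lipid-contrast directions of the default ensemble fall below
  the SVD noise floor and the four-component structure is not recoverable by
  any method.
* **Cosmic spikes**: Poisson-count single-channel artifacts (default rate
  0.05 per spectrum) with amplitude ≥ 20 × the local noise σ.
* **Axis**: 1024 CCD channels mapped to 600–1800 cm⁻¹ through a mildly
  quadratic pixel→wavenumber map, so channel spacing varies ≈ 1.07–1.28
  cm⁻¹ across the detector.  This exercises the varying channels-per-bin
  correction in the binned visualization.

What the generator does **not** emulate: trapping-physics effects (size- or
position-dependent signal), wavenumber-calibration error, detector etaloning,
multimodal within-class composition, or inter-batch drift beyond seed
variation.  Green tests therefore demonstrate correctness of the analysis
chain under its own assumptions, not performance on real instrument data.

## Preprocessing chain

Order: cosmic-spike removal → relative-intensity response correction →
min/max post-thresholding → subtraction of 95 % of the averaged PBS
reference → fingerprint crop → Whittaker baseline subtraction →
first-order Savitzky–Golay smoothing (frame 7) → area normalization.

* **Spike removal** flags channels where both the deviation from a
  9-channel rolling median and the second difference exceed 8 robust σ
  (MAD-based), then linearly interpolates flagged channels from unflagged
  neighbors.  The thresholds are configurable; 8σ is conservative enough
  that realistic band curvature never triggers it.  The robust σ carries a
  tiny relative floor; on *exactly* noiseless band spectra the MAD of the
  median residual vanishes and band tops would be flagged, so the identity
  contract applies to realistic (noise-carrying or band-free) spectra.
* **Whittaker baseline**: asymmetric least squares with a second-difference
  penalty — minimize `Σ w_i (y_i − z_i)² + λ Σ (Δ²z)²` with `w_i = p` above
  the baseline and `1 − p` below, iterated until the weight pattern is
  stable.  The binary weights can enter a limit cycle at channels straddling
  the baseline; a repeated pattern is accepted as converged since further
  iteration adds no information.  Defaults λ = 10⁴, p = 10⁻⁴ (the values
  used in the entropy-minimization branch, the only ones stated); genuinely
  non-convergent runs raise with the iteration count.
* **Savitzky–Golay**: interior channels use the standard window-centered
  least-squares polynomial (first order, frame 7); edges use a symmetrically
  shrunk window down to a single channel, avoiding padding artifacts.
* **Area normalization** integrates by trapezoid over the *wavenumber* axis
  (the channel axis is nonuniform).
* PBS references are response-corrected identically before averaging;
  matching references per isolation batch and integration time is the
  caller's responsibility.
* Intensity post-thresholding (background-only traps, aggregates) operates
  on the per-spectrum maximum and is always a manual configuration, never
  auto-chosen.

## Dimensional reduction arrays (DRA)

Mean intensity per fixed-width wavenumber bin (default block 50 cm⁻¹), rows
either class means (mean over spectra, then over channels in the bin) or
individual spectra.  Bins are half-open, anchored at the low range edge,
with a partial final bin closed at the high edge so coverage is total.
Channels are assigned to bins by wavenumber, so bins carry different channel
counts on the nonlinear axis; cell values are means over assigned channels,
which corrects for that mismatch.  Empty bins are flagged missing (never
zero, which would distort the min/max color scale).  Rendering requires a
perceptually uniform colormap (viridis family); rainbow-style gradients are
rejected unless explicitly overridden.  Whether class rows are built from
normalized or raw means is a caller choice; the workflow uses post-pipeline
(normalized) spectra.

## PLS-DA classification

PLS2 on one-hot class indicators via SIMPLS with mean centering only (no
variance scaling).  Class assignment is argmax over predicted indicators.
The X-block variance captured per latent variable is reported;
cross-validation is venetian blinds (fold k holds out samples with index ≡ k
mod splits, dataset order, no shuffle — an explicit seeded pre-shuffle is
available), default 10 splits, model refit per fold, one-vs-rest
sensitivity/specificity pooled over folds.  Folds are not stratified by
subclass.  Defaults: 3 latent variables for the two-class study, 7 for
many-class panels.

Outlier exclusion computes per-sample Q residuals (squared distance off the
LV subspace; 95 % limit by moment-matched χ²) and Hotelling T² (leverage in
the subspace; 95 % F-distribution limit).  A sample is excluded only when
**both** statistics exceed their limits — single-statistic exclusion removes
an order of magnitude more samples than the small fractions this method
family reports — and the model is refit on the survivors.  One caveat of
the joint rule: a single sample extreme enough to dominate the training
variance can capture a latent variable of its own, which drives its Q
residual toward zero and lets it evade exclusion even though its T² is
enormous.  Moderate outliers (a few times the typical amplitude) are
flagged reliably; guarding against pathological single samples is the job
of the intensity post-thresholding step upstream.  ROC curves use the
continuous predicted indicators one-vs-rest with trapezoid AUC and a macro
average.

## Band-target entropy minimization (BTEM)

Self-modeling curve resolution for ensembles without spatial structure
(every trapped particle is a singleton mixture, so simplex-maximization
methods do not apply).  The pooled, batch-preprocessed matrix (standard
chain with the λ = 10⁴ / p = 10⁻⁴ baseline removal, no area normalization;
spectra unit-length normalized) is decomposed by SVD; a candidate pure
spectrum is `ŝ = Σ t_j v_j` over the first k right singular vectors (k = 10;
25 for the nucleic-acid target, which needs deeper basis coverage).  The
objective, following the classical BTEM construction, is the Shannon entropy
of the normalized absolute first derivative of ŝ (rescaled so its maximum
over the band-target window is 1) plus a quadratic penalty on negative
excursions and a large constant when the global maximum leaves the window.

* **Negativity penalty weight**: default 400, calibrated on synthetic
  ensembles with known components.  Much larger weights make any candidate
  carrying the basis's inevitable noise ripples costlier than a featureless
  positive blob (no component is ever recovered); much smaller ones let the
  minimizer sharpen multi-band spectra by cross-component cancellation.
* **Optimization**: simulated annealing over the rotation coefficients on
  the unit sphere (the objective is scale-invariant), 200 epochs × 50 moves,
  exponential cooling 0.95/epoch, proposal σ annealed 0.5 → 0.02 with
  temperature, initial temperature from the objective spread over 50
  perturbed draws.  Each restart starts from a pseudorandom perturbation of
  the subspace projection of a unit impulse at the band-target center, so
  the walk begins inside the feasible basin; proposals whose global maximum
  leaves the window are rejected.  Ten restarts per target (seeds derived
  from the master seed by restart index, so nested restart sets share their
  leading runs); each endpoint is polished by deterministic Nelder–Mead and
  the lowest-objective run is reported.  Output spectra are clipped at zero
  and unit-normalized.
* Default band-target windows: protein 1004 ± 10, nucleic acid 723 ± 10,
  phosphatidylcholine-like 1442 ± 15, sphingomyelin-like 989 ± 10 cm⁻¹.

**Known limitation.**  Recovery quality is bounded by the overlap structure
of the ensemble: the sphingomyelin-like component shares three of its four
bands with the phosphatidylcholine-like component and contributes the least
compositional variance, so its entropy minimum is a slightly mean-diluted
version of the true spectrum (cosine ≈ 0.93–0.96 against ground truth under
the default conditions, versus ≥ 0.95–0.99 for the other three).  This
instability of the sphingomyelin-like recovery is intrinsic to the
functional under realistic noise, not an optimizer artifact.  The
nucleic-acid recovery, which uses the deeper 25-vector basis, is similarly
realization-dependent: on most data realizations it reaches cosine
0.95–0.99, but the 21 noise-dominated basis vectors occasionally admit a
sharper non-truth minimum on an unlucky ensemble.

## Convex-mixing abundances

Each unit-length spectrum is modeled as a non-negative, sum-to-one
combination of the unit-length component spectra.  Because the L2 norm of a
convex mixture of unit vectors is below one, a unit-normalized spectrum is a
*scaled* convex combination; fitting the sum-to-one model directly to it
biases weights toward the uniform point.  The solver therefore first rescales
each spectrum onto the affine hull of the components (divide by the sum of
its unconstrained least-squares coefficients), then solves the constrained
problem by augmented-row NNLS (row weight 10⁴ × max|C|) with exact
renormalization onto the simplex.  On clean convex mixtures this recovers
the generating weights to ~10⁻⁶; on the default synthetic ensemble the
residual error (~0.02 RMSE even with the true components) is dominated by
the 5 % PBS remnant that the 95 % subtraction rule leaves in every spectrum
and by the asymmetric baseline's clipping of band tails — systematic
contributions the convex model cannot absorb.  Fit residuals are recorded
but never used to reject spectra.  Class summaries report mean weights (pie
charts) and median/quartile/1.5 × IQR whisker statistics (violin plots).

## Workflow, seeds, determinism

The umbrella workflow (simulate or ingest → preprocess → DRA → PLS-DA fit
on batch I, predict batch II → BTEM on pooled batch I → abundances) is
driven by one YAML document with strict schema validation (unknown keys
rejected).  A single master seed generates per-stage seeds by SHA-256 of
`"{seed}:{stage}"` (31-bit), so stages are reproducible independently.  All
artifacts embed the configuration hash and stage seed; bundles are written
as deterministic `.npz` containers, and a manifest of SHA-256 hashes makes
bit-identical reruns checkable.

## Problem sizes used in validation

The bundled studies run at desk scale, chosen as the smallest sizes at which
the statistical properties under test are stable: 300 spectra per class per
isolation batch for the classification study, 600 per class (1200 pooled)
for the unmixing study, 200 PBS references, and a 2 × 60 × 2-batch demo for
the end-to-end workflow.  The original experimental design this emulates
pooled thousands of spectra per condition.
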