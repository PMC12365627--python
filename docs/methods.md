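# Methods

## Scope

`evspec` models the computational chain of a label-free EV diagnostic:
size-exclusion fractionation of plasma-derived extracellular vesicles,
Raman fingerprint acquisition, spectral cleanup, supervised
self-organizing-map classification with discriminant-index feature
extraction, spectral barcoding, and diagnostic-performance evaluation.
No instrument data ships with the package; a synthetic generator supplies
spectra and particle populations with the statistical structure such
studies describe, so every stage is testable end to end.

## Synthetic spectra

A spectrum is a sum of Gaussian bands on the 700–1700 cm⁻¹ axis
(1 cm⁻¹ grid, 1001 points), degraded by acquisition artifacts:

    I(ν) = s · [ Σ_b A_b exp(−(ν − ν_b)²/2σ_b²) + p(ν) ] + ε(ν) + cosmic(ν)

* **Bands.** Centers follow the dominant biological assignments of the
  fingerprint region (nucleic acids 752/785, tyrosine 851,
  phosphatidylcholine 882, polysaccharide 960, phenylalanine 1003, lipids
  1124/1144, glycine backbone 1341, lipid+protein 1440, tryptophan 1553,
  Amide I/lipid 1656 cm⁻¹, …).  FWHM defaults to 12 cm⁻¹, a typical
  biological Raman bandwidth.  Base amplitudes (healthy raw plasma,
  arbitrary units) are generator knobs: 1.0 at 1440/1656, 0.9 at 1003,
  0.7 at 1341, 0.6 at 960/1124/1307, 0.5 at 752/851/882/1131/1553, 0.4
  elsewhere.
* **Fraction structure.** Lipid/protein bands (1124, 1440, 1656) scale
  1.0 / 0.8 / 0.65 / 0.5 for raw / large / mid / small — EV fractions
  carry less lipid and protein than whole plasma, small EVs least.  The
  phosphatidylcholine (882) and tryptophan (1553) bands are enriched ×1.4
  in every EV fraction; the glycine-backbone band (1341) ×1.5 in small
  EVs only.
* **Disease structure.** The CVD state multiplies the discriminant bands
  by fixed factors inside the 17–68 % band adopted as the disease effect
  size —
  752 ×1.30, 851 ×1.40, 960 ×1.50, 1144 ×1.25, 1440 ×1.20, 1656 ×1.35 —
  plus 1003 ×1.40 in small EVs only, and decreases tryptophan 1553 ×0.80
  in every fraction.
* **Artifacts.** Per-spectrum log-normal multiplicative scatter
  (σ = 0.10), a random quadratic baseline (coefficient SDs 0.1 / 10⁻⁴ /
  10⁻⁷ for constant / linear / quadratic terms in cm⁻¹ units), additive
  Gaussian noise (SD = 2 % of the largest band amplitude), and
  Poisson(0.2) cosmic-ray spikes of 5–20× the largest amplitude.  The
  within-class dispersion of real clinical spectra is not available to
  calibrate against; these defaults are chosen once as plausible
  bench-top values and define the study conditions for all benchmarks.
* **Reproducibility.** One root seed; spectrum *i* of a run draws from
  the child stream `SeedSequence([seed, i])`, so the first *k* spectra
  are invariant to the total number requested.

Passing tests on this generator demonstrates that the pipeline recovers
structure of this kind at realistic noise; it does not demonstrate
clinical performance.  In particular the generator has no
patient-level random effects, no instrument drift, no wavenumber
miscalibration, and its class differences are exactly the multiplier
tables above.

## Particle populations and the membrane cascade

EV sizes are truncated normals (small 61±23 nm floored at 30 nm, mid
189±84 nm, large 432±143 nm); a truncated normal rather than a lognormal
keeps the nominal mean/SD directly interpretable as distribution
parameters.  The bead panel uses the seven nominal sizes 40, 100, 200,
450, 500, 1000, 5000 nm with zero dispersion by default.

The cascade routes each particle top-down through the 5000 / 500 / 200 /
100 / 40 nm membranes; it is trapped at the first membrane with
diameter ≥ pore (so a 40 nm bead is caught by the 40 nm membrane), else
reaches the eluate.  Expected wells for the bead panel are computed by
applying that same rule to the nominal sizes, so generator and router
cannot disagree.  Separation efficiency is an ambiguous quantity (a
ratio of totals across membranes to a single membrane's count reads
≥ 1), so the report carries two well-defined readings:
`routing_accuracy` — the global fraction of particles found in their
expected well — and `well_purity` — per-well purity averaged over
occupied wells.  The benchmark uses the routing-accuracy reading.  A
per-membrane leak probability (default 0) is available for sensitivity
studies; no fluid dynamics or clogging is modeled.

## Preprocessing

Fixed order: **despike → baseline → (replicate averaging) → SNV**.
Despiking precedes the baseline fit because a cosmic spike biases the
polynomial; SNV comes last so it normalizes the cleaned signal.
Averaging-then-SNV (rather than the reverse) is the package's choice
where the order is underdetermined.

* **Despike:** a point is replaced by the running median (window 7) when
  its residual exceeds z = 8 × a robust scale (1.4826 × MAD of the
  residuals, floored at 1 % of the spectrum's peak-to-peak range).  The
  floor prevents band curvature from firing the test on noiseless
  spectra; it matters only when the MAD is degenerate.
* **Baseline:** iterative peak-clipping polynomial fit, degree 5, 30
  iterations (work signal clipped to min(signal, fit) each round).
  Degree and iteration count follow common fingerprint-region practice;
  degree 2 removes a pure quadratic exactly and preserves injected peak
  heights to within 5 %.
* **Averaging:** positional mean over consecutive groups of g spectra
  (map-location replicates); the group count must divide the row count.
* **SNV:** (x − mean)/SD with the n−1 sample SD (stated because it
  changes small-vector examples); idempotent and affine-invariant.

## SKiNET

* **Lattice:** hexagonal, 10 × 10 by default; offset rows at half-cell
  shift, row spacing √3/2, neighbor distance = Euclidean distance between
  hexagon centres.
* **Initialization:** spectral weights uniform in the per-variable data
  range ([−1, 1] when no data given); class weights uniform 1/K.
* **Training:** `steps = epochs × |train|` presentations (4 epochs
  default) cycling a seed-shuffled order.  At step t with BMU b:
  `W_i += η(t) h_i (x − W_i)` and `C_i += η(t) h_i (y − C_i)` with one-hot
  y, Gaussian neighborhood `h_i = exp(−d²(i,b)/2σ(t)²)`,
  `η(t) = η₀ e^(−t/steps)` (η₀ = 0.1), and
  `σ(t) = σ₀ e^(−t·ln σ₀/steps)` with σ₀ = max(rows, cols)/2, decaying to
  1 at the end of training (held constant when σ₀ ≤ 1, e.g. tiny grids).
  Exponential decay is the standard Kohonen schedule and is the
  package's choice where the procedure leaves it open.  The supervised step
  is exactly this joint C-update plus modal-class neuron labeling — no
  separate fine-tuning pass.  A constant-η option exists; with it a 1×1
  grid provably converges to the training mean (regression-tested).
* **Classification:** BMU on spectral weights only; score = BMU's class
  weights normalized to sum 1; argmax wins, ties to the lower class
  index; an all-zero class vector (impossible under default
  initialization) falls back to the nearest neuron with class mass.
* **SOMDI:** `S_k = Σ_i C_{ik}(W_i − W̄)`, rectified at 0, normalized to
  max 1.  This measures each wavenumber's contribution to a class as a
  class-weighted deviation of neuron prototypes from the lattice mean; peaks (minimum separation 5 grid points, to stop noise ripple on
  one band occupying several ranked slots) give the ranked wavenumbers.
* **Splits:** stratified 80:20 hold-out and stratified k-fold CV
  (round-robin within shuffled classes), both seeded.  Splitting is
  per-spectrum; a per-patient option is not modeled because the
  generator has no patient effects.
* **Model selection:** grid of (grid size, η₀, steps); ties resolve to
  the smaller grid, then fewer steps.

## Barcoding

Savitzky–Golay second derivative (window 21 points, polynomial order 2,
edges by polynomial extrapolation of the terminal windows), then
`bit[i] = 1 ⟺ |d_i| > 0.40 · max|d|`.  The threshold is applied to the
full derivative vector of the given (usually class-mean) spectrum; a
peak-local mode (bits only at local extrema of |d|) is available for
sparse tick-mark barcodes.  The absolute value means both the central
trough of a band and strong flanks can fire.  The barcode is invariant
to positive scaling and to SNV, and raising the threshold can only turn
bits off.

## Evaluation

Sensitivity TP/(TP+FN), specificity TN/(TN+FP), PPV, NPV and accuracy as
exact ratios; zero-denominator metrics are flagged `None`, not raised.
The Mann–Whitney U test uses midranks; p is exact by enumeration of all
rank splits for pooled n ≤ 10 (valid under ties since values, not ranks,
are permuted) and otherwise a tie-corrected normal approximation with
continuity correction.  ROC curves sweep the unique scores, are anchored
at (0,0) and (1,1), use trapezoid AUC (equal to U/(n₁n₂) on tie-free
data, asserted in tests), and a Hanley–McNeil normal 95 % CI.  Band
reports take the mean intensity in a ±4 cm⁻¹ window (the integration
rule is otherwise unspecified) and apply Benjamini–Hochberg control at
0.05 across bands — switchable off to mirror per-band-only reporting.
The classifier's ROC score is the BMU's normalized CVD class weight.

## Benchmark problem sizes

The reference experiments use 200 healthy spectra per fraction for the
4-class subgroup task and 100 + 100 spectra per healthy-vs-CVD
comparison (40 held-out spectra per run), 1000 beads per nominal size,
and the default 10×10/4-epoch SOM — sizes chosen so each experiment
completes in seconds on one CPU while keeping hold-out estimates stable.
`scripts/acceptance.py` reruns them all from scratch under a single seed.

## Known limitations

* Synthetic class structure is exactly the multiplier tables; real
  biological variance, patient effects and instrument drift are absent,
  so benchmark accuracies are upper-bound demonstrations of pipeline
  correctness, not clinical estimates.
* The cascade is ideal (no leakage, adsorption, clogging or throughput
  modeling); the efficiency statistic therefore saturates at 100 % for
  the zero-dispersion bead panel.
* SOMDI admits more than one formalization; the class-weighted deviation
  construction here is one documented realization.
* No wavenumber calibration/alignment and no vendor binary readers; all
  I/O is plain CSV/JSON/YAML.
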