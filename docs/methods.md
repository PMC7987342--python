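# Methods

`kinemap` implements the downstream numerical analysis of a pump–probe study
of a channelrhodopsin (the C1C2 chimera): difference Fourier maps and
extrapolated structure factors from time-resolved serial crystallography,
SVD/global-fit analysis of transient absorption spectra, and laser-flash
photocurrent processing.  The deposited experimental data are not required;
a synthetic-data module generates every input with known ground truth, so
each stage is validated as a parameter-recovery problem.

## Crystallographic conventions

* **Space group P1 throughout.**  Every implemented equation (structure
  factors, Fourier synthesis, scaling, extrapolation) is symmetry-agnostic;
  symmetry expansion is out of scope by design.
* Coordinates are stored fractionally; orthogonalization follows the PDB
  CRYST1 convention (*a* along *x*, *b* in the *xy* plane).
* Scattering variable `s = 1/d`; Debye–Waller factor `exp(−B·s²/4)`; atomic
  form factors `f(s) = Σᵢ aᵢ·exp(−bᵢ·s²/4) + c` with bundled 4-Gaussian
  coefficients for C, N, O, S (`f(0)` reproduces the electron count to
  <0.1%).  Elements without coefficients fall back to a constant `f = Z`
  with a warning.
* Calculated structure factors use **direct summation**
  `F(h) = Σⱼ occⱼ·fⱼ(s)·exp(−Bⱼs²/4)·exp(2πi h·xⱼ)`.  Toy models have ≤100
  atoms, so the O(atoms × reflections) cost is negligible and the direct sum
  doubles as the package's ground truth.  No bulk solvent, no anomalous
  scattering.

## Map synthesis

`ρ(x) = (1/V)·Σ_h F(h)·exp(−2πi h·x)` is evaluated by FFT after placing
coefficients on the reciprocal grid (Friedel mates completed by conjugation;
`F(000) = 0` unless supplied — difference and extrapolated maps carry only
contrast).  The grid uses the smallest even dimensions with spacing
≤ d_min/3, the standard oversampling for peak location, enlarged if needed
so no coefficient aliases.  A naive direct-summation path with the identical
contract is kept as the independent oracle; the two agree to ≤1e−6 relative
error on random coefficient sets (tested), and Parseval's identity closes to
1e−4.

σ-scaling subtracts the mean and divides by the rms over the full cell (P1;
there is no meaningful asymmetric-unit restriction here).  Peak search is a
26-neighbour local-extremum test on the periodic grid without interpolation,
sorted by |height| with lexicographic grid-index tie-break; peaks are
annotated with the nearest model atom under the minimum-image convention.
The display contour default is ±3.0σ and is configuration, not a constant
baked into any computation.

## Scaling light onto dark

Before differencing, the light amplitudes are placed on the dark scale with
the isotropic model `F_dark ≈ k·exp(−B_rel·s²/4)·F_light`, fit by weighted
least squares (weights `1/(σ_d²+σ_l²)`, unit weights when σ are absent) with
a log-linear seed.  Anisotropic and resolution-bin-local scaling are
deliberate non-goals; if the common reflections span a single resolution
shell, `B_rel` is indeterminate and fixed at 0 with a warning.

## Extrapolated structure factors and the activation-ratio scan

With only a fraction R of molecules photoactivated, the light data are a
partial-occupancy mixture.  The linear extrapolation

    F_extra = (F_o^light − F_o^dark)/R + F_o^dark

approximates the pure activated-state amplitudes.  Errors propagate linearly:
`σ_extra² = σ_light²/R² + (1−1/R)²·σ_dark²` (monotonically non-increasing in
R).  Negative extrapolated amplitudes are **kept**, counted and reported —
truncation would silently bias every downstream map.

R is estimated by the feature-disappearance scan: R runs from 1.0 downward
in steps of 0.01; at each step the extrapolated map with dark calculated
phases is synthesized and σ-scaled, and the density at a probe site is read;
the estimate is the largest R at which the probe feature has disappeared
(first-crossing rule).  Because map synthesis is linear in its coefficients
and F_extra is affine in 1/R, the whole scan is computed from two FFTs
(`ρ(R) = ρ_base + ρ_diff/R`, with mean/σ statistics in closed form); the
equivalence with per-R synthesis is asserted by a test.

Three quantification choices deserve explanation, because the source
procedure — "lower R until the dark-state feature disappears" — leaves them
open:

1. **Which map.**  A map whose amplitudes come from data but whose phases
   come from a model shows density *changes* at half weight (the classic
   difference-Fourier factor ½).  In the plain extrapolated map the dark
   feature therefore vanishes near R_true/2, not R_true (we measure ≈0.10
   for a 0.30 mixture).  The scan consequently judges feature presence in
   the 2Fo−Fc-style map (coefficients `2·F_extra − |Fc_dark|`, dark phases),
   which restores full weight and is the map type actually inspected when
   deciding whether a feature is present.  The plain map remains available
   (`feature_map="extra"`).
2. **Where to probe.**  At the centre of a sub-Å-shifted atom the displaced
   atom still contributes most of its density (a 0.6 Å shift against atomic
   widths of 0.5–0.8 Å), so no feature can vanish there.  The probe
   convention (`suggest_probe_site`) anchors at the dark-model atom nearest
   the strongest negative Fo−Fo difference peak and offsets 1.25 Å *against*
   the motion direction (the negative-minus-positive peak axis), onto the
   far edge of the lobe the atom genuinely vacates.  A scan is well-posed
   only if the probe feature is clearly present at R=1 (≥3σ, the usual
   significance contour); otherwise `estimate_activation_ratio` moves along
   the lobe (offsets 1.0, 1.5, 0.75 Å) and retries — the automated version
   of what an analyst does when a feature is propped up by neighbouring
   density.
3. **Disappearance threshold.**  Even when the feature is gone, a residual
   background of Fourier-truncation ripple, neighbouring-atom tails and the
   moved atom's own overlap remains at the probe.  The default threshold of
   2.0σ matches that typical residual; it was calibrated once against the
   synthetic generator's known R and then frozen.  Scanning to a lower
   cutoff systematically underestimates R.  The threshold is exposed in the
   API and CLI.

**Accuracy.**  On the toy conditions (15-atom P1 cell, one sulfur shifted
0.6 Å, B ∈ [10, 40] Å², 1.8 Å data), single replicates scatter with σ ≈ 0.08
around the generating ratio — the probe's local background varies with the
random B-factor and environment, and this is physics of the method, not
noise that averaging within one data set could remove.  The replicate
*ensemble* is unbiased: 10-seed means land within ±0.05 of truth for
noiseless data and ±0.10 at 5% amplitude noise, and track R_true across
0.2–0.5.  The acceptance suite asserts exactly this ensemble property.

## Synthetic generators

* **Toy crystal pair** — random non-clashing atoms (≥2 Å separation,
  C/N/O mix plus one sulfur emulating a cysteine Sγ), occupancy 1,
  B ∈ [10, 40] Å², in a 20×18×16 Å, β=96° P1 cell; the light model rigidly
  shifts selected atoms (default: the sulfur by 0.6 Å).  Deterministic under
  a seed.
* **Mixed observed amplitudes** — light observations are
  `|(1−R)·Fc_dark + R·Fc_light|`: the mixing is **complex-valued** (a
  partial-occupancy superposition of scatterers) while the extrapolation
  formula operates on amplitudes.  This deliberate mismatch is exactly the
  linear-approximation regime the formula assumes; at R_true the
  extrapolated amplitudes recover |Fc_light| with a median relative error
  ≈0.07 (frozen test bound 0.10).  Gaussian amplitude noise is drawn per
  Friedel *pair* and mirrored — merged data carry one amplitude per unique
  reflection, and independent mate noise would break Friedel symmetry.
* **Photocycle spectra** — sequential kinetics ground →(flash, fraction φ)
  P1 →(k₂) P2 →(k₃) P3, solved analytically (concentrations sum to φ at all
  t; the P2 maximum sits at `ln(k₂/k₃)/(k₂−k₃)`).  Species are Gaussian
  absorption bands: P1 and P3 at 520 nm, P2 at 390 nm, ground at 470 nm.
  Because P1 and P3 are spectrally identical the default matrix has rank 2 —
  matching the two-component reconstruction seen for this photochemistry —
  and the two apparent time constants are 1/k₂ and 1/k₃.  Defaults
  1/k₂ = 0.5 ms and 1/k₃ = 5 ms put the blue-shifted intermediate's rise in
  the hundreds-of-microseconds range and its decay in the milliseconds; the
  excited fraction defaults to φ = 0.30, the low quantum efficiency of
  retinal isomerisation in this chimera.
* **Photocurrents** — each trace is a voltage-independent fast
  charge-transfer transient plus a passive component proportional to the
  driving force (V − V_rev) with a single-exponential rise (default 100 µs)
  and biexponential decay (defaults 20 ms and 100 ms, 1:1).  At V = V_rev
  only the charge transfer remains — the same logic by which the 0 mV
  recording isolates intra-protein charge movement.

What the generators do *not* emulate: detector/jet noise structure, partial
and incomplete reflection observations, radiation damage, spectral baseline
drift, instrument response functions, or cell-to-cell variability in
electrophysiology.  Passing tests therefore demonstrate the correctness and
calibration of the *analysis* under the stated statistical model, not
robustness to every artifact of real data.

## Spectroscopy analysis

`ΔA = −log₁₀(I_after/I_before)` (decadic; positive ΔA = increased
absorption).  The ΔA(λ,t) matrix is decomposed with a full SVD; the number
of significant components is the count of singular values above the noise
floor `σ_noise·(√m + √n)` — the bulk edge where the largest singular value
of an i.i.d. noise matrix concentrates (a floor of `σ·√max(m,n)` would sit
*inside* the noise bulk and overcount).  Manual override is always possible.
Reconstruction from the leading k components strips random noise below the
generator's σ (tested).

The global fit uses **variable projection**: the nonlinear search runs only
over log τ (shared across wavelengths); at each evaluation the
decay-associated spectra — and an optional non-decaying offset spectrum,
default on, for a non-decaying photoproduct — are the exact linear
least-squares solution for all wavelengths at once.  Exponential-sum fitting
is multimodal, so the search multi-starts from log-spaced τ grids over the
observed time span with deterministic jitter; the best start wins.
Near-degenerate time constants (within 1%) trigger a warning that n_exp may
exceed the identifiable components.  The fit agrees with an
all-parameters-free nonlinear solve to 0.1% on noiseless data and recovers
constants separated 100× within 5% at SNR 100 (tested).

## Photocurrent processing

Order of operations: baseline subtraction and trigger alignment →
logarithmic binning (default **50 bins per temporal decade**, arithmetic
mean per bin, empty bins dropped with their count recorded, `t_start`
defaulting to the first positive sample since a log axis needs t > 0) →
normalisation of each cell's traces to the absolute peak of its −60 mV
reference trace → averaging over repetitions.  Binning before normalisation
is the package's documented choice (the peak of a binned trace is the
statistic a figure displays); normalisation is idempotent and
scale-invariant either way.  Passive currents are the pointwise difference
`I_V − I_0mV` (resampled to the coarser time axis on the overlap when axes
differ), which cancels common-mode components exactly.  The decay fit
`A_f·e^(−t/τ_f) + A_s·e^(−t/τ_s)` reuses the variable-projection engine on
one trace, times measured from the window start for conditioning; fits with
τ_slow/τ_fast < 1.2 or a negligible amplitude are flagged degenerate
(effectively single-exponential).

## Experiment-design arithmetic

Pure unit conversions, exact up to rounding: jet linear speed (volumetric
rate / nozzle cross-section), pump separation (speed / repetition rate),
pump fluence (pulse energy / beam area, in nJ/µm² — per *area*; a per-length
figure is dimensionally inconsistent), and reconstitution lipid
concentration (protein concentration × lipid:protein molar ratio).  Full
precision is returned; display rounds to 2 significant figures.

## Problem sizes and numerical hygiene

Analyses and tests run on desk-scale problems: ~4,000 reflections to 1.8 Å
in a ~5,800 ų cell (maps ≈ 34×30×28), 71×60 spectral matrices, and
photocurrent traces of ~4,200 samples; recovery suites use 10 replicate
seeds.  These sizes were chosen so the complete validation cycle runs in
seconds while every estimator operates far from small-sample degeneracy.
All stochastic paths take explicit integer seeds; reruns are bitwise
reproducible (the demo report is tested for this).  CCP4/MRC map I/O (mode
2) and mmCIF structure-factor parsing go through gemmi; the minimal PDB
reader/writer is hand-written to give line-numbered parse errors, and is
cross-checked against gemmi in the tests.

## Known limitations

* P1 only; no symmetry, no anisotropic B, no alternate conformers.
* Isotropic k/B scaling only; whether anisotropic scaling would be more
  faithful to the original processing cannot be determined from the source
  description, and is flagged rather than guessed.
* The activation-ratio estimate from a single data set inherits the ±0.08
  replicate scatter discussed above; treat a lone value as indicative and
  prefer replicate ensembles.
* The extrapolation is the first-order linear approximation; it degrades as
  the light-minus-dark differences grow beyond the small-difference regime.
* The kinetic model is a sum of exponentials (apparent time constants), not
  a branched target scheme; rate constants of a specific mechanism must be
  derived from the apparent constants separately.
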