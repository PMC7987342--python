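# kinemap

Downstream analysis for time-resolved pump–probe studies of channelrhodopsin
(and similar photoreceptor systems): difference Fourier maps and extrapolated
structure factors from serial crystallography, SVD + global kinetic fitting
of transient absorption spectra, and laser-flash photocurrent processing.
Every input can be generated synthetically with known ground truth, so the
whole pipeline is testable as a parameter-recovery problem — no deposited
experimental data required.

## Who this is for

Structural biologists and biophysicists who have (or want to prototype
against) three kinds of time-resolved data from a light-activated membrane
protein:

1. **Crystallography** — dark and light observed amplitude sets plus a
   refined dark model, from which the package computes Fo−Fo difference
   maps `(F_o^light − F_o^dark)·exp(iΦ_calc)`, searches them for the paired
   negative/positive peaks that betray atomic motion, and determines the
   activation ratio R by the extrapolation scan: lower R in steps of 0.01
   in `F_extra = (F_o^light − F_o^dark)/R + F_o^dark` until a dark-state
   feature disappears from the extrapolated map.
2. **Spectroscopy** — a ΔA(λ, t) matrix, decomposed as `A = U S Vᵀ` to count
   significant components, denoised by low-rank reconstruction, and fitted
   globally with exponentials whose time constants τᵢ are shared across all
   wavelengths (variable projection), yielding decay-associated spectra.
3. **Electrophysiology** — flash-evoked photocurrents, baseline-corrected,
   log-binned (50 points per temporal decade), normalised to the −60 mV
   peak, with passive currents isolated by subtracting the 0 mV trace and
   their biexponential decay fitted.

A small `experiment_geometry` module recomputes the pump–probe design
numbers (jet speed, pump separation, fluence, reconstitution concentrations).

## Worked example

The repository is organised as an analysis: numbered drivers under
`analysis/` run the package end to end on synthetic data and write their
tables under `results/`.

```bash
python analysis/01_simulate_inputs.py --seed 1
python analysis/02_difference_maps.py
python analysis/03_activation_ratio.py
```

prints

```
crystal pair: 15 atoms, S15 shifted 0.6 A; 4072 reflections to 1.8 A at R_true=0.3, 5% amplitude noise
...
scaling: k=0.9963, B_rel=-0.79 A^2 over 4072 reflections (weighted RMS 1.053)
26 peaks at |3.0| sigma (11 negative, 15 positive)
strongest pair: -14.4 sigma near S15 (0.27 A) / +24.1 sigma near S15 (1.01 A) — the paired -/+ signature of the imposed sulfur shift
activation ratio R = 0.17 (criterion: |height| < 2.0 sigma at probe (0.46, 0.511, 0.753); 730 negative extrapolated amplitudes retained)
note: single replicates scatter by ~0.08 around the generating ratio ...
```

Reading this: the generator moved one sulfur atom by 0.6 Å in 30% of the
molecules.  The difference map shows the classic signature — density leaving
the dark position (−14.4σ at the sulfur) and appearing along the shift
(+24.1σ, 1.0 Å away).  The disappearance scan then estimates the activated
fraction; a single replicate scatters around the true 0.30 (here 0.17), and
the replicate ensemble is unbiased (see `docs/methods.md` for why, and
`scripts/acceptance.py` for the 10-replicate mean).  Continuing,

```bash
python analysis/04_spectra_global_fit.py
python analysis/05_photocurrents.py
python analysis/06_geometry_worked_values.py
```

```
singular values: [7.664 2.843 0.031 0.03  0.029] ... -> 2 significant components
global fit apparent time constants: 0.499 ms, 5.012 ms (rms residual 2.94e-04)
passive current decay: tau_fast = 19.7 ms, tau_slow = 98.9 ms, amplitude ratio 0.90
jet speed (2.5 ul/min, 75 um nozzle): 9.431 -> 9.4 mm/s
pump separation (9.4 mm/s, 15 Hz): 626.7 -> 630 um
pump fluence (15 uJ, 300 um beam): 0.2122 -> 0.21 nJ/um^2
lipid conc (5 uM protein, 1:50): 250 -> 250 uM
```

The spectral matrix is rank 2 (the first and third intermediates absorb at
the same wavelength), and the global fit recovers the generating lifetimes
0.5 ms and 5 ms; the passive photocurrent's biexponential decay recovers
20 ms / 100 ms at 1:1 amplitudes.

The same pipeline is available as a console tool:

```bash
kinemap demo --seed 1 --out demo_out/          # end-to-end, writes report.json
kinemap diffmap --light L.hkl --dark D.hkl --model dark.pdb --dmin 2.5 \
        -o diff.ccp4 --peaks peaks.tsv
kinemap extrapolate --light L.hkl --dark D.hkl --model dark.pdb --dmin 2.5 \
        -o extra.hkl --trace trace.tsv
kinemap svdfit --matrix dA.csv --rank auto --nexp 2 -o fit.json
kinemap geometry speed 2.5 75
```

## File formats

PDB (CRYST1 + ATOM/HETATM, P1) for models; plain-text reflection lists with
header `h k l F sigF` (mmCIF structure-factor dialect also read); CCP4/MRC
mode-2 maps; CSV for spectra (first row times in s, first column wavelengths
in nm) and photocurrent traces (`time_s,current_pA,voltage_mV,pH`).

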