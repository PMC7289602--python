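# axlsfcs — axial line-scanning FCS for membrane ligand–receptor binding

`axlsfcs` measures how strongly a fluorescently labeled ligand binds a
cell-surface receptor, directly on a (simulated or recorded) membrane, by
dual-color fluorescence correlation spectroscopy with ultra-fast **axial**
line scanning: a resonant acoustic-gradient lens sweeps the confocal focus
through the membrane at ~147 kHz, so membrane movement no longer corrupts the
intensity fluctuations of diffusing receptors. The package takes time-tagged
photon streams to equilibrium dissociation coefficients (K_D), and ships a
photon-level Monte-Carlo simulator of the whole experiment for validation and
study design.

It is intended for quantitative fluorescence microscopists and method
developers who want a tested, scriptable implementation of the complete
analysis chain:

photon stream → PIE channel gating → kymograph (dwell-rescaled z-binning) →
membrane tracking → signal/background traces → background subtraction →
photobleaching correction γ(t) → auto-/cross-correlation (multi-tau) →
2D-diffusion model fits → Γ(C_L) statistic → binding isotherm → K_D.

## The model in brief

A single membrane species diffusing in 2D under a circular observation area
A = πω₀² gives the autocorrelation

```
G(τ) = (1/N) (1 + τ/τ_D)⁻¹,   τ_D = ω₀²/(4D),   N = C·A,
```

so amplitudes yield receptor densities and decays diffusion coefficients.
For a ligand (green) binding a receptor (red), the zero-lag amplitudes of the
two autocorrelations and the cross-correlation combine into

```
Γ(C_L) = G_×(0)² / (G_G(0)·G_R(0)) = A·β / (1 + K_D/C_L),
```

a scaled equilibrium binding isotherm. A = A_G·A_R/A_eff² (≈0.96 for 207/251
nm waists) is a pure geometry factor, and β is the fraction of
binding-competent receptors carrying a functional red tag. Γ is robust
against uncorrelated background — the attenuation factors cancel exactly in
the ratio — and the autocorrelation amplitudes are corrected for
photobleaching by the fitted γ(t) (cross-correlation needs no correction).
See `docs/methods.md` for the full model, corrections and numerical choices.

## Worked example

`examples/simulate_and_correlate.py` simulates one 20-s axial scan of a
membrane patch carrying 30 free receptors/µm² (red label) and 20
ligand-receptor complexes/µm² (dual label), runs the single-scan pipeline and
compares the fitted amplitudes with the noiseless species model:

```
$ python examples/simulate_and_correlate.py
simulated 490621 photons over 20 s
QC pass: True, membrane position SD 0.46 px
G_G(0): fitted 0.375 (model 0.371), tau_D = 40.4 ms
G_R(0): fitted 0.098 (model 0.101), tau_D = 40.2 ms
G_x(0): fitted 0.116 (model 0.120), tau_D = 65.8 ms
red channel: D = 0.39 um^2/s (truth 0.35), density = 52 um^-2 (truth 50)
Gamma = 0.365; with 40% of receptors bound, all complexes green-labeled
and A = 0.964, the model expects 0.386
```

Reading the numbers: the inverse amplitudes are the mean numbers of labeled
molecules in each observation area (1/0.098 ≈ 10 red receptors); the few-tens
of milliseconds decays are the diffusion times through the foci, converting
to D ≈ 0.4 µm²/s via D = ω₀²/4τ_D; and Γ estimates A·(bound fraction) —
noisy on a single scan (diffusion times especially so), which is why the
protocol averages at least three scans per concentration.

`examples/binding_isotherm.py` runs the full series (6 ligand concentrations
× 4 scans at a true K_D of 1 nM, with background and all corrections active)
and fits the isotherm — it prints per-concentration Γ ± SEM against the model
bound fractions and ends with

```
fitted K_D  = 0.993 +- 0.080 nM (simulated truth 1.0 nM)
fitted beta = 1.020 +- 0.007 (all receptors labeled: truth 1)
```

(the uncertainty is the scan-resampling bootstrap SE);
`examples/bleach_correction.py` shows γ(t) flattening a photobleached trace;
`examples/optics_calibration.py` walks through the focus-calibration
arithmetic.

A thin CLI wraps the same pipeline for shell use:

```bash
axlsfcs simulate --config run.yaml --out scan.npz --seed 1
axlsfcs process  --config run.yaml --stream scan.npz --out results/
axlsfcs bind     --config run.yaml --out results/       # K_D from a series
```

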