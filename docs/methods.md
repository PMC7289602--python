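# Methods

`axlsfcs` implements dual-color fluorescence correlation spectroscopy with
ultra-fast axial line scanning (axial lsFCS): a confocal observation volume is
swept sinusoidally along the optical axis through a membrane by a resonant
acoustic-gradient lens (~147 kHz, one membrane crossing every ~3.4 µs), so
that slow membrane movement no longer corrupts the intensity fluctuations of
membrane-bound fluorophores. The package covers the full chain from
time-tagged photons to equilibrium dissociation coefficients, plus a
photon-level simulator that stands in for the microscope.

## Physical model

**Observation volume.** A 3D Gaussian with lateral 1/e² waist ω₀ (per color:
ω_G, ω_R) and axial 1/e² half-length z₀ ≈ 5 ω₀. Sweeping it axially through a
membrane leaves a *circular* observation area A = πω₀² on the membrane plane;
the waists convert from bead-calibrated FWHM values via ω₀ = FWHM/√(2 ln 2)
(the convention consistent with the calibration numbers this package
reproduces: FWHM 295 nm → ω₀ ≈ 251 nm).

**Correlation functions.** A single membrane species diffusing in 2D gives

    G(τ) = (1/N) (1 + τ/τ_D)⁻¹,     τ_D = ω₀²/(4D),  N = C·πω₀²,

so the amplitude yields an area density and the decay a diffusion
coefficient (D = ω₀²/4τ_D). For lateral line scanning the observation area is
elongated (πω₀z₀) and the model gains an anisotropy factor

    G(τ) = (1/N) (1 + τ/τ_D)^(-1/2) (1 + τ/(S²τ_D))^(-1/2),  S = z₀/ω₀ ≥ 1,

which reduces to the circular form at S = 1. We use S = z₀/ω₀ (≥ 1) with
τ_D = ω₀²/4D: this is the only convention under which the elongated curve
decays more slowly than the circular one and fitted values like S ≈ 4 are
meaningful; literature statements of S sometimes print the reciprocal.

**Species-resolved amplitudes.** With red-labeled free receptors (C_R),
dual-labeled complexes (C_RL) and complexes on dark receptors (C_rL), the
zero-lag amplitudes are

    G_G(0) = 1/(A_G (C_rL + C_RL)),
    G_R(0) = 1/(A_R (C_R + C_RL)),
    G_×(0) = C_RL/(A_eff (C_R + C_RL)(C_rL + C_RL)),

with A_eff = πω_eff², ω_eff² = (ω_G² + ω_R²)/2. These serve as the noiseless
oracle against which the simulator is validated.

**The binding statistic.** The amplitude combination

    Γ(C_L) = G_×(0)² / (G_G(0) G_R(0)) = A·β / (1 + K_D/C_L)

is a scaled equilibrium isotherm: A = A_G·A_R/A_eff² ≤ 1 is a pure geometry
factor (0.964 from the 207/251 nm waists), β the fraction of
binding-competent receptors carrying a functional red tag, and K_D the
dissociation coefficient. Uncorrelated background attenuates G_G by b_G²,
G_R by b_R² and G_× by b_G·b_R (b = signal/(signal+background)), so the
attenuations cancel *exactly* in Γ — the basis of its background robustness.
Incomplete ligand-tag maturation η shifts the isotherm midpoint to ηK_D and
scales its amplitude to A·β·η; the fitted K_D is corrected as K_D/η.
Receptor-tag maturation and binding-incompetent receptors scale only β,
never K_D; they are reported as caveats on β.

**Heterodimer fractions.** For two labeled receptor species, area-weighted
amplitude ratios F_R′ = (A_eff/A_G)·G_×(0)/G_G(0) and
F_G′ = (A_eff/A_R)·G_×(0)/G_R(0) equal co-diffusion fractions at full
maturation; otherwise F = 1/(1/F′ + 1 − 1/η) recovers the true bound
fraction.

## Pipeline

1. **Gating** — photons split by micro time: green [0, 12.5) ns, red
   [12.5, 25) ns (pulsed interleaved excitation; half-open bins).
2. **z mapping** — z = a·sin(2π·phase), a = drive_fraction × lens amplitude
   (default 0.75 × 3.53 µm ≈ ±2.65 µm, a 5.3 µm span). 26 z-pixels
   (~0.2 µm each); per-pixel dwell weights ∝ arcsin differences of the pixel
   edges, capped at 5× the center weight at the turning points. Rescaled
   counts are raw counts divided by dwell weight (exactly invertible). Up-
   and down-sweep crossings accumulate into the same z pixels. A measured
   calibration table may replace the ideal sinusoid.
3. **Membrane tracking** — per 0.5-s kymograph line, ridge = argmax of
   channel-summed counts after a 3-line boxcar (smoothing is for
   localization only). One ridge for cells, two (sorted by z) for
   vesicle-style data. Positions are linearly interpolated to the fine grid.
4. **Trace extraction** — signal = dwell-rescaled counts in the 5-pixel
   window (ridge ± 2); background = one-pixel regions at ridge ± 10 pixels
   (~2 µm), scaled by the pixel-number ratio (5/2 for one membrane, 5/4 for
   two). Dwell rescaling makes that pixel-count scaling exact, because raw
   background counts per pixel are proportional to dwell time (~1.5× higher
   at ±10 pixels than at the center). Fine traces are binned directly at the
   correlation bin width (0.1 ms ≈ 29 crossings) from the photon stream.
5. **Quality control** (automated stand-ins for visual discard rules; all
   thresholds overridable): membrane position SD > 2 px → fluctuating; mean
   distance from sweep center > 25% of span → off-center; any sample above
   median + 8 MAD for ≥ 2 consecutive lines → bright cluster; mean signal
   < 2× scaled background → low signal. Later, scans whose two channels
   return diffusion times differing by more than 3× or outside [1 ms, 1 s]
   are excluded.
6. **Background subtraction** — I′ = I_raw − smooth(I_bg); the background
   trace is noise-filtered with the six-sine fit before subtraction
   (switchable); negative samples clip to 0, >10% clipping flags
   over-subtraction.
7. **Photobleaching correction** — γ(t) = Î′(0)/Î′(t) from a band-limited
   six-sine fit of the trace; γ renormalized to γ(0) = 1; I = I′·γ;
   ⟨γ⟩ stored. The corrected autocorrelation is divided by ⟨γ⟩; the
   cross-correlation is never rescaled (label losses factor out of it).
8. **Correlation** — multi-tau cascade (16 lags/stage, bin doubling,
   0.1 ms–10 s), symmetric normalization over the overlap; per-lag errors
   from 6 trace segments. Each cascade value equals a direct-sum evaluation
   on the identically rebinned trace to ≤ 1e-12.
9. **Fits and K_D** — weighted least squares of the circular model per curve
   (lags ≥ 1 ms by default; multi-start over τ_D decades; log-parametrized);
   Γ per scan from the three fitted amplitudes; mean ± SEM over ≥ 3 scans
   per concentration; weighted fit of A·β/(1 + K_D/C_L) with A fixed from
   the calibration.

## Simulator

Species R (red-only receptor), G (ligand on a dark receptor) and RL
(dual-labeled complex) diffuse as 2D Brownian motion in a periodic square
membrane patch; maturation yields η_G, η_R dark individual fluorophores at
creation (an RL with a dark red tag *is* a G particle, so β emerges
mechanistically). Per membrane crossing, each live fluorophore contributes a
Poisson photon count with mean brightness × exp(−2r²/ω²) × axial transit
dose (the numerically integrated Gaussian dose of one sinusoidal sweep,
~0.5–0.6 µs center-equivalent per crossing); photon times within a crossing
follow the axial Gaussian mapped through the arcsine of the sweep. Background
is homogeneous Poisson in time (hence dwell-shaped in z), which also stands
in for fast free ligand diffusing in 3D — its millisecond-scale correlations
are far below the membrane timescales. Bleaching is a memoryless per-crossing
hazard ∝ bleach_cross_section × lateral Gaussian. Optional slow sinusoidal
membrane drift exercises the tracker. One seed drives every draw; identical
seed ⇒ bit-identical stream.

**Defaults as study conditions**: 60-s scans, 147 kHz / 75% drive (5.3 µm
span), ω = 207/251 nm with z₀ = 5ω, receptor densities of tens per µm²
(the stable-transfection regime), D = 0.35 µm²/s, brightness 0.02–0.03
photons/µs at focus center (≈ 3–5 kHz per molecule — typical GFP-family
count rates), maturation yields 0.9 (green) / 0.5 (red) where exercised.

**What the simulator does not emulate**: triplet/blinking photophysics,
vectorial (non-Gaussian) PSFs, detector dead time and afterpulsing, membrane
curvature and topology changes, receptor clustering and nanodomains,
cell-to-cell variability, and explicit 3D ligand diffusion. Passing tests
therefore demonstrate correctness of the analysis chain under the stated
model, not robustness to every artifact of live-cell recordings.

## Numerical choices

- **Trajectory stride.** Positions advance once per correlation bin (0.1 ms
  ≈ 29 crossings) instead of every crossing: the per-crossing Brownian rms
  step is ~1.5 nm (≪ ω = 250 nm), so all resolvable lags are unaffected and
  the simulation is ~30× cheaper. The stride is configurable down to one
  crossing.
- **Six-sine fits** run on traces rebinned to ≤ 600 samples (the curves are
  band-limited, so nothing changes except cost). Frequencies are bounded to
  6 cycles per span in general, 2 cycles per span for the bleaching ratio —
  a looser band lets the fit chase diffusion-driven occupancy fluctuations
  and mis-anchor γ(0). Spectral initialization plus multi-start; a
  non-converged fit falls back to a monotone spline, flagged.
- **Trend gate on γ.** The correction is applied only when the coarse trace
  shows a significant (≈2σ) *decay* of more than 5% over the scan; otherwise
  γ ≡ 1. Bleaching can only dim, so rising or flat traces gain nothing from
  the correction and would only inherit its smoothing noise. A fitted
  ⟨γ⟩ < 0.95 (nonphysical for bleaching) is likewise replaced by γ ≡ 1.
- **Correlation input**: 0.1 ms bins (≥ 300× below the 30–50 ms diffusion
  times); lag grid 16 + 8/stage; amplitude fits exclude lags < 1 ms by
  default. I′(0) is read from the smooth fit, never from the noisy first
  bin; the γ denominator is the smoothed trace for the same reason.
- **Degenerate inputs**: empty kymographs are flagged, all-zero tracking
  lines carry the previous ridge forward and raise low-signal evidence;
  zero-mean traces raise; non-positive smoothed traces abort the bleach
  correction with a degenerate-trace error.
- **Isotherm fit**: log-parametrized K_D (positivity), β ∈ [0, 2] with a
  warning above 0.6 (complexes carrying several labeled receptors can push
  the apparent amplitude beyond the single-label expectation); A is fixed
  from the calibration, never fitted; series lying entirely on one side of
  the fitted K_D are flagged ill-conditioned.
- **K_D uncertainty.** The covariance SE of a weighted fit to a handful of
  concentration points, with weights from SEMs that are themselves estimated
  from a few scans, is systematically optimistic. The pipeline therefore
  also bootstraps the fit by resampling scans with replacement within each
  concentration (200 resamples, deterministic seed) and reports the
  bootstrap SD as the preferred K_D uncertainty alongside the covariance SE.

## Test-scale problem sizes

The statistical test suites run on scaled-down versions of the default
conditions so that the whole suite completes in minutes on one CPU: membrane
patches of 2.8 µm (≥ 10 waists; periodic-image correlations are negligible),
scans of 10–15 s instead of 60 s, 5–6 concentrations × 6 scans for the
recovery suites, and 20 seeds for the amplitude oracle. The amplitude
statistics at these sizes are noisier than at full scale but unbiased, which
is what the oracle comparisons assert (3 SE over seeds; 20% + 2 SE for the
end-to-end K_D).

## Known limitations

- Per-scan Γ estimates are noisy at low bound fraction (the green channel
  then holds ~1 molecule per observation area); the isotherm fit relies on
  averaging ≥ 3 scans per concentration, as the protocol prescribes.
- The γ(t) model is heuristic; on short stationary traces its noise exceeds
  its benefit, hence the trend gate. ⟨γ⟩ values on strongly bleached scans
  carry a few-percent anchor uncertainty that propagates into auto- (not
  cross-) amplitudes.
- The sinusoidal z(t) idealizes a resonant lens; a measured phase→z table
  can be supplied but no such table ships with the package.
- Two-membrane mode assumes two well-separated, non-adjacent ridges; no
  sub-pixel localization is attempted.
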