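"""Background subtraction and photobleaching correction.

Photobleaching continually removes fluorophores from the membrane, so the
intensity trace decays over the 60-s scan.  The correction forms the ratio
gamma(t) = I'(0)/I'(t) from a smoothed version of the background-corrected
trace, models it as a sum of six sine functions, and multiplies the trace by
gamma(t).  The time average <gamma> rescales the autocorrelation amplitudes
(the cross-correlation needs no rescaling because the losses cancel there).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
from scipy import optimize
from scipy.interpolate import PchipInterpolator

__all__ = [
    "SmoothCurve",
    "CorrectionState",
    "fit_six_sines",
    "subtract_background",
    "bleach_correct",
]

N_SINES = 6
#: traces are rebinned to at most this many samples before fitting; the
#: fitted curves are band-limited to a few cycles per scan, so nothing is
#: lost and the 18-parameter fit stays cheap on 10^5-sample traces.
MAX_FIT_SAMPLES = 600
#: default frequency cap: cycles per fitted time span.  Bleaching trends and
#: background drifts evolve over seconds to tens of seconds; letting the six
#: sines reach higher frequencies would track the diffusion-driven occupancy
#: fluctuations that the correlation analysis must keep.
MAX_CYCLES_PER_SPAN = 6.0
#: tighter cap for the photobleaching ratio fits: the decay is monotone on
#: the scan timescale, and a looser band would let the fit latch onto slow
#: occupancy fluctuations and mis-anchor gamma(0).
BLEACH_MAX_CYCLES_PER_SPAN = 2.0


@dataclass
class SmoothCurve:
    """Sum of six sines a_k sin(b_k t + c_k) fitted on [0, T].

    Falls back to a monotone (PCHIP) spline when the sine fit fails to
    converge; ``fallback`` records that.
    """

    amp: np.ndarray
    freq: np.ndarray
    phase: np.ndarray
    domain: Tuple[float, float]
    residual_rms: float
    fallback: bool = False
    _spline: Optional[PchipInterpolator] = None

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.fallback and self._spline is not None:
            lo, hi = self.domain
            return self._spline(np.clip(t, lo, hi))
        return np.sum(self.amp[:, None] * np.sin(self.freq[:, None] * t[None, :]
                                                 + self.phase[:, None]), axis=0)


def _rebin(t: np.ndarray, y: np.ndarray, max_samples: int = MAX_FIT_SAMPLES
           ) -> Tuple[np.ndarray, np.ndarray]:
    n = len(t)
    if n <= max_samples:
        return t, y
    k = int(math.ceil(n / max_samples))
    m = (n // k) * k
    tb = t[:m].reshape(-1, k).mean(axis=1)
    yb = y[:m].reshape(-1, k).mean(axis=1)
    return tb, yb


def _sine_design(t: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    cols = [np.cos(f * t) for f in freqs] + [np.sin(f * t) for f in freqs]
    return np.stack(cols, axis=1)


def _solve_linear(t: np.ndarray, y: np.ndarray, freqs: np.ndarray):
    m = _sine_design(t, freqs)
    coef, *_ = np.linalg.lstsq(m, y, rcond=None)
    resid = y - m @ coef
    return coef, resid


def _init_freqs(t: np.ndarray, y: np.ndarray, span: float) -> np.ndarray:
    """Spectral initialization: the strongest periodogram components plus a
    near-DC term that lets the sine sum carry an offset/slow trend."""
    n = len(t)
    dt = span / max(n - 1, 1)
    yc = y - y.mean()
    power = np.abs(np.fft.rfft(yc)) ** 2
    fgrid = 2.0 * np.pi * np.fft.rfftfreq(n, dt)
    order = np.argsort(power[1:])[::-1] + 1  # skip DC
    picks = [1e-3 * 2.0 * np.pi / span]  # near-DC
    for idx in order:
        f = fgrid[idx]
        if all(abs(f - p) > 1e-9 for p in picks):
            picks.append(f)
        if len(picks) == N_SINES:
            break
    k = 1
    while len(picks) < N_SINES:
        picks.append(2.0 * np.pi * k / span)
        k += 1
    return np.array(picks[:N_SINES])


def fit_six_sines(t: np.ndarray, y: np.ndarray, weights: Optional[np.ndarray] = None,
                  max_freq: Optional[float] = None, n_starts: int = 4) -> SmoothCurve:
    """Weighted least-squares fit of a sum of six sines.

    Uses variable projection: the six frequencies are optimized nonlinearly
    (initialized from the discrete spectrum, best of ``n_starts`` perturbed
    restarts) while amplitudes/phases are solved linearly at each step.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(t) < 50:
        raise ValueError("need at least 50 samples for the six-sine fit")
    span = float(t[-1] - t[0])
    if span <= 0:
        raise ValueError("time span must be positive")
    t_fit, y_fit = _rebin(t, y, MAX_FIT_SAMPLES)
    scale = float(np.std(y_fit)) or 1.0
    if max_freq is None:
        max_freq = 2.0 * np.pi * MAX_CYCLES_PER_SPAN / span
    f0 = np.clip(_init_freqs(t_fit, y_fit, span), 1e-6, max_freq)

    def resid_of_freqs(logf: np.ndarray) -> np.ndarray:
        _, resid = _solve_linear(t_fit, y_fit, np.exp(logf))
        return resid

    best = None
    rng = np.random.default_rng(12345)
    starts = [f0]
    for _ in range(max(0, n_starts - 1)):
        starts.append(np.clip(f0 * np.exp(rng.normal(0, 0.3, N_SINES)), 1e-6, max_freq))
    for fs in starts:
        try:
            sol = optimize.least_squares(
                resid_of_freqs, np.log(fs),
                bounds=(np.log(1e-7), np.log(max_freq)),
                xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=400,
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not np.all(np.isfinite(best.x)):
        return _spline_fallback(t_fit, y_fit, span)
    freqs = np.exp(best.x)
    coef, resid = _solve_linear(t_fit, y_fit, freqs)
    rms = float(np.sqrt(np.mean(resid**2)))
    if not np.isfinite(rms) or rms > 10.0 * scale:
        return _spline_fallback(t_fit, y_fit, span)
    a_cos = coef[:N_SINES]
    b_sin = coef[N_SINES:]
    amp = np.hypot(a_cos, b_sin)
    phase = np.arctan2(a_cos, b_sin)  # A cos + B sin = amp * sin(ft + phase)
    return SmoothCurve(amp=amp, freq=freqs, phase=phase,
                       domain=(float(t[0]), float(t[-1])), residual_rms=rms)


def _spline_fallback(t: np.ndarray, y: np.ndarray, span: float) -> SmoothCurve:
    # coarse median bins -> monotone-in-t spline; flagged as fallback
    n_knots = min(20, max(4, len(t) // 10))
    edges = np.linspace(t[0], t[-1], n_knots + 1)
    idx = np.clip(np.digitize(t, edges) - 1, 0, n_knots - 1)
    knots_t, knots_y = [], []
    for k in range(n_knots):
        m = idx == k
        if np.any(m):
            knots_t.append(t[m].mean())
            knots_y.append(np.median(y[m]))
    spline = PchipInterpolator(np.asarray(knots_t), np.asarray(knots_y))
    resid = y - spline(t)
    return SmoothCurve(
        amp=np.zeros(N_SINES), freq=np.ones(N_SINES), phase=np.zeros(N_SINES),
        domain=(float(t[0]), float(t[-1])),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        fallback=True, _spline=spline,
    )


@dataclass
class BackgroundResult:
    corrected: np.ndarray
    smooth_bg: SmoothCurve
    clip_fraction: float
    over_subtracted: bool


def subtract_background(i_raw: np.ndarray, i_bg: np.ndarray, t: np.ndarray,
                        smooth: bool = True) -> BackgroundResult:
    """I'(t) = I_raw(t) - smooth(I_bg)(t), clipped at zero.

    The background trace is noise-filtered with the six-sine fit before
    subtraction (switchable); more than 10% clipped samples flags likely
    over-subtraction.
    """
    i_raw = np.asarray(i_raw, dtype=float)
    i_bg = np.asarray(i_bg, dtype=float)
    if len(i_raw) != len(i_bg) or len(i_raw) != len(t):
        raise ValueError("traces must have equal length")
    if smooth and np.any(i_bg):
        curve = fit_six_sines(t, i_bg)
        bg_eval = curve(t)
    else:
        curve = SmoothCurve(np.zeros(N_SINES), np.ones(N_SINES), np.zeros(N_SINES),
                            (float(t[0]), float(t[-1])), 0.0)
        bg_eval = i_bg if not smooth else np.zeros_like(i_raw)
    corrected = i_raw - bg_eval
    clipped = corrected < 0
    corrected = np.where(clipped, 0.0, corrected)
    frac = float(np.mean(clipped))
    return BackgroundResult(corrected=corrected, smooth_bg=curve,
                            clip_fraction=frac, over_subtracted=frac > 0.10)


def _has_significant_trend(t: np.ndarray, y: np.ndarray,
                           n_bins: int = 30, min_decay: float = 0.05) -> bool:
    """True when the trace shows a real intensity trend worth correcting.

    A line is fitted to ~30 superbin means (spaced far beyond the diffusion
    time, so approximately independent); the trend must be a *decay* (photo-
    bleaching only dims), significant at ~2 sigma, AND imply more than
    ``min_decay`` relative loss over the scan.
    """
    tc, yc = _rebin(t, y, n_bins)
    if len(tc) < 6 or yc.mean() <= 0:
        return True  # too short to judge: let the fit decide
    x = tc - tc.mean()
    denom = float(np.sum(x * x))
    slope = float(np.sum(x * (yc - yc.mean()))) / denom
    resid = yc - yc.mean() - slope * x
    se = math.sqrt(float(np.sum(resid**2)) / max(len(yc) - 2, 1) / denom)
    rel_change = -slope * (t[-1] - t[0]) / yc.mean()
    return slope < -2.0 * se and rel_change > min_decay


@dataclass
class CorrectionState:
    """Per-channel correction bookkeeping carried with every scan."""

    gamma: Dict[str, SmoothCurve] = field(default_factory=dict)
    gamma_mean: Dict[str, float] = field(default_factory=dict)
    corrected: Dict[str, np.ndarray] = field(default_factory=dict)
    clip_fraction: Dict[str, float] = field(default_factory=dict)


def bleach_correct(i_prime: np.ndarray, t: np.ndarray
                   ) -> Tuple[np.ndarray, SmoothCurve, float]:
    """Multiply the trace by gamma(t) = I'(0)/I'(t) of its smooth fit.

    I'(0) is read from the smooth fit at t = 0 (the raw first bin would
    inject its shot noise into every corrected sample) and the denominator is
    the smoothed trace for the same reason.  gamma is itself refitted with
    six sines and normalized so gamma(0) = 1.  Returns the corrected trace,
    the gamma curve and its time average <gamma>.
    """
    i_prime = np.asarray(i_prime, dtype=float)
    if np.any(i_prime < 0):
        raise ValueError("bleach correction expects a non-negative trace")
    if not np.any(i_prime):
        raise ValueError("bleach correction needs a nonzero trace")
    span = float(t[-1] - t[0])
    if not _has_significant_trend(t, i_prime):
        # no detectable fluorophore loss: correcting would only inject the
        # smoothing noise of gamma into every sample
        unit = SmoothCurve(
            amp=np.array([1.0] + [0.0] * (N_SINES - 1)),
            freq=np.array([1e-12] * N_SINES),
            phase=np.array([np.pi / 2] + [0.0] * (N_SINES - 1)),
            domain=(float(t[0]), float(t[-1])), residual_rms=0.0)
        return i_prime.copy(), unit, 1.0
    max_freq = 2.0 * np.pi * BLEACH_MAX_CYCLES_PER_SPAN / span
    smooth_i = fit_six_sines(t, i_prime, max_freq=max_freq)
    t0 = float(t[0])
    t_coarse, _ = _rebin(t, i_prime)
    denom = smooth_i(t_coarse)
    if np.any(denom <= 0):
        raise ValueError("smoothed trace is non-positive: degenerate trace")
    i0 = float(smooth_i(np.array([t0]))[0])
    ratio = i0 / denom
    gamma_curve = fit_six_sines(t_coarse, ratio, max_freq=max_freq)
    g0 = float(gamma_curve(np.array([t0]))[0])
    if g0 <= 0 or not np.isfinite(g0):
        raise ValueError("gamma(0) is non-positive: degenerate trace")
    norm = 1.0 / g0
    gamma_curve = SmoothCurve(
        amp=gamma_curve.amp * norm, freq=gamma_curve.freq, phase=gamma_curve.phase,
        domain=gamma_curve.domain, residual_rms=gamma_curve.residual_rms * norm,
        fallback=gamma_curve.fallback, _spline=gamma_curve._spline,
    )
    if gamma_curve.fallback and gamma_curve._spline is not None:
        # normalization must also apply through the spline path
        spl = gamma_curve._spline
        gamma_curve._spline = PchipInterpolator(spl.x, spl(spl.x) * norm)
    gamma_t = gamma_curve(t)
    gamma_mean = float(np.mean(gamma_t))
    if gamma_mean < 0.95:
        # bleaching can only give <gamma> >= 1; a smaller value means the
        # sine fit chased fluctuations, so correcting would do net harm
        unit = SmoothCurve(
            amp=np.array([1.0] + [0.0] * (N_SINES - 1)),
            freq=np.array([1e-12] * N_SINES),
            phase=np.array([np.pi / 2] + [0.0] * (N_SINES - 1)),
            domain=(float(t[0]), float(t[-1])), residual_rms=0.0)
        return i_prime.copy(), unit, 1.0
    corrected = i_prime * gamma_t
    return corrected, gamma_curve, gamma_mean
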