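"""End-to-end analysis driver: photon stream -> Gamma(C_L) -> K_D.

One scan runs through gating, kymograph construction, membrane tracking,
signal/background extraction, background subtraction, photobleaching
correction, correlation and diffusion-model fitting; a concentration series
aggregates the per-scan Gamma values (mean +- SEM over >= 3 scans per point)
and fits the binding isotherm.  Scans failing quality control or returning
markedly deviant correlation times are excluded, never aborting the run; the
run errors out only when too few scans survive to constrain the isotherm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import binding as binding_mod
from . import corrections, correlation, fcsmodels, membrane, photonproc
from .fcsmodels import FitResult, OpticsCalibration
from .membrane import QCThresholds
from .simkymo import OpticsConfig, PhotonStream

__all__ = [
    "ScanOptions",
    "ScanResult",
    "SeriesResult",
    "QCStarvationError",
    "analyze_scan",
    "analyze_binding_series",
]


class QCStarvationError(RuntimeError):
    """Raised when quality control leaves too few scans for the isotherm."""


@dataclass(frozen=True)
class ScanOptions:
    """Processing switches of the per-scan pipeline."""

    line_time_s: float = 0.5
    bin_width_s: float = 1e-4
    halfwidth: int = 2
    bg_offset: int = 10
    n_pixels: int = 26
    n_membranes: int = 1
    subtract_background: bool = True
    smooth_background: bool = True
    bleach_correction: bool = True
    min_fit_lag_s: float = 1e-3
    max_lag_s: float = 1.0
    qc: QCThresholds = QCThresholds()
    enforce_qc: bool = True
    tau_ratio_max: float = 3.0
    tau_bounds_s: Tuple[float, float] = (1e-3, 1.0)


@dataclass
class ScanResult:
    """Everything the binding layer needs from one 60-s scan."""

    correlations: correlation.CorrelationSet
    fits: Dict[str, FitResult]
    gamma_mean: Dict[str, float]
    qc: membrane.QCReport
    gamma: float = float("nan")
    excluded: bool = False
    exclusion_reason: str = ""
    clip_fraction: Dict[str, float] = field(default_factory=dict)
    correction_state: Optional[corrections.CorrectionState] = None

    def summary(self) -> Dict:
        return {
            "gamma": self.gamma,
            "excluded": self.excluded,
            "exclusion_reason": self.exclusion_reason,
            "gamma_mean": self.gamma_mean,
            "qc_flags": self.qc.flags,
            "qc_evidence": self.qc.evidence,
            "fits": {
                ch: {"N": f.n, "G0": f.g0, "tau_d_s": f.tau_d_s, "ok": f.ok}
                for ch, f in self.fits.items()
            },
        }


def analyze_scan(stream: PhotonStream, optics: Optional[OpticsConfig] = None,
                 opts: ScanOptions = ScanOptions()) -> ScanResult:
    """Run the full single-scan pipeline.

    Deterministic given the stream and options.  The returned result carries
    the QC report and, when the scan is usable, the three amplitude fits and
    the Gamma statistic.
    """
    if optics is None:
        optics = stream.optics()
    mapping = photonproc.ZMapping(optics, n_pixels=opts.n_pixels)
    g_ph, r_ph = photonproc.gate_channels(stream, optics.pie_window_ns)
    dur = stream.duration_s
    kymos = {
        "G": photonproc.build_kymograph(g_ph, mapping, opts.line_time_s, dur, "G"),
        "R": photonproc.build_kymograph(r_ph, mapping, opts.line_time_s, dur, "R"),
    }
    trace = membrane.track_membrane(kymos, n_membranes=opts.n_membranes)
    # QC evidence from the display-resolution kymograph
    any_kymo = kymos["R"] if np.any(kymos["R"].raw_counts) else kymos["G"]
    sig_coarse = membrane.extract_signal(any_kymo, trace, opts.halfwidth)
    bg_coarse = membrane.extract_background(any_kymo, trace, opts.bg_offset, opts.halfwidth)
    qc = membrane.qc_checks(kymos, trace, sig_coarse, bg_coarse, opts.qc)

    traces = membrane.extract_traces(
        {"G": g_ph, "R": r_ph}, mapping, trace,
        bin_width_s=opts.bin_width_s, halfwidth=opts.halfwidth,
        bg_offset=opts.bg_offset, duration_s=dur,
    )
    state = corrections.CorrectionState()
    corrected: Dict[str, np.ndarray] = state.corrected
    gamma_mean: Dict[str, float] = state.gamma_mean
    clip_frac: Dict[str, float] = state.clip_fraction
    degenerate = ""
    for ch in ("G", "R"):
        i_raw = traces.i_raw[ch]
        if opts.subtract_background:
            bg_res = corrections.subtract_background(
                i_raw, traces.i_bg[ch], traces.t_s, smooth=opts.smooth_background)
            i_prime = bg_res.corrected
            clip_frac[ch] = bg_res.clip_fraction
        else:
            i_prime = i_raw
            clip_frac[ch] = 0.0
        if opts.bleach_correction:
            try:
                i_corr, gamma_curve, gmean = corrections.bleach_correct(
                    i_prime, traces.t_s)
                state.gamma[ch] = gamma_curve
            except ValueError as exc:
                degenerate = f"bleach correction failed on {ch}: {exc}"
                i_corr, gmean = i_prime, 1.0
        else:
            i_corr, gmean = i_prime, 1.0
        corrected[ch] = i_corr
        gamma_mean[ch] = gmean

    try:
        cs = correlation.correlate_traces(
            corrected["G"], corrected["R"], bin_s=opts.bin_width_s,
            gamma_mean_g=gamma_mean["G"], gamma_mean_r=gamma_mean["R"],
            max_lag_s=opts.max_lag_s,
        )
    except (ValueError, ZeroDivisionError) as exc:
        empty = correlation.CorrelationSet(
            tau_s=np.array([opts.bin_width_s]), g_g=np.array([np.nan]),
            g_r=np.array([np.nan]), g_x=np.array([np.nan]),
            err_g=np.array([np.nan]), err_r=np.array([np.nan]),
            err_x=np.array([np.nan]))
        return ScanResult(correlations=empty, fits={}, gamma_mean=gamma_mean,
                          qc=qc, excluded=True,
                          exclusion_reason=f"correlation failed: {exc}",
                          clip_fraction=clip_frac, correction_state=state)

    fits: Dict[str, FitResult] = {}
    for ch, g, err in (("G", cs.g_g, cs.err_g), ("R", cs.g_r, cs.err_r),
                       ("x", cs.g_x, cs.err_x)):
        try:
            fits[ch] = fcsmodels.fit_circular(cs.tau_s, g, err, opts.min_fit_lag_s)
        except ValueError:
            fits[ch] = FitResult(n=float("nan"), tau_d_s=float("nan"), ok=False)

    result = ScanResult(correlations=cs, fits=fits, gamma_mean=gamma_mean,
                        qc=qc, clip_fraction=clip_frac, correction_state=state)
    reasons: List[str] = []
    if degenerate:
        reasons.append(degenerate)
    if opts.enforce_qc and not qc.passed:
        reasons.append("QC: " + ",".join(qc.reasons()))
    if not (fits["G"].ok and fits["R"].ok):
        reasons.append("autocorrelation fit failed")
    else:
        td_g, td_r = fits["G"].tau_d_s, fits["R"].tau_d_s
        lo, hi = opts.tau_bounds_s
        if abs(math.log(td_g / td_r)) > math.log(opts.tau_ratio_max):
            reasons.append("deviant correlation times between channels")
        if not (lo <= td_g <= hi) or not (lo <= td_r <= hi):
            reasons.append("correlation time out of range")
    if reasons:
        result.excluded = True
        result.exclusion_reason = "; ".join(reasons)
        return result
    g_g0, g_r0 = fits["G"].g0, fits["R"].g0
    g_x0 = fits["x"].g0 if fits["x"].ok and np.isfinite(fits["x"].n) else _amplitude_fallback(cs)
    try:
        result.gamma = binding_mod.gamma_statistic(g_g0, g_r0, max(g_x0, 0.0))
    except ValueError:
        result.excluded = True
        result.exclusion_reason = "non-positive autocorrelation amplitude"
    return result


def _amplitude_fallback(cs: correlation.CorrelationSet) -> float:
    """Cross-amplitude for curves too flat/noisy to fit: mean of early lags.

    A series without bound complexes has a zero-amplitude cross-correlation
    that the diffusion model cannot fit; the early-lag average is then the
    unbiased amplitude estimate (scatter around zero stays around zero).
    """
    k = min(8, len(cs.tau_s))
    return float(np.nanmean(cs.g_x[:k]))


@dataclass
class SeriesResult:
    curve: Optional[binding_mod.BindingCurve]
    isotherm: Optional[binding_mod.IsothermFit]
    scans: List[Tuple[float, ScanResult]]
    excluded: List[Tuple[float, str]]
    dropped_points: List[float] = field(default_factory=list)

    def summary(self) -> Dict:
        out: Dict = {
            "n_scans": len(self.scans),
            "n_excluded": len(self.excluded),
            "exclusions": [{"c_l_nm": c, "reason": r} for c, r in self.excluded],
            "dropped_points_nm": self.dropped_points,
        }
        if self.curve is not None:
            out["binding_curve"] = {
                "c_l_nm": self.curve.c_l_nm.tolist(),
                "gamma": self.curve.gamma.tolist(),
                "sem": self.curve.sem.tolist(),
                "n_scans": self.curve.n_scans.tolist(),
            }
        if self.isotherm is not None:
            out["isotherm"] = {
                "k_d_nm": self.isotherm.k_d_nm,
                "k_d_se_nm": self.isotherm.k_d_se,
                "k_d_se_boot_nm": self.isotherm.k_d_se_boot,
                "beta_se_boot": self.isotherm.beta_se_boot,
                "beta": self.isotherm.beta,
                "beta_se": self.isotherm.beta_se,
                "a_factor": self.isotherm.a_factor,
                "ill_conditioned": self.isotherm.ill_conditioned,
                "beta_warning": self.isotherm.beta_warning,
            }
        return out


def analyze_binding_series(
    series: Sequence[Tuple[float, Sequence[PhotonStream]]],
    calib: OpticsCalibration,
    optics: Optional[OpticsConfig] = None,
    opts: ScanOptions = ScanOptions(),
    min_scans: int = binding_mod.MIN_SCANS_PER_POINT,
    bootstrap: bool = True,
    bootstrap_seed: int = 0,
) -> SeriesResult:
    """Per-scan analysis, Gamma aggregation and isotherm fit for a C_L series.

    Concentration points left with fewer than ``min_scans`` usable scans are
    dropped (recorded in the result); the run aborts with
    :class:`QCStarvationError` only when fewer than four points survive.
    """
    per_scan: List[Tuple[float, float]] = []
    scans: List[Tuple[float, ScanResult]] = []
    excluded: List[Tuple[float, str]] = []
    for c_l, streams in series:
        for stream in streams:
            res = analyze_scan(stream, optics, opts)
            scans.append((c_l, res))
            if res.excluded or not np.isfinite(res.gamma):
                excluded.append((c_l, res.exclusion_reason or "no Gamma"))
            else:
                per_scan.append((c_l, res.gamma))
    counts: Dict[float, int] = {}
    for c_l, _ in per_scan:
        counts[c_l] = counts.get(c_l, 0) + 1
    usable = [(c, g) for c, g in per_scan if counts[c] >= min_scans]
    dropped = sorted({c for c, _ in per_scan if counts[c] < min_scans}
                     | {c for c, _ in series if counts.get(c, 0) == 0})
    n_points = len({c for c, _ in usable})
    if n_points < 4:
        reasons = "; ".join(f"{c} nM: {r}" for c, r in excluded[:10])
        raise QCStarvationError(
            f"only {n_points} concentration points survived QC (need >= 4): {reasons}")
    curve = binding_mod.aggregate_gamma(usable, a_factor=calib.a_factor,
                                        min_scans=min_scans)
    isotherm = binding_mod.fit_isotherm(curve)
    if bootstrap:
        kd_se_b, beta_se_b = binding_mod.bootstrap_isotherm(
            usable, a_factor=calib.a_factor, seed=bootstrap_seed,
            min_scans=min_scans)
        if math.isfinite(kd_se_b):
            isotherm.k_d_se_boot = kd_se_b
            isotherm.beta_se_boot = beta_se_b
    return SeriesResult(curve=curve, isotherm=isotherm, scans=scans,
                        excluded=excluded, dropped_points=dropped)
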