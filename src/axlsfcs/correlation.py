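"""Auto- and cross-correlation estimators and the precision-vs-time metric.

The correlator is a multi-tau cascade: 16 lags at the base bin width, then 8
more per stage with the trace rebinned by a factor of two each stage, giving
a quasi-logarithmic lag grid from one bin up to a configurable maximum.  At
every stage the estimator evaluates

    G(tau) = <I(t) I(t+tau)> / (<I(t)> <I(t+tau)>) - 1

with the averages taken over the overlapping part of the (rebinned) trace,
which makes each reported value exactly equal to a direct-sum evaluation on
the identically rebinned trace.  Autocorrelation amplitudes are rescaled by
1/<gamma> to undo the photobleaching correction's amplitude inflation; the
cross-correlation needs no rescaling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "CorrelationSet",
    "direct_correlate",
    "multi_tau_lags",
    "multi_tau",
    "autocorrelate",
    "crosscorrelate",
    "correlate_traces",
    "sd_of_curves",
    "sd_vs_time",
]

M_CHANNELS = 16
DEFAULT_BIN_S = 1e-4
DEFAULT_MAX_LAG_S = 10.0
N_ERR_SEGMENTS = 6


def direct_correlate(x: np.ndarray, y: Optional[np.ndarray] = None,
                     lags: Sequence[int] = (1,)) -> np.ndarray:
    """Brute-force correlation estimator at integer lags (in bins).

    G(k) = mean(x[:n-k] * y[k:]) / (mean(x[:n-k]) * mean(y[k:])) - 1.
    Serves as the independent oracle for the multi-tau cascade.
    """
    x = np.asarray(x, dtype=float)
    y = x if y is None else np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("traces must have equal length")
    n = len(x)
    out = np.empty(len(lags))
    for i, k in enumerate(lags):
        if k < 0 or k >= n:
            raise ValueError(f"lag {k} outside trace")
        xv = x[: n - k] if k else x
        yv = y[k:] if k else y
        mx = xv.mean()
        my = yv.mean()
        if mx == 0 or my == 0:
            raise ZeroDivisionError("zero-mean trace: correlation undefined")
        out[i] = float(np.dot(xv, yv)) / (len(xv) * mx * my) - 1.0
    return out


def multi_tau_lags(n_samples: int, bin_s: float = DEFAULT_BIN_S,
                   max_lag_s: float = DEFAULT_MAX_LAG_S,
                   m: int = M_CHANNELS) -> List[Tuple[int, int]]:
    """(stage, lag-in-stage-bins) pairs of the cascade lag grid."""
    out: List[Tuple[int, int]] = []
    stage = 0
    length = n_samples
    while length >= 2 * m:
        ks = range(1, m + 1) if stage == 0 else range(m // 2 + 1, m + 1)
        for k in ks:
            tau = k * (2**stage) * bin_s
            if tau > max_lag_s:
                return out
            out.append((stage, k))
        stage += 1
        length //= 2
    return out


def _rebin2(x: np.ndarray) -> np.ndarray:
    n = (len(x) // 2) * 2
    return 0.5 * (x[:n:2] + x[1:n:2])


def multi_tau(x: np.ndarray, y: Optional[np.ndarray] = None,
              bin_s: float = DEFAULT_BIN_S, max_lag_s: float = DEFAULT_MAX_LAG_S,
              m: int = M_CHANNELS) -> Tuple[np.ndarray, np.ndarray]:
    """Multi-tau correlation; returns (tau_s, G).

    Stage 0 evaluates lags 1..m at the base bin; each further stage halves
    the time resolution (pairwise averaging) and evaluates lags m/2+1..m in
    the coarser bins.
    """
    x = np.asarray(x, dtype=float)
    y = x if y is None else np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("traces must have equal length")
    grid = multi_tau_lags(len(x), bin_s, max_lag_s, m)
    if not grid:
        raise ValueError("trace too short for the requested lag grid")
    taus: List[float] = []
    gs: List[float] = []
    xs, ys = x, y
    auto = y is x
    stage = 0
    for st, k in grid:
        while st > stage:
            xs = _rebin2(xs)
            ys = xs if auto else _rebin2(ys)
            stage += 1
        taus.append(k * (2**stage) * bin_s)
        gs.append(direct_correlate(xs, ys, [k])[0])
    return np.asarray(taus), np.asarray(gs)


def _segment_errors(x: np.ndarray, y: Optional[np.ndarray], tau: np.ndarray,
                    bin_s: float, n_segments: int = N_ERR_SEGMENTS,
                    m: int = M_CHANNELS) -> np.ndarray:
    """Per-lag SD of segment estimates / sqrt(n_segments)."""
    n = len(x)
    seg_len = n // n_segments
    if seg_len < 4 * m:
        return np.full(len(tau), np.nan)
    vals = np.full((n_segments, len(tau)), np.nan)
    for s in range(n_segments):
        xs = x[s * seg_len:(s + 1) * seg_len]
        ys = None if y is None else y[s * seg_len:(s + 1) * seg_len]
        try:
            t_s, g_s = multi_tau(xs, ys, bin_s, max_lag_s=tau[-1], m=m)
        except (ValueError, ZeroDivisionError):
            continue
        k = min(len(t_s), len(tau))
        vals[s, :k] = g_s[:k]
    n_ok = np.sum(np.isfinite(vals), axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.nansum(vals, axis=0) / np.maximum(n_ok, 1)
        ss = np.nansum((vals - mean[None, :]) ** 2, axis=0)
        sd = np.sqrt(ss / np.maximum(n_ok - 1, 1))
    err = sd / np.sqrt(np.maximum(n_ok, 1))
    err[n_ok < 2] = np.nan
    return err


def autocorrelate(i_trace: np.ndarray, bin_s: float = DEFAULT_BIN_S,
                  gamma_mean: float = 1.0, max_lag_s: float = DEFAULT_MAX_LAG_S,
                  with_err: bool = True) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Photobleaching-aware autocorrelation: G = (1/<gamma>) (<II>/<I>^2 - 1)."""
    i_trace = np.asarray(i_trace, dtype=float)
    if i_trace.mean() == 0:
        raise ZeroDivisionError("zero-mean trace: correlation undefined")
    tau, g = multi_tau(i_trace, None, bin_s, max_lag_s)
    g = g / gamma_mean
    err = (_segment_errors(i_trace, None, tau, bin_s) / gamma_mean
           if with_err else np.full(len(tau), np.nan))
    return tau, g, err


def crosscorrelate(i_g: np.ndarray, i_r: np.ndarray, bin_s: float = DEFAULT_BIN_S,
                   max_lag_s: float = DEFAULT_MAX_LAG_S, with_err: bool = True
                   ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cross-correlation G_x = <I_G(t) I_R(t+tau)>/(<I_G><I_R>) - 1 (no gamma)."""
    tau, g = multi_tau(np.asarray(i_g, float), np.asarray(i_r, float), bin_s, max_lag_s)
    err = (_segment_errors(np.asarray(i_g, float), np.asarray(i_r, float), tau, bin_s)
           if with_err else np.full(len(tau), np.nan))
    return tau, g, err


@dataclass
class CorrelationSet:
    """G_G, G_R and G_x on a shared quasi-logarithmic lag grid for one scan."""

    tau_s: np.ndarray
    g_g: np.ndarray
    g_r: np.ndarray
    g_x: np.ndarray
    err_g: np.ndarray
    err_r: np.ndarray
    err_x: np.ndarray
    meta: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.tau_s) <= 0):
            raise ValueError("tau grid must be strictly increasing")


def correlate_traces(i_g: np.ndarray, i_r: np.ndarray, bin_s: float = DEFAULT_BIN_S,
                     gamma_mean_g: float = 1.0, gamma_mean_r: float = 1.0,
                     max_lag_s: float = DEFAULT_MAX_LAG_S,
                     meta: Optional[Dict[str, float]] = None) -> CorrelationSet:
    tau, gg, eg = autocorrelate(i_g, bin_s, gamma_mean_g, max_lag_s)
    _, gr, er = autocorrelate(i_r, bin_s, gamma_mean_r, max_lag_s)
    _, gx, ex = crosscorrelate(i_g, i_r, bin_s, max_lag_s)
    md = {"bin_s": bin_s, "gamma_mean_g": gamma_mean_g, "gamma_mean_r": gamma_mean_r}
    if meta:
        md.update(meta)
    return CorrelationSet(tau_s=tau, g_g=gg, g_r=gr, g_x=gx,
                          err_g=eg, err_r=er, err_x=ex, meta=md)


def sd_of_curves(curves: Sequence[np.ndarray]) -> Tuple[np.ndarray, float, float]:
    """Scatter of individual correlation curves around their average.

    ``curves`` are already normalized to amplitude 1 and share a lag grid.
    Per curve, SD_i = sqrt(mean_tau (G_i - Gbar)^2); returns the per-curve
    SDs plus their ensemble mean and SD.
    """
    arr = np.stack([np.asarray(c, float) for c in curves])
    if arr.shape[0] < 2:
        raise ValueError("need at least two curves")
    gbar = arr.mean(axis=0)
    sd_i = np.sqrt(np.mean((arr - gbar[None, :]) ** 2, axis=1))
    return sd_i, float(sd_i.mean()), float(sd_i.std(ddof=1))


def sd_vs_time(curves_by_duration: Dict[float, Sequence[np.ndarray]]
               ) -> Dict[float, Tuple[float, float]]:
    """Mean and SD of the curve-scatter metric per acquisition duration.

    Input curves must be amplitude-normalized and share the lag grid within
    each duration; durations with mismatched grids raise.
    """
    out: Dict[float, Tuple[float, float]] = {}
    for dur, curves in curves_by_duration.items():
        lens = {len(c) for c in curves}
        if len(lens) != 1:
            raise ValueError("curves of one duration must share the lag grid")
        _, mean_sd, sd_sd = sd_of_curves(curves)
        out[dur] = (mean_sd, sd_sd)
    return out
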