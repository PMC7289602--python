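"""Membrane tracking, signal/background trace extraction and quality control.

The membrane shows up as a bright ridge in the kymograph; its position is
tracked per scan line from the channel-summed, 3-line boxcar-smoothed counts
(smoothing is used for localization only, never for the extracted
intensities).  The signal is the dwell-rescaled count sum over the ridge
pixel plus ``halfwidth`` neighbors on either side; the background is taken
from one-pixel regions ``offset`` pixels away on both sides and scaled to the
signal window by the pixel-number ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .photonproc import Kymograph, ZMapping
from .simkymo import PhotonStream

__all__ = [
    "MembraneTrace",
    "IntensityTraces",
    "QCReport",
    "QCThresholds",
    "track_membrane",
    "extract_signal",
    "extract_background",
    "extract_traces",
    "qc_checks",
]

DEFAULT_HALFWIDTH = 2
DEFAULT_BG_OFFSET = 10


@dataclass
class MembraneTrace:
    """Per-line membrane ridge positions (z-pixel indices).

    ``positions`` has shape (n_lines, n_membranes); for two membranes the
    columns are sorted so z_MEM1 <= z_MEM2 on every line.
    """

    positions: np.ndarray
    line_time_s: float
    n_pixels: int
    low_signal_lines: int = 0

    @property
    def n_membranes(self) -> int:
        return self.positions.shape[1]

    @property
    def position_sd(self) -> float:
        """Smoothness metric: SD of ridge position in pixels (worst membrane)."""
        return float(np.max(np.std(self.positions, axis=0)))

    def center_distance(self, center_pixel: float) -> float:
        """Mean distance of the ridge(s) from the sweep center, in pixels."""
        return float(np.mean(np.abs(self.positions - center_pixel)))

    def at_times(self, t_s: np.ndarray) -> np.ndarray:
        """Ridge positions linearly interpolated onto arbitrary times."""
        t_lines = (np.arange(len(self.positions)) + 0.5) * self.line_time_s
        out = np.empty((len(t_s), self.n_membranes))
        for m in range(self.n_membranes):
            out[:, m] = np.interp(t_s, t_lines, self.positions[:, m])
        return out


def _boxcar3(x: np.ndarray) -> np.ndarray:
    """3-line boxcar along the line (time) axis with edge replication."""
    padded = np.concatenate([x[:1], x, x[-1:]], axis=0)
    return (padded[:-2] + padded[1:-1] + padded[2:]) / 3.0


def track_membrane(kymos, n_membranes: int = 1) -> MembraneTrace:
    """Locate the membrane ridge(s) on every scan line.

    ``kymos`` may be a single Kymograph or a dict of per-channel kymographs,
    in which case the channel-summed counts are used.  Ridges are the pixels
    with the highest (smoothed) counts; in two-membrane mode the two highest
    non-adjacent pixels, sorted by z.  All-zero lines carry the previous
    position forward and are counted as low-signal evidence.
    """
    if isinstance(kymos, dict):
        items = list(kymos.values())
        counts = sum(k.counts for k in items)
        line_time = items[0].line_time_s
        n_pix = items[0].n_pixels
    else:
        counts = kymos.counts
        line_time = kymos.line_time_s
        n_pix = kymos.n_pixels
    if counts.size == 0 or not np.any(counts):
        raise ValueError("cannot track an empty kymograph")
    smooth = _boxcar3(counts)
    n_lines = smooth.shape[0]
    pos = np.zeros((n_lines, n_membranes))
    low_signal = 0
    prev: Optional[np.ndarray] = None
    for i in range(n_lines):
        line = smooth[i]
        if not np.any(line):
            low_signal += 1
            pos[i] = prev if prev is not None else n_pix // 2
            continue
        if n_membranes == 1:
            ridge = np.array([np.argmax(line)], dtype=float)
        else:
            first = int(np.argmax(line))
            masked = line.copy()
            lo = max(0, first - 1)
            masked[lo:first + 2] = -np.inf
            second = int(np.argmax(masked))
            ridge = np.sort(np.array([first, second], dtype=float))
        pos[i] = ridge
        prev = ridge
    return MembraneTrace(positions=pos, line_time_s=line_time, n_pixels=n_pix,
                         low_signal_lines=low_signal)


def _window_sum(counts: np.ndarray, centers: np.ndarray, halfwidth: int
                ) -> Tuple[np.ndarray, np.ndarray]:
    """Sum of (2*halfwidth+1) pixels around per-line centers.

    Returns (sums, clipped) where clipped marks lines whose window ran off
    the pixel range.
    """
    n_lines, n_pix = counts.shape
    c = np.rint(centers).astype(int)
    lo = c - halfwidth
    hi = c + halfwidth
    clipped = (lo < 0) | (hi >= n_pix)
    lo_c = np.clip(lo, 0, n_pix - 1)
    hi_c = np.clip(hi, 0, n_pix - 1)
    csum = np.concatenate([np.zeros((n_lines, 1)), np.cumsum(counts, axis=1)], axis=1)
    rows = np.arange(n_lines)
    return csum[rows, hi_c + 1] - csum[rows, lo_c], clipped


def extract_signal(kymo: Kymograph, trace: MembraneTrace,
                   halfwidth: int = DEFAULT_HALFWIDTH) -> np.ndarray:
    """Membrane signal per sample from a line-binned kymograph.

    One sample per (line, membrane), membranes interleaved in time order:
    shape (n_lines * n_membranes,).  Windows clipped by the array edge are
    dropped (set to NaN) and should raise the off-center QC flag.
    """
    if halfwidth < 0:
        raise ValueError("halfwidth must be >= 0")
    per_mem = []
    for m in range(trace.n_membranes):
        s, clipped = _window_sum(kymo.counts, trace.positions[:, m], halfwidth)
        s = s.astype(float)
        s[clipped] = np.nan
        per_mem.append(s)
    out = np.empty(kymo.n_lines * trace.n_membranes)
    for m, s in enumerate(per_mem):
        out[m::trace.n_membranes] = s
    return out


def extract_background(kymo: Kymograph, trace: MembraneTrace,
                       offset: int = DEFAULT_BG_OFFSET,
                       halfwidth: int = DEFAULT_HALFWIDTH) -> np.ndarray:
    """Scaled background per sample from one-pixel regions at ridge +- offset.

    The region sum is scaled by (signal pixels / background pixels); regions
    falling outside the pixel range are dropped with the scaling adjusted.
    Returned with the same interleaving as :func:`extract_signal`.
    """
    n_pix = kymo.n_pixels
    n_signal_px = 2 * halfwidth + 1
    rows = np.arange(kymo.n_lines)
    per_line_sum = np.zeros(kymo.n_lines)
    per_line_n = np.zeros(kymo.n_lines)
    for m in range(trace.n_membranes):
        c = np.rint(trace.positions[:, m]).astype(int)
        for side in (-offset, offset):
            px = c + side
            ok = (px >= 0) & (px < n_pix)
            per_line_sum[ok] += kymo.counts[rows[ok], px[ok]]
            per_line_n += ok
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = per_line_sum * (n_signal_px / per_line_n)
    scaled[per_line_n == 0] = np.nan
    out = np.empty(kymo.n_lines * trace.n_membranes)
    for m in range(trace.n_membranes):
        out[m::trace.n_membranes] = scaled
    return out


@dataclass
class IntensityTraces:
    """Signal and background time series for both channels."""

    t_s: np.ndarray
    i_raw: Dict[str, np.ndarray]
    i_bg: Dict[str, np.ndarray]
    sample_time_s: float
    qc: Optional["QCReport"] = None

    def __post_init__(self) -> None:
        n = len(self.t_s)
        for d in (self.i_raw, self.i_bg):
            for ch, arr in d.items():
                if len(arr) != n:
                    raise ValueError("trace lengths must match the time grid")


def extract_traces(gated: Dict[str, PhotonStream], mapping: ZMapping,
                   trace: MembraneTrace, bin_width_s: float = 1e-4,
                   halfwidth: int = DEFAULT_HALFWIDTH,
                   bg_offset: int = DEFAULT_BG_OFFSET,
                   duration_s: Optional[float] = None) -> IntensityTraces:
    """Fine-grained signal/background traces straight from gated photons.

    Photons are weighted by the inverse dwell weight of their z pixel (so
    that the pixel-number background scaling is exact), assigned to time bins
    of ``bin_width_s``, and summed over the 5-pixel membrane window / the
    one-pixel background regions around the interpolated ridge position.
    """
    any_stream = next(iter(gated.values()))
    if duration_s is None:
        duration_s = any_stream.duration_s
    n_bins = max(1, int(duration_s / bin_width_s))
    t = (np.arange(n_bins) + 0.5) * bin_width_s
    ridge = trace.at_times(t)  # (n_bins, n_membranes)
    n_signal_px = 2 * halfwidth + 1
    i_raw: Dict[str, np.ndarray] = {}
    i_bg: Dict[str, np.ndarray] = {}
    inv_dwell = 1.0 / mapping.dwell_weight
    for ch, ph in gated.items():
        if len(ph) == 0:
            i_raw[ch] = np.zeros(n_bins)
            i_bg[ch] = np.zeros(n_bins)
            continue
        t_ph = ph.macro_time_ns * 1e-9
        b = np.floor(t_ph / bin_width_s).astype(np.int64)
        pix = mapping.pixel_of_phase(ph.tag_phase)
        ok = (b >= 0) & (b < n_bins) & (pix >= 0)
        b = b[ok]
        pix = pix[ok]
        w = inv_dwell[pix]
        sig = np.zeros(n_bins)
        bg = np.zeros(n_bins)
        n_bg_px = np.zeros(n_bins)
        for m in range(trace.n_membranes):
            c = np.rint(ridge[:, m]).astype(int)
            dist = np.abs(pix - c[b])
            in_win = dist <= halfwidth
            np.add.at(sig, b[in_win], w[in_win])
            in_bg = dist == bg_offset
            np.add.at(bg, b[in_bg], w[in_bg])
            for side in (-bg_offset, bg_offset):
                n_bg_px += (c + side >= 0) & (c + side < mapping.n_pixels)
        with np.errstate(invalid="ignore", divide="ignore"):
            bg_scaled = bg * (n_signal_px / n_bg_px)
        bg_scaled[n_bg_px == 0] = 0.0
        i_raw[ch] = sig
        i_bg[ch] = bg_scaled
    return IntensityTraces(t_s=t, i_raw=i_raw, i_bg=i_bg, sample_time_s=bin_width_s)


@dataclass(frozen=True)
class QCThresholds:
    """Automated stand-ins for the visual discard rules.

    All are conservative defaults and overridable: a scan is discarded when
    the membrane position fluctuates by more than ``max_position_sd`` pixels,
    sits further than ``max_center_fraction`` of the sweep span from the
    middle, shows a bright cluster (samples above median + ``cluster_mads``
    median absolute deviations for at least ``cluster_lines`` consecutive
    lines), or carries too little signal over background.
    """

    max_position_sd: float = 2.0
    max_center_fraction: float = 0.25
    cluster_mads: float = 8.0
    cluster_lines: int = 2
    min_signal_to_bg: float = 2.0


@dataclass
class QCReport:
    flags: Dict[str, bool]
    evidence: Dict[str, float]

    @property
    def passed(self) -> bool:
        return not any(self.flags.values())

    def reasons(self) -> List[str]:
        return [k for k, v in self.flags.items() if v]


def _longest_run(mask: np.ndarray) -> int:
    best = run = 0
    for v in mask:
        run = run + 1 if v else 0
        best = max(best, run)
    return best


def qc_checks(kymo_or_kymos, trace: MembraneTrace, signal: np.ndarray,
              bg: np.ndarray, thresholds: QCThresholds = QCThresholds()) -> QCReport:
    """Apply the automated discard rules to one scan.

    Pure function of the scan: identical data and thresholds always give the
    same report.
    """
    if isinstance(kymo_or_kymos, dict):
        any_kymo = next(iter(kymo_or_kymos.values()))
    else:
        any_kymo = kymo_or_kymos
    center = any_kymo.mapping.center_pixel
    span = any_kymo.n_pixels
    sd = trace.position_sd
    cdist = trace.center_distance(center)
    sig = np.asarray(signal, dtype=float)
    sig = sig[np.isfinite(sig)]
    bgv = np.asarray(bg, dtype=float)
    bgv = bgv[np.isfinite(bgv)]
    med = np.median(sig) if len(sig) else 0.0
    mad = np.median(np.abs(sig - med)) if len(sig) else 0.0
    if len(sig):
        hot = sig > med + thresholds.cluster_mads * max(mad, 1e-12)
        cluster_run = _longest_run(hot)
    else:
        cluster_run = 0
    mean_sig = float(np.mean(sig)) if len(sig) else 0.0
    mean_bg = float(np.mean(bgv)) if len(bgv) else 0.0
    flags = {
        "fluctuating_membrane": sd > thresholds.max_position_sd,
        "off_center": cdist > thresholds.max_center_fraction * span,
        "bright_cluster": cluster_run >= thresholds.cluster_lines,
        "low_signal": (mean_sig < thresholds.min_signal_to_bg * mean_bg)
                       or trace.low_signal_lines > 0,
    }
    evidence = {
        "position_sd_px": sd,
        "center_distance_px": cdist,
        "cluster_run_lines": float(cluster_run),
        "mean_signal": mean_sig,
        "mean_background": mean_bg,
        "low_signal_lines": float(trace.low_signal_lines),
    }
    return QCReport(flags=flags, evidence=evidence)
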