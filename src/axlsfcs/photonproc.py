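"""Photon stream -> calibrated kymographs.

Channel gating by micro time (pulsed interleaved excitation), mapping of the
axial-oscillation phase to a z position, and dwell-time-rescaled binning into
scan-line x z-pixel count matrices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np

from .simkymo import OpticsConfig, PhotonStream, PULSE_PERIOD_NS

__all__ = [
    "ZMapping",
    "Kymograph",
    "gate_channels",
    "map_phase_to_z",
    "build_kymograph",
    "build_kymographs",
]

#: dwell weights at the sweep turning points are capped at this multiple of
#: the center-pixel weight (the membrane is kept near the middle of the sweep,
#: so the edge pixels never carry signal and would only amplify noise).
EDGE_WEIGHT_CAP = 5.0

DEFAULT_N_PIXELS = 26


def map_phase_to_z(phase, optics: OpticsConfig) -> Tuple[np.ndarray, np.ndarray]:
    """Axial focus position (um) and sweep direction for oscillation phases.

    z = a sin(2 pi phase) with a the drive-scaled amplitude; the sweep moves
    upward for phase in [0.75, 1) u [0, 0.25) and downward otherwise.
    """
    phase = np.asarray(phase, dtype=float)
    a = optics.axial_amplitude_um
    z = a * np.sin(2.0 * np.pi * phase)
    up = (phase < 0.25) | (phase >= 0.75)
    return z, up


@dataclass
class ZMapping:
    """Phase -> z mapping with pixel grid and per-pixel dwell weights.

    ``dwell_weight`` is the time the focus spends in each z pixel per
    crossing, relative to the center pixel; rescaled kymograph counts are raw
    counts divided by it.  A user-measured calibration may replace the ideal
    sinusoid by passing explicit ``pixel_edges``/``dwell_weight``.
    """

    optics: OpticsConfig
    n_pixels: int = DEFAULT_N_PIXELS
    pixel_edges: np.ndarray = field(default=None)  # type: ignore[assignment]
    dwell_weight: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        a = self.optics.axial_amplitude_um
        if self.pixel_edges is None:
            self.pixel_edges = np.linspace(-a, a, self.n_pixels + 1)
        else:
            self.pixel_edges = np.asarray(self.pixel_edges, dtype=float)
            self.n_pixels = len(self.pixel_edges) - 1
        if np.any(np.diff(self.pixel_edges) <= 0):
            raise ValueError("pixel_edges must be strictly increasing")
        if self.dwell_weight is None:
            self.dwell_weight = self._sinusoid_dwell()
        else:
            self.dwell_weight = np.asarray(self.dwell_weight, dtype=float)
        if len(self.dwell_weight) != self.n_pixels or np.any(self.dwell_weight <= 0):
            raise ValueError("dwell_weight must be positive, one entry per pixel")

    def _sinusoid_dwell(self) -> np.ndarray:
        a = self.optics.axial_amplitude_um
        lo = np.clip(self.pixel_edges[:-1] / a, -1.0, 1.0)
        hi = np.clip(self.pixel_edges[1:] / a, -1.0, 1.0)
        dt = np.arcsin(hi) - np.arcsin(lo)  # per crossing, up to 1/(2 pi f)
        center = int(np.searchsorted(self.pixel_edges, 0.0) - 1)
        center = min(max(center, 0), self.n_pixels - 1)
        w = dt / dt[center]
        return np.minimum(w, EDGE_WEIGHT_CAP)

    @property
    def z_pixel_size_um(self) -> float:
        return float(np.mean(np.diff(self.pixel_edges)))

    @property
    def center_pixel(self) -> float:
        """Pixel coordinate of the sweep center z = 0."""
        return float(np.interp(0.0, self.pixel_edges, np.arange(self.n_pixels + 1)) - 0.5)

    def z_of_phase(self, phase) -> Tuple[np.ndarray, np.ndarray]:
        return map_phase_to_z(phase, self.optics)

    def pixel_of_phase(self, phase) -> np.ndarray:
        """z-pixel index per photon phase; out-of-range photons get -1."""
        z, _ = self.z_of_phase(phase)
        pix = np.digitize(z, self.pixel_edges) - 1
        pix[(z < self.pixel_edges[0]) | (z >= self.pixel_edges[-1])] = -1
        # photons exactly at +a fall outside the half-open last bin; keep them
        pix[z == self.pixel_edges[-1]] = self.n_pixels - 1
        return pix

    def pixel_z_centers(self) -> np.ndarray:
        return 0.5 * (self.pixel_edges[:-1] + self.pixel_edges[1:])


def gate_channels(stream: PhotonStream, pie_window_ns: Optional[float] = None
                  ) -> Tuple[PhotonStream, PhotonStream]:
    """Split a stream into (green, red) by micro time.

    Green gate is [0, pie_window), red gate [pie_window, 25); half-open, so
    every photon lands in exactly one channel.
    """
    if pie_window_ns is None:
        pie_window_ns = float(stream.header.get("pie_window_ns", 12.5))
    if not (0 < pie_window_ns < PULSE_PERIOD_NS):
        raise ValueError("pie_window must lie strictly inside (0, 25) ns")
    green = stream.micro_time_ns < pie_window_ns

    def _sub(mask: np.ndarray) -> PhotonStream:
        return PhotonStream(
            macro_time_ns=stream.macro_time_ns[mask],
            micro_time_ns=stream.micro_time_ns[mask],
            tag_cycle=stream.tag_cycle[mask],
            tag_phase=stream.tag_phase[mask],
            header=dict(stream.header),
        )

    return _sub(green), _sub(~green)


@dataclass
class Kymograph:
    """Scan line x z-pixel count matrix for one color channel.

    ``counts`` is dwell-rescaled (raw counts divided by the per-pixel dwell
    weight); ``raw_counts`` keeps the histogrammed photons so that the
    rescaling is exactly invertible.
    """

    counts: np.ndarray
    raw_counts: np.ndarray
    line_time_s: float
    mapping: ZMapping
    channel: str = ""
    empty: bool = False

    @property
    def n_lines(self) -> int:
        return self.counts.shape[0]

    @property
    def n_pixels(self) -> int:
        return self.counts.shape[1]

    @property
    def z_pixel_size_um(self) -> float:
        return self.mapping.z_pixel_size_um

    @property
    def duration_s(self) -> float:
        return self.n_lines * self.line_time_s


def build_kymograph(photons: PhotonStream, mapping: ZMapping, line_time_s: float = 0.5,
                    duration_s: Optional[float] = None, channel: str = "") -> Kymograph:
    """Histogram gated photons into a dwell-rescaled kymograph.

    Both half-cycle crossings of each oscillation accumulate into the same z
    pixels.  An empty photon set yields an all-zero kymograph flagged
    ``empty``.
    """
    if duration_s is None:
        duration_s = photons.duration_s
    if line_time_s <= 0:
        raise ValueError("line_time must be > 0")
    n_lines = max(1, int(round(duration_s / line_time_s)))
    n_pix = mapping.n_pixels
    raw = np.zeros((n_lines, n_pix), dtype=np.float64)
    empty = len(photons) == 0
    if not empty:
        t_s = photons.macro_time_ns * 1e-9
        line = np.floor(t_s / line_time_s).astype(np.int64)
        pix = mapping.pixel_of_phase(photons.tag_phase)
        ok = (line >= 0) & (line < n_lines) & (pix >= 0)
        np.add.at(raw, (line[ok], pix[ok]), 1.0)
    counts = raw / mapping.dwell_weight[None, :]
    return Kymograph(counts=counts, raw_counts=raw, line_time_s=line_time_s,
                     mapping=mapping, channel=channel, empty=empty)


def build_kymographs(stream: PhotonStream, optics: Optional[OpticsConfig] = None,
                     line_time_s: float = 0.5, n_pixels: int = DEFAULT_N_PIXELS
                     ) -> Dict[str, Kymograph]:
    """Gate a stream and build one kymograph per color channel."""
    if optics is None:
        optics = stream.optics()
    mapping = ZMapping(optics, n_pixels=n_pixels)
    g, r = gate_channels(stream, optics.pie_window_ns)
    dur = stream.duration_s
    return {
        "G": build_kymograph(g, mapping, line_time_s, dur, channel="G"),
        "R": build_kymograph(r, mapping, line_time_s, dur, channel="R"),
    }
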