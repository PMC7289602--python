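"""Photon-level Monte-Carlo simulator of axial line-scanning FCS experiments.

The simulator emulates a dual-color confocal microscope whose observation
volume is swept sinusoidally along the optical axis by a resonant lens while
labeled receptors and ligand-receptor complexes diffuse in a flat membrane
patch.  Each membrane crossing of the focus deposits an excitation dose on
every fluorophore; detected photons are Poisson draws whose mean follows the
3D Gaussian observation volume, tagged with macro/micro times and the phase
of the axial oscillation, exactly like the time-tagged output of a
time-correlated single-photon-counting card with pulsed interleaved
excitation (green gate first, red gate second, 25 ns pulse period).

Species naming
--------------
``R``   receptor carrying only the red construct (ligand-free),
``G``   membrane-bound ligand on an unlabeled receptor (green only),
``RL``  dual-labeled ligand-receptor complex.
Maturation yields ``eta_g``/``eta_r`` dark a fraction of the constructs at
particle creation, which automatically produces the dark variants (an ``RL``
whose red chromophore failed to mature *is* a green-only complex).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np

__all__ = [
    "OpticsConfig",
    "SimConfig",
    "PhotonStream",
    "SPECIES_LABELS",
    "bound_fraction",
    "simulate_trajectories",
    "simulate_photons",
    "binding_series_configs",
    "make_binding_series",
]

PULSE_PERIOD_NS = 25.0

#: species -> (green labeled, red labeled)
SPECIES_LABELS: Dict[str, Tuple[bool, bool]] = {
    "R": (False, True),
    "G": (True, False),
    "RL": (True, True),
}


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass(frozen=True)
class OpticsConfig:
    """Optical calibration of the scanning confocal microscope.

    Waists are 1/e^2 radii.  ``tag_amplitude_um`` is the peak axial excursion
    at full drive; the effective half-span of the sweep is
    ``tag_amplitude_um * drive_fraction`` (default 0.75 drive gives a
    ~5.3 um total span for the default lens).
    """

    omega_g_nm: float = 207.0
    omega_r_nm: float = 251.0
    z0_g_nm: float = 1035.0
    z0_r_nm: float = 1255.0
    tag_frequency_khz: float = 147.0
    tag_amplitude_um: float = 3.53
    drive_fraction: float = 0.75
    pie_window_ns: float = 12.5

    def __post_init__(self) -> None:
        for name in ("omega_g_nm", "omega_r_nm", "z0_g_nm", "z0_r_nm"):
            _require(getattr(self, name) > 0, f"{name} must be > 0")
        _require(self.z0_g_nm >= self.omega_g_nm, "z0_g must be >= omega_g for a confocal volume")
        _require(self.z0_r_nm >= self.omega_r_nm, "z0_r must be >= omega_r for a confocal volume")
        _require(self.tag_frequency_khz > 0, "tag_frequency must be > 0")
        _require(self.tag_amplitude_um > 0, "tag_amplitude must be > 0")
        _require(0 < self.drive_fraction <= 1, "drive_fraction must be in (0, 1]")
        _require(0 < self.pie_window_ns < PULSE_PERIOD_NS, "pie_window must lie inside the pulse period")

    @property
    def period_s(self) -> float:
        return 1.0 / (self.tag_frequency_khz * 1e3)

    @property
    def axial_amplitude_um(self) -> float:
        """Half-span of the sweep at the configured drive."""
        return self.tag_amplitude_um * self.drive_fraction

    def waist_um(self, channel: str) -> float:
        return (self.omega_g_nm if channel == "G" else self.omega_r_nm) * 1e-3

    def z0_um(self, channel: str) -> float:
        return (self.z0_g_nm if channel == "G" else self.z0_r_nm) * 1e-3

    def to_header(self) -> Dict[str, float]:
        return {
            "omega_g_nm": self.omega_g_nm,
            "omega_r_nm": self.omega_r_nm,
            "z0_g_nm": self.z0_g_nm,
            "z0_r_nm": self.z0_r_nm,
            "tag_frequency_khz": self.tag_frequency_khz,
            "tag_amplitude_um": self.tag_amplitude_um,
            "drive_fraction": self.drive_fraction,
            "pie_window_ns": self.pie_window_ns,
        }

    @classmethod
    def from_header(cls, header: Dict[str, float]) -> "OpticsConfig":
        keys = (
            "omega_g_nm", "omega_r_nm", "z0_g_nm", "z0_r_nm",
            "tag_frequency_khz", "tag_amplitude_um", "drive_fraction", "pie_window_ns",
        )
        return cls(**{k: float(header[k]) for k in keys if k in header})


@dataclass(frozen=True)
class SimConfig:
    """Physical and numerical parameters of one simulated scan.

    Densities are per-species area densities (um^-2); diffusion coefficients
    are um^2/s; ``brightness_*`` is the mean detected photon rate per
    fluorophore per microsecond with the focus centered on the molecule;
    background rates are uncorrelated counts in kHz.  ``bleach_*`` is the
    photobleaching probability per membrane crossing for a fluorophore at the
    focus center (scaled down by the lateral Gaussian for off-center ones).
    """

    box_side_um: float = 4.0
    densities: Dict[str, float] = field(default_factory=lambda: {"R": 30.0, "RL": 20.0})
    diffusion: Dict[str, float] = field(default_factory=dict)
    default_diffusion: float = 0.35
    k_d_nm: Optional[float] = None
    c_l_series_nm: Tuple[float, ...] = ()
    eta_g: float = 1.0
    eta_r: float = 1.0
    brightness_g: float = 0.01
    brightness_r: float = 0.01
    background_g_khz: float = 0.0
    background_r_khz: float = 0.0
    bleach_g: float = 0.0
    bleach_r: float = 0.0
    crosstalk: float = 0.0
    duration_s: float = 60.0
    membrane_z_um: float = 0.0
    drift_amplitude_um: float = 0.0
    drift_period_s: float = 30.0
    traj_dt_s: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        _require(math.isfinite(self.box_side_um) and self.box_side_um > 0, "box_side must be positive")
        for name, val in self.densities.items():
            _require(name in SPECIES_LABELS, f"unknown species {name!r}")
            _require(math.isfinite(val) and val >= 0, f"density of {name!r} must be >= 0")
        for name, val in self.diffusion.items():
            _require(math.isfinite(val) and val >= 0, f"diffusion of {name!r} must be >= 0")
        _require(self.default_diffusion >= 0, "diffusion must be >= 0")
        _require(0 < self.eta_g <= 1, "eta_g must be in (0, 1]")
        _require(0 < self.eta_r <= 1, "eta_r must be in (0, 1]")
        for name in ("brightness_g", "brightness_r", "background_g_khz",
                     "background_r_khz", "bleach_g", "bleach_r"):
            v = getattr(self, name)
            _require(math.isfinite(v) and v >= 0, f"{name} must be >= 0")
        _require(0 <= self.crosstalk < 1, "crosstalk must be in [0, 1)")
        _require(self.duration_s > 0, "duration must be > 0")
        _require(self.traj_dt_s > 0, "traj_dt must be > 0")
        if self.k_d_nm is not None:
            _require(self.k_d_nm > 0, "K_D must be > 0")

    def d_of(self, species: str) -> float:
        return self.diffusion.get(species, self.default_diffusion)

    def to_header(self) -> Dict[str, float]:
        out = {
            "box_side_um": self.box_side_um,
            "duration_s": self.duration_s,
            "eta_g": self.eta_g,
            "eta_r": self.eta_r,
            "seed": self.seed,
        }
        for k, v in self.densities.items():
            out[f"density_{k}"] = v
        return out


def bound_fraction(k_d_nm: float, c_l_nm: float) -> float:
    """Equilibrium fraction of ligand-bound receptors, 1/(1 + K_D/C_L)."""
    if k_d_nm <= 0:
        raise ValueError("K_D must be > 0")
    if c_l_nm < 0:
        raise ValueError("C_L must be >= 0")
    if c_l_nm == 0:
        return 0.0
    return 1.0 / (1.0 + k_d_nm / c_l_nm)


# ---------------------------------------------------------------------------
# particle setup
# ---------------------------------------------------------------------------

def _draw_particles(cfg: SimConfig, rng: np.random.Generator):
    """Draw particle positions, label states and diffusion coefficients."""
    L = cfg.box_side_um
    pos_list: List[np.ndarray] = []
    lab_g: List[np.ndarray] = []
    lab_r: List[np.ndarray] = []
    dcoef: List[np.ndarray] = []
    names: List[str] = []
    counts: Dict[str, int] = {}
    for name in sorted(cfg.densities):
        dens = cfg.densities[name]
        n = int(rng.poisson(dens * L * L))
        counts[name] = n
        if n == 0:
            continue
        g_lbl, r_lbl = SPECIES_LABELS[name]
        pos_list.append(rng.uniform(-L / 2, L / 2, size=(n, 2)))
        lab_g.append((rng.random(n) < cfg.eta_g) if g_lbl else np.zeros(n, bool))
        lab_r.append((rng.random(n) < cfg.eta_r) if r_lbl else np.zeros(n, bool))
        dcoef.append(np.full(n, cfg.d_of(name)))
        names.extend([name] * n)
    if pos_list:
        pos = np.concatenate(pos_list)
        g = np.concatenate(lab_g)
        r = np.concatenate(lab_r)
        d = np.concatenate(dcoef)
    else:
        pos = np.zeros((0, 2))
        g = np.zeros(0, bool)
        r = np.zeros(0, bool)
        d = np.zeros(0)
    return pos, g, r, d, counts


def simulate_trajectories(
    cfg: SimConfig,
    optics: OpticsConfig = OpticsConfig(),
    n_steps: Optional[int] = None,
    dt_s: Optional[float] = None,
) -> Dict[str, np.ndarray]:
    """Simulate 2D Brownian trajectories with periodic wrapping.

    Returns a dict mapping species name to an array of shape
    ``(n_steps, n_particles, 2)`` (um).  By default positions are sampled on
    the scan half-period grid (one membrane crossing per step); pass ``dt_s``
    to coarsen.  Intended for validation and small problems - the photon
    simulator advances the same dynamics in a streaming fashion.
    """
    rng = np.random.default_rng(cfg.seed)
    dt = dt_s if dt_s is not None else optics.period_s / 2.0
    if n_steps is None:
        n_steps = max(1, int(cfg.duration_s / dt))
    L = cfg.box_side_um
    out: Dict[str, np.ndarray] = {}
    for name in sorted(cfg.densities):
        n = int(rng.poisson(cfg.densities[name] * L * L))
        start = rng.uniform(-L / 2, L / 2, size=(n, 2))
        sigma = math.sqrt(2.0 * cfg.d_of(name) * dt)
        steps = rng.standard_normal((n_steps - 1, n, 2)) * sigma
        traj = np.concatenate([start[None], start[None] + np.cumsum(steps, axis=0)])
        traj = (traj + L / 2) % L - L / 2
        out[name] = traj
    return out


# ---------------------------------------------------------------------------
# photon generation
# ---------------------------------------------------------------------------

def _axial_dose_us(z_m: np.ndarray, a_um: float, period_s: float, z0_um: float,
                   n_quad: int = 2048) -> np.ndarray:
    """Excitation dose (us of center-equivalent exposure) per membrane crossing.

    Integrates exp(-2 (z_m - z(t))^2 / z0^2) over one half period of
    z(t) = a sin(2 pi f t); valid for any membrane position inside the sweep.
    """
    z_m = np.atleast_1d(np.asarray(z_m, dtype=float))
    t = (np.arange(n_quad) + 0.5) / n_quad * (period_s / 2.0) - period_s / 4.0
    z = a_um * np.sin(2.0 * np.pi / period_s * t)
    w = np.exp(-2.0 * (z_m[:, None] - z[None, :]) ** 2 / z0_um**2)
    return w.mean(axis=1) * (period_s / 2.0) * 1e6


def _membrane_z(cfg: SimConfig, t_s: np.ndarray) -> np.ndarray:
    z = np.full_like(np.asarray(t_s, dtype=float), cfg.membrane_z_um)
    if cfg.drift_amplitude_um > 0:
        z = z + cfg.drift_amplitude_um * np.sin(2.0 * np.pi * t_s / cfg.drift_period_s)
    return z


@dataclass
class PhotonStream:
    """Time-tagged photon events from one scan (or one simulation).

    ``macro_time_ns`` is non-decreasing; ``micro_time_ns`` lies in [0, 25);
    ``tag_cycle`` counts axial oscillations and ``tag_phase`` is the fraction
    of the current oscillation in [0, 1).
    """

    macro_time_ns: np.ndarray
    micro_time_ns: np.ndarray
    tag_cycle: np.ndarray
    tag_phase: np.ndarray
    header: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.macro_time_ns)
        for name in ("micro_time_ns", "tag_cycle", "tag_phase"):
            if len(getattr(self, name)) != n:
                raise ValueError("photon columns must have equal length")
        if n:
            if np.any(np.diff(self.macro_time_ns) < 0):
                raise ValueError("macro_time must be non-decreasing")
            mt = self.micro_time_ns
            if mt.min() < 0 or mt.max() >= PULSE_PERIOD_NS:
                raise ValueError("micro_time must lie in [0, 25) ns")

    def __len__(self) -> int:
        return len(self.macro_time_ns)

    @property
    def duration_s(self) -> float:
        return float(self.header.get("duration_s", self.macro_time_ns[-1] * 1e-9 if len(self) else 0.0))

    def optics(self) -> OpticsConfig:
        return OpticsConfig.from_header(self.header)


def simulate_photons(cfg: SimConfig, optics: OpticsConfig = OpticsConfig()) -> PhotonStream:
    """Run the full photon-level simulation of one axial scan.

    Positions advance once per ``traj_dt_s`` (default 0.1 ms, about 29
    membrane crossings; the Brownian rms displacement per crossing is ~1.5 nm,
    far below the beam waist, so finer stepping changes nothing measurable).
    Per crossing, each live fluorophore contributes a Poisson mean of
    ``brightness x lateral Gaussian x axial transit dose``; photon times
    within a crossing follow the axial Gaussian emission profile mapped back
    through the arcsine of the sinusoidal sweep.  Identical seed gives a
    bit-identical stream.
    """
    rng = np.random.default_rng(cfg.seed)
    pos, lab_g, lab_r, dcoef, counts = _draw_particles(cfg, rng)
    n_part = len(pos)

    period = optics.period_s
    half = period / 2.0
    a = optics.axial_amplitude_um
    stride = max(1, int(round(cfg.traj_dt_s / half)))
    n_cross = int(cfg.duration_s / half)
    n_blocks = (n_cross + stride - 1) // stride
    L = cfg.box_side_um

    channels = {
        "G": (optics.waist_um("G"), optics.z0_um("G"), cfg.brightness_g, cfg.bleach_g, lab_g),
        "R": (optics.waist_um("R"), optics.z0_um("R"), cfg.brightness_r, cfg.bleach_r, lab_r),
    }

    # membrane position and axial dose per block
    t_blocks = (np.arange(n_blocks) + 0.5) * stride * half
    z_m_blocks = _membrane_z(cfg, t_blocks)
    dose: Dict[str, np.ndarray] = {}
    for ch, (_, z0, _, _, _) in channels.items():
        if cfg.drift_amplitude_um > 0 or cfg.membrane_z_um != 0.0:
            grid = np.linspace(z_m_blocks.min(), z_m_blocks.max(), 65)
            if grid[0] == grid[-1]:
                dose[ch] = np.full(n_blocks, _axial_dose_us(grid[:1], a, period, z0)[0])
            else:
                dose[ch] = np.interp(z_m_blocks, grid, _axial_dose_us(grid, a, period, z0))
        else:
            dose[ch] = np.full(n_blocks, _axial_dose_us(np.zeros(1), a, period, z0)[0])

    counts_per_cross = {ch: np.zeros(n_cross, dtype=np.int64) for ch in channels}

    if n_part and n_cross:
        sigma_step = np.sqrt(2.0 * dcoef * stride * half).astype(np.float32)
        pos32 = pos.astype(np.float32)
        bleach_thresh = {ch: rng.exponential(size=n_part) for ch in channels}
        cumhaz = {ch: np.zeros(n_part) for ch in channels}
        mask = {ch: channels[ch][4].astype(np.float32) for ch in channels}

        chunk = 512
        for b0 in range(0, n_blocks, chunk):
            b1 = min(b0 + chunk, n_blocks)
            nb = b1 - b0
            steps = rng.standard_normal((nb, n_part, 2), dtype=np.float32)
            steps *= sigma_step[None, :, None]
            path = pos32[None] + np.cumsum(steps, axis=0)
            pos32 = path[-1].copy()
            path += L / 2
            path %= L
            path -= L / 2
            r2 = np.square(path[..., 0]) + np.square(path[..., 1])  # (nb, n_part)
            c_lo = b0 * stride
            c_hi = min(b1 * stride, n_cross)
            # crossings per block within this chunk (last block may be partial)
            k_per_block = np.full(nb, stride, dtype=np.int64)
            tail = c_hi - c_lo - stride * (nb - 1)
            k_per_block[-1] = max(tail, 0)
            for ch, (omega, _, bright, sigma_b, _) in channels.items():
                w = np.exp(-2.0 * r2 / np.float32(omega * omega)) * mask[ch]
                if sigma_b > 0:
                    haz = (w.astype(np.float64) * dose[ch][b0:b1, None]
                           / dose[ch].max() * k_per_block[:, None]) * sigma_b
                    cum = cumhaz[ch][None, :] + np.cumsum(haz, axis=0)
                    alive = (cum - haz) < bleach_thresh[ch][None, :]
                    cumhaz[ch] = cum[-1]
                    w = w * alive
                mu_cross = bright * dose[ch][b0:b1] * w.sum(axis=1, dtype=np.float64)
                mu_rep = np.repeat(mu_cross, k_per_block)
                counts_per_cross[ch][c_lo:c_hi] = rng.poisson(mu_rep)

    # expand crossing counts into photon records
    pie = optics.pie_window_ns
    parts: List[Tuple[np.ndarray, np.ndarray]] = []  # (macro_s, micro_ns)
    for ch, (_, z0, _, _, _) in channels.items():
        cc = counts_per_cross[ch]
        nph = int(cc.sum())
        if nph:
            idx = np.repeat(np.arange(n_cross), cc)
            cycle = idx // 2
            up = (idx % 2) == 0
            z_mb = z_m_blocks[idx // stride]
            z_emit = z_mb + rng.normal(0.0, z0 / 2.0, size=nph)
            np.clip(z_emit, -0.999 * a, 0.999 * a, out=z_emit)
            p = np.arcsin(z_emit / a) / (2.0 * np.pi)
            phase = np.where(up, p, 0.5 - p)
            t = (cycle + phase) * period
            keep = (t >= 0) & (t < cfg.duration_s)
            t = t[keep]
            nph = len(t)
        else:
            t = np.zeros(0)
        if ch == "G":
            micro = rng.uniform(0.0, pie, size=nph)
            if cfg.crosstalk > 0 and nph:
                flip = rng.random(nph) < cfg.crosstalk
                micro[flip] = rng.uniform(pie, PULSE_PERIOD_NS, size=int(flip.sum()))
        else:
            micro = rng.uniform(pie, PULSE_PERIOD_NS, size=nph)
        parts.append((t, micro))
        # uncorrelated background, uniform in time (hence dwell-shaped in z)
        rate = cfg.background_g_khz if ch == "G" else cfg.background_r_khz
        n_bg = int(rng.poisson(rate * 1e3 * cfg.duration_s))
        if n_bg:
            tb = rng.uniform(0.0, cfg.duration_s, size=n_bg)
            mb = rng.uniform(0.0, pie, size=n_bg) if ch == "G" else rng.uniform(pie, PULSE_PERIOD_NS, size=n_bg)
            parts.append((tb, mb))

    t_all = np.concatenate([p[0] for p in parts])
    micro_all = np.concatenate([p[1] for p in parts])
    order = np.argsort(t_all, kind="stable")
    t_all = t_all[order]
    micro_all = micro_all[order]
    cyc = np.floor(t_all / period)
    phase = t_all / period - cyc

    header = dict(optics.to_header())
    header.update(cfg.to_header())
    for name, n in counts.items():
        header[f"n_particles_{name}"] = n
    return PhotonStream(
        macro_time_ns=t_all * 1e9,
        micro_time_ns=micro_all,
        tag_cycle=cyc.astype(np.int64),
        tag_phase=phase,
        header=header,
    )


# ---------------------------------------------------------------------------
# binding series
# ---------------------------------------------------------------------------

def binding_series_configs(cfg: SimConfig, n_scans: int = 1) -> List[Tuple[float, List[SimConfig]]]:
    """Split the labeled-receptor pool into bound/free per ligand concentration.

    For each C_L of ``cfg.c_l_series_nm`` the total labeled-receptor density
    (densities of ``R`` plus ``RL``) is conserved and split with bound
    fraction 1/(1 + K_D/C_L).  Returns ``[(C_L, [SimConfig, ...]), ...]``
    with ``n_scans`` distinct seeds per concentration.
    """
    if cfg.k_d_nm is None:
        raise ValueError("K_D must be set to build a binding series")
    if not cfg.c_l_series_nm:
        raise ValueError("C_L series must be non-empty")
    c_tot = cfg.densities.get("R", 0.0) + cfg.densities.get("RL", 0.0)
    out: List[Tuple[float, List[SimConfig]]] = []
    for i, c_l in enumerate(cfg.c_l_series_nm):
        f = bound_fraction(cfg.k_d_nm, c_l)
        dens = dict(cfg.densities)
        dens["RL"] = c_tot * f
        dens["R"] = c_tot * (1.0 - f)
        scans = [
            replace(cfg, densities=dens, seed=cfg.seed + 1000 * i + j)
            for j in range(n_scans)
        ]
        out.append((c_l, scans))
    return out


def make_binding_series(cfg: SimConfig, optics: OpticsConfig = OpticsConfig(),
                        n_scans: int = 1) -> List[Tuple[float, List[PhotonStream]]]:
    """Simulate one photon stream per scan per ligand concentration."""
    return [
        (c_l, [simulate_photons(c, optics) for c in scans])
        for c_l, scans in binding_series_configs(cfg, n_scans)
    ]
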