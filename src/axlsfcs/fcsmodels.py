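"""Diffusion model functions, correlation-curve fitting and optics arithmetic.

Axial scanning leaves a circular observation area A = pi omega0^2 on the
membrane, so a single 2D-diffusing species gives

    G(tau) = (1/N) (1 + tau/tau_D)^-1,          tau_D = omega0^2 / (4 D),

with N the mean number of labeled molecules in the area.  Lateral line
scanning sees an elongated area (pi omega0 z0) and picks up a second, slower
factor governed by the anisotropy S = z0/omega0 >= 1:

    G(tau) = (1/N) (1 + tau/tau_D)^-1/2 (1 + tau/(S^2 tau_D))^-1/2,

which reduces to the circular form at S = 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
from scipy import optimize

__all__ = [
    "FitResult",
    "OpticsCalibration",
    "model_circular",
    "model_elongated",
    "fit_circular",
    "fit_elongated",
    "density_from_amplitude",
    "diffusion_from_tau",
    "calibrate_focus",
]

SQRT_2LN2 = math.sqrt(2.0 * math.log(2.0))


def model_circular(tau, n: float, tau_d: float) -> np.ndarray:
    tau = np.asarray(tau, dtype=float)
    return (1.0 / n) / (1.0 + tau / tau_d)


def model_elongated(tau, n: float, tau_d: float, s: float) -> np.ndarray:
    tau = np.asarray(tau, dtype=float)
    return (1.0 / n) / np.sqrt((1.0 + tau / tau_d) * (1.0 + tau / (s * s * tau_d)))


@dataclass
class FitResult:
    """Parameters of a correlation-curve fit.

    ``n`` is the mean occupancy of the observation area, ``tau_d_s`` the
    diffusion time; ``s`` is the anisotropy ratio (elongated model only).
    """

    n: float
    tau_d_s: float
    s: Optional[float] = None
    cov: Optional[np.ndarray] = None
    red_chi2: float = float("nan")
    ok: bool = True
    s_at_bound: bool = False

    @property
    def g0(self) -> float:
        return 1.0 / self.n

    @property
    def n_err(self) -> float:
        if self.cov is None or not np.isfinite(self.cov[0, 0]):
            return float("nan")
        return float(np.sqrt(self.cov[0, 0]))

    @property
    def g0_err(self) -> float:
        return self.n_err / self.n**2 if np.isfinite(self.n_err) else float("nan")


def _prepare(tau, g, err, min_lag_s):
    tau = np.asarray(tau, dtype=float)
    g = np.asarray(g, dtype=float)
    keep = np.isfinite(g) & (tau >= (min_lag_s or 0.0))
    if err is not None:
        err = np.asarray(err, dtype=float)
        w_ok = np.isfinite(err) & (err > 0)
        # inverse-variance weights where available, unweighted elsewhere
        med = np.median(err[w_ok]) if np.any(w_ok) else 1.0
        sig = np.where(w_ok, err, med if med > 0 else 1.0)
    else:
        sig = np.ones_like(g)
    tau, g, sig = tau[keep], g[keep], sig[keep]
    if len(tau) < 10:
        raise ValueError("need at least 10 lags spanning the decay")
    return tau, g, sig


def _ls_fit(residual, x0s, n_params):
    best = None
    for x0 in x0s:
        try:
            sol = optimize.least_squares(residual, x0, xtol=1e-15, ftol=1e-15,
                                         gtol=1e-15, max_nfev=2000)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    return best


def _covariance(sol, n_data: int, n_par: int) -> Tuple[Optional[np.ndarray], float]:
    dof = max(n_data - n_par, 1)
    red = 2.0 * sol.cost / dof
    try:
        jtj = sol.jac.T @ sol.jac
        cov = np.linalg.inv(jtj) * red
    except np.linalg.LinAlgError:
        cov = None
    return cov, red


def fit_circular(tau, g, err=None, min_lag_s: float = 0.0) -> FitResult:
    """Weighted LS fit of the circular-area 2D diffusion model (N, tau_D).

    Multi-start over diffusion-time decades; a curve that does not decay
    comes back with ``ok=False``.
    """
    tau, g, sig = _prepare(tau, g, err, min_lag_s)
    g0_guess = max(np.median(g[: max(3, len(g) // 10)]), 1e-12)

    def residual(x):
        n, td = np.exp(x)
        return (model_circular(tau, n, td) - g) / sig

    x0s = [np.array([math.log(1.0 / g0_guess), math.log(td)])
           for td in (1e-3, 1e-2, 3e-2, 1e-1, 1.0)]
    sol = _ls_fit(residual, x0s, 2)
    if sol is None or not np.all(np.isfinite(sol.x)):
        return FitResult(n=float("nan"), tau_d_s=float("nan"), ok=False)
    n, td = np.exp(sol.x)
    cov_log, red = _covariance(sol, len(tau), 2)
    cov = None
    if cov_log is not None:
        jac_exp = np.diag([n, td])  # delta-method back to linear scale
        cov = jac_exp @ cov_log @ jac_exp
    decays = model_circular(tau[0], n, td) > 2.0 * model_circular(tau[-1], n, td)
    return FitResult(n=float(n), tau_d_s=float(td), cov=cov, red_chi2=red, ok=bool(decays))


def fit_elongated(tau, g, err=None, min_lag_s: float = 0.0,
                  s_max: float = 50.0) -> FitResult:
    """Fit (N, tau_D, S) of the elongated-area model; S is bounded >= 1.

    A fit pinned at S = 1 is flagged ``s_at_bound`` (the extra parameter
    makes the fit more ambiguous, so the flag warrants a second look).
    """
    tau, g, sig = _prepare(tau, g, err, min_lag_s)
    g0_guess = max(np.median(g[: max(3, len(g) // 10)]), 1e-12)

    def residual(x):
        n, td = np.exp(x[:2])
        s = x[2]
        return (model_elongated(tau, n, td, s) - g) / sig

    x0s = []
    for td in (1e-3, 1e-2, 5e-2, 2e-1):
        for s in (1.5, 4.0, 8.0):
            x0s.append(np.array([math.log(1.0 / g0_guess), math.log(td), s]))
    best = None
    for x0 in x0s:
        try:
            sol = optimize.least_squares(
                residual, x0,
                bounds=([-np.inf, -np.inf, 1.0], [np.inf, np.inf, s_max]),
                xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=3000)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not np.all(np.isfinite(best.x)):
        return FitResult(n=float("nan"), tau_d_s=float("nan"), s=float("nan"), ok=False)
    n, td = np.exp(best.x[:2])
    s = float(best.x[2])
    cov_log, red = _covariance(best, len(tau), 3)
    cov = None
    if cov_log is not None:
        jac = np.diag([n, td, 1.0])
        cov = jac @ cov_log @ jac
    return FitResult(n=float(n), tau_d_s=float(td), s=s, cov=cov, red_chi2=red,
                     ok=True, s_at_bound=s <= 1.0 + 1e-6)


def density_from_amplitude(g0: float, omega0_um: float) -> float:
    """Area density C = 1/(G0 pi omega0^2) in um^-2 (labeled molecules only)."""
    if g0 <= 0:
        raise ValueError("G0 must be > 0")
    return 1.0 / (g0 * math.pi * omega0_um**2)


def diffusion_from_tau(tau_d_s: float, omega0_um: float) -> float:
    """Diffusion coefficient D = omega0^2/(4 tau_D) in um^2/s."""
    if tau_d_s <= 0:
        raise ValueError("tau_D must be > 0")
    return omega0_um**2 / (4.0 * tau_d_s)


@dataclass(frozen=True)
class OpticsCalibration:
    """Two-color observation-area arithmetic from a bead calibration.

    Waists follow omega0 = FWHM / sqrt(2 ln 2); the effective dual-color area
    uses omega_eff^2 = (omega_G^2 + omega_R^2)/2 and the geometry factor
    A = A_G A_R / A_eff^2 <= 1 corrects the binding statistic for unequal
    observation areas.
    """

    omega_g_nm: float
    omega_r_nm: float
    fwhm_measured_nm: Optional[Tuple[float, float]] = None
    bead_diameter_nm: float = 0.0

    def __post_init__(self) -> None:
        if self.omega_g_nm <= 0 or self.omega_r_nm <= 0:
            raise ValueError("waists must be positive")

    @property
    def fwhm_nm(self) -> Tuple[float, float]:
        return (self.omega_g_nm * SQRT_2LN2, self.omega_r_nm * SQRT_2LN2)

    @property
    def area_g_um2(self) -> float:
        return math.pi * (self.omega_g_nm * 1e-3) ** 2

    @property
    def area_r_um2(self) -> float:
        return math.pi * (self.omega_r_nm * 1e-3) ** 2

    @property
    def omega_eff_nm(self) -> float:
        return math.sqrt((self.omega_g_nm**2 + self.omega_r_nm**2) / 2.0)

    @property
    def area_eff_um2(self) -> float:
        return math.pi * (self.omega_eff_nm * 1e-3) ** 2

    @property
    def ratio_eff_g(self) -> float:
        """A_eff / A_G."""
        return self.area_eff_um2 / self.area_g_um2

    @property
    def ratio_eff_r(self) -> float:
        """A_eff / A_R."""
        return self.area_eff_um2 / self.area_r_um2

    @property
    def a_factor(self) -> float:
        """A = A_G A_R / A_eff^2, in (0, 1], equal to 1 iff the waists match."""
        return self.area_g_um2 * self.area_r_um2 / self.area_eff_um2**2

    @classmethod
    def from_waists(cls, omega_g_nm: float, omega_r_nm: float) -> "OpticsCalibration":
        return cls(omega_g_nm=omega_g_nm, omega_r_nm=omega_r_nm)


def calibrate_focus(fwhm_measured_g_nm: float, fwhm_measured_r_nm: float,
                    bead_diameter_nm: float = 0.0) -> OpticsCalibration:
    """Bead-size-corrected focus calibration.

    FWHM = sqrt(FWHM_measured^2 - d^2), then omega0 = FWHM / sqrt(2 ln 2).
    """
    for fw in (fwhm_measured_g_nm, fwhm_measured_r_nm):
        if fw <= bead_diameter_nm:
            raise ValueError("measured FWHM must exceed the bead diameter")
    fw_g = math.sqrt(fwhm_measured_g_nm**2 - bead_diameter_nm**2)
    fw_r = math.sqrt(fwhm_measured_r_nm**2 - bead_diameter_nm**2)
    return OpticsCalibration(
        omega_g_nm=fw_g / SQRT_2LN2,
        omega_r_nm=fw_r / SQRT_2LN2,
        fwhm_measured_nm=(fwhm_measured_g_nm, fwhm_measured_r_nm),
        bead_diameter_nm=bead_diameter_nm,
    )
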