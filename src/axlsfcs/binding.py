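"""The K_D layer: the Gamma amplitude statistic and binding-isotherm fitting.

Gamma(C_L) = G_x(0)^2 / (G_G(0) G_R(0)) is a scaled equilibrium binding
isotherm,

    Gamma(C_L) = A beta / (1 + K_D / C_L),

with A the two-color observation-area factor and beta the fraction of
binding-competent receptors carrying a functional red tag.  Gamma is robust
against uncorrelated background because the background attenuation factors of
the three amplitudes cancel in the ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize

from .fcsmodels import OpticsCalibration

__all__ = [
    "BindingCurve",
    "IsothermFit",
    "HeterodimerResult",
    "gamma_statistic",
    "model_amplitudes",
    "fit_isotherm",
    "correct_ligand_maturation",
    "bound_fractions",
    "incubation_time_min",
    "aggregate_gamma",
]

MIN_SCANS_PER_POINT = 3
#: a fitted beta above this prints a warning flag: complexes with more than
#: one labeled receptor can push the apparent amplitude beyond expectation.
BETA_WARN = 0.6
REFERENCE_INCUBATION_MIN = 5.0
REFERENCE_C_L_NM = 3.5


def gamma_statistic(g_g0: float, g_r0: float, g_x0: float) -> float:
    """Gamma = G_x(0)^2 / (G_G(0) G_R(0))."""
    if g_g0 <= 0 or g_r0 <= 0:
        raise ValueError("autocorrelation amplitudes must be positive")
    if g_x0 < 0:
        g_x0 = 0.0
    return g_x0 * g_x0 / (g_g0 * g_r0)


def model_amplitudes(c_r: float, c_rl: float, c_rl_dark: float,
                     calib: OpticsCalibration) -> Tuple[float, float, float]:
    """Noiseless species-resolved correlation amplitudes.

    ``c_r``: red-only receptors, ``c_rl``: dual-labeled complexes,
    ``c_rl_dark``: complexes whose receptor tag is dark (green only), all in
    um^-2.  Returns (G_G(0), G_R(0), G_x(0)); the central oracle for
    validating the simulator:

        G_G(0) = 1 / (A_G (C_rL + C_RL))
        G_R(0) = 1 / (A_R (C_R + C_RL))
        G_x(0) = C_RL / (A_eff (C_R + C_RL)(C_rL + C_RL))
    """
    for c in (c_r, c_rl, c_rl_dark):
        if c < 0 or not math.isfinite(c):
            raise ValueError("concentrations must be finite and >= 0")
    green_total = c_rl_dark + c_rl
    red_total = c_r + c_rl
    if green_total == 0 or red_total == 0:
        raise ZeroDivisionError("no fluorescent species in one channel: amplitude undefined")
    g_g0 = 1.0 / (calib.area_g_um2 * green_total)
    g_r0 = 1.0 / (calib.area_r_um2 * red_total)
    g_x0 = c_rl / (calib.area_eff_um2 * red_total * green_total)
    return g_g0, g_r0, g_x0


@dataclass
class BindingCurve:
    """Gamma versus ligand concentration, averaged over scans."""

    c_l_nm: np.ndarray
    gamma: np.ndarray
    sem: np.ndarray
    n_scans: np.ndarray
    a_factor: float = 1.0

    def __post_init__(self) -> None:
        self.c_l_nm = np.asarray(self.c_l_nm, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)
        self.sem = np.asarray(self.sem, dtype=float)
        self.n_scans = np.asarray(self.n_scans, dtype=int)
        if np.any(self.n_scans < MIN_SCANS_PER_POINT):
            raise ValueError(
                f"each concentration needs >= {MIN_SCANS_PER_POINT} scans")
        if np.any(self.sem < 0):
            raise ValueError("SEM must be >= 0")


@dataclass
class IsothermFit:
    """Fitted equilibrium dissociation coefficient and amplitude.

    ``k_d_se``/``beta_se`` come from the fit covariance; when the fit was run
    on aggregated scans, ``k_d_se_boot``/``beta_se_boot`` hold the
    scan-resampling bootstrap values, which are better calibrated than a
    covariance from a handful of points with noisy SEM weights.
    """

    k_d_nm: float
    beta: float
    k_d_se: float
    beta_se: float
    cov: Optional[np.ndarray] = None
    a_factor: float = 1.0
    ill_conditioned: bool = False
    beta_warning: bool = False
    k_d_se_boot: Optional[float] = None
    beta_se_boot: Optional[float] = None

    @property
    def k_d_uncertainty(self) -> float:
        """The preferred SE of K_D: bootstrap when available, else covariance."""
        return self.k_d_se_boot if self.k_d_se_boot is not None else self.k_d_se

    def fraction_bound(self, c_l_nm) -> np.ndarray:
        """F(C_L) = 1/(1 + K_D/C_L); F(K_D) = 0.5 exactly."""
        c = np.asarray(c_l_nm, dtype=float)
        return 1.0 / (1.0 + self.k_d_nm / c)

    def gamma_model(self, c_l_nm) -> np.ndarray:
        return self.a_factor * self.beta * self.fraction_bound(c_l_nm)


def fit_isotherm(curve: BindingCurve, a_factor: Optional[float] = None) -> IsothermFit:
    """Weighted nonlinear LS fit of Gamma(C_L) = A beta / (1 + K_D/C_L).

    A is fixed from the optics calibration (never a free parameter); weights
    are 1/SEM^2 where available.  A concentration series lying entirely on
    one side of the fitted K_D flags the fit as ill-conditioned (beta and K_D
    become degenerate there).
    """
    if a_factor is None:
        a_factor = curve.a_factor
    c = curve.c_l_nm
    y = curve.gamma
    pos = c > 0
    if np.count_nonzero(pos) < 4:
        raise ValueError("need at least 4 nonzero ligand concentrations")
    if (np.log10(c[pos].max()) - np.log10(c[pos].min())) < 1.0:
        raise ValueError("concentrations must span at least one decade")
    sem = curve.sem.copy()
    ok = np.isfinite(sem) & (sem > 0)
    fill = np.median(sem[ok]) if np.any(ok) else 1.0
    sem[~ok] = fill if fill > 0 else 1.0

    def residual(x):
        kd, beta = np.exp(x[0]), x[1]
        model = np.where(c > 0, a_factor * beta / (1.0 + kd / np.maximum(c, 1e-30)), 0.0)
        return (model - y) / sem

    kd0s = np.geomspace(max(c[pos].min(), 1e-4), c[pos].max(), 5)
    beta0 = min(max(y.max() / a_factor, 0.05), 1.0)
    best = None
    for kd0 in kd0s:
        sol = optimize.least_squares(residual, np.array([math.log(kd0), beta0]),
                                     bounds=([-np.inf, 0.0], [np.inf, 2.0]),
                                     xtol=1e-15, ftol=1e-15, gtol=1e-15)
        if best is None or sol.cost < best.cost:
            best = sol
    kd = float(np.exp(best.x[0]))
    beta = float(best.x[1])
    dof = max(len(y) - 2, 1)
    red = 2.0 * best.cost / dof
    cov = None
    kd_se = beta_se = float("nan")
    try:
        cov_log = np.linalg.inv(best.jac.T @ best.jac) * red
        jac = np.diag([kd, 1.0])
        cov = jac @ cov_log @ jac
        kd_se = float(np.sqrt(cov[0, 0]))
        beta_se = float(np.sqrt(cov[1, 1]))
    except np.linalg.LinAlgError:
        pass
    ill = bool(np.all(c[pos] > 8 * kd) or np.all(c[pos] < kd / 8))
    return IsothermFit(k_d_nm=kd, beta=beta, k_d_se=kd_se, beta_se=beta_se,
                       cov=cov, a_factor=a_factor, ill_conditioned=ill,
                       beta_warning=beta > BETA_WARN)


def bootstrap_isotherm(per_scan: Sequence[Tuple[float, float]],
                       a_factor: float = 1.0, n_boot: int = 200,
                       seed: int = 0, min_scans: int = MIN_SCANS_PER_POINT
                       ) -> Tuple[float, float]:
    """Scan-resampling bootstrap SEs of (K_D, beta).

    Scans are resampled with replacement *within* each concentration, the
    aggregation and weighted fit are repeated, and the SDs of the resampled
    estimates are returned.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    by_c: Dict[float, List[float]] = {}
    for c_l, gam in per_scan:
        by_c.setdefault(float(c_l), []).append(float(gam))
    kds: List[float] = []
    betas: List[float] = []
    for _ in range(n_boot):
        sample: List[Tuple[float, float]] = []
        for c_l, vals in by_c.items():
            idx = rng.integers(0, len(vals), size=len(vals))
            sample.extend((c_l, vals[i]) for i in idx)
        try:
            curve = aggregate_gamma(sample, a_factor=a_factor,
                                    min_scans=min_scans)
            fit = fit_isotherm(curve)
        except (ValueError, ZeroDivisionError):
            continue
        kds.append(fit.k_d_nm)
        betas.append(fit.beta)
    if len(kds) < max(20, n_boot // 4):
        return float("nan"), float("nan")
    return float(np.std(kds, ddof=1)), float(np.std(betas, ddof=1))


def correct_ligand_maturation(k_d_fit_nm: float, eta_ligand: float) -> float:
    """True K_D when the ligand tag matures incompletely: K_D_fit / eta.

    With a ligand maturation yield eta < 1 the isotherm midpoint sits at
    eta*K_D and its amplitude becomes A*beta*eta; fitting the simple isotherm
    therefore underestimates K_D by the factor eta.
    """
    if not (0 < eta_ligand <= 1):
        raise ValueError("eta must be in (0, 1]")
    return k_d_fit_nm / eta_ligand


@dataclass
class HeterodimerResult:
    """Receptor-receptor co-diffusion fractions from amplitude ratios."""

    f_r_prime: float
    f_g_prime: float
    f_r: float
    f_g: float
    eta_g: float
    eta_r: float


def bound_fractions(g_g0: float, g_r0: float, g_x0: float,
                    calib: OpticsCalibration, eta_g: float = 1.0,
                    eta_r: float = 1.0) -> HeterodimerResult:
    """Heterodimer bound fractions from the three amplitudes.

    F_R' = (A_eff/A_G) G_x(0)/G_G(0) and F_G' = (A_eff/A_R) G_x(0)/G_R(0)
    equal the bound fractions only at full maturation; the corrections

        F_R = 1 / (1/F_R' + 1 - 1/eta_G),  F_G = 1 / (1/F_G' + 1 - 1/eta_R)

    recover the true fractions of red receptors bound to (any) green partner
    and vice versa.
    """
    if g_g0 <= 0 or g_r0 <= 0 or g_x0 <= 0:
        raise ValueError("amplitudes must be positive")
    if not (0 < eta_g <= 1) or not (0 < eta_r <= 1):
        raise ValueError("maturation yields must be in (0, 1]")
    f_r_prime = calib.ratio_eff_g * g_x0 / g_g0
    f_g_prime = calib.ratio_eff_r * g_x0 / g_r0
    den_r = 1.0 / f_r_prime + 1.0 - 1.0 / eta_g
    den_g = 1.0 / f_g_prime + 1.0 - 1.0 / eta_r
    if den_r <= 0 or den_g <= 0:
        raise ValueError("amplitude ratio too small for the given maturation yield")
    return HeterodimerResult(
        f_r_prime=float(f_r_prime), f_g_prime=float(f_g_prime),
        f_r=float(1.0 / den_r), f_g=float(1.0 / den_g),
        eta_g=eta_g, eta_r=eta_r,
    )


def incubation_time_min(c_l_nm: float, cap_min: float = 120.0) -> float:
    """Advisory equilibration time: 5 min at 3.5 nM, scaled by 3.5/C_L."""
    if c_l_nm <= 0:
        raise ValueError("C_L must be > 0")
    return min(REFERENCE_INCUBATION_MIN * REFERENCE_C_L_NM / c_l_nm, cap_min)


def aggregate_gamma(per_scan: Sequence[Tuple[float, float]],
                    a_factor: float = 1.0,
                    min_scans: int = MIN_SCANS_PER_POINT) -> BindingCurve:
    """Mean +- SEM of per-scan Gamma values grouped by ligand concentration.

    ``per_scan`` holds (C_L, Gamma) pairs of scans that already passed QC and
    the deviant-correlation-time exclusion.
    """
    by_c: Dict[float, List[float]] = {}
    for c_l, gam in per_scan:
        by_c.setdefault(float(c_l), []).append(float(gam))
    cs, means, sems, ns = [], [], [], []
    for c_l in sorted(by_c):
        vals = np.asarray(by_c[c_l])
        if len(vals) < min_scans:
            raise ValueError(
                f"C_L = {c_l} nM has {len(vals)} scans, need >= {min_scans}")
        cs.append(c_l)
        means.append(vals.mean())
        sems.append(vals.std(ddof=1) / math.sqrt(len(vals)) if len(vals) > 1 else 0.0)
        ns.append(len(vals))
    return BindingCurve(c_l_nm=np.array(cs), gamma=np.array(means),
                        sem=np.array(sems), n_scans=np.array(ns), a_factor=a_factor)
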