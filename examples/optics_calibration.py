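"""Focus-size calibration arithmetic for a dual-color experiment.

Bead scans give the measured FWHM of each excitation focus; correcting for
the bead size and converting to 1/e^2 waists yields the observation areas,
the effective dual-color area and the geometry factor A that scales the
binding statistic.
"""

import math

import axlsfcs as ax

# bead-corrected full widths at half maximum from the bead calibration (nm)
calib = ax.calibrate_focus(fwhm_measured_g_nm=242.0, fwhm_measured_r_nm=295.0,
                           bead_diameter_nm=0.0)

print(f"waists:           omega_G = {calib.omega_g_nm:.1f} nm, "
      f"omega_R = {calib.omega_r_nm:.1f} nm")
print(f"observation areas: A_G = {calib.area_g_um2:.4f} um^2, "
      f"A_R = {calib.area_r_um2:.4f} um^2, A_eff = {calib.area_eff_um2:.4f} um^2")
print(f"area ratios:      A_eff/A_G = {calib.ratio_eff_g:.3f}, "
      f"A_eff/A_R = {calib.ratio_eff_r:.3f}")
print(f"geometry factor:  A = {calib.a_factor:.4f}")
print()
print("A multiplies the binding isotherm amplitude: it is 1 for perfectly")
print("matched two-color observation areas and shrinks as they diverge.")

# a 0.25-um waist observes 0.20 um^2 of membrane; an autocorrelation
# amplitude G(0) then converts directly to a receptor area density
omega0_um = 0.25
print(f"\nexample density: G_R(0) = 0.10, omega0 = {omega0_um} um "
      f"(area {math.pi * omega0_um**2:.2f} um^2) -> "
      f"C = {ax.density_from_amplitude(0.10, omega0_um):.1f} receptors/um^2")
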