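"""Simulator: trajectories, photon statistics, binding series, determinism."""

import math

import numpy as np
import pytest
from scipy import integrate

import axlsfcs as ax
from axlsfcs import simkymo


def unwrap_displacements(traj: np.ndarray, box: float) -> np.ndarray:
    """Cumulative displacement with minimum-image unwrapping."""
    d = np.diff(traj, axis=0)
    d = (d + box / 2) % box - box / 2
    return np.concatenate([np.zeros((1,) + traj.shape[1:]), np.cumsum(d, axis=0)])


class TestTrajectories:
    def test_particle_count_is_poisson_with_density_mean(self):
        counts = []
        for seed in range(200):
            cfg = ax.SimConfig(box_side_um=10.0, densities={"R": 50.0},
                               duration_s=0.01, seed=seed)
            traj = ax.simulate_trajectories(cfg, n_steps=1)
            counts.append(traj["R"].shape[1])
        counts = np.array(counts)
        # Poisson(5000): mean within 3 SE, variance of the right order
        assert abs(counts.mean() - 5000) <= 3 * math.sqrt(5000 / len(counts))
        assert 0.7 * 5000 < counts.var(ddof=1) < 1.4 * 5000

    def test_msd_regression_recovers_diffusion_coefficient(self):
        d_true = 0.4
        cfg = ax.SimConfig(box_side_um=30.0, densities={"R": 2.0},
                           diffusion={"R": d_true}, duration_s=1.0, seed=5)
        traj = ax.simulate_trajectories(cfg, n_steps=200, dt_s=1e-3)["R"]
        assert traj.shape[1] >= 1000
        disp = unwrap_displacements(traj, cfg.box_side_um)
        msd = (disp**2).sum(-1).mean(1)
        dt = np.arange(len(msd)) * 1e-3
        design = np.vstack([dt, np.ones_like(dt)]).T
        coef, res_ss, *_ = np.linalg.lstsq(design, msd, rcond=None)
        sigma2 = float(res_ss[0]) / (len(msd) - 2)
        se = math.sqrt(sigma2 / np.sum((dt - dt.mean()) ** 2))
        assert abs(coef[0] - 4 * d_true) <= max(3 * se, 0.02 * 4 * d_true)

    def test_zero_diffusion_freezes_positions(self):
        cfg = ax.SimConfig(box_side_um=5.0, densities={"R": 3.0},
                           default_diffusion=0.0, duration_s=0.01, seed=2)
        traj = ax.simulate_trajectories(cfg, n_steps=50)["R"]
        assert np.all(traj == traj[0])

    def test_positions_stay_in_box(self):
        cfg = ax.SimConfig(box_side_um=2.0, densities={"R": 10.0},
                           diffusion={"R": 5.0}, duration_s=0.01, seed=3)
        traj = ax.simulate_trajectories(cfg, n_steps=100, dt_s=1e-3)["R"]
        assert traj.min() >= -1.0 and traj.max() < 1.0

    @pytest.mark.parametrize("bad", [
        dict(box_side_um=-1.0),
        dict(densities={"R": -5.0}),
        dict(eta_g=0.0),
        dict(eta_g=1.5),
        dict(duration_s=0.0),
        dict(brightness_g=-0.1),
        dict(densities={"bogus": 1.0}),
        dict(k_d_nm=-2.0),
    ])
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ValueError):
            ax.SimConfig(**bad)


class TestPhotonEmission:
    def test_zero_brightness_leaves_poisson_background(self, optics):
        rate = 2.0  # kHz
        totals = {"G": [], "R": []}
        for seed in range(12):
            cfg = ax.SimConfig(box_side_um=2.0, densities={"RL": 20.0},
                               brightness_g=0.0, brightness_r=0.0,
                               background_g_khz=rate, background_r_khz=rate,
                               duration_s=2.0, seed=40 + seed)
            stream = ax.simulate_photons(cfg, optics)
            g, r = ax.gate_channels(stream, optics.pie_window_ns)
            totals["G"].append(len(g))
            totals["R"].append(len(r))
        mean_expected = rate * 1e3 * 2.0
        for ch in ("G", "R"):
            v = np.array(totals[ch])
            se = math.sqrt(mean_expected / len(v))
            assert abs(v.mean() - mean_expected) <= 3 * se

    def test_single_emitter_transit_dose(self, optics, monkeypatch):
        """One immobile dual-label particle at the focus center emits, per
        membrane crossing, the brightness times the numerically integrated
        axial Gaussian transit dose."""
        def one_particle(cfg, rng):
            return (np.zeros((1, 2)), np.ones(1, bool), np.ones(1, bool),
                    np.zeros(1), {"RL": 1})

        monkeypatch.setattr(simkymo, "_draw_particles", one_particle)
        cfg = ax.SimConfig(box_side_um=2.0, densities={"RL": 1.0},
                           brightness_g=0.05, brightness_r=0.05,
                           duration_s=2.0, seed=9)
        stream = ax.simulate_photons(cfg, optics)
        g, r = ax.gate_channels(stream, optics.pie_window_ns)
        period = optics.period_s
        a = optics.axial_amplitude_um
        n_cross = int(cfg.duration_s / (period / 2))
        for ph, z0 in ((g, optics.z0_um("G")), (r, optics.z0_um("R"))):
            dose_us, _ = integrate.quad(
                lambda t: math.exp(-2 * (a * math.sin(2 * math.pi * t / period))**2
                                   / z0**2) * 1e6,
                -period / 4, period / 4)
            expected = 0.05 * dose_us * n_cross
            assert abs(len(ph) - expected) <= 3 * math.sqrt(expected)

    def test_no_bleaching_is_stationary(self, optics):
        cfg = ax.SimConfig(box_side_um=2.8, densities={"RL": 40.0},
                           brightness_g=0.03, brightness_r=0.02,
                           duration_s=6.0, traj_dt_s=2e-4, seed=13)
        stream = ax.simulate_photons(cfg, optics)
        t = stream.macro_time_ns * 1e-9
        bins = np.histogram(t, bins=60, range=(0, 6.0))[0].astype(float)
        first, second = bins[:30], bins[30:]
        se = math.sqrt(first.var(ddof=1) / 30 + second.var(ddof=1) / 30)
        assert abs(first.mean() - second.mean()) <= 3 * se

    def test_bleaching_depletes_signal(self, optics):
        cfg = ax.SimConfig(box_side_um=2.8, densities={"RL": 40.0},
                           brightness_g=0.03, brightness_r=0.02,
                           bleach_g=2e-5, bleach_r=2e-5,
                           duration_s=10.0, traj_dt_s=2e-4, seed=13)
        stream = ax.simulate_photons(cfg, optics)
        t = stream.macro_time_ns * 1e-9
        first = np.count_nonzero(t < 5.0)
        second = len(t) - first
        assert second < 0.9 * first

    def test_stream_invariants_and_determinism(self, optics):
        cfg = ax.SimConfig(box_side_um=2.0, densities={"R": 10.0, "RL": 5.0},
                           background_g_khz=1.0, duration_s=1.0, seed=21)
        s1 = ax.simulate_photons(cfg, optics)
        s2 = ax.simulate_photons(cfg, optics)
        assert np.array_equal(s1.macro_time_ns, s2.macro_time_ns)
        assert np.array_equal(s1.micro_time_ns, s2.micro_time_ns)
        assert np.all(np.diff(s1.macro_time_ns) >= 0)
        assert s1.micro_time_ns.min() >= 0
        assert s1.micro_time_ns.max() < 25.0
        assert np.all((s1.tag_phase >= 0) & (s1.tag_phase < 1))
        s3 = ax.simulate_photons(
            ax.SimConfig(**{**cfg.__dict__, "seed": 22}), optics)
        assert not np.array_equal(s1.macro_time_ns, s3.macro_time_ns)


class TestBindingSeries:
    def test_bound_fraction_isotherm(self):
        assert ax.bound_fraction(1.0, 1.0) == pytest.approx(0.5)
        assert ax.bound_fraction(0.08, 0.4) == pytest.approx(1 / 1.2)
        assert ax.bound_fraction(1.0, 0.0) == 0.0
        with pytest.raises(ValueError):
            ax.bound_fraction(0.0, 1.0)

    def test_series_conserves_receptor_density(self):
        cfg = ax.SimConfig(densities={"R": 30.0, "RL": 20.0}, k_d_nm=1.0,
                           c_l_series_nm=(0.1, 1.0, 10.0))
        series = ax.binding_series_configs(cfg, n_scans=2)
        assert [c for c, _ in series] == [0.1, 1.0, 10.0]
        for c_l, cfgs in series:
            assert len(cfgs) == 2
            f = ax.bound_fraction(1.0, c_l)
            for c in cfgs:
                assert c.densities["RL"] == pytest.approx(50.0 * f)
                assert c.densities["RL"] + c.densities["R"] == pytest.approx(50.0)
        seeds = [c.seed for _, cfgs in series for c in cfgs]
        assert len(set(seeds)) == len(seeds)

    def test_series_requires_kd_and_concentrations(self):
        with pytest.raises(ValueError):
            ax.binding_series_configs(ax.SimConfig(c_l_series_nm=(1.0,)))
        with pytest.raises(ValueError):
            ax.binding_series_configs(ax.SimConfig(k_d_nm=1.0))

    def test_zero_ligand_means_all_free(self):
        cfg = ax.SimConfig(densities={"R": 10.0, "RL": 10.0}, k_d_nm=1.0,
                           c_l_series_nm=(0.0,))
        (c_l, cfgs), = ax.binding_series_configs(cfg)
        assert cfgs[0].densities["RL"] == 0.0
        assert cfgs[0].densities["R"] == 20.0
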