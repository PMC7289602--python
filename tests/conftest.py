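import warnings

import numpy as np
import pytest

import axlsfcs as ax


@pytest.fixture(autouse=True)
def _quiet_numpy():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", category=RuntimeWarning)
        yield


@pytest.fixture(scope="session")
def optics() -> ax.OpticsConfig:
    return ax.OpticsConfig()


@pytest.fixture(scope="session")
def calib() -> ax.OpticsCalibration:
    return ax.OpticsCalibration.from_waists(207.0, 251.0)


@pytest.fixture(scope="session")
def small_stream(optics) -> ax.PhotonStream:
    """One 5-s dual-species scan reused by several processing tests."""
    cfg = ax.SimConfig(
        box_side_um=2.8, densities={"R": 30.0, "RL": 20.0},
        brightness_g=0.03, brightness_r=0.02,
        duration_s=5.0, traj_dt_s=2e-4, seed=11,
    )
    return ax.simulate_photons(cfg, optics)


def make_uniform_stream(optics, rate_hz: float, duration_s: float,
                        seed: int = 0) -> ax.PhotonStream:
    """Photons uniform in time (background-like), split evenly over gates."""
    rng = np.random.default_rng(seed)
    n = rng.poisson(rate_hz * duration_s)
    t = np.sort(rng.uniform(0, duration_s, n))
    cyc = np.floor(t / optics.period_s)
    return ax.PhotonStream(
        macro_time_ns=t * 1e9,
        micro_time_ns=rng.uniform(0, 25, n),
        tag_cycle=cyc.astype(np.int64),
        tag_phase=t / optics.period_s - cyc,
        header={"duration_s": duration_s, **optics.to_header()},
    )
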