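import numpy as np
import pytest

import gawkit as gk

# closure level used when recovering programmed phase durations: just above
# the area floor so the floor counts as the closed phase
RECOVERY_REL = 1e-3


@pytest.fixture(scope="session")
def clean_params():
    """Noiseless kinematics with every ground truth nontrivial."""
    return gk.KinematicParams(
        f0_hz=176.0, fs_fps=15000.0, n_cycles=110,
        open_quotient=0.9, speed_quotient=1.25, gap_fraction=0.05,
        phase_asym=-0.02, jitter_ms=0.3, shimmer_db=0.2, noise_sd=0.0, seed=3,
    )


@pytest.fixture(scope="session")
def clean_gaw(clean_params):
    gaw, truth = gk.generate_gaw(clean_params)
    return gaw, truth


@pytest.fixture(scope="session")
def periodic_gaw():
    """Strictly periodic GAW: 106 cycles of exactly 75 frames at 15 kfps."""
    params = gk.KinematicParams(
        f0_hz=200.0, fs_fps=15000.0, n_cycles=106,
        jitter_ms=0.0, shimmer_db=0.0, noise_sd=0.0, phase_asym=0.0, seed=0,
    )
    gaw, truth = gk.generate_gaw(params)
    return gaw, truth


def make_study_recordings(n_recordings=20, seed=0, n_cycles=110, noise_sd=2.0):
    """The synthetic stand-in for the study corpus: n recordings of sustained
    phonation at 15 kfps, F0 drawn around 176 +- 11 Hz."""
    rng = np.random.default_rng(seed)
    recordings = {}
    truths = {}
    for i in range(n_recordings):
        f0 = float(np.clip(rng.normal(176.0, 11.0), 140.0, 220.0))
        params = gk.KinematicParams(
            f0_hz=f0, fs_fps=15000.0, n_cycles=n_cycles,
            open_quotient=0.9, speed_quotient=1.25,
            gap_fraction=float(rng.uniform(0.05, 0.07)),
            phase_asym=-0.02, jitter_ms=0.3, shimmer_db=0.2,
            noise_sd=noise_sd, peak_area_px=4000.0,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        rec_id = f"rec{i:02d}"
        recordings[rec_id], truths[rec_id] = gk.generate_gaw(params)
    return recordings, truths


@pytest.fixture(scope="session")
def study_sweep_table():
    """Full 20-recording x 15-rate sweep analyzed into a RateSweepTable."""
    recordings, _ = make_study_recordings(20, seed=42)
    plan = gk.RateSweepPlan()
    sweep = gk.build_sweep(recordings, plan)
    df = gk.parameter_table(sweep)
    return gk.RateSweepTable.from_dataframe(df), df
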