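import numpy as np
import pytest

from destain.kinetics import BoutonTrace
from destain.simulate import SimulationConfig, simulate_movie, simulate_trace


@pytest.fixture(scope="session")
def tiny_movie():
    """Small default-noise movie with known ground truth (shared, read-only)."""
    cfg = SimulationConfig(width=128, height=128, n_frames=40, stim_frame=10,
                           stim_duration_frames=30, n_boutons=8,
                           n_trafficking=2, seed=1)
    return simulate_movie(cfg)


@pytest.fixture(scope="session")
def clean_movie():
    """Noise-free, drift-free movie for exact-value checks."""
    cfg = SimulationConfig(width=96, height=96, n_frames=24, stim_frame=6,
                           stim_duration_frames=18, n_boutons=4,
                           n_trafficking=0, shot_noise=False, read_noise_sd=0.0,
                           drift_step_sd_nm=0.0, seed=2)
    return simulate_movie(cfg)


def make_trace_cohort(seed, n_per_class=100, depth_sd=0.03,
                      n_frames=330, stim_frame=30, stim_duration=300):
    """Simulated weak/strong BoutonTraces with per-trace depth jitter."""
    rng = np.random.default_rng(seed)
    traces, truth = [], {}
    for i in range(2 * n_per_class):
        cls = "strong" if i < n_per_class else "weak"
        depth = rng.normal(0.35 if cls == "strong" else 0.18, depth_sd)
        series = simulate_trace(depth, n_frames=n_frames, stim_frame=stim_frame,
                                stim_duration=stim_duration)
        traces.append(BoutonTrace(i, np.arange(n_frames), series,
                                  stim_frame, stim_duration))
        truth[i] = cls
    return traces, truth
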