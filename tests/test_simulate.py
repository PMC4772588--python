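"""Generator correctness: exact rendering, seeding, trace and EM properties."""

import numpy as np
import pandas as pd
import pytest

from destain.errors import ConfigError, ValidationError
from destain.simulate import (EMSimConfig, FWHM_FACTOR, SimulationConfig,
                              simulate_em_dataset, simulate_movie,
                              simulate_trace, unloading_factor)


def _noise_free(**kw):
    base = dict(width=96, height=96, n_frames=20, stim_frame=5,
                stim_duration_frames=15, shot_noise=False, read_noise_sd=0.0,
                drift_step_sd_nm=0.0, bleach_rate_per_frame=0.0,
                n_trafficking=0, seed=0)
    base.update(kw)
    return SimulationConfig(**base)


@pytest.mark.parametrize("field, value", [
    ("class_fractions", {"weak": 0.7, "strong": 0.7}),
    ("unloading_depth", {"weak": 1.2, "strong": 0.35}),
    ("stim_duration_frames", 1000),
    ("bouton_sigma_range_nm", (800.0, 300.0)),
    ("unloading_shape", "sigmoid"),
    ("bleach_rate_per_frame", 1.5),
])
def test_invalid_config_raises_naming_field(field, value):
    cfg = SimulationConfig(**{field: value})
    with pytest.raises(ConfigError):
        cfg.validate()


def test_empty_field_is_pure_background_times_bleach():
    cfg = _noise_free(n_boutons=0, bleach_rate_per_frame=0.001)
    movie, truth = simulate_movie(cfg)
    bleach = (1 - 0.001) ** np.arange(cfg.n_frames)
    expected = cfg.background_level * bleach[:, None, None]
    np.testing.assert_allclose(movie.frames, np.broadcast_to(
        expected, movie.frames.shape), rtol=1e-12)
    assert truth.boutons.empty


def test_noise_free_movie_matches_closed_form():
    """Each frame equals bleach x (background + sum of unloading Gaussians)."""
    cfg = _noise_free(n_boutons=5, bleach_rate_per_frame=5e-4, seed=3)
    movie, truth = simulate_movie(cfg)
    yy, xx = np.mgrid[0:cfg.height, 0:cfg.width].astype(float)
    for t in [0, cfg.stim_frame, cfg.n_frames - 1]:
        img = np.full((cfg.height, cfg.width), float(cfg.background_level))
        for _, b in truth.boutons.iterrows():
            u = unloading_factor(np.array([t]), b.depth, cfg.stim_frame,
                                 cfg.stim_duration_frames)[0]
            sig = b.sigma_nm / cfg.pixel_size_nm
            img += b.amplitude * u * np.exp(
                -((xx - b.x_px) ** 2 + (yy - b.y_px) ** 2) / (2 * sig ** 2))
        bleach = (1 - cfg.bleach_rate_per_frame) ** t
        # rendering truncates at 4 sigma; tail below amplitude*exp(-8)
        np.testing.assert_allclose(movie.frames[t], img * bleach, atol=0.5)


def test_strong_bouton_peak_reaches_one_minus_depth():
    """At the last stimulation frame a strong bouton sits at 0.65 x baseline."""
    cfg = _noise_free(n_boutons=6, bleach_rate_per_frame=1e-3,
                      class_fractions={"strong": 1.0},
                      unloading_depth={"strong": 0.35}, seed=4)
    movie, truth = simulate_movie(cfg)
    t_last = cfg.stim_frame + cfg.stim_duration_frames - 1
    bleach = (1 - cfg.bleach_rate_per_frame) ** t_last
    for _, b in truth.boutons.iterrows():
        xi, yi = int(round(b.x_px)), int(round(b.y_px))
        sig = b.sigma_nm / cfg.pixel_size_nm
        g = np.exp(-((xi - b.x_px) ** 2 + (yi - b.y_px) ** 2) / (2 * sig ** 2))
        expected = bleach * (cfg.background_level + (1 - 0.35) * b.amplitude * g)
        assert movie.frames[t_last, yi, xi] == pytest.approx(expected, abs=0.5)


def test_seeded_determinism_bit_identical():
    cfg = SimulationConfig(width=64, height=64, n_frames=10, stim_frame=3,
                           stim_duration_frames=7, n_boutons=5, seed=11)
    m1, t1 = simulate_movie(cfg)
    m2, t2 = simulate_movie(cfg)
    np.testing.assert_array_equal(m1.frames, m2.frames)
    pd.testing.assert_frame_equal(t1.boutons, t2.boutons)
    np.testing.assert_array_equal(t1.drift, t2.drift)


def test_non_unloading_bouton_conserves_integrated_intensity():
    cfg = _noise_free(n_boutons=3, unloading_depth={"weak": 0.0, "strong": 0.0},
                      seed=5)
    movie, _ = simulate_movie(cfg)
    signal = movie.frames.sum(axis=(1, 2)) - \
        cfg.background_level * cfg.width * cfg.height
    np.testing.assert_allclose(signal, signal[0], rtol=1e-9)


def test_ground_truth_objects_inside_field():
    for seed in range(3):
        cfg = SimulationConfig(width=128, height=128, n_frames=6, stim_frame=2,
                               stim_duration_frames=4, n_boutons=20,
                               n_trafficking=4, seed=seed)
        _, truth = simulate_movie(cfg)
        assert truth.boutons.x_px.between(0, cfg.width - 1).all()
        assert truth.boutons.y_px.between(0, cfg.height - 1).all()
        frame0 = truth.trafficking.query("frame == 0")
        assert frame0.x_px.between(0, cfg.width - 1).all()
        assert frame0.y_px.between(0, cfg.height - 1).all()
        # full-width sizes in [300, 800] nm; rendered sigma is size/2.355
        assert truth.boutons.sigma_nm.between(300 / FWHM_FACTOR,
                                              800 / FWHM_FACTOR).all()


def test_min_separation_is_respected(tiny_movie):
    _, truth = tiny_movie
    pos = truth.boutons[["x_px", "y_px"]].to_numpy()
    d = np.hypot(*(pos[:, None, :] - pos[None, :, :]).T)
    np.fill_diagonal(d, np.inf)
    assert d.min() * 160.0 >= 2000.0


# ---------------------------------------------------------------------------
# simulate_trace
# ---------------------------------------------------------------------------

def test_trace_zero_depth_is_constant_one():
    s = simulate_trace(0.0, n_frames=50, stim_frame=10, stim_duration=40)
    np.testing.assert_array_equal(s, np.ones(50))


def test_trace_linear_final_value_exact():
    s = simulate_trace(0.18, n_frames=330, stim_frame=30, stim_duration=300)
    assert s[329] == pytest.approx(0.82, abs=1e-12)
    assert s[:30].mean() == 1.0


def test_trace_noisy_plateau_mean_within_3se():
    n_rep, noise = 1000, 0.02
    finals = np.array([
        simulate_trace(0.35, n_frames=60, stim_frame=10, stim_duration=50,
                       noise_sd=noise, seed=i)[-1]
        for i in range(n_rep)])
    se = noise / np.sqrt(n_rep)
    assert abs(finals.mean() - 0.65) <= 3 * se


def test_trace_invalid_depth_rejected():
    with pytest.raises(ValidationError):
        simulate_trace(1.0, n_frames=20, stim_frame=5, stim_duration=10)
    with pytest.raises(ValidationError):
        simulate_trace(0.2, n_frames=10, stim_frame=5, stim_duration=10)


def test_trace_exponential_shape_plateaus():
    s = simulate_trace(0.3, n_frames=400, stim_frame=20, stim_duration=380,
                       shape="exponential", tau_frames=20.0)
    assert s[-1] == pytest.approx(0.7, abs=1e-6)


# ---------------------------------------------------------------------------
# simulate_em_dataset
# ---------------------------------------------------------------------------

def test_em_null_correlation_near_zero():
    cfg = EMSimConfig(n_per_group=10000, groups=("a", "b"),
                      density_az_correlation={"a": 0.0, "b": 0.0}, seed=1)
    df = simulate_em_dataset(cfg)
    for g in ("a", "b"):
        sub = df[df.group == g]
        r = np.corrcoef(sub.az_length_nm, sub.vesicle_density_per_um2)[0, 1]
        assert abs(r) <= 0.03


def test_em_configured_correlation_recovered():
    cfg = EMSimConfig(n_per_group=10000, groups=("KO",),
                      density_az_correlation={"KO": -0.36}, seed=2)
    df = simulate_em_dataset(cfg)
    r = np.corrcoef(df.az_length_nm, df.vesicle_density_per_um2)[0, 1]
    assert r == pytest.approx(-0.36, abs=0.03)


def test_em_table_is_consistent_and_seeded():
    cfg = EMSimConfig(n_per_group=50, seed=9)
    df1 = simulate_em_dataset(cfg)
    df2 = simulate_em_dataset(cfg)
    pd.testing.assert_frame_equal(df1, df2)
    assert (df1[["az_length_nm", "presyn_area_um2",
                 "vesicle_density_per_um2"]] > 0).all().all()
    np.testing.assert_allclose(df1.vesicle_density_per_um2,
                               df1.vesicle_count / df1.presyn_area_um2)


def test_em_invalid_config_rejected():
    with pytest.raises(ConfigError):
        EMSimConfig(n_per_group=2).validate()
    with pytest.raises(ConfigError):
        EMSimConfig(density_az_correlation={"KO": -1.5, "WT": 0.0}).validate()
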