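"""Synthetic FM1-43 movies, single-bouton traces and EM measurement tables.

The generator emulates the live-cell destaining experiment: a field of
stationary synaptic boutons stained with FM1-43, imaged at fixed frame
rate, then depolarized with high K+ for a fixed window during which each
bouton loses a class-specific fraction of its fluorescence ("unloading
depth": strong ~= 0.35, weak ~= 0.18).  Mobile trafficking puncta, global
stage drift, photobleaching and shot/read noise are added so that every
downstream stage (drift correction, detection, tracking, kinetics,
statistics) can be scored against exact ground truth.

Intensity model for one frame t (before noise)::

    I_t(p) = bleach(t) * [ background
                           + sum_i A_i * u_i(t) * G(p; c_i + drift_t, sigma_i) ]

with ``bleach(t) = (1 - bleach_rate_per_frame)**t``, ``u_i(t)`` the
unloading factor (1 during baseline, decaying to ``1 - depth_i`` across
the stimulation window), and ``G`` an isotropic 2-D Gaussian evaluated at
pixel centres and truncated at 4 sigma.  Shot noise is Poisson on the
clean image; read noise is additive Gaussian; the result is rounded to
integer camera counts and clipped at zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, PlacementError, ValidationError
from .io import Movie, log_stage

#: FWHM = FWHM_FACTOR * sigma for a Gaussian profile
FWHM_FACTOR = float(2.0 * math.sqrt(2.0 * math.log(2.0)))


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Study conditions for a synthetic destaining movie.

    Defaults model a conventional widefield FM1-43 experiment: 512x512
    field at 160 nm/px, 1 frame/s, 30 baseline frames, then a 5-minute
    (300-frame) high-K+ stimulation window.  Bouton sizes of 300-800 nm
    are treated as full-width scales, so the rendered Gaussian sigma is
    drawn uniformly from [300, 800]/2.355 nm.
    """

    width: int = 512
    height: int = 512
    n_frames: int = 330
    pixel_size_nm: float = 160.0
    frame_interval_s: float = 1.0
    stim_frame: int = 30
    stim_duration_frames: int = 300
    n_boutons: int = 60
    class_fractions: dict = field(
        default_factory=lambda: {"weak": 0.5, "strong": 0.5})
    unloading_depth: dict = field(
        default_factory=lambda: {"weak": 0.18, "strong": 0.35})
    unloading_shape: str = "linear"            # {"linear", "exponential"}
    tau_frames: float = 60.0                   # exponential time constant
    bouton_sigma_range_nm: tuple = (300.0, 800.0)  # full-width (FWHM) scale
    amplitude_mean: float = 300.0
    amplitude_cv: float = 0.2
    background_level: float = 100.0
    bleach_rate_per_frame: float = 2e-4
    read_noise_sd: float = 4.0
    shot_noise: bool = True
    n_trafficking: int = 5
    trafficking_speed_nm_per_frame: float = 400.0
    drift_step_sd_nm: float = 20.0
    min_separation_nm: float = 2000.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("width", "height", "n_frames", "n_boutons",
                     "n_trafficking", "stim_frame", "stim_duration_frames"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name}: must be >= 0, got {getattr(self, name)}")
        if self.width < 8 or self.height < 8 or self.n_frames < 1:
            raise ConfigError("width/height/n_frames: field too small")
        if self.pixel_size_nm <= 0:
            raise ConfigError(f"pixel_size_nm: must be > 0, got {self.pixel_size_nm}")
        if self.stim_frame + self.stim_duration_frames > self.n_frames:
            raise ConfigError(
                "stim_frame + stim_duration_frames must be <= n_frames "
                f"({self.stim_frame} + {self.stim_duration_frames} > {self.n_frames})")
        if abs(sum(self.class_fractions.values()) - 1.0) > 1e-9:
            raise ConfigError(
                f"class_fractions: must sum to 1, got {self.class_fractions}")
        for cls, d in self.unloading_depth.items():
            if not 0.0 <= d < 1.0:
                raise ConfigError(
                    f"unloading_depth[{cls!r}]: must be in [0, 1), got {d}")
        for cls in self.class_fractions:
            if cls not in self.unloading_depth:
                raise ConfigError(f"unloading_depth: missing class {cls!r}")
        lo, hi = self.bouton_sigma_range_nm
        if not (0 < lo <= hi):
            raise ConfigError(
                f"bouton_sigma_range_nm: need 0 < lo <= hi, got {(lo, hi)}")
        if self.unloading_shape not in ("linear", "exponential"):
            raise ConfigError(
                f"unloading_shape: must be 'linear' or 'exponential', "
                f"got {self.unloading_shape!r}")
        if self.unloading_shape == "exponential" and self.tau_frames <= 0:
            raise ConfigError(f"tau_frames: must be > 0, got {self.tau_frames}")
        if self.amplitude_mean <= 0 or self.amplitude_cv < 0:
            raise ConfigError("amplitude_mean/amplitude_cv: invalid")
        if self.background_level < 0 or self.read_noise_sd < 0:
            raise ConfigError("background_level/read_noise_sd: must be >= 0")
        if not 0 <= self.bleach_rate_per_frame < 1:
            raise ConfigError(
                f"bleach_rate_per_frame: must be in [0, 1), "
                f"got {self.bleach_rate_per_frame}")


@dataclass
class EMSimConfig:
    """Study conditions for a synthetic EM measurement table.

    Per group, active-zone length and vesicle density are drawn from a
    bivariate normal with the configured correlation; presynaptic area is
    independent.  Default means/SDs are typical for Purkinje-cell
    terminals on ultrathin sections.
    """

    n_per_group: int = 20
    groups: tuple = ("KO", "WT")
    az_length_mean_nm: float = 420.0
    az_length_sd_nm: float = 100.0
    presyn_area_mean_um2: float = 0.55
    presyn_area_sd_um2: float = 0.15
    vesicle_density_mean_per_um2: float = 90.0
    vesicle_density_sd_per_um2: float = 20.0
    density_az_correlation: dict = field(
        default_factory=lambda: {"KO": -0.36, "WT": 0.059})
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_group < 3:
            raise ConfigError(f"n_per_group: must be >= 3, got {self.n_per_group}")
        for name in ("az_length_sd_nm", "presyn_area_sd_um2",
                     "vesicle_density_sd_per_um2"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name}: must be > 0")
        for g in self.groups:
            r = self.density_az_correlation.get(g)
            if r is None or not -1.0 <= r <= 1.0:
                raise ConfigError(
                    f"density_az_correlation[{g!r}]: must be in [-1, 1], got {r}")


@dataclass
class GroundTruth:
    """Everything needed to score detection, tracking and classification.

    ``boutons``: one row per bouton (object_id, x_px, y_px, sigma_nm,
    amplitude, class_label, depth) with positions at frame 0 (pre-drift).
    ``trafficking``: one row per object per frame (object_id, frame,
    x_px, y_px).  ``drift``: (n_frames, 2) array of (dx, dy) in pixels
    relative to frame 0.
    """

    boutons: pd.DataFrame
    trafficking: pd.DataFrame
    drift: np.ndarray


# ---------------------------------------------------------------------------
# Building blocks
# ---------------------------------------------------------------------------

def unloading_factor(t: np.ndarray, depth: float, stim_frame: int,
                     stim_duration: int, shape: str = "linear",
                     tau_frames: float = 60.0) -> np.ndarray:
    """Relative fluorescence u(t): 1 at baseline, -> 1 - depth during stimulation.

    Linear shape reaches the plateau exactly at the last stimulation
    frame; exponential approaches it with time constant ``tau_frames``.
    """
    t = np.asarray(t, dtype=float)
    u = np.ones_like(t)
    rel = t - stim_frame
    in_stim = rel >= 0
    if shape == "linear":
        if stim_duration > 1:
            prog = np.clip(rel / (stim_duration - 1), 0.0, 1.0)
        else:
            prog = (rel >= 0).astype(float)
        u = np.where(in_stim, 1.0 - depth * prog, u)
    elif shape == "exponential":
        u = np.where(in_stim, 1.0 - depth * (1.0 - np.exp(-rel / tau_frames)), u)
    else:
        raise ConfigError(f"unloading_shape: unknown shape {shape!r}")
    return u


def render_gaussian(image: np.ndarray, x: float, y: float, sigma_px: float,
                    amplitude: float, truncate: float = 4.0) -> None:
    """Add an isotropic 2-D Gaussian to ``image`` in place.

    Evaluated at pixel centres, truncated at ``truncate * sigma``.
    """
    h, w = image.shape
    r = truncate * sigma_px
    x0, x1 = max(0, int(math.floor(x - r))), min(w, int(math.ceil(x + r)) + 1)
    y0, y1 = max(0, int(math.floor(y - r))), min(h, int(math.ceil(y + r)) + 1)
    if x0 >= x1 or y0 >= y1:
        return
    xs = np.arange(x0, x1, dtype=float) - x
    ys = np.arange(y0, y1, dtype=float) - y
    g = np.exp(-(ys[:, None] ** 2 + xs[None, :] ** 2) / (2.0 * sigma_px ** 2))
    image[y0:y1, x0:x1] += amplitude * g


def _place_boutons(config: SimulationConfig, rng: np.random.Generator,
                   margin_px: float) -> np.ndarray:
    """Rejection-sample bouton centres under the minimum-separation rule."""
    n = config.n_boutons
    min_sep_px = config.min_separation_nm / config.pixel_size_nm
    positions = np.empty((0, 2))
    max_tries = 1000 * max(n, 1)
    tries = 0
    while len(positions) < n:
        if tries >= max_tries:
            raise PlacementError(
                f"could not place {n} boutons with min_separation_nm="
                f"{config.min_separation_nm} in a {config.width}x{config.height} "
                f"field after {max_tries} attempts")
        tries += 1
        cand = np.array([rng.uniform(margin_px, config.width - 1 - margin_px),
                         rng.uniform(margin_px, config.height - 1 - margin_px)])
        if len(positions) == 0 or \
                np.min(np.hypot(*(positions - cand).T)) >= min_sep_px:
            positions = np.vstack([positions, cand])
    return positions


# ---------------------------------------------------------------------------
# Main generators
# ---------------------------------------------------------------------------

def simulate_movie(config: SimulationConfig) -> tuple[Movie, GroundTruth]:
    """Render a synthetic destaining movie and its ground truth.

    Drift is applied analytically: every object is rendered at its
    drifted sub-pixel centre (the constant background is
    shift-invariant), so the ground-truth drift series is exact.  Noise
    order: render -> bleach -> Poisson shot noise -> Gaussian read noise
    -> round to integer counts, clipped at 0.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    px = config.pixel_size_nm

    sig_lo, sig_hi = config.bouton_sigma_range_nm
    # bouton "size" is a full-width scale; rendered Gaussian sigma = size/2.355
    sigma_nm = rng.uniform(sig_lo, sig_hi, size=config.n_boutons) / FWHM_FACTOR
    sigma_px = sigma_nm / px
    margin = 4.0 * (sig_hi / FWHM_FACTOR / px) + 1.0

    centres = _place_boutons(config, rng, margin)
    amps = np.empty(config.n_boutons)
    for i in range(config.n_boutons):
        a = -1.0
        while a <= 0:
            a = rng.normal(config.amplitude_mean,
                           config.amplitude_cv * config.amplitude_mean)
        amps[i] = a
    classes = list(config.class_fractions)
    labels = rng.choice(classes, size=config.n_boutons,
                        p=[config.class_fractions[c] for c in classes])
    depths = np.array([config.unloading_depth[c] for c in labels])

    # trafficking puncta: ballistic, random heading, may leave the field
    traf_rows = []
    traf_sigma_px = rng.uniform(sig_lo, sig_hi, config.n_trafficking) / FWHM_FACTOR / px
    traf_amp = np.empty(config.n_trafficking)
    for i in range(config.n_trafficking):
        a = -1.0
        while a <= 0:
            a = rng.normal(config.amplitude_mean,
                           config.amplitude_cv * config.amplitude_mean)
        traf_amp[i] = a
    traf_start = np.column_stack([
        rng.uniform(margin, config.width - 1 - margin, config.n_trafficking),
        rng.uniform(margin, config.height - 1 - margin, config.n_trafficking)])
    heading = rng.uniform(0, 2 * np.pi, config.n_trafficking)
    speed_px = config.trafficking_speed_nm_per_frame / px
    vel = speed_px * np.column_stack([np.cos(heading), np.sin(heading)])

    # global drift: 2-D Gaussian random walk, (0, 0) at frame 0
    steps = rng.normal(0.0, config.drift_step_sd_nm / px,
                       size=(config.n_frames, 2))
    steps[0] = 0.0
    drift = np.cumsum(steps, axis=0)

    bleach = (1.0 - config.bleach_rate_per_frame) ** np.arange(config.n_frames)
    t_all = np.arange(config.n_frames)
    ufac = np.stack([
        unloading_factor(t_all, d, config.stim_frame, config.stim_duration_frames,
                         config.unloading_shape, config.tau_frames)
        for d in depths]) if config.n_boutons else np.empty((0, config.n_frames))

    frames = np.empty((config.n_frames, config.height, config.width))
    for t in range(config.n_frames):
        img = np.full((config.height, config.width), float(config.background_level))
        dx, dy = drift[t]
        for i in range(config.n_boutons):
            render_gaussian(img, centres[i, 0] + dx, centres[i, 1] + dy,
                            sigma_px[i], amps[i] * ufac[i, t])
        for j in range(config.n_trafficking):
            pos = traf_start[j] + vel[j] * t
            traf_rows.append((j, t, pos[0] + dx, pos[1] + dy))
            render_gaussian(img, pos[0] + dx, pos[1] + dy,
                            traf_sigma_px[j], traf_amp[j])
        img *= bleach[t]
        if config.shot_noise:
            img = rng.poisson(img).astype(float)
        if config.read_noise_sd > 0:
            img += rng.normal(0.0, config.read_noise_sd, img.shape)
        if config.shot_noise or config.read_noise_sd > 0:
            img = np.clip(np.rint(img), 0.0, None)
        frames[t] = img

    movie = Movie(frames, pixel_size_nm=px,
                  frame_interval_s=config.frame_interval_s,
                  stim_frame=config.stim_frame,
                  stim_duration_frames=config.stim_duration_frames)
    boutons = pd.DataFrame({
        "object_id": np.arange(config.n_boutons),
        "x_px": centres[:, 0] if config.n_boutons else [],
        "y_px": centres[:, 1] if config.n_boutons else [],
        "sigma_nm": sigma_nm,
        "amplitude": amps,
        "class_label": labels,
        "depth": depths,
    })
    trafficking = pd.DataFrame(
        traf_rows, columns=["object_id", "frame", "x_px", "y_px"])
    log_stage("simulate_movie", frames=config.n_frames,
              boutons=config.n_boutons, trafficking=config.n_trafficking)
    return movie, GroundTruth(boutons, trafficking, drift)


def simulate_trace(depth: float, *, n_frames: int = 330, stim_frame: int = 30,
                   stim_duration: int = 300, shape: str = "linear",
                   tau_frames: float = 60.0, noise_sd: float = 0.0,
                   seed: int | None = None,
                   rng: np.random.Generator | None = None) -> np.ndarray:
    """Unit-level relative-intensity trace: baseline mean 1, plateau 1 - depth.

    The noiseless series is exactly the unloading factor; Gaussian noise
    of SD ``noise_sd`` is added when requested.
    """
    if not 0.0 <= depth < 1.0:
        raise ValidationError(f"depth: must be in [0, 1), got {depth}")
    if stim_frame < 1 or stim_frame + stim_duration > n_frames:
        raise ValidationError(
            "timebase must include baseline and stimulation windows "
            f"(n_frames={n_frames}, stim_frame={stim_frame}, "
            f"stim_duration={stim_duration})")
    series = unloading_factor(np.arange(n_frames), depth, stim_frame,
                              stim_duration, shape, tau_frames)
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(seed)
        series = series + rng.normal(0.0, noise_sd, size=n_frames)
    return series


def simulate_em_dataset(config: EMSimConfig) -> pd.DataFrame:
    """Draw a grouped EM measurement table with controllable density-AZ correlation.

    Non-positive draws are rejected and resampled (documented truncation).
    ``vesicle_count`` is the rounded product density x area and the
    reported density is recomputed from it, so count/area/density are
    exactly consistent.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    rows = []
    sid = 0
    for group in config.groups:
        r = float(config.density_az_correlation[group])
        cov = np.array([
            [config.az_length_sd_nm ** 2,
             r * config.az_length_sd_nm * config.vesicle_density_sd_per_um2],
            [r * config.az_length_sd_nm * config.vesicle_density_sd_per_um2,
             config.vesicle_density_sd_per_um2 ** 2]])
        mean = [config.az_length_mean_nm, config.vesicle_density_mean_per_um2]
        n_left = config.n_per_group
        tries = 0
        while n_left > 0:
            if tries > 1000:
                raise ConfigError(
                    "simulate_em_dataset: cannot draw positive measurements "
                    "under the configured means/SDs")
            tries += 1
            draw = rng.multivariate_normal(mean, cov, size=n_left)
            area = rng.normal(config.presyn_area_mean_um2,
                              config.presyn_area_sd_um2, size=n_left)
            ok = (draw[:, 0] > 0) & (draw[:, 1] > 0) & (area > 0)
            for az, dens, a in zip(draw[ok, 0], draw[ok, 1], area[ok]):
                count = max(1, int(round(dens * a)))
                rows.append((sid, group, az, a, count, count / a))
                sid += 1
            n_left -= int(ok.sum())
    df = pd.DataFrame(rows, columns=["synapse_id", "group", "az_length_nm",
                                     "presyn_area_um2", "vesicle_count",
                                     "vesicle_density_per_um2"])
    log_stage("simulate_em_dataset", records=len(df),
              groups=len(config.groups))
    return df
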