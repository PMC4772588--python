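"""Spot linking, motion classification, track selection and ROI measurement.

Linking is greedy mutual-nearest-neighbour frame-to-frame: at each
frame, an open track end and a new spot are linked when each is the
other's nearest admissible partner, the frame gap is at most ``max_gap``
and the end-to-end displacement is strictly below ``max_disp_nm``.
Ties are broken by distance, then higher spot amplitude, then
lexicographic position, making linking deterministic and independent of
input row order.

The motion rule separating stationary boutons from trafficking puncta
is the net-displacement criterion: a track is stationary iff every pair
of observations at most ``window`` (default 3) frames apart is displaced
by strictly less than ``max_disp_nm`` (default 500 nm); a displacement of
exactly 500 nm makes the track trafficking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import Movie, log_stage

STATIONARY = "stationary"
TRAFFICKING = "trafficking"


@dataclass
class Track:
    """One linked object: ordered (frame, x, y) observations.

    ``median_sigma_nm`` carries the median detected scale when the track
    was built from a detection table; it is not serialized to CSV.
    """

    track_id: int
    frames: np.ndarray
    x_px: np.ndarray
    y_px: np.ndarray
    motion_class: str = STATIONARY
    flagged_short: bool = False
    median_sigma_nm: float | None = None

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=int)
        self.x_px = np.asarray(self.x_px, dtype=float)
        self.y_px = np.asarray(self.y_px, dtype=float)
        if len(self.frames) >= 2 and np.any(np.diff(self.frames) <= 0):
            raise ValidationError(
                f"track {self.track_id}: frames must be strictly increasing")

    @property
    def start_frame(self) -> int:
        return int(self.frames[0])

    @property
    def end_frame(self) -> int:
        return int(self.frames[-1])

    @property
    def n_observations(self) -> int:
        return len(self.frames)

    @property
    def span(self) -> int:
        """Number of frames covered, inclusive of gaps."""
        return self.end_frame - self.start_frame + 1

    def interpolated_positions(self):
        """(frames, x, y) for every frame in [start, end], gaps linear."""
        full = np.arange(self.start_frame, self.end_frame + 1)
        return (full,
                np.interp(full, self.frames, self.x_px),
                np.interp(full, self.frames, self.y_px))


@dataclass
class RawTrace:
    """Background-subtracted intensity of one track, one value per frame.

    Frames where the measurement disk leaves the image are NaN with
    ``missing`` set.  Values may be negative after background
    subtraction.
    """

    track_id: int
    frames: np.ndarray
    intensity: np.ndarray
    missing: np.ndarray
    radius_px: float = 0.0
    annulus: tuple = (0.0, 0.0)

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=int)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.missing = np.asarray(self.missing, dtype=bool)


# ---------------------------------------------------------------------------
# Table conversion (used by destain.io)
# ---------------------------------------------------------------------------

def tracks_to_table(tracks) -> pd.DataFrame:
    rows = []
    for tr in tracks:
        for f, x, y in zip(tr.frames, tr.x_px, tr.y_px):
            rows.append((tr.track_id, int(f), float(x), float(y),
                         tr.motion_class))
    df = pd.DataFrame(rows, columns=["track_id", "frame", "x_px", "y_px",
                                     "motion_class"])
    return df.sort_values(["track_id", "frame"]).reset_index(drop=True)


def tracks_from_table(df: pd.DataFrame):
    tracks = []
    for tid, grp in df.sort_values(["track_id", "frame"]).groupby("track_id"):
        tracks.append(Track(int(tid), grp["frame"].to_numpy(),
                            grp["x_px"].to_numpy(), grp["y_px"].to_numpy(),
                            motion_class=str(grp["motion_class"].iloc[0])))
    return tracks


def traces_to_table(traces) -> pd.DataFrame:
    rows = []
    for tr in traces:
        for f, v, m in zip(tr.frames, tr.intensity, tr.missing):
            rows.append((tr.track_id, int(f),
                         float(v) if not m else np.nan, bool(m)))
    return pd.DataFrame(rows, columns=["track_id", "frame", "intensity",
                                       "missing_flag"])


def traces_from_table(df: pd.DataFrame):
    traces = []
    for tid, grp in df.sort_values(["track_id", "frame"]).groupby("track_id"):
        traces.append(RawTrace(int(tid), grp["frame"].to_numpy(),
                               grp["intensity"].to_numpy(),
                               grp["missing_flag"].to_numpy(dtype=bool)))
    return traces


# ---------------------------------------------------------------------------
# Linking
# ---------------------------------------------------------------------------

def _mutual_nn_pairs(ends_xy, spots_xy, spot_amp, gate_px):
    """Indices of mutual-nearest-neighbour (end, spot) pairs within gate.

    Ties on distance are broken by higher amplitude, then lexicographic
    spot position, applied symmetrically so the match is order-free.
    """
    if len(ends_xy) == 0 or len(spots_xy) == 0:
        return []
    d = np.hypot(ends_xy[:, 0][:, None] - spots_xy[:, 0][None, :],
                 ends_xy[:, 1][:, None] - spots_xy[:, 1][None, :])
    d = np.where(d < gate_px[:, None], d, np.inf)
    pairs = []
    used_e = np.zeros(len(ends_xy), bool)
    used_s = np.zeros(len(spots_xy), bool)
    # deterministic tie keys for spots: (-amplitude, x, y)
    spot_rank = np.lexsort((spots_xy[:, 1], spots_xy[:, 0], -spot_amp))
    spot_order = np.empty(len(spots_xy), int)
    spot_order[spot_rank] = np.arange(len(spots_xy))
    while True:
        best_spot = np.full(len(ends_xy), -1)
        for i in np.flatnonzero(~used_e):
            cand = np.flatnonzero(~used_s & np.isfinite(d[i]))
            if len(cand):
                key = sorted(cand, key=lambda j: (d[i, j], spot_order[j]))
                best_spot[i] = key[0]
        best_end = np.full(len(spots_xy), -1)
        for j in np.flatnonzero(~used_s):
            cand = np.flatnonzero(~used_e & np.isfinite(d[:, j]))
            if len(cand):
                key = sorted(cand, key=lambda i: (d[i, j], i))
                best_end[j] = key[0]
        linked_any = False
        for i in np.flatnonzero(~used_e):
            j = best_spot[i]
            if j >= 0 and best_end[j] == i:
                pairs.append((i, j))
                used_e[i] = used_s[j] = True
                linked_any = True
        if not linked_any:
            return pairs


def link_spots(spots: pd.DataFrame, max_disp_nm: float = 500.0,
               max_gap: int = 3, pixel_size_nm: float = 160.0,
               classify: bool = True, motion_window: int = 3):
    """Link a per-frame spots table into tracks.

    Parameters
    ----------
    spots
        DataFrame with columns frame, x_px, y_px and optionally
        amplitude, sigma_nm.
    max_disp_nm
        Strict upper bound on the end-to-end displacement of any link,
        including links bridging up to ``max_gap`` frames.
    classify
        When true, each surviving track gets its motion class from
        :func:`classify_motion`.

    Returns
    -------
    list of :class:`Track`.  Singletons (one observation) are discarded;
    every input spot belongs to exactly one track or one discarded
    singleton.
    """
    if max_disp_nm <= 0:
        raise ValidationError(f"max_disp_nm: must be > 0, got {max_disp_nm}")
    if max_gap < 1:
        raise ValidationError(f"max_gap: must be >= 1, got {max_gap}")
    if len(spots) == 0:
        return []
    spots = spots.sort_values(["frame", "x_px", "y_px"]).reset_index(drop=True)
    has_amp = "amplitude" in spots.columns
    has_sigma = "sigma_nm" in spots.columns
    gate_px = max_disp_nm / pixel_size_nm

    open_tracks: list[dict] = []   # obs: list of (frame, x, y, sigma)
    done: list[dict] = []
    for f, grp in spots.groupby("frame", sort=True):
        f = int(f)
        still_open = []
        for tr in open_tracks:
            (done if f - tr["obs"][-1][0] > max_gap else still_open).append(tr)
        open_tracks = still_open
        xy = grp[["x_px", "y_px"]].to_numpy(float)
        amp = grp["amplitude"].to_numpy(float) if has_amp \
            else np.zeros(len(grp))
        sig = grp["sigma_nm"].to_numpy(float) if has_sigma \
            else np.full(len(grp), np.nan)
        ends = np.array([[tr["obs"][-1][1], tr["obs"][-1][2]]
                         for tr in open_tracks]).reshape(-1, 2)
        gates = np.full(len(open_tracks), gate_px)
        pairs = _mutual_nn_pairs(ends, xy, amp, gates)
        matched_spots = set()
        for i, j in pairs:
            open_tracks[i]["obs"].append((f, xy[j, 0], xy[j, 1], sig[j]))
            matched_spots.add(j)
        for j in range(len(grp)):
            if j not in matched_spots:
                open_tracks.append({"obs": [(f, xy[j, 0], xy[j, 1], sig[j])]})
    done.extend(open_tracks)

    tracks = []
    multi = [tr for tr in done if len(tr["obs"]) >= 2]
    multi.sort(key=lambda tr: (tr["obs"][0][0], tr["obs"][0][1], tr["obs"][0][2]))
    for tid, tr in enumerate(multi):
        obs = np.array([(o[0], o[1], o[2]) for o in tr["obs"]])
        sigs = np.array([o[3] for o in tr["obs"]])
        t = Track(tid, obs[:, 0], obs[:, 1], obs[:, 2])
        if has_sigma and np.any(np.isfinite(sigs)):
            t.median_sigma_nm = float(np.nanmedian(sigs))
        tracks.append(t)
    if classify:
        for t in tracks:
            t.motion_class = classify_motion(
                t, max_disp_nm=max_disp_nm, window=motion_window,
                pixel_size_nm=pixel_size_nm)
    log_stage("link_spots", spots=len(spots), tracks=len(tracks),
              singletons=len(done) - len(multi))
    return tracks


def classify_motion(track: Track, max_disp_nm: float = 500.0, window: int = 3,
                    pixel_size_nm: float = 160.0) -> str:
    """Stationary iff every displacement within ``window`` frames is < max_disp_nm.

    The bound is strict: a net displacement of exactly ``max_disp_nm``
    within the window classifies the object as trafficking.  Tracks
    spanning fewer frames than ``window`` are classified on the
    available span and flagged via ``track.flagged_short``.
    """
    if track.span <= window:
        track.flagged_short = True
    n = track.n_observations
    for i in range(n):
        for j in range(i + 1, n):
            dt = track.frames[j] - track.frames[i]
            if dt > window:
                break
            disp_nm = np.hypot(track.x_px[j] - track.x_px[i],
                               track.y_px[j] - track.y_px[i]) * pixel_size_nm
            if disp_nm >= max_disp_nm:
                return TRAFFICKING
    return STATIONARY


def filter_tracks(tracks, latest_start_frame: int = 3,
                  min_length_frames: int = 0):
    """Select analysable bouton tracks.

    Keeps tracks that are stationary, start no later than
    ``latest_start_frame`` and span at least ``min_length_frames``.
    """
    if latest_start_frame < 0 or min_length_frames < 0:
        raise ValidationError("filter_tracks: thresholds must be >= 0")
    kept = [t for t in tracks
            if t.motion_class == STATIONARY
            and t.start_frame <= latest_start_frame
            and t.span >= min_length_frames]
    log_stage("filter_tracks", before=len(tracks), after=len(kept))
    return kept


# ---------------------------------------------------------------------------
# Intensity measurement
# ---------------------------------------------------------------------------

def measure_intensity(movie: Movie, track: Track, radius_px: float | None = None,
                      annulus: tuple | None = None) -> RawTrace:
    """Disk-mean minus annulus-median intensity along a track.

    Per frame of the track span (gap positions linearly interpolated),
    the value is the mean intensity within ``radius_px`` of the position
    minus the median of the background annulus ``(r_in, r_out]``.  Frames
    where the disk leaves the image are flagged missing (NaN), never an
    exception.

    Defaults: radius = 2 x the track's median detected sigma in pixels
    (minimum 2 px); annulus = (radius + 2, radius + 5).
    """
    if radius_px is None:
        if track.median_sigma_nm is not None:
            radius_px = max(2.0, 2.0 * track.median_sigma_nm / movie.pixel_size_nm)
        else:
            radius_px = 3.0
    if annulus is None:
        annulus = (radius_px + 2.0, radius_px + 5.0)
    r_in, r_out = annulus
    if radius_px < 1.0:
        raise ValidationError(f"radius_px: must be >= 1, got {radius_px}")
    if not radius_px < r_in < r_out:
        raise ValidationError(
            f"annulus: need radius < r_in < r_out, got radius={radius_px}, "
            f"annulus={annulus}")

    frames, xs, ys = track.interpolated_positions()
    h, w = movie.frames.shape[1:]
    n = len(frames)
    intensity = np.full(n, np.nan)
    missing = np.zeros(n, bool)
    rr = int(np.ceil(r_out))
    for k in range(n):
        x, y = xs[k], ys[k]
        if x - radius_px < -0.5 or x + radius_px > w - 0.5 or \
                y - radius_px < -0.5 or y + radius_px > h - 0.5:
            missing[k] = True
            continue
        x0, x1 = max(0, int(np.floor(x - rr))), min(w, int(np.ceil(x + rr)) + 1)
        y0, y1 = max(0, int(np.floor(y - rr))), min(h, int(np.ceil(y + rr)) + 1)
        patch = movie.frames[int(frames[k]), y0:y1, x0:x1].astype(float)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        dist = np.hypot(xx - x, yy - y)
        # partial-pixel (anti-aliased) disk weights: a hard in/out mask
        # would jump as boundary pixels flip with sub-pixel centre motion
        wts = np.clip(radius_px + 0.5 - dist, 0.0, 1.0)
        ann = (dist > r_in) & (dist <= r_out)
        if wts.sum() == 0 or not ann.any():
            missing[k] = True
            continue
        intensity[k] = float((wts * patch).sum() / wts.sum()) - \
            float(np.median(patch[ann]))
    return RawTrace(track.track_id, frames, intensity, missing,
                    radius_px=float(radius_px), annulus=(float(r_in), float(r_out)))
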