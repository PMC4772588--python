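"""Readers and writers for every artifact file format.

Conventions used throughout the package
---------------------------------------
* Coordinates are 0-based pixel indices; ``(x, y) = (column, row)``.
  Sub-pixel positions are continuous with the pixel centre at integer
  coordinates.
* Frame windows are half-open ``[start, end)``.  The baseline window is
  ``[0, stim_frame)`` and the stimulation window is
  ``[stim_frame, stim_frame + stim_duration_frames)``.
* All tables are UTF-8 CSV with a fixed column order (documented per
  function).  Movies are multi-page TIFF (one page per frame) with a
  flat-YAML sidecar carrying the acquisition metadata.

Readers never mutate files, and every validation error names the
offending field or row.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import ConfigError, FormatError, MetadataError, ValidationError

logger = logging.getLogger("destain")

#: metadata keys stored in a movie's YAML sidecar
MOVIE_META_KEYS = ("pixel_size_nm", "frame_interval_s", "stim_frame",
                   "stim_duration_frames")

TRACK_COLUMNS = ["track_id", "frame", "x_px", "y_px", "motion_class"]
TRACE_COLUMNS = ["track_id", "frame", "intensity", "missing_flag"]
EM_REQUIRED_COLUMNS = ["group", "az_length_nm", "presyn_area_um2",
                       "vesicle_density_per_um2"]


def log_stage(stage: str, **counts) -> None:
    """Emit one structured log line for a pipeline stage."""
    kv = " ".join(f"{k}={v}" for k, v in counts.items())
    logger.info("stage=%s %s", stage, kv)


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------

@dataclass
class Movie:
    """A single-channel time-lapse stack plus its acquisition metadata.

    Parameters
    ----------
    frames
        ``(T, H, W)`` array of non-negative intensities.
    pixel_size_nm
        Physical pixel size in nanometres.
    frame_interval_s
        Time between consecutive frames in seconds.
    stim_frame
        0-based index of the first stimulation frame.
    stim_duration_frames
        Number of frames the stimulation lasts.
    """

    frames: np.ndarray
    pixel_size_nm: float
    frame_interval_s: float
    stim_frame: int
    stim_duration_frames: int

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        self.validate()

    def validate(self) -> None:
        if self.frames.ndim != 3:
            raise ValidationError(
                f"frames: expected a (T, H, W) stack, got ndim={self.frames.ndim}")
        if self.pixel_size_nm is None or not np.isfinite(self.pixel_size_nm) \
                or self.pixel_size_nm <= 0:
            raise ValidationError(
                f"pixel_size_nm: must be a positive number, got {self.pixel_size_nm}")
        if self.frame_interval_s <= 0:
            raise ValidationError(
                f"frame_interval_s: must be positive, got {self.frame_interval_s}")
        if not (0 <= int(self.stim_frame) < self.n_frames):
            raise ValidationError(
                f"stim_frame: must satisfy 0 <= stim_frame < T={self.n_frames}, "
                f"got {self.stim_frame}")
        if self.stim_duration_frames < 0 or \
                self.stim_frame + self.stim_duration_frames > self.n_frames:
            raise ValidationError(
                "stim_duration_frames: stimulation window "
                f"[{self.stim_frame}, {self.stim_frame + self.stim_duration_frames}) "
                f"exceeds T={self.n_frames}")
        if np.issubdtype(self.frames.dtype, np.floating):
            if not np.all(np.isfinite(self.frames)):
                raise ValidationError("frames: non-finite intensity values")
            if np.any(self.frames < 0):
                raise ValidationError("frames: negative intensity values")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self):
        return self.frames.shape

    @property
    def baseline_window(self):
        """Half-open ``(0, stim_frame)``."""
        return (0, int(self.stim_frame))

    @property
    def stim_window(self):
        """Half-open ``(stim_frame, stim_frame + stim_duration_frames)``."""
        s = int(self.stim_frame)
        return (s, s + int(self.stim_duration_frames))

    def with_frames(self, frames: np.ndarray) -> "Movie":
        """Copy of this movie with ``frames`` replaced, metadata unchanged."""
        return Movie(frames, self.pixel_size_nm, self.frame_interval_s,
                     self.stim_frame, self.stim_duration_frames)

    def metadata(self) -> dict:
        return {"pixel_size_nm": float(self.pixel_size_nm),
                "frame_interval_s": float(self.frame_interval_s),
                "stim_frame": int(self.stim_frame),
                "stim_duration_frames": int(self.stim_duration_frames)}


# ---------------------------------------------------------------------------
# Movie I/O
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".yaml")


def write_movie(movie: Movie, path) -> Path:
    """Write a movie as multi-page uint16 TIFF plus a YAML metadata sidecar.

    Floating-point frames are rounded to the nearest integer and clipped
    to the uint16 range (camera counts are integral; the simulator's
    noise model already yields near-integer values).
    Returns the TIFF path; the sidecar sits next to it with ``.yaml``
    extension.
    """
    path = Path(path)
    frames = movie.frames
    if np.issubdtype(frames.dtype, np.floating):
        frames = np.clip(np.rint(frames), 0, np.iinfo(np.uint16).max)
    frames = frames.astype(np.uint16)
    tifffile.imwrite(path, frames, photometric="minisblack")
    with open(_sidecar_path(path), "w", encoding="utf-8") as fh:
        yaml.safe_dump(movie.metadata(), fh, sort_keys=True)
    log_stage("write_movie", path=path.name, frames=movie.n_frames)
    return path


def read_movie(path, metadata: dict | None = None) -> Movie:
    """Read a multi-page TIFF into a :class:`Movie`.

    Page order is preserved as time order and pixel data are promoted
    losslessly to float64.  Metadata comes from the YAML sidecar written
    by :func:`write_movie`; an explicit ``metadata`` dict may supply it
    instead, but must agree with the sidecar when both are present.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        frames = tifffile.imread(path)
    except Exception as exc:  # truncated / corrupt stack
        raise FormatError(f"{path}: cannot read TIFF ({exc})") from exc
    if frames.ndim == 2:
        frames = frames[None]

    sidecar = _sidecar_path(path)
    meta: dict = {}
    if sidecar.exists():
        with open(sidecar, encoding="utf-8") as fh:
            meta = yaml.safe_load(fh) or {}
    if metadata is not None:
        for key, val in metadata.items():
            if key not in MOVIE_META_KEYS:
                raise MetadataError(f"unknown metadata key: {key!r}")
            if key in meta and not np.isclose(float(meta[key]), float(val)):
                raise MetadataError(
                    f"{key}: explicit value {val!r} contradicts sidecar value "
                    f"{meta[key]!r}")
            meta[key] = val
    missing = [k for k in MOVIE_META_KEYS if k not in meta]
    if missing:
        raise MetadataError(
            f"missing metadata key(s) {missing}; supply a sidecar file or "
            "explicit values")
    try:
        pixel_size = float(meta["pixel_size_nm"])
    except (TypeError, ValueError) as exc:
        raise ValidationError(
            f"pixel_size_nm: non-numeric value {meta['pixel_size_nm']!r}") from exc
    movie = Movie(frames.astype(np.float64),
                  pixel_size_nm=pixel_size,
                  frame_interval_s=float(meta["frame_interval_s"]),
                  stim_frame=int(meta["stim_frame"]),
                  stim_duration_frames=int(meta["stim_duration_frames"]))
    log_stage("read_movie", path=path.name, frames=movie.n_frames)
    return movie


# ---------------------------------------------------------------------------
# Track / trace tables
# ---------------------------------------------------------------------------

def write_tracks(tracks, path) -> Path:
    """Write tracks as CSV: track_id, frame, x_px, y_px, motion_class."""
    from .track import tracks_to_table
    path = Path(path)
    tracks_to_table(tracks).to_csv(path, index=False)
    log_stage("write_tracks", path=path.name, tracks=len(tracks))
    return path


def read_tracks(path):
    """Read a track CSV back into a list of :class:`destain.track.Track`.

    Exact inverse of :func:`write_tracks`.  Duplicate ``(track_id, frame)``
    rows are a format error; frame gaps within a track are legal.
    """
    from .track import tracks_from_table
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    dup = df.duplicated(subset=["track_id", "frame"])
    if dup.any():
        rows = df.loc[dup, ["track_id", "frame"]].to_records(index=False).tolist()
        raise FormatError(f"{path}: duplicate (track_id, frame) rows: {rows}")
    tracks = tracks_from_table(df[TRACK_COLUMNS])
    log_stage("read_tracks", path=path.name, tracks=len(tracks))
    return tracks


def write_traces(traces, path) -> Path:
    """Write raw intensity traces as CSV: track_id, frame, intensity, missing_flag."""
    from .track import traces_to_table
    path = Path(path)
    traces_to_table(traces).to_csv(path, index=False)
    log_stage("write_traces", path=path.name, traces=len(traces))
    return path


def read_traces(path):
    """Inverse of :func:`write_traces`; returns a list of RawTrace."""
    from .track import traces_from_table
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    dup = df.duplicated(subset=["track_id", "frame"])
    if dup.any():
        raise FormatError(f"{path}: duplicate (track_id, frame) rows")
    return traces_from_table(df[TRACE_COLUMNS])


# ---------------------------------------------------------------------------
# EM measurement tables
# ---------------------------------------------------------------------------

def validate_em_table(df: pd.DataFrame, density_tol: float = 0.01) -> pd.DataFrame:
    """Validate an EM measurement table in place and return it.

    Checks positivity of all measurements and, when ``vesicle_count`` is
    present, that ``vesicle_density_per_um2 == vesicle_count /
    presyn_area_um2`` to within ``density_tol`` relative tolerance.
    """
    missing = [c for c in EM_REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"EM table: missing column(s) {missing}")
    for col in ["az_length_nm", "presyn_area_um2", "vesicle_density_per_um2"]:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[~np.isfinite(vals) | (vals <= 0)].tolist()
        if bad:
            raise ValidationError(
                f"EM table: column {col!r} non-positive or non-numeric in "
                f"row(s) {bad}")
    if "vesicle_count" in df.columns:
        counts = pd.to_numeric(df["vesicle_count"], errors="coerce")
        bad = df.index[~np.isfinite(counts) | (counts <= 0)].tolist()
        if bad:
            raise ValidationError(
                f"EM table: column 'vesicle_count' non-positive in row(s) {bad}")
        recomputed = counts / df["presyn_area_um2"]
        rel = np.abs(recomputed - df["vesicle_density_per_um2"]) \
            / df["vesicle_density_per_um2"]
        bad = df.index[rel > density_tol].tolist()
        if bad:
            raise ValidationError(
                "EM table: vesicle_density_per_um2 inconsistent with "
                f"vesicle_count/presyn_area_um2 (> {density_tol:.0%}) in "
                f"row(s) {bad}")
    return df


def read_em_table(path) -> pd.DataFrame:
    """Read and validate an EM measurement CSV.

    Required columns: group, az_length_nm, presyn_area_um2,
    vesicle_density_per_um2; optional: synapse_id, vesicle_count.
    """
    df = pd.read_csv(path)
    validate_em_table(df)
    log_stage("read_em_table", path=Path(path).name, records=len(df))
    return df


def write_em_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    validate_em_table(df)
    cols = [c for c in ["synapse_id", "group", "az_length_nm", "presyn_area_um2",
                        "vesicle_count", "vesicle_density_per_um2"]
            if c in df.columns]
    df[cols].to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# Flat key/value config files
# ---------------------------------------------------------------------------

def read_config(path, schema):
    """Read a flat YAML mapping into dataclass ``schema``.

    Unknown keys are configuration errors (catches typos); missing keys
    fall back to the dataclass defaults.
    """
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a flat key/value mapping")
    allowed = {f.name for f in dc_fields(schema)}
    unknown = sorted(set(data) - allowed)
    if unknown:
        raise ConfigError(f"{path}: unknown configuration key(s) {unknown}")
    return schema(**data)


def write_config(config, path) -> Path:
    """Write a dataclass config as a flat YAML mapping."""
    path = Path(path)
    data = {}
    for f in dc_fields(config):
        val = getattr(config, f.name)
        if isinstance(val, tuple):
            val = list(val)
        data[f.name] = val
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
    return path
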