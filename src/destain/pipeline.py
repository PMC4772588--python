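"""End-to-end glue: movie -> spots -> tracks -> traces -> classification.

This is the thin orchestration layer behind the CLI and the acceptance
script; every step is an ordinary call into the library modules so the
pipeline stays scriptable piecewise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import detect as _detect
from . import kinetics as _kinetics
from . import track as _track
from .io import Movie, log_stage, write_tracks, write_traces


@dataclass
class PipelineResult:
    drift: np.ndarray
    spots: pd.DataFrame
    tracks: list
    kept_tracks: list
    raw_traces: list
    traces: list                       # BoutonTraces surviving normalization
    classification: object
    features: dict

    def classification_table(self) -> pd.DataFrame:
        rows = []
        for tid, label in sorted(self.classification.labels.items()):
            f = self.features.get(tid)
            rows.append((tid, label,
                         f.depth if f else np.nan,
                         f.slope_drop if f else np.nan,
                         f.baseline_cv if f else np.nan))
        return pd.DataFrame(rows, columns=["track_id", "label", "depth",
                                           "slope_drop", "baseline_cv"])

    def summary_tables(self):
        return _kinetics.summarize_profiles(self.classification, self.traces)

    def write(self, outdir) -> None:
        """Write tracks/traces/classification/summary CSVs into ``outdir``."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_tracks(self.kept_tracks, outdir / "tracks.csv")
        write_traces(self.raw_traces, outdir / "traces.csv")
        self.classification_table().to_csv(
            outdir / "classification.csv", index=False)
        summary, mean_ri = self.summary_tables()
        summary.to_csv(outdir / "class_summary.csv", index=False)
        mean_ri.to_csv(outdir / "class_mean_ri.csv", index=False)
        pd.DataFrame(self.drift, columns=["dx_px", "dy_px"]).to_csv(
            outdir / "drift.csv", index_label="frame")


def run_unloading_pipeline(movie: Movie, *,
                           correct_drift: bool = True,
                           sigma_range_nm: tuple = (300.0, 800.0),
                           threshold_mad: float = 5.0,
                           max_disp_nm: float = 500.0,
                           max_gap: int = 3,
                           latest_start_frame: int = 3,
                           min_length_fraction: float = 0.9,
                           cv_max: float = 0.5,
                           baseline_slope_max: float = 0.1,
                           responder_threshold: float = 0.05,
                           responder_gate: bool = True) -> PipelineResult:
    """Run the full unloading analysis on one movie.

    Track selection keeps stationary tracks starting by
    ``latest_start_frame`` and spanning at least ``min_length_fraction``
    of the movie.  Returns every intermediate product for inspection.
    """
    if correct_drift:
        drift = _detect.estimate_drift(movie)
        work = _detect.apply_drift_correction(movie, drift)
    else:
        drift = np.zeros((movie.n_frames, 2))
        work = movie
    spots = _detect.detect_movie(work, sigma_range_nm=sigma_range_nm,
                                 threshold_mad=threshold_mad)
    tracks = _track.link_spots(spots, max_disp_nm=max_disp_nm,
                               max_gap=max_gap,
                               pixel_size_nm=movie.pixel_size_nm)
    kept = _track.filter_tracks(
        tracks, latest_start_frame=latest_start_frame,
        min_length_frames=int(np.ceil(min_length_fraction * movie.n_frames)))
    # measure on the ORIGINAL frames at drift-adjusted positions: resampling
    # the corrected movie would modulate peak intensities with the
    # fractional part of the shift and inflate baseline variability
    raw_traces = []
    for t in kept:
        adj = _track.Track(t.track_id, t.frames,
                           t.x_px + drift[t.frames, 0],
                           t.y_px + drift[t.frames, 1],
                           motion_class=t.motion_class)
        adj.median_sigma_nm = t.median_sigma_nm
        raw_traces.append(_track.measure_intensity(movie, adj))
    traces = []
    for rt in raw_traces:
        try:
            traces.append(_kinetics.normalize_trace(
                rt, movie.stim_frame, movie.stim_duration_frames))
        except Exception:
            continue
    classification, features = _kinetics.classify_traces(
        traces, cv_max=cv_max, baseline_slope_max=baseline_slope_max,
        responder_threshold=responder_threshold,
        responder_gate=responder_gate)
    log_stage("pipeline", tracks=len(tracks), kept=len(kept),
              traces=len(traces))
    return PipelineResult(drift, spots, tracks, kept, raw_traces, traces,
                          classification, features)
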