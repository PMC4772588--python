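"""Baseline normalization, QC, unloading features and profile clustering.

A raw bouton trace is converted to relative intensity (RI) by dividing
by its mean over the baseline window, so the baseline mean of every
valid trace is exactly 1.  Three threshold criteria gate the analysis:

1. response: the post-stimulation slope must drop relative to baseline
   by at least ``responder_threshold`` when projected over the whole
   stimulation window (``slope_drop``);
2. variability: the baseline coefficient of variation (stdev/mean) must
   be below ``cv_max`` (default 0.5);
3. baseline stability: the fitted baseline slope, accumulated over the
   baseline window, must not exceed ``baseline_slope_max`` RI.

QC-passing responders are hierarchically clustered (Ward linkage,
Euclidean distance) on their plateau depth into two sub-populations; the
cluster with the larger mean depth is labelled ``strong``, the other
``weak``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .errors import DegenerateInputError, ValidationError
from .io import log_stage
from .track import RawTrace

LABEL_WEAK = "weak"
LABEL_STRONG = "strong"
LABEL_EXCLUDED = "excluded_qc"
LABEL_NON_RESPONDER = "non_responder"


@dataclass
class BoutonTrace:
    """Baseline-normalized relative-intensity time series for one bouton."""

    track_id: int
    frames: np.ndarray
    ri: np.ndarray
    stim_frame: int
    stim_duration: int

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=int)
        self.ri = np.asarray(self.ri, dtype=float)
        if not np.all(np.isfinite(self.ri)):
            raise ValidationError(
                f"trace {self.track_id}: non-finite RI values")

    def baseline_mask(self) -> np.ndarray:
        return self.frames < self.stim_frame

    def stim_mask(self) -> np.ndarray:
        return (self.frames >= self.stim_frame) & \
            (self.frames < self.stim_frame + self.stim_duration)


@dataclass
class UnloadingFeatures:
    """Scalar summaries of one trace's destaining kinetics."""

    track_id: int
    baseline_slope: float       # RI per frame over the baseline window
    post_slope: float           # RI per frame over the early stimulation window
    slope_drop: float           # (baseline - post) slope x stim duration
    baseline_cv: float          # stdev/mean of baseline RI
    depth: float                # 1 - mean RI over the plateau window
    responder: bool = True


@dataclass
class QCResult:
    track_id: int
    passed: bool
    reasons: list = field(default_factory=list)


@dataclass
class UnloadingClassification:
    """Per-trace labels plus cluster summaries."""

    labels: dict                 # track_id -> label
    class_counts: dict           # label -> n
    class_mean_depth: dict       # weak/strong -> mean plateau depth
    linkage: np.ndarray | None   # scipy linkage matrix of the clustered traces
    degenerate: bool = False


# ---------------------------------------------------------------------------
# Normalization and QC
# ---------------------------------------------------------------------------

def normalize_trace(raw: RawTrace, stim_frame: int, stim_duration: int,
                    min_baseline_points: int = 5) -> BoutonTrace:
    """Divide a raw trace by its mean over the baseline window.

    Missing frames are dropped.  Rejects traces with fewer than
    ``min_baseline_points`` baseline values or a non-positive baseline
    mean.
    """
    ok = ~raw.missing & np.isfinite(raw.intensity)
    frames = raw.frames[ok]
    vals = raw.intensity[ok]
    base = vals[frames < stim_frame]
    if len(base) < min_baseline_points:
        raise ValidationError(
            f"trace {raw.track_id}: only {len(base)} baseline values "
            f"(need >= {min_baseline_points})")
    mean = base.mean()
    if mean <= 0:
        raise ValidationError(
            f"trace {raw.track_id}: baseline mean {mean:.3g} <= 0")
    return BoutonTrace(raw.track_id, frames, vals / mean,
                       stim_frame=int(stim_frame),
                       stim_duration=int(stim_duration))


def _ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    if len(x) < 2:
        return 0.0
    return float(np.polyfit(x.astype(float), y, 1)[0])


def qc_trace(trace: BoutonTrace, cv_max: float = 0.5,
             baseline_slope_max: float = 0.1) -> QCResult:
    """Apply the variability and baseline-stability criteria.

    ``baseline_slope_max`` is expressed in RI accumulated over the whole
    baseline window (default 0.1).
    """
    reasons = []
    base = trace.ri[trace.baseline_mask()]
    bframes = trace.frames[trace.baseline_mask()]
    cv = float(base.std() / base.mean()) if base.mean() != 0 else np.inf
    if cv >= cv_max:
        reasons.append(f"baseline_cv {cv:.3f} >= {cv_max}")
    slope = _ols_slope(bframes, base)
    accumulated = abs(slope) * trace.stim_frame
    if accumulated > baseline_slope_max:
        reasons.append(
            f"baseline slope {accumulated:.3f} RI/baseline-window > "
            f"{baseline_slope_max}")
    return QCResult(trace.track_id, passed=not reasons, reasons=reasons)


# ---------------------------------------------------------------------------
# Features and clustering
# ---------------------------------------------------------------------------

def compute_unloading_features(trace: BoutonTrace,
                               post_window_fraction: float = 0.5,
                               plateau_fraction: float = 0.25,
                               responder_threshold: float = 0.05
                               ) -> UnloadingFeatures:
    """Slopes, slope drop and plateau depth of one trace.

    ``post_slope`` is fitted over the first ``post_window_fraction`` of
    the stimulation window ("decrease of signal immediately after
    stimulation"); ``slope_drop`` projects the slope change over the
    whole window; ``depth`` is 1 minus the mean RI over the final
    ``plateau_fraction`` of the stimulation window.
    """
    s, dur = trace.stim_frame, trace.stim_duration
    if dur < 5:
        raise ValidationError(
            f"trace {trace.track_id}: stimulation window of {dur} frames "
            "is too short (need >= 5)")
    base_m = trace.baseline_mask()
    baseline_slope = _ols_slope(trace.frames[base_m], trace.ri[base_m])
    post_end = s + max(5, int(round(dur * post_window_fraction)))
    post_m = (trace.frames >= s) & (trace.frames < post_end)
    post_slope = _ols_slope(trace.frames[post_m], trace.ri[post_m])
    slope_drop = (baseline_slope - post_slope) * dur
    plat_start = s + int(round(dur * (1.0 - plateau_fraction)))
    plat_m = (trace.frames >= plat_start) & (trace.frames < s + dur)
    if not plat_m.any():
        raise ValidationError(
            f"trace {trace.track_id}: no values in the plateau window")
    depth = float(1.0 - trace.ri[plat_m].mean())
    base = trace.ri[base_m]
    cv = float(base.std() / base.mean()) if len(base) and base.mean() != 0 else np.inf
    return UnloadingFeatures(trace.track_id,
                             baseline_slope=baseline_slope,
                             post_slope=post_slope,
                             slope_drop=float(slope_drop),
                             baseline_cv=cv,
                             depth=depth,
                             responder=slope_drop >= responder_threshold)


def cluster_profiles(features, k: int = 2,
                     feature: str = "depth") -> UnloadingClassification:
    """Ward/Euclidean hierarchical clustering of unloading features.

    ``features`` is a sequence of :class:`UnloadingFeatures` (QC-passing
    responders).  The tree is cut at ``k`` clusters; with k=2 the
    cluster with the larger mean depth is labelled strong.  If all
    feature values are identical the result is a single class with a
    degenerate-clustering warning.
    """
    features = list(features)
    if len(features) < 2:
        raise DegenerateInputError(
            f"cluster_profiles: need >= 2 traces, got {len(features)}")
    vals = np.array([getattr(f, feature) for f in features], dtype=float)
    ids = [f.track_id for f in features]
    depths = np.array([f.depth for f in features])

    if np.ptp(vals) == 0:
        warnings.warn("cluster_profiles: all features identical; "
                      "returning a single class", stacklevel=2)
        labels = {tid: LABEL_STRONG for tid in ids}
        return UnloadingClassification(
            labels, {LABEL_STRONG: len(ids)},
            {LABEL_STRONG: float(depths.mean())}, linkage=None, degenerate=True)

    Z = hierarchy.linkage(vals[:, None], method="ward")
    assign = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    # order clusters by mean depth: largest mean depth -> "strong"
    cluster_ids = np.unique(assign)
    mean_depth = {c: depths[assign == c].mean() for c in cluster_ids}
    ordered = sorted(cluster_ids, key=lambda c: -mean_depth[c])
    if k == 2 and len(ordered) == 2:
        name = {ordered[0]: LABEL_STRONG, ordered[1]: LABEL_WEAK}
    else:
        name = {c: (LABEL_STRONG if i == 0 else f"cluster_{i + 1}")
                for i, c in enumerate(ordered)}
    labels = {tid: name[c] for tid, c in zip(ids, assign)}
    counts = {name[c]: int((assign == c).sum()) for c in cluster_ids}
    class_depth = {name[c]: float(mean_depth[c]) for c in cluster_ids}
    return UnloadingClassification(labels, counts, class_depth, linkage=Z)


def classify_traces(traces, cv_max: float = 0.5, baseline_slope_max: float = 0.1,
                    responder_threshold: float = 0.05,
                    post_window_fraction: float = 0.5,
                    plateau_fraction: float = 0.25,
                    responder_gate: bool = True):
    """Full QC -> feature -> clustering pass over a set of BoutonTraces.

    Returns ``(classification, features_by_id)``.  Traces failing QC are
    labelled ``excluded_qc``; QC-passing non-responders
    ``non_responder`` (when ``responder_gate`` is set); the rest get
    weak/strong labels from :func:`cluster_profiles`.
    """
    labels = {}
    feats = {}
    clusterable = []
    for tr in traces:
        qc = qc_trace(tr, cv_max=cv_max, baseline_slope_max=baseline_slope_max)
        if not qc.passed:
            labels[tr.track_id] = LABEL_EXCLUDED
            continue
        try:
            f = compute_unloading_features(
                tr, post_window_fraction=post_window_fraction,
                plateau_fraction=plateau_fraction,
                responder_threshold=responder_threshold)
        except ValidationError:
            # e.g. a track ending before the plateau window is reached
            labels[tr.track_id] = LABEL_EXCLUDED
            continue
        feats[tr.track_id] = f
        if responder_gate and not f.responder:
            labels[tr.track_id] = LABEL_NON_RESPONDER
            continue
        clusterable.append(f)
    if len(clusterable) >= 2:
        clustering = cluster_profiles(clusterable)
        labels.update(clustering.labels)
        counts = dict(clustering.class_counts)
        class_depth = dict(clustering.class_mean_depth)
        linkage = clustering.linkage
        degenerate = clustering.degenerate
    else:
        for f in clusterable:
            labels[f.track_id] = LABEL_STRONG
        counts, class_depth, linkage, degenerate = {}, {}, None, len(clusterable) > 0
    for lab in (LABEL_EXCLUDED, LABEL_NON_RESPONDER):
        n = sum(1 for v in labels.values() if v == lab)
        if n:
            counts[lab] = n
    log_stage("classify_traces", traces=len(list(labels)),
              **{k: v for k, v in counts.items()})
    return UnloadingClassification(labels, counts, class_depth, linkage,
                                   degenerate), feats


def summarize_profiles(classification: UnloadingClassification, traces):
    """Per-class summary and per-class mean RI time course.

    Returns ``(summary, mean_ri)``: ``summary`` has one row per class
    with n, mean depth and mean post-stimulation slope; ``mean_ri`` is a
    tidy frame (label, frame, mean_ri, n) averaging RI across the traces
    of each class at each frame.
    """
    by_id = {tr.track_id: tr for tr in traces}
    rows = []
    ri_rows = []
    for lab in sorted(set(classification.labels.values())):
        ids = [tid for tid, l in classification.labels.items() if l == lab]
        members = [by_id[tid] for tid in ids if tid in by_id]
        if not members:
            continue
        depths, slopes = [], []
        for tr in members:
            try:
                f = compute_unloading_features(tr)
            except ValidationError:
                continue
            depths.append(f.depth)
            slopes.append(f.post_slope)
        rows.append((lab, len(members),
                     float(np.mean(depths)) if depths else np.nan,
                     float(np.mean(slopes)) if slopes else np.nan))
        frames = np.unique(np.concatenate([tr.frames for tr in members]))
        for f in frames:
            vals = [tr.ri[tr.frames == f][0] for tr in members
                    if np.any(tr.frames == f)]
            ri_rows.append((lab, int(f), float(np.mean(vals)), len(vals)))
    summary = pd.DataFrame(rows, columns=["label", "n", "mean_depth",
                                          "mean_post_slope"])
    mean_ri = pd.DataFrame(ri_rows, columns=["label", "frame", "mean_ri", "n"])
    return summary, mean_ri
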